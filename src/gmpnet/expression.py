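"""Differential-expression summaries, ranked lists, and ddCt fold changes.

The pipeline consumes DE summary tables (gene, log2 fold change, FDR) from
upstream tools or the synthetic generator; no count model is fitted here.
Significant DEGs use an inclusive symmetric threshold (|log2FC| >= cut and
FDR <= cut).  The ranked list L orders all genes by a differential-
expression score, descending, and feeds the gene-module-pair statistic.
qPCR Ct tables are reduced to fold changes via the 2^(-ddCt) method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DGERecord",
    "RankedList",
    "CtTable",
    "load_dge_table",
    "write_dge_table",
    "filter_degs",
    "build_ranked_list",
    "write_rnk",
    "read_rnk",
    "load_ct_table",
    "ddct_fold_change",
]

FDR_FLOOR = 1e-300  # avoids infinite -log10(FDR) scores


@dataclass(frozen=True)
class DGERecord:
    gene: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.gene}: FDR {self.fdr} outside [0, 1]")


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a non-increasing differential-expression score."""

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores are not non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def position_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def load_dge_table(path: str | Path) -> list[DGERecord]:
    """Read a DE summary TSV with columns gene, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, encoding="utf-8")
    missing = [c for c in ("gene", "log2fc", "fdr") if c not in df.columns]
    if missing:
        raise ValueError(f"DGE table missing columns: {missing}")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in DGE table: {dupes[:5]}")
    return [
        DGERecord(gene=r.gene, log2fc=float(r.log2fc), fdr=float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def write_dge_table(records: Sequence[DGERecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": r.gene, "log2fc": r.log2fc, "fdr": r.fdr} for r in records]
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")


def filter_degs(
    records: Sequence[DGERecord], lfc_min: float = 1.0, fdr_max: float = 0.05
) -> tuple[list[DGERecord], list[DGERecord]]:
    """Split significant DEGs into (up, down) lists, both thresholds inclusive.

    up: log2fc >= lfc_min and fdr <= fdr_max;
    down: log2fc <= -lfc_min and fdr <= fdr_max.
    """
    if lfc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    up = [r for r in records if r.log2fc >= lfc_min and r.fdr <= fdr_max]
    down = [r for r in records if r.log2fc <= -lfc_min and r.fdr <= fdr_max]
    return up, down


def build_ranked_list(
    records: Sequence[DGERecord], metric: Literal["lfc", "signed_logp"] = "lfc"
) -> RankedList:
    """Order all genes into the ranked list L, best score first.

    ``lfc`` ranks by log2 fold change; ``signed_logp`` by
    sign(log2fc) * -log10(max(fdr, floor)).  Score ties are broken
    lexicographically by gene symbol so the order is reproducible.
    """
    if not records:
        raise ValueError("cannot rank an empty DGE table")
    if metric == "lfc":
        scored = [(r.gene, r.log2fc) for r in records]
    elif metric == "signed_logp":
        scored = [
            (r.gene, np.sign(r.log2fc) * -np.log10(max(r.fdr, FDR_FLOOR)))
            for r in records
        ]
    else:
        raise ValueError(f"unknown ranking metric: {metric!r}")
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    return RankedList(
        genes=tuple(g for g, _ in scored), scores=tuple(s for _, s in scored)
    )


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    """Write a two-column RNK-style TSV (gene, score)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g, s in zip(ranked.genes, ranked.scores):
            fh.write(f"{g}\t{s:.10g}\n")


def read_rnk(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], dtype={0: str})
    return RankedList(genes=tuple(df["gene"]), scores=tuple(df["score"].astype(float)))


@dataclass
class CtTable:
    """Mean qPCR threshold cycles per (group, gene), with a reference gene."""

    ct: dict[tuple[str, str], float]  # (group, gene) -> mean Ct
    reference_gene: str

    def __post_init__(self) -> None:
        groups = {g for g, _ in self.ct}
        for grp in groups:
            if (grp, self.reference_gene) not in self.ct:
                raise ValueError(f"reference gene missing from group {grp!r}")
        for key, val in self.ct.items():
            if val <= 0:
                raise ValueError(f"non-positive Ct for {key}")


def load_ct_table(path: str | Path, reference_gene: str) -> CtTable:
    """Read a Ct TSV with columns group, gene, mean_ct."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "gene": str})
    missing = [c for c in ("group", "gene", "mean_ct") if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = {
        (r.group, r.gene): float(r.mean_ct) for r in df.itertuples(index=False)
    }
    return CtTable(ct=ct, reference_gene=reference_gene)


def ddct_fold_change(
    ct: CtTable, target_gene: str, treated_group: str, control_group: str
) -> float:
    """Relative expression fold change by the 2^(-ddCt) method.

    ddCt = (Ct_target - Ct_ref) in the treated group minus the same
    difference in the control group; fold change = 2**(-ddCt).  A fold of 1
    means no change relative to the internal control.
    """
    try:
        d_treated = ct.ct[(treated_group, target_gene)] - ct.ct[
            (treated_group, ct.reference_gene)
        ]
        d_control = ct.ct[(control_group, target_gene)] - ct.ct[
            (control_group, ct.reference_gene)
        ]
    except KeyError as exc:
        raise KeyError(f"missing Ct entry for {exc.args[0]}") from None
    return float(2.0 ** -(d_treated - d_control))
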