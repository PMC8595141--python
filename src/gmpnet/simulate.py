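"""Synthetic inputs for every pipeline stage, with truth sidecars.

The study databases (component/target exports, disease gene lists) and the
raw RNA-seq behind the DE summaries are not redistributable, so every
input the pipeline consumes can be generated here with stated
distributions:

* component tables whose OB/DL marginals pass the screening thresholds at
  configurable rates (or at exact planted counts),
* gene-module-pair catalogs of disjoint k-gene up/down modules,
* DE profiles with a Gaussian log2FC baseline and an additive effect
  planted into chosen targets' modules (a stylized stand-in for a count
  model, not an RNA-seq simulator),
* qPCR Ct grids with known implied fold changes.

Every generator is a pure function of its configuration: the same seed
yields byte-identical output.  Each generator draws from its own stream
derived from (seed, generator name), so adding one generator never
perturbs another.  Alongside every dataset a "truth" dict records what was
planted, enabling closed-loop testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gmpti import GeneModulePair, bh_adjust

__all__ = [
    "SimulationConfig",
    "gen_component_table",
    "gen_gmp_catalog",
    "gen_de_profile",
    "gen_ct_table",
    "write_with_truth",
]

_HERBS = [f"HERB{i:02d}" for i in range(1, 21)]  # twenty-herb formula


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the analysed study's scale where it is stated
    (1610 candidate components with 51.0% passing OB >= 30 and 41.2%
    passing DL >= 0.18) and a desk-scale transcriptome otherwise.
    ``effect_size`` is in log2FC units and ``noise_sd`` is the standard
    deviation of the null log2FC distribution; the default plants a
    two-sigma shift.
    """

    seed: int = 0
    n_genes: int = 2000
    n_components: int = 1610
    n_targets: int = 50
    module_size: int = 10  # k genes per up/down module
    effect_size: float = 2.0  # delta, log2FC units
    noise_sd: float = 1.0  # sigma of baseline log2FC
    frac_ob_pass: float = 0.510
    frac_dl_pass: float = 0.412
    planted_targets: list[str] = field(default_factory=list)
    ob_threshold: float = 30.0
    dl_threshold: float = 0.18

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_components, self.n_targets, self.module_size) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.frac_ob_pass <= 1 and 0 <= self.frac_dl_pass <= 1):
            raise ValueError("pass fractions must lie in [0, 1]")
        if 2 * self.module_size > self.n_genes:
            raise ValueError("2k must not exceed n_genes")

    def gene_universe(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def _stream(cfg: SimulationConfig, name: str) -> np.random.Generator:
    code = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, code]))


def gen_component_table(
    cfg: SimulationConfig, exact_counts: tuple[int, int, int] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Synthetic component table with controlled OB/DL screening marginals.

    By default each component independently passes the OB threshold with
    probability ``frac_ob_pass`` (OB drawn uniformly above the threshold on
    a pass, below it otherwise) and analogously for DL, so the expected
    joint pass count is n x f_ob x f_dl.  ``exact_counts = (n_ob, n_dl,
    n_joint)`` instead plants exactly those marginal and joint counts,
    emulating a table whose realized screening counts are known.
    """
    rng = _stream(cfg, "components")
    n = cfg.n_components
    if exact_counts is None:
        ob_pass = rng.random(n) < cfg.frac_ob_pass
        dl_pass = rng.random(n) < cfg.frac_dl_pass
    else:
        n_ob, n_dl, n_joint = exact_counts
        if not (0 <= n_joint <= min(n_ob, n_dl) and max(n_ob, n_dl) <= n):
            raise ValueError(f"inconsistent exact counts: {exact_counts}")
        if n_ob + n_dl - n_joint > n:
            raise ValueError("exact counts exceed table size")
        ob_pass = np.zeros(n, dtype=bool)
        dl_pass = np.zeros(n, dtype=bool)
        ob_pass[:n_ob] = True  # joint block first, then OB-only, then DL-only
        dl_pass[:n_joint] = True
        dl_pass[n_ob : n_ob + (n_dl - n_joint)] = True
        perm = rng.permutation(n)
        ob_pass, dl_pass = ob_pass[perm], dl_pass[perm]
    ob = np.where(
        ob_pass,
        rng.uniform(cfg.ob_threshold, 100.0, n),
        rng.uniform(0.0, cfg.ob_threshold, n),
    )
    dl = np.where(
        dl_pass,
        rng.uniform(cfg.dl_threshold, 1.0, n),
        rng.uniform(0.0, cfg.dl_threshold, n),
    )
    genes = cfg.gene_universe()
    rows = []
    for i in range(n):
        n_herbs = int(rng.integers(1, 4))
        herbs = rng.choice(_HERBS, size=n_herbs, replace=False)
        n_tgt = int(rng.integers(0, 9))
        targets = rng.choice(genes, size=n_tgt, replace=False)
        rows.append(
            {
                "component_id": f"MOL{i + 1:05d}",
                "name": f"component-{i + 1}",
                "herb_ids": ";".join(sorted(herbs)),
                "ob": round(float(ob[i]), 4),
                "dl": round(float(dl[i]), 4),
                "targets": ";".join(sorted(targets)),
            }
        )
    df = pd.DataFrame(rows)
    truth = {
        "n_components": n,
        "n_ob_pass": int(ob_pass.sum()),
        "n_dl_pass": int(dl_pass.sum()),
        "n_joint_pass": int((ob_pass & dl_pass).sum()),
        "ob_threshold": cfg.ob_threshold,
        "dl_threshold": cfg.dl_threshold,
    }
    return df, truth


def gen_gmp_catalog(cfg: SimulationConfig) -> tuple[list[GeneModulePair], dict]:
    """Catalog of ``n_targets`` GMPs with disjoint k-gene up/down modules."""
    rng = _stream(cfg, "gmps")
    genes = np.array(cfg.gene_universe())
    k = cfg.module_size
    catalog = []
    for i in range(cfg.n_targets):
        idx = rng.choice(cfg.n_genes, size=2 * k, replace=False)
        catalog.append(
            GeneModulePair(
                target_id=f"T{i + 1:04d}",
                up_genes=frozenset(genes[idx[:k]]),
                down_genes=frozenset(genes[idx[k:]]),
            )
        )
    truth = {"n_targets": cfg.n_targets, "module_size": k}
    return catalog, truth


def gen_de_profile(
    cfg: SimulationConfig,
    catalog: Sequence[GeneModulePair],
    planted_targets: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """DE summary table with target signatures planted into a Gaussian baseline.

    Baseline log2FC ~ Normal(0, noise_sd) per gene; genes in a planted
    target's up module receive +effect_size, its down module -effect_size.
    FDR values are BH-adjusted two-sided normal p-values of the implied
    z-scores — a stylized stand-in for a count-model fit.
    """
    planted = list(planted_targets if planted_targets is not None else cfg.planted_targets)
    by_id = {g.target_id: g for g in catalog}
    unknown = [t for t in planted if t not in by_id]
    if unknown:
        raise ValueError(f"planted targets absent from catalog: {unknown}")
    rng = _stream(cfg, "dge")
    genes = cfg.gene_universe()
    log2fc = rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    for tid in planted:
        gmp = by_id[tid]
        for g in gmp.up_genes:
            log2fc[index[g]] += cfg.effect_size
        for g in gmp.down_genes:
            log2fc[index[g]] -= cfg.effect_size
    z = log2fc / cfg.noise_sd
    pvals = 2.0 * norm.sf(np.abs(z))
    fdr = np.array(bh_adjust(pvals))
    df = pd.DataFrame({"gene": genes, "log2fc": log2fc, "fdr": fdr})
    truth = {
        "planted_targets": planted,
        "effect_size": cfg.effect_size,
        "noise_sd": cfg.noise_sd,
    }
    return df, truth


def gen_ct_table(
    cfg: SimulationConfig,
    genes: Sequence[str] = ("SMAD4", "HIF1A", "PRKAA1", "HRAS"),
    groups: Sequence[str] = ("control", "treated"),
    reference_gene: str = "ACTB",
) -> tuple[pd.DataFrame, dict]:
    """Mean-Ct grid over groups x genes with known implied fold changes.

    The reference gene has identical Ct in every group, so its own fold
    change is exactly 1.  Target ddCt values are drawn uniformly in
    [-3, 3]; the truth sidecar records the implied fold change 2**(-ddCt)
    of each gene in each non-control group versus the first group.
    """
    rng = _stream(cfg, "ct")
    base_ref = 15.0
    rows = [
        {"group": grp, "gene": reference_gene, "mean_ct": base_ref} for grp in groups
    ]
    truth_folds: dict[str, dict[str, float]] = {}
    base_ct = {g: round(float(rng.uniform(18.0, 28.0)), 3) for g in genes}
    for grp in groups[1:]:
        truth_folds[grp] = {reference_gene: 1.0}
    for g in genes:
        rows.append({"group": groups[0], "gene": g, "mean_ct": base_ct[g]})
        for grp in groups[1:]:
            treated_ct = round(base_ct[g] + float(rng.uniform(-3.0, 3.0)), 3)
            rows.append({"group": grp, "gene": g, "mean_ct": treated_ct})
            truth_folds[grp][g] = 2.0 ** (base_ct[g] - treated_ct)
    df = pd.DataFrame(rows, columns=["group", "gene", "mean_ct"])
    truth = {"reference_gene": reference_gene, "fold_changes": truth_folds}
    return df, truth


def write_with_truth(
    df: pd.DataFrame, truth: dict, path: str | Path
) -> tuple[Path, Path]:
    """Write a generated table as TSV plus a ``.truth.json`` sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    truth_path = path.with_suffix(path.suffix + ".truth.json")
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return path, truth_path
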