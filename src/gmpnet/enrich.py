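"""Over-representation analysis (hypergeometric test with BH adjustment).

Annotation catalogs (GO/KEGG-style term -> gene set maps) are supplied as
GMT files; no live database access or ontology propagation happens here.
For a query gene set, each term with at least one overlapping gene is
tested with the one-sided hypergeometric tail P(X >= k), and q-values are
Benjamini-Hochberg adjusted across the tested terms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .gmpti import bh_adjust

__all__ = [
    "AnnotationCatalog",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_tail",
    "ora",
]


@dataclass
class AnnotationCatalog:
    """Term annotations and the background gene universe.

    The universe defaults to the union of all term genes; supply an
    explicit (e.g. measured-gene) universe to change the background, which
    changes every p-value.
    """

    terms: dict[str, tuple[str, frozenset[str]]]  # term_id -> (name, genes)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(genes for _, genes in self.terms.values())
            )
        if not self.universe:
            raise ValueError("annotation universe is empty")
        for tid, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {tid!r} has genes outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap: int  # k
    term_size: int  # K
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    q_value: float


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into {term_id: (description, gene set)}."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return terms


def write_gmt(terms: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, (name, genes) in terms.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def hypergeometric_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k successes in a size-n draw, K marked genes in a universe of N.
    """
    if not (0 <= k <= min(big_k, n) and big_k <= big_n and n <= big_n):
        raise ValueError(
            f"inconsistent counts: k={k}, K={big_k}, n={n}, N={big_n}"
        )
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def ora(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    top_k: int = 20,
) -> list[EnrichmentResult]:
    """Over-representation of a query gene set across catalog terms.

    The query is restricted to the catalog universe first.  Terms with zero
    overlap are not tested (and do not count toward the BH family size).
    Results are sorted by p ascending, ties by term id; the ``top_k`` best
    are returned.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    q = frozenset(query) & catalog.universe
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    big_n = len(catalog.universe)
    n = len(q)
    tested: list[tuple[str, str, int, int, float]] = []
    for tid, (name, genes) in catalog.terms.items():
        k = len(q & genes)
        if k == 0:
            continue
        tested.append((tid, name, k, len(genes), hypergeometric_tail(k, len(genes), n, big_n)))
    qvals = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=name,
            overlap=k,
            term_size=big_k,
            query_size=n,
            universe_size=big_n,
            p_value=p,
            q_value=qv,
        )
        for (tid, name, k, big_k, p), qv in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results[:top_k]
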