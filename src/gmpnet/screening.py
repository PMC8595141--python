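"""OB/DL bioactive-component screening and the herb-compound-target network.

Candidate herbal components carry an oral bioavailability (OB, percent) and
a drug-likeness index (DL, unitless).  Components passing both thresholds
(inclusive; the conventional cut is OB >= 30 and DL >= 0.18) are treated as
bioactive.  Their protein targets are intersected with a disease gene set,
and the surviving herb-compound and compound-target associations form a
tripartite network whose degree statistics identify hub compounds and hub
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ComponentRecord",
    "DiseaseGeneSet",
    "ScreenResult",
    "TripartiteNetwork",
    "load_component_table",
    "write_component_table",
    "screen_components",
    "intersect_targets",
    "build_tripartite_network",
    "degree_ranking",
    "export_network",
    "import_graphml_network",
    "load_gene_list",
]


@dataclass
class ComponentRecord:
    """A candidate herbal component with its screening scores and targets."""

    component_id: str
    name: str
    herb_ids: set[str]
    ob: float
    dl: float
    targets: set[str]

    def __post_init__(self) -> None:
        if self.ob < 0 or self.dl < 0:
            raise ValueError(f"{self.component_id}: OB and DL must be non-negative")


@dataclass
class DiseaseGeneSet:
    disease_label: str
    genes: set[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("disease gene set is empty")
        self.genes = {g.upper() for g in self.genes}


def load_component_table(path: str | Path) -> list[ComponentRecord]:
    """Read a component TSV (component_id, name, herb_ids, ob, dl, targets).

    ``herb_ids`` and ``targets`` are semicolon-delimited; targets may be
    empty.  Duplicate ``component_id`` rows are merged by union of herbs and
    targets, but only when their OB/DL values agree — a conflict is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8").fillna("")
    required = ["component_id", "name", "herb_ids", "ob", "dl", "targets"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"component table missing columns: {missing}")
    merged: dict[str, ComponentRecord] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        cid = row["component_id"].strip()
        rec = ComponentRecord(
            component_id=cid,
            name=row["name"].strip(),
            herb_ids={h.strip() for h in row["herb_ids"].split(";") if h.strip()},
            ob=float(row["ob"]),
            dl=float(row["dl"]),
            targets={t.strip().upper() for t in row["targets"].split(";") if t.strip()},
        )
        if cid in merged:
            prev = merged[cid]
            if prev.ob != rec.ob or prev.dl != rec.dl:
                raise ValueError(
                    f"conflicting OB/DL for duplicated component {cid!r}: "
                    f"({prev.ob}, {prev.dl}) vs ({rec.ob}, {rec.dl})"
                )
            prev.herb_ids |= rec.herb_ids
            prev.targets |= rec.targets
        else:
            merged[cid] = rec
            order.append(cid)
    return [merged[cid] for cid in order]


def write_component_table(records: Iterable[ComponentRecord], path: str | Path) -> None:
    rows = [
        {
            "component_id": r.component_id,
            "name": r.name,
            "herb_ids": ";".join(sorted(r.herb_ids)),
            "ob": r.ob,
            "dl": r.dl,
            "targets": ";".join(sorted(r.targets)),
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["component_id", "name", "herb_ids", "ob", "dl", "targets"]
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")


@dataclass
class ScreenResult:
    """Outcome of OB/DL screening with the three marginal counts."""

    passed: list[ComponentRecord]
    n_total: int
    n_ob_pass: int
    n_dl_pass: int
    n_joint_pass: int


def screen_components(
    records: Sequence[ComponentRecord], ob_min: float, dl_min: float
) -> ScreenResult:
    """Retain components with ``ob >= ob_min`` and ``dl >= dl_min`` (inclusive).

    Input order is preserved.  The result also reports how many components
    met the OB criterion alone and the DL criterion alone.
    """
    if ob_min < 0 or dl_min < 0:
        raise ValueError("screening thresholds must be non-negative")
    ob_pass = [r for r in records if r.ob >= ob_min]
    dl_pass = [r for r in records if r.dl >= dl_min]
    joint = [r for r in records if r.ob >= ob_min and r.dl >= dl_min]
    return ScreenResult(
        passed=joint,
        n_total=len(records),
        n_ob_pass=len(ob_pass),
        n_dl_pass=len(dl_pass),
        n_joint_pass=len(joint),
    )


def intersect_targets(component_targets: set[str], disease: DiseaseGeneSet) -> list[str]:
    """Exact intersection of component targets with the disease gene set.

    Symbols are case-folded to upper case; the result is sorted for
    deterministic downstream use.
    """
    targets = {t.upper() for t in component_targets}
    return sorted(targets & disease.genes)


_CLASS_KEY = "node_class"


@dataclass
class TripartiteNetwork:
    """Herb-compound-target network with disjoint node classes.

    Edges run only herb-compound and compound-target.  Backed by an
    undirected :class:`networkx.Graph` whose nodes carry a ``node_class``
    attribute in {herb, compound, target} and a display ``label``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d[_CLASS_KEY] == node_class
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def _check(self) -> None:
        allowed = {frozenset({"herb", "compound"}), frozenset({"compound", "target"})}
        for u, v in self.graph.edges():
            pair = frozenset(
                {self.graph.nodes[u][_CLASS_KEY], self.graph.nodes[v][_CLASS_KEY]}
            )
            if pair not in allowed:
                raise ValueError(f"illegal edge between classes: {u!r} - {v!r}")


def build_tripartite_network(
    screened: Sequence[ComponentRecord], kept_targets: set[str]
) -> TripartiteNetwork:
    """Assemble the tripartite network from screened components.

    Nodes are the herbs of retained compounds, the compounds that carry at
    least one kept target, and the kept targets themselves.  A compound with
    no surviving target is dropped from the network (it still counts toward
    screening totals upstream).
    """
    kept_targets = {t.upper() for t in kept_targets}
    net = TripartiteNetwork()
    g = net.graph
    for rec in screened:
        hits = {t.upper() for t in rec.targets} & kept_targets
        if not hits:
            continue
        if not rec.herb_ids:
            raise ValueError(f"component {rec.component_id!r} has no herb membership")
        g.add_node(rec.component_id, **{_CLASS_KEY: "compound", "label": rec.name})
        for herb in rec.herb_ids:
            g.add_node(herb, **{_CLASS_KEY: "herb", "label": herb})
            g.add_edge(herb, rec.component_id)
        for t in sorted(hits):
            g.add_node(t, **{_CLASS_KEY: "target", "label": t})
            g.add_edge(rec.component_id, t)
    net._check()
    return net


def degree_ranking(
    net: TripartiteNetwork, node_class: Literal["herb", "compound", "target"], k: int
) -> list[tuple[str, int]]:
    """Top-``k`` nodes of a class by degree, ties broken lexicographically."""
    if node_class not in ("herb", "compound", "target"):
        raise ValueError(f"unknown node class: {node_class!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = net.nodes_of_class(node_class)
    ranked = sorted(nodes, key=lambda n: (-net.graph.degree[n], n))
    return [(n, net.graph.degree[n]) for n in ranked[:k]]


def export_network(
    net: TripartiteNetwork, fmt: Literal["graphml", "sif", "tsv"], path: str | Path
) -> None:
    """Export the network losslessly (GraphML) or as SIF / node+edge TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(net.graph.edges()):
                cu = net.graph.nodes[u][_CLASS_KEY]
                cv = net.graph.nodes[v][_CLASS_KEY]
                if cv == "herb" or (cv == "compound" and cu == "target"):
                    u, v, cu, cv = v, u, cv, cu  # orient herb->compound->target
                rel = "contains" if cu == "herb" else "targets"
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif fmt == "tsv":
        nodes = pd.DataFrame(
            [
                {"node": n, "node_class": d[_CLASS_KEY], "label": d.get("label", n)}
                for n, d in sorted(net.graph.nodes(data=True))
            ]
        )
        edges = pd.DataFrame(
            [{"source": u, "target": v} for u, v in sorted(net.graph.edges())]
        )
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unsupported export format: {fmt!r}")


def import_graphml_network(path: str | Path) -> TripartiteNetwork:
    """Re-import a GraphML export; inverse of ``export_network(..., 'graphml')``."""
    g = nx.read_graphml(path)
    net = TripartiteNetwork(graph=nx.Graph(g))
    net._check()
    return net


def load_gene_list(path: str | Path, disease_label: str = "disease") -> DiseaseGeneSet:
    """Read a one-symbol-per-line gene list into a :class:`DiseaseGeneSet`."""
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym.upper())
    return DiseaseGeneSet(disease_label=disease_label, genes=genes, source_tag=str(path))
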