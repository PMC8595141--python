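"""End-to-end orchestration: simulate -> screen -> rank -> gmpti -> ora.

A single config drives all stages; every file read or written is recorded
in a run manifest with a content digest, so a rerun with the same config
can be checked for bit-identical outputs.  Any stage failure aborts the
run with a stage-tagged error.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .enrich import AnnotationCatalog, ora
from .expression import build_ranked_list, filter_degs, load_dge_table, write_rnk
from .gmpti import rank_targets, read_paired_gmt, write_paired_gmt
from .screening import (
    DiseaseGeneSet,
    build_tripartite_network,
    export_network,
    intersect_targets,
    load_component_table,
    load_gene_list,
    screen_components,
)
from .simulate import (
    SimulationConfig,
    gen_component_table,
    gen_ct_table,
    gen_de_profile,
    gen_gmp_catalog,
    write_with_truth,
)

__all__ = ["ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration is invalid; nothing was executed."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    cfg = dict(config)
    simulate = cfg.get("simulate")
    if simulate is not None and "seed" not in cfg:
        raise ConfigError("simulation requested but no seed given")
    if simulate is None and "inputs" not in cfg:
        raise ConfigError("either a 'simulate' block or an 'inputs' block is required")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the pipeline and return the run manifest (also written to disk).

    With a ``simulate`` block all inputs are generated from the seed;
    otherwise an ``inputs`` block must point at existing component, DE,
    disease-gene and GMP-catalog files.
    """
    cfg = _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "gmpnet",
        "version": __version__,
        "config": cfg,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    files: dict[str, Path] = {}

    def record(stage: str, **paths: Path) -> None:
        entry = manifest["stages"].setdefault(stage, {})
        for key, p in paths.items():
            entry[key] = {"path": str(p), "sha256": _sha256(p)}
            files[key] = p

    # --- inputs: simulate or load ------------------------------------
    stage = "simulate"
    try:
        if "simulate" in cfg:
            sim = SimulationConfig(seed=cfg["seed"], **(cfg["simulate"] or {}))
            comp_df, comp_truth = gen_component_table(sim)
            catalog, cat_truth = gen_gmp_catalog(sim)
            planted = sim.planted_targets
            dge_df, dge_truth = gen_de_profile(sim, catalog, planted)
            ct_df, ct_truth = gen_ct_table(sim)
            comp_path, comp_truth_p = write_with_truth(
                comp_df, comp_truth, out / "components.tsv"
            )
            gmt_path = out / "gmp_catalog.gmt"
            write_paired_gmt(catalog, gmt_path)
            dge_path, dge_truth_p = write_with_truth(dge_df, dge_truth, out / "dge.tsv")
            ct_path, ct_truth_p = write_with_truth(ct_df, ct_truth, out / "ct.tsv")
            disease_genes = None  # derived below from the simulated universe
            record(
                stage,
                components=comp_path,
                components_truth=comp_truth_p,
                gmp_catalog=gmt_path,
                dge=dge_path,
                dge_truth=dge_truth_p,
                ct=ct_path,
                ct_truth=ct_truth_p,
            )
        else:
            inputs = cfg["inputs"]
            comp_path = Path(inputs["components"])
            dge_path = Path(inputs["dge"])
            gmt_path = Path(inputs["gmp_catalog"])
            disease_genes = load_gene_list(Path(inputs["disease_genes"]))
            for p in (comp_path, dge_path, gmt_path):
                if not p.exists():
                    raise FileNotFoundError(f"missing input file: {p}")
            catalog = read_paired_gmt(gmt_path)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"[{stage}] {exc}") from exc

    # --- screen -------------------------------------------------------
    stage = "screen"
    try:
        screen_cfg = cfg.get("screen", {})
        components = load_component_table(comp_path)
        result = screen_components(
            components,
            ob_min=screen_cfg.get("ob_min", 30.0),
            dl_min=screen_cfg.get("dl_min", 0.18),
        )
        all_targets = set().union(*(r.targets for r in result.passed), set())
        if disease_genes is None:
            # all-synthetic run: the disease set is the simulated gene universe
            universe = set(pd.read_csv(dge_path, sep="\t")["gene"].astype(str))
            disease_genes = DiseaseGeneSet("synthetic-disease", universe, "simulated")
        kept = set(intersect_targets(all_targets, disease_genes))
        net = build_tripartite_network(result.passed, kept)
        counts = {
            "n_components": result.n_total,
            "n_ob_pass": result.n_ob_pass,
            "n_dl_pass": result.n_dl_pass,
            "n_joint_pass": result.n_joint_pass,
            "n_kept_targets": len(kept),
            "network_nodes": net.n_nodes,
            "network_edges": net.n_edges,
        }
        counts_path = out / "screening_counts.json"
        counts_path.write_text(json.dumps(counts, indent=2, sort_keys=True))
        net_path = out / "network.graphml"
        export_network(net, "graphml", net_path)
        record(stage, screening_counts=counts_path, network=net_path)
    except Exception as exc:
        raise StageError(f"[{stage}] {exc}") from exc

    # --- rank ---------------------------------------------------------
    stage = "rank"
    try:
        rank_cfg = cfg.get("rank", {})
        records = load_dge_table(dge_path)
        up, down = filter_degs(
            records,
            lfc_min=rank_cfg.get("lfc_min", 1.0),
            fdr_max=rank_cfg.get("fdr_max", 0.05),
        )
        ranked = build_ranked_list(records, metric=rank_cfg.get("metric", "lfc"))
        rnk_path = out / "ranked_list.rnk"
        write_rnk(ranked, rnk_path)
        deg_path = out / "deg_counts.json"
        deg_path.write_text(
            json.dumps({"n_up": len(up), "n_down": len(down)}, sort_keys=True)
        )
        record(stage, ranked_list=rnk_path, deg_counts=deg_path)
    except Exception as exc:
        raise StageError(f"[{stage}] {exc}") from exc

    # --- gmpti ----------------------------------------------------------
    stage = "gmpti"
    try:
        g_cfg = cfg.get("gmpti", {})
        results, skipped = rank_targets(
            ranked,
            catalog,
            n_perm=g_cfg.get("n_perm", 1000),
            seed=cfg.get("seed", 0),
            weight_exp=g_cfg.get("weight_exp", 1.0),
        )
        res_df = pd.DataFrame([asdict(r) for r in results])
        res_path = out / "gmpti_results.tsv"
        res_df.to_csv(res_path, sep="\t", index=False)
        skip_path = out / "gmpti_skipped.tsv"
        pd.DataFrame(skipped, columns=["target_id", "reason"]).to_csv(
            skip_path, sep="\t", index=False
        )
        record(stage, gmpti_results=res_path, gmpti_skipped=skip_path)
    except Exception as exc:
        raise StageError(f"[{stage}] {exc}") from exc

    # --- ora ------------------------------------------------------------
    stage = "ora"
    try:
        ora_cfg = cfg.get("ora", {})
        if "annotations" in ora_cfg:
            from .enrich import read_gmt

            terms = read_gmt(ora_cfg["annotations"])
        else:
            # default catalog: each target's combined module as one term
            terms = {
                g.target_id: (g.target_id, frozenset(g.up_genes | g.down_genes))
                for g in catalog
            }
        universe = frozenset(r.gene for r in records) | frozenset().union(
            *(genes for _, genes in terms.values())
        )
        ann = AnnotationCatalog(terms=dict(terms), universe=universe)
        query = {r.gene for r in up} | {r.gene for r in down}
        if query:
            enr = ora(query, ann, top_k=ora_cfg.get("top_k", 20))
            enr_df = pd.DataFrame([asdict(e) for e in enr])
        else:
            enr_df = pd.DataFrame(
                columns=[
                    "term_id",
                    "term_name",
                    "overlap",
                    "term_size",
                    "query_size",
                    "universe_size",
                    "p_value",
                    "q_value",
                ]
            )
        enr_path = out / "ora_results.tsv"
        enr_df.to_csv(enr_path, sep="\t", index=False)
        record(stage, ora_results=enr_path)
    except Exception as exc:
        raise StageError(f"[{stage}] {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
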