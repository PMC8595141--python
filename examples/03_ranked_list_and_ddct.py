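"""DEG filtering, ranked-list construction and ddCt fold changes.

Simulates a DE summary table, applies the |log2FC| >= 1 and FDR <= 0.05
thresholds, builds the ranked list used by target identification, and
computes a qPCR fold change by the 2^(-ddCt) method.
"""

from gmpnet.expression import (
    CtTable,
    DGERecord,
    build_ranked_list,
    ddct_fold_change,
    filter_degs,
)
from gmpnet.simulate import SimulationConfig, gen_ct_table, gen_de_profile, gen_gmp_catalog

cfg = SimulationConfig(seed=7, n_genes=2000, n_targets=20, effect_size=4.0)
catalog, _ = gen_gmp_catalog(cfg)
df, _ = gen_de_profile(cfg, catalog, planted_targets=["T0001"])
records = [DGERecord(r.gene, r.log2fc, r.fdr) for r in df.itertuples(index=False)]

up, down = filter_degs(records, lfc_min=1.0, fdr_max=0.05)
print(f"{len(up)} up-regulated and {len(down)} down-regulated significant DEGs")

ranked = build_ranked_list(records, metric="lfc")
print(f"ranked list of {len(ranked)} genes; best score {ranked.scores[0]:.2f} "
      f"({ranked.genes[0]}), worst {ranked.scores[-1]:.2f}")

ct_df, truth = gen_ct_table(cfg)
ct = CtTable(
    ct={(r.group, r.gene): r.mean_ct for r in ct_df.itertuples(index=False)},
    reference_gene=truth["reference_gene"],
)
gene = "SMAD4"
fold = ddct_fold_change(ct, gene, "treated", "control")
print(f"{gene} fold change (treated vs control, vs {truth['reference_gene']}): {fold:.3f}")
print("a fold > 1 means higher expression in the treated group")
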