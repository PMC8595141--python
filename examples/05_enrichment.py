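"""Over-representation analysis of a query gene set against a GMT catalog.

Builds a small annotation catalog, queries it with a gene set concentrated
in one term, and prints the hypergeometric p-values and BH q-values.
"""

from gmpnet.enrich import AnnotationCatalog, ora

universe = frozenset(f"G{i:03d}" for i in range(200))
terms = {
    "PATH_INFLAM": ("inflammatory response", frozenset(f"G{i:03d}" for i in range(0, 20))),
    "PATH_HYPOXIA": ("response to hypoxia", frozenset(f"G{i:03d}" for i in range(20, 50))),
    "PATH_CYCLE": ("cell cycle", frozenset(f"G{i:03d}" for i in range(50, 90))),
}
catalog = AnnotationCatalog(terms=terms, universe=universe)

query = {f"G{i:03d}" for i in range(0, 15)} | {"G060", "G061"}
results = ora(query, catalog, top_k=20)
print(f"query of {len(query)} genes against {len(terms)} terms (universe {len(universe)}):")
for r in results:
    print(
        f"  {r.term_id} ({r.term_name}): overlap {r.overlap}/{r.term_size}, "
        f"p={r.p_value:.3g}, q={r.q_value:.3g}"
    )
print("small p: the overlap is larger than a random draw of that size would give")
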