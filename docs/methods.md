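# Methods

## Scope and data model

The pipeline operates entirely at the summary-table level. It consumes a
compound-characterization table (UPLC-HRMS annotations), a candidate
component table with OB/DL scores and target assignments, disease gene
lists, differential-expression summaries (gene, log2FC, FDR), a catalog of
target gene module pairs, and qPCR Ct tables. It does not process raw
spectra, align reads, fit count models, query live databases (TCMSP,
SymMap, GeneCards, OMIM, CTD, STRING, GO/KEGG), score protein–protein
interactions, or dock ligands; those steps sit upstream or outside the
analysis and their outputs enter as files.

## Mass arithmetic

Monoisotopic atomic masses are fixed constants (Da): C 12 (exact, defines
the scale), H 1.00782503, N 14.00307401, O 15.99491462, Na 22.98976928,
S 31.97207117, P 30.97376200; proton 1.00727646, electron 0.00054858.
Adduct m/z for singly charged species is neutral mass + delta, with deltas
+proton (`[M+H]+`), −proton (`[M-H]-`), +Na − electron (`[M+Na]+`), and
+(formic acid − proton) = +44.99820 (`[M+FA-H]-`). For an intrinsic
cation (`[M]+`) the formula already describes the charged species and the
m/z is its mass minus one electron. The ppm error is
(measured − expected)/expected × 10⁶, kept at full precision internally;
display rounding is half-away-from-zero to the printed precision (4
decimals for m/z, 1 for ppm).

QC of a characterization table recomputes (a) ppm from the printed
measured/expected pair and (b) expected m/z from formula and adduct, and
flags rows deviating beyond `tol_ppm` (default 0.15) or `tol_mz` (default
0.0005 Da). Printed values are authoritative: flags record drift, nothing
is overwritten. On the packaged 150-compound table, 130 rows reproduce
their printed ppm within 0.15; the remainder are printing inconsistencies
in the source table (some printed ppm values match neither the printed m/z
pair nor the formula-derived m/z), which the report surfaces but cannot
resolve. A useful detail: several printed ppm cells are consistent with a
ppm computed against the *unrounded* theoretical m/z rather than the
4-decimal printed expected value, which explains sub-0.1-ppm drift on
otherwise clean rows.

## Screening and network

Both screening thresholds are inclusive (≥). OB ≥ 30 % is the
conventional oral-bioavailability cut; DL is treated symmetrically at
≥ 0.18. Components are counted per unique component id: duplicate rows
(one per herb in some exports) merge by union of herbs and targets and
must agree on OB/DL. Gene symbols are uppercased; no alias resolution is
attempted — inputs are expected to be pre-canonicalized.

The tripartite network keeps herb, compound and target classes disjoint,
with edges only herb–compound and compound–target. Compounds whose
targets all fall outside the disease intersection are dropped from the
network but still count in screening totals. Degree rankings break ties
lexicographically so output is deterministic. GraphML export is lossless
(re-import reproduces node and edge sets); SIF and node/edge TSV are
provided for interoperability.

## Ranked list

The DEG filter is symmetric (|log2FC| ≥ cut) even though such thresholds
are often quoted one-sided; a one-sided reading cannot produce
down-regulated gene lists, so the symmetric reading is the only coherent
one. The ranking metric for *L* defaults to log2FC; `signed_logp`
(sign(log2FC) × −log10 FDR, FDR floored at 1e−300) is available when fold
changes saturate. Ties are broken lexicographically by gene symbol, fixed
upstream of scoring, so every downstream statistic sees one realized
order.

## The target-identification statistic

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: walking down *L*, a module hit adds |score|^w normalized by the total
hit weight, a miss subtracts 1/(N − N_hit); ES is the running-sum value of
maximal absolute deviation, signed. With w = 0 this is the unweighted KS
statistic; the default w = 1 weights hits by their ranking scores. The
signed-maximal-deviation convention (rather than max-positive-only) is
required for ES_down ≈ −1 on a bottom-concentrated module, which is what
lets TCS = ES_up − ES_down span the full [−2, 2] range. When two
deviations tie in magnitude the positive one is reported. If every hit
score is exactly zero the hit weights degenerate to equal weights. The
implementation evaluates the running sum only at hit positions (its
extremes can occur nowhere else); tests check it against a full O(N)
walk by exhaustive enumeration on small instances.

The permutation null draws, per permutation, a uniformly random pair of
disjoint gene sets of the observed module sizes from *L*'s gene universe —
module resampling, not score shuffling, matching the idea that the null
target is a random module pair. The nominal p is the plug-in
count/n_perm (default n_perm = 1000); it can be exactly 0, which is the
standard convention for this estimator, and an optional
(count+1)/(n_perm+1) correction is available but off by default. Per-target
permutation streams are derived from SHA-256 of (run seed, target id), so
results are independent of catalog order and stable under catalog edits.
BH q-values (via statsmodels) are computed across all scorable targets;
targets whose modules miss *L* entirely go to a skip list instead of
failing the batch.

GMP extraction from a target's own induced profile takes the top-k genes
as t_up and bottom-k as t_down (disjoint whenever 2k ≤ N). The module
size k the original analysts used is not documented anywhere we could
verify, so k is an explicit parameter (default 10 in the simulator) rather
than a baked-in constant.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) with the
catalog union as the default universe (configurable to a measured-gene
background — this changes every p-value and is the single most
consequential choice in ORA). Terms with zero overlap are not tested and
do not count toward the BH family size. Note the correct direction of the
background effect: enlarging the universe with genes outside query and
terms makes every tested overlap more surprising, so p-values decrease.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis assumes,
at desk scale:

* **Component tables** — 1610 components by default with independent
  per-component Bernoulli passes at rates 0.510 (OB) and 0.412 (DL),
  matching the screening marginals of the motivating study; scores are
  drawn uniformly on the pass/fail side of each threshold. An
  `exact_counts` mode plants exact OB/DL/joint counts for tests that need
  a table with known realized marginals (a synthetic stand-in for the
  study's supplementary export, which has no public accession).
* **GMP catalogs** — disjoint k-gene modules sampled without replacement;
  default 50 targets, k = 10, over 2000 genes.
* **DE profiles** — baseline log2FC ~ Normal(0, σ), σ = 1 log2 unit by
  default; planted targets add +δ to their up module and −δ to their down
  module, δ = 2σ by default. FDR columns are BH-adjusted two-sided normal
  p-values of the implied z-scores — a stylized stand-in, not a
  count-model (e.g. negative-binomial) simulation. Passing tests on these
  profiles therefore demonstrate correct statistics under clean Gaussian
  noise, not robustness to dispersion, library-size or outlier artifacts
  of real RNA-seq.
* **Ct tables** — group × gene mean-Ct grids with the reference gene held
  constant, ΔΔCt drawn uniformly in [−3, 3], implied folds recorded in a
  truth sidecar.

Every generator draws from a stream seeded by (seed, generator name), so
adding a generator never perturbs another, and identical configs are
byte-identical on disk. Truth sidecars (planted targets, realized pass
counts, implied folds) accompany every dataset.

## Numerical and scale choices

Problem sizes in the test and acceptance runs are chosen for a laptop-class
single-core budget: the TCS range check uses 1000 lists of 500 genes with
module sizes 10–100; null-uniformity uses 500 replicates of 200-gene lists
at 200 permutations (empirical Kolmogorov distance to uniform < 0.08);
planted-target recovery uses 100 replicates of a 50-target catalog over
1000 genes with k = 10 and δ = 2σ, requiring the planted target to rank
first in ≥ 95 % of replicates. Permutation counts below the 1000 default
are used where only the ranking, not the p-value resolution, is under
test.

## Known limitations

* The exact variant of the enrichment statistic used by the original
  target-identification service is undocumented ("slightly adjusted" from
  GSEA); this implementation is the classic weighted KS with the exponent
  exposed. Absolute TCS values may therefore differ from that service even
  on identical inputs, though the range, antisymmetry and null behaviour
  are the same.
* Whether permutation draws are shared across targets in the original
  analysis is unknown; here each target gets an independent derived
  stream.
* No attempt is made to reproduce database-version-bound counts (numbers
  of retrieved targets, GO/KEGG term counts); they are inputs, not
  statistics.
* ORA ignores term–term dependence (no GO DAG propagation) and treats the
  catalog as flat.
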