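# Methods

This note documents the models, algorithms and parameter choices behind
`anaerodesign`, what the synthetic generators do and do not emulate, and the
numerical conventions.

## Domain architectures and persistence

A protein's domain architecture is the list of its domain accessions ordered
by start position on the protein (ties broken by end, then accession, so
results are independent of input row order). The key string joins accessions
with `;`. Overlapping hits are kept — the ordering rule is the only
resolution applied — and identical architectures within one genome are
counted as copies. Copy number is part of the orthology identity where it
matters (`ArchitectureMatrix.copy_number_view()` exposes `arch|cN` keys);
the presence/absence view used for PCA, clustering and the random forest
collapses copies. This reconciles two legitimate orthology notions: a
genome carrying two identical copies is a different ortholog state than a
single-copy genome for persistence purposes, while presence/absence is the
right resolution for ordination of thousands of binary features.

Persistence of an architecture in a strain group is N(orth)/N. Thresholds:

| parameter | default | meaning |
| --- | --- | --- |
| τ (core) | 0.95 | domain core: persistence ≥ τ within a group |
| τ (restricted) | 0.90 | core threshold when scoped to a dendrogram branch |
| ε (rare) | 0.01 | "nearly absent" threshold of the low-persistence rule |

The low-persistence rule additionally requires persistence ≥ τ in the focal
group; without that presence requirement, architectures absent everywhere
would count as "specific" to both lifestyles.

Ordination uses PCA on the centered (not scaled) binary matrix; degenerate
all-identical inputs return zero variance fractions rather than failing.
Clustering uses complete-linkage hierarchical clustering on Euclidean
distances of the binary profiles (both configurable; these are the defaults
of the standard implementations of the two methods). Branch extraction for
restricted lists is explicit — a focal strain plus a split depth from the
root — because choosing the branch is an interpretive step best kept under
the analyst's control.

## Random-forest cumulative Gini

Each repetition draws a balanced subsample (`n_per_class` genomes per
lifestyle, without replacement within a repetition, independently across
repetitions from a single seed) and trains a random-forest classifier
(default 500 trees, √p features per split). Importances are **unnormalized**
mean impurity decreases per model: the per-tree proportion-weighted Gini
decrease times the training-sample count, matching the MeanDecreaseGini
scale of the classical R implementation. The cumulative Gini coefficient is
the arithmetic sum over repetitions; ranking is descending with
lexicographic tie-breaks. Because the scale grows with sample size, tree
count and repetitions, absolute selection thresholds (defaults 20 and 100)
are configuration, not portable constants.

## Transcriptome consistency filter

Size factors are median-of-ratios: per gene, the geometric mean across
samples over genes with no zero count forms the reference; a sample's
factor is its median ratio to that reference. Multiplying one sample's
counts by c shifts all factors by a common geometric-mean constant but moves
that sample's *relative* factor by exactly c, leaving every fold change
unchanged — the property that matters.

Replicates are collapsed by mean of normalized counts; each non-reference
condition is compared with the anaerobic reference as
log2(reference/condition), so positive = up-regulated during anaerobic
respiration. Non-finite cells (zero means) are imputed: ±∞ becomes ±4 when
the gene's two-group test is significant (BH-adjusted fdr < 0.05), else 0;
0/0 (absent in both groups) has no defined direction and becomes 0.

The per-gene test backing the fdr is a Welch t-test on log2(normalized
counts + 0.5) with BH correction across genes. This is a deliberate
simplification of a negative-binomial exact test: the fdr's only role here
is gating the imputation of cells that already have an extreme observed
direction, for which a simple location test on stabilized values is
adequate. Conditions with fewer than two replicates get fdr 1 (no
imputation to ±4).

Selection: a gene passes with direction *d* when ≥ `min_consistent` (7) of
the 13 comparisons have sign *d* and ≥ `min_strong` (3) of those
same-direction comparisons reach |log2FC| ≥ log2(4). The strong-fold count
is taken over the same-direction cells only; zero cells count for neither
direction. Raising either threshold can only shrink the selection.

## Toy metabolic model and gap analysis

FBA is the LP max c·v s.t. S·v = 0, l ≤ v ≤ u, solved with HiGHS
(`scipy.optimize.linprog`). Conventions: exchange reactions are named
`EX_*`, touch one metabolite with coefficient −1, and take lower bound
−uptake from the medium (uptake = negative flux); exchanges not in the
medium are closed for uptake; insertable reactions are fixed to zero unless
explicitly enabled. Growth/blocked threshold 1e−6; steady-state and bound
tolerance on optimal solutions 1e−9. The default medium opens the carbon
source at 6.14 mmol gdw⁻¹ h⁻¹ (the measured maximal sugar uptake this class
of models standardly uses) and inorganic nutrients at 1000.

The toy network (25 reactions) has: sugar uptake → glycolysis (pyruvate,
ATP, NADH) → either O2 respiration or an *insertable* four-step
denitrification chain (NO3⁻ → NO2⁻ → NO → N2O → N2, each step conserving
energy) as the only NADH sinks; three O2-requiring cofactor syntheses (B12-,
B6-, K2-like) whose products are biomass precursors with closed uptake
exchanges; ATP-maintenance and pyruvate-overflow sinks so growth is
substrate-limited rather than artificially balance-limited. Consequences,
all verified by tests: aerobic growth 3.684; anoxic growth 0 (no electron
sink, so no flux at all); anoxic growth 0 even with denitrification (the
cofactors remain unmakeable); growth 2.865 with denitrification plus the
three cofactor uptakes, which form the unique minimal supplement set.

The blocked-precursor scan and oxygen-dependency tracing run on the
**denitrification-enabled** anoxic variant. Under plain anoxia the toy
network carries no flux at all, so every precursor is trivially blocked;
the informative question — mirroring a design round in which the
respiration pathway is slated for insertion — is what remains blocked once
an anaerobic electron sink exists, and the answer is exactly the three
O2-dependent cofactors. Tracing tests three single reliefs per candidate:
removing a reaction's oxygen requirement, enabling a disabled insertable
reaction, and opening a closed exchange (never the oxygen exchange itself).
The supplement search enumerates exchange subsets exhaustively up to size 4
(the design needs 3), reporting only minimal sets.

Models round-trip through a tabular reaction format
(`reaction_id equation lower upper genes flags`); SBML import is available
through cobrapy. cobrapy also serves as an independent solver cross-check
in the tests, alongside a brute-force vertex-enumeration oracle for tiny
models; neither stands in for the implementation.

## Evidence integration

The evidence table is the union of PDC-specific architectures, consistency-
filtered genes mapped to architectures, and gap-analysis gene labels, each
tagged with its sources ({PDC, T, GSM}), weighted by cumulative Gini where
available, and categorized. Gini weights are carried and reported but do
not gate inclusion — no formal weighting rule is imposed. Aerobe-specific
entries are categorized `excluded` and dropped from the design totals. DUF
co-localisation defaults: window 5 gene positions, retained in ≥ 50% of
carrier genomes, strand-agnostic; a gene is never its own neighbour, so
window 0 retains nothing.

The packaged reference design table is a curated, categorized gene/domain
list for the KT2440 respiration design (35 nitrogen-metabolism genes with
45 domains, 9 hydrogenase genes, 1 cytochrome-C gene, 3 pyrimidine/amino-
acid genes with 6 domains given 3 supplemented vitamins, 1 ATP-generation
gene, 8 unknown-function domains; 3 vitamins). In synthetic mode the manual
functional curation of a real design round is replaced by rule-driven
category assignment (DUF-named keys → unknown function; known toy-model
gene labels → their pathway category; others cycled deterministically) — a
stated simplification.

## Synthetic data: what it emulates, what it does not

The genome generator plants shared-core, aerobe-specific, anaerobe-specific
and accessory architectures over two lifestyle groups, perturbed by dropout
(an expected architecture missing from a genome, default 0.02) and
cross-group contamination (default 0.005); accessory architectures get one
random background frequency in [0.05, 0.6] common to both groups (no
signal). Coordinates are 1-based gene-order indices with planted
anaerobe-specific genes laid out in consecutive operon blocks (default 4
genes). Default sizes: 200+200 strains, 50 shared / 10+20 specific / 200
accessory architectures. The generator does **not** produce sequences,
realistic phylogenetic structure beyond the two groups, or Pfam clan
relationships — so passing tests show the *statistical machinery* recovers
planted structure under binomial presence noise, not that real genome
collections are this clean (real lifestyle labels are noisy, and real
presence patterns are phylogenetically autocorrelated, which inflates
apparent specificity).

The transcriptome generator draws negative-binomial counts (shared
dispersion, default 0.05) around condition means with per-sample library
factors log-uniform in [0.5, 2]. Fourteen conditions with 3 replicates each
plus one extra replicate in the first five non-reference conditions give 47
samples; the per-condition split of the emulated design is not on record,
so this layout is the package's choice. Planted up/down genes shift the
reference mean by the planted fold (default 8); weak decoys are constructed
to fail the default rule deterministically (strong in 5 of 13 comparisons,
mildly opposite in the rest); planted genes get a configurable number of
near-zero dropout conditions to exercise imputation. Not emulated:
gene-length effects, batch structure, dispersion trends, or correlated
regulons.

All generators use one `numpy` Generator seeded per call; identical config
and seed give byte-identical outputs, and the end-to-end pipeline writes
bit-identical bundles under a fixed manifest.

## Evaluation problem sizes

The desk-scale evaluation experiments (`anaerodesign.benchmarks`, used by
`scripts/acceptance.py` and the acceptance tests) run at: persistence-list
recovery on 200+200 genomes (dropout 0.02, contamination 0.005); RF top-10
recovery over 20 seeds at 150+150 genomes, 5 planted discriminators among
500 accessory architectures, with the protocol scaled to 10 repetitions ×
100 trees on 100-genome class subsamples; consistency-filter recovery on
2000 genes / 47 samples and a 20-seed null at 300 genes. The recorded
full-scale setting (1628 genomes, 5831 domains, 100 repetitions × 300
genomes per class) is a cluster-scale computation whose list sizes depend
on the exact genome collection and annotation-tool version; those counts
are recorded as reference constants, not recomputed.

## Known limitations

- Lifestyle labels are consumed as given; no label-noise modelling.
- The fdr behind imputation is a stand-in test, adequate only because it
  gates imputation rather than selection.
- The restricted-branch workflow requires the analyst to pick the branch;
  no automatic branch selection is attempted.
- The toy model demonstrates the gap-analysis mechanism; its numeric optima
  are properties of the toy stoichiometry, not predictions for any genome-
  scale reconstruction.
- The supplement search is exhaustive and capped at subsets of size 4.
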