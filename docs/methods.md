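# Methods

`soilroot` implements the statistical workflow used to describe bacterial
community assembly along the soil–root continuum (bulk soil → rhizosphere →
endosphere) of a crop host: abundance sub-community partition, per-OTU flow
classification between compartments, α/β diversity with PERMANOVA, the Sloan
neutral community model, Levins' niche breadth, and thresholded Spearman
co-occurrence networks with natural-connectivity robustness. This note
records the models, the defaults and why they were chosen, and what the
synthetic generators do and do not emulate.

## Abundance sub-communities

OTUs are partitioned per group (compartment × host variety) by mean relative
abundance across the group's samples: **abundant** above 1% of total
sequences, **rare** below 0.01%, **moderate** between (moderate ∪ rare form
the "low abundance" view). Because the defining thresholds are strict
("above 1%", "below 0.01%"), the boundary values 1% and 0.01% classify as
moderate; this is documented and tested. The abundance basis defaults to the
group mean of per-sample proportions, which removes depth differences
between replicates; a pooled-reads basis is available
(`classify_abundance(..., basis="pooled")`) and coincides with the mean when
depths are equal. Cumulative class abundances sum to 100% per group by
construction. The summary's `ratio` helper returns full-precision fold
changes; 2-decimal rounding or truncation is available for presentation
only.

## Flow classification

For a source→target comparison each OTU present in either compartment is
classified:

* **emerging** — zero in every source sample, present in ≥1 target sample;
* **filtered** — the reverse;
* otherwise a two-sided Wilcoxon rank-sum test on per-sample relative
  abundances, Benjamini–Hochberg adjusted across tested OTUs; **enriched**
  / **depleted** require adjusted p < α (default 0.05) with positive /
  negative log2 fold change, the rest are **unchanged**.

The rank-sum test was chosen because it is robust to the strong skew of
relative-abundance data and consistent with the rank-based comparisons used
elsewhere in the workflow; a Welch t-test on log abundances is available
(`method="welch_log"`), as is raw-p thresholding (`adjust="none"`). The fold
change uses a pseudo-abundance ε equal to half the smallest nonzero relative
abundance in the union of the two groups — scale-aware and deterministic —
added to both group means. Swapping source and target maps
enriched↔depleted and emerging↔filtered exactly, with p-values unchanged.

Relative-abundance flow classification is inherently compositional: if the
enriched set gains total mass Z, every untouched OTU shifts by −log2 Z. The
synthetic truth tables therefore carry both the construction label and the
realized expected log2 fold change from the final probability vectors;
recall is assessed against construction labels and precision against the
realized sign (see Calibration below).

## Diversity

Chao1 uses the bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)), which is
defined even without doubletons; the classic F1²/(2F2) form is available by
flag. Shannon entropy is reported in nats. No rarefaction is applied by
default; `rarefy(cm, depth, seed)` performs multivariate-hypergeometric
(without-replacement) subsampling when depth standardization is wanted.
Group comparisons are two-sided Wilcoxon rank-sum with the star convention
\*, \*\*, \*\*\*, \*\*\*\* at 0.05, 0.01, 0.001, 0.0001.

β diversity is Bray–Curtis on proportions (d = 1 − Σ min(p_a, p_b)).
Ordination is classical metric scaling: Gower double-centring of −D²/2,
eigendecomposition, coordinates scaled by √λ. Negative eigenvalues (possible
for non-Euclidean dissimilarities) are reported in the output but excluded
from the variance-explained denominator, so variance explained sums to 100%
over retained axes. PERMANOVA is the distance-based pseudo-F (between/within
sums of squared distances), R² = SS_between/SS_total, with a seeded free
permutation of labels and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); no
strata are supported because the design has a single crossed factor
structure. The implementation is checked against exhaustive enumeration at
n ≤ 6 in the tests.

## Sloan neutral community model

The NCM predicts a taxon's occupancy frequency (fraction of local
communities where it is detected) from its metacommunity mean relative
abundance p, with the migration rate m as sole parameter. Under Sloan's beta
approximation the local relative abundance is Beta(Nmp, Nm(1−p)), so the
expected occupancy above a detection limit d is F(p) = 1 − I_d(Nmp,
Nm(1−p)). `fit_ncm` estimates m by bounded scalar least squares on
Σ(f_i − F(p_i))²; R² = 1 − SSR/SST. N defaults to the mean sample depth; the
95% band is the Wilson score interval around F(p) with one trial per
community, and OTUs are partitioned above/within/below the band. Nm is
reported as N·m̂ (metacommunity size × immigration).

**Detection limit.** The default is d = 1/(2N), not 1/N. Occupancy in count
data means n ≥ 1 individuals; the continuous beta stands in for a discrete
count distribution, and the boundary between n = 0 and n = 1 sits at the
midpoint 0.5/N. The choice matters: fitting Sloan's curve to the *exact*
stationary occupancy of the Hubbell birth–death chain (computed by detailed
balance at N = 1000) shows that d = 1/N inflates the fitted m by ≈ +26%,
+40% and +96% at true m = 0.05, 0.1 and 0.3 respectively, while the
continuity-corrected d = 1/(2N) recovers m to within a few percent. d
remains an explicit argument for users who want the uncorrected convention.

## Levins' niche breadth

B_j = 1/Σ_i P_ij², with P_ij the proportion of taxon j's total abundance
found at site i; B ranges from 1 (single-site specialist) to the number of
sites (perfectly even generalist). Sites default to individual samples
within a group; a `sites` mapping aggregates samples into site means first
(e.g. one site per compartment). OTUs absent from all sites are excluded
with a warning. Group-level comparisons are Wilcoxon rank-sum over OTU-level
B distributions.

## Co-occurrence networks

Within a group, pairwise Spearman correlations (mid-rank ties, t-
approximation p-values) are computed over per-sample abundances, BH-adjusted
across all pairs, and edges retained at |ρ| > 0.6 and adjusted p < 0.01 by
default. Applying the p < 0.01 threshold to *adjusted* p is the conservative
reading; raw-p mode (`adjust="none"`) and the alternative p < 0.05 threshold
are configuration choices. Taxa present in fewer than one third of the
group's samples are dropped before correlation, because tied zeros generate
spurious perfect correlations; the filter is configurable. Correlation at
the genus level is the default in the pipeline when a taxonomy is supplied.

Node metrics: degree, normalized betweenness, harmonic closeness (well
defined on disconnected graphs), eigenvector centrality of the largest
component (zero elsewhere), clustering coefficient. Network metrics include
edge density, diameter and average path length on the largest component,
average clustering, greedy-agglomerative modularity (deterministic
tie-breaking, checked against exhaustive bipartition on small graphs),
linkage density as the "complexity index" (edges per node — defined here
explicitly since the term has no standard formula), and Freeman
centralizations. Robustness is natural connectivity,
nc = ln((1/n) Σ e^{λ_i}) over adjacency eigenvalues (log-sum-exp
stabilized; the edgeless graph gives exactly 0), tracked as nodes are
removed uniformly at random (averaged over seeded repeats) or in descending
degree order with id tie-break.

## Synthetic generators

The generators exist so every stage — including NCM parameter recovery — is
testable end-to-end without any sequencing data.

* **Metacommunity**: lognormal species-abundance distribution (default
  2000 OTUs, σ = 2), the canonical skewed SAD in which a few abundant taxa
  dominate; at σ = 2 the top 1% of OTUs carry ≈ 37% of abundance in
  expectation.
* **Compartment gradient**: bulk soil samples are multinomial draws from
  the metacommunity; the rhizosphere applies log2 fold changes +2/−2 to
  randomly chosen enriched (25% of OTUs) and depleted (5%) sets and adds
  emerging OTUs (15%, drawn from the lower half of abundance ranks, since
  emerging taxa recruit as moderate/rare); the endosphere zeroes 55% of
  rhizosphere OTUs (host filtering removes more than half of rhizosphere
  taxa) and renormalizes. Defaults: depth 50 000 reads, 6 replicates per
  compartment × variety, two varieties. Truth labels and realized expected
  fold changes are returned per OTU and transition.
* **Neutral assembly**: individual-based zero-sum (Hubbell-type) dynamics —
  each generation sweeps every slot of every community in random order,
  replacing the resident with probability m by a metacommunity draw and
  otherwise by the offspring of a random current resident, with immediate
  updates. This is deliberately *not* the beta approximation the fitter
  assumes, so recovery tests validate the fitter against an independent
  forward model. At m = 1 one generation reduces exactly to a multinomial
  draw from the metacommunity. Default 50 generations ensures stationarity
  for m ≥ 0.05 (relaxation time ≈ 1/(m + 1/N) generations).

What the generators do **not** emulate: sequencing error, chimeras, PCR
amplification bias, overdispersion beyond multinomial sampling, taxonomic
structure in the effect sets, and environmental covariates. Passing the
recovery and calibration suites therefore shows the statistics are
implemented correctly and calibrated under the assumed sampling model — not
that real amplicon data meet those assumptions.

## Calibration and problem sizes

The test suite and acceptance script use the following scales, chosen to
give stable statistics at desk scale: NCM recovery at m ∈ {0.05, 0.1, 0.3},
N = 1000, M = 50 communities, averaged over seeds (tolerance ±25% on the
mean, R² > 0.6); flow recall/precision on 2000 OTUs at depth 50 000 with 6
replicates, assessed on OTUs above 0.01% abundance (below the sampling
detection limit absence is uninformative); null calibration with effect
fractions set to zero (flow false-positive rate ≤ 6% at q < 0.05),
200 PERMANOVA null runs (type-I error in [0.02, 0.08] at p < 0.05), and
20-seed null networks (edge retention ≤ 1%).

## Known limitations

* Relative-abundance differential tests are compositional; strong
  enrichment necessarily depresses all other proportions. The truth tables
  make this explicit rather than hiding it.
* Sloan's beta law is itself an approximation to the discrete chain; the
  continuity-corrected detection limit removes the dominant bias but small
  residual bias remains at large m.
* PERMANOVA assumes exchangeable samples under the null; the permutation is
  free (no nested/strata designs).
* Networks use plain Spearman correlation, as in the workflow this package
  implements; compositionality-aware inference (e.g. SparCC-style) is out
  of scope.
* With few samples per group (n = 6), BH-adjusted network p-values rarely
  pass p < 0.01 — realistic networks need the pooled metacommunity design
  (compartment × variety groups with ≥ 10 samples) or the raw-p mode.
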