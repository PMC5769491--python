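# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Expression units and transforms

All expression is transcripts-per-million (TPM); the pipeline never
re-normalises library size. The pipeline-wide log transform is
log₂(TPM + 1). Two deliberate exceptions: per-gene CVs are computed on
linear TPM by default (`cv_scale` switches to log), and the TF expression
filter uses natural log — a TF counts as expressed when its mean ln(TPM+1)
exceeds 1 (≈ mean TPM > 1.72) in at least one state — matching the
convention of the assay this pipeline models.

## QC

Cells pass with aligned reads > 200,000, ribosomal reads < 2% and > 2000
genes expressed (TPM > 1). All three are strict inequalities; boundary
values fail. Replicate consistency pools cells by summing TPM within each
replicate and correlates log₂(pooled + 1) profiles; pairs below r = 0.96
are flagged. Genes enter the analysis universe when expressed (TPM > 1) in
strictly more than five cells, minus a configurable cell-cycle list.

## State map and pseudotransition (stand-in)

Workflows of this kind typically use DDRTree/Monocle2 here. That algorithm
is an external published method and is not re-implemented; the stand-in is:

1. PCA of log₂(TPM+1) on the 1000 most variable analysis genes, PAM
   (k-medoids; greedy BUILD + SWAP, deterministic under seed) in the top
   10 components → provisional clusters;
2. *ordering genes*: per provisional cluster, the 50 genes with the
   largest |mean log difference| vs the rest (union over clusters). This
   deliberately excludes genes whose variability carries no mean shift —
   e.g. genes with state-specific dispersion but preserved means — which a
   plain high-variance selection would let dominate the embedding;
3. final PCA + PAM on the ordering genes; cluster letters assigned by
   descending size (a label convention, not an identity claim);
4. pseudotime: minimum spanning tree over on-path cluster centroids in a
   3-component PC space of the ordering genes (the original method reduced
   to a final dimensionality of two); cells are projected onto the
   piecewise-linear centroid path, with the two terminal segments extended
   so end-state cells spread instead of piling onto the endpoints; arc
   length is rescaled to [0, 1] with the designated start state at 0. If
   sampling noise branches the centroid MST, the shortest start-anchored
   Hamiltonian path is used instead (exact enumeration; at most a handful
   of on-path states).

Marker genes: log-expression is regressed on log₁₀(aligned reads) and
replicate dummies where available; a two-sided Mann–Whitney rank test
(normal approximation, tie and continuity corrected, vectorised across
genes) is applied to residuals per state-vs-rest; BH across genes within
each state; reported markers satisfy |log₂FC| > 0.5 (pseudocount 1 on
group mean TPM) and adjusted p < 0.05. This replaces the original
VGAM-based likelihood-ratio test with the same covariates and identical
reporting filters.

All downstream stages read `state` and `pseudotime` columns from the
annotation table, so externally computed (e.g. Monocle) orderings drop in
directly.

## Heterogeneity statistics

**TCOV** (intracellular): per cell, sample sd / mean of log₂(TPM+1) over
analysis genes ((n−1) denominator). Log scale bounds the influence of
single high-abundance transcripts. The pseudotime trend uses a local
quadratic regression with tricube weights and span 0.75; start-state-vs-
other-state contrasts use the two-sample KS test.

**Two-sample KS** is implemented once and shared by every stage. The
statistic is the exact supremum ECDF difference (ties handled by
evaluating at run ends); the p-value is the asymptotic Kolmogorov survival
function at √(mn/(m+n))·D. Exactness of the statistic is enforced against
a brute-force oracle in the tests.

**Differential dispersion** (intercellular): per gene and state,
log₂(TPM+1) values are centred by their own group mean and the state
residuals compared with the rest residuals by KS; BH across genes within
state. A gene is differentially dispersed when q < 0.05 and its CV fold
change (linear TPM, (n−1) sd) between state and rest exceeds 2. Genes with
a zero group mean keep their table row but cannot be flagged.

*Dropout alignment.* The non-detection class (TPM = 0) is a point mass.
Centring by each group's own mean moves the two masses to locations that
differ by the sampling noise of the group means, and the KS statistic
would count the entire dropout mass as signal — on null data this produced
false-positive rates near 40%. Centred zeros are therefore re-aligned to a
common per-gene location below the residual range in both groups: a
*difference in dropout fraction* still registers as dispersion signal,
while identical distributions stay null. For the continuous part,
own-group centring makes the test slightly conservative (as for any
location-adjusted KS), which the measured null rates confirm
(≈ 0.001 at q < 0.05).

**Mean-rank gene-set enrichment**: genes ranked by score (ascending,
average ranks); per set a two-sided Wilcoxon rank-sum comparison of in-set
vs out-of-set ranks (normal approximation, tie + continuity corrected);
a set spanning the whole universe has no out-group and is defined to have
p = 1; BH across sets.

## Proportion shifts

Overall homogeneity: Fisher's exact test on the 2 × k state × condition
table — scipy's exact test for 2×2, full enumeration of tables with the
observed margins when their count is ≤ 2×10⁶, otherwise seeded Monte-Carlo
from the multivariate hypergeometric null with the (1+hits)/(1+draws)
estimator. Per state: a two-sided exact binomial test (minimum-likelihood
convention) of the treated count against the pooled treated fraction —
the natural exchangeability null; the design ratio can be supplied
instead. Pseudotime densities per condition use a Gaussian KDE (Silverman
bandwidth) with boundary reflection at 0 and 1, renormalised to unit
trapezoidal mass, alongside a KS test of the raw pseudotimes.

## Gene dynamics and TF enrichment

Each gene's log₂(TPM+1) is regressed on a natural cubic spline basis of
pseudotime with 3 degrees of freedom (boundary knots at the data range,
interior knots at the 33rd/67th percentiles — the classic trajectory
default) against an intercept-only null; the Gaussian likelihood-ratio
statistic n·ln(RSS₀/RSS₁) is referred to χ²(3); BH gives the FDR, with
dynamic genes called at q < 0.05. Fitted curves on a 50-point grid,
z-scored per gene, are grouped by Ward-linkage hierarchical clustering
into four temporal patterns, numbered I–IV by mean peak position and
ordered by per-gene peak pseudotime.

The proliferation index averages per-cell z-scores of log₂(TPM+1) for
S-phase markers (zero-variance markers dropped) and min–max rescales to
[0, 1]. The packaged `s_phase_genes.txt` is a compact curated list of
mouse DNA-replication machinery genes (MCM complex, PCNA, RRM1/2, …);
`cell_cycle_genes.txt` carries the widely used S and G2/M program symbols.
Both are conveniences for real data — the synthetic tests pass explicit
lists — and index values are not comparable gene-for-gene across marker
choices.

TF over-representation: one-sided hypergeometric tail of the overlap
between a TF's target set and the dynamic set within the analysis
universe; TFs failing the expression filter are removed before BH
correction (kept in the output, unscored). Directionality is the log₂
fold change of mean TPM (+1) between the designated end states with a
±0.5 log₂ dead-band for "neutral" — the dead-band is a package choice,
configurable.

## Spatial neighbour quantification

Neighbours are **all** cells within 20 µm (nucleus-to-nucleus, 2-D
Euclidean); the radius reading is the only one consistent with a mean
neighbour count of ~5 in sub-confluent monolayers. Graphs use a k-d tree
(optionally toroidal for geometry checks). Per transgene index cell:
neighbour count, transgene-neighbour count, per-channel mean intensity
over non-transgene neighbours; index cells with more than two transgene
neighbours are excluded from downstream summaries. Condition comparisons
pool replicates and apply the shared KS test to index-cell intensities and
to neighbour means. EdU stratification: TF-high is nuclear intensity above
the within-replicate upper quartile among non-transgene cells
(configurable quantile); per-replicate EdU⁺ fractions are compared across
conditions with a two-sided t-test on replicate-level values (zero
variance in both groups reports p = 1 with a warning).

*Limitation.* Pooling replicates makes the KS comparison operate on
correlated values wherever neighbourhoods overlap (at co-culture density
the mean degree is ≈ 5), which measurably inflates its null rejection rate
(≈ 0.08 at nominal 0.05 in simulation). The replicate-level t-test on EdU
fractions does not share this issue; treat pooled KS p-values near the
threshold with caution.

## Synthetic data: what is emulated

The generator reproduces the statistical structure the analysis assumes,
at the scale of the modelled experiment (125 control + 129 treated cells,
8000 genes, 4000–8000 expressed per cell):

* **States and pseudotime**: five states, A–D on-path with pseudotime
  uniform on consecutive quartile intervals, E off-path. Treated cells are
  drawn with state A depleted (0.32 → 0.10) and state D enriched
  (0.10 → 0.32); the effect size is a package design choice — only the
  direction of the redistribution is biologically constrained — sized by
  an exact-binomial power calculation to ≥ 98% per-state detectability at
  this cell count.
* **Counts**: negative-binomial (size 2) around per-gene lognormal
  baseline means, multiplied by a per-cell lognormal library-size factor
  (σ = 0.5, matching the severalfold depth spread of real single-cell
  libraries), then scaled per cell to TPM. Depth variation matters: it
  smears the per-count quantisation of TPM that would otherwise make
  log-expression unrealistically discrete.
* **Markers**: 40 genes per state at 8-fold elevation. On-path markers
  hold their full fold inside their state's pseudotime interval and decay
  with narrow Gaussian shoulders (σ = 0.03) into neighbouring intervals,
  so the population has both distinct clusters and a graded transition
  path; state-E markers are discrete.
* **Dispersed genes**: 200 genes with CV inflated 4-fold in state A at
  preserved mean, via gamma-mixture scaling of the per-cell NB mean (unit
  mean, variance solved per gene from the target fold). Mean preservation
  holds in the systematic sense — the median state/rest mean ratio stays
  within 5% of 1 — while individual sample means of a fold-4 CV gene
  necessarily fluctuate by ~CV/√n.
* **Dynamic genes**: 200 genes following early-, mid-, late-peak or
  monotone log-scale programs of amplitude 2 (log₂).
* **Planted gene sets are disjoint** and drawn from genes whose baseline
  mean is ≥ 2 counts, since a planted effect in a never-detected gene is
  unrecoverable by any method and meaningless as ground truth.
* **QC metadata**: lognormal read counts, beta ribosomal fractions,
  read-correlated gene counts; exactly ⌈fail_fraction·n⌉ cells planted to
  violate at least one threshold.
* **Imaging fields**: homogeneous Poisson or hexagonal layouts, Bernoulli
  transgene labels (default fraction 0.1 — the 9:1 co-culture), lognormal
  intensities with an additive shift for cells within 20 µm of a
  transgene cell in the activated condition, and EdU probabilities of 0.18
  baseline with a 0.15 contact boost (a roughly twofold proliferation
  increase, typical of such co-culture effects); the `low_calcium` flag
  removes the contact effect entirely, emulating blocked cell–cell
  contacts.

Not emulated: read-level artefacts, gene–gene correlation beyond the
state/pseudotime model, doublets, transgene transcript detection, cell
segmentation errors. Passing recovery tests on these simulations
demonstrates that the implementations detect what they claim to detect at
realistic scale and noise — not that real keratinocyte data satisfy the
generative assumptions.

## Problem sizes in the checks

The automated checks run at the scale of the modelled study or a
documented fraction of it: null calibration at 2000 genes × 300 cells over
20 seeds; planted-dispersion recovery at 2000 genes (200 planted, fold 4)
with ≥ 40 cells in the target state; dynamic recovery at amplitude 2 with
200 on-path cells; proportion-shift detection over 50 simulated
experiments (with a reduced gene count, as state assignment does not
depend on it); trajectory recovery at the full default scale; spatial
geometry on a 20,000-cell toroidal field; contact-effect logic at 3
replicates × 700–2000 cells per condition.

## Known limitations

* The state map and pseudotime are a simplified stand-in; branch-point
  detection and graph embeddings are out of scope. The pipeline assumes a
  single on-path trajectory.
* Asymptotic KS p-values (not exact small-sample ones) are used
  throughout; with fewer than ~10 observations per group they are
  conservative.
* The dispersion test conditions on the analysis-gene filter; genes
  expressed in ≤ 5 cells are never tested.
* Pooled spatial KS comparisons inherit spatial correlation (above).
* The Fisher 2×k Monte-Carlo p-value has resolution 1/(1+draws)
  (default ≈ 10⁻⁵).
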