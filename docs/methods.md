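# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Bayesian site-composition comparison

**Model.** For one cluster and one tissue site, each individual *i*
contributes a count pair (xᵢ, nᵢ): the number of the individual's cells in
the cluster and the individual's total cell count at that site. Counts are
modelled as xᵢ ~ Binomial(nᵢ, p_site) with a single shared site proportion
and a Uniform(0, 1) prior on p_site. Because the likelihood factorises over
individuals with a common p, the posterior depends on the data only through
the pooled sums and is conjugate:

    p_site | data ~ Beta(1 + Σxᵢ, 1 + Σ(nᵢ − xᵢ)).

Pooling individuals is the reading under which this shared-p model is
coherent; a per-individual random-effect (hierarchical) model is an explicit
non-goal. With no observed cells the prior Beta(1, 1) is returned unchanged,
so clusters absent from one site need no special-casing — their posterior
simply stays diffuse.

**Sampling.** δ = p_A − p_B is summarised from independent Beta draws per
site, differenced. Because the posterior is available in closed form, MCMC
is unnecessary; the draws are organised as 4 pseudo-chains × 25,000 draws to
retain a familiar sampling effort and to feed a split-R̂ diagnostic, which
must stay below 1.01 (trivially satisfied for i.i.d. draws; the diagnostic
guards against future sampler changes). Tests verify the sampled moments
against the analytic Beta moments within 3 Monte-Carlo standard errors —
the conjugate form is the oracle.

**Intervals.** The 98% highest-density interval is the shortest interval
holding the requested mass. Sample mode slides a window of ⌈mass·n⌉ draws
over the sorted draws; analytic Beta mode minimises ppf(q + mass) − ppf(q)
on a 10,001-point grid of lower-tail probabilities. For flat or plateau
densities all windows tie; the tie-break returns the central (equal-tailed)
interval, so Beta(1, 1) at mass 0.98 yields [0.01, 0.99].

**Posterior → FDR bridge.** Clusters are ranked by the two-sided posterior
tail probability p = 2·min(Pr(δ ≤ 0), Pr(δ ≥ 0)), floored at 1/draws (a
Monte-Carlo estimate cannot honestly claim less), fed to Benjamini–Hochberg
across clusters and flagged at q < 0.05. This bridge is a convention of this
package: it behaves like a p-value under the null (verified by simulation,
KS test against uniform) but is not a frequentist error rate.

## Repertoire Gini and TRA calling

The Gini index is the population form G = Σᵢⱼ|xᵢ − xⱼ| / (2 n Σx), computed
by the O(n log n) sorted expression Σᵢ(2i − n − 1)x₍ᵢ₎ / (n Σx) and checked
against the O(n²) pairwise oracle to 1e-12. Equality gives 0, full
concentration gives (n − 1)/n; the index is scale-invariant and
Schur-convex. Repertoire Gini aggregates read counts (`duplicate_count`) by
CDR3 amino-acid sequence per sample — read weighting rather than clone
weighting is a documented choice (`level="clonotype"` switches the
aggregation key). Empty samples are skipped with a logged warning rather
than poisoning a cohort run.

Segment usage is the read-weighted fraction of a sample's repertoire per V,
J, or V–J pair; group comparisons use the two-sided Mann–Whitney U on
per-sample fractions with BH across segments (≥ 2 samples per group
required). V–J pair fold change is the ratio of pooled read fractions, with
an explicit, logged infinity when the pair is absent from the reference
group.

TRA calling applies strict inequalities exactly as stated: Gini > 0.8
across tissue means AND max-tissue mean TPM > 100. A gene expressed in
exactly k of N tissues can reach Gini at most (N − k)/N, so the rule needs
several tissues to be satisfiable; all-zero genes get a missing Gini and
are never called.

## Gene-set scoring with binned controls

Genes are ranked by mean expression over **all** cells (ties broken by gene
id for determinism) and cut into 25 equal-size bins; each set gene draws 50
control genes without replacement from its own bin, set genes excluded; the
per-cell score is mean(set genes) − mean(pooled, de-duplicated controls).
Defaults (25 bins, 50 controls) are the conventional defaults of this
scoring scheme. The score is invariant to adding a constant to every gene
of every cell, and deterministic under a fixed seed. A single random set
carries a small baseline offset (its genes vs their bin-matched controls);
only the expectation over sets is zero — tests therefore average over sets.
Degenerate case: a set covering whole bins leaves no controls and is an
error rather than a silent fallback. Cluster enrichment is cluster-vs-rest
Mann–Whitney with BH across clusters and a sign giving direction.

## IHC quantification

**Optical density and separation.** OD_c = −ln(max(I_c, 1)/I₀) per channel
with I₀ = 255; clipping at intensity 1 bounds the OD of saturated pixels.
Concentrations solve OD = c·M for a stain matrix M whose rows are unit
absorption vectors; negatives are clipped to zero after solving. Default
vectors: the published hematoxylin and DAB vectors; the purple chromogen's
vector is unpublished, so the default third channel is the orthogonal
complement of H and DAB with negative components clipped to zero and
re-normalised — this preserves invertibility without inventing dye
chemistry, and is overridable from the YAML config. White balance rescales
each channel so its 99.9th percentile maps to 255.

**Blobs and colocalization.** Blob detection is the scale-normalised
Laplacian of Gaussian (scikit-image `blob_log`), returning (row, col, σ);
coordinates are 0-based pixels, origin top-left. Nearest-blob distances use
a k-d tree and are validated against brute force. A nucleus is positive for
a stain iff a blob of that stain lies within a configurable radius (default
5 px) of the nucleus centre; the resulting 2×2 table feeds Fisher's exact
test. Top-k region counting places k (default 3) non-overlapping windows
greedily by contained blob count and reports the mean count — matching the
practice of averaging the three densest fields of view; if all cells sit in
one field the other windows legitimately contribute zeros.

**Thresholds.** Area-fraction thresholds, blob parameters, the matching
radius and the window size are unknowable from the source protocol and are
config-surfaced with the defaults above.

## Statistical kernels and conventions

- Mann–Whitney U: exact enumeration when both groups ≤ 8 without ties,
  otherwise the normal approximation with tie and continuity corrections
  (delegated to scipy, whose switch matches this rule). U counts pairs
  xᵢ > yⱼ plus half the ties. All-identical pooled data short-circuits to
  p = 1.
- Fisher's exact test: two-sided probability-mass rule; the reported odds
  ratio is the unconditional cross-product ratio a·d/(b·c) with an explicit
  infinity (b·c = 0, a·d > 0), not the conditional MLE.
- BH: statsmodels step-up with clipping at 1; adjusted ≥ raw elementwise.
- Every test implementation is cross-checked against an independent
  brute-force oracle (rank-assignment enumeration, hypergeometric table
  enumeration, pairwise Gini, density-level HDI grid) that lives only in
  the test suite.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed); identical inputs give
byte-identical outputs, and ground truth is written beside every dataset.

- **Cell counts**: multinomial draws per individual with site-dependent
  proportions. Defaults mirror the study conditions — 4 thymoma
  individuals of ~8,000 cells and 2 blood individuals of ~15,000 cells over
  8 clusters, reflecting a few-patient single-cell cohort with imbalanced
  per-site cell recovery. Not emulated: overdispersion between individuals
  (the shared-p model is exactly true in the simulation), doublets, or
  ambient RNA — so passing composition tests shows correctness of the
  inference, not robustness to inter-individual heterogeneity.
- **Repertoires**: distinct CDR3 strings with clone sizes from a geometric
  or zipf law (spanning low- and high-clonality regimes; under zipf a
  *smaller* exponent gives a heavier tail and a higher Gini) and V/J calls
  from given segment distributions. Not emulated: somatic hypermutation,
  shared/public clones, sequencing error.
- **Tissue expression**: background genes share a log-normal baseline
  (median 20 TPM, σ_log = 1) with ±25% per-tissue jitter; TRA genes are
  expressed in exactly one of 30 tissues at 150–1000 TPM. The margins to
  both thresholds make perfect classification the correct expectation;
  real tissue atlases have correlated tissues and borderline genes.
- **Expression matrix**: per-gene log-normal baselines plus Gaussian
  per-cell noise; module genes gain an additive log-scale shift in one
  cluster (default δ = 1.0 in a 200-cell cluster of 2,000 cells). All other
  structure is exchangeable, which is exactly what the null-calibration
  tests require.
- **IHC images**: nuclei on a jittered grid guaranteeing pairwise
  separation ≥ 4σ (an over-crowded request is an error), Gaussian dye
  deposits of peak OD 1.0 (hematoxylin, DAB) and 0.8 (purple), mixed
  through the stain matrix, imaged as 255·e^(−OD) with optional Gaussian
  pixel noise. DAB/purple positivity follows a joint law given by two
  marginals and the double-positive probability. Not emulated: touching or
  overlapping cells, uneven illumination, out-of-focus blur — blob
  precision/recall of 1.0 is expected *in this well-separated regime* and
  says nothing about confluent tissue.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicates for HDI coverage, 100 null
replicates × 20 clusters for FDR calibration, 50 seeds for enrichment
recovery and 100 random sets for its null, 1,000 vectors for the Gini
oracle, and 512×512 images with 200 nuclei — sizes chosen so the full
verification runs in well under a minute each while keeping Monte-Carlo
bands narrow. Sub-seeds are spawned from the master seed via
`numpy.random.SeedSequence`, so stages are independently reproducible.

## Known limitations

- The composition model ignores between-individual variation; with strongly
  heterogeneous individuals its intervals will be anti-conservative.
- The tail-probability/BH bridge is a pragmatic ranking device, not a
  decision-theoretic posterior error control.
- Stain separation assumes the configured vectors; it does not estimate
  them from the image, and pixels outside the stain span are clipped.
- Top-k region counting uses axis-aligned windows and a greedy (not
  globally optimal) placement.
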