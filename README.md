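# thymoquant

Quantitative building blocks for studies of thymoma and thymoma-associated
myasthenia gravis (MG) that combine single-cell transcriptomics, immune
repertoires, and brightfield immunohistochemistry (IHC). The package
re-implements, as a tested and reusable library with a CLI, the bespoke
computations such a study needs:

- **Cell-composition comparison between tissue sites.** Per cluster and site,
  individuals' cell counts are modelled as binomial draws sharing a site
  proportion *p* with a Uniform(0, 1) prior, giving the conjugate posterior
  *p* | data ~ Beta(1 + Σx, 1 + Σ(n − x)). The difference
  δ = p_thymus − p_blood is summarised by Monte Carlo draws (default 4 × 25,000),
  a 98% highest-density interval (HDI), a two-sided posterior tail
  probability, and Benjamini–Hochberg FDR flags across clusters (q < 0.05).
- **Repertoire clonality and tissue-restricted antigens (TRA).** The
  population Gini index G = Σᵢⱼ|xᵢ − xⱼ| / (2 n Σx) applied to CDR3 clone
  sizes per sample, V/J segment-usage comparisons (Mann–Whitney U + BH), V–J
  pair fold changes, and TRA calling on a tissue × gene mean-TPM table
  (Gini > 0.8 and max-tissue TPM > 100).
- **Gene-set enrichment scoring.** Per-cell score = mean expression of the
  set genes minus the mean of expression-matched controls drawn from 25
  equal-size bins of the gene-average ranking (50 controls per set gene),
  followed by cluster-vs-rest Mann–Whitney tests with BH correction.
- **IHC quantification.** Beer–Lambert optical density (OD = −ln I/I₀),
  stain separation for hematoxylin / DAB / purple by matrix inversion,
  thresholded area fractions, Laplacian-of-Gaussian blob detection,
  nearest-blob distances, top-3-region cell counts, and nucleus-anchored
  positivity cross-tables tested with Fisher's exact test.
- **Synthetic data with ground truth** for every input type, so each stage is
  verifiable without access to controlled patient data.

## Worked example

Simulate a full dataset bundle and run every stage:

```sh
thymoquant all --out run1 --seed 7
```

`run1/composition/composition.tsv` compares cluster proportions between 4
thymoma and 2 blood "individuals" whose true thymic proportion of
`cluster_0` was shifted by +0.05:

```text
cluster     delta_mean  hdi_low  hdi_high  p_tail   q        significant
cluster_0   0.0463      0.0397   0.0530    1e-05    8e-05    True
cluster_1   -0.0029     -0.0092  0.0030    0.267    0.267    False
```

The shifted cluster's posterior mean δ ≈ 0.046 recovers the simulated +0.05
with a 98% HDI excluding 0 and q ≪ 0.05; unshifted clusters are not flagged.
`run1/tra/tra_calls.tsv` reports per-gene tissue Gini and the maximally
expressing tissue (e.g. `GENE00000 gini=0.071 max_tpm=186.9 is_tra=False` —
high expression but even across tissues, so not tissue-restricted).
`run1/score/cluster_tests.tsv` shows the spiked gene module detected in its
target cluster (`cluster_0 mean_score=0.886, q ≈ 2e-118, direction=+1`), and
`run1/ihc/colocalization.json` the double-staining cross-table of the
synthetic slide (odds ratio 13.2, p ≈ 6e-16 for 200 nuclei).

Each stage is equally usable from Python (`thymoquant.composition_test`,
`thymoquant.call_tras`, `thymoquant.score_gene_set`, …) and writes a
`manifest.json` with parameters, seeds and input/output checksums; re-running
an identical invocation reproduces byte-identical tables.

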