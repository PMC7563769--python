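# pcsig

Attribution of bulk transcriptome variation to a planned overexpression
factor, for two-cell-line × three-condition (wild type / empty vector /
overexpression) microarray designs — the setting where the difference
between cell lines dwarfs the effect you actually care about.

The package is aimed at analysts working with small-replicate expression
experiments who need the complete chain: low-expression filtering, PCA-based
gene-signature selection, clustering-based attribution of components to
experimental factors, moderated-t differential expression, and pathway
over-representation analysis — plus a seeded synthetic-data generator that
emulates the whole design so every stage can be validated against a known
ground truth.

## Methods at a glance

- **Filtering.** A gene is kept when its signal reaches a threshold
  (default 5 on the log2 scale) in strictly more than a minimum number of
  arrays (default 3).
- **PCA signatures.** The gene-centered matrix (genes × samples) is
  decomposed by SVD; samples are observations, genes variables. The
  signature of component *k* is the set of genes with |loading| > *W*·*N*^(−1/2),
  where *N* is the number of genes decomposed and *W* = 3.5 by default.
- **Component attribution.** Samples are clustered hierarchically
  (row-centered Euclidean distances, average linkage by default) on each
  component's signature; a component is attributed to overexpression when
  the best cluster-to-level bijection matches the overexpression split with
  concordance ≥ 0.9 and beats the cell-line concordance.
- **Moderated t.** Per cell line and control type, a two-group contrast
  with empirical-Bayes variance shrinkage: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),
  with (d₀, s₀²) estimated by moment matching on log variances (trigamma
  inversion); t̃_g is referred to a t distribution with d₀ + d_g df;
  Benjamini–Hochberg adjustment; significant sets from the two cell lines
  are intersected. Numerically identical to the Bioconductor reference
  implementation of this estimator (cross-checked in the test suite).
- **ORA.** One-sided hypergeometric tail P(X ≥ k) of the
  signature/pathway overlap against the filtered-gene universe, summed in
  log space; BH-adjusted p-values are reported informatively.

## Worked example

```bash
pcsig simulate --seed 1 --out fixtures/
pcsig pipeline --expr fixtures/expr.tsv --annotation fixtures/ann.tsv \
               --gmt fixtures/sets.gmt --out run/
```

or, from Python, the numbered drivers under `analysis/` run the same stages
with a narrated summary. `python analysis/02_filter_and_pan_pca.py` prints:

```
filter (signal >= 5 in > 3 arrays): 4742 of 5000 genes kept
     variance_fraction  eta2_cell_line  eta2_overexpression
PC1             0.7628          0.9999               0.0000
PC2             0.0682          0.0000               0.9986
```

— the cell-line difference owns 76% of the variance (PC1), while the
planted overexpression contrast surfaces on PC2. `analysis/03_per_line_signatures.py`
then shows that within each cell line the attributed component's W = 3.5
signature recovers ~96% of the 150 planted genes at ~3% false inclusion,
and `analysis/05_enrichment.py` ranks the planted pathway first among 50
decoys (p ≈ 6×10⁻³⁷). `analysis/04_differential_expression.py` reports the
moderated-t models (estimated prior d₀ ≈ 4.1, s₀² ≈ 0.050 against a
simulated truth of 4 and 0.05) and makes the power ceiling of the strict
adjusted-p < 10⁻⁴ call explicit: with three replicates per group the
posterior t has ~8 df, so the cross-line intersection is empty at 10⁻⁴ but
recovers 86% of planted genes at adjusted p < 0.01 with zero false
positives.

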