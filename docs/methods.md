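# Methods

## Model and procedure

`tdfe` treats a multiomics dataset as a dense real tensor with one large
feature mode (genes or fixed-width genome windows) and several small sample
modes (tissue, disease, omics measurement group, biological replicate).
The decomposition is the plain higher-order SVD: the factor matrix of each
mode is the matrix of left singular vectors of that mode's unfolding, and
the core tensor is the data contracted with every factor transpose. No
iterative Tucker refinement (HOOI) is performed, and no CP or tensor-train
variants are offered; the selection procedure only needs the leading
singular vectors of each unfolding and the core entries linking them.

Selection proceeds in three steps. First, one singular value vector per
sample mode is designated as "of interest" — either manually (the
reproduction configurations pin the indices: (1, 1) for the synthetic
benchmark, (1, 2, 1) for the multiomics workflow) or automatically from
categorical labels via the class-separation score η² (between-class sum of
squares over total). Second, the core tensor is screened along the feature
mode with the sample-mode indices fixed; the feature-mode vector with the
largest |G| is the one whose variation across features co-varies with the
chosen sample-mode pattern. Ties break toward the smaller index, i.e.
toward the mathematically primary factor. Third, each feature's coordinate
in that vector is standardized by the vector's standard deviation σ and
referred to a χ² null with one degree of freedom; Benjamini–Hochberg
adjustment and a strict threshold (adjusted p < α) give the selected set.

The χ² null deserves a note. Under the null a feature contributes only
noise, and its coordinate in any fixed unit vector is approximately
Gaussian; its squared standardized coordinate is then χ²₁. One degree of
freedom is used because exactly one squared coordinate is attributed per
feature. σ is computed over the *whole* vector, signal features included,
with the mean removed (default). Including the signal inflates σ and
shrinks every null feature's statistic, which is what drives the method's
near-zero false-positive rate; a raw root-mean-square variant is available
behind `sigma_centered=False`. Because the statistic is a square and the
screening uses absolute core values, all results are invariant to the sign
convention of the singular vectors (each factor column's largest-magnitude
entry is made positive, purely to stabilize plots and tests) and to global
rescaling of the data.

## Automatic sample-vector choice

η² ranks candidate vectors well whenever classes have replicated levels.
On a mode where every class has exactly one level — tumor vs normal on a
two-level tissue mode — η² is identically 1 for every non-constant vector
and carries no information. There the choice falls back to ranking vectors
by non-constancy (centered sum of squares over uncentered), which
distinguishes the grand-mean-like first vector from the contrast-like
second and reproduces the usual manual choice of the tumor/normal contrast.
Manual indices always win over the automatic choice.

## Synthetic benchmark

The generator plants 100 signal features among 10⁵ on a 9 × 9 sample grid:
three tissue subclasses × three replicates crossed with three disease
subclasses × three replicates. Signal entries have mean
⌈j/3⌉·⌈k/3⌉ + 3 on 1-based grid indices (the 3-groups-of-3 subclass
structure only emerges with 1-based ceilings); every entry receives
independent Gaussian noise with standard deviation 3. These defaults *are*
the study conditions; unit tests scale down only the number of null
features, never the signal strength, noise level or grid.

Trial *t* of a repeated benchmark uses seed `base_seed + t` with a
counter-based generator (numpy Philox), so trials are independent and
individually reproducible. Averaged confusion matrices are reported to one
decimal; reference tabulations of this benchmark print integer means, which
matters at lenient thresholds: TD-FE admits a single false positive at
threshold 0.1 in roughly a third of trials (mean FP ≈ 0.35, which rounds
to 0), while at 0.01 and 0.001 the false-positive count is exactly zero
trial after trial. The benchmark emulates the simplest integration
scenario — one subclass-dependent mean pattern, homoscedastic Gaussian
noise, no correlation between features, no batch structure. Passing it
shows the machinery is correct and calibrated under those assumptions; it
does not certify behaviour under the heavy tails, feature correlation and
missingness of real coverage data.

## Comparator methods

**Categorical regression (two-factor ANOVA).** Each feature is fit with
the additive model x_s = Σ_J a_J δ_Js + Σ_K b_K δ_Ks. The model carries no
intercept term, so the overall F-statistic — the single per-feature
p-value a linear-model summary reports for such a fit — tests against the
zero model with the uncentered total sum of squares and
df_model = rank(design). This uncentered test is what gives the method
full power on features whose grand mean sits away from zero (the centered
intercept-style test, available via `intercept=True`, loses the grand-mean
signal and misses planted features at stringent thresholds). All features
share one design, so the fit is vectorised through a single hat-matrix
product; it was verified against statsmodels OLS and R's `lm` on small
fixtures. Degenerate rows: an all-zero feature has nothing to test (p = 1,
logged); a constant nonzero feature is a perfect zero-model rejection and
receives the numerical floor.

**Multiple NMF.** Matrices sharing a row space are factorised jointly by
NMF of their column-wise concatenation (the summed per-block squared
Frobenius objectives equal the concatenated objective exactly). The
implementation is the classic multiplicative update with uniform random
initialisation scaled to the data, 200 iterations maximum and a 1e-4
relative-change stopping rule; the per-iteration objective trace is stored
and is non-increasing. Synthetic input is shifted by its global minimum
before factorisation; nonnegative coverage data has exact zeros replaced by
1e-10. MNMF's latent variables are nonnegative and admit no Gaussian null,
so no p-values are attributed to them; where a confusion matrix is needed
for comparison the benchmark uses matched-size top-k selection (k = number
of planted signals) on the per-feature latent weights — the most charitable
evaluation available to a method without a selection rule.

**Random forest.** Delegated to scikit-learn's `RandomForestClassifier`
(500 trees by default, mirroring the common R default). Selection is
"nonzero importance", with a top-k mode for matched-size comparisons.
Importance values are Gini-based and learner-dependent; counts derived from
them are treated as qualitative.

**LOO-LDA evaluation.** The tensor restricted to the selected features is
re-decomposed, and each sample (j, k, m) is represented by the products of
its sample-mode singular-vector coordinates over configurable index ranges
(default: all available). Leave-one-out cross-validated LDA over the
design classes yields an error rate and confusion matrix. A caveat
discovered during validation: this representation encodes each sample's
grid position deterministically, so even on unstructured data the
leave-one-out error is a function of the random factor geometry rather
than being pinned at the 1 − 1/K chance level; error rates from this
evaluation are therefore only meaningful relative to a baseline on the
same design.

## Genomic workflow

Coverage tracks (bedGraph-like interval + value records) are averaged over
fixed-width windows (default 25,000 bp) tiling each chromosome left to
right, the last window truncated at the chromosome end. Window values are
length-weighted means with uncovered bases counting as zero (coverage
semantics; a covered-bases-only mode exists but is not the default — the
choice is unobservable for fully covered tracks). Binning conserves signal
mass and is invariant to splitting intervals at interior points. All
internal coordinates are 0-based half-open; GTF/GFF3 annotation (1-based
inclusive) is converted on read by pyranges, and strand is ignored
throughout. The window count is driven by the supplied chromosome-size
table rather than hard-coded, since genome builds and included contigs
vary. A sample manifest (path, omics group, tissue, replicate) assembles
per-sample window vectors into the 4-mode tensor; a missing design slot or
a window-set mismatch is a hard error naming the offender.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `alpha` | 0.01 | BH-adjusted p threshold; selection is strict (<) |
| `dof` | 1 | χ² degrees of freedom of the null |
| `sigma_centered` | True | σ removes the mean of the feature-mode vector |
| `feature_rank` | 10 | feature-mode singular vectors computed and screened; the full p × p factor is never materialised (only a handful of columns are ever inspected, and a 10⁵ × 10⁵ orthogonal matrix would not fit in memory) |
| `n` (MNMF) | 3 | latent dimension |
| `width` | 25,000 bp | genome window width |
| `n_estimators` (RF) | 500 | trees |

## Numerical choices

SVDs are dense LAPACK economy decompositions (any backend accurate to
1e-10 relative would do); singular-value ties keep input order. Core
screening ties break toward the smaller index. BH adjustment is
statsmodels' step-up implementation, cross-checked in the tests against a
brute-force step-up oracle. The ANOVA p floor is 1e-300. Problem sizes in
the shipped test and acceptance runs: 20 full-scale (10⁵-feature) trials
for TD-FE/PCA/regression, 3 for the MNMF control, 2 for random forest —
enough that the Monte-Carlo standard errors of the reported means are well
below the differences being demonstrated.

## Known limitations

* The χ² attribution assumes approximately Gaussian null coordinates; it
  is exact only in the synthetic model's homoscedastic Gaussian world.
* HOSVD offers no tunable dial: if no singular value vector expresses the
  contrast of interest, the method has nothing to select — this is
  inherent to the approach, not a bug.
* Penalized LDA is not implemented (an external method; the benchmark
  harness accepts a plug-in adapter for it).
* BAM/bigWig ingestion, peak calling and enrichment-service clients are
  out of scope; tracks must be pre-converted to bedGraph-like text.
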