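# Methods

## Design and estimand

The unit of analysis is one cross between two homozygous lines, with
both parental genotypes and the two reciprocal F1 heterozygotes measured
in both sexes (default 3 replicates per cell, 24 samples per cross).
Because the parents are isogenic, F1s are heterozygous wherever the
lines carry fixed differences, and the contrast between the heterozygote
and the parental midpoint measures dominance of regulatory variation.

The estimand is the per-sex dominance coefficient on the natural scale,

δ_s = ln(het_s / midparent_s), midparent_s = (AA_s + BB_s)/2,

computed from size-factor-normalized group means, with the heterozygote
mean taken as the average of the two reciprocal-direction means (robust
to unbalanced replication after sample exclusions).  The two reciprocal
directions are pooled because parent-of-origin effects are tested
separately and are rare; δ is reported only for transcripts whose
midparent is positive, which the low-count filter guarantees in
practice.  Orientation (which line is called `BB`) is decided per
transcript by the pooled-sex parental means, with exact ties broken to
the lexicographically first line; δ itself and all likelihood-ratio
tests are invariant to orientation, which only fixes the sign
convention of reported additive and parent-of-origin coefficients.

## Count model and tests

Each transcript is modelled as NB2 (variance μ + φμ²) with log link and
log size-factor offsets.  The full design per cross is
`1 + sex + a + h + p + sex·a + sex·h + sex·p` with sex ∈ {+1 female, −1
male}, a ∈ {−1, 0, +1} (homozygotes vs. heterozygotes), h ∈ {0, 1}
(heterozygote indicator) and p ∈ {−1, 0, +1} (reciprocal direction, dam
of the +1-coded line → +1; zero for homozygotes).  With a complete
4-genotype × 2-sex design this model is saturated (8 parameters, 8
cells) and full rank.

Fitting is by iteratively reweighted least squares with step-halving,
converged when the relative log-likelihood change is below 1e−10 (at
most 100 iterations).  The dispersion φ is estimated once per transcript
by maximizing the Cox–Reid adjusted profile likelihood under a saturated
one-indicator-per-(genotype, sex) model (bounded scalar search on ln φ
over [1e−8, 10], tolerance 0.02 on the log scale), and held fixed across
all of that transcript's nested fits, so every likelihood-ratio
statistic compares models on a common variance function.  No
information is shared across transcripts: with 24 samples and 16
residual degrees of freedom the per-gene estimate is usable, and
cross-gene shrinkage would add an empirically unverifiable layer.

Hypothesis tests are 1-df likelihood ratio statistics: the sex ×
dominance interaction drops `sex·h` from the full model; per-sex
nonadditivity and parent-of-origin tests drop `h` or `p` from the
within-sex model `1 + a + h + p`.  The statistic divided by its df is
referred to an F(df, r) distribution, where r is the residual df of the
saturated dispersion model (quasi-likelihood style), rather than to
χ²(df).  The χ² reference is exact for known φ and is exposed as
`nbglm.lrt`, but with φ estimated from 16 df its far tail is about
threefold anti-conservative, which inflates the realized FDR of
q-value-thresholded calls (measured up to 0.27 on null-heavy
simulations); the F reference restores tail calibration (measured
type-I error 0.040 at α = 0.05; realized SSD FDR 0.02–0.08) and
converges to χ² as r grows.  Wald z-tests are provided for single
coefficients but no headline call uses them.

## Preprocessing

Y-linked transcripts are removed first.  A transcript is then removed
when its mean raw count per sample is below 3 within *every* sex
(strict <; configurable to an any-sex rule) — the within-every-sex
reading keeps strongly sex-limited transcripts, which matter for the
sex-bias analyses.  Size factors are median-of-ratios (per-gene
geometric-mean reference over all-positive genes, factors rescaled to
geometric mean 1).  The pipeline additionally applies a second,
control-gene pass: with ~half the transcriptome line-different,
heterozygotes genuinely express those genes near the arithmetic
midparent, which lies above the parental geometric mean, and plain
median-of-ratios absorbs part of that real signal into heterozygote
size factors, biasing δ̂ by about −0.03; re-estimating factors on genes
with parental |log2 FC| < 0.25 (first-pass normalized; fallback to the
plain estimate below 50 control genes) removes the bias (measured
|bias| ≤ 0.02 across seeds).

The inspection transform is log2(normalized + 1) — deterministic,
monotone, zero-preserving — used only for PCA and outlier detection,
never for inference.  PCA is gene-centered SVD over all retained genes
with a deterministic sign convention.  Mis-sexed samples are flagged by
a leave-one-out nearest-sex-centroid rule in the top-2 PC space
(skipped with a warning if a sex has fewer than 2 samples); flagged
samples are recorded and excluded by the pipeline, and size factors are
re-estimated on the retained samples.

## Focal filtering, multiplicity, classification

Using parental samples only: step 1 keeps transcripts with a
significant line main effect (`1+sex+a` vs. `1+sex`); step 2 removes
transcripts with a significant sex × line interaction (`1+sex+a+sex·a`
vs. `1+sex+a`).  Both use q ≤ 0.05; step-2 q-values are computed over
step-1 survivors.  All q-value families (step 1, step 2, sex ×
dominance, per-sex nonadditivity, per-sex POE) are computed separately
per cross and per chromosome class (autosome / X), matching the
per-cross, per-class analysis structure.

q-values are Storey's: π̂₀ = min(1, #{p > λ}/((1−λ)m)) with fixed
λ = 0.5, step-up q_(i) = min_{j≥i} π̂₀ m p_(j)/j.  The fixed λ keeps the
estimate deterministic and testable; at the pipeline's family sizes the
smoother over a λ grid changes q-values negligibly.  With π̂₀ = 1 the
procedure equals Benjamini–Hochberg exactly (tested).

Classification at q ≤ 0.05: per sex, dominant (δ > 0), recessive
(δ < 0) or additive from the per-sex nonadditivity test; SSD from the
sex × dominance interaction; reversal = SSD with oppositely signed
nonzero deltas (so reversal ⊆ SSD).  Sex-consistent parent-of-origin =
POE q ≤ 0.05 in both sexes.  Greater/lesser sex bias in heterozygotes
compares D_het = |log2(het_f/het_m)| with D_mid = |log2(mid_f/mid_m)|.
Non-converged fits are flagged and excluded from every q family rather
than contributing unstable p-values.

X-linked transcripts: males are hemizygous (no heterozygote state), so
dominance, nonadditivity and POE are tested in females only and no male
δ is reported; male heterozygote X data feed a dam-clustering
diagnostic (fraction of sample × transcript pairs closer in log space
to the dam line's male mean than the sire's).  The focal filter uses
parental samples of both sexes, which remain valid on the X.  Sex-bias
log2 fold change (positive = female-biased) comes from the full model's
sex coefficient for autosomes, and from the parental-only model on the
X, where the full cross design does not apply.

## Post-hoc statistics

Major-axis (type II) regression of δ_f on δ_m uses the leading
eigenvector of the 2×2 covariance matrix; its confidence interval
rotates the axis by the angle with sin²(angle) = t²·λ₁λ₂ /
((n−2)(λ₁−λ₂)²) (Jolicoeur's method; unbounded when that quantity
reaches 1).  Simulated coverage of the generating slope is ~95%
(tested ≥ 90%).  The equal-proportions χ² is 1-df without continuity
correction — the uncorrected statistic reproduces the worked values
8.30 (260/330) and 0.47 (8/19) exactly.  Fisher's exact 2×2 test sums
hypergeometric probabilities ≤ the observed one (relative tie tolerance
1e−12; p = 1 for an empty margin).  The directional KS statistic is
D⁺ = sup_t [ECDF_ref(t) − ECDF_test(t)] (test set stochastically
larger), with the one-sided asymptotic bound
p = exp(−2 D⁺² mn/(m+n)) — adequate at the hundreds-to-thousands
sample sizes involved, slightly conservative below that.

GO over-representation uses the classic per-term hypergeometric
upper-tail test of the SSD set against the cross's focal set (never all
genes), skipping terms with fewer than 5 universe genes, with Storey
q-values over tested terms.  Annotation propagation to ancestor terms
runs only when an ontology edge list is supplied; graph-decorrelation
algorithms (elim/weight) are out of scope.

## Synthetic data

The generator emulates the post-quantification structure of the study
design: per gene, a baseline (log2 mean uniform on [4, 10]), a sex
effect (probability 0.5, |effect| uniform on [0.5, 6] log2 — matching a
transcriptome where about half of genes are strongly sex-biased and PC1
of the transformed data carries >85% of the variance), and an NB
dispersion (log-normal, median 0.02, clipped to [1e−4, 0.5] — tight, as
expected for pooled isogenic replicates); these are gene properties
shared across crosses.  Per cross: a line effect (probability 0.5,
|effect| uniform on [0.25, 2] log2), of which 30% are sexually
discordant (independent per-sex draws — these are exactly what step 2
removes); among concordant line-different autosomal genes, 10% get
sex-specific dominance (independent per-sex δ ~ N(0, 0.5) truncated at
|1.2|) and the rest a shared δ ~ N(0, 0.3) truncated likewise; 2% get a
parent-of-origin effect (|ln fold| uniform on [0.35, 1.0]).  δ is
injected on the natural scale around the arithmetic midparent — the
estimand itself — so recovery tests are direct.  Heterozygous males
express the dam line's level for X-linked genes; Y-linked genes are
male-limited; library sizes are log-normal (sd 0.3 in log space,
geometric mean 1); mis-sexed samples (default 2 per run, as whole
samples, since the pooled sample is the unit that can be mislabeled)
are generated with the opposite sex while keeping the annotated sex.
The default is three crosses of 2,500 transcripts — a desk-scale
transcriptome chosen so that full runs and the acceptance script finish
in minutes; effect proportions mirror the per-step retention pattern of
the motivating study (about half of transcripts removed at step 1,
~30% of survivors at step 2, ~8% of focal transcripts SSD).

What the generator does *not* emulate: cross-gene correlation,
GC/length biases, batch structure, partial within-line heterozygosity,
or dominance at genes without parental differences (pure over/under-
dominance, which the focal filter excludes by design).  Passing
recovery tests therefore validates the statistical machinery under the
model's own assumptions, not robustness to those violations.

Truth tables have one row per gene per cross.  SSD truth flags are
restricted to autosomes: a male dominance coefficient does not exist
under X hemizygosity, so X genes carry δ_f only.

## Numerical choices and degenerate inputs

Linear predictors are clipped to ±30 before exponentiation; singular
weighted normal equations fall back to least squares; all-zero genes
return the dispersion floor (1e−8) and are flagged.  Nested chains are
warm-started from the smaller model so likelihoods are monotone; a
full-model likelihood below a reduced one beyond 1e−6 triggers a refit
and, if persistent, a non-convergence flag.  LRT statistics are clipped
at zero.  Exact ties in orientation and in the greater/lesser
comparison are labelled explicitly rather than broken arbitrarily.
Seeded runs are bit-identical; the pipeline itself contains no
randomness.

## Known limitations

Per-gene dispersion without shrinkage needs ≥3 replicates per cell to
be usable, and the F-calibrated tests are mildly conservative at that
depth.  Sensitivity for sex-specific dominance is bounded by the focal
filter: genes whose parental difference is below ~0.5 log2 at modest
expression are invisible to the method regardless of how strong their
dominance reversal is (measured end-to-end sensitivity for planted
|δ_f − δ_m| ≥ 1 is ~0.8, not 1).  The δ estimator is a ratio of group
means and carries O(1/n) small-sample curvature bias at low counts.
The KS p-value is asymptotic, and the GO stage tests terms marginally,
ignoring ontology dependence.
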