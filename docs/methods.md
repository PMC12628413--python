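# Methods

This note documents the models implemented in `dustgeorisk`, the
parameter values they default to, the numerical choices made where the
conventions in the literature diverge, and what the test suite does and
does not establish.

## Data model

The universal input is a samples × elements matrix of total element
concentrations in mg/kg with one categorical group label per sample.
The canonical element order is (Pb, Cu, Zn, Ni, Cr, Mn, Fe). Group
labels are arbitrary for user data (at least two groups of two samples
are needed by the comparison statistics); the packaged dataset uses six
functional groups of four samples (N = 24). Concentrations must be
finite and non-negative; the log-based quantities (Igeo, PLI, the
supervised preprocessing) additionally require strictly positive values
and report zeros as missing or reject them, never silently.

Three built-in geochemical background sets are provided: average shale
(default; Pb 20, Cu 45, Zn 95, Ni 68, Cr 90, Mn 850, Fe 47,200 mg/kg),
upper continental crust, and mean crustal abundance. Backgrounds are
interchangeable at every call site.

## Contamination indices

CF = C/B; Igeo = log2(C/(1.5·B)), where the 1.5 factor absorbs natural
lithogenic variability. The exact identity Igeo = log2(CF) − log2(1.5)
is asserted by the tests. Composites operate on the per-sample CF
vector: Cdeg = ΣCF; PLI = geometric mean; NPI = √((CF̄² + CF_max²)/n).

Two conventions deserve emphasis:

* **NPI denominator.** The classical Nemerow form divides by 2; the
  variant replicated here divides by the element count n. The group and
  site values of the packaged dataset are only reproduced with the
  n-denominator, which is therefore the default;
  `nemerow_index(..., denominator=2)` restores the classical form.
* **Aggregation of nonlinear composites.** Group/overall Cdeg and PLI
  are arithmetic means of member-sample values (for Cdeg this equals
  the value of the mean profile, by linearity). Group and overall NPI
  are computed from the group-mean (respectively all-sample-mean) CF
  profile, because NPI is dominated by the maximum CF and the study
  being replicated reports profile-based values. Both conventions are
  hard-coded and verified against the packaged dataset.

Class scales: CF < 1 low, 1–3 moderate, 3–6 considerable, ≥ 6 very
high; Igeo classes 0–6 with half-open-left boundaries (class k covers
(k−1, k]); Cdeg boundaries 6/12/24; PLI bands at 1; NPI bands at
0.7/1/2/3, with interval edges assigned to the higher class wherever
the scale uses "≥". Note one documented discrepancy: the study labels
Cr (Igeo up to 0.26) "uncontaminated", although the standard scale puts
any positive Igeo in class 1; the implementation follows the standard
scale.

## Ecological risk

Er = Tr·CF with Tr = {Pb 5, Cu 5, Ni 5, Cr 2, Zn 1, Mn 1};
RI = ΣEr. The Mn weight of 1 is not part of Hakanson's published list
but is uniquely determined by the replicated study's per-sample table
(its Mn risk column equals the Mn CF column). Fe has no established
factor and is excluded from Er/RI with a log notice. Class bands:
Er < 40 low, 40/80/160/320; RI < 150 low, 150/300/600.

## Human health risk

Doses per pathway (mg/kg/day), with C in mg/kg:

* ADD_ing = C·IR_ing·ED·EF/(BW·AT)·UCF
* ADD_inh = C·IR_inh·ED·EF/(BW·AT·PEF)
* ADD_derm = C·SA·AF·DAF·ED·EF/(BW·AT)·UCF

UCF = 1e−6 kg/mg is the mass conversion (the inhalation route converts
through the particle emission factor PEF = 1.36e9 m³/kg instead). The
"CF" symbol often used for this conversion factor in the exposure
literature is renamed UCF here to avoid collision with the
contamination factor.

Default receptor scenarios (units: mg/day, m³/day, days/yr, yr, kg,
days, cm², mg/(cm²·day)):

| parameter | child | adult |
|---|---|---|
| IR_ing | 200 | 100 |
| IR_inh | 7.63 | 20 |
| EF | 350 | 350 |
| ED | 6 | 24 |
| BW | 15 | 70 |
| AT | 2190 | 8760 |
| SA | 2800 | 5700 |
| AF | 0.2 | 0.07 |
| DAF | 0.001 | 0.001 |

RfDs (ing/inh/derm, mg/kg/day): Pb 3.5e−3/3.52e−3/5.25e−4;
Cu 4e−2/4.02e−2/1.2e−2; Zn 0.3/0.3/6e−2; Ni 2e−2/2.06e−2/5.4e−3;
Cr 3e−3/2.86e−5/6e−5. CSFs ((mg/kg/day)⁻¹, all pathways): Pb 8.5e−3,
Ni 0.84, Cr 0.5.

Two deliberate replication choices, each with the orthodox alternative
selectable:

* **Carcinogenic averaging time.** The replicated study's cancer risks
  use the same averaging time as the non-carcinogenic model
  (AT = ED·365); the USEPA lifetime convention (AT = 70·365) is
  available via `lifetime_at=True` and scales the risks by ED/70.
* **Cr inhalation slope factor.** The replication default applies the
  oral slope factor (0.5) to all three pathways; the conventional
  inhalation value (42) is available via
  `ToxicityReference.orthodox_cr_inhalation()`.

Exposure uses the all-sample mean concentration by default (the
replicated study's convention); any element → concentration mapping can
be passed instead for per-sample or per-group runs.

## Group statistics

The comparison route per element: Shapiro–Wilk per group (reported
only, and flagged as low-powered at n = 4), Levene's test across
groups, then one-way ANOVA when variances are homogeneous (Levene
p > 0.05) and Welch's ANOVA otherwise. Levene centering defaults to the
group **median** (Brown–Forsythe): this is what reproduces the
replicated study's homogeneity statistics exactly, and it is the more
robust choice at these group sizes; mean centering is an option. A
zero-variance group makes Levene undefined; the route then falls to
Welch with a degenerate-input note. p-values below 1e−4 are displayed
as "< 0.0001". Welch's statistic carries a finite-sample denominator
correction, so it only converges to the classic F for equal variances
as group sizes grow — the tests assert the exact corrected identity.

Pearson correlations are labelled strong (|r| > 0.7), moderate
(0.4 ≤ |r| ≤ 0.7) or weak. Bartlett's sphericity uses
χ² = −(n − 1 − (2p + 5)/6)·ln det(R) with df = p(p−1)/2.

## Multivariate structure

PCA runs on the correlation matrix (i.e. z-scored concentrations);
components with unrotated eigenvalue > 1 are retained and
varimax-rotated with Kaiser normalization (SVD sweeps, tolerance 1e−6,
at most 100 iterations). Component signs are fixed so each component's
largest-magnitude loading is positive; components are ordered by
rotated sum of squared loadings, and explained variance is that sum
over p. Rotation preserves per-element communalities and the retained
total — both are asserted. Loadings with |value| ≥ 0.70 are flagged
strong.

Element-mode clustering uses Ward linkage on correlation distance
(1 − r); sample-mode uses Ward on squared Euclidean distance over
z-scored columns. Standardization in sample mode is the package's own
choice (an option disables it): with raw mg/kg the Fe column, three
orders of magnitude above the rest, would be the only effective
variable, which contradicts the multi-element cluster structure the
method is meant to expose.

## Supervised fingerprinting

Predictors are natural-log transformed and autoscaled; the fitted
transform is stored for reuse. Exception: the PLS-DA stage defaults to
autoscaled **raw** concentrations, which is what the replicated
analysis demonstrably used (its variable-importance profile is only
reproduced without the log step); the log route remains available.

* **MLR** — unpenalized multinomial logit (lbfgs, iteration cap 100),
  reporting −2LL, AIC, BIC, the likelihood-ratio test against the
  intercept-only null, and coefficients re-expressed against a
  designated reference class (default A2) with odds ratios. On
  separable data the fit proceeds to the cap with a convergence note;
  coefficients are then not uniquely determined and should be read
  qualitatively.
* **DTC** — Gini splitting with minimum leaf size 4. Several elements
  of the packaged dataset separate the same group blocks with identical
  impurity decrease, so the tree is tie-break dependent; the tie-break
  seed defaults to 7 and is recorded in the run. Variable importance
  follows the classical CART definition — each split's weighted
  impurity decrease credited to the primary variable and, scaled by
  adjusted agreement, to surrogate variables — normalised so the top
  predictor reads 100%. The cost-complexity path is evaluated under
  seeded 5-fold CV and the 1-SE selection is reported alongside the
  grown tree; training metrics quote the grown tree. One-vs-rest AUC
  per class is computed from leaf class-probability scores.
* **SVM** — RBF kernel, C = 1, gamma = 'scale', tolerance 1e−3,
  shrinking, one-vs-rest, probability outputs. Besides the standard
  all-data mode, a protocol mode trains on one representative sample
  per group (the sample nearest its group centroid in preprocessed
  space — the representative choice is the package's own, as no
  standard exists) and evaluates on all samples. Confidence scores from
  such 6-point fits are qualitative.
* **PLS-DA** — PLS regression against a numeric zone code (1..k in a
  fixed class order; one-hot coding optional). The component count is
  chosen by leave-one-out prediction error when not fixed. Reported
  diagnostics: per-component X- and Y-variance, VIP scores (the
  normalization identity mean(VIP²) = 1 is asserted; relevance
  threshold 0.8), standardized coefficients, per-sample leverage,
  Hotelling T² and residuals. With as many components as the predictor
  rank the predictions coincide with ordinary least squares, which the
  tests verify.

Cross-validation folds are seeded; they are stratified by group
whenever the per-class counts allow (with four samples per class a
5-fold scheme cannot stratify and falls back to a seeded shuffled
split).

## Synthetic data

The generator emulates the grouped structure of the packaged dataset:
per-(group, element) location/scale pairs, by default the group means
and within-group sample SDs of the packaged data. Draws are lognormal
with moment matching (σ² = ln(1 + cv²), μ = ln m − σ²/2), reflecting
strictly positive, right-skewed concentrations (the packaged Cu column
has CV ≈ 143%); a zero-truncated normal is available. Optional
inter-element correlation is applied to the underlying Gaussian (a
Gaussian copula in log space) through an eigendecomposition of the
target matrix, preserving positivity; the realised Pearson correlation
approximates the target (checked at r = 0.9, n = 500). A single integer
seed governs all draws.

What the generator does **not** emulate: spatial autocorrelation,
temporal drift, detection-limit censoring, and the exact multivariate
dependence of real dust (correlations are user-specified, not
estimated). Tests passing on synthetic tables therefore demonstrate
algorithmic correctness and parameter recovery, not field validity.

## Numerical and reporting conventions

* Sample SDs use the n−1 denominator throughout; CV% = 100·SD/mean.
* Published-table comparisons in the test suite mirror the display
  conventions of the replicated study where its printed cells derive
  from rounded intermediates (contamination factors rounded half-up to
  two decimals in the ecological-risk table; doses displayed at three
  significant figures feeding some hazard/risk ratios). The library
  itself always computes at full precision.
* Reports serialize numbers at full precision; rounding (two decimals
  for indices, three significant figures in scientific notation for
  risks) applies only to human-readable summaries.
* Pipeline reruns with the same config and seeds are byte-identical
  (timings are kept out of the consolidated report).

## Known limitations

* The ecological-risk weights cover the seven packaged elements only;
  other elements need user-supplied factors.
* Health risk is a deterministic point-estimate model: no Monte-Carlo
  exposure distributions, no bioaccessibility adjustment.
* No detection-limit (censored-value) handling; no enrichment-factor
  normalization.
* In-sample classifier metrics at N = 24 (four per class) measure
  separability of this dataset, not generalization; cross-validated
  accuracies are reported for that reason, and they are substantially
  lower.
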