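# Methods

This note records the models, the parameter choices that matter, and the
known limits of what the synthetic study can demonstrate.

## One-compartment kinetics and its calibration

Profiles follow C(t) = (D/(V/F)) · ka/(ka−ke) · (e^(−ke·t) − e^(−ka·t)),
the single-dose oral one-compartment model with first-order absorption.
Defaults: D = 1e8 ng (100 mg), ka = 0.219 h⁻¹, ke = 0.0735 h⁻¹,
V/F = 2e5 mL. These were calibrated so the closed-form time of peak,
ln(ka/ke)/(ka−ke), is 7.50 h, the terminal half-life ln 2/ke is 9.43 h,
and the peak concentration is ≈ 288 ng/mL — typical reported values for
a 100 mg oral dose of an SNRI-class drug in healthy volunteers. The
sampling grid defaults to 0, 0.5, 1, 2, 3, 4, 5, 6, 7, 7.5, 8, 10, 12,
24, 36, 48, 72 h. Inter-individual variability is log-normal with CV
30% on ka and 25% on ke and V/F (producing ≈ 25% CV on Cmax and AUC in
the cohort summary); proportional assay noise is log-normal with a
configurable CV (pipeline default 5%). If a subject's drawn ka collides
with ke the absorption rate is perturbed by 1%, since the closed form is
singular at ka = ke.

## Non-compartmental analysis

* AUC0–t uses the linear trapezoidal rule from dose to the last positive
  concentration. The linear rule is exact on piecewise-linear data and
  overestimates a convex exponential decay; on the default grid the bias
  against a fine-grid quadrature is under 3%.
* The terminal constant comes from OLS of ln C on t over a suffix window
  of k ∈ {3..8} positive points strictly after Tmax, choosing the window
  with the highest adjusted R² (ties toward more points). On noiseless
  two-exponential profiles this selects the latest window, where
  absorption contamination is smallest; the recovered ke is within 0.5%
  of truth (the residual −ka exponential biases it slightly low, so the
  estimated half-life on the default grid is 9.45 h rather than the
  analytic 9.43 h).
* Tmax ties break to the earliest time; zero concentrations are excluded
  from the log-linear fit; T½·Kel = ln 2 holds exactly by construction.

## Synthetic feature matrix

Feature log-intensities (natural log) are μ_f + b_sf + ε, with feature
means μ_f ~ N(12, 1.5), a subject random effect b_sf ~ N(0, 0.30) shared
between a subject's pre- and post-dose samples, and residual noise
SD 0.20. Post-dose samples of planted differential features are shifted
by a log-fold-change of random sign and magnitude uniform on
[1, 1.5]·(base magnitude 1). Planted metabolite–target dependencies are
written into the subject effect as b = σ·(γ·z ± √(1−γ²)·e), where z is
the standardized target (PK parameter or characteristic) and γ is found
by bisection so the realized sample distance correlation of the
generated post-dose vector against the target matches the requested
strength (tolerance 0.005). Coupled features stand in for identified,
well-measured metabolites: they get a reduced residual SD (0.05) and a
baseline-abundance floor (μ ≥ 12.5), and they are counted inside the
planted differential set so that they pass feature selection and reach
the network stage, as identified differential metabolites do in a real
analysis.

Injection order is a random permutation of the 2n biological samples
with one pooled-QC injection (feature-wise mean of the biological
samples, log-normal noise SD 0.05) after every 10th injection.
A random half of the features receive a monotone multiplicative drift in
injection order — a 50/50 blend of a linear ramp and a saturating
exponential from 1 to an end multiplier uniform on [0.8, 1.25].
Below-detection zeros are generated by censoring at a global detection
limit: the lowest 0.5% of all intensities read out as 0. Censoring (not
random masking) is the physically sensible mechanism and keeps
"below detection" attached to genuinely low signals.

What the generator does **not** emulate: chromatographic structure
(m/z, retention time, adducts, isotopes), correlated feature blocks from
shared compounds, batch changeovers, missing-at-random dropouts, or
heavy-tailed biological variation. Passing tests therefore demonstrate
the statistical machinery under idealized log-normal data, not
performance on real LC-MS output.

## Preprocessing choices

The stage order is fixed: drift correction → zero imputation → IQR
filter → QC-RSD filter → log/Pareto. The drift smoother is LOWESS
(span 0.75) on QC intensity vs injection order, interpolated to all
injections, divided out, and rescaled to the feature's QC median;
features with fewer than 3 positive QC values fall back to a global
median-ratio normalization. A random-forest QC normalizer would also
satisfy this contract; the local-regression smoother was chosen because
it is deterministic, dependency-free and directly testable against the
generator's known drift curves. The zero-replacement minimum is global
over the matrix (per-feature available via flag); the IQR rank uses
biological samples only; the log base is 10. Pareto scaling divides by
√SD so that high-abundance features do not dominate distance-based
statistics as they would under no scaling, while inflating noise less
than full autoscaling.

## Paired moderated-t selection

With exactly one pre and one post sample per subject, the blocking
factor is eliminated by differencing (post − pre), which is equivalent
in expectation to a mixed model with a consensus intra-subject
correlation but deterministic and exactly testable; this is a documented
deviation from the reference implementation's blocking mechanism. The
design is intercept (dose effect) + sex + centered age + centered BMI +
period; constant columns are dropped with a warning. Hyperparameters
(d0, s0²) come from matching the first two moments of log s²_g through
digamma/trigamma inversion, with two reference-matching details: the
moment equation uses the ddof-1 variance of the log residual spread, and
when the spread is no larger than sampling noise d0 = ∞ and s0² is the
mean of the s²_g. The total df for p-values is capped at the pooled
residual df. A cross-check test reproduces the reference R
implementation's (d0, s0², t, p) to 1e-8 on shared input.

## Distance-correlation network

The V-statistic (biased) estimator is used: dCor² = mean(A∘B) /
√(mean(A∘A)·mean(B∘B)) over doubly centered |xᵢ−xⱼ| matrices. It lives
on [0, 1], matching the retention rule d ≥ 0.5; the unbiased estimator
can be negative and would not. Constant vectors get dCor = 0 with a
warning. The permutation p-value is the add-one estimator
p = (1 + #{d_perm ≥ d_obs})/(1 + n_perm). Its floor is 1/(n_perm+1), so
for BH at level α over m pairs with k true signals one needs
m/(k·(n_perm+1)) ≤ α: the per-call default stays 1000, but the pipeline
default is 5000 permutations so the default 40-metabolite × 20-target
family can retain its edges. Within the association stage one
permutation null tensor is built per target and shared across
metabolites — still a valid seeded permutation test, ~50× faster.
The BH family is all metabolite × target pairs within one phase; the
Pearson sign is stored as an edge attribute and not used as a negative
weight (communities are found on dependence magnitudes). Leiden runs on
the RB-configuration objective, which equals modularity at the default
resolution 1.0, with an explicit seed; module ids are relabeled by
decreasing size with lexicographic tie-breaks, so runs are bit
reproducible. Targets with no retained edge are omitted from the graph.

## Enrichment and integration

One-sided hypergeometric (Fisher enrichment direction) per pathway, with
membership intersected with the background first. The background is the
set of identified metabolites entering the analysis (in the pipeline:
all features surviving preprocessing), not the full annotation universe;
pathway size is counted after background intersection. Only pathways
with intersected size in [5, 150] enter the BH family; retention then
requires ≥ 2 hits and q ≤ 0.05. The rollup ranks top-level groups by
distinct hit metabolites (ties alphabetical). The integrated report
emits one row per retained edge whose metabolite and target share a
Leiden module, labeled with every retained pathway containing the
metabolite as "top level (sub-pathway)" joined by "/", or the fallback
"Individual evidence in the literature (N/A)".

The pathway fixture is synthetic: random member sets over the feature id
space with Reactome-style labels, optionally seeding a fraction of
pathways from the planted differential set so the enrichment and
integration stages have true positives to find.

## Problem sizes and reproducibility

Default study conditions mirror the target design: 35 subjects, one
pre and one post sample each, QC every 10 injections, 500 features with
50 differentials, association strengths 0.7–0.8. Test-suite and
acceptance computations use these sizes (some calibration loops use 200–
300 features per replicate, 10–20 seeded replicates) — sizes chosen as
the package's own balance between statistical resolution and quick
feedback. One seed drives every stage; stage seeds are small fixed
offsets of it, and permutation and Leiden randomness are both seeded, so
a rerun with the same config is bit-identical.

## Known limitations

* The NCA terminal fit assumes a mono-exponential tail; profiles with
  pronounced multi-phase disposition will bias Kel low.
* Paired differencing cannot use subjects with replicate samples per
  phase; the design requires exactly one pre and one post sample.
* The permutation p floor ties edge retention to the permutation budget
  (arithmetic above); very large association families need
  proportionally more permutations.
* The IQR filter ranks raw-scale dispersion and therefore mostly removes
  low-abundance features; that matches common practice but is not a
  variance filter on the log scale.
* Distance correlation at n = 35 has limited power below d ≈ 0.5; the
  retention threshold is part of the method, not a tunable significance
  level.
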