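# Methods

`rmdose` estimates the absorbed dose to red marrow during
[¹⁷⁷Lu]Lu-DOTATATE therapy from image-derived time–activity concentrations,
separating receptor-mediated ("specific") marrow uptake from the blood-borne
("nonspecific") background. This note documents the model, the numerical
choices, and what the synthetic cohort does and does not establish.

## Units

Time is hours post-injection everywhere; the conversion to seconds (×3600)
happens only inside the dose step, because S values are per MBq·s. Activity
concentration is MBq per cm³ of VOI per GBq administered, so doses come out
in Gy/GBq. S values are mGy/MBq/s (÷1000 at the dose step).

## Blood input function

The descending-aorta VOI concentration stands in for the blood concentration
and is fitted with a biexponential,

    C_blood(t) = A1·exp(−λ1 t) + A2·exp(−λ2 t),

by bounded trust-region least squares (unit weights) with multi-start
initialization: rates seeded from log-linear fits to the early and late
curve segments, amplitudes from non-negative least squares given the rates,
plus a single-exponential fallback candidate, so the returned residual never
exceeds the best single-exponential fit. Data are max-normalized before
fitting (the fit is scale-equivariant); the fast term is reported first
(λ1 ≥ λ2). Physical decay of ¹⁷⁷Lu is folded into the rates because
activities are measured in situ.

Identifiability guards. With 4 samples and 4 parameters the least-squares
problem is an interpolation problem, and exact interpolants exist whose
fast component back-extrapolates to an absurd concentration at t = 0 —
invisible to the data (first scan ≈ 4 h) but catastrophic for the [0, ∞)
integral that dosimetry multiplies. Three constraints keep the fit
physical:

1. **Rates ≥ ¹⁷⁷Lu physical decay** (ln2/159.5 h⁻¹): in-situ activity
   cannot decay slower than physical decay.
2. **Amplitude caps**: each amplitude ≤ 100× the curve maximum (a fast
   half-life shorter than ~25–40 min is unobservable and implausible with
   a first scan at ~4 h), and, in the package's standard units, ≤ 1.0
   MBq/cm³ per GBq — the administered activity dissolved in a minimal ~1 L
   blood volume. Pass `max_initial_concentration=None` for arbitrary-unit
   data.
3. **Equivalence-band selection**: multi-start solutions whose residuals
   differ by less than 0.1% of the curve maximum are observationally
   indistinguishable (quantitative SPECT is accurate to a few percent at
   best); among them the solution with the smallest extrapolated integral
   A1/λ1 + A2/λ2 is returned. This systematically prefers the conservative
   extrapolation over interpolants that hide a large unobserved bolus.

## Compartment model

The specific concentration at a skeletal site or tumor obeys

    dC_spec/dt = k1·f·C_blood(t) − k2·C_spec(t),    C_spec(0) = 0,

where f (dimensionless, 0–1) maps blood concentration onto the nonspecific
concentration in the marrow cavity, k1 (h⁻¹) is the uptake rate and k2
(h⁻¹) the release rate. The measured tissue curve is modelled as
f·C_blood + C_spec. With a biexponential input the solution is closed-form,

    C_spec(t) = k1·f·Σᵢ Aᵢ/(k2−λᵢ)·(e^(−λᵢ t) − e^(−k2 t)),

with the limit term k1·f·Aᵢ·t·e^(−k2 t) when |k2−λᵢ| < 1e−10 h⁻¹ (the
switch threshold is far below the level at which the subtractive form loses
precision).

Fitting minimizes the unweighted RMSE at the observed time points over a
grid — k1 log-spaced on [1e−4, 1] h⁻¹ (25 points), k2 log-spaced on
[1e−4, 0.2] h⁻¹ (25 points, bracketing the observed effective half-lives of
83–94 h), f on [0, 1] in steps of 0.02 — followed by local refinement.
Because 4-point designs leave several shallow near-optimal basins, the five
best coarse candidates are each refined with two passes of 5×-finer local
grids (final resolution ≈1.6% in the rates, 0.0008 in f); ties break toward
smaller k1, then k2, then f. An all-zero curve returns k1 = 0, f = 0 with a
warning. f is searched jointly with (k1, k2) rather than fixed from
anatomy.

**Effective half-life** is ln2/λ from a log-linear fit to the specific
concentration strictly later than 48 h — measured samples when a curve is
given, or a 1 h grid over (48, 170] h when a fitted model is given.

## Dosimetry

Concentration–time integrals are scaled to time-integrated activities with
the packaged reference constants (University of Florida male/female hybrid
phantom; RM←RM S values, red-marrow volumes and volume fractions per site;
ICRP 70 cellularity is carried but enters no equation):

    TIA_spec = k1·f·(A1/λ1 + A2/λ2)/k2 · f_RM · V_RM · 3600
    TIA_nonspec =        (A1/λ1 + A2/λ2) · f_RM · V_RM · 3600
    D_RM = (TIA_spec + TIA_nonspec) · S / 1000          [Gy/GBq]

The nonspecific term deliberately omits the fitted f: it assumes
blood–marrow concentration equivalence (the plasma-fraction constant
belongs to the cavity mixture model during fitting, not to the dose
bookkeeping). The sums in the dose equations are read as time integrals of
the fitted continuous curves over [0, ∞) — that is the quantity an S value
multiplies; a four-point sum has no consistent units.

The blood-based comparator applies the skeletal-average constants directly
to the blood integral (the EANM-style whole-skeleton estimate):

    D_blood = S_avg · (A1/λ1 + A2/λ2) · f_RM,avg · V_RM,avg · 3600 / 1000.

The delineated T9–L5 vertebrae use the combined T/L reference row by
default (the VOI spans both regions); `PipelineConfig.vertebrae_row`
exposes the T-only and L-only rows. When a patient's sex is unrecorded,
female constants are used with a logged warning (the larger S values — the
conservative choice). Summary SDs use the sample (n−1) convention; report
tables round half-up to 3 decimals. Exclusions (e.g. a patient with
metastases in every analyzed site) are an explicit list, never
auto-detected.

## Synthetic cohort

The generator emulates the study design, not its patients: 17 patients
(≈41% with bone metastases), four scan times drawn from N(4.1, 1.1²),
N(18.8, 2.4²), N(53.0, 21.8²), N(169.6, 10.6²) h, truncated above 0.5 h and
sorted; multiplicative log-normal noise with CV 7% on every measurement
(SPECT concentration errors scale with signal).

Parameter medians and their rationale:

| parameter | median | why |
|---|---|---|
| blood A1, λ1 | 0.24 MBq/cm³/GBq, ln2/1.5 h⁻¹ | fast distribution half-life ~1.5 h; t=0 concentration ≈ administered activity in ~4 L blood |
| blood A2, λ2 | 0.0025, ln2/11 h⁻¹ | terminal blood half-life ~11 h, the standard figure for this compound; together the integral puts the skeletal-average blood-based dose near 0.013 Gy/GBq |
| vertebrae k2 | ln2/94 h⁻¹ | observed specific-uptake effective half-life |
| hip k2, tumor k2 | ln2/85, ln2/83 h⁻¹ | likewise |
| f | 0.2 (0.1 adipose) | plasma fraction of the cavity volume |
| k1 | 0.059 (vert), 0.061 (hip), 0.15 (tumor), 0 (adipose) | sets the specific/nonspecific dose ratio k1·f/k2 to ≈1.6/1.5, matching the reported ~50% excess of specific over nonspecific uptake |
| bone-met vertebral k1 | ×2.0 | elevated uptake in involved vertebrae |
| between-patient spread | lognormal, σ(log)=0.25 | moderate biological variability; draws are independent (the true covariance of (k1, k2, f) is unknown) |

Adipose tissue has k1 = 0 (pure plasma background), mirroring its observed
blood-like biodistribution.

What a green synthetic test establishes: the estimators recover the
parameters and orderings of data generated by the model the pipeline
assumes, at the study's sampling design and noise level. What it does not:
image-domain effects (partial volume, spill-in from adjacent tumors,
delineation error), inter-patient covariance of kinetics, deviations from
biexponential blood kinetics, or recirculation of tumor-released ¹⁷⁷Lu.
In particular the half-life regression (difference site−tumor vs tumor)
produces a negative slope in the synthetic world purely by regression to
the mean — site and tumor half-lives are generated independently — so that
regression here checks the statistical machinery, not the transferrin
hypothesis.

## Numerical notes and limitations

* The grid search evaluates all (k1, k2, f) combinations vectorized;
  a full fit costs ~20 ms.
* Exact recovery of on-grid truth from noiseless data is guaranteed
  (the truth point is evaluated and ties break toward it only if equal);
  off-grid truth is recovered to the local-grid resolution when the scan
  design identifies it, and only to the coarse-grid scale when it does not
  (e.g. a third scan drifting past 90 h).
* Doses from a 4-point design inherit the blood-integral uncertainty: the
  head of the blood curve (0 to ~4 h) is extrapolated, not measured. The
  guards above bound, but cannot eliminate, this uncertainty.
* Only RM←RM self-dose is computed (no cross-fire from other organs), and
  no tumor dosimetry — tumor curves serve the half-life comparison only.
* The per-patient doses of the original cohort cannot be recomputed from
  scratch (the images are not public); the packaged per-patient dose table
  anchors the summary arithmetic instead.
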