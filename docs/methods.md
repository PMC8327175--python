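# Methods

## Respiratory-mechanics model

Virtual patients are linear single-compartment respiratory systems with
the lung and chest wall in series: respiratory-system elastance
`Ers = EL + Ecw` (cmH2O/L) and airway resistance `Rrs` (cmH2O·s/L).
Under volume-controlled ventilation the airway pressure follows the
equation of motion `Paw(t) = PEEP + Rrs·V̇(t) + Ers·V(t)` and the
esophageal pressure `Peso(t) = P_pl,0 + Ecw·V(t)` plus a cardiac
sinusoid (1.3 Hz, default amplitude 1 cmH2O) and Gaussian sensor noise
(defaults: 0.2 cmH2O on Paw, 0.3 cmH2O on Peso). During the occlusion
pauses flow is zero, so the noiseless plateau is exactly
`PEEP + Ers·TV` and the Peso tidal swing exactly `Ecw·TV` — these are
the closed-form oracles the analysis chain is tested against.

The model is deliberately linear: no volume-dependent elastance and no
spontaneous effort (the target population is sedated and paralyzed).
Expiration is passive-exponential with time constant `Rrs/Ers`,
truncated and rescaled so each breath empties completely.

### Discretization

Waveforms are sampled at 100 Hz (EIT at 20 Hz; both configurable,
typical of ICU monitors and EIT devices). Flow-profile amplitudes are
scaled so that the *discrete trapezoidal* integral of each inspiratory
run equals TV exactly and each full cycle integrates exactly to zero: a
zero-bounded sample run integrates to `dt·Σsamples` under the trapezoid
rule, so a single scale factor per phase makes volume conservation
exact rather than O(dt) accurate. A leading zero sample makes every
breath's bounded run identical. This is what lets the noiseless
round-trip tests assert `Pplat − PEEP = Ers·TV` to 1e-6 cmH2O at an
ordinary sampling rate.

## Breath analysis

Breaths are segmented at flow upcrossings of `min_insp_flow` (default
50 ml/s, walked back to the zero-crossing); tidal volume is the
trapezoidal integral of the initial positive-flow run. Occlusion
windows are runs with |flow| < 10 ml/s lasting ≥ 0.2 s — the first
after peak volume (inspiratory) and the last before the next breath
(expiratory). Pause pressures are read as the **median of the final
half** of the window: a single-sample read would alias the cardiac
artifact, whose amplitude (≈1 cmH2O) is of the same order as the
pressures' tidal resolution, while the median over ≥0.1 s suppresses
it and any transient at pause onset.

Per-breath landmarks are averaged over the last up-to-10 usable breaths
and the mechanics formulas applied to the averages (the
formulas-then-average alternative is available via `per_breath=True`;
the two differ only at second order). End-expiratory P_L may be
negative and is never clamped. PEEPtot is the measured expiratory-pause
airway pressure, so intrinsic PEEP is included by construction.

## EIT regional analysis

The tidal image is the mean, over the last up-to-10 breaths, of the
end-inspiratory minus end-expiratory pause-window frame medians —
aligning the EIT quantities with the same pressure landmarks used by
the mechanics. Negative tidal pixels (pendelluft or artifact) are
floored at zero and counted. ROI bands are the four equal-height
horizontal quarters of the 32×32 image (row 0 most ventral): the
vendor's anthropometric lung contouring is proprietary, and equal bands
are the standard, openly stated fallback. ROI fractions computed from
the ensemble image (rather than per breath then averaged) are the
implemented route; for noiseless data the two coincide.

Regional compliance is `RC_ROI_i = TV·(ROI%_i/100)/DP/IBW`
(ml/cmH2O/kg); the four values sum to the IBW-specific compliance
`(TV/DP)/IBW` identically.

## The prediction model

`DrivingPressureRegressor` is a scikit-learn estimator holding the
five-regressor linear equation. Two fitting conventions exist for
panel data; the description "pooled OLS with patient ID as a fixed
factor" is internally contradictory (pooled OLS has no unit dummies),
and plain OLS on the stacked rows is the convention that reproduces a
self-evaluation Bland-Altman bias of zero to machine precision, so it
is the default; a fixed-effects within-estimator is provided
(`method="within"`) for sensitivity analysis. Note that IBW is constant
within patient, so the within transform annihilates its coefficient —
a structural property, not a bug.

Two unit conventions had to be pinned down:

* `EL_EIT` is computed as `DP_L,EIT / TV` (cmH2O/L). The reciprocal
  form appears in some descriptions but is dimensionally inconsistent
  with `EL = DP_L/TV`; the chain `DP_L → EL → PI` is tested to be
  invariant to the ml↔L bookkeeping.
* ROI percentages enter on the 0–100 scale: with the reference
  coefficient γ ≈ −0.21 a ventral fraction of ≈19% contributes ≈−4
  cmH2O, which is physiologically plausible only on that scale.

Reference coefficients are stored at full printed precision and never
rounded internally. No regularization or interaction terms: the model
is a plain five-regressor OLS by design.

## Agreement statistics

Written from first principles (and cross-checked against an independent
implementation in the test suite):

* **rmcorr** — within-subject centering of both variables, pooled
  correlation of the deviations (equivalently ANCOVA with subject
  intercepts and a common slope), `df = n_obs − n_subjects − 1`,
  two-sided p from the t distribution. Subjects with <2 complete pairs
  are excluded; missing pairs are dropped listwise.
* **Bland-Altman** — bias = mean difference, limits of agreement =
  bias ± **2**·sd (sample sd, n−1). The multiplier 2 rather than 1.96
  follows the reported convention; 1.96 is available via argument.
* **Simple regression** — OLS slope/intercept, R² as squared Pearson
  correlation, p from the slope t-test.

No multiple-testing correction is applied by default (raw p-values are
the reported convention). A `quality_ok` flag column on cohort tables
is honored by all statistics, mirroring per-measurement quality
control.

## Synthetic cohort conditions

The cohort generator's defaults encode the study population: 20
patients × 3 PEEP conditions; covariates centered on the cohort medians
(IBW 65 kg, Ers 27 cmH2O/L, ROI% 19/37/31/13) with spreads set from the
interquartile ranges via sd ≈ IQR/1.35 (Ers 9, roi1 5, roi2 6.5,
roi3 6; IBW 8); Ers truncated to [5, 80] cmH2O/L and ROI% to [0, 100];
severity strata map EL to mild [8, 15], moderate [12, 30], severe
[25, 45] cmH2O/L with Ecw in [5, 15] — bracketing the cohort EL median
of 18 [14–23]. PEEP conditions are a per-patient clinical base
U(8, 14) cmH2O with offsets −3/0/+3; the ventilation distribution
shifts dorsally with PEEP, linearly in PEEP then renormalized. IBW uses
the Devine formula (male 50 + 0.91·(height − 152.4); female 45.5 +
0.91·(height − 152.4)); a user-supplied IBW overrides it.

`equation` mode generates the measured DP_L directly from the reference
equation plus Gaussian noise (default sd 1.2 cmH2O, the scale implied
by limits of agreement of ±2.4); `mechanistic` mode simulates the full
signal chain per measurement and lets the analysis derive everything.
Acceptance-style experiments use 60-row (20×3) panels for the
self-evaluation bias and 300-row (100×3) panels for coefficient
recovery; the rmcorr recovery panel is 200 subjects × 3 pairs.

What the generator does **not** emulate: nonlinear or time-varying
mechanics, recruitment/derecruitment hysteresis, spontaneous effort,
real EIT reconstruction artifacts, electrode drift, or anatomically
realistic impedance images (band signals are spread uniformly within
each band). Passing tests therefore demonstrate the correctness of the
computation chain and the statistical machinery under the stated
generative model — not clinical performance on real recordings.

## Numerical choices and degenerate inputs

* All randomness flows through explicit `numpy.random.default_rng`
  seeds; identical seeds give bit-identical cohorts and pipeline
  outputs.
* Zero tidal volume yields flat pressures (no division by zero);
  infeasible breath timing raises an error naming the violated
  constraint; absent pauses flag the breath unusable rather than
  crashing; `ers ≤ 0` after averaging is rejected as non-physiologic.
* Pressure-ordering violations (`ppeak ≥ pplat ≥ peep_tot`) under noise
  are flagged, not fatal.
* Rank-deficient design matrices abort the fit and name the collinear
  columns.
* In the pipeline, a failing measurement is excluded and logged with
  its identifier; the run aborts only if more than half fail, and the
  manifest's accounting (generated = analyzed + excluded) always
  reconciles.

## Known limitations

The equal-band ROI definition and the uniform within-band image model
are simplifications of device-specific processing; the reference
coefficients were estimated on data from one EIT device and the package
makes no claim of transferability across devices. Regional (per-ROI)
transpulmonary pressure estimation and ΔEELV/PEEP-step elastance
methods are out of scope.
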