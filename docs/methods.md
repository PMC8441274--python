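# Methods

This note documents the models, estimators, defaults and numerical
choices behind `ossindent`, and what the synthetic-data generator does
and does not emulate.

## Units

Instrument units throughout: load mN, depth nm, time s. Conversions are
exact: 1 mN/nm² = 10⁶ GPa for moduli and hardness, 1 mN·nm = 1 pJ for
energies. Indentation energies are reported in pJ; the natural scale of a
~2–3 mN, 500 nm indent is hundreds of pJ, and the package does not
rescale to nJ.

## Forward model of an indentation site

A site is described by `MaterialTruth`: specimen modulus `E_s` (GPa),
Poisson ratio `nu_s` (0.3 default for bone tissue), resistance to plastic
deformation `H_true` (GPa), creep amplitude (nm), thermal drift rate
(nm/s) and depth-noise SD (nm). The four protocol phases
(`IndentationProtocol`) follow the displacement-controlled bone protocol:
load at 0.25 mN/s until the depth reaches 500 nm, hold 60 s at maximum
load, unload at the same rate to 10% of maximum load, hold 100 s there.

* **Loading** follows the conical elastic–plastic series model
  `h(P) = sqrt(P/C_e) + sqrt(P/C_p)` with
  `C_e = (2/pi) E_r tan(psi)` (psi = 70.3°, the Berkovich-equivalent cone)
  and `C_p = 24.5 H_true` in instrument units, where `E_r` combines the
  specimen with the diamond tip (E_i = 1141 GPa, nu_i = 0.07).
* **Creep** during the load hold is logarithmic,
  `creep_amp · ln(1 + t/10 s)`: the standard shape for bone at constant
  load, with a single free amplitude (default 5 nm). The 10 s time
  constant is fixed.
* **Unloading** is the power law `P = B (h − h_f)^m` anchored at the
  post-creep peak, with `(B, h_f, m)` chosen so the tangent at the peak
  equals the stiffness implied by the Oliver–Pharr fixed point
  `S = 2 beta E_r sqrt(C0/pi) · (h_max − eps P_max/S)` (solved in closed
  form). The exponent interpolates between 2 (pure elastic parabola) and
  1.35 (typical experimental value) according to the plastic share of the
  depth. For `H_true = inf` the unloading branch retraces the elastic
  loading parabola exactly. Anchoring at the fixed point makes the
  forward→inverse round trip exact on noise-free curves, which is what a
  self-consistency test should require.
* **Drift and noise.** Linear drift `drift_rate · t` (default 0.05 nm/s)
  and i.i.d. Gaussian depth noise (default 2 nm; the noisy-recovery
  studies use 5 nm ≈ 1% of the target depth) are added to depth only —
  the load channel is commanded, hence clean, under displacement control.
* **Sampling density.** Curves are sampled at 300 Hz (~2000 samples in
  the unloading segment), a density typical of commercial depth-sensing
  platforms. A Cramér–Rao analysis of the three-parameter unloading fit
  shows the stiffness precision targeted by the recovery studies (median
  error < 3% at 1% depth noise) requires roughly this many unloading
  samples; at 10 Hz the information bound alone is ~21%.

## Curve reduction

1. **Segmentation** assigns the four phases from sign changes of the load
   rate (threshold 10% of the peak rate), in fixed protocol order. P_max
   is the median hold load; h_max is the mean depth over the last second
   of the hold (creep there is negligible, and averaging ~300 samples
   reduces the depth noise to ~0.3 nm). A missing loading or unloading
   ramp is an error; an empty creep hold is tolerated.
2. **Drift correction** regresses depth on time over the low-load hold,
   excluding its first 20 s (settling), and subtracts `rate · t` from all
   depths — exactly the form the generator applies. If the hold is absent
   or shorter than the exclusion window the curve passes through
   uncorrected with a warning.
3. **Unloading fit.** `P = B (h − h_f)^m` over the top 80% of the
   unloading load range. Two estimator choices matter at realistic noise:
   residuals are taken on the *depth* channel
   (`h = h_f + (P/B)^(1/m)`), because depth is the noisy measurement —
   fitting load residuals against noisy depth suffers classic
   errors-in-variables attenuation (~30% low on S at 1% noise); and the
   power law is *anchored at the measured peak* (h_max, P_max), reducing
   the free parameters to (h_f, m). Multistart on m ∈ {1.2, 1.5, 2.0},
   bounds m ∈ [1, 2.5] with a warning at a bound, lowest depth-RMS wins.
   Stiffness `S = B m (h_max − h_f)^(m−1)`.
4. **Oliver–Pharr.** `h_c = h_max − eps P_max/S` (eps = 0.75 default;
   `CONE_EPSILON` = 2(π−2)/π ≈ 0.727 is provided and is the exact value
   for an ideal cone — the Sneddon-oracle test uses it, since 0.75 on a
   true cone is intrinsically ~1.9% high), area `A = C0 h_c²` with
   C0 = 24.5 by default plus optional polynomial calibration terms,
   `E_r = sqrt(pi)/(2 beta) · S/sqrt(A)` (beta = 1.0 default, 1.034
   optional), specimen modulus from
   `1/E_r = (1 − nu_s²)/E + (1 − nu_i²)/E_i`, and `Hc = P_max/A`.
5. **Loading decomposition.** `K` is estimated from
   `1/sqrt(K) = sum(h sqrt(P))/sum(P)` over the loading branch (depth
   residuals again), excluding the first 20% of depth where
   surface-detection noise dominates. Then
   `1/sqrt(C_p) = 1/sqrt(K) − 1/sqrt(C_e)` and `H = C_p/alpha1` with
   alpha1 = C0. A loading branch elastic to within tolerance yields
   `H = inf` ("no measurable plasticity", capped at 100 GPa); a branch
   stiffer than the elastic limit by more than 2% is a hard error.
6. **Energies.** Trapezoidal `∫P dh` over loading-plus-hold gives
   U_total (the creep hold does work at constant load), the magnitude of
   the unloading integral gives Ue, and Up = U_total − Ue by definition.
   The last pre-unloading sample is prepended to the unloading integral
   so both integrals share the peak vertex; without it the partition is
   systematically off by the top sliver and piecewise-linear toy curves
   are not integrated exactly. Note Ue only counts work recovered down to
   the 10% hold load where the protocol stops; on a purely elastic
   protocol curve ~3% of the stored energy sits below that load and shows
   up in Up.
7. **Aggregation.** Cortical: mean/SD over valid sites. Cancellous: each
   trabecula's sites are averaged first, then mean/SD across trabecula
   means — so an unbalanced trabecula still contributes exactly one
   value. Failed sites are excluded and counted, never interpolated.

## Histomorphometry

Indices per envelope (cancellous, intracortical, endosteal):
surface fractions are `100 · length/BS`; O.Th and W.Th are means of their
reading lists; `BV/TV = 100 · bone_area/tissue_area`;
`Tb.Th = 2 · bone_area/bone_perimeter` (parallel-plate model, no
obliquity correction); `Tb.N = (BV/TV)/Tb.Th` per mm — Tb.N is reported
per mm, the dimensionally consistent unit for a plate-model derivation.
Dynamic indices with a 14-day label interval:
`MS/BS = 100 (dLS + sLS/2)/BS` (double plus half of single label, the
recommended convention), `MAR = mean interlabel distance / 14 d` when
double labels exist, `BFR/BS = MAR · (MS/BS) · 365` (annualized — the
μm³/μm²/year unit demands the factor), `Ac.f = (BFR/BS)/W.Th`.

Imputation: single-label-only surfaces get the minimum detectable
MAR = 0.3 μm/day; label-free surfaces get *missing* MAR (empty field in
every serialization, never 0) and exactly zero MS/BS, BFR/BS and Ac.f.
The identity `Ac.f · W.Th = BFR/BS` holds to machine precision for every
labeled envelope. The 0.3 floor applies only to single-label surfaces; a
double-label MAR below 0.3 is reported as computed.

## Cohort generator

`CohortSpec` defaults mirror the study design: 16 subjects per arm,
durations 7.4 ± 4.8 vs 11.6 ± 4.9 years, 60 cortical sites and
5 trabeculae × 12 sites per subject. Site-level properties follow a
subject random-intercept model: the between-subject SD equals the group
summary SD and the within-subject SD follows from the intraclass
correlation (`icc`, default 0.5 — a configurable guess, since
within-subject variance of indentation properties is rarely reported).

Nanomechanical group means are anchored to representative published
per-curve values (cortical E 16.2 vs 18.6 GPa, H 1.178 vs 1.63 GPa);
cancellous moduli are equal across groups (no group difference is
expected there). The 2.0 GPa between-subject SD for E is a typical
spread for human bone tissue; H and Hc use 0.25/0.12 GPa. In the forward
pipeline Hc and the energies are *derived* from each site's curve, so
only E and H act as generating truths for curve simulation; the directly
drawn Hc column in the site table serves the statistics stage only.

Two label modes: observational (`or_per_gpa=None`) fixes group sizes and
draws every variable from its group normal; mechanistic (`or_per_gpa`
numeric) draws subject-mean cortical E from a single pooled normal and
the AFF label from `logit p = log(or_per_gpa) · (E − mean)`, making
`or_per_gpa=1` an exact null (label independent of E, coin-flip groups).
Using the subject *mean* as the linear predictor keeps the generating OR
interpretable per GPa.

Histomorphometry primitives are drawn so derived indices land on the
published group summaries; configurable fractions of subjects
(defaults 0.30 no-label, 0.20 single-label, consistent with severely
suppressed turnover where many envelopes carry no tetracycline label)
exercise the imputation paths. Primitives are generated at the
measurement-table level; no image synthesis.

## Statistics

* Group summaries: mean ± SD (n−1), per group, with n.
* Unpaired t test: Student pooled-variance by default, Welch optional;
  raw vectors are reduced to summaries and routed through the identical
  computation, so both input forms give identical (t, df, p).
* Odds ratios: AFF status on treatment duration plus one property.
  Site-level tables: exchangeable GEE clustered by subject with
  bias-reduced (Kauermann–Carroll/Mancl–DeRouen) robust SEs, the
  appropriate sandwich below ~50 clusters. **Caveat**: when the outcome
  is constant within subject and the predictor varies between sites, the
  exchangeable working-correlation estimate approaches 1 and the
  fitted coefficient of the site-varying predictor collapses toward
  zero; this is a property of the estimator, not a bug, and it is why
  the subject-level fit is the package's primary estimator for OR
  recovery. Subject-level tables: ordinary logistic regression, Wald
  95% CI, p-value from the likelihood-ratio test (better calibrated
  than Wald at a few dozen subjects: ~6% vs ~2% empirical type-I at the
  nominal 5%, n = 32). Perfect separation is flagged and the CI reported
  as unbounded, never fabricated. No multiple-testing adjustment
  (α = 0.05 per variable).

## Calibration facts established by simulation

(Computed by the test suite and `scripts/acceptance.py`; sizes chosen to
keep each study under a few minutes on one CPU.)

* Sneddon cone oracle (E_r = 20 GPa): E_r recovered within 0.05%,
  plastic energy < 1% of total.
* Noise-free forward→inverse round trip: E and H exact to numerical
  precision across E ∈ [10, 30] GPa × H ∈ [0.5, 2.5] GPa.
* With 1% depth noise, 20 replicates per grid point: median |ΔE|/E ≈
  2.6%, median |ΔH|/H ≈ 2.5%, median stiffness error ≈ 2.5%.
* OR recovery (32 subjects × 60 sites, true OR 1.15/GPa, 500
  replicates): geometric-mean OR within a few percent of truth (the MLE
  carries a small away-from-null bias at n = 32, and 10% of the true
  log-OR is only ~1.5 Monte-Carlo SDs of a 500-replicate mean, so this
  quantity is intrinsically seed-sensitive); Wald CI coverage 95–97%;
  null type-I ~6% with the LR test.
* Null-calibration of the generator+estimator pair (OR within
  [0.8, 1.25] in ≥90% of replicates) requires se(log OR) ≲ 0.136, i.e.
  ≈128 subjects at the 2 GPa modulus SD; the property test sizes it
  accordingly. At the study's own n = 32 the estimator's sampling SD
  (~0.21) makes that band unreachable for any unbiased estimator.

## What the generator does not emulate

Real indentation data exhibit surface-detection errors, tip-area
miscalibration, pile-up/sink-in beyond the Oliver–Pharr assumptions,
spatially correlated tissue heterogeneity (osteonal vs interstitial
sites), and non-Gaussian vibration noise; the generator's truths are
draws from the same model family the reduction assumes. Passing
recovery tests therefore demonstrates internal consistency and estimator
calibration — not robustness to model misspecification on real curves.
Similarly, histomorphometry primitives are statistically calibrated to
group summaries but carry no section geometry, and the cohort's AFF
labels follow an idealized logistic link. Printed group-level results
from patient data (Table-level means, the published ORs of 1.13 and
7.88) cannot be reproduced from simulation and are not claimed.

## Known limitations

* No creep correction to S beyond the hold itself; the 60 s hold is
  assumed sufficient, as the protocol intends.
* No tip-area calibration procedure; calibration polynomials are
  accepted via `IndenterSpec.area_coeffs` but none ship.
* Whether the original analysis fitted site-level or subject-mean
  predictors is unknown; both are provided and neither is claimed to
  reproduce the printed odds ratios.
* Several published p-values are not consistent with Student/Welch
  t tests of the printed summaries; the transformation actually used is
  unknown and is not guessed.
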