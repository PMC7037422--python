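# Methods

`radsynergy` asks one question of a co-exposure experiment: does a
nanomaterial make irradiated cells die more than the nanomaterial and the
radiation would independently? This note documents the models, the
synthetic-data generator, the numerical choices, and the limits of what
the test suite demonstrates.

## Dose–response model

Mortality versus nanomaterial surface dose d (µg/cm²) is modelled with a
four-parameter log-logistic (LL4/4PL) curve

    f(d) = lower + (upper − lower) / (1 + (ed50/d)^shape),   f(0) = lower

with `lower`, `upper` ∈ [0, 1] the asymptotic mortalities at zero and
infinite dose, `ed50` > 0 the dose giving the halfway response, and
`shape` > 0 the steepness. This parameterisation is algebraically the
common b/c/d/e form, but constraining `shape` > 0 removes the sign
ambiguity of the slope for curves that must increase. Dose 0 is a real
data point (control wells) handled through the analytic limit, never
through `log(0)`.

Fitting is bounded multi-start least squares (`scipy.optimize.least_squares`,
trust-region reflective): asymptotes boxed to [0, 1], `ed50` and `shape`
optimised in log space so positivity is structural. The starting point
sets the asymptotes to the response range, `ed50` by linear interpolation
of the half-response dose and `shape` = 1; four further starts perturb it
(seeded Gaussian jitter), and the lowest-SSE solution wins. The loss is
unweighted least squares on mortality fractions — per-well event counts
are treated as equal across wells. A constant response profile returns a
flagged degenerate fit (`lower = upper`, `ed50` unidentifiable) rather
than an error; non-convergence is flagged, never silent.

Known behaviour: when the dose grid ends below the true `ed50`, `upper`
and `ed50` are weakly identified (they trade off along a ridge). The
recovery tests quantify this: noise-free data on the standard grid
{0, 6, 16, 32, 48, 64} µg/cm² recovers all four parameters to 1e-3
relative error, and with Gaussian noise sd 0.02 the median `ed50` error
stays below 15% over 100 replicates.

## Independent-action null and synergy score

The null model is Bliss independence. From the dose-0 controls the *IR
impulse* — the conditional kill of irradiation among cells that baseline
conditions spared — is

    q = (p_ir_ctrl − p_ni_ctrl) / (1 − p_ni_ctrl),

and transferring it onto every non-irradiated condition gives the
theoretical "NM alone + IR alone" mortality

    p_sim(d) = 1 − (1 − p_ni(d)) (1 − q).

Both the simulated and the observed irradiated dose–responses are fitted
with the same LL4 machinery, and divergence is scored as the Euclidean
distance between the coefficient vectors `(lower, upper, ln ed50, shape)`.
`ed50` enters on the log scale; otherwise its units (µg/cm²) would
dominate the other three coordinates, which live on [0, 1]-ish scales.
The default is unit scaling of the four coordinates; an optional custom
scaling (e.g. bootstrap standard errors) divides each coordinate
difference. The distance gets a direction from the mean per-dose
observed-minus-simulated mortality over the nonzero doses: +1 (synergy)
above +0.005, −1 (antagonism/saturation) below −0.005, else 0. The
half-percent dead band absorbs counting noise at typical event counts.

Because the raw distance between two fits of noisy curves is itself
noisy (the `ln ed50`/`shape` ridge again), "distance ≈ 0" is defined by
calibration, not by eye: `null_distance_tolerance` takes the 95th
percentile of the distance over seeded replicates of a null world.
The suite verifies both calibration (the signed score is centred at zero
over 200 null replicates) and power (a world whose combined mortality
exceeds the null by ≥ 10 percentage points at the top dose is called
positive in ≥ 95% of 100 replicates at 10⁴ events/well).

Protective irradiation (`p_ir_ctrl < p_ni_ctrl`) is out of scope and
rejected loudly; so are Loewe additivity and Chou–Talalay-style scores.

## Cytometry gating

Uptake gating places a threshold at an empirical quantile of the control
sample's side scatter: the smallest observed SSC value v with
fraction(SSC ≤ v) ≥ target (empirical-CDF inversion; deterministic under
ties, with a warning on a constant column). Targets are 0.70 for
non-irradiated and 0.60 for irradiated controls, re-derived per timepoint
from that timepoint's own controls; a sample's SSC-high fraction (strictly
above threshold) then proxies particle uptake.

Death classification reads the DiOC6(3)/PI quadrants with PI precedence:
PI-positive events are dead regardless of DiOC (membrane integrity is
gone), the remaining DiOC-positive events are live, and the double
negatives — membrane potential lost but dye exclusion intact — are
apoptotic. The three fractions partition every sample exactly. Mortality
is reported as 1 − live, i.e. apoptotic cells count as death; reporting
only PI-positive death is a different, stricter convention and would
lower every number.

DiOC/PI gate placement is either explicit values or a KDE valley finder:
Gaussian KDE on log intensity, threshold at the density minimum between
the two tallest modes, error if the distribution is unimodal. No
compensation, doublet exclusion or debris gating is implemented.

## Imaging

Nucleus counting: Gaussian smooth (sigma 2 px) → global Otsu threshold →
8-connected labelling → discard components under 20 px. All parameters
are exposed. Because Otsu always produces a split even on a
foreground-free noise field, a separation guard rejects thresholds whose
two classes differ by less than 2 overall standard deviations; such
fields count 0. The Otsu route makes counts invariant to positive
intensity rescaling. There is no watershed splitting: nuclei closer than
the global threshold can resolve merge into one component — a declared
limitation, pinned by a fixture with two blobs 4 px apart counting as
one. Growth series average the per-field counts per day (five fields per
condition by default); missing days stay missing. Growth inhibition is
1 − treated/control at a chosen day. Image origin is top-left, 0-based
(row, col).

## qPCR

Relative quantification is textbook 2^−ΔΔCt with amplification
efficiency fixed at 2 (TaqMan-style assays, no efficiency correction):
target Ct minus reference-gene Ct within a sample, normalised to the
untreated non-irradiated control *of the same timepoint*. Replicate Cts
are averaged before the ΔΔCt. The reference gene must be named
explicitly (the generator emits a stable `GAPDH`); there is no default
normaliser for real data.

Welch's unequal-variance t-test is implemented from the standard formulas
(statistic, Welch–Satterthwaite df, two-sided p from the t distribution)
and cross-checked against `scipy.stats.ttest_ind(equal_var=False)` to
1e-8 in the suite. Two comparison families are computed on mortality
tables: each irradiated condition versus its non-irradiated counterpart
(`*` stars) and each nanomaterial dose on irradiated cells versus the
irradiated no-NM control (`#` hashes). No multiple-testing correction is
applied by default — the analysis convention these experiments use — and
a Benjamini–Hochberg option exists for sensitivity checks.

## The synthetic-data generator

The generator is first-class, tested code. It produces exactly the
structure the analysis assumes, with ground truth recorded, so every
stage has an oracle:

* **Mortality.** `p = 1 − (1 − p_nm(d)) (1 − ir_kill·IR) (1 − synergy_coeff·p_nm(d)·IR)`,
  clipped to [0, 1]. With `synergy_coeff = 0` the world satisfies
  independent action *exactly* — the calibration null. The interaction
  term scales with the nanomaterial's own dose response, so synergy
  grows with dose, as a photocatalytic mechanism would.
* **Events.** Cell fate is Bernoulli in the true mortality; the
  apoptotic share of dying cells (`apoptotic_split`) decays with
  timepoint (apoptotic → dead progression). Channels are log-normal:
  SSC baseline median 100 a.u. (sigma 0.4 in log space), multiplied by
  `ssc_shift` (default 3) for the particle-laden fraction, which follows
  a saturating Hill curve in dose (max 0.95, half-dose 12 µg/cm²).
  DiOC modes at 1000/40 a.u. and PI modes at 800/15 a.u. are separated
  by ~4.5 log-sd, so quadrant classification is effectively error-free
  and binomial fate sampling dominates the statistics. That is a
  deliberate idealisation: real cytometry has spectral overlap, debris
  and smeared transitional states, so passing recovery tests here
  validates the *estimator logic*, not robustness to instrument noise.
* **Default curves.** NM-alone curves per material and timepoint are
  anchored so that at 72 h the single-agent mortalities at 64 µg/cm²
  (32 µg/cm² for the double-coated material) match the reported values
  (27.95%, 36.5%, 41.55%, 60%), with `ir_kill` 0.255 at 72 h and 0.634
  at 7 d. Untreated-control baseline mortality (0.05) and the 24/48 h
  values are **assumptions** — the source experiments do not report
  them — chosen once as plausible for a slowly dying normal epithelial
  culture and not revisited.
* **Growth images.** Expected count per field follows logistic growth:
  exponential at 0.69/day (~24 h doubling) saturating at a confluence
  capacity of 150 nuclei/field, attenuated by the survival fraction;
  per-field counts are Poisson. Pure exponential growth cannot be
  rendered in a finite field while preserving the zero-overlap guarantee
  the counting oracle relies on, and real wells saturate anyway. Nuclei
  are Gaussian blobs (sigma 3 px) placed by rejection sampling at ≥ 6
  sigma separation; an `overlap_rate` knob deliberately violates the
  separation to stress-test the counter. Requested counts that cannot be
  placed raise an error. Ground truth lives in each image's metadata.
* **Ct tables.** Stress score `dose/64 + IR + 0.5·(dose/64)·IR`; HMOX1
  Ct falls 2 cycles per stress unit, NQO1/TXNRD1 slopes are 0 (no
  defence-gene induction), the reference gene is flat, technical noise
  is Gaussian sd 0.15 cycles.
* **Seeding.** Sub-streams derive from
  `SeedSequence([master_seed, *counters])` with documented counters
  (arm, dose index, replicate, day, field), so runs are bit-reproducible
  and streams never collide. Replicate-heavy suites (null calibration,
  power, type-I error) sample well mortalities binomially
  (`simulate_death_dataset`) instead of classifying 10⁵ events per well
  per replicate — statistically equivalent under the error-free quadrant
  separation above, and verified against the full event-level route by
  the end-to-end recovery test at 10⁵ events.

## Pipeline

`run_pipeline` chains simulate → gate → death → fit → synergy → growth →
pcr → report, communicating only through files (CSV/JSON/TIFF) so any
stage can be re-run in isolation and reproduces its outputs
bit-identically. The config is schema-validated (pydantic, unknown keys
rejected, violations enumerated); the structured log records every stage
with seed and parameters, and the report carries a SHA-256 provenance
hash over the config and stage outputs — two runs of the same config
hash identically. Death-stage DiOC/PI gates come from the valley rule on
events pooled across the timepoint's samples, so both live and dead
modes are always represented.

## Problem sizes in the shipped suites

Event-level recovery tests run at 10⁵ events; null calibration uses 200
replicates at 10⁴ events/well, power 100 replicates at 10⁴, LL4 noisy
recovery 100 replicates; pipeline tests run miniature grids (800–6000
events, 2–3 replicates). These sizes put Monte-Carlo error well inside
the asserted tolerances while keeping the whole suite inside a coffee
break on one core.

## Dose units

Surface dose (µg/cm²) is canonical throughout; the fixed pairing to
suspension concentrations (6, 16, 32, 48, 64 µg/cm² ↔ 10, 25, 50, 75,
100 µg/mL) ships as a lookup table, never as a computed conversion.

## Known limitations

* Mortality at a timepoint is drawn from that timepoint's curve; there is
  no within-simulation kinetic model linking timepoints.
* The valley rule needs both fluorescence modes present; a sample that is
  all-live (or all-dead) requires explicit thresholds.
* No FCS ingestion: event tables are CSV.
* The synergy score compares coefficient vectors, not curves; two curves
  can differ in coefficients while nearly coinciding over the sampled
  dose range (the `upper`/`ed50` ridge). The calibrated null tolerance is
  the guard against over-reading such differences.
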