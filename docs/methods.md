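# Methods

This note records the models, estimators, and numerical choices behind
`dsfbind`, and what the simulation-based validation does and does not show.

## Melt-curve processing

A well's trace is fluorescence *F* against temperature *T* on a uniform
grid (default analyses assume plate-reader exports; the shipped simulator
uses 50–90 °C at 0.3 °C steps, the range typical for serum-albumin DSF).
Processing is:

1. **Smoothing** — Savitzky–Golay, window 7 points, polynomial order 3, on
   the raw fluorescence.  The window is deliberately light: it suppresses
   point noise without broadening the unfolding transition (which spans
   tens of grid points).  Smoothing is applied before differentiation only;
   fitted dose–response data are never smoothed, since smoothing the
   isotherm would bias *K*<sub>d</sub>.
2. **Derivative** — d*F*/d*T* by central differences (one-sided at the
   ends).  With a constant instrument ramp rate this is proportional to the
   derivative with respect to time, so results are reported per °C.
3. **Tm** — temperature of the global derivative maximum, refined by
   quadratic interpolation through the three points around the grid argmax
   (clamped to half a grid step).  Ties break toward lower temperature,
   deterministically.  The refinement recovers sub-grid resolution: on
   noiseless two-state curves over a 0.3 °C grid the worst-case error
   across random parameter draws is below 0.06 °C (the acceptance script
   recomputes this).
4. **Peak detection** — scipy `find_peaks` on the derivative with both a
   prominence and an absolute-height floor at a fraction (default 0.1) of
   the global maximum, and a minimum separation (default 2 °C).  The
   derivative is pre-smoothed with a wide quadratic Savitzky–Golay window
   (25 points by default) first: genuine unfolding transitions are several
   °C wide, while noise ripple in a flat baseline otherwise produces bumps
   whose peak-to-dip prominence is ~2× the noise amplitude.  The height
   floor matters for the same reason — noise bumps can be prominent without
   being tall.  Each peak is assigned the share of total positive-derivative
   area in its watershed cell (boundaries at inter-peak derivative minima);
   area past the point where the derivative first turns negative after the
   last peak is excluded, which removes the high-temperature
   dye-dissociation region from the accounting.

Normalization to a 0–100 scale is min-max by default, with a
max-only option (`mode="max"`) for the "percent of maximum" convention;
normalization is cosmetic and never feeds the estimators.

## Dose–response and binding models

ΔTm for a sample well is its Tm minus the mean vehicle Tm of the **same
protein on the same plate**, so plate-to-plate baseline drift cancels.  A
group is classified nonbinding when the largest per-concentration mean
|ΔTm| stays below 1.0 °C; among the study compounds the smallest genuine
saturating shift is 3.53 °C while nonbinders show sub-0.5 °C jitter, so the
threshold splits the classes with a wide margin.

**Single-site fit.** ΔTm(*c*) = ΔTm<sub>max</sub>·*c*/(*K*<sub>d</sub>+*c*)
by least squares (scipy `curve_fit`, *K*<sub>d</sub> bounded positive,
initial values from the data).  The model is fitted on linear
concentration; log axes are only a display convention.  Each replicate
series is fitted separately and the reported *K*<sub>d</sub> (and plateau)
is the mean ± SEM over replicate estimates with n the number of replicate
fits — matching the "*K*<sub>d</sub> ± SEM, n replicate values" convention
of affinity tables in this assay family.  r² comes from a pooled fit of all
points.  Both the fitted plateau and the observed maximal mean ΔTm are
reported, since summary tables sometimes print the latter.  A negative
fitted plateau is flagged as a destabilizing ligand rather than being
reported as an affinity.

**Biphasic occupancy.** When ligand-free and ligand-bound populations
unfold at different temperatures the derivative shows two peaks.  The
analysis first anchors the two transition centers — baseline from the
vehicle wells' Tm, saturating from the dominant peak of the
highest-concentration wells — then estimates each well's bound fraction as
the share of positive-derivative area on the high-temperature side of a
watershed cut placed at the derivative minimum between the anchors.  The
cut-based split (rather than requiring two *detected* peaks per well) keeps
the estimator defined when the minor population is too small to register as
a separate peak, which is exactly where occupancy approaches 0 or 1;
clipping those tails would bias the Hill slope upward.  Biphasic
*detection* is stricter than estimation: two peaks must be resolved in the
derivative of a per-concentration replicate-mean curve (averaging
suppresses noise so a single-site group is not misrouted), and the anchors
must be separated by at least the peak-separation floor.  A two-component
global melt fit would be a natural extension point; the area-split
estimator was chosen because it is direct, assumption-light, and testable
against simulation truth.

**Hill fit.** φ(*c*) = *c*<sup>h</sup>/(*K*<sub>½</sub><sup>h</sup> +
*c*<sup>h</sup>) by least squares with φ(0) = 0; standard errors from the
fit covariance.  The series must traverse the transition (span below 0.2
and above 0.8) — outside that range *h* is ill-determined.  For biphasic
data both *K*<sub>½</sub> (reported in the Kd field of the fit) and *h* are
returned; whether *K*<sub>½</sub> is "the" dissociation constant for a
cooperative system is a matter of interpretation, so the model label
distinguishes it from single-site *K*<sub>d</sub>.

## Contrast statistics

Cross-species and cross-congener comparisons use the symmetric percent
difference 200·|a−b|/(a+b), bounded in [0, 200); this statistic
reproduces, to the printed decimal, every percentage quoted in the source
study when applied to its published *K*<sub>d</sub> table, which is why it
was adopted as the canonical contrast.  Direction ("X-higher-affinity") is
reported separately because affinity ordering is inverse to *K*<sub>d</sub>
ordering and sign confusion is the main practical hazard.  Cohen's d uses
the classical pooled-SD formula with group SD recovered as SEM·√n and the
0.2/0.5/0.8 class boundaries (inclusive upward).  Published tables in this
area sometimes print d values derived from a fitted GLM instead; those do
not coincide with the classical formula (e.g. 4.49 here vs 3.77 printed for
one pair), and this package's value is the documented, reproducible one.
Inferential machinery (GLMs, multiplicity-corrected p-values) is out of
scope: only effect statistics are computed.

The affinity rank matrix ranks species per ligand by ascending
*K*<sub>d</sub> (ties share the mean rank); nonbinders are excluded.

## Docking aggregation

Docking tables carry ΔG (kcal/mol) for up to 9 pose modes in each of 6
binding sites per structure–ligand pair.  Aggregation is the arithmetic
mean per site, then a geometric mean across sites.  A geometric mean of
negative numbers is undefined in the reals, so it is computed on the
magnitudes with the favorable sign restored, −(∏|ΔG<sub>i</sub>|)^(1/k) —
the only reading under which the protocol is computable for uniformly
favorable energies; mixed-sign inputs are rejected rather than silently
averaged.  Pearson correlation between aggregated ΔG and *K*<sub>d</sub>
(paired by ligand, optional exclusions) uses the t-transform p-value with
n − 2 degrees of freedom.

## Synthetic plates

The simulator exists to test estimator correctness, not thermodynamic
theory, and is deliberately phenomenological:

* **Melt shape** — two-state van 't Hoff unfolding:
  f<sub>u</sub>(T) = 1/(1 + exp[(ΔH/R)(1/T − 1/T<sub>m</sub>)]) with
  temperatures in Kelvin inside the formula only, mixed between linear
  folded and unfolded baselines, with optional exponential post-transition
  decay (default off).  Default ΔH = 180 kcal/mol gives a derivative-peak
  FWHM of ≈ 4.6 °C, resembling published albumin DSF traces; albumin
  van 't Hoff enthalpies are not well pinned down, so this is a shape
  choice, not a thermodynamic claim.
* **Ligand effect** — a Tm shift following the single-site isotherm itself
  (or, in biphasic mode, a two-population mixture whose bound fraction
  follows a Hill curve with a fixed shifted-Tm offset, default 10 °C).
  Generating data from the fitted model's own response family is the right
  construction for parameter-recovery validation; it does not test model
  misspecification.
* **Noise** — additive Gaussian per point, default 12 RFU, calibrated once
  so that per-well Tm scatter through the default extraction pipeline is
  ≈ 0.3 °C — the replicate-to-replicate spread the recovery analyses
  assume.  Replicate Tm jitter thus *emerges* from point noise, as on a
  real instrument, rather than being injected at the Tm level.
* **Plate layout** — n replicates per concentration (vehicle = 0 mM rows),
  two no-protein dye-background wells, ground-truth manifest (JSON) with
  per-well true Tm / true occupancy, fully reproducible from (config, seed).
* **Presets** — the four study albumins at their ligand-free melting
  temperatures (HSA 71.3, BSA 62.6, PSA 71.3, RSA 66.8 °C).

What passing the simulation-based checks does **not** show: robustness to
non-two-state melts, sloped or curved instrument baselines beyond the
linear family, dye-binding kinetics, inner-filter or multi-dye ratio
artifacts, plate-edge effects, or binding mechanisms outside the
single-site / Hill families.  Real-data idiosyncrasies of those kinds
still require eyes on the diagnostic output.

## Validation problem sizes

The recovery experiments (`dsfbind.validation`, reused by
`scripts/acceptance.py` and the test suite) use the study's plate design:
8 half-log concentrations spanning 0.1–10 × *K*<sub>d</sub> with 6
replicates for single-site recovery (100 plates); 50 random noiseless
curves for Tm extraction; 100 runs each for Hill recovery (true h uniform
in [1.5, 4.5], occupancy noise 0.05) and for end-to-end cooperativity
detection at h = 3.5; 20 seeds for nonbinder classification.  These sizes
give stable Monte-Carlo estimates (results vary by well under a percentage
point across seeds) while keeping a full validation run in the tens of
seconds.

## Degenerate inputs and tie-breaks

Constant traces raise a degenerate-curve error (nothing to normalize, no
transition); flat derivatives raise a no-transition error; argmax ties
break toward lower temperature; quadratic refinement falls back to the
grid point at array ends or collinear neighborhoods; occupancy at zero
concentration is defined as 0; geometric-mean aggregation refuses
mixed-sign inputs; a zero pooled SD with unequal means yields an infinite
Cohen's d, flagged rather than masked.

## Known limitations

* The biphasic estimator assumes exactly two populations with
  concentration-independent component Tm values; drifting component
  temperatures would bias the area split.
* SEM-over-replicates requires ≥ 2 replicate series; with one series the
  fit is still reported but without a finite SEM.
* The nonbinder threshold is a fixed ΔTm cut, not a statistical test; at
  replicate noise far above ~0.5 °C it would need re-examination.
* Plate files are read in one wide-CSV dialect (`temperature_C` + one
  column per well); vendor binary formats must be exported to CSV first.
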