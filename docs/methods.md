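# Methods

## The gating model behind the synthetic recordings

The generator treats the whole-cell current as
`I(t) = C·(cd_base + g(t)·cd(V))` with `C` the membrane capacitance (pF),
`cd(V)` the current density (pA/pF) the fully open channel population
produces at voltage `V`, and `g(t) ∈ [0, 1]` a dimensionless open fraction
driven by the light schedule:

* **Blue → UV (activation).**  On UV onset the open fraction rises along
  the accelerating exponential `g = a·(2^{Δt/τ_act} − 1)` and is capped at
  1, with `a` fixed so the cap is reached at 3.33·τ_act.  The accelerating
  form is deliberately the same functional family the activation fit
  assumes, so a noiseless generator trace is an exact-recovery oracle: the
  fitted half-life must equal the generating one to optimizer precision.
  The 3.33·τ span places the 30%-of-peak normalisation point
  (`t = τ·log2(1 + 0.3/a) ≈ 1.9 τ`) well inside the rise.  A saturating
  rise (`1 − 2^{−Δt/τ}`) would be more mechanistic but makes the rising-
  exponential fit ill-posed, so it is not the default.
* **Sustained UV (inactivation).**  After the cap the open fraction decays
  biphasically, `g = (1−c)·[f·2^{−Δt/τ_fast} + (1−f)·2^{−Δt/τ_slow}] + c`,
  with amplitude share `f` of the fast component and a non-inactivating
  residual `c` (default 0).
* **UV → blue (deactivation).**  From whatever level `g_b` the switch
  finds, `g = g_b·2^{−Δt/τ_deact}` — continuity is preserved at every
  light event.

All half-lives use base-2 exponents (`τ` is literally the doubling or
halving time).  Default parameters are the cohort medians observed for
OptoDArG under high-power LEDs: τ_act 5.8 ms, τ_deact 8.4 ms, inactivation
0.3 s / 13.1 s with equal amplitudes, peak current density 100 pA/pF at
+100 mV, 10 pF capacitance.  Light-source intensity does not rescale the
kinetics automatically: slower sources are emulated by supplying their
observed (larger) τ values, because no rate law linking lamp power density
to τ is established.

I–V shape comes from a monotone-cubic template anchored at (−100 mV,
inward), (0 mV, 0) and (+100 mV, outward): the near-symmetric template
mimics DAG-analog-activated currents, the outward-rectifying template
(default 3:1) the GSK-derivative phenotype.  Holding traces sample at
2 kHz; ramp sessions use the 2 Hz (50/400/50 ms) or 50 Hz (7/10/3 ms)
protocol at 5 kHz acquisition, with an optional 4th-order low-pass at the
nominal 2.5 kHz anti-alias cutoff (off by default — real 2 kHz kinetics
traces arrive already filtered/decimated).  Cohorts draw per-cell
parameters from log-normal distributions (median + geometric SD) with
per-cell seeds spawned from the master seed, and return a true-parameter
manifest for recovery checks.

What the generator does *not* emulate — and hence what passing tests do
not show about instrument data: series-resistance and capacitive-transient
artefacts, rundown/drift, photochemical isomerization dynamics (photon
flux → isomer fraction), line noise, and seal leaks.  Noise is white
Gaussian in current.

## Segment preparation

All fits run on the current magnitude `m(t)` (inward currents are
negative; a direction flag handles outward deflections), with the time
axis shifted so the fitted window starts at 0 — a pure time shift only
rescales the amplitude `a` of an exponential, never τ.

* **Activation**: baseline = median of a 1 s pre-UV window, subtracted;
  the peak is located on a moving-median-smoothed copy (11 samples) so a
  noise spike cannot define it; `y = m / (0.30·m_peak)`; the window ends
  at the first sample with y ≥ 1.  The 30% cap excludes the inactivation
  that already builds up near the peak.  The fraction is configurable
  within [0.2, 0.5].
* **Deactivation**: `y = (m − m_tail) / (m_pre − m_tail)` with medians of
  a 1 s pre-switch window and of the last 10% of the post-switch segment.
* **Inactivation**: `y = (m − m_ss) / (m_peak − m_ss)` from the raw peak
  sample (located via the smoothed trace) to the end of the UV period;
  steady state = median of the last 10% of the UV period.  Plateau levels
  use medians throughout because they are robust against the switching
  transients.  A UV period shorter than 5× the slow-τ start value is
  flagged, not rejected.

## Fitting

Unconstrained Nelder–Mead simplex minimisation of the SSE, mirroring the
classic `fminsearch` behaviour: termination requires the simplex spread
and the SSE spread to satisfy `tol_x = 1e−10` **and** `tol_fun = 1e−6`
jointly, within caps of 5000 function evaluations and 10000 iterations;
hitting a cap returns the best point with `converged=False` rather than an
error.  Start points: activation `(a, τ, c) = (0.01, 1 ms, 0.01)`,
deactivation `(0.7, 7 ms, 0.1)`, inactivation
`(a₁, τ₁, a₂, τ₂, c) = (1, 0.02 s, 1, 3.8 s, 0.1)`.  The τ starts are
interpreted on each kind's natural time scale — milliseconds for
activation/deactivation (observed 5–200 ms), seconds for inactivation
(0.3–190 s).  With second-scale activation/deactivation starts the simplex
reliably falls into a flat valley where the model is locally affine in t
and τ grows without bound; the millisecond reading is the only one from
which all observed scales are recovered.

Two numerical safeguards:

* Positive exponents are clipped at e^700 so a runaway vertex produces a
  large finite penalty instead of an overflow.
* If the fitted τ ends up more than 100× the segment span or below 1% of
  the sample interval — a collapsed or runaway component, not a plausible
  half-life — the simplex restarts once from a data-driven start point
  (amplitudes from the segment's end values, τ from the span) and the
  lower-SSE result is kept and flagged `restarted_from_data_scale`.
  Nothing else about the optimizer changes.

Negative fitted τ values are reflected to positive and flagged.  The
bi-exponential output is ordered fast ≤ slow; τ ratios below 3 are flagged
`components_indistinct` but reported.  No parameter bounds are imposed.

Thermal relaxation reuses the decaying mono fit on `A_∞ − A(t)` with the
time axis in minutes; since the canonical start-point table has no row for
this fit, the start is data-driven (amplitude = first gap, τ = span/4).
The photostationary-state estimator is the absorbance-ratio approximation
`%trans = 100·A_PSS/A_dark` at the trans band maximum, which assumes the
cis isomer absorbs negligibly there; NMR-grade quantification is out of
scope.

## Normalized slope conductance

Each I–V curve (current density vs. command voltage, ≥10 grid points) is
fitted with a cubic smoothing spline; the roughness penalty is selected by
generalised cross-validation unless fixed, and a fixed, recorded value is
enforced across cells inside any group comparison (the pipeline default is
λ = 1).  The inward (V<0) and outward (V>0) branches are normalised
independently so the ±100 mV anchors map to ±100% — this deliberately
discards the rectification ratio and keeps only curve shape.  The NSC is
the analytic derivative of the spline (scaled per branch), rescaled so
each branch's mean NSC is 1; an ohmic conductor is identically 1.  V = 0
is excluded (its normalisation is degenerate) and branch endpoints carry a
one-sided-derivative flag.  The exact normalisation constants used are
recorded in each curve's metadata; other NSC conventions differ mainly in
the rescaling constant, which cancels in any within-convention comparison.
Group comparisons are pointwise per voltage (Mann-Whitney U for two
groups, Kruskal-Wallis beyond) with no across-voltage multiplicity
adjustment by default; a Holm option exists.  Only the 2 Hz ramp dialect
is used for NSC by default.

## Statistics

Mid-ranks with tie-corrected variances everywhere.  The Mann-Whitney test
enumerates all C(n+m, n) group assignments when min(n, m) ≤ 8 (exact,
tie-safe; two-sided p = 2·min tail, capped at 1) and otherwise uses the
normal approximation.  Kruskal-Wallis, Friedman and Wilcoxon delegate to
scipy; all-identical inputs short-circuit to p = 1 (a constant sample
carries no evidence).  Dunn's post hoc computes z statistics on mean ranks
with the tie-corrected pooled variance; the pair-wise adjustment defaults
to Bonferroni (configurable: none/holm) and is recorded in the test name.
Activation factors are per-cell |cis|/|trans| current-density ratios,
summarised as median ± SD; cells with a near-zero trans denominator are
excluded with a warning.  The τ-vs-amplitude check reports the OLS R².

## Pipeline and reproducibility

A study config (YAML) declares arms (compound × light source), each with
its own parameter population, plus the master seed (mandatory).  Per-arm
and per-cell seeds are spawned deterministically from the master seed, so
`run-all` is byte-reproducible; every output table carries the config hash
and seed.  The default kinetics schedule is 1 s blue baseline, sustained
UV (default 60 s), blue tail — one trace yields all three kinetics.  The
CLI (`optoswitch simulate|fit-kinetics|nsc|stats|run-all`) is a thin layer
over the library; exit codes are 0 (success), 2 (schema/config error) and
3 (non-convergence under `--strict`).

## Problem sizes and test design

The test suite and the recovery script run at the scales the analysis
itself prescribes: 2 kHz kinetics traces of 2–300 s (the 300 s sustained-UV
run is only used for the slowest inactivation pair), 5 kHz ramp sweeps,
cohorts of 3–8 cells for pipeline checks, 200-replicate seeded calibration
suites for noisy-fit and type-I-error rates, and 400-draw sampling checks
for the cohort medians.  Noiseless generator traces provide exact-recovery
oracles; independent oracles elsewhere are brute-force enumeration (rank
tests), profiled grid search with linear subproblems (noisy mono fits) and
closed-form derivatives (NSC on polynomial I–V shapes).

## Known limitations

* The activation fit is only well-posed because the 30% window keeps the
  data inside the accelerating phase; fitting a saturating rise with a
  positive-exponent model is biased by construction.
* The bi-exponential SSE surface has local minima when one component
  covers a tiny fraction of the window; the restart heuristic catches the
  collapsed-component case but a genuinely indistinct pair (τ ratio < 3)
  is inherently unstable and only flagged.
* Exact Mann-Whitney enumeration grows as C(n+m, n); above the n ≤ 8
  threshold the normal approximation is used.
* GCV can undersmooth a noiseless polynomial I–V; analytic-derivative
  comparisons therefore fix a light penalty.
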