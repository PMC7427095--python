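# Methods

## Binding model

A 1:1 Langmuir interaction observed by bio-layer interferometry is
described per analyte concentration C_i (µM) by an association phase

    y_bind,i(t) = [a_on,i (1 − e^{−(k_on C_i + k_off) t}) + b_on,i] e^{−k_leak t}

and a dissociation phase

    y_unbind,i(t) = [a_off,i e^{−k_off t} + b_off,i] e^{−k_leak t}

with signal in nm and t in seconds measured from the start of each phase
(the leak clock therefore also resets at the phase boundary; the model is
implemented exactly as written, phase-local). k_on (µM⁻¹ s⁻¹) and k_off
(s⁻¹) are shared across all curves of a dataset; k_leak (s⁻¹) models the
slow loss of the His-tag-immobilized binder from the probe as a
multiplicative decay of the whole signal. Each of the n
association/dissociation pairs contributes four shape parameters
(a_on, b_on, a_off, b_off), giving 4n + 3 free parameters. The derived
affinity is K_d = k_off/k_on (µM); the pseudo-first-order apparent rate
is k_obs = k_on·C + k_off.

Assumptions: a single binding site class, no mass-transport limitation,
no analyte rebinding during dissociation, additive observation noise.
Signals are not baseline-aligned on ingest — baselines are model
parameters.

## Global fit

All curves are pooled into one unweighted sum of squared residuals and
minimized with trust-region-reflective least squares. Numerical choices:

- **Log-rate parameterization.** The three rates are optimized as log₁₀
  values. This guarantees positivity without active bounds and puts the
  lit and dark regimes — whose rates differ by more than an order of
  magnitude — on comparable step scales. Shape parameters stay linear
  and unbounded.
- **Bounds.** k_on ∈ [1e−5, 10] µM⁻¹s⁻¹, k_off ∈ [1e−5, 10] s⁻¹,
  k_leak ∈ [1e−7, 0.1] s⁻¹: at least two decades of margin around every
  regime the package targets. When the fitted k_on pins its lower bound,
  K_d is reported as a one-sided bound (`kd_is_lower_bound`), mirroring
  how very weak lit-state affinities are tabulated (k_on < 0.001,
  K_d > 100 µM).
- **Initialization.** k_off from the median early-decay log-linear slope
  of the dissociation curves; per-curve k_obs from single-exponential
  fits to the association curves and k_on from the slope of k_obs versus
  concentration (clamped positive; with a single concentration k_on
  falls back to (k_obs − k_off)/C with a warning); k_leak from the
  late-tail decay of the dissociation curves minus the k_off estimate
  (the tail of a low-baseline curve decays at ≈ k_off + k_leak), floored
  at 1e−6 s⁻¹. Amplitudes start at each curve's signal range, baselines
  at its first value; flat curves degenerate to zero amplitudes with
  rates at their floors and the fit flags the rates unidentifiable.
- **Multi-start.** Default 5 restarts; restart 0 is the plain initial
  guess, later restarts jitter rates by N(0, 0.3) in log₁₀ units and
  shapes by the same relative scale, all driven by the seed. Strictly
  best converged objective wins; ties break to the lower restart index.
  If no restart converges the fit raises with per-restart diagnostics
  rather than returning a best-so-far.
- **Tolerances.** ftol = xtol = gtol = 1e−12, max 2000 function
  evaluations. Datasets without dissociation curves are refused (k_off
  and k_leak are unidentifiable in this parameterization).

Replicates are fit independently and summarized as the mean and sample
SD (n − 1) of per-replicate K_d values; the SD of a single replicate is
reported as NaN, not 0. Averaging per-replicate K_d values (not taking
the ratio of mean rates) is the convention used throughout; the two
differ noticeably when rates vary across replicates.

## Bootstrap confidence intervals

Nonparametric residual bootstrap, 200 replicates and 95% percentile
intervals by default. Each replicate resamples every curve's residual
vector with replacement, adds it to that curve's fitted values and
refits warm-started from the point estimate with a single start (the
basin does not change under residual resampling, and this keeps 200
refits cheap). More than 20% refit failures aborts with diagnostics.
Raw percentile intervals can exclude the point estimate at finite
replicate counts; intervals are therefore expanded to include it, which
keeps the invariant lower ≤ estimate ≤ upper without affecting coverage.

## Thermodynamics

Fold-changes convert to free energies by ΔΔG = RT·ln(fold) with
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 298.15 K. The 25 °C
default is a deliberate back-calculation: a 3.8 kcal/mol ceiling maps to
~610-fold (rounding to ~600) only near 298 K (310 K would give ~480).
Transmission efficiency is RT·ln(measured fold)/ΔΔG_max, clamped to 1
with a warning if the measurement exceeds the ceiling.

## Synthetic data

The generator emulates multi-concentration BLI curve pairs: for each
concentration it evaluates the closed forms above, makes the
dissociation curve start exactly where the association curve ended
(continuity at the phase boundary, leak clock reset), and adds i.i.d.
Gaussian noise. Defaults, fixed once and overridable:

| parameter | default | rationale |
|---|---|---|
| association / dissociation duration | 300 s / 600 s | typical BLI step lengths; dissociation needs ≥ 1/k_off at the dark regime |
| sampling interval | 1 s | typical instrument export rate |
| noise SD | 0.01 nm | typical shot-to-shot BLI noise; the real magnitude is unpublished |
| amplitudes | a_on,i = R_max·C_i/(C_i + K_d), R_max = 1 nm | occupancy scaling; loading to a few nm is only an upper bound on R_max |
| baseline | 0 nm | reference-subtracted signals |
| k_leak | 5×10⁻⁴ s⁻¹ | slow relative to k_off in every regime, visible over 900 s |
| concentrations | log-spaced K_d/3 … 3·K_d, capped at 300 µM | informative curvature around K_d; cap reflects solubility |

Presets pin (k_on, k_off) to the measured regimes: `ha4`
(0.0631, 0.0145), `dark_c450v` (0.071, 0.01), `lit_v416l` (0.004, 0.23).

What the generator does **not** emulate: loading/regeneration phases,
reference-sensor subtraction, instrument drift beyond k_leak, mass
transport, correlated noise, or concentration errors in the analyte
series. Passing recovery tests therefore demonstrates the estimator is
correct under the model's own assumptions, not that real sensorgrams
are free of systematic deviations from a 1:1 model.

The purification generator back-computes fraction concentrations and
volumes from a stated yield/capacity/purity truth and perturbs measured
concentrations with mean-1 lognormal noise (lognormal so simulated
concentrations stay positive); at zero noise the forward accounting
recovers the truth identically.

## Purification accounting

Yield y = 100·TPE/TPB with TPE = [TPE]·TPEvol (light-eluted mass),
TPB = [TRP]·TRPvol + TPE (mass initially bound) and resin capacity
C_R = TPB/V_R. Multiple light-eluted fractions are pooled
mass-consistently before the arithmetic. Densitometric purity is the
target band's share of its lane's total integrated intensity, computed
per lane and summarized as mean ± SD over lanes; the screen readout is
the dark/light band intensity ratio reported at two significant figures.
Purity SDs are taken over purification runs (lanes), the reading adopted
where the provenance of published SDs is ambiguous.

## Problem sizes and determinism

Test-suite simulations use 3 concentrations with 1 s sampling (about
2700 points per dataset) where accuracy matters, and 5 s sampling for
optimizer-heavy statistical checks such as the 40-simulation bootstrap
coverage study (100 bootstrap replicates each) — sizes chosen to keep
the full suite around a minute while leaving every estimate comfortably
inside its tolerance. All stochastic stages (simulation, multi-start
jitter, bootstrap resampling) run off explicit integer seeds;
deterministic stages re-run bit-identically, and every report embeds the
package version, seed and a configuration hash.

## Known limitations

- Only the 1:1 model with multiplicative leak; no heterogeneous-ligand,
  2:1 or mass-transport-limited variants.
- k_leak identifiability relies on the dissociation tail; with large
  baselines and short dissociation phases it correlates with b_off.
- The residual bootstrap assumes exchangeable residuals within a curve;
  autocorrelated instrument noise would make intervals anti-conservative.
- No instrument-native (proprietary export) parsing; sensorgrams arrive
  as delimited text with explicit unit-suffixed headers.
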