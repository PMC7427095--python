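# optobind

Kinetic analysis of light-switchable protein binders from bio-layer
interferometry (BLI) sensorgrams, plus the mass-balance accounting of
light-controlled affinity chromatography (LCAC).

Optogenetic binders such as OptoMonobodies — a monobody fused to the
AsLOV2 photosensory domain — change their affinity for a target (here the
Abl-kinase SH2 domain) when illuminated with blue light. Quantifying that
switch means extracting the association rate constant k_on (µM⁻¹ s⁻¹),
the dissociation rate constant k_off (s⁻¹) and the equilibrium constant
K_d = k_off/k_on (µM) in both the lit and dark states, then expressing
the lit/dark K_d ratio as a binding free-energy difference
ΔΔG = RT·ln(fold). `optobind` is for protein engineers and biophysicists
doing exactly that.

## The model

Each analyte concentration C_i contributes an association curve and a
paired dissociation curve (signal in nm, t in seconds, phase-local):

    y_bind,i(t)   = [a_on,i (1 − e^{−(k_on C_i + k_off) t}) + b_on,i] e^{−k_leak t}
    y_unbind,i(t) = [a_off,i e^{−k_off t} + b_off,i] e^{−k_leak t}

k_on, k_off and k_leak (a slow probe-leak decay from loss of the
His-tagged binder) are shared across all curves; each pair adds four
shape parameters, so n concentrations give a 4n + 3-parameter global
least-squares problem. Rates are optimized in log₁₀ space with a seeded
multi-start; confidence intervals come from a residual bootstrap.
Replicate experiments are fit independently and summarized as
mean ± SD of the per-replicate K_d values.

Because no machine-readable sensorgrams ship with the package, a
synthetic generator produces datasets with the same structure (presets
`ha4`, `dark_c450v`, `lit_v416l` at the measured rate regimes) alongside
a `truth.json` so recovery can always be checked.

## Worked example

```sh
$ optobind -q reproduce --seed 1 --skip-ci --out report/
dark state (dark_c450v): Kd = 0.139 +/- 0.000545 uM (n = 3; truth 0.141 uM)
lit state  (lit_v416l): Kd = 57.2 +/- 1.46 uM (n = 3; truth 57.5 uM)

lit/dark affinity fold-change: 410.3 (~410; truth 408.2; mean of per-replicate ratios 410.4)
ddG = RT ln(fold) = 3.56 kcal/mol at 298.15 K
free-energy ceiling 3.8 kcal/mol -> theoretical max fold 610
transmission efficiency: 94%
```

This simulates triplicate BLI experiments at the dark-locked and
lit-stabilized presets, fits each replicate globally, and averages the
per-replicate K_d values: the dark state binds at ~0.14 µM, the lit state
at ~57 µM, a ~410-fold affinity shift (the ratio of the preset truth
rates), i.e. 3.56 kcal/mol of the 3.8 kcal/mol the photosensor can
transmit. With measured per-state mean K_d values the same conversions
give the familiar numbers:

```sh
$ optobind -q foldchange --kd-lit 63 --kd-dark 0.19
{"fold_change": 331.57894736842104, "fold_change_2sf": 330.0}
$ optobind -q thermo --ddg 3.8
{"ddg_kcal_per_mol": 3.8, "fold_change": 610.1341005787843, "temperature_K": 298.15}
```

From Python:

```python
import optobind as ob

truth = ob.preset_truth("ha4", seed=11)          # k_on 0.0631, k_off 0.0145
dataset = ob.simulate_dataset(truth)
fit = ob.fit_global(dataset, ob.FitOptions(seed=1))
print(fit.kd_report)                              # "0.2309 uM"
ci = ob.bootstrap_ci(dataset, fit, n_boot=200, seed=7)
```

Other subcommands: `simulate`, `fit`, `ci`, `purify` (yield %, resin
capacity mg/mL from a fraction table), `purity` (densitometric purity
from band intensities) and `bandfold` (dark/light band-intensity ratio).

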