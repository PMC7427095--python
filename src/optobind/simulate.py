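"""Synthetic sensorgram and purification-table generator.

Emulates the statistical structure of a BLI experiment on a
light-switchable binder: for each analyte concentration an association
curve and a paired dissociation curve obeying the closed-form 1:1 model
with probe leak, per-curve amplitudes that scale with fractional
occupancy, additive i.i.d. Gaussian observation noise, and triplicate
replicates.  Three rate-constant presets cover the regimes measured for
the parent monobody (HA4), the dark-locked chimera (C450V) and the
lit-stabilized chimera (V416L).

Defaults (all overridable): 300 s association / 600 s dissociation at
1 s sampling, observation noise SD 0.01 nm, amplitude R_max = 1 nm scaled
by occupancy conc/(conc + K_d), leak rate 5e-4 s^-1.  These are typical
BLI scales, chosen once and documented in the methods note; the real
instrument's noise magnitude and concentration series are not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .model import (
    BindingDataset,
    CurveShapeParams,
    GlobalKineticParams,
    PairShapes,
    Phase,
    SensorgramCurve,
    eval_association,
    eval_dissociation,
)
from .purification import LaneDensitometry, PurificationRecord

__all__ = [
    "SimulationTruth",
    "REGIME_PRESETS",
    "preset_truth",
    "default_concentrations",
    "simulate_dataset",
    "simulate_replicates",
    "simulate_purification_table",
]

#: Solubility-motivated ceiling on simulated analyte concentrations (uM).
CONC_CEILING_UM = 300.0


@dataclass(frozen=True)
class RegimePreset:
    """Named rate regime; values are the measured Table rows for each state."""

    name: str
    k_on: float  # uM^-1 s^-1
    k_off: float  # s^-1


#: Measured rate regimes: parent monobody, dark-locked and lit-stabilized
#: photoswitch variants.
REGIME_PRESETS: dict[str, RegimePreset] = {
    "ha4": RegimePreset("ha4", k_on=0.0631, k_off=0.0145),
    "dark_c450v": RegimePreset("dark_c450v", k_on=0.071, k_off=0.01),
    "lit_v416l": RegimePreset("lit_v416l", k_on=0.004, k_off=0.23),
}


@dataclass
class SimulationTruth:
    """Ground-truth configuration of one simulated BLI experiment."""

    k_on: float
    k_off: float
    k_leak: float = 5e-4
    concentrations: list[float] = field(default_factory=list)
    association_duration: float = 300.0
    dissociation_duration: float = 600.0
    sampling_interval: float = 1.0
    noise_sd: float = 0.01
    n_replicates: int = 1
    seed: int = 0
    r_max: float = 1.0
    baseline: float = 0.0
    shapes: dict[str, PairShapes] | None = None  # overrides occupancy-scaled defaults

    def __post_init__(self):
        if self.association_duration <= 0 or self.dissociation_duration <= 0:
            raise InputError("phase durations must be > 0")
        if self.sampling_interval <= 0 or self.sampling_interval >= min(
            self.association_duration, self.dissociation_duration
        ):
            raise InputError("sampling_interval must be positive and smaller than both durations")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if not self.concentrations:
            self.concentrations = list(
                default_concentrations(self.k_off / self.k_on, 3)
            )

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on

    def true_params(self) -> GlobalKineticParams:
        """Generator truth as a fit-comparable parameter object."""
        per_curve = {cid: shp for cid, shp in self._pair_shapes()}
        return GlobalKineticParams(
            k_on=self.k_on, k_off=self.k_off, k_leak=self.k_leak, per_curve=per_curve
        )

    def _pair_shapes(self):
        out = []
        for i, conc in enumerate(self.concentrations):
            cid = f"c{i + 1}"
            if self.shapes is not None and cid in self.shapes:
                out.append((cid, self.shapes[cid]))
                continue
            a_on = self.r_max * conc / (conc + self.kd)
            b_on = self.baseline
            # continuity: dissociation starts where association ended; the
            # leak clock resets at the phase boundary
            end = float(
                eval_association(
                    self.k_on,
                    self.k_off,
                    self.k_leak,
                    conc,
                    CurveShapeParams(a_on, b_on),
                    np.array([self.association_duration]),
                )[0]
            )
            b_off = b_on
            a_off = end - b_off
            out.append(
                (cid, PairShapes(CurveShapeParams(a_on, b_on), CurveShapeParams(a_off, b_off)))
            )
        return out


def preset_truth(name: str, **overrides) -> SimulationTruth:
    """Build a :class:`SimulationTruth` from a named rate-regime preset."""
    try:
        preset = REGIME_PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown preset {name!r}; choose from {sorted(REGIME_PRESETS)}"
        ) from None
    return SimulationTruth(k_on=preset.k_on, k_off=preset.k_off, **overrides)


def default_concentrations(kd_truth: float, n: int) -> np.ndarray:
    """Log-spaced analyte series from K_d/3 to 3*K_d (capped at 300 uM).

    Brackets the dissociation constant so both the curvature of the
    occupancy amplitudes and the concentration dependence of k_obs are
    informative.
    """
    if n < 2:
        raise InputError("need at least 2 concentrations")
    if kd_truth <= 0:
        raise InputError("kd_truth must be > 0")
    lo = min(kd_truth / 3.0, CONC_CEILING_UM)
    hi = min(3.0 * kd_truth, CONC_CEILING_UM)
    return np.geomspace(lo, hi, n)


def simulate_dataset(
    truth: SimulationTruth,
    replicate_id: int = 0,
    condition_label: str = "",
    rng: np.random.Generator | None = None,
) -> BindingDataset:
    """Simulate one replicate: a paired curve set plus Gaussian noise.

    Deterministic for a given ``truth.seed``/``replicate_id``; with
    ``noise_sd = 0`` the curves equal the closed-form evaluators exactly.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(replicate_id + 1)[-1])
    t_a = np.arange(0.0, truth.association_duration + 0.5 * truth.sampling_interval,
                    truth.sampling_interval)
    t_d = np.arange(0.0, truth.dissociation_duration + 0.5 * truth.sampling_interval,
                    truth.sampling_interval)
    curves = []
    for (cid, shp), conc in zip(truth._pair_shapes(), truth.concentrations):
        y_a = eval_association(truth.k_on, truth.k_off, truth.k_leak, conc, shp.on, t_a)
        y_d = eval_dissociation(truth.k_off, truth.k_leak, shp.off, t_d)
        if truth.noise_sd > 0:
            y_a = y_a + rng.normal(0.0, truth.noise_sd, size=y_a.size)
            y_d = y_d + rng.normal(0.0, truth.noise_sd, size=y_d.size)
        curves.append(SensorgramCurve(cid, Phase.ASSOCIATION, t_a, y_a, conc))
        curves.append(SensorgramCurve(cid, Phase.DISSOCIATION, t_d, y_d, conc))
    return BindingDataset(curves, condition_label=condition_label, replicate_id=replicate_id)


def simulate_replicates(truth: SimulationTruth, condition_label: str = "") -> list[BindingDataset]:
    """Simulate ``truth.n_replicates`` independent datasets (e.g. triplicates)."""
    children = np.random.SeedSequence(truth.seed).spawn(truth.n_replicates)
    return [
        simulate_dataset(
            truth,
            replicate_id=i,
            condition_label=condition_label,
            rng=np.random.default_rng(children[i]),
        )
        for i in range(truth.n_replicates)
    ]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    # multiplicative noise with mean exactly 1 and the requested CV;
    # cv = 0 degenerates to the identity
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def simulate_purification_table(
    true_yield_fraction: float,
    true_capacity: float,
    resin_volume: float,
    purity_fraction: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    eluate_volume: float = 10.0,
    residual_volume: float = 5.0,
    n_lanes: int = 3,
    total_lane_intensity: float = 1000.0,
) -> tuple[PurificationRecord, list[LaneDensitometry]]:
    """Back-compute a purification record consistent with a stated truth.

    Masses follow the chromatography accounting identities: total bound
    protein TPB = capacity * resin volume, light-eluted mass
    TPE = yield * TPB, residual mass TRP = TPB - TPE; concentrations are
    masses over the stated fraction volumes, perturbed by mean-1 lognormal
    noise of the given coefficient of variation (lognormal keeps simulated
    concentrations positive).  Lane band intensities are emitted so the
    target band's share equals ``purity_fraction``.

    With ``noise_cv = 0`` the forward accounting recovers the truth
    exactly; identical seeds reproduce the table bit-for-bit.
    """
    if not (0 < true_yield_fraction <= 1) or not (0 < purity_fraction <= 1):
        raise InputError("yield and purity fractions must be in (0, 1]")
    if true_capacity <= 0 or resin_volume <= 0 or eluate_volume <= 0 or residual_volume <= 0:
        raise InputError("capacity and volumes must be > 0")
    if noise_cv < 0:
        raise InputError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    tpb = true_capacity * resin_volume  # mg
    tpe = true_yield_fraction * tpb
    trp = tpb - tpe
    tpe_conc = tpe / eluate_volume * _lognormal_factor(rng, noise_cv)
    trp_conc = trp / residual_volume * _lognormal_factor(rng, noise_cv)
    record = PurificationRecord(
        tpe_conc=float(tpe_conc),
        tpe_vol=eluate_volume,
        trp_conc=float(trp_conc),
        trp_vol=residual_volume,
        resin_vol=resin_volume,
    )

    lanes = []
    for i in range(n_lanes):
        target = purity_fraction * total_lane_intensity * _lognormal_factor(rng, noise_cv)
        contaminant = (1.0 - purity_fraction) * total_lane_intensity * _lognormal_factor(
            rng, noise_cv
        )
        bands = [("target", float(target), True)]
        if contaminant > 0:
            bands.append(("contaminant", float(contaminant), False))
        lanes.append(LaneDensitometry(lane_id=f"lane{i + 1}", bands=bands))
    return record, lanes
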