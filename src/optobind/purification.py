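"""Light-controlled affinity chromatography (LCAC) accounting.

Captures the mass-balance arithmetic of a light-elution purification:
total protein eluted with light (TPE), total protein initially bound to
the resin (TPB = TPE + residual mass recovered afterwards), percentage
yield y = 100*TPE/TPB, and resin binding capacity C_R = TPB/V_R.  Purity
comes from gel densitometry: the target band's share of the total
integrated intensity in its lane.  The screen-stage readout — how much
more intensely a band pulls down in darkness than under light — is a
simple intensity ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "PurificationRecord",
    "LaneDensitometry",
    "total_protein_eluted",
    "total_protein_bound",
    "yield_percent",
    "resin_capacity",
    "purity_percent",
    "summarize_purity",
    "band_fold_difference",
    "pool_fractions",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class PurificationRecord:
    """Concentrations/volumes of the light-eluted and residual fractions.

    Fields: ``tpe_conc`` [mg/mL] and ``tpe_vol`` [mL] describe the pooled
    light eluate; ``trp_conc``/``trp_vol`` the residual protein recovered
    from the resin after light elution; ``resin_vol`` [mL] the resin bed
    volume V_R.
    """

    tpe_conc: float
    tpe_vol: float
    trp_conc: float
    trp_vol: float
    resin_vol: float
    protein_label: str = ""
    resin_label: str = ""

    def __post_init__(self):
        if self.tpe_conc < 0 or self.trp_conc < 0:
            raise InputError("concentrations must be >= 0 mg/mL")
        if self.tpe_vol <= 0 or self.trp_vol <= 0 or self.resin_vol <= 0:
            raise InputError("volumes must be > 0 mL")


@dataclass
class LaneDensitometry:
    """Integrated band intensities of one gel lane.

    ``bands`` is a list of ``(band_label, intensity, is_target)`` tuples in
    arbitrary densitometry units; exactly one band per lane carries the
    target flag.
    """

    lane_id: str
    bands: list[tuple[str, float, bool]] = field(default_factory=list)

    def __post_init__(self):
        if any(intensity < 0 for _, intensity, _ in self.bands):
            raise InputError(f"lane {self.lane_id!r}: band intensities must be >= 0")
        n_target = sum(1 for _, _, is_target in self.bands if is_target)
        if n_target != 1:
            raise InputError(
                f"lane {self.lane_id!r}: exactly one target band required, found {n_target}"
            )


def pool_fractions(fractions: list[tuple[float, float]]) -> tuple[float, float]:
    """Pool per-fraction (conc mg/mL, vol mL) rows into one (conc, vol) pair.

    Total mass is the sum of per-fraction masses; the pooled concentration
    is that mass over the total volume, so downstream mass arithmetic is
    unchanged whether fractions arrive pooled or separately.
    """
    if not fractions:
        raise InputError("no fractions to pool")
    if any(v <= 0 for _, v in fractions) or any(c < 0 for c, _ in fractions):
        raise InputError("fraction volumes must be > 0 and concentrations >= 0")
    total_vol = sum(v for _, v in fractions)
    total_mass = sum(c * v for c, v in fractions)
    return total_mass / total_vol, total_vol


def total_protein_eluted(rec: PurificationRecord) -> float:
    """Mass of protein eluted with light: TPE = [TPE] * TPEvol (mg)."""
    return rec.tpe_conc * rec.tpe_vol


def total_protein_bound(rec: PurificationRecord) -> float:
    """Mass initially bound to the resin: TPB = [TRP]*TRPvol + TPE (mg)."""
    return rec.trp_conc * rec.trp_vol + total_protein_eluted(rec)


def yield_percent(rec: PurificationRecord) -> float:
    """Percentage of bound protein recovered by light elution: 100*TPE/TPB."""
    tpb = total_protein_bound(rec)
    if tpb == 0:
        raise InputError("yield undefined: no protein bound (TPB = 0)")
    return 100.0 * total_protein_eluted(rec) / tpb


def resin_capacity(rec: PurificationRecord) -> float:
    """Resin binding capacity C_R = TPB / V_R (mg protein per mL resin)."""
    return total_protein_bound(rec) / rec.resin_vol


def purity_percent(lane: LaneDensitometry) -> float:
    """Target band intensity as a percentage of the lane's total intensity.

    Scale-free: multiplying every band by the same positive constant
    leaves the result unchanged.
    """
    total = sum(intensity for _, intensity, _ in lane.bands)
    if total <= 0:
        raise InputError(f"lane {lane.lane_id!r}: total intensity must be > 0")
    target = next(intensity for _, intensity, is_target in lane.bands if is_target)
    return 100.0 * target / total


def summarize_purity(lanes: list[LaneDensitometry]) -> dict:
    """Mean +/- sample SD of per-lane purity; SD is NaN for a single lane."""
    if not lanes:
        raise InputError("no lanes to summarize")
    values = np.array([purity_percent(lane) for lane in lanes])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return {
        "per_lane_percent": values.tolist(),
        "mean_percent": float(np.mean(values)),
        "sd_percent": sd,
        "n": int(values.size),
    }


def band_fold_difference(intensity_dark: float, intensity_light: float) -> float:
    """Dark/light band intensity ratio (unitless), e.g. the screen readout.

    Report with :func:`round_sig` at 2 significant figures alongside the
    full-precision value.
    """
    if intensity_dark <= 0 or intensity_light <= 0:
        raise InputError("band intensities must be > 0 for a fold-difference")
    return intensity_dark / intensity_light
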