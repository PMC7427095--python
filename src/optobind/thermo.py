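"""Conversions between affinity fold-changes and binding free energies.

A fold-change f in the dissociation constant between two states maps to a
free-energy difference ddG = R*T*ln(f); conversely f = exp(ddG/(R*T)).
The default temperature is 298.15 K (25 C).  Used here to compare the
measured lit/dark affinity shift of a photoswitchable binder against the
theoretical ceiling set by the free energy the photosensor makes
available on photon absorption (3.8 kcal/mol for wild-type AsLOV2, which
corresponds to a ~600-fold affinity ratio at 25 C).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InputError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoContext",
    "ddg_to_fold",
    "fold_to_ddg",
    "transmission_efficiency",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ThermoContext:
    """Temperature (K) and gas constant (kcal mol^-1 K^-1) for conversions."""

    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self):
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise InputError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def rt(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.gas_constant * self.temperature


def ddg_to_fold(ddg: float, ctx: ThermoContext | None = None) -> float:
    """Affinity fold-change implied by a free-energy difference (kcal/mol)."""
    ctx = ctx or ThermoContext()
    return math.exp(ddg / ctx.rt)


def fold_to_ddg(fold: float, ctx: ThermoContext | None = None) -> float:
    """Free-energy difference (kcal/mol) implied by an affinity fold-change."""
    ctx = ctx or ThermoContext()
    if fold <= 0 or not math.isfinite(fold):
        raise InputError(f"fold-change must be > 0, got {fold}")
    return ctx.rt * math.log(fold)


def log10_fold_to_ddg(log10_fold: float, ctx: ThermoContext | None = None) -> float:
    """Base-10 convenience variant: ddG for a fold-change of 10**log10_fold."""
    return fold_to_ddg(10.0 ** log10_fold, ctx)


def transmission_efficiency(
    measured_fold: float, max_ddg: float, ctx: ThermoContext | None = None
) -> float:
    """Fraction of the available free energy realized as an affinity shift.

    Ratio of the measured ddG = R*T*ln(measured_fold) to the stated
    ceiling ``max_ddg``.  A ratio above 1 (measured shift exceeding the
    ceiling) is clamped to 1 with a warning, since it indicates either an
    underestimated ceiling or measurement error.
    """
    ctx = ctx or ThermoContext()
    if measured_fold <= 1:
        raise InputError("measured_fold must be > 1 for a meaningful efficiency")
    if max_ddg <= 0:
        raise InputError("max_ddg must be > 0 kcal/mol")
    efficiency = fold_to_ddg(measured_fold, ctx) / max_ddg
    if efficiency > 1:
        warnings.warn(
            f"measured fold-change implies {efficiency:.2f}x the stated "
            "free-energy ceiling; clamping efficiency to 1",
            stacklevel=2,
        )
        return 1.0
    return efficiency
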