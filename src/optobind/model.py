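"""Binding data model and closed-form sensorgram curves.

A bio-layer interferometry (BLI) experiment on a light-switchable binder
produces, for each analyte concentration, an association phase (analyte
present) followed by a dissociation phase (buffer only).  Both phases are
described by a 1:1 Langmuir model multiplied by a slow exponential "leak"
that accounts for gradual loss of the His-tagged binder from the probe:

    association:  y(t) = [a * (1 - exp(-(k_on*C + k_off)*t)) + b] * exp(-k_leak*t)
    dissociation: y(t) = [a * exp(-k_off*t) + b] * exp(-k_leak*t)

with t phase-local (t = 0 at the start of each phase), C the analyte
concentration in uM, signal in nm.  Units are fixed package-wide:
concentrations uM, time s, k_on uM^-1 s^-1, k_off and k_leak s^-1,
signal nm.

A dataset of n association/dissociation pairs fitted globally has
4*n + 3 free parameters: shared (k_on, k_off, k_leak) plus per-pair
(a_on, b_on, a_off, b_off).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, UndefinedAffinityError

__all__ = [
    "Phase",
    "SensorgramCurve",
    "CurveShapeParams",
    "PairShapes",
    "GlobalKineticParams",
    "BindingDataset",
    "eval_association",
    "eval_dissociation",
    "observed_rate",
    "kd",
]


class Phase(str, enum.Enum):
    """Which phase of the sensorgram a curve belongs to."""

    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SensorgramCurve:
    """One phase-local time series of probe response.

    Parameters
    ----------
    curve_id
        Opaque label; an association curve and its paired dissociation
        curve share the same id.
    phase
        ``Phase.ASSOCIATION`` or ``Phase.DISSOCIATION``.
    times
        Seconds since the start of this phase; strictly increasing, >= 0.
    signal
        Probe response in nm, same length as ``times``.
    analyte_conc
        Analyte (SH2) concentration in uM.  Required and positive for
        association curves; optional for dissociation curves, where it is
        recorded only for pairing/bookkeeping.
    """

    curve_id: str
    phase: Phase
    times: np.ndarray
    signal: np.ndarray
    analyte_conc: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "phase", Phase(self.phase))
        times = _as_float_array(self.times, "times")
        signal = _as_float_array(self.signal, "signal")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)
        if times.size == 0:
            raise InputError(f"curve {self.curve_id!r}: empty time series")
        if times.size != signal.size:
            raise InputError(
                f"curve {self.curve_id!r}: times ({times.size}) and signal "
                f"({signal.size}) lengths differ"
            )
        if not np.all(np.isfinite(times)) or times[0] < 0:
            raise InputError(f"curve {self.curve_id!r}: times must be finite and >= 0")
        if np.any(np.diff(times) <= 0):
            raise InputError(f"curve {self.curve_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(signal)):
            raise InputError(f"curve {self.curve_id!r}: signal contains non-finite values")
        if self.phase is Phase.ASSOCIATION:
            if self.analyte_conc is None or not np.isfinite(self.analyte_conc):
                raise InputError(
                    f"curve {self.curve_id!r}: association curve requires a finite analyte_conc"
                )
            if self.analyte_conc <= 0:
                raise InputError(
                    f"curve {self.curve_id!r}: analyte_conc must be > 0 uM, "
                    f"got {self.analyte_conc}"
                )

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def equals(self, other: "SensorgramCurve", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if self.curve_id != other.curve_id or self.phase is not other.phase:
            return False
        conc_ok = (self.analyte_conc is None and other.analyte_conc is None) or (
            self.analyte_conc is not None
            and other.analyte_conc is not None
            and np.isclose(self.analyte_conc, other.analyte_conc, rtol=rtol, atol=atol)
        )
        return (
            conc_ok
            and self.times.size == other.times.size
            and np.allclose(self.times, other.times, rtol=rtol, atol=atol)
            and np.allclose(self.signal, other.signal, rtol=rtol, atol=atol)
        )


@dataclass
class CurveShapeParams:
    """Per-curve shape: total signal change ``a`` and baseline ``b`` (nm).

    ``a`` may carry any sign on input; physically sensible fits have
    ``a >= 0``.
    """

    a: float
    b: float

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise InputError(f"shape parameters must be finite, got a={self.a}, b={self.b}")


@dataclass
class PairShapes:
    """Shape parameters of one association/dissociation curve pair."""

    on: CurveShapeParams
    off: CurveShapeParams


@dataclass
class GlobalKineticParams:
    """Shared rate constants plus per-pair shape parameters.

    ``k_on`` (uM^-1 s^-1) and ``k_off`` (s^-1) are enforced identical
    across all curves of a dataset; ``k_leak`` (s^-1) models slow loss of
    the immobilized binder from the probe.  For n pairs the total free
    parameter count is 4*n + 3.
    """

    k_on: float
    k_off: float
    k_leak: float
    per_curve: dict[str, PairShapes] = field(default_factory=dict)

    def __post_init__(self):
        for name, value in (("k_on", self.k_on), ("k_off", self.k_off), ("k_leak", self.k_leak)):
            if not np.isfinite(value):
                raise InputError(f"{name} must be finite, got {value}")
        if self.k_on <= 0:
            raise InputError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0 or self.k_leak < 0:
            raise InputError("k_off and k_leak must be >= 0")

    @property
    def n_parameters(self) -> int:
        return 3 + 4 * len(self.per_curve)

    @property
    def kd(self) -> float:
        return kd(self.k_on, self.k_off)


class BindingDataset:
    """A set of paired association/dissociation curves; the unit of one fit.

    Pairing is by ``curve_id``: every association curve must have exactly
    one dissociation curve with the same id and vice versa (a bijection).
    Duplicate analyte concentrations across association curves are allowed
    but warned about, since the global model counts parameters per
    *distinct* concentration series member.
    """

    def __init__(
        self,
        curves: list[SensorgramCurve],
        condition_label: str = "",
        replicate_id: int = 0,
    ):
        self.curves = list(curves)
        self.condition_label = condition_label
        self.replicate_id = int(replicate_id)
        self._validate()

    def _validate(self):
        assoc = {c.curve_id for c in self.curves if c.phase is Phase.ASSOCIATION}
        dissoc = {c.curve_id for c in self.curves if c.phase is Phase.DISSOCIATION}
        if len(assoc) != sum(1 for c in self.curves if c.phase is Phase.ASSOCIATION):
            raise InputError("duplicate association curve_id in dataset")
        if len(dissoc) != sum(1 for c in self.curves if c.phase is Phase.DISSOCIATION):
            raise InputError("duplicate dissociation curve_id in dataset")
        concs = [c.analyte_conc for c in self.curves if c.phase is Phase.ASSOCIATION]
        if len(concs) != len(set(concs)):
            warnings.warn(
                "duplicate analyte concentrations within a dataset; the global "
                "model counts parameters per distinct concentration",
                stacklevel=3,
            )

    @property
    def association_curves(self) -> list[SensorgramCurve]:
        return [c for c in self.curves if c.phase is Phase.ASSOCIATION]

    @property
    def dissociation_curves(self) -> list[SensorgramCurve]:
        return [c for c in self.curves if c.phase is Phase.DISSOCIATION]

    def pairs(self) -> list[tuple[SensorgramCurve, SensorgramCurve]]:
        """Association/dissociation pairs matched by curve_id.

        Raises :class:`InputError` if the pairing is not a bijection.
        """
        assoc = {c.curve_id: c for c in self.association_curves}
        dissoc = {c.curve_id: c for c in self.dissociation_curves}
        unmatched = set(assoc) ^ set(dissoc)
        if unmatched:
            raise InputError(
                "association/dissociation pairing is not a bijection; "
                f"unpaired curve ids: {sorted(unmatched)}"
            )
        return [(assoc[cid], dissoc[cid]) for cid in sorted(assoc)]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs())

    def equals(self, other: "BindingDataset", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if len(self.curves) != len(other.curves):
            return False
        key = lambda c: (c.curve_id, c.phase.value)
        mine = sorted(self.curves, key=key)
        theirs = sorted(other.curves, key=key)
        return all(a.equals(b, rtol=rtol, atol=atol) for a, b in zip(mine, theirs))


# -- curve evaluation ---------------------------------------------------------

def _check_rates(k_on, k_off, k_leak):
    for name, value in (("k_on", k_on), ("k_off", k_off), ("k_leak", k_leak)):
        if not np.isfinite(value):
            raise InputError(f"{name} must be finite, got {value}")
    if k_on < 0 or k_off < 0 or k_leak < 0:
        raise InputError("rate constants must be non-negative")


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("times must be finite")
    if np.any(t < 0):
        raise InputError("times must be >= 0 (phase-local clock)")
    return t


def _assoc_raw(k_on, k_off, k_leak, conc, a, b, t):
    # shared formula; used by the public evaluator and by the fitter
    return (a * (1.0 - np.exp(-(k_on * conc + k_off) * t)) + b) * np.exp(-k_leak * t)


def _dissoc_raw(k_off, k_leak, a, b, t):
    return (a * np.exp(-k_off * t) + b) * np.exp(-k_leak * t)


def eval_association(k_on, k_off, k_leak, conc, shape: CurveShapeParams, t):
    """Evaluate the association-phase curve at phase-local times ``t``.

    Returns ``[a*(1 - exp(-(k_on*conc + k_off)*t)) + b] * exp(-k_leak*t)``
    in nm; vectorized over ``t`` preserving order.
    """
    _check_rates(k_on, k_off, k_leak)
    if not np.isfinite(conc) or conc <= 0:
        raise InputError(f"analyte concentration must be > 0 uM, got {conc}")
    t = _check_times(t)
    return _assoc_raw(k_on, k_off, k_leak, conc, shape.a, shape.b, t)


def eval_dissociation(k_off, k_leak, shape: CurveShapeParams, t):
    """Evaluate the dissociation-phase curve at phase-local times ``t``.

    Returns ``[a*exp(-k_off*t) + b] * exp(-k_leak*t)`` in nm; monotone
    non-increasing whenever a, b, k_off, k_leak are all >= 0.
    """
    _check_rates(0.0, k_off, k_leak)
    t = _check_times(t)
    return _dissoc_raw(k_off, k_leak, shape.a, shape.b, t)


def observed_rate(k_on, k_off, conc):
    """Pseudo-first-order apparent rate k_obs = k_on*conc + k_off (s^-1).

    Linear in concentration with slope k_on and intercept k_off; fitting a
    line to k_obs over >= 2 distinct concentrations recovers both rates.
    """
    if not np.all(np.isfinite(np.asarray(conc, dtype=float))) or np.any(
        np.asarray(conc, dtype=float) < 0
    ):
        raise InputError("concentration must be finite and >= 0")
    _check_rates(k_on, k_off, 0.0)
    return k_on * np.asarray(conc, dtype=float) + k_off


def kd(k_on, k_off):
    """Equilibrium dissociation constant K_d = k_off / k_on (uM)."""
    if not (np.isfinite(k_on) and np.isfinite(k_off)):
        raise InputError("rates must be finite")
    if k_on == 0:
        raise UndefinedAffinityError("K_d is undefined for k_on = 0")
    if k_on < 0 or k_off < 0:
        raise InputError("rates must be non-negative")
    return k_off / k_on
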