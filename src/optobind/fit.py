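"""Global nonlinear fit of paired sensorgram curves.

All association and dissociation curves of one dataset are fit
simultaneously by unweighted least squares to the closed-form 1:1 model
with probe leak: the three rate constants (k_on, k_off, k_leak) are
shared across every curve, and each association/dissociation pair
contributes four shape parameters (a_on, b_on, a_off, b_off), giving
4n + 3 free parameters for n pairs.

Rates are optimized in log10 space, which enforces positivity without
active bounds and equalizes step sizes across regimes whose rates span
several orders of magnitude (the lit and dark states of a photoswitchable
binder differ ~20-fold in k_on and k_off).  Shape parameters stay linear.
Optimization uses trust-region-reflective least squares with a
deterministic seeded multi-start; confidence intervals come from a
nonparametric residual bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import BootstrapError, FitConvergenceError, InputError
from .model import (
    BindingDataset,
    CurveShapeParams,
    GlobalKineticParams,
    PairShapes,
    Phase,
    SensorgramCurve,
    _assoc_raw,
    _dissoc_raw,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitOptions",
    "FitResult",
    "IntervalSet",
    "ReplicateSummary",
    "initial_guess",
    "fit_global",
    "bootstrap_ci",
    "summarize_replicates",
    "fold_change",
]

_RATE_NAMES = ("k_on", "k_off", "k_leak")

#: Default rate bounds: every measured regime sits >= 2 decades inside them.
DEFAULT_BOUNDS = {
    "k_on": (1e-5, 10.0),  # uM^-1 s^-1
    "k_off": (1e-5, 10.0),  # s^-1
    "k_leak": (1e-7, 0.1),  # s^-1
}

#: Fitted |a_on| below this (nm) marks a dataset with no binding signal,
#: for which the shared rates are unidentifiable.
_AMPLITUDE_FLOOR_NM = 1e-6


@dataclass
class FitOptions:
    """Optimizer configuration for :func:`fit_global`.

    ``n_restarts`` seeded multi-start runs are performed; restart 0 starts
    at the data-driven initial guess, later restarts jitter the rate
    constants by Gaussian perturbations of ``jitter_scale`` log10 units
    (and shapes by the same relative scale).  The best converged objective
    wins; ties go to the lowest restart index.
    """

    n_restarts: int = 5
    jitter_scale: float = 0.3
    max_iterations: int = 2000
    objective_tolerance: float = 1e-12
    parameter_log_scale: bool = True
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int = 0
    fixed_rates: dict[str, float] = field(default_factory=dict)
    fixed_shapes: dict[str, PairShapes] | None = None

    def __post_init__(self):
        if self.n_restarts < 1:
            raise InputError("n_restarts must be >= 1")
        if self.objective_tolerance <= 0 or self.max_iterations < 1:
            raise InputError("tolerances must be > 0 and max_iterations >= 1")
        for name in _RATE_NAMES:
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
            if not lo < hi:
                raise InputError(f"bounds for {name} must satisfy lower < upper")
            self.bounds[name] = (lo, hi)
        unknown = set(self.fixed_rates) - set(_RATE_NAMES)
        if unknown:
            raise InputError(f"unknown fixed rate(s): {sorted(unknown)}")


@dataclass
class FitResult:
    """Outcome of one global fit."""

    params: GlobalKineticParams
    kd: float
    sum_squared_residuals: float
    per_curve_residuals: dict[str, dict[str, np.ndarray]]
    converged: bool
    n_parameters: int
    restarts_tried: int
    best_restart_index: int
    n_observations: int
    kd_is_lower_bound: bool = False
    rates_identifiable: bool = True
    message: str = ""

    @property
    def kd_report(self) -> str:
        """Human-readable K_d, one-sided when k_on pinned its lower bound."""
        return (f"> {self.kd:.4g} uM" if self.kd_is_lower_bound else f"{self.kd:.4g} uM")


@dataclass
class IntervalSet:
    """Percentile bootstrap confidence intervals for the shared parameters."""

    intervals: dict[str, tuple[float, float]]
    estimates: dict[str, float]
    level: float
    method: str
    n_boot: int
    n_failed: int
    seed: int


@dataclass
class ReplicateSummary:
    """Per-replicate K_d values with their mean and sample SD.

    Replicates are fit independently and their K_d values averaged — the
    mean of per-replicate ratios, not the ratio of mean rates.  SD uses
    the n-1 denominator and is NaN (undefined), not 0, for n = 1.
    """

    condition_label: str
    kds: list[float]
    mean_kd: float
    sd_kd: float
    n: int


# -- parameter packing --------------------------------------------------------


class _ParamLayout:
    """Maps between the flat optimizer vector and GlobalKineticParams."""

    def __init__(self, pair_ids: list[str], options: FitOptions):
        self.pair_ids = pair_ids
        self.options = options
        self.free_rates = [r for r in _RATE_NAMES if r not in options.fixed_rates]
        self.shapes_free = options.fixed_shapes is None
        self.n_free = len(self.free_rates) + (4 * len(pair_ids) if self.shapes_free else 0)

    def pack(self, params: GlobalKineticParams) -> np.ndarray:
        theta = []
        for r in self.free_rates:
            value = getattr(params, r)
            lo, hi = self.options.bounds[r]
            theta.append(np.log10(np.clip(value, lo, hi)))
        if self.shapes_free:
            for cid in self.pair_ids:
                shp = params.per_curve[cid]
                theta.extend([shp.on.a, shp.on.b, shp.off.a, shp.off.b])
        return np.array(theta)

    def unpack(self, theta: np.ndarray) -> GlobalKineticParams:
        rates = dict(self.options.fixed_rates)
        for i, r in enumerate(self.free_rates):
            rates[r] = 10.0 ** theta[i]
        per_curve = {}
        if self.shapes_free:
            off = len(self.free_rates)
            for j, cid in enumerate(self.pair_ids):
                a_on, b_on, a_off, b_off = theta[off + 4 * j : off + 4 * j + 4]
                per_curve[cid] = PairShapes(
                    CurveShapeParams(a_on, b_on), CurveShapeParams(a_off, b_off)
                )
        else:
            per_curve = {cid: self.options.fixed_shapes[cid] for cid in self.pair_ids}
        return GlobalKineticParams(per_curve=per_curve, **rates)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for r in self.free_rates:
            b = self.options.bounds[r]
            lo.append(np.log10(b[0]))
            hi.append(np.log10(b[1]))
        if self.shapes_free:
            lo.extend([-np.inf] * 4 * len(self.pair_ids))
            hi.extend([np.inf] * 4 * len(self.pair_ids))
        return np.array(lo), np.array(hi)


def _pooled_residuals(theta, layout: _ParamLayout, pairs):
    """Concatenated (model - observed) over every curve of the dataset."""
    rates = dict(layout.options.fixed_rates)
    for i, r in enumerate(layout.free_rates):
        rates[r] = 10.0 ** theta[i]
    k_on, k_off, k_leak = rates["k_on"], rates["k_off"], rates["k_leak"]
    out = []
    n_rates = len(layout.free_rates)
    for j, (ac, dc) in enumerate(pairs):
        if layout.shapes_free:
            a_on, b_on, a_off, b_off = theta[n_rates + 4 * j : n_rates + 4 * j + 4]
        else:
            shp = layout.options.fixed_shapes[ac.curve_id]
            a_on, b_on, a_off, b_off = shp.on.a, shp.on.b, shp.off.a, shp.off.b
        out.append(_assoc_raw(k_on, k_off, k_leak, ac.analyte_conc, a_on, b_on, ac.times)
                   - ac.signal)
        out.append(_dissoc_raw(k_off, k_leak, a_off, b_off, dc.times) - dc.signal)
    return np.concatenate(out)


# -- initialization -----------------------------------------------------------


def _single_exp_kobs(curve: SensorgramCurve) -> float | None:
    """Apparent rate of one association curve from a single-exponential fit."""
    t, y = curve.times, curve.signal
    b0 = float(y[0])
    tail = max(3, y.size // 10)
    plateau = float(np.median(y[-tail:]))
    amp = plateau - b0
    if abs(amp) < 1e-9:
        return None
    # 63.2% crossing gives a robust starting rate for the refinement fit
    target = b0 + 0.632 * amp
    crossed = np.nonzero((y - target) * np.sign(amp) >= 0)[0]
    t63 = float(t[crossed[0]]) if crossed.size and t[crossed[0]] > 0 else float(t[-1]) / 3
    k0 = 1.0 / max(t63, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tt, a, b, k: a * (1.0 - np.exp(-k * tt)) + b,
                t, y, p0=[amp, b0, k0], maxfev=5000,
            )
        k = float(popt[2])
        return k if np.isfinite(k) and k > 0 else k0
    except (RuntimeError, ValueError):
        return k0


def _early_decay_rate(curve: SensorgramCurve) -> float | None:
    """Log-linear decay rate of a dissociation curve's early portion."""
    t, y = curve.times, curve.signal
    tail = max(3, y.size // 10)
    b0 = float(np.median(y[-tail:]))
    resid = y - b0
    first = float(resid[0])
    if abs(first) < 1e-9:
        return None
    # early decay: down to 1/e of the initial excursion, at least 5 points
    mask = resid * np.sign(first) > abs(first) / np.e
    n_early = max(5, int(np.count_nonzero(mask)))
    n_early = min(n_early, y.size)
    tt, rr = t[:n_early], resid[:n_early] * np.sign(first)
    keep = rr > 0
    if np.count_nonzero(keep) < 2:
        return None
    slope = np.polyfit(tt[keep], np.log(rr[keep]), 1)[0]
    return -float(slope) if slope < 0 else None


def _late_decay_rate(curve: SensorgramCurve) -> float | None:
    """Decay rate of the final quarter of a dissociation curve."""
    n_late = max(5, curve.n_points // 4)
    t, y = curve.times[-n_late:], curve.signal[-n_late:]
    keep = y > 1e-9
    if np.count_nonzero(keep) < 2:
        return None
    slope = np.polyfit(t[keep], np.log(y[keep]), 1)[0]
    return -float(slope) if slope < 0 else None


def initial_guess(dataset: BindingDataset, options: FitOptions | None = None) -> GlobalKineticParams:
    """Data-driven starting point for the global fit.

    k_off is the median early-decay rate of the dissociation curves; each
    association curve contributes a single-exponential apparent rate
    k_obs, and k_on comes from the slope of k_obs against concentration
    (clamped positive).  k_leak is taken from the late-time decay of the
    dissociation curves, floored at 1e-6 s^-1.  Amplitudes start at each
    curve's signal range and baselines at its first value.
    """
    options = options or FitOptions()
    pairs = dataset.pairs()
    if not pairs:
        raise InputError("dataset has no association/dissociation pairs")

    koff_lo, koff_hi = options.bounds["k_off"]
    kon_lo, kon_hi = options.bounds["k_on"]
    kleak_lo, kleak_hi = options.bounds["k_leak"]

    koff_estimates = [r for _, dc in pairs if (r := _early_decay_rate(dc)) is not None]
    k_off = float(np.clip(np.median(koff_estimates), koff_lo, koff_hi)) if koff_estimates else koff_lo

    kobs, concs = [], []
    for ac, _ in pairs:
        k = _single_exp_kobs(ac)
        if k is not None:
            kobs.append(k)
            concs.append(ac.analyte_conc)
    if len(set(concs)) >= 2:
        slope = np.polyfit(concs, kobs, 1)[0]
        k_on = float(np.clip(slope, kon_lo, kon_hi))
    elif kobs:
        warnings.warn(
            "fewer than 2 distinct concentrations; initializing k_on from a "
            "single k_obs",
            stacklevel=2,
        )
        k_on = float(np.clip(max(kobs[0] - k_off, kon_lo) / concs[0], kon_lo, kon_hi))
    else:
        k_on = float(np.clip(np.sqrt(kon_lo * kon_hi), kon_lo, kon_hi))

    late = [r for _, dc in pairs if (r := _late_decay_rate(dc)) is not None]
    # the late tail decays at roughly k_off + k_leak when the baseline is
    # small, so subtract the k_off estimate before clamping
    k_leak = (
        float(np.clip(min(late) - k_off, kleak_lo, kleak_hi)) if late else max(1e-6, kleak_lo)
    )
    k_leak = max(k_leak, 1e-6)

    per_curve = {}
    for ac, dc in pairs:
        a_on = float(np.max(ac.signal) - ac.signal[0])
        b_on = float(ac.signal[0])
        a_off = float(dc.signal[0] - np.min(dc.signal))
        b_off = float(np.min(dc.signal))
        per_curve[ac.curve_id] = PairShapes(
            CurveShapeParams(a_on, b_on), CurveShapeParams(a_off, b_off)
        )
    return GlobalKineticParams(k_on=k_on, k_off=k_off, k_leak=k_leak, per_curve=per_curve)


# -- global fit ---------------------------------------------------------------


def fit_global(
    dataset: BindingDataset,
    options: FitOptions | None = None,
    initial: GlobalKineticParams | None = None,
) -> FitResult:
    """Fit all curves of a dataset simultaneously by pooled least squares.

    Minimizes the single sum of squared residuals over every association
    and dissociation curve with the three rates shared; returns the best
    of ``options.n_restarts`` seeded multi-start runs.  Deterministic for
    a given seed.

    Raises
    ------
    InputError
        If the dataset has no dissociation curves (k_off and k_leak are
        then unidentifiable as parameterized).
    FitConvergenceError
        If no restart converges; carries per-restart diagnostics.
    """
    options = options or FitOptions()
    pairs = dataset.pairs()
    if not pairs:
        raise InputError("dataset has no association/dissociation pairs")
    if not dataset.dissociation_curves:
        raise InputError("dataset has no dissociation curves; k_off is unidentifiable")

    layout = _ParamLayout([ac.curve_id for ac, _ in pairs], options)
    theta0 = layout.pack(initial if initial is not None else initial_guess(dataset, options))
    lo, hi = layout.bounds_arrays()
    theta0 = np.clip(theta0, lo, hi)
    rng = np.random.default_rng(options.seed)
    n_rates = len(layout.free_rates)

    results = []
    for restart in range(options.n_restarts):
        theta = theta0.copy()
        if restart > 0:
            theta[:n_rates] += rng.normal(0.0, options.jitter_scale, size=n_rates)
            if layout.shapes_free:
                shape_part = theta[n_rates:]
                theta[n_rates:] = shape_part * (
                    1.0 + rng.normal(0.0, options.jitter_scale, size=shape_part.size)
                )
            theta = np.clip(theta, lo, hi)
        try:
            sol = least_squares(
                _pooled_residuals,
                theta,
                args=(layout, pairs),
                bounds=(lo, hi),
                method="trf",
                ftol=options.objective_tolerance,
                xtol=options.objective_tolerance,
                gtol=options.objective_tolerance,
                max_nfev=options.max_iterations,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            results.append({"restart": restart, "ok": False, "message": str(exc)})
            continue
        results.append(
            {
                "restart": restart,
                "ok": sol.status > 0,
                "cost": float(sol.cost),
                "theta": sol.x,
                "message": sol.message,
            }
        )
        logger.debug("restart %d: status=%s cost=%.6g", restart, sol.status, sol.cost)

    converged = [r for r in results if r.get("ok")]
    if not converged:
        raise FitConvergenceError(
            f"global fit failed to converge in all {options.n_restarts} restarts",
            diagnostics=results,
        )
    best = min(converged, key=lambda r: (r["cost"], r["restart"]))
    params = layout.unpack(best["theta"])

    residuals = {}
    ssr = 0.0
    for ac, dc in pairs:
        shp = params.per_curve[ac.curve_id]
        r_a = (
            _assoc_raw(params.k_on, params.k_off, params.k_leak, ac.analyte_conc,
                       shp.on.a, shp.on.b, ac.times)
            - ac.signal
        )
        r_d = _dissoc_raw(params.k_off, params.k_leak, shp.off.a, shp.off.b, dc.times) - dc.signal
        residuals[ac.curve_id] = {"association": r_a, "dissociation": r_d}
        ssr += float(r_a @ r_a + r_d @ r_d)

    max_amp = max(abs(shp.on.a) for shp in params.per_curve.values())
    identifiable = max_amp > _AMPLITUDE_FLOOR_NM
    kon_lo = options.bounds["k_on"][0]
    # k_on pinned at its lower bound: only a lower bound on K_d is supported
    pinned = "k_on" not in options.fixed_rates and params.k_on <= kon_lo * (1 + 1e-6)

    n_obs = sum(ac.n_points + dc.n_points for ac, dc in pairs)
    message = best["message"] if identifiable else (
        best["message"] + "; no binding signal detected: rates unidentifiable"
    )
    if not identifiable:
        logger.warning("fit for %r: %s", dataset.condition_label, message)
    logger.info(
        "fit %r replicate %d: k_on=%.4g k_off=%.4g k_leak=%.4g Kd=%.4g (ssr=%.4g, "
        "restart %d of %d)",
        dataset.condition_label, dataset.replicate_id, params.k_on, params.k_off,
        params.k_leak, params.kd, best["restart"], options.n_restarts,
    )
    return FitResult(
        params=params,
        kd=params.kd,
        sum_squared_residuals=ssr,
        per_curve_residuals=residuals,
        converged=True,
        n_parameters=layout.n_free,
        restarts_tried=len(results),
        best_restart_index=best["restart"],
        n_observations=n_obs,
        kd_is_lower_bound=bool(pinned),
        rates_identifiable=bool(identifiable),
        message=message,
    )


# -- bootstrap ----------------------------------------------------------------


def bootstrap_ci(
    dataset: BindingDataset,
    fit: FitResult,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
    options: FitOptions | None = None,
    max_failure_rate: float = 0.2,
) -> IntervalSet:
    """Percentile confidence intervals from a residual bootstrap.

    Each replicate resamples every curve's residual vector with
    replacement, adds it to that curve's fitted values, and refits the
    global model warm-started from the point estimate.  Intervals are the
    percentile range at ``level`` for k_on, k_off, k_leak and K_d,
    expanded where necessary to include the point estimate (relevant only
    at small n_boot).  Reproducible for a given seed.

    Raises :class:`BootstrapError` when more than ``max_failure_rate`` of
    replicates fail to refit.
    """
    if not fit.converged:
        raise InputError("bootstrap requires a converged fit")
    if n_boot < 50:
        raise InputError("n_boot must be >= 50")
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    base_options = options or FitOptions()
    refit_options = replace(base_options, n_restarts=1)
    pairs = dataset.pairs()
    rng = np.random.default_rng(seed)

    fitted = {}
    for ac, dc in pairs:
        res = fit.per_curve_residuals[ac.curve_id]
        fitted[ac.curve_id] = (ac.signal - res["association"], dc.signal - res["dissociation"])

    draws = {name: [] for name in ("k_on", "k_off", "k_leak", "kd")}
    n_failed = 0
    for _ in range(n_boot):
        curves = []
        for ac, dc in pairs:
            res = fit.per_curve_residuals[ac.curve_id]
            fit_a, fit_d = fitted[ac.curve_id]
            r_a = res["association"][rng.integers(0, res["association"].size,
                                                  size=res["association"].size)]
            r_d = res["dissociation"][rng.integers(0, res["dissociation"].size,
                                                   size=res["dissociation"].size)]
            curves.append(SensorgramCurve(ac.curve_id, Phase.ASSOCIATION, ac.times,
                                          fit_a + r_a, ac.analyte_conc))
            curves.append(SensorgramCurve(dc.curve_id, Phase.DISSOCIATION, dc.times,
                                          fit_d + r_d, dc.analyte_conc))
        boot_ds = BindingDataset(curves, dataset.condition_label, dataset.replicate_id)
        try:
            boot_fit = fit_global(boot_ds, refit_options, initial=fit.params)
        except (FitConvergenceError, InputError):
            n_failed += 1
            continue
        draws["k_on"].append(boot_fit.params.k_on)
        draws["k_off"].append(boot_fit.params.k_off)
        draws["k_leak"].append(boot_fit.params.k_leak)
        draws["kd"].append(boot_fit.kd)

    if n_failed > max_failure_rate * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap refits failed (> {max_failure_rate:.0%})",
            n_failed=n_failed,
            n_total=n_boot,
        )

    alpha = (1.0 - level) / 2.0
    estimates = {
        "k_on": fit.params.k_on,
        "k_off": fit.params.k_off,
        "k_leak": fit.params.k_leak,
        "kd": fit.kd,
    }
    intervals = {}
    for name, values in draws.items():
        arr = np.array(values)
        lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
        intervals[name] = (min(float(lo), estimates[name]), max(float(hi), estimates[name]))
    return IntervalSet(
        intervals=intervals,
        estimates=estimates,
        level=level,
        method="percentile residual bootstrap",
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )


# -- summaries ----------------------------------------------------------------


def summarize_replicates(fits: list[FitResult], condition_label: str = "") -> ReplicateSummary:
    """Mean and sample SD of per-replicate K_d values."""
    if not fits:
        raise InputError("no fits to summarize")
    kds = [f.kd for f in fits]
    mean = float(np.mean(kds))
    sd = float(np.std(kds, ddof=1)) if len(kds) > 1 else float("nan")
    return ReplicateSummary(
        condition_label=condition_label, kds=kds, mean_kd=mean, sd_kd=sd, n=len(kds)
    )


def fold_change(kd_state_a: float, kd_state_b: float) -> float:
    """Affinity fold-change K_d(a)/K_d(b); for a lit/dark comparison pass
    the lit-state K_d as the numerator."""
    if kd_state_a <= 0 or kd_state_b <= 0:
        raise InputError("K_d values must be > 0 for a fold-change")
    return kd_state_a / kd_state_b
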