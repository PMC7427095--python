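"""File readers and writers.

Sensorgram files are delimited text (comma or tab, autodetected) with a
required header ``curve_id, phase, time_s, signal_nm, conc_uM``; the
column names carry the package-wide units (seconds, nm, uM) and files
using other unit suffixes are refused rather than silently converted.
Dissociation rows may leave ``conc_uM`` empty.  Purification fraction
and gel-lane densitometry tables are plain CSV.  Fit results serialize
to JSON with units spelled out in the field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .fit import FitResult, IntervalSet
from .model import BindingDataset, Phase, SensorgramCurve
from .purification import LaneDensitometry, PurificationRecord, pool_fractions

SENSORGRAM_COLUMNS = ["curve_id", "phase", "time_s", "signal_nm", "conc_uM"]

_UNIT_PREFIXES = {"time": "time_s", "signal": "signal_nm", "conc": "conc_uM"}


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"{path}: empty input file")
    return "\t" if "\t" in header else ","


def _check_columns(columns, path):
    missing = [c for c in SENSORGRAM_COLUMNS if c not in columns]
    for col in columns:
        for prefix, expected in _UNIT_PREFIXES.items():
            if col.startswith(prefix) and col != expected:
                raise InputError(
                    f"{path}: column {col!r} has an unexpected unit annotation; "
                    f"expected {expected!r} (package units are s, nm, uM)"
                )
    if missing:
        raise InputError(f"{path}: missing required column(s): {missing}")


def read_sensorgrams(
    path, condition_label: str = "", replicate_id: int = 0
) -> BindingDataset:
    """Read a sensorgram table into a validated :class:`BindingDataset`.

    Malformed rows are reported with their 1-based file line numbers
    (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    sep = _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"curve_id": str, "phase": str})
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty input file") from None
    _check_columns(df.columns, path)
    if df.empty:
        raise InputError(f"{path}: file contains a header but no data rows")

    bad_phase = df.index[~df["phase"].isin([p.value for p in Phase])]
    if len(bad_phase):
        lines = [int(i) + 2 for i in bad_phase[:5]]
        raise InputError(
            f"{path}: invalid phase value(s) at line(s) {lines}; "
            f"field 'phase' must be one of {[p.value for p in Phase]}"
        )
    for col in ("time_s", "signal_nm"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise InputError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = values
    df["conc_uM"] = pd.to_numeric(df["conc_uM"], errors="coerce")

    curves = []
    for (cid, phase), grp in df.groupby(["curve_id", "phase"], sort=False):
        conc = grp["conc_uM"].dropna()
        conc_value = float(conc.iloc[0]) if len(conc) else None
        try:
            curves.append(
                SensorgramCurve(
                    curve_id=str(cid),
                    phase=Phase(phase),
                    times=grp["time_s"].to_numpy(),
                    signal=grp["signal_nm"].to_numpy(),
                    analyte_conc=conc_value,
                )
            )
        except InputError as exc:
            first_line = int(grp.index[0]) + 2
            raise InputError(f"{path}: rows starting at line {first_line}: {exc}") from None
    return BindingDataset(curves, condition_label=condition_label, replicate_id=replicate_id)


def write_sensorgrams(dataset: BindingDataset, path, sep: str = ",") -> None:
    """Write a dataset in the same dialect :func:`read_sensorgrams` accepts."""
    rows = []
    for c in dataset.curves:
        conc = "" if c.analyte_conc is None else np.repeat(c.analyte_conc, c.n_points)
        rows.append(
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "phase": c.phase.value,
                    "time_s": c.times,
                    "signal_nm": c.signal,
                    "conc_uM": conc,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep=sep, index=False, float_format="%.10g")


# -- purification tables ------------------------------------------------------


def read_fractions(path, resin_vol: float) -> PurificationRecord:
    """Read a fraction table (light eluates + residual) into a record.

    Expected CSV columns: ``fraction_type`` (``light_eluate`` or
    ``residual``), ``conc_mg_ml``, ``vol_ml``.  Multiple light-eluate rows
    are pooled mass-consistently; multiple residual rows likewise.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty input file") from None
    required = {"fraction_type", "conc_mg_ml", "vol_ml"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing required column(s): {sorted(missing)}")
    valid = {"light_eluate", "residual"}
    bad = df.index[~df["fraction_type"].isin(valid)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise InputError(
            f"{path}: invalid fraction_type at line(s) {lines}; expected one of {sorted(valid)}"
        )
    eluates = [
        (float(r.conc_mg_ml), float(r.vol_ml))
        for r in df[df["fraction_type"] == "light_eluate"].itertuples()
    ]
    residuals = [
        (float(r.conc_mg_ml), float(r.vol_ml))
        for r in df[df["fraction_type"] == "residual"].itertuples()
    ]
    if not eluates or not residuals:
        raise InputError(f"{path}: need at least one light_eluate and one residual row")
    tpe_conc, tpe_vol = pool_fractions(eluates)
    trp_conc, trp_vol = pool_fractions(residuals)
    return PurificationRecord(
        tpe_conc=tpe_conc, tpe_vol=tpe_vol, trp_conc=trp_conc, trp_vol=trp_vol,
        resin_vol=resin_vol,
    )


def read_lanes(path) -> list[LaneDensitometry]:
    """Read a densitometry table: ``lane_id, band_label, intensity, is_target``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty input file") from None
    required = {"lane_id", "band_label", "intensity", "is_target"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing required column(s): {sorted(missing)}")
    lanes = []
    for lane_id, grp in df.groupby("lane_id", sort=False):
        bands = [
            (str(r.band_label), float(r.intensity), bool(r.is_target))
            for r in grp.itertuples()
        ]
        lanes.append(LaneDensitometry(lane_id=str(lane_id), bands=bands))
    return lanes


# -- JSON serialization -------------------------------------------------------


def fit_result_to_dict(fit: FitResult, extra: dict | None = None) -> dict:
    """JSON-ready dictionary for a fit result, units in the field names."""
    out = {
        "k_on_per_uM_per_s": fit.params.k_on,
        "k_off_per_s": fit.params.k_off,
        "k_leak_per_s": fit.params.k_leak,
        "kd_uM": fit.kd,
        "kd_is_lower_bound": fit.kd_is_lower_bound,
        "kd_report": fit.kd_report,
        "sum_squared_residuals_nm2": fit.sum_squared_residuals,
        "n_parameters": fit.n_parameters,
        "n_observations": fit.n_observations,
        "converged": fit.converged,
        "rates_identifiable": fit.rates_identifiable,
        "restarts_tried": fit.restarts_tried,
        "best_restart_index": fit.best_restart_index,
        "per_curve_nm": {
            cid: {
                "a_on_nm": shp.on.a,
                "b_on_nm": shp.on.b,
                "a_off_nm": shp.off.a,
                "b_off_nm": shp.off.b,
            }
            for cid, shp in fit.params.per_curve.items()
        },
    }
    if extra:
        out.update(extra)
    return out


def interval_set_to_dict(ci: IntervalSet) -> dict:
    units = {
        "k_on": "per_uM_per_s",
        "k_off": "per_s",
        "k_leak": "per_s",
        "kd": "uM",
    }
    return {
        "method": ci.method,
        "level": ci.level,
        "n_boot": ci.n_boot,
        "n_failed": ci.n_failed,
        "seed": ci.seed,
        "intervals": {
            f"{name}_{units[name]}": {
                "estimate": ci.estimates[name],
                "lower": lo,
                "upper": hi,
            }
            for name, (lo, hi) in ci.intervals.items()
        },
    }


def residuals_to_frame(fit: FitResult) -> pd.DataFrame:
    """Per-point residuals as a tidy table for CSV export."""
    rows = []
    for cid, phases in fit.per_curve_residuals.items():
        for phase, res in phases.items():
            rows.append(
                pd.DataFrame({"curve_id": cid, "phase": phase,
                              "point_index": np.arange(res.size), "residual_nm": res})
            )
    return pd.concat(rows, ignore_index=True)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
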