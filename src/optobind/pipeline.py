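"""End-to-end orchestration: simulate -> fit -> summarize -> thermodynamics.

Runs triplicate simulated BLI experiments at the dark-locked and
lit-stabilized rate presets, fits each replicate globally, averages the
per-replicate K_d values, forms the lit/dark affinity fold-change,
converts it to a binding free-energy difference and compares against the
photosensor's free-energy ceiling.  Every artifact embeds the package
version, seed and a hash of the configuration, so deterministic stages
re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import OptobindError
from .fit import (
    FitOptions,
    bootstrap_ci,
    fit_global,
    fold_change,
    summarize_replicates,
)
from .io import fit_result_to_dict, interval_set_to_dict, write_json
from .purification import round_sig
from .simulate import preset_truth, simulate_replicates
from .thermo import ThermoContext, ddg_to_fold, fold_to_ddg, transmission_efficiency

logger = logging.getLogger(__name__)

#: Free energy (kcal/mol) available from the photosensor's dark-to-light
#: conformational change; the ceiling on the achievable affinity shift.
MAX_TRANSMITTED_DDG_KCAL = 3.8


@dataclass
class RunConfig:
    """Configuration of one :func:`reproduce` run."""

    dark_preset: str = "dark_c450v"
    lit_preset: str = "lit_v416l"
    n_concentrations: int = 3
    n_replicates: int = 3
    noise_sd: float = 0.01
    sampling_interval: float = 1.0
    association_duration: float = 300.0
    dissociation_duration: float = 600.0
    k_leak: float = 5e-4
    seed: int = 0
    with_ci: bool = True
    n_boot: int = 200
    ci_level: float = 0.95
    temperature_k: float = 298.15
    max_ddg_kcal: float = MAX_TRANSMITTED_DDG_KCAL
    fit: FitOptions = field(default_factory=FitOptions)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["fit"].pop("fixed_shapes", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _fit_condition(config: RunConfig, preset: str, label: str, seed: int):
    truth = preset_truth(
        preset,
        n_replicates=config.n_replicates,
        noise_sd=config.noise_sd,
        sampling_interval=config.sampling_interval,
        association_duration=config.association_duration,
        dissociation_duration=config.dissociation_duration,
        k_leak=config.k_leak,
        seed=seed,
    )
    datasets = simulate_replicates(truth, condition_label=label)
    fits = []
    for i, ds in enumerate(datasets):
        opts = FitOptions(
            n_restarts=config.fit.n_restarts,
            jitter_scale=config.fit.jitter_scale,
            max_iterations=config.fit.max_iterations,
            objective_tolerance=config.fit.objective_tolerance,
            seed=seed + 1000 + i,
        )
        fits.append(fit_global(ds, opts))
    return truth, datasets, fits


def reproduce(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full simulate/fit/summarize/thermo pipeline; return the report.

    When ``out_dir`` is given, writes ``report.json`` and a human-readable
    ``report.txt`` there.  Any stage failure raises with the stage named;
    partial outputs written so far are left in place.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    stage = "simulate+fit dark"
    try:
        dark_truth, _, dark_fits = _fit_condition(
            config, config.dark_preset, "dark", int(seeds[0])
        )
        stage = "simulate+fit lit"
        lit_truth, lit_datasets, lit_fits = _fit_condition(
            config, config.lit_preset, "lit", int(seeds[1])
        )

        stage = "summarize replicates"
        dark_summary = summarize_replicates(dark_fits, "dark")
        lit_summary = summarize_replicates(lit_fits, "lit")

        stage = "fold-change and thermodynamics"
        fold_of_means = fold_change(lit_summary.mean_kd, dark_summary.mean_kd)
        per_replicate_folds = [
            fold_change(lit_kd, dark_kd)
            for lit_kd, dark_kd in zip(lit_summary.kds, dark_summary.kds)
        ]
        mean_of_folds = float(np.mean(per_replicate_folds))
        ctx = ThermoContext(temperature=config.temperature_k)
        ddg = fold_to_ddg(fold_of_means, ctx)
        ceiling_fold = ddg_to_fold(config.max_ddg_kcal, ctx)
        efficiency = transmission_efficiency(fold_of_means, config.max_ddg_kcal, ctx)

        report = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "conditions": {
                "dark": {
                    "preset": config.dark_preset,
                    "true_k_on_per_uM_per_s": dark_truth.k_on,
                    "true_k_off_per_s": dark_truth.k_off,
                    "true_kd_uM": dark_truth.kd,
                    "fits": [fit_result_to_dict(f) for f in dark_fits],
                    "kd_mean_uM": dark_summary.mean_kd,
                    "kd_sd_uM": dark_summary.sd_kd,
                    "n": dark_summary.n,
                },
                "lit": {
                    "preset": config.lit_preset,
                    "true_k_on_per_uM_per_s": lit_truth.k_on,
                    "true_k_off_per_s": lit_truth.k_off,
                    "true_kd_uM": lit_truth.kd,
                    "fits": [fit_result_to_dict(f) for f in lit_fits],
                    "kd_mean_uM": lit_summary.mean_kd,
                    "kd_sd_uM": lit_summary.sd_kd,
                    "n": lit_summary.n,
                },
            },
            "fold_change": {
                "true_fold": lit_truth.kd / dark_truth.kd,
                "ratio_of_mean_kds": fold_of_means,
                "ratio_of_mean_kds_2sf": round_sig(fold_of_means, 2),
                "mean_of_per_replicate_ratios": mean_of_folds,
                "per_replicate_ratios": per_replicate_folds,
            },
            "thermodynamics": {
                "temperature_K": config.temperature_k,
                "ddg_measured_kcal_per_mol": ddg,
                "max_ddg_kcal_per_mol": config.max_ddg_kcal,
                "theoretical_max_fold": ceiling_fold,
                "transmission_efficiency": efficiency,
            },
        }

        if config.with_ci:
            stage = "bootstrap confidence intervals"
            ci = bootstrap_ci(
                lit_datasets[0],
                lit_fits[0],
                n_boot=config.n_boot,
                level=config.ci_level,
                seed=int(seeds[1]) + 7,
            )
            report["confidence_intervals"] = {
                "note": "lit condition, replicate 0",
                **interval_set_to_dict(ci),
            }
    except OptobindError as exc:
        raise type(exc)(f"reproduce failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_json(report, out_dir / "report.json")
        (out_dir / "report.txt").write_text(format_report(report))
        logger.info("report written to %s", out_dir)
    return report


def format_report(report: dict) -> str:
    """Human-readable one-page summary of a reproduce report."""
    dark = report["conditions"]["dark"]
    lit = report["conditions"]["lit"]
    fc = report["fold_change"]
    th = report["thermodynamics"]
    lines = [
        f"optobind {report['package_version']} reproduce report "
        f"(seed {report['seed']}, config {report['config_hash']})",
        "",
        f"dark state ({dark['preset']}): "
        f"Kd = {dark['kd_mean_uM']:.3g} +/- {dark['kd_sd_uM']:.3g} uM "
        f"(n = {dark['n']}; truth {dark['true_kd_uM']:.3g} uM)",
        f"lit state  ({lit['preset']}): "
        f"Kd = {lit['kd_mean_uM']:.3g} +/- {lit['kd_sd_uM']:.3g} uM "
        f"(n = {lit['n']}; truth {lit['true_kd_uM']:.3g} uM)",
        "",
        f"lit/dark affinity fold-change: {fc['ratio_of_mean_kds']:.1f} "
        f"(~{fc['ratio_of_mean_kds_2sf']:g}; truth {fc['true_fold']:.1f}; "
        f"mean of per-replicate ratios {fc['mean_of_per_replicate_ratios']:.1f})",
        f"ddG = RT ln(fold) = {th['ddg_measured_kcal_per_mol']:.2f} kcal/mol at "
        f"{th['temperature_K']:.2f} K",
        f"free-energy ceiling {th['max_ddg_kcal_per_mol']:.1f} kcal/mol "
        f"-> theoretical max fold {th['theoretical_max_fold']:.0f}",
        f"transmission efficiency: {th['transmission_efficiency']:.0%}",
    ]
    if "confidence_intervals" in report:
        ci = report["confidence_intervals"]
        lines.append("")
        lines.append(
            f"bootstrap {ci['level']:.0%} CIs ({ci['note']}, n_boot={ci['n_boot']}):"
        )
        for name, entry in ci["intervals"].items():
            lines.append(
                f"  {name}: {entry['estimate']:.4g} "
                f"[{entry['lower']:.4g}, {entry['upper']:.4g}]"
            )
    return "\n".join(lines) + "\n"
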