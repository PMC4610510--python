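"""The reproducible synthetic transfer benchmark.

Stands in for a fleet of real fed-batches: two synthetic clones differing
only in per-cell capacitance (amplitude ratio 1/0.69), each with five
training and six validation runs under debris-heavy, disturbed, noisy
conditions. The model-selection ladder mirrors the practical progression
from single-frequency linear calibration to the windowed, slope-adapted
PLS model:

    lr_exponential      dual-mode LR calibrated on the exponential phase
    lr_whole            dual-mode LR calibrated on the whole run
    pls_same_clone      PLS validated on held-out runs of its own clone
    pls_transfer_raw    cross-clone PLS, all 17 frequencies, no slope fix
    pls_windowed        cross-clone PLS, frequencies 1:10, no slope fix
    pls_windowed_kappa  frequencies 1:10 plus kappa adaptation (headline)
    pls_full_kappa      all 17 frequencies plus kappa (window ablation)

Everything is deterministic given one root seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataio import FermentationRun, spline_align
from .evaluate import EvaluationReport, evaluate_run, run_transfer_experiment, summarize
from .model import fit_linear_baseline, fit_pls
from .preprocess import FrequencyWindow
from .simulate import (CloneProfile, CultureParams, DisturbanceSpec, SamplingSpec,
                       generate_clone_pair, simulate_run)
from .transfer import estimate_kappa

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_benchmark",
           "default_disturbances", "scenario_from_dict"]


def default_disturbances() -> DisturbanceSpec:
    """Debris-era process disturbances: two bolus feeds, three bubble bursts,
    setup-specific frequency-weighted baseline drift, 2% multiplicative
    probe noise."""
    return DisturbanceSpec(
        bolus_times=((120.0, 0.04), (216.0, 0.04)),
        bubble_bursts=((61.3, 0.05, 0.7), (151.7, 0.05, 0.7), (262.4, 0.05, 0.7)),
        drift_rate=0.03,
        noise_cv=0.02,
    )


@dataclass(frozen=True)
class BenchmarkConfig:
    n_train: int = 5
    n_validation: int = 6
    amplitude_ratio: float = 1.0 / 0.69
    clone: CloneProfile = field(default_factory=CloneProfile)
    culture: CultureParams = field(default_factory=CultureParams)
    disturbance: DisturbanceSpec = field(default_factory=default_disturbances)
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    window: FrequencyWindow = field(default_factory=FrequencyWindow.fixed)
    scaling_mode: str = "mean_center"
    n_components: int = 3
    lag_time: float = 6.0
    kappa_mode: str = "regression"
    culture_jitter: float = 0.05
    fc_debris_jitter: float = 0.15

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        kw = dict(d)
        if "clone" in kw:
            kw["clone"] = CloneProfile(**kw["clone"])
        if "culture" in kw:
            kw["culture"] = CultureParams(**kw["culture"])
        if "disturbance" in kw:
            kw["disturbance"] = _disturbance_from_dict(kw["disturbance"])
        if "sampling" in kw:
            kw["sampling"] = SamplingSpec(**kw["sampling"])
        if "window" in kw:
            kw["window"] = FrequencyWindow.upto(int(kw["window"]))
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _disturbance_from_dict(d: dict) -> DisturbanceSpec:
    return DisturbanceSpec(
        bolus_times=tuple(tuple(b) for b in d.get("bolus_times", ())),
        bubble_bursts=tuple(tuple(b) for b in d.get("bubble_bursts", ())),
        drift_rate=float(d.get("drift_rate", 0.0)),
        noise_cv=float(d.get("noise_cv", 0.02)),
    )


def scenario_from_dict(d: dict):
    """(clone, culture, disturbance, sampling) from a scenario mapping."""
    clone = CloneProfile(**d.get("clone", {}))
    culture = CultureParams(**d.get("culture", {}))
    disturb = _disturbance_from_dict(d.get("disturbance", {}))
    sampling = SamplingSpec(**d.get("sampling", {}))
    return clone, culture, disturb, sampling


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    seed: int
    reports: dict[str, list[EvaluationReport]]
    summary: dict

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for variant, reports in sorted(self.reports.items()):
            for r in reports:
                rows.append({
                    "variant": variant,
                    "run_id": r.run_id,
                    "n_points": r.n_points,
                    "rmse_whole": r.rmse_whole,
                    "cvrmse_whole_pct": r.cvrmse_whole,
                    "cvrmse_exponential_pct": r.cvrmse_exponential,
                    "kappa": r.kappa,
                    "verdict": r.verdict,
                })
        return pd.DataFrame(rows)


def _to_runs(sruns, clone_tag: str, scale_tag: str, offset: int = 0):
    return [s.to_fermentation_run(f"{clone_tag}{i + 1 + offset:02d}", clone=clone_tag,
                                  scale=scale_tag)
            for i, s in enumerate(sruns)]


def run_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> BenchmarkResult:
    """Generate the fleets, fit both clone models, and score the ladder."""
    cfg = config if config is not None else BenchmarkConfig()
    n_total = cfg.n_train + cfg.n_validation
    sruns_a, sruns_b = generate_clone_pair(
        cfg.clone, cfg.amplitude_ratio, cfg.culture, n_total, seed=seed,
        disturb=cfg.disturbance, sampling=cfg.sampling,
        culture_jitter=cfg.culture_jitter, fc_debris_jitter=cfg.fc_debris_jitter,
    )
    runs_a = _to_runs(sruns_a, "A", "scale1")
    runs_b = _to_runs(sruns_b, "B", "scale2")
    train_a, val_a = runs_a[: cfg.n_train], runs_a[cfg.n_train:]
    train_b, val_b = runs_b[: cfg.n_train], runs_b[cfg.n_train:]
    val_all = val_b + val_a

    reports: dict[str, list[EvaluationReport]] = {}

    # --- single-frequency dual-mode baselines, calibrated per run -----------
    for variant, phase in (("lr_exponential", "exponential_only"), ("lr_whole", "whole_run")):
        rows = []
        for run in val_all:
            lm = fit_linear_baseline(spline_align(run), calibration_phase=phase)
            rows.append(evaluate_run(lm, run))
        reports[variant] = rows

    # --- PLS models ---------------------------------------------------------
    aligned_a = [spline_align(r) for r in train_a]
    aligned_b = [spline_align(r) for r in train_b]
    full, win = FrequencyWindow.full(), cfg.window
    model_a = fit_pls(aligned_a, window=win, scaling_mode=cfg.scaling_mode,
                      n_components=cfg.n_components)
    model_b = fit_pls(aligned_b, window=win, scaling_mode=cfg.scaling_mode,
                      n_components=cfg.n_components)
    model_a_full = fit_pls(aligned_a, window=full, scaling_mode=cfg.scaling_mode,
                           n_components=cfg.n_components)
    model_b_full = fit_pls(aligned_b, window=full, scaling_mode=cfg.scaling_mode,
                           n_components=cfg.n_components)

    reports["pls_same_clone"] = ([evaluate_run(model_a, r) for r in val_a]
                                 + [evaluate_run(model_b, r) for r in val_b])
    reports["pls_transfer_raw"] = ([evaluate_run(model_a_full, r) for r in val_b]
                                   + [evaluate_run(model_b_full, r) for r in val_a])
    reports["pls_windowed"] = ([evaluate_run(model_a, r) for r in val_b]
                               + [evaluate_run(model_b, r) for r in val_a])

    def kappa_reports(m_for_b, m_for_a):
        rows = []
        for model, fleet in ((m_for_b, val_b), (m_for_a, val_a)):
            for run in fleet:
                tm = estimate_kappa(model, run, lag_time=cfg.lag_time, mode=cfg.kappa_mode)
                rows.append(evaluate_run(tm, run))
        return rows

    reports["pls_windowed_kappa"] = kappa_reports(model_a, model_b)
    reports["pls_full_kappa"] = kappa_reports(model_a_full, model_b_full)

    # --- side quantities ----------------------------------------------------
    # Correlation of the dual-mode single frequency with VCC under standard,
    # disturbance-free conditions (highly viable exponential phase).
    clean = simulate_run(
        cfg.clone, cfg.culture,
        DisturbanceSpec(noise_cv=0.0),
        replace(cfg.sampling, offline_noise_cv=0.0),
        seed=seed + 1,
    )
    clean_run = clean.to_fermentation_run("A-clean", clone="A")
    lr_clean = fit_linear_baseline(spline_align(clean_run), calibration_phase="exponential_only")

    r2_same_clone = []
    for model, fleet in ((model_a, val_a), (model_b, val_b)):
        for run in fleet:
            from .transfer import base_estimate_at_offline
            y, yh = run.vcc_offline, base_estimate_at_offline(model, run)
            sst = float(np.sum((y - y.mean()) ** 2))
            r2_same_clone.append(1.0 - float(np.sum((y - yh) ** 2)) / sst)

    headline = reports["pls_windowed_kappa"]
    a_to_b = headline[: len(val_b)]  # A-model applied to clone-B validation runs
    summary = {
        "seed": seed,
        "n_validation_runs": len(val_all),
        "ladder": {variant: summarize(rows) for variant, rows in reports.items()},
        "max_cvrmse_whole_a_to_b": max(r.cvrmse_whole for r in a_to_b),
        "max_cvrmse_exponential_a_to_b": max(r.cvrmse_exponential for r in a_to_b),
        "max_cvrmse_whole_bidirectional": max(r.cvrmse_whole for r in headline),
        "mean_cvrmse_whole_bidirectional": float(np.mean([r.cvrmse_whole for r in headline])),
        "x_variance_pct_3pc": float(model_a.x_variance_explained[-1] * 100.0),
        "n_training_rows": int(sum(len(a) for a in aligned_a)),
        "lr_exponential_cvrmse_mean": float(np.mean(
            [r.cvrmse_whole for r in reports["lr_exponential"]])),
        "r2_single_frequency_exponential": lr_clean.r_squared,
        "r2_same_clone_mean": float(np.mean(r2_same_clone)),
        "r2_same_clone_min": float(np.min(r2_same_clone)),
        "kappa_mean_a_to_b": float(np.mean([r.kappa for r in a_to_b])),
    }
    return BenchmarkResult(config=cfg, seed=seed, reports=reports, summary=summary)
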