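"""Error metrics, acceptance verdicts, and transfer experiments.

The acceptance statistic is the coefficient of variation of the RMSE,

    RMSE   = sqrt( sum((y - y_hat)^2) / (n - 1) )
    CVRMSE = RMSE / mean(y_hat) * 100   [%]

with the *estimated* VCC in the denominator (the convention followed
throughout; a flag switches to the mean of the measurements). A model is
accepted when CVRMSE stays within 25% over the exponential growth phase and
33% over the whole process; beyond an absolute 50% it is rejected, and the
band in between is flagged questionable.

Errors are computed at the offline sampling timestamps, where measured VCC
exists without interpolation error; the estimate is taken from the nearest
online spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import FermentationRun
from .errors import DegenerateDataError, InsufficientDataError
from .model import LinearModel, PLSModel, predict_linear, predict_vcc
from .preprocess import FrequencyWindow
from .transfer import TransferredModel, base_estimate_at_offline, estimate_kappa, predict_transferred

__all__ = [
    "rmse",
    "cvrmse",
    "classify_acceptance",
    "split_phases",
    "EvaluationReport",
    "predict_model",
    "evaluate_run",
    "run_transfer_experiment",
]

#: Acceptance thresholds in % CVRMSE.
EXPONENTIAL_LIMIT = 25.0
WHOLE_PROCESS_LIMIT = 33.0
REJECTION_LIMIT = 50.0


def rmse(y, y_hat) -> float:
    """Sample RMSE with n-1 denominator, in 1e5 cells/mL."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    n = y.size
    if n < 2:
        raise ValueError(f"RMSE needs at least 2 observations, got {n}")
    return float(np.sqrt(np.sum((y - y_hat) ** 2) / (n - 1)))


def cvrmse(y, y_hat, denominator: str = "estimated") -> float:
    """RMSE relative to the mean estimate, in %.

    ``denominator='measured'`` uses the mean of the measurements instead —
    the more common convention, but not the default here.
    """
    if denominator not in ("estimated", "measured"):
        raise ValueError(f"denominator must be 'estimated' or 'measured', got {denominator!r}")
    ref = np.mean(np.asarray(y_hat if denominator == "estimated" else y, float))
    if ref <= 0:
        raise DegenerateDataError(f"non-positive mean {denominator} VCC ({ref:.4g})")
    return rmse(y, y_hat) / float(ref) * 100.0


def classify_acceptance(cvrmse_whole: float, cvrmse_exponential: float) -> str:
    """Verdict from the two phase errors: accepted / questionable / rejected."""
    if cvrmse_whole < 0 or cvrmse_exponential < 0:
        raise ValueError("CVRMSE values must be >= 0")
    if cvrmse_whole > REJECTION_LIMIT:
        return "rejected"
    if cvrmse_whole <= WHOLE_PROCESS_LIMIT and cvrmse_exponential <= EXPONENTIAL_LIMIT:
        return "accepted"
    return "questionable"


def split_phases(run: FermentationRun) -> dict[str, np.ndarray]:
    """Offline-sample index sets for the exponential and whole-process phases.

    The exponential phase runs from inoculation to the offline sample with
    maximum measured VCC.
    """
    if run.times_offline.size < 3:
        raise InsufficientDataError("phase split needs at least 3 offline samples")
    peak = int(np.argmax(run.vcc_offline))
    if peak == 0:
        warnings.warn(
            f"run {run.run_id}: offline VCC declines from the first sample; "
            "exponential phase contains a single point", stacklevel=2)
    return {
        "exponential": np.arange(peak + 1),
        "whole": np.arange(run.times_offline.size),
    }


@dataclass(frozen=True)
class EvaluationReport:
    run_id: str
    n_points: int
    n_exponential: int
    rmse_whole: float            # 1e5 cells/mL
    cvrmse_whole: float          # %
    rmse_exponential: float
    cvrmse_exponential: float    # %
    verdict: str
    kappa: float | None = None


def predict_model(model, spectra: np.ndarray) -> np.ndarray:
    """Dispatch prediction over the three model kinds."""
    if isinstance(model, TransferredModel):
        return predict_transferred(model, spectra)
    if isinstance(model, PLSModel):
        return predict_vcc(model, spectra)
    if isinstance(model, LinearModel):
        return predict_linear(model, spectra)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def evaluate_run(model, run: FermentationRun,
                 denominator: str = "estimated") -> EvaluationReport:
    """Score a model against a run's offline counts, both phases."""
    base = model.base if isinstance(model, TransferredModel) else model
    if isinstance(base, PLSModel):
        xhat = base_estimate_at_offline(base, run)
        if isinstance(model, TransferredModel):
            y_hat = model.kappa * xhat + model.offset
        else:
            y_hat = xhat
    else:
        # nearest-online pairing for the linear baseline as well
        t_on, t_off = run.times_online, run.times_offline
        idx = np.clip(np.searchsorted(t_on, t_off), 0, t_on.size - 1)
        idx_lo = np.clip(idx - 1, 0, t_on.size - 1)
        idx = np.where(np.abs(t_on[idx_lo] - t_off) < np.abs(t_on[idx] - t_off), idx_lo, idx)
        y_hat = predict_model(model, run.spectra[idx])
    y = run.vcc_offline
    phases = split_phases(run)
    exp_idx = phases["exponential"]
    report = EvaluationReport(
        run_id=run.run_id,
        n_points=int(y.size),
        n_exponential=int(exp_idx.size),
        rmse_whole=rmse(y, y_hat),
        cvrmse_whole=cvrmse(y, y_hat, denominator),
        rmse_exponential=rmse(y[exp_idx], y_hat[exp_idx]),
        cvrmse_exponential=cvrmse(y[exp_idx], y_hat[exp_idx], denominator),
        verdict=classify_acceptance(
            cvrmse(y, y_hat, denominator), cvrmse(y[exp_idx], y_hat[exp_idx], denominator)
        ),
        kappa=model.kappa if isinstance(model, TransferredModel) else None,
    )
    return report


def summarize(reports: list[EvaluationReport]) -> dict:
    whole = np.array([r.cvrmse_whole for r in reports])
    expo = np.array([r.cvrmse_exponential for r in reports])
    return {
        "n_runs": len(reports),
        "mean_cvrmse_whole": float(whole.mean()),
        "sd_cvrmse_whole": float(whole.std(ddof=1)) if len(reports) > 1 else 0.0,
        "max_cvrmse_whole": float(whole.max()),
        "mean_cvrmse_exponential": float(expo.mean()),
        "max_cvrmse_exponential": float(expo.max()),
        "n_accepted": int(sum(r.verdict == "accepted" for r in reports)),
    }


def run_transfer_experiment(
    train_fleet: list[FermentationRun],
    validation_fleet: list[FermentationRun],
    window: FrequencyWindow | None = None,
    scaling_mode: str = "mean_center",
    n_components: int = 3,
    lag_time: float = 6.0,
    kappa_mode: str = "regression",
    apply_kappa: bool = True,
):
    """Fit on one fleet, kappa-transfer to each validation run, and score.

    Returns ``(model, reports, summary)``; the summary carries the fleet
    mean, standard deviation and maximum of the whole-process CVRMSE (and
    the exponential-phase equivalents).
    """
    from .dataio import spline_align
    from .model import fit_pls

    if not train_fleet or not validation_fleet:
        raise ValueError("train and validation fleets must be non-empty")
    model = fit_pls([spline_align(r) for r in train_fleet],
                    window=window, scaling_mode=scaling_mode, n_components=n_components)
    reports = []
    for run in validation_fleet:
        scored = (estimate_kappa(model, run, lag_time=lag_time, mode=kappa_mode)
                  if apply_kappa else model)
        reports.append(evaluate_run(scored, run))
    return model, reports, summarize(reports)
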