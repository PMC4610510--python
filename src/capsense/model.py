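"""PLS soft-sensor (SIMPLS) and the single-frequency dual-mode baseline.

The estimator is the linear prediction model

    y_hat = a1*c1 + a2*c2 + ... + aF*cF + d

with a_i the capacitance (pF/cm) at retained frequency i, c_i the
regression coefficients in (cm * 1e5)/(pF*mL), and d the intercept in
1e5 cells/mL. Coefficients come from SIMPLS (de Jong 1993) on scaled
columns and are stored mapped back to raw capacitance units, so a
serialized model applies directly to raw spectra and its coefficients are
human-readable. By convention, models with three or more retained
frequencies use exactly three latent components (they capture >99% of the
spectral variance; the remainder is noise); narrower windows fall back to
as many components as there are frequencies.

The baseline is the classical dual-mode linear regression: one working
frequency (nearest 1 MHz) with the highest frequency subtracted as
background, calibrated by ordinary least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import AlignedDataset
from .errors import DegenerateDataError, InsufficientDataError, RankError, SchemaError
from .preprocess import (FrequencyWindow, ScalingParams, apply_scaling, fit_scaling)
from .simulate import make_frequency_grid

__all__ = [
    "PLSModel",
    "LinearModel",
    "fit_pls",
    "predict_vcc",
    "fit_linear_baseline",
    "predict_linear",
]


def _simpls(X0: np.ndarray, y0: np.ndarray, n_components: int):
    """Univariate SIMPLS on centered (optionally standardized) data.

    Score vectors are computed directly from the deflated cross-covariance
    X0'y0; returns the coefficient vector in the scaled space and the
    cumulative fraction of X-variance captured per component. Extraction
    stops early (without error) once the response covariance is exhausted,
    e.g. when y is exactly linear in fewer directions than requested.
    """
    n, p = X0.shape
    rank = np.linalg.matrix_rank(X0)
    if n_components > rank:
        raise RankError(
            f"{n_components} components requested but predictor rank is {rank}"
        )
    total_xvar = float(np.sum(X0 * X0))
    s = X0.T @ y0
    s_scale = float(np.linalg.norm(s))
    R = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    V = np.zeros((p, n_components))
    xvar = np.zeros(n_components)
    used = 0
    for a in range(n_components):
        if np.linalg.norm(s) <= 1e-12 * max(s_scale, 1e-300):
            break  # response fully explained by previous components
        r = s.copy()
        t = X0 @ r
        tn = np.linalg.norm(t)
        if tn <= 0:
            break
        t /= tn
        r /= tn
        p_a = X0.T @ t
        q_a = float(y0 @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        vn = np.linalg.norm(v)
        if vn <= 0:
            break
        v /= vn
        s = s - v * (v @ s)
        R[:, a] = r
        Q[a] = q_a
        V[:, a] = v
        xvar[a] = float(p_a @ p_a) / total_xvar if total_xvar > 0 else 0.0
        used = a + 1
    coef = R[:, :used] @ Q[:used]
    cum_xvar = np.cumsum(xvar)
    cum_xvar[used:] = cum_xvar[used - 1] if used else 0.0
    return coef, cum_xvar


@dataclass(frozen=True)
class PLSModel:
    """Serialized-friendly PLS estimator in raw capacitance units."""

    frequency_window: FrequencyWindow
    scaling: ScalingParams
    n_components: int
    coefficients: tuple[float, ...]   # (cm * 1e5)/(pF*mL), one per window frequency
    intercept: float                  # 1e5 cells/mL
    x_variance_explained: tuple[float, ...] = ()  # cumulative, per component
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "type": "pls",
            "frequency_window": list(self.frequency_window.indices),
            "scaling": self.scaling.to_dict(),
            "n_components": self.n_components,
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "x_variance_explained": list(self.x_variance_explained),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            frequency_window=FrequencyWindow(tuple(d["frequency_window"])),
            scaling=ScalingParams.from_dict(d["scaling"]),
            n_components=int(d["n_components"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            x_variance_explained=tuple(d.get("x_variance_explained", ())),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _pool(train) -> tuple[np.ndarray, np.ndarray]:
    datasets = [train] if isinstance(train, AlignedDataset) else list(train)
    if not datasets:
        raise ValueError("no training datasets given")
    X = np.vstack([d.X for d in datasets])
    y = np.concatenate([d.y for d in datasets])
    return X, y


def _window_columns(X: np.ndarray, window: FrequencyWindow) -> np.ndarray:
    """Restrict a spectra matrix to the window columns.

    Accepts either the full instrument matrix (>= max window index columns)
    or a matrix already restricted to exactly the window width.
    """
    F = len(window)
    if X.shape[1] == F:
        return X
    if X.shape[1] >= window.indices[-1]:
        return X[:, window.slice]
    raise SchemaError(
        f"spectra has {X.shape[1]} columns; window needs {F} (indices up to {window.indices[-1]})"
    )


def fit_pls(
    train,
    window: FrequencyWindow | None = None,
    scaling_mode: str = "mean_center",
    n_components: int = 3,
) -> PLSModel:
    """Fit the PLS estimator on one or more aligned datasets (rows pooled).

    ``n_components`` is capped at the window width, implementing the
    convention that windows of one or two frequencies use one resp. two
    components. The response is centered but never standardized.
    """
    window = window if window is not None else FrequencyWindow.fixed()
    X, y = _pool(train)
    Xw = _window_columns(np.atleast_2d(np.asarray(X, float)), window)
    y = np.asarray(y, float)
    ncomp = min(int(n_components), len(window))
    if ncomp < 1:
        raise ValueError("n_components must be >= 1")
    if Xw.shape[0] < ncomp + 1:
        raise InsufficientDataError(
            f"need at least n_components + 1 = {ncomp + 1} pooled rows, got {Xw.shape[0]}"
        )
    scaling = fit_scaling(Xw, scaling_mode)
    X0 = apply_scaling(Xw, scaling)
    ybar = float(y.mean())
    coef_scaled, cum_xvar = _simpls(X0, y - ybar, ncomp)
    coef_raw = coef_scaled / np.asarray(scaling.sds)
    intercept = ybar - float(coef_raw @ np.asarray(scaling.means))
    return PLSModel(
        frequency_window=window,
        scaling=scaling,
        n_components=ncomp,
        coefficients=tuple(coef_raw),
        intercept=intercept,
        x_variance_explained=tuple(cum_xvar),
    )


def predict_vcc(model: PLSModel, spectra: np.ndarray, times=None) -> np.ndarray:
    """Apply the prediction equation to raw spectra; no clipping.

    Negative estimates are reported as-is so that evaluation sees the raw
    estimator.
    """
    X = np.atleast_2d(np.asarray(spectra, float))
    Xw = _window_columns(X, model.frequency_window)
    return Xw @ np.asarray(model.coefficients) + model.intercept


@dataclass(frozen=True)
class LinearModel:
    """Dual-mode single-frequency baseline: y ~ slope*(a_work - a_ref) + b."""

    working_frequency: int    # 1-based index, grid frequency nearest 1 MHz
    reference_frequency: int  # 1-based, the highest frequency
    slope: float              # (cm * 1e5)/(pF*mL)
    intercept: float          # 1e5 cells/mL
    calibration_phase: str = "exponential_only"
    r_squared: float = float("nan")  # on the calibration rows

    def to_dict(self) -> dict:
        return {
            "type": "linear",
            "working_frequency": self.working_frequency,
            "reference_frequency": self.reference_frequency,
            "slope": self.slope,
            "intercept": self.intercept,
            "calibration_phase": self.calibration_phase,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            working_frequency=int(d["working_frequency"]),
            reference_frequency=int(d["reference_frequency"]),
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            calibration_phase=d.get("calibration_phase", "exponential_only"),
            r_squared=float(d.get("r_squared", float("nan"))),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_linear_baseline(
    train: AlignedDataset,
    frequencies: np.ndarray | None = None,
    calibration_phase: str = "exponential_only",
    working_frequency: int | None = None,
) -> LinearModel:
    """Calibrate the dual-mode baseline by OLS.

    The working channel defaults to the grid frequency nearest 1 MHz (the
    manufacturer's standard) and the reference is the highest channel.
    ``exponential_only`` restricts calibration rows to times up to the
    maximum of the aligned VCC; ``whole_run`` uses everything.
    """
    if calibration_phase not in ("exponential_only", "whole_run"):
        raise ValueError(f"unknown calibration_phase {calibration_phase!r}")
    X = np.atleast_2d(np.asarray(train.X, float))
    nf = X.shape[1]
    if nf < 2:
        raise SchemaError("dual-mode baseline needs at least 2 frequency channels")
    if working_frequency is None:
        freqs = make_frequency_grid(nf) if frequencies is None else np.asarray(frequencies, float)
        work = int(np.argmin(np.abs(freqs - 1.0)))
    else:
        work = int(working_frequency) - 1
    ref = nf - 1
    if work == ref:
        raise ValueError("working frequency must differ from the reference (highest) frequency")

    y = np.asarray(train.y, float)
    if calibration_phase == "exponential_only":
        peak = int(np.argmax(y))
        rows = slice(0, peak + 1)
    else:
        rows = slice(None)
    r = X[rows, work] - X[rows, ref]
    yy = y[rows]
    if len(yy) < 2:
        raise InsufficientDataError("linear calibration needs at least 2 rows")
    if np.std(r) <= 1e-12 * (np.max(np.abs(r)) + 1.0):
        raise DegenerateDataError("dual-mode regressor is constant over the calibration rows")
    A = np.column_stack([r, np.ones_like(r)])
    (slope, intercept), *_ = np.linalg.lstsq(A, yy, rcond=None)
    resid = yy - (slope * r + intercept)
    sst = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    return LinearModel(
        working_frequency=work + 1,
        reference_frequency=ref + 1,
        slope=float(slope),
        intercept=float(intercept),
        calibration_phase=calibration_phase,
        r_squared=r2,
    )


def predict_linear(model: LinearModel, spectra: np.ndarray, times=None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(spectra, float))
    need = max(model.working_frequency, model.reference_frequency)
    if X.shape[1] < need:
        raise SchemaError(f"spectra has {X.shape[1]} columns, model needs {need}")
    r = X[:, model.working_frequency - 1] - X[:, model.reference_frequency - 1]
    return model.slope * r + model.intercept
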