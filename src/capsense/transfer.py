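"""Slope transfer of a PLS soft-sensor to a new clone or scale.

A model trained on one clone over- or under-estimates another clone's VCC
by a clone-specific factor, because each clone contributes a different
amount of capacitance per cell. The transfer is the affine correction

    y_hat = kappa * x_hat + d

where x_hat is the prior model's estimate, kappa a dimensionless
attenuation factor and d an offset in 1e5 cells/mL. kappa is estimable
online from the first offline counts of the new run, after a short lag
(early process events — pH regulation, aeration — make the very first
hours unreliable). Two estimation modes are provided: ``regression`` fits
kappa and d jointly by least squares; ``offset_anchored`` pins d with the
single biomass measurement at inoculation and fits kappa through that
anchor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dataio import FermentationRun
from .errors import DegenerateDataError, InsufficientDataError, TransferError
from .model import PLSModel, predict_vcc

__all__ = [
    "TransferredModel",
    "estimate_kappa",
    "update_kappa_online",
    "predict_transferred",
]

KAPPA_MODES = ("regression", "offset_anchored")


@dataclass(frozen=True)
class TransferredModel:
    """A base PLS model with its slope/offset correction and estimation log."""

    base: PLSModel
    kappa: float
    offset: float                      # d, 1e5 cells/mL
    mode: str = "regression"
    lag_time: float = 6.0              # h
    min_samples: int = 3
    sample_times: tuple[float, ...] = ()
    sample_vcc: tuple[float, ...] = ()
    sample_xhat: tuple[float, ...] = ()
    anchor: tuple[float, float] | None = None  # (x_hat0, y0) at inoculation
    kappa_trace: tuple[tuple[float, float], ...] = ()  # (time_h, kappa)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    def to_dict(self) -> dict:
        d = self.base.to_dict()
        d.update({
            "type": "transferred_pls",
            "kappa": self.kappa,
            "offset": self.offset,
            "mode": self.mode,
            "lag_time_h": self.lag_time,
            "min_samples": self.min_samples,
            "sample_times": list(self.sample_times),
            "sample_vcc": list(self.sample_vcc),
            "sample_xhat": list(self.sample_xhat),
            "anchor": list(self.anchor) if self.anchor is not None else None,
            "kappa_trace": [{"time_h": t, "kappa": k} for t, k in self.kappa_trace],
        })
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransferredModel":
        return cls(
            base=PLSModel.from_dict(d),
            kappa=float(d["kappa"]),
            offset=float(d["offset"]),
            mode=d.get("mode", "regression"),
            lag_time=float(d.get("lag_time_h", 6.0)),
            min_samples=int(d.get("min_samples", 3)),
            sample_times=tuple(d.get("sample_times", ())),
            sample_vcc=tuple(d.get("sample_vcc", ())),
            sample_xhat=tuple(d.get("sample_xhat", ())),
            anchor=tuple(d["anchor"]) if d.get("anchor") is not None else None,
            kappa_trace=tuple((e["time_h"], e["kappa"]) for e in d.get("kappa_trace", ())),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "TransferredModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def base_estimate_at_offline(base: PLSModel, run: FermentationRun,
                             times: np.ndarray | None = None) -> np.ndarray:
    """x_hat at offline timestamps via the nearest online spectrum.

    Spline-free on purpose: each offline count is paired with the closest
    online spectrum, which must lie within one online sampling interval.
    """
    t_on = run.times_online
    t_off = run.times_offline if times is None else np.asarray(times, float)
    interval = float(np.median(np.diff(t_on))) if t_on.size > 1 else np.inf
    idx = np.clip(np.searchsorted(t_on, t_off), 0, t_on.size - 1)
    idx_lo = np.clip(idx - 1, 0, t_on.size - 1)
    nearer_lo = np.abs(t_on[idx_lo] - t_off) < np.abs(t_on[idx] - t_off)
    idx = np.where(nearer_lo, idx_lo, idx)
    gap = np.abs(t_on[idx] - t_off)
    if np.any(gap > interval + 1e-9):
        bad = t_off[gap > interval + 1e-9]
        raise InsufficientDataError(
            f"no online spectrum within one sampling interval of offline time(s) {bad.tolist()}"
        )
    return predict_vcc(base, run.spectra[idx])


def _fit_kappa(mode: str, x: np.ndarray, y: np.ndarray,
               anchor: tuple[float, float] | None) -> tuple[float, float]:
    if mode == "regression":
        A = np.column_stack([x, np.ones_like(x)])
        (kappa, d), *_ = np.linalg.lstsq(A, y, rcond=None)
    else:
        x0, y0 = anchor
        denom = float(np.sum((x - x0) ** 2))
        if denom <= 0:
            raise DegenerateDataError("all base estimates coincide with the anchor")
        kappa = float(np.sum((x - x0) * (y - y0)) / denom)
        d = y0 - kappa * x0
    if kappa <= 0:
        raise TransferError(
            f"estimated kappa = {kappa:.4g} <= 0; base model does not track this run"
        )
    return float(kappa), float(d)


def estimate_kappa(
    base: PLSModel,
    run: FermentationRun,
    lag_time: float = 6.0,
    min_samples: int = 3,
    mode: str = "regression",
    until: float | None = None,
) -> TransferredModel:
    """Estimate (kappa, d) from a run's offline counts at t >= lag_time.

    ``until`` restricts the samples to t <= until, emulating the state of
    knowledge partway through the run (the online workflow then continues
    with :func:`update_kappa_online`).
    """
    if mode not in KAPPA_MODES:
        raise ValueError(f"mode must be one of {KAPPA_MODES}, got {mode!r}")
    t_off = run.times_offline
    y_off = run.vcc_offline
    if until is not None:
        keep = t_off <= until + 1e-9
        t_off, y_off = t_off[keep], y_off[keep]
    if t_off.size == 0:
        raise InsufficientDataError("run has no offline samples")
    xhat = base_estimate_at_offline(base, run, t_off)

    anchor = None
    if mode == "offset_anchored":
        anchor = (float(xhat[0]), float(y_off[0]))  # inoculation sample
    qualify = t_off >= lag_time - 1e-9
    if int(qualify.sum()) < min_samples:
        raise InsufficientDataError(
            f"only {int(qualify.sum())} offline samples at t >= {lag_time} h, "
            f"need {min_samples}"
        )
    xq, yq, tq = xhat[qualify], y_off[qualify], t_off[qualify]
    kappa, d = _fit_kappa(mode, xq, yq, anchor)
    return TransferredModel(
        base=base,
        kappa=kappa,
        offset=d,
        mode=mode,
        lag_time=lag_time,
        min_samples=min_samples,
        sample_times=tuple(tq),
        sample_vcc=tuple(yq),
        sample_xhat=tuple(xq),
        anchor=anchor,
        kappa_trace=((float(tq[-1]), kappa),),
    )


def update_kappa_online(
    tm: TransferredModel,
    run: FermentationRun,
    time_h: float,
    vcc: float,
) -> TransferredModel:
    """Fold a new offline count into the transfer and append to the trace.

    kappa (and d, in regression mode) are re-fit from all qualifying
    samples, so feeding samples one by one ends at exactly the batch
    estimate. Earlier trace entries are immutable — estimates already
    logged are not retroactively changed.
    """
    if time_h < tm.lag_time - 1e-9:
        raise ValueError(f"sample at t={time_h} h is before the lag time ({tm.lag_time} h)")
    if tm.sample_times and time_h <= tm.sample_times[-1] + 1e-9:
        raise ValueError(
            f"out-of-order sample: t={time_h} h is not after the last sample "
            f"at t={tm.sample_times[-1]} h"
        )
    xhat_new = float(base_estimate_at_offline(tm.base, run, np.array([time_h]))[0])
    x = np.array(tm.sample_xhat + (xhat_new,))
    y = np.array(tm.sample_vcc + (float(vcc),))
    kappa, d = _fit_kappa(tm.mode, x, y, tm.anchor)
    return replace(
        tm,
        kappa=kappa,
        offset=d,
        sample_times=tm.sample_times + (float(time_h),),
        sample_vcc=tm.sample_vcc + (float(vcc),),
        sample_xhat=tm.sample_xhat + (xhat_new,),
        kappa_trace=tm.kappa_trace + ((float(time_h), kappa),),
    )


def predict_transferred(tm: TransferredModel, spectra: np.ndarray, times=None) -> np.ndarray:
    """y_hat = kappa * x_hat + d, elementwise on the base model's estimate."""
    return tm.kappa * predict_vcc(tm.base, spectra) + tm.offset
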