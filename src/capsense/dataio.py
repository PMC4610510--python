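"""Run containers, CSV round-trips, and spline alignment.

The offline viable cell count is sparse (tens of points per run) while the
capacitance spectrum is dense (hundreds); model fitting needs both on the
same grid. Alignment interpolates the offline VCC with a cubic spline
(not-a-knot end conditions, preserving the curvy character of the VCC
between samples) and never extrapolates beyond the offline time hull.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import FormatError, InsufficientDataError

__all__ = [
    "FermentationRun",
    "AlignedDataset",
    "read_run",
    "write_run",
    "write_synthetic_run",
    "read_truth",
    "spline_align",
]

_OFFLINE_COLS = ("time_h", "vcc_1e5_per_ml", "tcc_1e5_per_ml", "viability_pct")


@dataclass
class FermentationRun:
    """One fed-batch: dense online spectra plus sparse offline counts."""

    run_id: str
    times_online: np.ndarray     # (n,) h
    spectra: np.ndarray          # (n, F) pF/cm
    times_offline: np.ndarray    # (m,) h
    vcc_offline: np.ndarray      # (m,) 1e5 cells/mL
    tcc_offline: np.ndarray | None = None
    viability_offline: np.ndarray | None = None
    clone: str = ""
    scale: str = ""

    def __post_init__(self) -> None:
        self.times_online = np.asarray(self.times_online, float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, float))
        self.times_offline = np.asarray(self.times_offline, float)
        self.vcc_offline = np.asarray(self.vcc_offline, float)
        if self.spectra.shape[0] != self.times_online.size:
            raise FormatError(
                f"run {self.run_id}: spectra has {self.spectra.shape[0]} rows "
                f"but {self.times_online.size} online timestamps"
            )
        for name, t in (("online", self.times_online), ("offline", self.times_offline)):
            if t.size > 1 and np.any(np.diff(t) <= 0):
                row = int(np.argmax(np.diff(t) <= 0)) + 1
                raise FormatError(f"run {self.run_id}: {name} times not strictly increasing at row {row}")
        if self.vcc_offline.size != self.times_offline.size:
            raise FormatError(f"run {self.run_id}: offline VCC length mismatch")
        for name, arr in (("spectra", self.spectra), ("vcc_offline", self.vcc_offline)):
            if np.any(~np.isfinite(arr)):
                where = np.argwhere(~np.isfinite(np.atleast_2d(arr)))[0]
                raise FormatError(f"run {self.run_id}: non-finite value in {name} at {tuple(where)}")

    @property
    def n_frequencies(self) -> int:
        return self.spectra.shape[1]


@dataclass
class AlignedDataset:
    """Online-grid design matrix with spline-interpolated VCC response."""

    times: np.ndarray  # (n,) h
    X: np.ndarray      # (n, F) pF/cm
    y: np.ndarray      # (n,) 1e5 cells/mL

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.X) == len(self.y)):
            raise FormatError("aligned dataset length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x_fq{i + 1:02d}": self.X[:, i] for i in range(self.X.shape[1])}
        return pd.DataFrame({"time_h": self.times, "y": self.y, **cols})

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _fq_columns(df: pd.DataFrame) -> list[str]:
    cols = sorted(c for c in df.columns if c.startswith("fq"))
    if not cols:
        raise FormatError("online CSV has no fq* capacitance columns")
    return cols


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_run(online_csv, offline_csv, run_id: str | None = None,
             clone: str = "", scale: str = "") -> FermentationRun:
    """Read one run from its online/offline CSV pair."""
    online_csv, offline_csv = Path(online_csv), Path(offline_csv)
    on = pd.read_csv(online_csv)
    off = pd.read_csv(offline_csv)
    _require(on, ["time_h"], online_csv)
    _require(off, ["time_h", "vcc_1e5_per_ml"], offline_csv)
    fq = _fq_columns(on)
    if run_id is None:
        run_id = online_csv.stem.removesuffix("_online")
    return FermentationRun(
        run_id=run_id,
        clone=clone,
        scale=scale,
        times_online=on["time_h"].to_numpy(float),
        spectra=on[fq].to_numpy(float),
        times_offline=off["time_h"].to_numpy(float),
        vcc_offline=off["vcc_1e5_per_ml"].to_numpy(float),
        tcc_offline=off["tcc_1e5_per_ml"].to_numpy(float) if "tcc_1e5_per_ml" in off else None,
        viability_offline=off["viability_pct"].to_numpy(float) if "viability_pct" in off else None,
    )


def write_run(run: FermentationRun, outdir) -> tuple[Path, Path]:
    """Write ``<run_id>_online.csv`` and ``<run_id>_offline.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fq = {f"fq{i + 1:02d}": run.spectra[:, i] for i in range(run.n_frequencies)}
    online = pd.DataFrame({"time_h": run.times_online, **fq})
    offline = pd.DataFrame({"time_h": run.times_offline, "vcc_1e5_per_ml": run.vcc_offline})
    if run.tcc_offline is not None:
        offline["tcc_1e5_per_ml"] = run.tcc_offline
    if run.viability_offline is not None:
        offline["viability_pct"] = run.viability_offline
    p_on = outdir / f"{run.run_id}_online.csv"
    p_off = outdir / f"{run.run_id}_offline.csv"
    online.to_csv(p_on, index=False)
    offline.to_csv(p_off, index=False)
    return p_on, p_off


def write_synthetic_run(srun, outdir, run_id: str, clone: str = "", scale: str = ""):
    """Write a synthetic run as online/offline CSVs plus a ground-truth CSV."""
    run = srun.to_fermentation_run(run_id, clone=clone, scale=scale)
    p_on, p_off = write_run(run, outdir)
    truth = pd.DataFrame({"time_h": srun.times_online, "vcc_true": srun.ground_truth_vcc})
    p_truth = Path(outdir) / f"{run_id}_truth.csv"
    truth.to_csv(p_truth, index=False)
    return p_on, p_off, p_truth


def read_truth(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    _require(df, ["time_h", "vcc_true"], path)
    return df["time_h"].to_numpy(float), df["vcc_true"].to_numpy(float)


def spline_align(run: FermentationRun, window: tuple[float, float] | None = None) -> AlignedDataset:
    """Interpolate offline VCC onto the online grid inside the offline hull.

    A cubic interpolating spline with not-a-knot end conditions passes
    through every offline sample (two samples degrade gracefully to linear
    interpolation). Online timestamps outside [first, last] offline sample
    are dropped rather than extrapolated.
    """
    t_off, y_off = run.times_offline, run.vcc_offline
    if t_off.size < 2:
        raise InsufficientDataError(
            f"run {run.run_id}: spline alignment needs >= 2 offline points, got {t_off.size}"
        )
    lo, hi = float(t_off[0]), float(t_off[-1])
    if window is not None:
        w_lo, w_hi = window
        if w_lo < lo - 1e-9 or w_hi > hi + 1e-9 or w_lo > w_hi:
            raise ValueError(
                f"window [{w_lo}, {w_hi}] outside offline hull [{lo}, {hi}]"
            )
        lo, hi = max(lo, w_lo), min(hi, w_hi)
    mask = (run.times_online >= lo - 1e-9) & (run.times_online <= hi + 1e-9)
    times = run.times_online[mask]
    if t_off.size == 2:
        y = np.interp(times, t_off, y_off)
    else:
        y = CubicSpline(t_off, y_off, bc_type="not-a-knot")(times)
    return AlignedDataset(times=times, X=run.spectra[mask], y=np.asarray(y, float))
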