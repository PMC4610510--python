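"""Column scaling, capacitance maps, and frequency-window selection.

Before a transferable model is fit, two things happen to the spectra: the
columns are mean-centered or standardized, and the excitation-frequency
window is chosen. High frequencies correlate with particles smaller than
viable cells (debris), so retaining them makes a model track debris in the
declining phase. The cross-run "capacitance map" — per-frequency min-max
normalized trajectories with the normalized VCC as the leftmost column —
makes those channels visible; ``select_frequencies`` offers both the fixed
published window (frequencies 1:10, 0.3–2.16 MHz) and an automated
correlation rule that reproduces the visual procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import FermentationRun, spline_align
from .errors import DegenerateDataError

__all__ = [
    "ScalingParams",
    "fit_scaling",
    "apply_scaling",
    "inverse_scaling",
    "FrequencyWindow",
    "CapacitanceMap",
    "build_capacitance_map",
    "select_frequencies",
]

SCALING_MODES = ("mean_center", "standardize")


@dataclass(frozen=True)
class ScalingParams:
    mode: str
    means: tuple[float, ...]   # pF/cm per retained column
    sds: tuple[float, ...]     # 1.0 for mean_center

    def to_dict(self) -> dict:
        return {"mode": self.mode, "means": list(self.means), "sds": list(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(mode=d["mode"], means=tuple(d["means"]), sds=tuple(d["sds"]))


def fit_scaling(X: np.ndarray, mode: str = "mean_center") -> ScalingParams:
    if mode not in SCALING_MODES:
        raise ValueError(f"mode must be one of {SCALING_MODES}, got {mode!r}")
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] < 2:
        raise DegenerateDataError("scaling needs at least 2 rows")
    means = X.mean(axis=0)
    if mode == "standardize":
        sds = X.std(axis=0, ddof=1)
        scale = np.max(np.abs(X), axis=0) + 1.0
        bad = np.flatnonzero(sds <= 1e-12 * scale)
        if bad.size:
            raise DegenerateDataError(
                f"constant column(s) under standardize: frequencies {[int(i) + 1 for i in bad]}"
            )
    else:
        sds = np.ones_like(means)
    return ScalingParams(mode=mode, means=tuple(means), sds=tuple(sds))


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    return (X - np.asarray(params.means)) / np.asarray(params.sds)


def inverse_scaling(X_scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    X_scaled = np.atleast_2d(np.asarray(X_scaled, float))
    return X_scaled * np.asarray(params.sds) + np.asarray(params.means)


@dataclass(frozen=True)
class FrequencyWindow:
    """Contiguous retained frequency indices, 1-based and anchored at FQ1.

    Windows are prefixes 1:k of the grid by design: transferable models keep
    the low-frequency end and ablate from the top, so arbitrary subsets are
    not representable.
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("frequency window must be non-empty")
        if list(self.indices) != list(range(1, len(self.indices) + 1)):
            raise ValueError(
                f"window must be contiguous 1:k (anchored at FQ1), got {self.indices}"
            )
        if self.indices[-1] > 17:
            raise ValueError("window indices must lie in 1..17")

    @classmethod
    def upto(cls, k: int) -> "FrequencyWindow":
        return cls(tuple(range(1, k + 1)))

    @classmethod
    def fixed(cls) -> "FrequencyWindow":
        """The published transfer window: frequencies 1:10 (0.3–2.16 MHz)."""
        return cls.upto(10)

    @classmethod
    def full(cls) -> "FrequencyWindow":
        return cls.upto(17)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    @property
    def slice(self) -> slice:
        return slice(0, len(self.indices))


def _minmax(values: np.ndarray, lo, hi) -> np.ndarray:
    span = np.asarray(hi, float) - np.asarray(lo, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


@dataclass
class CapacitanceMap:
    """Cross-run, per-frequency normalized capacitance with normalized VCC.

    Normalization constants are global across the pooled runs, so the
    maximum of each frequency over *all* runs maps to 1 and the minimum to
    0; rendered as a heat map with time running top to bottom and the VCC
    column leftmost.
    """

    run_ids: list[str]
    times: list[np.ndarray]
    vcc_norm: list[np.ndarray]
    spectra_norm: list[np.ndarray]
    freq_min: np.ndarray
    freq_max: np.ndarray
    vcc_min: float
    vcc_max: float

    @property
    def n_frequencies(self) -> int:
        return self.spectra_norm[0].shape[1]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for rid, t, v, s in zip(self.run_ids, self.times, self.vcc_norm, self.spectra_norm):
            cols = {f"fq{i + 1:02d}": s[:, i] for i in range(s.shape[1])}
            frames.append(pd.DataFrame({"run_id": rid, "time_h": t, "vcc": v, **cols}))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def plot(self, path=None):
        """Render the map (one panel per run, VCC as leftmost column)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.run_ids)
        fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 6), squeeze=False)
        for ax, rid, v, s in zip(axes[0], self.run_ids, self.vcc_norm, self.spectra_norm):
            img = np.column_stack([v, s])
            ax.imshow(img, aspect="auto", cmap="Greens", vmin=0.0, vmax=1.0,
                      interpolation="nearest")
            ax.set_title(rid)
            ax.set_xlabel("VCC | FQ1..FQ%d" % s.shape[1])
            ax.set_ylabel("time →")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def build_capacitance_map(runs: list[FermentationRun]) -> CapacitanceMap:
    """Min-max normalize spectra and splined VCC over the pooled runs."""
    if not runs:
        raise ValueError("build_capacitance_map needs at least one run")
    aligned = [spline_align(r) for r in runs]
    X_all = np.vstack([a.X for a in aligned])
    y_all = np.concatenate([a.y for a in aligned])
    f_min, f_max = X_all.min(axis=0), X_all.max(axis=0)
    v_min, v_max = float(y_all.min()), float(y_all.max())
    return CapacitanceMap(
        run_ids=[r.run_id for r in runs],
        times=[a.times for a in aligned],
        vcc_norm=[_minmax(a.y, v_min, v_max) for a in aligned],
        spectra_norm=[_minmax(a.X, f_min, f_max) for a in aligned],
        freq_min=f_min,
        freq_max=f_max,
        vcc_min=v_min,
        vcc_max=v_max,
    )


def select_frequencies(
    runs: list[FermentationRun],
    mode: str = "fixed",
    threshold: float = 0.8,
) -> FrequencyWindow:
    """Choose the retained frequency window 1:k.

    ``fixed`` returns the published window 1:10 regardless of data.
    ``data_driven`` automates the capacitance-map reading: it keeps the
    longest prefix 1:k in which every channel's whole-run Pearson
    correlation with the splined VCC, averaged across runs, stays at or
    above ``threshold``. Channels that keep rising after the VCC has
    declined (debris-dominated) fail that test and are cut.
    """
    if mode == "fixed":
        return FrequencyWindow.fixed()
    if mode != "data_driven":
        raise ValueError(f"mode must be 'fixed' or 'data_driven', got {mode!r}")
    if not runs:
        raise ValueError("select_frequencies needs at least one run")

    aligned = [spline_align(r) for r in runs]
    if all(int(np.argmax(a.y)) == len(a.y) - 1 for a in aligned):
        warnings.warn(
            "no run shows a decline phase; data-driven frequency selection is "
            "only informative when debris accumulates", stacklevel=2)
    n_freq = aligned[0].X.shape[1]
    corr = np.zeros((len(aligned), n_freq))
    for i, a in enumerate(aligned):
        y = a.y - a.y.mean()
        ynorm = np.linalg.norm(y)
        for k in range(n_freq):
            x = a.X[:, k] - a.X[:, k].mean()
            denom = np.linalg.norm(x) * ynorm
            corr[i, k] = (x @ y) / denom if denom > 0 else 0.0
    mean_corr = corr.mean(axis=0)
    k = 0
    while k < n_freq and mean_corr[k] >= threshold:
        k += 1
    return FrequencyWindow.upto(max(k, 1))
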