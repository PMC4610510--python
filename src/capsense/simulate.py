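"""Synthetic dielectric fed-batch generator.

Produces fermentation runs with the statistical structure a multi-frequency
capacitance soft sensor has to cope with: a viable cell concentration (VCC)
that rises logistically and then declines, dead cells that lyse into
sub-cellular debris, a beta-dispersion-like low-pass frequency response in
which viable cells dominate the low excitation frequencies and debris the
high ones, multiplicative probe noise, baseline drift, bolus dilutions and
bubble-burst transients.

Units used throughout the package: time in hours from inoculation,
frequency in MHz, capacitance in pF/cm, cell concentrations in 1e5 cells/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CloneProfile",
    "CultureParams",
    "DisturbanceSpec",
    "SamplingSpec",
    "SyntheticRun",
    "make_frequency_grid",
    "dispersion_response",
    "simulate_run",
    "generate_clone_pair",
]

#: Width (h) of the smooth hand-over from growth to death around death_onset.
_PHASE_SWITCH_WIDTH_H = 6.0


def make_frequency_grid(n: int = 17, fmin: float = 0.3, fmax: float = 10.0) -> np.ndarray:
    """Logarithmically spaced excitation-frequency grid in MHz.

    The default mirrors a scanning capacitance probe stepping through 17
    frequencies from 0.3 to 10 MHz; on that grid the 10th frequency falls at
    0.3 * (10/0.3)**(9/16) = 2.16 MHz, the upper edge of the low-frequency
    window used for transferable models.
    """
    if n < 2:
        raise ValueError(f"need at least 2 frequencies, got {n}")
    if not (0 < fmin < fmax):
        raise ValueError(f"require 0 < fmin < fmax, got fmin={fmin}, fmax={fmax}")
    return np.geomspace(fmin, fmax, n)


def dispersion_response(f, fc: float, alpha: float = 0.0):
    """Relative dispersion amplitude remaining at excitation frequency ``f``.

    Real part of the Cole-Cole relaxation 1 / (1 + (i f/fc)^(1-alpha)),
    which reduces to the Debye form 1 / (1 + (f/fc)^2) at ``alpha = 0``.
    Monotonically decreasing in ``f``; 1 in the low-frequency plateau and 0
    far above the critical frequency ``fc``.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"cole_cole_alpha must lie in [0, 1), got {alpha}")
    if fc <= 0:
        raise ValueError(f"critical frequency must be positive, got {fc}")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    x = (f / fc) ** (1.0 - alpha)
    c = math.cos(math.pi / 2.0 * (1.0 - alpha))
    out = (1.0 + x * c) / (1.0 + 2.0 * x * c + x * x)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CloneProfile:
    """Dielectric signature of one cell clone.

    per_cell_capacitance
        pF/cm contributed per 1e5 viable cells/mL in the low-frequency
        plateau; the clone-specific amplitude that the kappa transfer
        compensates for.
    critical_frequency_cells
        Beta-dispersion midpoint of viable cells (MHz).
    cole_cole_alpha
        Dispersion broadening, 0 = pure Debye relaxation.
    debris_critical_frequency
        Dispersion midpoint of sub-cellular debris (MHz); smaller particles
        relax at higher frequency, so this must exceed the cell value.
    debris_amplitude
        pF/cm per debris unit (lysed-cell equivalents per mL, 1e5 scale).
    """

    per_cell_capacitance: float = 0.8
    critical_frequency_cells: float = 1.2
    cole_cole_alpha: float = 0.1
    debris_critical_frequency: float = 8.0
    debris_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.per_cell_capacitance <= 0:
            raise ValueError("per_cell_capacitance must be > 0")
        if self.debris_amplitude < 0:
            raise ValueError("debris_amplitude must be >= 0")
        if not 0 <= self.cole_cole_alpha < 1:
            raise ValueError("cole_cole_alpha must lie in [0, 1)")
        if self.critical_frequency_cells <= 0:
            raise ValueError("critical_frequency_cells must be > 0")
        if self.debris_critical_frequency <= self.critical_frequency_cells:
            raise ValueError(
                "debris_critical_frequency must exceed critical_frequency_cells "
                f"({self.debris_critical_frequency} <= {self.critical_frequency_cells})"
            )


@dataclass(frozen=True)
class CultureParams:
    """Kinetics of one fed-batch: logistic growth, delayed death, lysis."""

    mu_max: float = 0.04          # 1/h
    capacity: float = 150.0       # 1e5 cells/mL, logistic ceiling on TCC
    death_onset: float = 192.0    # h
    death_rate: float = 0.02      # 1/h
    lysis_rate: float = 0.02      # 1/h, dead cells -> debris
    duration: float = 336.0       # h
    inoculum: float = 5.0         # 1e5 cells/mL

    def __post_init__(self) -> None:
        if not (self.duration > self.death_onset > 0):
            raise ValueError("require duration > death_onset > 0")
        if not 3.0 <= self.inoculum <= 10.0:
            raise ValueError(
                f"inoculum must lie in the seeding range 3-10 (1e5/mL), got {self.inoculum}"
            )
        for name in ("mu_max", "capacity", "death_rate", "lysis_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DisturbanceSpec:
    """Process disturbances applied to the capacitance signal.

    bolus_times: (time_h, dilution_fraction) pairs; a bolus feed instantly
    dilutes cells, dead cells and debris by (1 - fraction).
    bubble_bursts: (time_h, depth, width_h) Gaussian dips multiplying the
    dielectric signal (a burst of gas bubbles transiently displaces broth
    at the probe).
    drift_rate: scale of additive baseline drift, pF/cm/h at the highest
    frequency. Electrode polarization, fouling and grounding artifacts
    drift hardest at high excitation frequencies and in a direction that
    depends on the individual setup, so each channel drifts linearly with
    slope drift_rate * (f / f_max) * z_f, with z_f a run-specific standard
    normal draw. This is what makes the high-frequency channels
    non-transferable between runs and setups.
    noise_cv: multiplicative measurement noise per channel and timepoint.
    """

    bolus_times: tuple[tuple[float, float], ...] = ()
    bubble_bursts: tuple[tuple[float, float, float], ...] = ()
    drift_rate: float = 0.0
    noise_cv: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for t, frac in self.bolus_times:
            if not 0 < frac < 1:
                raise ValueError(f"bolus dilution fraction must lie in (0, 1), got {frac}")
            if t < 0:
                raise ValueError("bolus time must be >= 0")
        for t, depth, width in self.bubble_bursts:
            if not 0 <= depth < 1 or width <= 0:
                raise ValueError("bubble burst needs 0 <= depth < 1 and width > 0")


@dataclass(frozen=True)
class SamplingSpec:
    """Online/offline sampling cadence and offline counting noise."""

    online_interval: float = 0.5     # h, ~2 spectra per hour
    offline_interval: float = 12.0   # h, trypan-blue counts
    offline_noise_cv: float = 0.05   # counter repeatability

    def __post_init__(self) -> None:
        if self.online_interval <= 0:
            raise ValueError("online_interval must be > 0")
        if self.offline_interval < self.online_interval:
            raise ValueError(
                "offline_interval must be >= online_interval "
                f"({self.offline_interval} < {self.online_interval})"
            )
        if self.offline_noise_cv < 0:
            raise ValueError("offline_noise_cv must be >= 0")


@dataclass
class SyntheticRun:
    """One simulated fed-batch with ground truth on the online grid."""

    frequencies: np.ndarray          # (F,) MHz
    times_online: np.ndarray         # (n,) h
    spectra: np.ndarray              # (n, F) pF/cm
    times_offline: np.ndarray        # (m,) h
    vcc_offline: np.ndarray          # (m,) 1e5 cells/mL, with counting noise
    tcc_offline: np.ndarray          # (m,) 1e5 cells/mL
    viability_offline: np.ndarray    # (m,) %
    ground_truth_vcc: np.ndarray     # (n,)
    ground_truth_tcc: np.ndarray     # (n,)
    ground_truth_debris: np.ndarray  # (n,) lysed-cell equivalents

    def to_fermentation_run(self, run_id: str, clone: str = "", scale: str = ""):
        """View this run as the measured-data container used for fitting."""
        from .dataio import FermentationRun

        return FermentationRun(
            run_id=run_id,
            clone=clone,
            scale=scale,
            times_online=self.times_online.copy(),
            spectra=self.spectra.copy(),
            times_offline=self.times_offline.copy(),
            vcc_offline=self.vcc_offline.copy(),
            tcc_offline=self.tcc_offline.copy(),
            viability_offline=self.viability_offline.copy(),
        )


def _culture_trajectory(culture: CultureParams, disturb: DisturbanceSpec, times: np.ndarray):
    """Integrate (VCC, dead, debris) with fixed-step RK4 on a fine grid.

    Growth is logistic in total cells and hands over smoothly to first-order
    death around ``death_onset`` (sigmoid switch); dead cells lyse to debris
    at ``lysis_rate``. Bolus dilutions are applied as instantaneous state
    jumps. The bookkeeping conserves cells: d(VCC+dead+debris)/dt equals the
    growth term alone between boluses.
    """
    substeps = 5
    dt = (times[1] - times[0]) / substeps if len(times) > 1 else 0.1
    boluses = sorted(disturb.bolus_times)

    def rates(t: float, s: np.ndarray) -> np.ndarray:
        v, d, _ = s
        sw = 1.0 / (1.0 + math.exp(min(50.0, (t - culture.death_onset) / _PHASE_SWITCH_WIDTH_H)))
        mu = culture.mu_max * sw * (1.0 - (v + d) / culture.capacity)
        delta = culture.death_rate * (1.0 - sw)
        return np.array([mu * v - delta * v, delta * v - culture.lysis_rate * d,
                         culture.lysis_rate * d])

    state = np.array([culture.inoculum, 0.0, 0.0])
    out = np.empty((len(times), 3))
    out[0] = state
    bolus_i = 0
    t = times[0]
    for i in range(1, len(times)):
        for _ in range(substeps):
            while bolus_i < len(boluses) and t >= boluses[bolus_i][0] - 1e-9:
                state = state * (1.0 - boluses[bolus_i][1])
                bolus_i += 1
            k1 = rates(t, state)
            k2 = rates(t + dt / 2, state + dt / 2 * k1)
            k3 = rates(t + dt / 2, state + dt / 2 * k2)
            k4 = rates(t + dt, state + dt * k3)
            state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        out[i] = state
    return out[:, 0], out[:, 1], out[:, 2]


def simulate_run(
    clone: CloneProfile,
    culture: CultureParams,
    disturb: DisturbanceSpec | None = None,
    sampling: SamplingSpec | None = None,
    seed: int = 0,
    frequencies: np.ndarray | None = None,
) -> SyntheticRun:
    """Simulate one fed-batch run; all randomness is fixed by ``seed``."""
    disturb = disturb if disturb is not None else DisturbanceSpec()
    sampling = sampling if sampling is not None else SamplingSpec()
    freqs = make_frequency_grid() if frequencies is None else np.asarray(frequencies, float)
    rng = np.random.default_rng(seed)

    n_online = int(math.floor(culture.duration / sampling.online_interval + 1e-9)) + 1
    t_on = np.arange(n_online) * sampling.online_interval
    vcc, dead, debris = _culture_trajectory(culture, disturb, t_on)

    disp_cells = dispersion_response(freqs, clone.critical_frequency_cells, clone.cole_cole_alpha)
    disp_debris = dispersion_response(freqs, clone.debris_critical_frequency, clone.cole_cole_alpha)
    base = (clone.per_cell_capacitance * vcc[:, None] * disp_cells[None, :]
            + clone.debris_amplitude * debris[:, None] * disp_debris[None, :])

    dip = np.ones_like(t_on)
    for t0, depth, width in disturb.bubble_bursts:
        dip -= depth * np.exp(-0.5 * ((t_on - t0) / width) ** 2)
    spectra = base * dip[:, None]
    if disturb.noise_cv > 0:
        spectra = spectra * (1.0 + disturb.noise_cv * rng.standard_normal(spectra.shape))
    if disturb.drift_rate != 0.0:
        drift_slope = disturb.drift_rate * (freqs / freqs[-1]) * rng.standard_normal(freqs.size)
        spectra = spectra + t_on[:, None] * drift_slope[None, :]
    np.clip(spectra, 0.0, None, out=spectra)

    n_offline = int(math.floor(culture.duration / sampling.offline_interval + 1e-9)) + 1
    t_off = np.arange(n_offline) * sampling.offline_interval
    idx = np.rint(t_off / sampling.online_interval).astype(int)
    idx = np.clip(idx, 0, n_online - 1)
    cv = sampling.offline_noise_cv
    vcc_off = vcc[idx] * (1.0 + cv * rng.standard_normal(n_offline))
    tcc_off = (vcc[idx] + dead[idx]) * (1.0 + cv * rng.standard_normal(n_offline))
    vcc_off = np.clip(vcc_off, 1e-6, None)
    tcc_off = np.maximum(tcc_off, vcc_off)
    viability = vcc_off / tcc_off * 100.0

    return SyntheticRun(
        frequencies=freqs,
        times_online=t_on,
        spectra=spectra,
        times_offline=t_off,
        vcc_offline=vcc_off,
        tcc_offline=tcc_off,
        viability_offline=viability,
        ground_truth_vcc=vcc,
        ground_truth_tcc=vcc + dead,
        ground_truth_debris=debris,
    )


def generate_clone_pair(
    base: CloneProfile,
    amplitude_ratio: float,
    shared: CultureParams,
    n_runs_each: int,
    seed: int = 0,
    disturb: DisturbanceSpec | None = None,
    sampling: SamplingSpec | None = None,
    culture_jitter: float = 0.05,
    fc_debris_jitter: float = 0.15,
) -> tuple[list[SyntheticRun], list[SyntheticRun]]:
    """Two fleets of runs whose only systematic difference is the per-cell amplitude.

    The second clone's ``per_cell_capacitance`` is the base value times
    ``amplitude_ratio`` — the stable phenotype that a kappa transfer must
    recover as 1/ratio. On top of that, every run draws seeded biological
    variation: lognormal jitter of the culture kinetics (``culture_jitter``)
    and of the debris critical frequency (``fc_debris_jitter``; debris
    particle-size distributions differ run to run).
    """
    if amplitude_ratio <= 0:
        raise ValueError(f"amplitude_ratio must be > 0, got {amplitude_ratio}")
    if n_runs_each < 0:
        raise ValueError("n_runs_each must be >= 0")
    rng = np.random.default_rng(seed)
    other = replace(base, per_cell_capacitance=base.per_cell_capacitance * amplitude_ratio)

    fleets: list[list[SyntheticRun]] = []
    for profile in (base, other):
        runs = []
        for _ in range(n_runs_each):
            j = lambda s: float(np.exp(s * rng.standard_normal()))
            culture = replace(
                shared,
                mu_max=shared.mu_max * j(culture_jitter),
                capacity=shared.capacity * j(culture_jitter),
                death_onset=shared.death_onset * j(culture_jitter / 2),
                death_rate=shared.death_rate * j(culture_jitter),
                lysis_rate=shared.lysis_rate * j(culture_jitter),
                inoculum=float(np.clip(shared.inoculum * j(culture_jitter), 3.0, 10.0)),
            )
            fc_d = profile.debris_critical_frequency * j(fc_debris_jitter)
            fc_d = max(fc_d, profile.critical_frequency_cells * 1.5)
            clone_i = replace(profile, debris_critical_frequency=fc_d)
            run_seed = int(rng.integers(0, 2**31 - 1))
            runs.append(simulate_run(clone_i, culture, disturb, sampling, seed=run_seed))
        fleets.append(runs)
    return fleets[0], fleets[1]
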