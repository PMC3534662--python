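"""Synthetic fast-Off retinal ganglion cell (RGC) population.

Stands in for recorded salamander RGC responses to flashed square-wave
gratings.  The generator reproduces the statistical structure the readout
analyses rely on:

* cosine tuning of the first-spike latency with the grating phase,
  f(phi) = b + a cos(phi - phi0), latencies in ms;
* cosine tuning of the spike count, in antiphase (180 deg) with the latency
  tuning — phases that are responded to quickly are responded to strongly;
* preferred phases phi0 spread uniformly over the population, baselines and
  amplitudes drawn independently;
* an additive latency shift shared by all cells when contrast drops;
* trial-to-trial latency jitter split into a component shared across
  simultaneously active cells and a private component, giving positive
  pairwise latency correlations rho = sd_sh^2 / (sd_sh^2 + sd_pr^2);
* burst structure (extra spikes at a fixed inter-spike interval after the
  first) inside the 150 ms response window, and occasional whole-trial
  spike failures that become more frequent at low contrast.

The module also provides the continuous-stimulus geometry used by the
orientation experiment: the fraction of a Gaussian receptive field covered
by the dark bars of a grating of arbitrary phase and orientation, and the
latency law driven by that coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .spikeio import DEFAULT_WINDOW_MS, Dataset, SpikeTrain, TrialPattern

PHASE_STEP_DEG = 45.0  # 8 grating phases, quarter-bar-width shifts


def phase_deg(phase_index: int) -> float:
    """Grating phase angle of index i in 1..8: (i-1) * 45 degrees."""
    return (phase_index - 1) * PHASE_STEP_DEG


@dataclass(frozen=True)
class SyntheticRGC:
    """Generative parameters of one model ganglion cell."""

    latency_baseline: float  # b, ms
    latency_amplitude: float  # a, ms; fastest response at phi = phi0 - 180
    phase_offset_deg: float  # phi0 of the latency tuning curve
    count_baseline: float = 3.0  # spikes
    count_amplitude: float = 2.0  # spikes
    burst_isi: float = 8.0  # ms between successive burst spikes
    rf_center: tuple[float, float] | None = None  # orientation model only
    rf_sigma: float | None = None

    def __post_init__(self) -> None:
        if not self.latency_baseline > self.latency_amplitude >= 0:
            raise ValueError("need b > a >= 0 so latencies stay positive")

    def latency_at(self, phase: float) -> float:
        """Noise-free latency tuning curve, phase in degrees."""
        return self.latency_baseline + self.latency_amplitude * math.cos(
            math.radians(phase - self.phase_offset_deg)
        )

    def count_at(self, phase: float) -> float:
        """Noise-free count tuning curve, antiphase to the latency curve."""
        return self.count_baseline + self.count_amplitude * math.cos(
            math.radians(phase - self.phase_offset_deg - 180.0)
        )


@dataclass(frozen=True)
class PopulationConfig:
    """Generative defaults for a grating-indexed population.

    Latency baselines ~ N(80, 10) ms and amplitudes ~ N(25, 5) ms
    (resampled until b > a > 0), preferred phases uniform on [0, 360).
    Contrast levels map to an additive latency shift shared by all cells
    and to a per-cell spike-failure probability.
    """

    n_cells: int = 8
    latency_baseline_mean: float = 80.0
    latency_baseline_sd: float = 10.0
    latency_amplitude_mean: float = 25.0
    latency_amplitude_sd: float = 5.0
    count_baseline_mean: float = 3.5
    count_baseline_sd: float = 0.8
    count_amplitude_mean: float = 2.0
    count_amplitude_sd: float = 0.5
    burst_isi: float = 8.0
    contrast_shift_ms: dict = field(default_factory=lambda: {100.0: 0.0})
    failure_rate: dict = field(default_factory=lambda: {100.0: 0.0})
    jitter_shared_sd: float = 2.0
    jitter_private_sd: float = 2.0
    count_noise_sd: float = 1.0
    seed: int = 0


def sample_population(config: PopulationConfig) -> list[SyntheticRGC]:
    """Draw the cell parameters of one population (seeded)."""
    if config.n_cells < 1:
        raise ValueError("need at least one cell")
    for sd in (
        config.latency_baseline_sd,
        config.latency_amplitude_sd,
        config.count_baseline_sd,
        config.count_amplitude_sd,
    ):
        if sd < 0:
            raise ValueError("distribution sds must be non-negative")
    rng = np.random.default_rng(config.seed)
    cells = []
    for _ in range(config.n_cells):
        while True:  # truncate to b > a > 0
            b = rng.normal(config.latency_baseline_mean, config.latency_baseline_sd)
            a = rng.normal(config.latency_amplitude_mean, config.latency_amplitude_sd)
            if b > a > 0:
                break
        cb = max(rng.normal(config.count_baseline_mean, config.count_baseline_sd), 1.0)
        ca = abs(rng.normal(config.count_amplitude_mean, config.count_amplitude_sd))
        ca = min(ca, cb - 0.5)
        cells.append(
            SyntheticRGC(
                latency_baseline=b,
                latency_amplitude=a,
                phase_offset_deg=float(rng.uniform(0.0, 360.0)),
                count_baseline=cb,
                count_amplitude=max(ca, 0.0),
                burst_isi=config.burst_isi,
            )
        )
    return cells


def simulate_trial(
    population: list[SyntheticRGC],
    phase_index: int,
    contrast: float,
    config: PopulationConfig,
    rng: np.random.Generator,
    trial_id: int = 0,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> TrialPattern:
    """One stimulus presentation for the whole population.

    The shared jitter component is drawn once per trial and added to every
    cell's latency; the private component is per cell.  A cell fails
    (empty train) with the contrast's failure probability.
    """
    if not 1 <= phase_index <= 8:
        raise ValueError("phase_index must be in 1..8")
    shift = config.contrast_shift_ms.get(contrast)
    if shift is None:
        raise ValueError(f"contrast {contrast} has no configured latency shift")
    p_fail = config.failure_rate.get(contrast, 0.0)
    phi = phase_deg(phase_index)
    eta_shared = rng.normal(0.0, config.jitter_shared_sd) if config.jitter_shared_sd else 0.0
    trains = []
    for i, cell in enumerate(population):
        if p_fail > 0 and rng.random() < p_fail:
            trains.append(SpikeTrain(i, ()))
            continue
        latency = (
            cell.latency_at(phi)
            + shift
            + eta_shared
            + (rng.normal(0.0, config.jitter_private_sd) if config.jitter_private_sd else 0.0)
        )
        if latency <= 0:
            latency = 0.5  # clip pathological draws just after onset
        count = cell.count_at(phi) + (
            rng.normal(0.0, config.count_noise_sd) if config.count_noise_sd else 0.0
        )
        count = max(int(round(count)), 1)
        times = tuple(
            t
            for j in range(count)
            if (t := latency + j * cell.burst_isi) <= window_ms
        )
        if not times:  # latency beyond the window counts as a failure
            trains.append(SpikeTrain(i, ()))
        else:
            trains.append(SpikeTrain(i, times))
    return TrialPattern(
        trial_id=trial_id,
        trains=tuple(trains),
        phase_index=phase_index,
        contrast=contrast,
    )


def simulate_dataset(
    population: list[SyntheticRGC],
    config: PopulationConfig,
    trials_per_condition: int = 30,
    phases: tuple[int, ...] = tuple(range(1, 9)),
    contrasts: tuple[float, ...] | None = None,
    seed: int | None = None,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> Dataset:
    """A full grating dataset: every phase x contrast condition repeated
    ``trials_per_condition`` times, in condition-major order."""
    if contrasts is None:
        contrasts = tuple(sorted(config.contrast_shift_ms))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trials = []
    tid = 0
    for contrast in contrasts:
        for phase in phases:
            for _ in range(trials_per_condition):
                trials.append(
                    simulate_trial(
                        population, phase, contrast, config, rng, tid, window_ms
                    )
                )
                tid += 1
    return Dataset(
        tuple(trials),
        window_ms,
        {"contrast_levels": list(contrasts), "n_cells": len(population)},
    )


# ------------------------------------------------ continuous-grating geometry


def dark_fraction(
    rf_center: tuple[float, float],
    sigma_rf: float,
    phase_deg_: float,
    orientation_deg: float = 0.0,
    period: float = 1.0,
) -> float:
    """Fraction of a Gaussian receptive field covered by the dark bars of a
    square grating (period 1 by default).

    The isotropic 2-D Gaussian projects to a 1-D Gaussian along the
    grating's modulation axis; D is the Gaussian measure of the dark
    half-period intervals, summed until the omitted tail is below 1e-12.
    """
    if sigma_rf <= 0:
        raise ValueError("sigma_rf must be positive")
    psi = math.radians(orientation_deg)
    ax, ay = math.cos(psi), math.sin(psi)
    if ax < 0 or (ax == 0 and ay < 0):
        ax, ay = -ax, -ay  # orientation is a direction mod 180 degrees
    # coordinate along the modulation axis, in periods
    u = (rf_center[0] * ax + rf_center[1] * ay) / period
    s = sigma_rf / period
    # dark bars: u in [phase/360 + k, phase/360 + 0.5 + k) for integer k
    lo0 = phase_deg_ / 360.0
    n_half = int(math.ceil(8 * s + 2))  # +/- n periods cover all but < 1e-12
    total = 0.0
    for k in range(-n_half, n_half + 1):
        a = lo0 + k
        total += norm.cdf((a + 0.5 - u) / s) - norm.cdf((a - u) / s)
    return min(max(total, 0.0), 1.0)


def latency_from_dark_fraction(
    D: float, baseline: float, amplitude: float, noise: float = 0.0
) -> float:
    """Latency law of the orientation model: b + a cos(pi D) + noise.

    Monotone decreasing in D — the darker the receptive field turns, the
    faster the fast-Off cell responds (D=1 gives b-a, D=0 gives b+a).
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("dark fraction must be in [0, 1]")
    latency = baseline + amplitude * math.cos(math.pi * D) + noise
    return max(latency, 0.5)


def sample_orientation_population(
    n_cells: int = 200,
    placement_radius: float = 1.5,
    rf_sigma: float = 0.12,
    latency_baseline_mean: float = 80.0,
    latency_baseline_sd: float = 10.0,
    latency_amplitude_mean: float = 25.0,
    latency_amplitude_sd: float = 5.0,
    seed: int = 0,
) -> list[SyntheticRGC]:
    """Model retinal patch for the orientation experiment: Gaussian receptive
    fields placed uniformly in a disc (radius in grating periods)."""
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        while True:
            x, y = rng.uniform(-placement_radius, placement_radius, 2)
            if x * x + y * y <= placement_radius**2:
                break
        while True:
            b = rng.normal(latency_baseline_mean, latency_baseline_sd)
            a = rng.normal(latency_amplitude_mean, latency_amplitude_sd)
            if b > a > 0:
                break
        cells.append(
            SyntheticRGC(
                latency_baseline=b,
                latency_amplitude=a,
                phase_offset_deg=0.0,
                rf_center=(float(x), float(y)),
                rf_sigma=rf_sigma,
            )
        )
    return cells


def dark_fraction_grid(
    centers: np.ndarray,
    sigma_rf,
    phases: np.ndarray,
    orientations: np.ndarray,
    period: float = 1.0,
) -> np.ndarray:
    """Vectorized :func:`dark_fraction` over stimuli x cells.

    ``centers`` is (n_cells, 2); ``phases`` and ``orientations`` are
    per-stimulus arrays of equal length.  Returns (n_stimuli, n_cells).
    """
    centers = np.asarray(centers, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma_rf, dtype=float), (centers.shape[0],))
    if np.any(sigma <= 0):
        raise ValueError("sigma_rf must be positive")
    psi = np.radians(np.asarray(orientations, dtype=float))
    ax, ay = np.cos(psi), np.sin(psi)
    flip = (ax < 0) | ((ax == 0) & (ay < 0))
    ax, ay = np.where(flip, -ax, ax), np.where(flip, -ay, ay)
    u = (np.outer(ax, centers[:, 0]) + np.outer(ay, centers[:, 1])) / period
    s = sigma[None, :] / period
    lo0 = (np.asarray(phases, dtype=float) / 360.0)[:, None]
    n_half = int(math.ceil(8 * float(np.max(s)) + 2))
    total = np.zeros_like(u)
    for k in range(-n_half, n_half + 1):
        a = lo0 + k
        total += norm.cdf((a + 0.5 - u) / s) - norm.cdf((a - u) / s)
    return np.clip(total, 0.0, 1.0)


def orientation_latency_matrix(
    population: list["SyntheticRGC"], phases, orientations
) -> np.ndarray:
    """First-spike latencies (n_stimuli, n_cells) for continuous gratings,
    noise-free."""
    centers = np.array([c.rf_center for c in population])
    sigma = np.array([c.rf_sigma for c in population])
    D = dark_fraction_grid(centers, sigma, np.asarray(phases), np.asarray(orientations))
    b = np.array([c.latency_baseline for c in population])
    a = np.array([c.latency_amplitude for c in population])
    return np.maximum(b[None, :] + a[None, :] * np.cos(math.pi * D), 0.5)


def orientation_latencies(
    population: list[SyntheticRGC],
    phase: float,
    orientation: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """First-spike latency of every cell for one continuous grating."""
    out = np.empty(len(population))
    for i, cell in enumerate(population):
        D = dark_fraction(cell.rf_center, cell.rf_sigma, phase, orientation)
        noise = rng.normal(0.0, noise_sd) if (noise_sd and rng is not None) else 0.0
        out[i] = latency_from_dark_fraction(
            D, cell.latency_baseline, cell.latency_amplitude, noise
        )
    return out


# ------------------------------------------------------- hexagonal schematic


HEX_CENTERS = [
    (0.0, 0.0),
    (1.0, 0.0),
    (0.5, math.sqrt(3) / 2),
    (-0.5, math.sqrt(3) / 2),
    (-1.0, 0.0),
    (-0.5, -math.sqrt(3) / 2),
    (0.5, -math.sqrt(3) / 2),
]


def hex_schematic(
    preferred: tuple[int, ...],
    delta_t: float = 30.0,
    t_early: float = 20.0,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> tuple[Dataset, np.ndarray]:
    """All 128 binary dark/bright stimuli over a 7-cell hexagonal patch.

    Each cell fires exactly one spike: early (t_early) if its receptive
    field turns dark, late (t_early + delta_t) if bright.  Returns the
    128-trial dataset and a target mask marking the preferred grating and
    its polarity inverse (2 targets, 126 nulls).
    """
    if len(preferred) != 7 or any(b not in (0, 1) for b in preferred):
        raise ValueError("preferred must be a binary 7-vector (1 = dark)")
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    preferred = tuple(preferred)
    inverse = tuple(1 - b for b in preferred)
    trials = []
    targets = np.zeros(128, dtype=bool)
    for idx in range(128):
        bits = tuple((idx >> i) & 1 for i in range(7))
        trains = tuple(
            SpikeTrain(i, (t_early if b else t_early + delta_t,))
            for i, b in enumerate(bits)
        )
        trials.append(
            TrialPattern(trial_id=idx, trains=trains, class_label=int(bits in (preferred, inverse)))
        )
        targets[idx] = bits in (preferred, inverse)
    return Dataset(tuple(trials), window_ms, {"preferred": preferred}), targets
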