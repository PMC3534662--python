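"""Phase-invariant orientation tuning with a single tempotron.

A model retinal patch of 200 ganglion cells (Gaussian receptive fields,
latency driven by the dark-covered fraction of the field) is stimulated
with square gratings over a fine phase x orientation grid.  One tempotron
is trained to fire for every grating whose orientation lies within a target
band (|psi| <= 15 deg or 30 deg), regardless of spatial phase — the
defining property of cortical complex cells — and to stay silent
everywhere else.

Training uses a +/-10%-of-threshold margin except in a narrow exclusion
zone around the orientation boundary, a decaying step size
lambda_n = lambda0 / (1 + n / decay_scale), momentum 0.99, and up to
10,000 cycles through the grid in a random but fixed order.  A run counts
as converged when the margin-free classification error on the full grid
reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fast import grid_error, train_margin_schedule, vmax_single_spike
from .retina import (
    SyntheticRGC,
    orientation_latencies,
    orientation_latency_matrix,
    sample_orientation_population,
)
from .tempotron import PSPKernel


@dataclass(frozen=True)
class GridSpec:
    """Phase x orientation stimulus grid with a target orientation band."""

    n_phases: int = 201  # linear in [-180, 180] deg
    n_orientations: int = 101  # linear in [-90, 90] deg
    target_halfwidth: float = 15.0  # deg; 15 narrow, 30 wide
    margin: float = 0.1  # fraction of threshold
    exclusion_halfwidth: float = 3.0  # deg around the band edge; 3 narrow, 6 wide

    @property
    def phases(self) -> np.ndarray:
        return np.linspace(-180.0, 180.0, self.n_phases)

    @property
    def orientations(self) -> np.ndarray:
        return np.linspace(-90.0, 90.0, self.n_orientations)


REDUCED_GRID = dict(n_phases=41, n_orientations=21)


@dataclass(frozen=True)
class ScheduleSpec:
    """Step-size schedule and run length of the orientation training."""

    lambda0: float = 3e-4
    decay_scale: float = 2e5  # presentations until the step size halves
    momentum: float = 0.99
    cycles: int = 10000
    init_sd: float = 0.001
    check_every: int = 50  # cycles between full-grid convergence checks


def build_grid(spec: GridSpec) -> list[dict]:
    """All (phase, orientation) stimuli with labels and margin activity.

    label = 1 iff |psi| <= target_halfwidth; the margin is dropped within
    exclusion_halfwidth of the band edges so near-boundary stimuli only
    need the bare fire/no-fire behaviour.
    """
    out = []
    hw, ex = spec.target_halfwidth, spec.exclusion_halfwidth
    for psi in spec.orientations:
        label = int(abs(psi) <= hw)
        margin_active = not (abs(abs(psi) - hw) <= ex)
        for phi in spec.phases:
            out.append(
                {
                    "phase": float(phi),
                    "orientation": float(psi),
                    "label": label,
                    "margin_active": margin_active,
                }
            )
    return out


def _grid_arrays(
    population: list[SyntheticRGC], grid: list[dict], margin: float
):
    """Precompute sorted latency matrices for the compiled training loop."""
    lat = orientation_latency_matrix(
        population,
        [s["phase"] for s in grid],
        [s["orientation"] for s in grid],
    )
    order = np.argsort(lat, axis=1, kind="stable").astype(np.int64)
    times = np.take_along_axis(lat, order, axis=1)
    labels = np.array([s["label"] for s in grid], dtype=np.int64)
    margins = np.array([margin if s["margin_active"] else 0.0 for s in grid])
    return times, order, labels, margins


@dataclass
class OrientationResult:
    weights: np.ndarray
    converged: bool
    cycles_run: int
    final_grid_errors: int
    kernel: PSPKernel = field(default_factory=PSPKernel)
    threshold: float = 1.0


def train_orientation(
    population: list[SyntheticRGC],
    grid_spec: GridSpec,
    schedule: ScheduleSpec = ScheduleSpec(),
    kernel: PSPKernel | None = None,
    threshold: float = 1.0,
    seed: int = 0,
) -> OrientationResult:
    """Train one tempotron to fire inside the orientation band at every
    phase; converged means zero margin-free error on the full grid."""
    kernel = kernel or PSPKernel()
    grid = build_grid(grid_spec)
    times, order, labels, margins = _grid_arrays(population, grid, grid_spec.margin)
    horizon = float(times.max() + 5.0 * kernel.tau_m)
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, schedule.init_sd, len(population))
    presentation_order = rng.permutation(len(grid))
    converged, cycles_run, n_err = train_margin_schedule(
        times,
        order,
        labels,
        margins,
        w,
        threshold,
        kernel.tau_m,
        kernel.tau_s,
        kernel.v0,
        horizon,
        schedule.lambda0,
        schedule.decay_scale,
        schedule.momentum,
        schedule.cycles,
        schedule.check_every,
        presentation_order,
    )
    return OrientationResult(w, bool(converged), int(cycles_run), int(n_err), kernel, threshold)


def convergence_runs(
    population_seed: int,
    grid_spec: GridSpec,
    schedule: ScheduleSpec = ScheduleSpec(),
    n_runs: int = 20,
    n_cells: int = 200,
    seed: int = 0,
) -> list[OrientationResult]:
    """Independent training runs (fresh population and initialization each)
    for convergence-rate statistics."""
    results = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_runs):
        s = int(child.generate_state(2)[0] % 2**31)
        pop = sample_orientation_population(n_cells=n_cells, seed=s + population_seed)
        results.append(
            train_orientation(pop, grid_spec, schedule, seed=s)
        )
    return results


def _vmax_for_stimulus(
    population, result: OrientationResult, phase: float, orientation: float
) -> tuple[float, float]:
    lat = orientation_latencies(population, phase, orientation)
    idx = np.argsort(lat, kind="stable")
    horizon = float(lat.max() + 5.0 * result.kernel.tau_m)
    return vmax_single_spike(
        lat[idx],
        idx.astype(np.int64),
        result.weights,
        result.kernel.tau_m,
        result.kernel.tau_s,
        result.kernel.v0,
        horizon,
    )


def tuning_curves(
    population: list[SyntheticRGC],
    result: OrientationResult,
    grid_spec: GridSpec,
    probe_phases=(-90.0, 0.0, 90.0, 180.0),
) -> dict[float, np.ndarray]:
    """Max-voltage vs orientation, one noiseless curve per probe phase."""
    curves = {}
    for phi in probe_phases:
        curves[float(phi)] = np.array(
            [
                _vmax_for_stimulus(population, result, phi, psi)[0]
                for psi in grid_spec.orientations
            ]
        )
    return curves


def latency_map(
    population: list[SyntheticRGC],
    result: OrientationResult,
    grid_spec: GridSpec,
) -> np.ndarray:
    """Output spike time per (orientation, phase), relative to the grid-wide
    minimum; NaN where the model stays silent.

    The first threshold crossing is located by bisection inside the
    interval in which the voltage first reaches threshold.
    """
    from .spikeio import SpikeTrain, TrialPattern
    from .tempotron import TempotronModel, classify

    model = TempotronModel(result.weights, result.threshold, result.kernel)
    out = np.full((grid_spec.n_orientations, grid_spec.n_phases), np.nan)
    for i, psi in enumerate(grid_spec.orientations):
        for j, phi in enumerate(grid_spec.phases):
            lat = orientation_latencies(population, phi, psi)
            pattern = TrialPattern(
                trial_id=0,
                trains=tuple(SpikeTrain(k, (float(t),)) for k, t in enumerate(lat)),
            )
            fired, t_spike = classify(pattern, model)
            if fired:
                out[i, j] = t_spike
    if np.any(np.isfinite(out)):
        out -= np.nanmin(out)
    return out
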