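"""Tempotron: an integrate-and-fire neuron used as a binary classifier of
spike patterns.

The membrane voltage is a weighted sum of stereotyped postsynaptic
potentials (PSPs), one per input spike:

    V(t) = sum_i w_i sum_j R_ij K(t - t_ij),

with the double-exponential kernel

    K(t) = V0 (exp(-t/tau_m) - exp(-t/tau_s)),   t > 0,

normalized so its peak equals 1.  The neuron classifies a pattern by firing
(V reaches the threshold theta) or staying silent.  R_ij are short-term
depression factors (all 1 for static synapses).

Learning is error-driven: after a miss on a target pattern every efficacy is
incremented by lambda * sum_{t_ij < t_vmax} R_ij K(t_vmax - t_ij), where
t_vmax is the time of the voltage maximum; after a false alarm on a null
pattern the same amount is subtracted.  A momentum term accelerates
convergence.

Voltage maxima are found exactly, not on a grid: between consecutive input
spikes V(t) is A exp(-t/tau_m) - B exp(-t/tau_s), whose interior extremum
has a closed form, so the global peak is the best over per-interval
candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spikeio import Dataset, SpikeTrain, TrialPattern


@dataclass(frozen=True)
class PSPKernel:
    """Double-exponential PSP shape, unit peak amplitude.

    tau_m is the membrane integration constant, tau_s the synaptic current
    decay; tau_s = tau_m / 4 keeps a fixed, biologically realistic PSP shape
    as tau_m varies.
    """

    tau_m: float = 10.0
    tau_s: float = 2.5

    def __post_init__(self) -> None:
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("need tau_m > tau_s > 0")

    @property
    def t_peak(self) -> float:
        """Time to peak of the kernel (closed form)."""
        tm, ts = self.tau_m, self.tau_s
        return tm * ts / (tm - ts) * math.log(tm / ts)

    @property
    def v0(self) -> float:
        """Normalization making max_t K(t) = 1."""
        tm, ts = self.tau_m, self.tau_s
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / tm) - math.exp(-tp / ts))

    def __call__(self, t):
        return psp_kernel(t, self)


def psp_kernel(t, kernel: PSPKernel):
    """Evaluate K(t); zero for t <= 0 (causality).  Accepts scalars or arrays."""
    t = np.asarray(t, dtype=float)
    out = kernel.v0 * (np.exp(-t / kernel.tau_m) - np.exp(-t / kernel.tau_s))
    out = np.where(t > 0, out, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DepressionParams:
    """Short-term depression: each spike uses a fraction U of synaptic
    resources, which recover exponentially with time constant tau_d (ms)."""

    U: float
    tau_d: float

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")


def depression_factors(train: SpikeTrain | tuple, U: float, tau_d: float) -> np.ndarray:
    """Per-spike resource factors R_j in [0, 1]; R_1 = 1.

    Between spikes the resource relaxes toward 1:
        R_{j+1} = 1 - (1 - (1 - U) R_j) * exp(-ISI / tau_d)
    """
    params = DepressionParams(U, tau_d)
    times = train.times if isinstance(train, SpikeTrain) else tuple(train)
    if any(times[i] >= times[i + 1] for i in range(len(times) - 1)):
        raise ValueError("spike train must be strictly increasing")
    R = np.empty(len(times))
    r = 1.0
    for j, _ in enumerate(times):
        if j > 0:
            isi = times[j] - times[j - 1]
            r = 1.0 - (1.0 - (1.0 - params.U) * r) * math.exp(-isi / params.tau_d)
        R[j] = r
    return R


@dataclass
class TempotronModel:
    """Synaptic efficacies, threshold and PSP kernel of one readout neuron."""

    weights: np.ndarray
    threshold: float = 1.0
    kernel: PSPKernel = field(default_factory=PSPKernel)
    depression: DepressionParams | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def copy(self) -> "TempotronModel":
        return TempotronModel(
            self.weights.copy(), self.threshold, self.kernel, self.depression
        )


def _effective_spikes(pattern: TrialPattern, model: TempotronModel):
    """Flattened (time, effective weight) pairs sorted by time.

    The effective weight of spike j of afferent i is w_i * R_ij * V0, so the
    voltage between events is a plain two-exponential.
    """
    k = model.kernel
    events = []
    for i, train in enumerate(pattern.trains):
        if not train.times:
            continue
        if model.depression is not None:
            R = depression_factors(train, model.depression.U, model.depression.tau_d)
        else:
            R = np.ones(len(train.times))
        w = model.weights[i] * k.v0
        events.extend((t, w * r) for t, r in zip(train.times, R))
    events.sort(key=lambda e: e[0])
    return events


def _scan_voltage(events, kernel: PSPKernel, horizon: float):
    """Event-driven sweep; returns (v_max, t_vmax) of V over (0, horizon].

    A and B carry the two exponential amplitudes re-anchored at each event
    time for numerical stability.
    """
    tm, ts = kernel.tau_m, kernel.tau_s
    c = tm * ts / (tm - ts)
    A = B = 0.0
    v_max, t_max = 0.0, None
    prev_t = None
    for idx, (t, w) in enumerate(events):
        if prev_t is not None:
            dt = t - prev_t
            A *= math.exp(-dt / tm)
            B *= math.exp(-dt / ts)
        A += w
        B += w
        prev_t = t
        length = (events[idx + 1][0] - t) if idx + 1 < len(events) else horizon - t
        if length <= 0:
            continue
        # candidates inside (0, length]: interior extremum and the right edge
        # (the left edge equals the previous interval's right edge; V(t_event)
        # itself is A - B, continuous across the event)
        v_here = A - B
        if v_here > v_max:
            v_max, t_max = v_here, t
        ratio = (B * tm) / (A * ts) if A != 0 else -1.0
        if ratio > 0:
            s_star = c * math.log(ratio)
            if 0 < s_star < length:
                v = A * math.exp(-s_star / tm) - B * math.exp(-s_star / ts)
                if v > v_max:
                    v_max, t_max = v, t + s_star
        v_end = A * math.exp(-length / tm) - B * math.exp(-length / ts)
        if v_end > v_max:
            v_max, t_max = v_end, t + length
    return v_max, t_max


def voltage_trace(pattern: TrialPattern, model: TempotronModel, t_grid) -> np.ndarray:
    """V(t) sampled on an arbitrary time grid (for plots and oracle checks)."""
    t_grid = np.asarray(t_grid, dtype=float)
    v = np.zeros_like(t_grid)
    for t_s, w in _effective_spikes(pattern, model):
        dt = t_grid - t_s
        mask = dt > 0
        v[mask] += w * (
            np.exp(-dt[mask] / model.kernel.tau_m) - np.exp(-dt[mask] / model.kernel.tau_s)
        )
    return v


def peak_voltage(
    pattern: TrialPattern, model: TempotronModel, horizon: float | None = None
) -> tuple[float, float | None]:
    """Global maximum of the voltage and its time.

    Exact (closed-form per inter-spike interval), no time discretization.
    An all-empty pattern gives (0.0, None).
    """
    if len(model.weights) != pattern.n_afferents:
        raise ValueError("weight count does not match afferent count")
    events = _effective_spikes(pattern, model)
    if not events:
        return 0.0, None
    if horizon is None:
        horizon = events[-1][0] + 5.0 * model.kernel.tau_m
    return _scan_voltage(events, model.kernel, horizon)


def classify(
    pattern: TrialPattern, model: TempotronModel
) -> tuple[bool, float | None]:
    """Fire/no-fire decision and the first threshold-crossing time.

    Fires iff v_max >= theta; the output spike time is the earliest t with
    V(t) = theta, located by bisection inside the interval that first
    reaches threshold.
    """
    v_max, t_vmax = peak_voltage(pattern, model)
    theta = model.threshold
    if v_max < theta or t_vmax is None:
        return False, None
    events = _effective_spikes(pattern, model)
    tm, ts = model.kernel.tau_m, model.kernel.tau_s
    c = tm * ts / (tm - ts)
    A = B = 0.0
    prev_t = None
    horizon = t_vmax + 1e-12
    for idx, (t, w) in enumerate(events):
        if prev_t is not None:
            dt = t - prev_t
            A *= math.exp(-dt / tm)
            B *= math.exp(-dt / ts)
        A += w
        B += w
        prev_t = t
        end = events[idx + 1][0] if idx + 1 < len(events) else horizon
        end = min(end, horizon)
        length = end - t
        if length <= 0:
            continue

        def V(s, A=A, B=B):
            return A * math.exp(-s / tm) - B * math.exp(-s / ts)

        # interval maximum in closed form: candidates are the interior
        # extremum (if any) and the right edge
        s_at_max, v_best = length, V(length)
        ratio = (B * tm) / (A * ts) if A != 0 else -1.0
        if ratio > 0:
            s_star = c * math.log(ratio)
            if 0 < s_star < length and V(s_star) > v_best:
                s_at_max, v_best = s_star, V(s_star)
        if v_best >= theta:
            # V at interval start is < theta (no earlier interval crossed),
            # V is monotone up to its unique interior extremum: bisect
            lo, hi = 0.0, s_at_max
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if V(mid) >= theta:
                    hi = mid
                else:
                    lo = mid
            return True, t + hi
    return True, t_vmax  # crossing only at the peak itself


@dataclass
class LearnState:
    """Learning-rule state: step size lambda, momentum mu and the running
    per-weight velocity."""

    step_size: float
    momentum: float = 0.9
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


def _gradient(pattern: TrialPattern, model: TempotronModel, t_vmax: float) -> np.ndarray:
    """d v_max / d w_i = sum_{t_ij < t_vmax} R_ij K(t_vmax - t_ij)."""
    k = model.kernel
    grad = np.zeros(len(model.weights))
    for i, train in enumerate(pattern.trains):
        if not train.times:
            continue
        if model.depression is not None:
            R = depression_factors(train, model.depression.U, model.depression.tau_d)
        else:
            R = np.ones(len(train.times))
        for t, r in zip(train.times, R):
            if t < t_vmax:
                grad[i] += r * psp_kernel(t_vmax - t, k)
    return grad


def learn_step(
    pattern: TrialPattern,
    label: int,
    model: TempotronModel,
    state: LearnState,
    margin: float = 0.0,
) -> bool:
    """One error-driven update, in place.  Returns True if the trial was an
    error (under the optional multiplicative training margin).

    Target patterns must reach theta*(1+margin), null patterns must stay
    below theta*(1-margin); at margin 0 this is the plain fire/no-fire rule.
    """
    if state.velocity is None:
        state.velocity = np.zeros(len(model.weights))
    v_max, t_vmax = peak_voltage(pattern, model)
    theta = model.threshold
    if label:
        err = v_max < theta * (1.0 + margin)
        sign = +1.0
    else:
        err = v_max > theta * (1.0 - margin)
        sign = -1.0
    if not err:
        return False
    if t_vmax is None:
        return True  # target pattern without spikes: no defined update
    delta = sign * state.step_size * _gradient(pattern, model, t_vmax)
    state.velocity = state.momentum * state.velocity + delta
    model.weights = model.weights + state.velocity
    return True


def smooth_error_curve(errors: np.ndarray, window: int = 50) -> np.ndarray:
    """Centered moving average over learning cycles (shorter windows at the
    edges)."""
    errors = np.asarray(errors, dtype=float)
    n = len(errors)
    half = window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(errors)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + window - half)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


@dataclass
class TrainResult:
    model: TempotronModel
    error_curve: np.ndarray
    smoothed: np.ndarray
    best_cycle: int

    @property
    def best_error(self) -> float:
        return float(self.smoothed[self.best_cycle])


def train(
    dataset: Dataset,
    labels,
    step_size: float = 3e-3,
    momentum: float = 0.9,
    cycles: int = 2000,
    init_sd: float = 0.05,
    seed: int = 0,
    smooth_window: int = 50,
    kernel: PSPKernel | None = None,
    depression: DepressionParams | None = None,
    margin: float = 0.0,
    threshold: float = 1.0,
) -> TrainResult:
    """Train a tempotron on labelled trials.

    Trials are cycled in a seeded random order, fixed across cycles.  The
    per-cycle misclassification fraction is smoothed by a centered moving
    average and the returned model is the snapshot at the minimum of the
    smoothed curve (earliest cycle on ties).
    """
    labels = np.asarray(labels, dtype=int)
    if cycles < 1:
        raise ValueError("need at least one training cycle")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one target and one null trial")
    rng = np.random.default_rng(seed)
    n_aff = dataset.n_afferents
    model = TempotronModel(
        rng.normal(0.0, init_sd, n_aff),
        threshold=threshold,
        kernel=kernel or PSPKernel(),
        depression=depression,
    )
    state = LearnState(step_size, momentum, np.zeros(n_aff))
    order = rng.permutation(len(dataset.trials))
    errors = np.empty(cycles)
    snapshots = np.empty((cycles, n_aff))
    for c in range(cycles):
        n_err = 0
        for idx in order:
            n_err += learn_step(
                dataset.trials[idx], labels[idx], model, state, margin=margin
            )
        errors[c] = n_err / len(order)
        snapshots[c] = model.weights
    smoothed = smooth_error_curve(errors, smooth_window)
    best_cycle = int(np.argmin(smoothed))
    best = TempotronModel(
        snapshots[best_cycle].copy(), threshold, model.kernel, depression
    )
    return TrainResult(best, errors, smoothed, best_cycle)


def evaluate(
    dataset: Dataset, labels, model: TempotronModel, margin: float = 0.0
) -> float:
    """Fraction of trials misclassified by a fixed model."""
    labels = np.asarray(labels, dtype=int)
    theta = model.threshold
    n_err = 0
    for trial, y in zip(dataset.trials, labels):
        v_max, _ = peak_voltage(trial, model)
        if y:
            n_err += v_max < theta * (1.0 + margin)
        else:
            n_err += v_max > theta * (1.0 - margin)
    return n_err / len(labels)
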