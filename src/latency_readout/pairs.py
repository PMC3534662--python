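"""Analytic treatment of the tempotron with two afferents.

With exactly one spike per afferent, the only stimulus variable the neuron
sees is the relative latency dt = t2 - t1.  The peak voltage V_max(dt) it
produces has a closed form, is non-monotonic, and spans

    V_max(0)         = w1 + w2        (synchronous spikes),
    V_max(|dt|->inf) = max(w1, w2)    (isolated PSPs).

With a threshold between these two values the neuron dissects the dt axis
into three parts: two positive weights (++) make it fire inside an interval
[dt-, dt+] around synchrony; one excitatory and one inhibitory weight make
it fire outside such an interval.  The module solves the forward problem
(boundaries from weights), the inverse problem (weights realizing requested
boundaries), and builds on both for threshold-noise robustness and
readout-time analyses of ganglion-cell pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .spikeio import Dataset, restrict_spikes
from .tempotron import PSPKernel


def vmax_of_dt(dt, w1: float, w2: float, kernel: PSPKernel | None = None):
    """Peak voltage of w1 K(t) + w2 K(t - dt); dt may be an array.

    Closed form: on [0, |dt|] only the first PSP is active (its interior
    maximum is the normalized peak), on [|dt|, inf) the voltage is a plain
    two-exponential whose extremum is analytic.
    """
    kernel = kernel or PSPKernel()
    dt = np.asarray(dt, dtype=float)
    scalar = dt.ndim == 0
    dt = np.atleast_1d(dt)
    # vmax(dt, w1, w2) = vmax(-dt, w2, w1): reorder so the first spike leads
    wa = np.where(dt >= 0, w1, w2)
    wb = np.where(dt >= 0, w2, w1)
    d = np.abs(dt)
    tm, ts, v0 = kernel.tau_m, kernel.tau_s, kernel.v0
    tp = kernel.t_peak
    c = tm * ts / (tm - ts)

    out = np.full(d.shape, -np.inf)
    # candidate 1: isolated peak of the leading PSP (needs room before the
    # second spike and a positive weight)
    cand1 = np.where((wa > 0) & (tp <= d), wa, -np.inf)
    # interval beyond the second spike: V(s) = A exp(-s/tm) - B exp(-s/ts)
    A = v0 * (wa * np.exp(-d / tm) + wb)
    B = v0 * (wa * np.exp(-d / ts) + wb)
    # candidate 2: value at the second spike time
    cand2 = A - B
    # candidate 3: interior extremum of the final interval
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (B * tm) / (A * ts)
        s_star = c * np.log(ratio)
        valid = (ratio > 0) & (s_star > 0)
        cand3 = np.where(
            valid,
            A * np.exp(-np.clip(s_star, 0, None) / tm)
            - B * np.exp(-np.clip(s_star, 0, None) / ts),
            -np.inf,
        )
    out = np.maximum(np.maximum(cand1, cand2), cand3)
    out = np.maximum(out, 0.0)  # V -> 0 at large t
    return float(out[0]) if scalar else out


def solve_dt_boundaries(
    w1: float,
    w2: float,
    theta: float = 1.0,
    kernel: PSPKernel | None = None,
    dt_span: float = None,
) -> tuple[float, float] | None:
    """The two relative-latency roots of V_max(dt) = theta, one per firing
    order; None when the threshold is outside the attainable range.

    Roots are bracketed on each side of synchrony and refined to 1e-6 ms.
    """
    kernel = kernel or PSPKernel()
    if dt_span is None:
        dt_span = 50.0 * kernel.tau_m

    def g(dt):
        return vmax_of_dt(dt, w1, w2, kernel) - theta

    roots = []
    for side in (-1.0, 1.0):
        a, b = 0.0, side * dt_span
        ga, gb = g(a), g(b)
        if ga == 0.0:
            roots.append(0.0)
            continue
        if ga * gb > 0:
            return None  # no crossing on this side: theta unattainable
        lo, hi = (b, a) if side < 0 else (a, b)
        roots.append(brentq(g, lo, hi, xtol=1e-6))
    dt_minus, dt_plus = sorted(roots)
    return dt_minus, dt_plus


@dataclass(frozen=True)
class PairSolution:
    dt_minus: float
    dt_plus: float
    w1: float
    w2: float
    regime: str  # "++" fires inside [dt-, dt+]; "+-"/"-+" fire outside

    @property
    def weight_ratio(self) -> float:
        return self.w2 / self.w1


def weights_for_boundaries(
    dt_minus: float,
    dt_plus: float,
    theta: float = 1.0,
    kernel: PSPKernel | None = None,
    n_ratio: int = 2001,
) -> PairSolution:
    """Synaptic weights placing the decision boundaries at the requested
    relative latencies.

    Because V_max is linear under a common scaling of both weights, the 2-D
    system V_max(dt-) = V_max(dt+) = theta collapses to a 1-D root search in
    the weight ratio rho = w2/w1: find rho with V_max(dt-; 1, rho) =
    V_max(dt+; 1, rho), then scale both weights to put the level at theta.
    """
    kernel = kernel or PSPKernel()
    if not dt_minus < dt_plus:
        raise ValueError("need dt_minus < dt_plus")

    # one-parameter weight families (overall scale handled separately):
    # both excitatory, inhibitory second afferent, inhibitory first afferent
    families = [
        lambda r: (1.0, r),
        lambda r: (1.0, -r),
        lambda r: (-r, 1.0),
    ]
    grids = [
        np.geomspace(1e-3, 1e3, n_ratio),
        np.geomspace(1e-3, 1.0, n_ratio, endpoint=False),
        np.geomspace(1e-3, 1.0, n_ratio, endpoint=False),
    ]
    for family, grid in zip(families, grids):

        def residual(r, family=family):
            wa, wb = family(r)
            return vmax_of_dt(dt_plus, wa, wb, kernel) - vmax_of_dt(
                dt_minus, wa, wb, kernel
            )

        vals = np.array([residual(r) for r in grid])
        sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        exact = np.flatnonzero(vals == 0.0)
        r_root = None
        if exact.size:
            r_root = float(grid[exact[0]])
        elif sign_change.size:
            i = sign_change[0]
            r_root = brentq(residual, grid[i], grid[i + 1], xtol=1e-12)
        if r_root is None:
            continue
        wa, wb = family(r_root)
        level = vmax_of_dt(dt_plus, wa, wb, kernel)
        if level <= 0:
            continue
        scale = theta / level
        w1, w2 = scale * wa, scale * wb
        # verify the requested boundaries really delimit the firing set
        sol = solve_dt_boundaries(w1, w2, theta, kernel)
        if sol is None:
            continue
        if abs(sol[0] - dt_minus) > 1e-3 or abs(sol[1] - dt_plus) > 1e-3:
            continue
        if w1 > 0 and w2 > 0:
            regime = "++"
        elif w1 > 0:
            regime = "+-"
        else:
            regime = "-+"
        return PairSolution(dt_minus, dt_plus, float(w1), float(w2), regime)
    raise ValueError(
        "no weight pair realizes these boundaries with the current kernel; "
        "a shorter or longer PSP time course (tau_m) may make them feasible"
    )


@dataclass(frozen=True)
class NoiseModel:
    """Per-stimulus Gaussian model of the relative latency dt, plus Gaussian
    threshold noise expressed as a fraction of the mean weight magnitude."""

    stimuli: tuple  # ((mean_dt, sd_dt, label), ...) with label 1=target
    threshold_noise_frac: float = 0.05

    def __post_init__(self) -> None:
        for _, sd, _ in self.stimuli:
            if sd <= 0:
                raise ValueError("latency sd must be positive")


def threshold_noise_error(
    noise: NoiseModel,
    w1: float,
    w2: float,
    theta: float = 1.0,
    kernel: PSPKernel | None = None,
    n_quad: int = 401,
) -> float:
    """Expected misclassification under Gaussian threshold noise.

    error = mean over stimuli of  E_dt[ P(wrong | V_max(dt)) ],  where the
    firing probability is Phi((V_max - theta)/sigma_theta) and sigma_theta
    = threshold_noise_frac * mean(|w1|, |w2|).  Gauss quadrature over
    +/- 5 sd of each stimulus Gaussian.
    """
    kernel = kernel or PSPKernel()
    sigma_theta = noise.threshold_noise_frac * 0.5 * (abs(w1) + abs(w2))
    errs = []
    for mean_dt, sd_dt, label in noise.stimuli:
        grid = np.linspace(mean_dt - 5 * sd_dt, mean_dt + 5 * sd_dt, n_quad)
        pdf = norm.pdf(grid, mean_dt, sd_dt)
        vmax = vmax_of_dt(grid, w1, w2, kernel)
        if sigma_theta > 0:
            p_fire = norm.cdf((vmax - theta) / sigma_theta)
        else:
            p_fire = (vmax >= theta).astype(float)
        p_wrong = 1.0 - p_fire if label else p_fire
        if not np.all(np.isfinite(p_wrong)):
            raise ValueError("non-finite integrand")
        errs.append(np.trapezoid(pdf * p_wrong, grid))
    return float(np.mean(errs))


def optimize_pair(
    noise: NoiseModel,
    theta: float = 1.0,
    tau_grid=None,
    weight_grid=None,
    constraint: str | None = None,
    n_quad: int = 201,
) -> list[dict]:
    """Exhaustive weight search minimizing the threshold-noise error, for
    each membrane time constant (tau_s = tau_m / 4 throughout).

    ``constraint`` restricts the search to purely excitatory solutions
    ("++") or mixed-sign ones ("+-"); None searches everything.  Returns one
    record per tau with the best weights and error (the error-vs-tau curve).
    """
    if tau_grid is None:
        tau_grid = np.geomspace(1.0, 100.0, 13)
    if weight_grid is None:
        weight_grid = np.linspace(-3.0 * theta, 3.0 * theta, 201)
    weight_grid = np.asarray(weight_grid, dtype=float)
    W1, W2 = np.meshgrid(weight_grid, weight_grid, indexing="ij")
    w1f, w2f = W1.ravel(), W2.ravel()
    ok = (w1f + w2f > 0) & (np.maximum(w1f, w2f) > 0)
    if constraint == "++":
        ok &= (w1f > 0) & (w2f > 0)
    elif constraint == "+-":
        ok &= (w1f * w2f) < 0
    w1f, w2f = w1f[ok], w2f[ok]

    results = []
    for tau in tau_grid:
        kernel = PSPKernel(tau_m=float(tau), tau_s=float(tau) / 4.0)
        sigma_theta = noise.threshold_noise_frac * 0.5 * (np.abs(w1f) + np.abs(w2f))
        total = np.zeros(len(w1f))
        for mean_dt, sd_dt, label in noise.stimuli:
            grid = np.linspace(mean_dt - 5 * sd_dt, mean_dt + 5 * sd_dt, n_quad)
            pdf = norm.pdf(grid, mean_dt, sd_dt)
            # chunk over weight combinations to bound memory
            chunk = 20000
            for lo in range(0, len(w1f), chunk):
                hi = min(lo + chunk, len(w1f))
                vmax = vmax_of_dt(
                    grid[None, :], w1f[lo:hi, None], w2f[lo:hi, None], kernel
                )
                st = sigma_theta[lo:hi, None]
                with np.errstate(divide="ignore", invalid="ignore"):
                    p_fire = np.where(
                        st > 0, norm.cdf((vmax - theta) / np.where(st > 0, st, 1.0)),
                        (vmax >= theta).astype(float),
                    )
                p_wrong = 1.0 - p_fire if label else p_fire
                total[lo:hi] += np.trapezoid(pdf[None, :] * p_wrong, grid, axis=1)
        total /= len(noise.stimuli)
        best = int(np.argmin(total))
        results.append(
            {
                "tau_m": float(tau),
                "w1": float(w1f[best]),
                "w2": float(w2f[best]),
                "error": float(total[best]),
            }
        )
    return results


# ------------------------------------------------- empirical pair analyses


def _pair_trial_features(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dt, fired_1, fired_2) per trial for a 2-afferent first-spike dataset;
    dt is NaN unless both cells fired."""
    if dataset.n_afferents != 2:
        raise ValueError("pair analyses need exactly 2 afferents")
    t1, t2, dts = [], [], []
    for trial in dataset.trials:
        a, b = trial.trains
        t1.append(a.first)
        t2.append(b.first)
        if a.first is not None and b.first is not None:
            dts.append(b.first - a.first)
        else:
            dts.append(np.nan)
    fired1 = np.array([t is not None for t in t1])
    fired2 = np.array([t is not None for t in t2])
    return np.asarray(dts, dtype=float), fired1, fired2


def pair_error_on_trials(
    dataset: Dataset,
    labels,
    weight_grid,
    theta: float = 1.0,
    kernel: PSPKernel | None = None,
) -> dict:
    """Exhaustive (w1, w2) search minimizing the trial misclassification
    count on a first-spike-restricted 2-cell dataset.

    All trials count, including spike failures: a trial with one silent cell
    sees a single PSP (fires iff that weight >= theta), a fully silent trial
    never fires.
    """
    kernel = kernel or PSPKernel()
    labels = np.asarray(labels, dtype=int)
    dts, fired1, fired2 = _pair_trial_features(dataset)
    weight_grid = np.asarray(weight_grid, dtype=float)
    W1, W2 = np.meshgrid(weight_grid, weight_grid, indexing="ij")
    w1f, w2f = W1.ravel(), W2.ravel()

    both = fired1 & fired2
    only1 = fired1 & ~fired2
    only2 = fired2 & ~fired1
    silent = ~fired1 & ~fired2

    n_err = np.zeros(len(w1f))
    if both.any():
        vmax = vmax_of_dt(dts[both][None, :], w1f[:, None], w2f[:, None], kernel)
        fired = vmax >= theta
        n_err += np.sum(fired != labels[both][None, :].astype(bool), axis=1)
    for mask, w in ((only1, w1f), (only2, w2f)):
        if mask.any():
            fired = w[:, None] >= theta  # single PSP peaks at the weight
            n_err += np.sum(fired != labels[mask][None, :].astype(bool), axis=1)
    if silent.any():
        n_err += np.sum(labels[silent] == 1)  # silent trials never fire
    err = n_err / len(labels)
    best = int(np.argmin(err))
    return {
        "w1": float(w1f[best]),
        "w2": float(w2f[best]),
        "error": float(err[best]),
        "fraction_correct": 1.0 - float(err[best]),
    }


def readout_time_sweep(
    dataset: Dataset,
    labels,
    t_max_grid,
    weight_grid=None,
    theta: float = 1.0,
    kernel: PSPKernel | None = None,
) -> list[dict]:
    """Fraction correct of the optimal pair tempotron when only first spikes
    earlier than t_max are admitted, with weights re-optimized per t_max."""
    t_max_grid = list(t_max_grid)
    if not t_max_grid:
        raise ValueError("t_max grid must be non-empty")
    if weight_grid is None:
        weight_grid = np.linspace(-3.0 * theta, 3.0 * theta, 61)
    first = restrict_spikes(dataset, k_max=1)
    out = []
    for t_max in t_max_grid:
        cut = restrict_spikes(first, t_max=float(t_max))
        res = pair_error_on_trials(cut, labels, weight_grid, theta, kernel)
        out.append({"t_max": float(t_max), **res})
    return out
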