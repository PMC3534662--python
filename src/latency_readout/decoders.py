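"""Benchmark readouts to compare against the tempotron.

Three classic decoders of population activity:

* a spike-count perceptron — thresholds a weighted sum of per-afferent
  spike counts inside a fixed window, trained by the standard perceptron
  rule; blind to spike timing;
* a temporal winner-take-all (TWTA) — each afferent carries a binary class
  label and the earliest spike (or a majority over the k earliest) decides;
* a rank-order decoder — an integrate-and-fire unit whose potential is
  sum_i w_i m^{r_i}, with r_i the rank of afferent i's spike latency and
  m < 1 a per-spike desensitization factor; sensitive to the firing order
  but not to the actual latencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .spikeio import Dataset, TrialPattern
from .tempotron import smooth_error_curve


# ---------------------------------------------------------------- perceptron


@dataclass
class PerceptronModel:
    weights: np.ndarray
    bias: float
    count_window: float = 150.0


def spike_counts(pattern: TrialPattern, window: float) -> np.ndarray:
    """Per-afferent spike counts within [0, window] ms."""
    if window <= 0:
        raise ValueError("count window must be positive")
    return np.array(
        [sum(t <= window for t in tr.times) for tr in pattern.trains], dtype=float
    )


def perceptron_decide(pattern: TrialPattern, model: PerceptronModel) -> int:
    x = spike_counts(pattern, model.count_window)
    return int(x @ model.weights + model.bias >= 0)


def perceptron_fit(
    dataset: Dataset,
    labels,
    count_window: float = 150.0,
    step_size: float = 0.1,
    cycles: int = 2000,
    init_sd: float = 0.05,
    seed: int = 0,
    smooth_window: int = 50,
):
    """Perceptron on count vectors with the same training protocol as the
    tempotron: seeded fixed order, 50-cycle smoothing, best-snapshot model.

    Returns (PerceptronModel, error_curve, smoothed_curve).
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    counts = np.array([spike_counts(t, count_window) for t in dataset.trials])
    n_aff = counts.shape[1]
    w = rng.normal(0.0, init_sd, n_aff)
    b = 0.0
    order = rng.permutation(len(labels))
    errors = np.empty(cycles)
    snaps = np.empty((cycles, n_aff + 1))
    for c in range(cycles):
        n_err = 0
        for idx in order:
            pred = int(counts[idx] @ w + b >= 0)
            if pred != labels[idx]:
                n_err += 1
                sgn = 1.0 if labels[idx] else -1.0
                w = w + step_size * sgn * counts[idx]
                b = b + step_size * sgn
        errors[c] = n_err / len(order)
        snaps[c] = np.concatenate([w, [b]])
    smoothed = smooth_error_curve(errors, smooth_window)
    best = int(np.argmin(smoothed))
    model = PerceptronModel(snaps[best, :-1].copy(), float(snaps[best, -1]), count_window)
    return model, errors, smoothed


def perceptron_error(dataset: Dataset, labels, model: PerceptronModel) -> float:
    labels = np.asarray(labels, dtype=int)
    wrong = sum(
        perceptron_decide(t, model) != y for t, y in zip(dataset.trials, labels)
    )
    return wrong / len(labels)


# ------------------------------------------------------- winner-take-all


@dataclass
class TwtaModel:
    """Per-afferent binary vote; decision by the k earliest spikes (k odd)."""

    labels: tuple[int, ...]
    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")


def twta_decide(pattern: TrialPattern, model: TwtaModel) -> int:
    """Vote of the earliest-firing afferents; spikeless trials vote null (0).

    Latency ties break toward the lower afferent index.
    """
    firing = [
        (tr.times[0], i) for i, tr in enumerate(pattern.trains) if tr.times
    ]
    if not firing:
        return 0
    firing.sort()
    votes = [model.labels[i] for _, i in firing[: model.k]]
    return int(sum(votes) * 2 > len(votes))


def twta_fit(dataset: Dataset, labels, k: int = 1) -> tuple[TwtaModel, float]:
    """Exhaustive search over all 2^N afferent labelings; first-found wins
    ties (lexicographic order over labelings)."""
    labels = np.asarray(labels, dtype=int)
    n = dataset.n_afferents
    if n > 25:
        raise ValueError(
            "exhaustive labeling search is limited to 25 afferents; "
            "restrict the population first"
        )
    best_model, best_err = None, np.inf
    for bits in itertools.product((0, 1), repeat=n):
        model = TwtaModel(bits, k)
        err = (
            sum(twta_decide(t, model) != y for t, y in zip(dataset.trials, labels))
            / len(labels)
        )
        if err < best_err:
            best_model, best_err = model, err
    return best_model, float(best_err)


# ---------------------------------------------------------------- rank order


@dataclass
class RankOrderModel:
    weights: np.ndarray
    attenuation: float  # m in (0, 1]
    threshold: float


def _ranks(pattern: TrialPattern) -> dict[int, int]:
    """Rank (0-based) of each firing afferent by ascending first latency;
    only firing afferents are counted, ties break by afferent index."""
    firing = sorted(
        (tr.times[0], i) for i, tr in enumerate(pattern.trains) if tr.times
    )
    return {i: r for r, (_, i) in enumerate(firing)}


def rank_decode(pattern: TrialPattern, model: RankOrderModel) -> tuple[float, int]:
    """Potential sum_i w_i m^{r_i} over firing afferents, and the threshold
    decision."""
    ranks = _ranks(pattern)
    pot = sum(model.weights[i] * model.attenuation**r for i, r in ranks.items())
    return float(pot), int(pot >= model.threshold)


def _target_average_weights(dataset: Dataset, labels, m: float) -> np.ndarray:
    """Each weight is the afferent's average attenuation factor m^{r_i} over
    the target-condition patterns (the decoder's prescribed weight rule)."""
    labels = np.asarray(labels, dtype=int)
    n = dataset.n_afferents
    acc = np.zeros(n)
    n_target = 0
    for trial, y in zip(dataset.trials, labels):
        if not y:
            continue
        n_target += 1
        for i, r in _ranks(trial).items():
            acc[i] += m**r
    if n_target == 0:
        raise ValueError("no target trials")
    return acc / n_target


def rank_fit(
    dataset: Dataset,
    labels,
    m_grid=None,
    n_threshold_quantiles: int = 100,
) -> tuple[RankOrderModel, float]:
    """Set weights by the target-average rule and grid-search the
    attenuation m and the firing threshold (over quantiles of the training
    potentials)."""
    labels = np.asarray(labels, dtype=int)
    if m_grid is None:
        m_grid = [0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99]
    best, best_err = None, np.inf
    for m in m_grid:
        w = _target_average_weights(dataset, labels, m)
        probe = RankOrderModel(w, m, 0.0)
        pots = np.array([rank_decode(t, probe)[0] for t in dataset.trials])
        qs = np.quantile(pots, np.linspace(0.0, 1.0, n_threshold_quantiles))
        for theta in np.unique(qs):
            pred = (pots >= theta).astype(int)
            err = float(np.mean(pred != labels))
            if err < best_err:
                best, best_err = RankOrderModel(w.copy(), m, float(theta)), err
    return best, float(best_err)


def rank_error(dataset: Dataset, labels, model: RankOrderModel) -> float:
    labels = np.asarray(labels, dtype=int)
    wrong = sum(
        rank_decode(t, model)[1] != y for t, y in zip(dataset.trials, labels)
    )
    return wrong / len(labels)
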