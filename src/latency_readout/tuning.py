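"""Cosine tuning-curve characterization and latency-correlation analyses.

A cell's first-spike latency (and its spike count) as a function of grating
phase phi is summarized by a cosine tuning curve

    f(phi) = b + a cos(phi - phi0),

fitted by least squares on single trials.  The fit is solved exactly by the
linearization b + alpha cos(phi) + beta sin(phi) — the same model class,
but a convex linear problem — with (a, phi0) = (hypot(alpha, beta),
atan2(beta, alpha)).

Two coefficients of determination are reported: r2_single, on the
single-trial responses, and r2_mean, which measures how well the same fit
predicts the per-phase mean responses.  Large trial-to-trial noise pushes
r2_single down even when the cosine model captures the means perfectly.

The correlation analyses quantify shared trial-to-trial latency jitter
across simultaneously recorded cells: Pearson correlations of first-spike
latencies within each stimulus condition, and the trial-shift control that
destroys the shared component by pairing each trial of one cell with the
next trial of the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spikeio import Dataset


@dataclass(frozen=True)
class CosineFit:
    baseline: float  # b (ms or spikes)
    amplitude: float  # a >= 0
    phase_offset_deg: float  # phi0, in [0, 360)
    r2_single: float
    degenerate: bool = False  # all responses identical; phi0 meaningless

    def predict(self, phase_deg):
        phase = np.asarray(phase_deg, dtype=float)
        return self.baseline + self.amplitude * np.cos(
            np.radians(phase - self.phase_offset_deg)
        )


def fit_cosine(responses) -> CosineFit:
    """Least-squares cosine fit to (phase_deg, value) single-trial pairs.

    For latency tuning, spikeless trials must be dropped by the caller.
    r2_single is not clipped at zero: a fit worse than the mean reports a
    negative value.
    """
    responses = [(float(p), float(v)) for p, v in responses]
    phases = np.array([p for p, _ in responses])
    values = np.array([v for _, v in responses])
    if len(np.unique(np.mod(phases, 360.0))) < 3:
        raise ValueError("need responses at >= 3 distinct phases")
    if np.allclose(values, values[0]):
        return CosineFit(float(values[0]), 0.0, 0.0, 1.0, degenerate=True)
    rad = np.radians(phases)
    X = np.column_stack([np.ones_like(rad), np.cos(rad), np.sin(rad)])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    b, alpha, beta = coef
    a = math.hypot(alpha, beta)
    phi0 = math.degrees(math.atan2(beta, alpha)) % 360.0
    resid = values - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return CosineFit(float(b), float(a), float(phi0), float(r2))


def r2_of_means(fit: CosineFit, responses) -> float:
    """Variance in the per-phase mean responses explained by the fit.

    r2_mean = 1 - sum_i (mean_i - fit_i)^2 / sum_i (mean_i - grand_mean)^2
    over the distinct phases i.
    """
    responses = [(float(p), float(v)) for p, v in responses]
    by_phase: dict[float, list[float]] = {}
    for p, v in responses:
        by_phase.setdefault(p % 360.0, []).append(v)
    if len(by_phase) < 2:
        raise ValueError("need >= 2 distinct phases")
    phases = np.array(sorted(by_phase))
    means = np.array([np.mean(by_phase[p]) for p in phases])
    pred = fit.predict(phases)
    ss_res = float(np.sum((means - pred) ** 2))
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def latency_table(dataset: Dataset) -> dict:
    """Per-condition first-spike latencies: {(phase, contrast): array of
    shape (n_trials, n_afferents), NaN where a cell failed}."""
    out: dict = {}
    for trial in dataset.trials:
        key = (trial.phase_index, trial.contrast)
        out.setdefault(key, []).append(trial.first_latencies())
    return {k: np.array(v) for k, v in out.items()}


def latency_correlation(
    cell_a: dict, cell_b: dict, min_trials: int = 3
) -> tuple[dict, float]:
    """Pearson correlation of two cells' first-spike latencies, per stimulus.

    ``cell_a``/``cell_b`` map stimulus key -> per-trial latency array (NaN on
    failure trials).  Trials where either cell failed are dropped; stimuli
    with fewer than ``min_trials`` complete pairs or zero variance are
    skipped.  Returns (per-stimulus r, mean r).
    """
    per_stim = {}
    for key in cell_a:
        if key not in cell_b:
            continue
        x, y = np.asarray(cell_a[key], float), np.asarray(cell_b[key], float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < min_trials or np.std(x) == 0 or np.std(y) == 0:
            continue
        per_stim[key] = float(stats.pearsonr(x, y)[0])
    mean_r = float(np.mean(list(per_stim.values()))) if per_stim else float("nan")
    return per_stim, mean_r


def pair_latency_correlation(
    dataset: Dataset, cell_i: int, cell_j: int, min_trials: int = 3
) -> tuple[dict, float]:
    """Latency correlation of one afferent pair across all stimuli of a
    dataset."""
    table = latency_table(dataset)
    a = {k: v[:, cell_i] for k, v in table.items()}
    b = {k: v[:, cell_j] for k, v in table.items()}
    return latency_correlation(a, b, min_trials)


def shift_trials(latencies_by_stim: dict, by: int = 1) -> dict:
    """Rotate each stimulus condition's trial order by ``by`` trials.

    The control for shared jitter: correlating cell A's trial t with cell
    B's trial t+1 removes the common component while keeping each cell's
    marginal statistics.  Single-trial conditions are left unshifted.
    """
    out = {}
    for key, vals in latencies_by_stim.items():
        vals = np.asarray(vals)
        if len(vals) < 2:
            out[key] = vals.copy()
        else:
            out[key] = np.roll(vals, -by, axis=0)
    return out
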