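"""Visual discrimination tasks over the 8-phase grating set and the
training/evaluation protocols.

The 8 gratings are quarter-bar-width phase shifts of one square grating;
phase i and i+4 are polarity inverses of each other.  Two task families:

* luminance task — is a given retinal location bright or dark?  Target =
  an adjacent phase pair {i, i+1}, null = its polarity-inverted pair
  {i+4, i+5}.  8 realizations (4 cyclic pairs x 2 role assignments).
* boundary task — is there a light/dark edge at the location, regardless
  of polarity?  Target = a polarity pair {i, i+4}, null = the
  quarter-period-shifted pair {i+2, i+6}.  4 realizations.

Protocols: best-of-runs training over a (step size, init sd) grid,
stratified 75/25 cross-validation with an optimized training margin,
contrast-generalization (train on a contrast subset, freeze, evaluate per
contrast) and population resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoders
from .spikeio import Dataset
from .tempotron import (
    DepressionParams,
    PSPKernel,
    TrainResult,
    evaluate,
    train,
)


def _wrap(i: int) -> int:
    return (i - 1) % 8 + 1


@dataclass(frozen=True)
class TaskSpec:
    task_type: str  # "luminance" | "boundary"
    target_phases: frozenset
    null_phases: frozenset

    def __post_init__(self) -> None:
        if self.target_phases & self.null_phases:
            raise ValueError("target and null phase sets must be disjoint")
        if len(self.target_phases) != 2 or len(self.null_phases) != 2:
            raise ValueError("each class holds exactly two phases")


def enumerate_realizations(task_type: str) -> list[TaskSpec]:
    """All distinct realizations of a task: 8 (luminance) or 4 (boundary).

    Role swaps (target vs null) count as distinct realizations; cyclically
    identical phase groupings do not.
    """
    specs = []
    if task_type == "luminance":
        for i in range(1, 9):
            target = frozenset({_wrap(i), _wrap(i + 1)})
            null = frozenset({_wrap(i + 4), _wrap(i + 5)})
            specs.append(TaskSpec(task_type, target, null))
    elif task_type == "boundary":
        for i in (1, 2):
            pair = frozenset({i, i + 4})
            shifted = frozenset({i + 2, i + 6})
            specs.append(TaskSpec(task_type, pair, shifted))
            specs.append(TaskSpec(task_type, shifted, pair))
    else:
        raise ValueError(f"unknown task type {task_type!r}")
    return specs


def label_trials(dataset: Dataset, spec: TaskSpec) -> tuple[Dataset, np.ndarray]:
    """Subset to the trials of the task and label them (target=1, null=0)."""
    keep, labels = [], []
    phases_seen = set()
    for trial in dataset.trials:
        phases_seen.add(trial.phase_index)
        if trial.phase_index in spec.target_phases:
            keep.append(True)
            labels.append(1)
        elif trial.phase_index in spec.null_phases:
            keep.append(True)
            labels.append(0)
        else:
            keep.append(False)
    missing = (spec.target_phases | spec.null_phases) - phases_seen
    if missing and dataset.trials:
        import warnings

        warnings.warn(f"task phases {sorted(missing)} absent from dataset")
    return dataset.subset(keep), np.asarray(labels, dtype=int)


@dataclass
class ProtocolConfig:
    """Training-protocol hyperparameters (defaults follow the standard
    2000-cycle, 50-cycle-smoothing, best-of-runs recipe)."""

    cycles: int = 2000
    smooth_window: int = 50
    runs_per_grid_point: int = 5
    lambda_grid: tuple[float, ...] = (1e-3, 3e-3, 1e-2)
    init_sd_grid: tuple[float, ...] = (0.01, 0.05)
    margin_grid: tuple[float, ...] = (0.0, 0.025, 0.05, 0.1, 0.15, 0.2)
    momentum: float = 0.9
    kernel: PSPKernel = field(default_factory=PSPKernel)
    depression: DepressionParams | None = None
    seed: int = 0


LEARNING_DECODERS = {"tempotron", "tempotron+depression", "perceptron"}
SEARCH_DECODERS = {"twta1", "twta3", "rank"}


@dataclass
class ProtocolResult:
    decoder: str
    spec: TaskSpec
    best_error: float
    best_params: dict
    model: object


def run_protocol(
    dataset: Dataset, spec: TaskSpec, decoder_kind: str, config: ProtocolConfig
) -> ProtocolResult:
    """Train/search one decoder on one task realization; report the minimum
    (smoothed) training error over runs and the hyperparameter grid."""
    data, labels = label_trials(dataset, spec)
    if decoder_kind in ("tempotron", "tempotron+depression"):
        depression = config.depression
        if decoder_kind == "tempotron+depression" and depression is None:
            depression = DepressionParams(U=0.5, tau_d=500.0)
        best: TrainResult | None = None
        best_params: dict = {}
        seed_seq = np.random.SeedSequence(config.seed)
        for lam in config.lambda_grid:
            for sd in config.init_sd_grid:
                for child in seed_seq.spawn(config.runs_per_grid_point):
                    run_seed = int(child.generate_state(1)[0] % 2**31)
                    res = train(
                        data,
                        labels,
                        step_size=lam,
                        momentum=config.momentum,
                        cycles=config.cycles,
                        init_sd=sd,
                        seed=run_seed,
                        smooth_window=config.smooth_window,
                        kernel=config.kernel,
                        depression=depression,
                    )
                    if best is None or res.best_error < best.best_error:
                        best = res
                        best_params = {"lambda": lam, "init_sd": sd, "seed": run_seed}
        return ProtocolResult(decoder_kind, spec, best.best_error, best_params, best.model)
    if decoder_kind == "perceptron":
        best_err, best_model, best_params = np.inf, None, {}
        seed_seq = np.random.SeedSequence(config.seed)
        for lam in config.lambda_grid:
            for sd in config.init_sd_grid:
                for child in seed_seq.spawn(config.runs_per_grid_point):
                    run_seed = int(child.generate_state(1)[0] % 2**31)
                    model, _, smoothed = decoders.perceptron_fit(
                        data,
                        labels,
                        step_size=lam,
                        cycles=config.cycles,
                        init_sd=sd,
                        seed=run_seed,
                        smooth_window=config.smooth_window,
                    )
                    err = float(np.min(smoothed))
                    if err < best_err:
                        best_err, best_model = err, model
                        best_params = {"lambda": lam, "init_sd": sd, "seed": run_seed}
        return ProtocolResult(decoder_kind, spec, best_err, best_params, best_model)
    if decoder_kind in ("twta1", "twta3"):
        k = 1 if decoder_kind == "twta1" else 3
        model, err = decoders.twta_fit(data, labels, k=k)
        return ProtocolResult(decoder_kind, spec, err, {"k": k}, model)
    if decoder_kind == "rank":
        model, err = decoders.rank_fit(data, labels)
        return ProtocolResult(
            decoder_kind,
            spec,
            err,
            {"m": model.attenuation, "threshold": model.threshold},
            model,
        )
    raise ValueError(f"unknown decoder {decoder_kind!r}")


def run_task_average(
    dataset: Dataset, task_type: str, decoder_kind: str, config: ProtocolConfig
) -> tuple[float, list[ProtocolResult]]:
    """Error averaged over all realizations of a task."""
    results = [
        run_protocol(dataset, spec, decoder_kind, config)
        for spec in enumerate_realizations(task_type)
    ]
    return float(np.mean([r.best_error for r in results])), results


def stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; both classes present in both parts."""
    labels = np.asarray(labels, dtype=int)
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(len(idx) * test_fraction)))
        n_test = min(n_test, len(idx) - 1)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def crossvalidate(
    dataset: Dataset,
    spec: TaskSpec,
    config: ProtocolConfig,
    test_fraction: float = 0.25,
) -> dict:
    """75/25 stratified cross-validation of the tempotron with a training
    margin chosen on the training split.

    A target trial counts as correct only if v_max >= theta (1 + margin),
    a null only if v_max <= theta (1 - margin); test evaluation uses
    margin 0.
    """
    data, labels = label_trials(dataset, spec)
    if len(labels) < 8:
        raise ValueError("need at least 8 trials to cross-validate")
    rng = np.random.default_rng(config.seed)
    tr_idx, te_idx = stratified_split(labels, test_fraction, rng)
    d_train, y_train = data.subset(tr_idx), labels[tr_idx]
    d_test, y_test = data.subset(te_idx), labels[te_idx]

    best = None
    for margin in config.margin_grid:
        res = train(
            d_train,
            y_train,
            step_size=config.lambda_grid[0],
            momentum=config.momentum,
            cycles=config.cycles,
            init_sd=config.init_sd_grid[0],
            seed=config.seed,
            smooth_window=config.smooth_window,
            kernel=config.kernel,
            depression=config.depression,
            margin=margin,
        )
        train_err = evaluate(d_train, y_train, res.model, margin=margin)
        if best is None or train_err < best[0]:
            best = (train_err, margin, res.model)
    train_err, margin, model = best
    test_err = evaluate(d_test, y_test, model, margin=0.0)
    return {
        "train_error": float(train_err),
        "test_error": float(test_err),
        "margin": float(margin),
        "model": model,
    }


def contrast_generalization(
    dataset: Dataset,
    spec: TaskSpec,
    config: ProtocolConfig,
    train_contrasts: str = "all",
    eval_dataset: Dataset | None = None,
) -> dict:
    """Train once on a contrast subset, freeze the weights, evaluate the
    frozen model separately at every contrast level present.

    With ``eval_dataset`` the frozen model is scored on independent trials,
    putting trained and held-out contrasts on equal footing.
    """
    levels = dataset.contrasts()
    if len(levels) < 2:
        raise ValueError("contrast generalization needs >= 2 contrast levels")
    if train_contrasts == "all":
        subset_levels = levels
    elif train_contrasts == "extremes":
        subset_levels = [levels[0], levels[-1]]
    else:
        subset_levels = sorted(train_contrasts)
        missing = set(subset_levels) - set(levels)
        if missing:
            raise ValueError(f"contrasts {sorted(missing)} absent from dataset")
    train_data = dataset.subset([t.contrast in subset_levels for t in dataset.trials])
    result = run_protocol(train_data, spec, "tempotron", config)
    score_on = eval_dataset if eval_dataset is not None else dataset
    per_contrast = {}
    for level in levels:
        d_level = score_on.subset([t.contrast == level for t in score_on.trials])
        d_level, y_level = label_trials(d_level, spec)
        per_contrast[level] = 1.0 - evaluate(d_level, y_level, result.model)
    return {
        "trained_on": subset_levels,
        "fraction_correct": per_contrast,
        "model": result.model,
        "train_error": result.best_error,
    }


def resample_populations(
    pool: Dataset, n_cells: int, n_samples: int, seed: int = 0
) -> list[Dataset]:
    """Seeded sub-populations of n_cells afferents drawn without replacement
    (within each sample) from the pooled dataset."""
    if n_cells > pool.n_afferents:
        raise ValueError("cannot sample more cells than the pool holds")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        chosen = np.sort(rng.choice(pool.n_afferents, size=n_cells, replace=False))
        trials = tuple(
            type(t)(
                trial_id=t.trial_id,
                trains=tuple(t.trains[i] for i in chosen),
                phase_index=t.phase_index,
                contrast=t.contrast,
                class_label=t.class_label,
            )
            for t in pool.trials
        )
        out.append(Dataset(trials, pool.window_ms, dict(pool.metadata)))
    return out
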