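"""Spike-pattern data model and tabular I/O.

All downstream analyses operate on :class:`Dataset` objects: collections of
trials, each holding one spike train per afferent (a retinal ganglion cell),
tagged with the stimulus phase and contrast of the trial.  Spike times are in
milliseconds relative to stimulus onset and live inside a response window
(150 ms by default).

On disk a dataset is a pair of plain CSV files: a spike table with one row
per spike (``trial_id, afferent_id, time_ms``) and a stimulus table with one
row per trial (``trial_id, phase_index, contrast``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW_MS = 150.0


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one afferent in one trial.

    May be empty: spike failures are legal everywhere and each decoder
    documents its behaviour on them.
    """

    afferent_id: int
    times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        t = self.times
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError(
                f"spike times of afferent {self.afferent_id} must be strictly increasing"
            )
        if t and t[0] < 0:
            raise ValueError("negative spike time")

    @property
    def first(self) -> float | None:
        """First-spike latency, or None on a failure trial."""
        return self.times[0] if self.times else None

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TrialPattern:
    """All afferents' spike trains for a single stimulus presentation."""

    trial_id: int
    trains: tuple[SpikeTrain, ...]
    phase_index: int | float | None = None
    contrast: float | None = None
    class_label: int | None = None

    @property
    def afferent_ids(self) -> tuple[int, ...]:
        return tuple(tr.afferent_id for tr in self.trains)

    @property
    def n_afferents(self) -> int:
        return len(self.trains)

    def all_spikes(self) -> list[tuple[int, float]]:
        """(afferent index, time) pairs, in afferent order."""
        return [(i, t) for i, tr in enumerate(self.trains) for t in tr.times]

    def first_latencies(self) -> np.ndarray:
        """First-spike latency per afferent; NaN on failure trials."""
        return np.array(
            [tr.times[0] if tr.times else np.nan for tr in self.trains]
        )


@dataclass(frozen=True)
class Dataset:
    """A set of trials sharing one afferent population and response window."""

    trials: tuple[TrialPattern, ...]
    window_ms: float = DEFAULT_WINDOW_MS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = None
        for trial in self.trials:
            if ids is None:
                ids = trial.afferent_ids
            elif trial.afferent_ids != ids:
                raise ValueError("all trials must share the same afferent set")
            for tr in trial.trains:
                if tr.times and tr.times[-1] > self.window_ms:
                    raise ValueError(
                        f"spike at {tr.times[-1]} ms exceeds window {self.window_ms} ms"
                    )

    @property
    def afferent_ids(self) -> tuple[int, ...]:
        return self.trials[0].afferent_ids if self.trials else ()

    @property
    def n_afferents(self) -> int:
        return len(self.afferent_ids)

    def __len__(self) -> int:
        return len(self.trials)

    def contrasts(self) -> list[float]:
        return sorted({t.contrast for t in self.trials if t.contrast is not None})

    def phases(self) -> list:
        return sorted({t.phase_index for t in self.trials if t.phase_index is not None})

    def subset(self, keep: Iterable[bool] | Iterable[int]) -> "Dataset":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            trials = tuple(t for t, k in zip(self.trials, keep) if k)
        else:
            trials = tuple(self.trials[i] for i in keep)
        return Dataset(trials, self.window_ms, dict(self.metadata))


def dataset_from_trials(
    trials: Sequence[TrialPattern], window_ms: float = DEFAULT_WINDOW_MS, **metadata
) -> Dataset:
    return Dataset(tuple(trials), window_ms, metadata)


def read_spike_table(path, stimulus_path, window_ms: float = DEFAULT_WINDOW_MS) -> Dataset:
    """Read a spike-table / stimulus-table CSV pair into a Dataset.

    Every trial in the stimulus table appears in the result; afferents with
    no spike row in a trial get an empty train.  The afferent set is the
    union of afferent ids over the whole spike table.
    """
    spikes = pd.read_csv(path)
    stim = pd.read_csv(stimulus_path)
    required = {"trial_id", "afferent_id", "time_ms"}
    if not required.issubset(spikes.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}")
    if not {"trial_id", "phase_index", "contrast"}.issubset(stim.columns):
        raise ValueError("stimulus table must have columns trial_id, phase_index, contrast")

    known = set(stim["trial_id"])
    unknown = set(spikes["trial_id"]) - known
    if unknown:
        raise ValueError(f"spike table references unknown trial ids: {sorted(unknown)[:5]}")
    if len(spikes) and (spikes["time_ms"].min() < 0 or spikes["time_ms"].max() > window_ms):
        raise ValueError(f"spike times must lie in [0, {window_ms}] ms")

    afferents = sorted(set(spikes["afferent_id"]))
    by_trial = {tid: g for tid, g in spikes.groupby("trial_id")}
    trials = []
    for row in stim.itertuples(index=False):
        g = by_trial.get(row.trial_id)
        trains = []
        for aff in afferents:
            if g is not None:
                times = tuple(np.sort(g.loc[g["afferent_id"] == aff, "time_ms"].to_numpy()))
            else:
                times = ()
            trains.append(SpikeTrain(aff, tuple(float(t) for t in times)))
        trials.append(
            TrialPattern(
                trial_id=int(row.trial_id),
                trains=tuple(trains),
                phase_index=row.phase_index,
                contrast=float(row.contrast),
            )
        )
    return Dataset(tuple(trials), window_ms)


def write_spike_table(dataset: Dataset, path, stimulus_path=None) -> None:
    """Write a Dataset as CSVs re-readable by :func:`read_spike_table`.

    Times are written with 6 decimal places so a read/write round trip is
    exact to well below 1e-3 ms.
    """
    rows = [
        (trial.trial_id, tr.afferent_id, t)
        for trial in dataset.trials
        for tr in trial.trains
        for t in tr.times
    ]
    df = pd.DataFrame(rows, columns=["trial_id", "afferent_id", "time_ms"])
    df.to_csv(path, index=False, float_format="%.6f")
    if stimulus_path is not None:
        stim = pd.DataFrame(
            [
                (t.trial_id, t.phase_index, t.contrast)
                for t in dataset.trials
            ],
            columns=["trial_id", "phase_index", "contrast"],
        )
        stim.to_csv(stimulus_path, index=False)


def restrict_spikes(
    dataset: Dataset, k_max: int | None = None, t_max: float | None = None
) -> Dataset:
    """Truncate each train to its first ``k_max`` spikes, then drop spikes later
    than ``t_max``.  The original dataset is unmodified; the operation is
    idempotent.
    """
    if k_max is not None and k_max < 1:
        raise ValueError("k_max must be >= 1 (a classifier needs at least one spike)")
    if t_max is not None and t_max <= 0:
        raise ValueError("t_max must be positive")

    def cut(times: tuple[float, ...]) -> tuple[float, ...]:
        if k_max is not None:
            times = times[:k_max]
        if t_max is not None:
            times = tuple(t for t in times if t <= t_max)
        return times

    trials = tuple(
        replace(
            trial,
            trains=tuple(SpikeTrain(tr.afferent_id, cut(tr.times)) for tr in trial.trains),
        )
        for trial in dataset.trials
    )
    return Dataset(trials, dataset.window_ms, dict(dataset.metadata))
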