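"""IED and control event handling: exclusion rules, epoching, averaging.

Events whose analysis window overlaps a long (> 5 s) motion-artifact segment
are discarded; control markers are drawn uniformly from IED-free periods to
build the exchangeable pool for the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventSet",
    "EpochSet",
    "discard_events_near_artifacts",
    "select_control_events",
    "epoch",
    "average_epochs",
]

DEFAULT_WINDOW = (-20.0, 40.0)  # covers every response bound in the cohort table


@dataclass
class EventSet:
    """Marker times (s from run start) with labels in {'ied', 'control'}."""

    times: np.ndarray
    labels: np.ndarray
    run_id: str = "run-1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.labels = np.asarray(self.labels, dtype=object)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.labels = self.labels[order]

    def select(self, label: str) -> np.ndarray:
        return self.times[self.labels == label]

    def __len__(self) -> int:
        return len(self.times)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"onset_s": self.times, "label": self.labels, "run_id": self.run_id}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "EventSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        run = str(df["run_id"].iloc[0]) if len(df) else "run-1"
        return cls(times=df["onset_s"].to_numpy(float), labels=df["label"].to_numpy(object), run_id=run)


@dataclass
class EpochSet:
    """Event-locked slices: (events, ..., time) at sampling rate fs."""

    data: np.ndarray
    window: tuple[float, float]
    fs: float
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def times_s(self) -> np.ndarray:
        n = self.data.shape[-1]
        return self.window[0] + np.arange(n) / self.fs


def discard_events_near_artifacts(
    events: EventSet,
    artifact_segments: list[tuple[float, float]],
    min_artifact_s: float = 5.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[EventSet, list[dict]]:
    """Drop events whose window overlaps any artifact longer than 5 s."""
    long_segs = [(a, b) for a, b in artifact_segments if (b - a) > min_artifact_s]
    keep = np.ones(len(events), dtype=bool)
    log = []
    for i, t in enumerate(events.times):
        w0, w1 = t + window[0], t + window[1]
        for a, b in long_segs:
            if w0 < b and a < w1:
                keep[i] = False
                log.append({"time_s": float(t), "label": events.labels[i], "artifact": (a, b)})
                break
    kept = EventSet(times=events.times[keep], labels=events.labels[keep], run_id=events.run_id)
    return kept, log


def select_control_events(
    ied_times: np.ndarray,
    artifact_segments: list[tuple[float, float]],
    run_duration_s: float,
    n: int,
    seed: int | np.random.Generator,
    guard_s: float = 60.0,
    min_spacing_s: float = 5.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_artifact_s: float = 5.0,
) -> EventSet:
    """Draw ``n`` control markers uniformly from IED-free, artifact-free time.

    Admissible times lie at least ``guard_s`` from every IED, admit a full
    epoch window, avoid long artifacts, and are pairwise separated by at
    least ``min_spacing_s``.  Reproducible under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ied_times = np.asarray(ied_times, float)
    step = 0.05
    grid = np.arange(-window[0], run_duration_s - window[1] + 1e-9, step)
    ok = np.ones(len(grid), dtype=bool)
    for t in ied_times:
        ok &= np.abs(grid - t) >= guard_s
    for a, b in artifact_segments:
        if (b - a) > min_artifact_s:
            ok &= ~((grid + window[0] < b) & (a < grid + window[1]))
    admissible = grid[ok]
    chosen: list[float] = []
    pool = admissible.copy()
    for _ in range(n):
        if len(pool) == 0:
            raise ValueError(
                f"not enough IED-free time for {n} control events "
                f"(only {len(chosen)} achievable)"
            )
        t = float(rng.choice(pool))
        chosen.append(t)
        pool = pool[np.abs(pool - t) >= min_spacing_s]
    return EventSet(times=np.array(chosen), labels=np.array(["control"] * n, object))


def epoch(
    values: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[EpochSet, list[float]]:
    """Slice ``values`` (..., time) around each event; no baseline subtraction.

    Events whose window would be truncated are dropped and reported.
    """
    if window[1] <= window[0]:
        raise ValueError("degenerate epoch window")
    nt = values.shape[-1]
    n_win = int(round((window[1] - window[0]) * fs))
    slices, kept, dropped = [], [], []
    for t in np.asarray(event_times, float):
        i0 = int(round((t + window[0]) * fs))
        if i0 < 0 or i0 + n_win > nt:
            dropped.append(float(t))
            continue
        slices.append(values[..., i0 : i0 + n_win])
        kept.append(t)
    data = np.stack(slices, axis=0) if slices else np.empty((0,) + values.shape[:-1] + (n_win,))
    return EpochSet(data=data, window=window, fs=fs, event_times=np.asarray(kept)), dropped


def average_epochs(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray | None]:
    """Pointwise mean and standard error across the event axis."""
    n = epochs.data.shape[0]
    if n == 0:
        raise ValueError("no epochs to average")
    mean = epochs.data.mean(axis=0)
    if n < 2:
        return mean, None
    se = epochs.data.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, se
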