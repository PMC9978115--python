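"""Reading, writing and reshaping multi-electrode spike-time tables.

Spike times are stored in seconds throughout; detection parameters quoted in
milliseconds in the literature are converted at the parameter boundary, never
inside the data structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "Recording",
    "PooledTrain",
    "PhasePlan",
    "SpikeTableError",
    "read_spike_table",
    "flatten",
    "segment",
    "write_results",
]


class SpikeTableError(ValueError):
    """Raised for malformed spike tables or invalid segmentation plans."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) of one electrode.

    Times are strictly increasing; a physical electrode cannot report two
    spikes with the same timestamp, so duplicates are collapsed on
    construction from file input.
    """

    electrode_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise SpikeTableError(f"{self.electrode_id}: times must be 1-D")
        if t.size and np.any(np.diff(t) <= 0):
            raise SpikeTableError(
                f"{self.electrode_id}: times must be strictly increasing"
            )
        if t.size and t[0] < 0:
            raise SpikeTableError(f"{self.electrode_id}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class Recording:
    """A set of electrode spike trains with a common duration (seconds)."""

    trains: dict[str, SpikeTrain]
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SpikeTableError("recording duration must be positive")
        for eid, tr in self.trains.items():
            if eid != tr.electrode_id:
                raise SpikeTableError("train key does not match electrode_id")
            if tr.times.size and tr.times[-1] > self.duration:
                raise SpikeTableError(
                    f"{eid}: spike time beyond recording duration"
                )

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains.values())

    @property
    def electrode_ids(self) -> list[str]:
        return sorted(self.trains)


@dataclass(frozen=True)
class PooledTrain:
    """All electrodes' spikes merged into one time-sorted train.

    ``source_electrode`` runs parallel to ``times`` and records which
    electrode fired each spike.  Cross-electrode ties are kept and ordered
    stably by electrode id.
    """

    times: np.ndarray
    source_electrode: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.source_electrode)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "source_electrode", s)
        if t.size != s.size:
            raise SpikeTableError("times and source_electrode length mismatch")
        if t.size and np.any(np.diff(t) < 0):
            raise SpikeTableError("pooled times must be sorted ascending")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PhasePlan:
    """Ordered half-open ``[start, end)`` intervals labelling recording phases."""

    phases: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.phases:
            if end <= start:
                raise SpikeTableError(f"phase {label!r}: end must exceed start")
            if start < prev_end:
                raise SpikeTableError(f"phase {label!r}: overlaps previous phase")
            if start < 0:
                raise SpikeTableError(f"phase {label!r}: negative start")
            prev_end = end

    @classmethod
    def from_entries(cls, entries: Iterable[str]) -> "PhasePlan":
        """Parse ``label:start_s:end_s`` config strings."""
        phases = []
        for e in entries:
            label, start, end = e.split(":")
            phases.append((label, float(start), float(end)))
        return cls(tuple(phases))

    @classmethod
    def equal_phases(
        cls, labels: Sequence[str], total_duration: float
    ) -> "PhasePlan":
        """Split ``[0, total_duration)`` into equal consecutive phases."""
        width = total_duration / len(labels)
        return cls(
            tuple(
                (lab, i * width, (i + 1) * width) for i, lab in enumerate(labels)
            )
        )


def read_spike_table(
    path: str | Path,
    duration: float | None = None,
    electrode_col: str = "electrode",
    time_col: str = "time_s",
) -> Recording:
    """Read a columnar spike table (CSV, one row per spike) into a Recording.

    If ``duration`` is absent it is inferred as the last spike time and the
    recording metadata is flagged ``duration_inferred`` so rate denominators
    stay auditable.
    """
    df = pd.read_csv(path)
    missing = {electrode_col, time_col} - set(df.columns)
    if missing:
        raise SpikeTableError(f"{path}: missing columns {sorted(missing)}")
    if len(df) and (df[time_col] < 0).any():
        raise SpikeTableError(f"{path}: negative spike times")

    trains: dict[str, SpikeTrain] = {}
    n_dup = 0
    for eid, grp in df.groupby(electrode_col, sort=True):
        t = np.unique(np.asarray(grp[time_col], dtype=float))
        n_dup += len(grp) - t.size
        trains[str(eid)] = SpikeTrain(str(eid), t)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate spike rows", path, n_dup)

    meta: dict = {}
    if duration is None:
        if not trains:
            raise SpikeTableError(
                f"{path}: empty table and no duration supplied"
            )
        duration = max(tr.times[-1] for tr in trains.values() if tr.n_spikes)
        meta["duration_inferred"] = True
    return Recording(trains=trains, duration=float(duration), metadata=meta)


def flatten(recording: Recording) -> PooledTrain:
    """Merge all electrode trains into one time-sorted pooled train.

    The pooled (flattened) train is the substrate for the adaptive
    network-burst threshold.  Spike count is conserved; ties across
    electrodes are ordered by electrode id.
    """
    if recording.n_spikes == 0:
        raise SpikeTableError("cannot flatten a recording with zero spikes")
    ids = recording.electrode_ids
    times = np.concatenate([recording.trains[e].times for e in ids])
    codes = np.concatenate(
        [np.full(recording.trains[e].n_spikes, i) for i, e in enumerate(ids)]
    )
    order = np.lexsort((codes, times))
    id_arr = np.asarray(ids, dtype=object)
    return PooledTrain(times=times[order], source_electrode=id_arr[codes[order]])


def segment(recording: Recording, plan: PhasePlan) -> list[Recording]:
    """Cut a recording into phase recordings per a half-open phase plan.

    Each phase's spike times are re-zeroed to the phase start; a spike at a
    phase boundary belongs to the later phase.  Spike counts over the planned
    span are conserved.
    """
    out = []
    for label, start, end in plan.phases:
        if end > recording.duration + 1e-9:
            raise SpikeTableError(
                f"phase {label!r} extends beyond recording duration"
            )
        trains = {}
        for eid, tr in recording.trains.items():
            lo, hi = np.searchsorted(tr.times, [start, end], side="left")
            trains[eid] = SpikeTrain(eid, tr.times[lo:hi] - start)
        meta = dict(recording.metadata)
        meta["phase"] = label
        meta["phase_start_s"] = start
        out.append(Recording(trains=trains, duration=end - start, metadata=meta))
    return out


def recording_to_table(recording: Recording) -> pd.DataFrame:
    """Long-format spike table (``electrode,time_s``) for a recording."""
    rows = [
        pd.DataFrame(
            {"electrode": eid, "time_s": recording.trains[eid].times}
        )
        for eid in recording.electrode_ids
    ]
    if not rows:
        return pd.DataFrame({"electrode": [], "time_s": []})
    return pd.concat(rows, ignore_index=True)


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Write result tables as CSV with deterministic column order.

    Returns the written paths keyed by table name.  Re-reading a written
    table yields identical values (round-trip identity).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
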