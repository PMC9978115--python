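"""Per-recording activity metrics.

Implements the metric battery used to characterise cultured-network
development and perturbation response:

* recording spike frequency per channel, f = (spikes - 1) / dt, where dt is
  the span from first to last spike;
* instantaneous spike frequency on a moving window (1 s window, 0.1 s
  step), f_window = spikes_in_window / (n_active * width);
* burstiness index — the fraction of total activity contained in the 15%
  most active windows, optionally rescaled so uniform activity maps to 0
  and total concentration to 1;
* coherence index — SD / mean of the instantaneous-frequency series (a
  coefficient of variation; higher means activity is concentrated in
  co-occurring bursts);
* burst-composition statistics: mean burst duration, inter-burst interval
  (IBI) and network IBI (NIBI), fractions of spikes inside bursts and
  network bursts, and the spikes-per-burst occurrence histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .burst_detection import Burst, NetworkBurst
from .spike_io import Recording, SpikeTrain, flatten

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSeries",
    "MetricsSummary",
    "UndefinedMetricError",
    "firing_rate",
    "active_electrodes",
    "instantaneous_rate",
    "burstiness_index",
    "coherence_index",
    "burst_composition",
    "compute_summary",
]

DEFAULT_ACTIVE_RATE_HZ = 0.1  # >= 6 spikes/min counts as an active electrode


class UndefinedMetricError(ValueError):
    """A metric is undefined on this input (too few spikes, zero activity)."""


@dataclass(frozen=True)
class WindowSeries:
    """Instantaneous spike-frequency series on a sliding window grid.

    ``counts`` holds the raw pooled spike counts per window (substrate of
    the burstiness index); ``values`` = counts / (n_active * width).
    """

    window_start: np.ndarray  # s
    window_width: float  # s
    values: np.ndarray  # Hz
    counts: np.ndarray
    n_active: int


@dataclass
class MetricsSummary:
    """One recording's metric vector.  Undefined entries are None, not 0."""

    mean_firing_rate: float | None = None  # Hz
    mean_isi: float | None = None  # s
    burstiness_index: float | None = None
    burstiness_f15: float | None = None
    coherence_index: float | None = None
    mean_burst_duration: float | None = None  # s
    mean_ibi: float | None = None  # s
    mean_nibi: float | None = None  # s
    frac_spikes_in_bursts: float | None = None
    frac_spikes_in_network_bursts: float | None = None
    n_bursts: int = 0
    n_network_bursts: int = 0
    spikes_per_burst_histogram: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "spikes_per_burst_histogram"
        }
        return d


def firing_rate(train: SpikeTrain) -> float:
    """Recording spike frequency of one channel: (spikes - 1) / dt.

    dt is the interval between the first and last spike of the channel.
    Undefined for fewer than two spikes.
    """
    if train.n_spikes < 2:
        raise UndefinedMetricError(
            f"{train.electrode_id}: firing rate needs >= 2 spikes"
        )
    dt = train.times[-1] - train.times[0]
    if dt <= 0:
        raise UndefinedMetricError(f"{train.electrode_id}: zero spike span")
    return (train.n_spikes - 1) / dt


def active_electrodes(
    recording: Recording, min_rate_hz: float = DEFAULT_ACTIVE_RATE_HZ
) -> list[str]:
    """Electrodes whose overall rate (spikes / duration) reaches ``min_rate_hz``."""
    return [
        eid
        for eid in recording.electrode_ids
        if recording.trains[eid].n_spikes / recording.duration >= min_rate_hz
    ]


def instantaneous_rate(
    recording: Recording,
    width: float = 1.0,
    step: float = 0.1,
    min_rate_hz: float = DEFAULT_ACTIVE_RATE_HZ,
) -> WindowSeries:
    """Instantaneous spike frequency on an overlapping moving-window grid.

    Windows of ``width`` seconds start at 0 and advance by ``step``; the last
    window starts at ``duration - width``.  The numerator pools spikes over
    the active electrodes; the denominator is the fixed per-recording count
    of active electrodes times the window width.
    """
    active = active_electrodes(recording, min_rate_hz)
    if not active:
        raise UndefinedMetricError("no active electrodes in recording")
    if recording.duration < width:
        raise UndefinedMetricError("recording shorter than one window")
    pooled = np.sort(
        np.concatenate([recording.trains[e].times for e in active])
    )
    n_windows = int(np.floor((recording.duration - width) / step + 1e-9)) + 1
    starts = np.arange(n_windows) * step
    lo = np.searchsorted(pooled, starts, side="left")
    hi = np.searchsorted(pooled, starts + width, side="left")
    counts = (hi - lo).astype(float)
    values = counts / (len(active) * width)
    return WindowSeries(
        window_start=starts,
        window_width=width,
        values=values,
        counts=counts,
        n_active=len(active),
    )


def burstiness_index(
    series: WindowSeries,
    top_fraction: float = 0.15,
    normalized: bool = True,
) -> float:
    """Fraction of total activity in the ``top_fraction`` most active windows.

    The raw fraction f15 lies in [top_fraction, 1]: the most active 15% of
    windows always carry at least their proportional share.  When
    ``normalized`` (the default), the index is rescaled to
    (f15 - 0.15) / 0.85 so perfectly uniform activity maps to 0 and complete
    concentration to 1.
    """
    counts = series.counts
    total = counts.sum()
    if total == 0:
        raise UndefinedMetricError("zero total activity; burstiness undefined")
    k = int(np.ceil(top_fraction * counts.size))
    top = np.sort(counts)[::-1][:k]
    f_top = top.sum() / total
    if not normalized:
        return float(f_top)
    return float((f_top - top_fraction) / (1 - top_fraction))


def coherence_index(series: WindowSeries) -> float:
    """Coefficient of variation (population SD / mean) of f_window values."""
    mean = series.values.mean()
    if mean <= 0:
        raise UndefinedMetricError("zero mean rate; coherence undefined")
    return float(series.values.std() / mean)


def _mean_gap(intervals: list[tuple[float, float]]) -> float | None:
    """Mean quiescent gap between consecutive non-overlapping intervals."""
    if len(intervals) < 2:
        return None
    gaps = [
        intervals[i + 1][0] - intervals[i][1] for i in range(len(intervals) - 1)
    ]
    return float(np.mean(gaps))


def _count_in_intervals(
    times: np.ndarray, intervals: list[tuple[float, float]]
) -> int:
    if not intervals:
        return 0
    n = 0
    for lo, hi in intervals:
        # closed interval: burst boundaries are member spike times
        a = np.searchsorted(times, lo, side="left")
        b = np.searchsorted(times, hi, side="right")
        n += b - a
    return int(n)


def burst_composition(
    recording: Recording,
    bursts: list[Burst],
    network_bursts: list[NetworkBurst],
) -> MetricsSummary:
    """Burst-composition statistics for one recording.

    IBI is averaged within each electrode (over electrodes with >= 2 bursts)
    and then across electrodes, so high-burst electrodes do not dominate.
    Fractions count spikes inside closed burst intervals of their own
    electrode (bursts) or of the pooled train (network bursts).  Undefined
    means are reported as None.
    """
    out = MetricsSummary()
    out.n_bursts = len(bursts)
    out.n_network_bursts = len(network_bursts)

    if bursts:
        out.mean_burst_duration = float(np.mean([b.duration for b in bursts]))
        hist: dict[int, int] = {}
        for b in bursts:
            hist[b.n_spikes] = hist.get(b.n_spikes, 0) + 1
        out.spikes_per_burst_histogram = hist

        per_elec: dict[str, list[tuple[float, float]]] = {}
        for b in bursts:
            per_elec.setdefault(b.electrode_id, []).append((b.t_start, b.t_end))
        ibis = [
            g
            for iv in per_elec.values()
            if (g := _mean_gap(sorted(iv))) is not None
        ]
        if ibis:
            out.mean_ibi = float(np.mean(ibis))

        total = recording.n_spikes
        if total:
            in_bursts = sum(
                _count_in_intervals(
                    recording.trains[eid].times, sorted(iv)
                )
                for eid, iv in per_elec.items()
            )
            out.frac_spikes_in_bursts = in_bursts / total

    if network_bursts:
        nb_iv = sorted((nb.t_start, nb.t_end) for nb in network_bursts)
        out.mean_nibi = _mean_gap(nb_iv)
        total = recording.n_spikes
        if total:
            pooled = flatten(recording)
            out.frac_spikes_in_network_bursts = (
                _count_in_intervals(pooled.times, nb_iv) / total
            )
    return out


def compute_summary(
    recording: Recording,
    bursts: list[Burst],
    network_bursts: list[NetworkBurst],
    width: float = 1.0,
    step: float = 0.1,
    min_rate_hz: float = DEFAULT_ACTIVE_RATE_HZ,
) -> MetricsSummary:
    """Full metric vector for one recording.

    The mean firing rate and mean ISI average per-electrode values over
    electrodes with at least two spikes; electrodes with fewer are excluded
    (and logged), not counted as zero.
    """
    out = burst_composition(recording, bursts, network_bursts)

    rates, isis = [], []
    n_skipped = 0
    for eid in recording.electrode_ids:
        tr = recording.trains[eid]
        if tr.n_spikes < 2:
            n_skipped += 1
            continue
        rates.append(firing_rate(tr))
        isis.append(float(np.mean(np.diff(tr.times))))
    if n_skipped:
        logger.debug("%d electrodes with <2 spikes excluded from rate means",
                     n_skipped)
    if rates:
        out.mean_firing_rate = float(np.mean(rates))
        out.mean_isi = float(np.mean(isis))

    try:
        series = instantaneous_rate(recording, width, step, min_rate_hz)
        out.burstiness_f15 = burstiness_index(series, normalized=False)
        out.burstiness_index = burstiness_index(series, normalized=True)
        out.coherence_index = coherence_index(series)
    except UndefinedMetricError as err:
        logger.debug("window metrics undefined: %s", err)
    return out
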