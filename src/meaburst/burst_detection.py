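"""Per-electrode burst detection and adaptive network-burst detection.

Two detectors are implemented:

* a fixed-threshold run detector on single-electrode trains — maximal
  sequences of at least ``min_spikes`` spikes whose every inter-spike
  interval (ISI) is below ``isi_threshold`` (default 100 ms, 4 spikes);

* an adaptive detector on the flattened (pooled) train.  The span of
  ``n_consecutive`` spikes (ISI_N, default N = 6) is histogrammed on a
  logarithmic scale; the bimodal histogram separates an intra-burst mode
  from a background mode, and the network-burst threshold is the geometric
  mean of the two peak locations, clamped to [12, 300] ms.  Spikes whose
  ISI_N span falls below the threshold seed network bursts; overlapping
  seeded blocks are merged and kept if they contain at least
  ``min_spikes_nb`` spikes (default 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .spike_io import PooledTrain, SpikeTrain

__all__ = [
    "BurstParams",
    "NetBurstParams",
    "Burst",
    "NetworkBurst",
    "ThresholdDiagnostics",
    "detect_bursts",
    "isi_n_spans",
    "adaptive_isi_n_threshold",
    "detect_network_bursts",
    "match_events",
]


@dataclass(frozen=True)
class BurstParams:
    """Fixed-threshold single-electrode burst detection parameters."""

    isi_threshold: float = 0.100  # seconds
    min_spikes: int = 4

    def __post_init__(self) -> None:
        if self.isi_threshold <= 0:
            raise ValueError("isi_threshold must be positive")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be at least 2")


@dataclass(frozen=True)
class NetBurstParams:
    """Adaptive network-burst detection parameters.

    ``threshold_min``/``threshold_max`` clamp the adaptive ISI_N threshold
    to 12–300 ms; ``fallback_threshold`` is used when the log-ISI_N
    histogram is not bimodal.
    """

    n_consecutive: int = 6
    threshold_min: float = 0.012
    threshold_max: float = 0.300
    min_spikes_nb: int = 6
    bins_per_decade: int = 10
    smoothing_width: int = 3
    peak_prominence_frac: float = 0.05
    fallback_threshold: float = 0.100

    def __post_init__(self) -> None:
        if not self.threshold_min < self.threshold_max:
            raise ValueError("threshold_min must be below threshold_max")
        if self.min_spikes_nb < self.n_consecutive:
            raise ValueError("min_spikes_nb must be >= n_consecutive")


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    t_start: float
    t_end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class NetworkBurst:
    t_start: float
    t_end: float
    n_spikes: int
    n_electrodes: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class ThresholdDiagnostics:
    """Provenance of one adaptive-threshold estimate."""

    bin_edges: np.ndarray  # seconds, log-spaced
    counts: np.ndarray  # smoothed counts per bin
    peaks: tuple[float, ...]  # peak locations, seconds
    threshold: float  # chosen threshold, seconds
    fallback_used: bool
    clamped: bool = False
    paired_peaks: tuple[float, float] | None = None


def detect_bursts(
    train: SpikeTrain, params: BurstParams = BurstParams()
) -> list[Burst]:
    """Maximal runs of >= ``min_spikes`` spikes with every ISI below threshold.

    Burst boundaries are the first and last member spike times; ties at
    exactly the threshold do not join a burst (strict inequality).
    """
    t = train.times
    if t.size < params.min_spikes:
        return []
    ok = np.diff(t) < params.isi_threshold
    bursts: list[Burst] = []
    # boundaries of maximal runs of consecutive True gaps
    padded = np.concatenate(([False], ok, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        n = e - s + 1  # spikes in the run (e-s gaps)
        if n >= params.min_spikes:
            bursts.append(Burst(train.electrode_id, t[s], t[e], int(n)))
    return bursts


def isi_n_spans(times: np.ndarray, n_consecutive: int) -> np.ndarray:
    """Span of ``n_consecutive`` spikes: t[i+N-1] - t[i] at every index i."""
    t = np.asarray(times, dtype=float)
    if t.size < n_consecutive:
        return np.empty(0)
    return t[n_consecutive - 1 :] - t[: t.size - n_consecutive + 1]


def adaptive_isi_n_threshold(
    pooled: PooledTrain, params: NetBurstParams = NetBurstParams()
) -> ThresholdDiagnostics:
    """Estimate the network-burst ISI_N threshold from the pooled train.

    The log10 ISI_N histogram (``bins_per_decade`` bins per decade, padded
    one bin each side, smoothed by a centred moving average) is searched for
    local maxima with prominence at least ``peak_prominence_frac`` of the
    tallest bin.  The lowest-ISI peak (intra-burst mode) is paired with the
    tallest peak at strictly larger ISI (background mode); the threshold is
    their geometric mean clamped to ``[threshold_min, threshold_max]``.
    With fewer than two peaks the fixed ``fallback_threshold`` is used and
    flagged.
    """
    spans = isi_n_spans(pooled.times, params.n_consecutive)
    if spans.size == 0:
        raise ValueError(
            f"pooled train too short for ISI_{params.n_consecutive}"
        )
    spans = spans[spans > 0]
    if spans.size == 0:
        raise ValueError("all ISI_N spans are zero; degenerate pooled train")

    log_spans = np.log10(spans)
    width = 1.0 / params.bins_per_decade
    # pad beyond the smoothing reach so a boundary mode still forms a peak
    pad = max(1, params.smoothing_width) * width
    lo = np.floor(log_spans.min() / width) * width - pad
    hi = np.ceil(log_spans.max() / width) * width + pad
    n_bins = max(int(round((hi - lo) / width)), 1)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(log_spans, bins=edges)

    w = params.smoothing_width
    kernel = np.ones(w) / w
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")

    prominence = params.peak_prominence_frac * smoothed.max()
    idx, _ = find_peaks(smoothed, prominence=prominence)
    centers = 10 ** ((edges[:-1] + edges[1:]) / 2)
    peak_locs = tuple(float(c) for c in centers[idx])

    if len(idx) < 2:
        return ThresholdDiagnostics(
            bin_edges=10**edges,
            counts=smoothed,
            peaks=peak_locs,
            threshold=params.fallback_threshold,
            fallback_used=True,
        )

    # lowest-ISI peak = intra-burst mode; tallest peak at larger ISI = background
    first = idx[0]
    rest = idx[1:]
    second = rest[np.argmax(smoothed[rest])]
    p_low, p_high = centers[first], centers[second]
    raw = float(np.sqrt(p_low * p_high))  # geometric mean = centre on log scale
    threshold = float(np.clip(raw, params.threshold_min, params.threshold_max))
    return ThresholdDiagnostics(
        bin_edges=10**edges,
        counts=smoothed,
        peaks=peak_locs,
        threshold=threshold,
        fallback_used=False,
        clamped=threshold != raw,
        paired_peaks=(float(p_low), float(p_high)),
    )


def detect_network_bursts(
    pooled: PooledTrain,
    params: NetBurstParams = NetBurstParams(),
    threshold: float | None = None,
    merge_within_threshold: bool = True,
) -> list[NetworkBurst]:
    """Detect network bursts on the pooled train.

    Every index i whose ISI_N span is below the threshold marks spikes
    i..i+N-1 as in-burst; maximal unions of overlapping marked blocks become
    candidates.  Because the threshold picks out dense burst *cores*, one
    synchronized episode can fragment into a core plus small trailing
    clusters; network bursts are collective sequences of synchronized
    bursts within the detected ISI threshold, so by default candidate
    blocks separated by a quiescent gap shorter than the threshold are
    merged (``merge_within_threshold``).  Candidates holding at least
    ``min_spikes_nb`` spikes are returned.  When ``threshold`` is omitted
    the adaptive estimate is used.
    """
    if threshold is None:
        threshold = adaptive_isi_n_threshold(pooled, params).threshold
    t = pooled.times
    n = params.n_consecutive
    spans = isi_n_spans(t, n)
    if spans.size == 0:
        return []
    seed_idx = np.flatnonzero(spans < threshold)
    if seed_idx.size == 0:
        return []

    # merge marked blocks [i, i+n-1] that overlap (share at least one spike)
    gaps = np.flatnonzero(np.diff(seed_idx) > n - 1)
    boundaries = np.concatenate((gaps, [seed_idx.size - 1]))
    blocks: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries:
        blocks.append((int(seed_idx[prev]), int(seed_idx[b]) + n - 1))
        prev = b + 1

    if merge_within_threshold:
        merged: list[tuple[int, int]] = [blocks[0]]
        for s, e in blocks[1:]:
            ps, pe = merged[-1]
            if t[s] - t[pe] < threshold:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        blocks = merged

    bursts: list[NetworkBurst] = []
    for block_start, block_end in blocks:
        n_spikes = block_end - block_start + 1
        if n_spikes >= params.min_spikes_nb:
            elecs = np.unique(pooled.source_electrode[block_start : block_end + 1])
            bursts.append(
                NetworkBurst(
                    t_start=float(t[block_start]),
                    t_end=float(t[block_end]),
                    n_spikes=int(n_spikes),
                    n_electrodes=int(elecs.size),
                )
            )
    return bursts


def _jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def match_events(
    detected: list[tuple[float, float]] | list[NetworkBurst],
    truth: list[tuple[float, float]],
    min_overlap: float = 0.5,
) -> tuple[float, float]:
    """Greedy one-to-one interval matching; returns (precision, recall).

    Pairs are matched in descending Jaccard order, requiring Jaccard >=
    ``min_overlap``.  With zero detections precision is reported as 1 by
    convention (nothing was falsely claimed).
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    det = [
        (d.t_start, d.t_end) if isinstance(d, NetworkBurst) else tuple(d)
        for d in detected
    ]
    tru = [tuple(x[:2]) for x in truth]
    pairs = []
    for i, d in enumerate(det):
        for j, g in enumerate(tru):
            jac = _jaccard(d, g)
            if jac >= min_overlap:
                pairs.append((jac, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    n_match = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n_match += 1
    precision = n_match / len(det) if det else 1.0
    recall = n_match / len(tru) if tru else 1.0
    return precision, recall
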