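"""Synthetic MEA recordings with planted ground truth.

The generator emulates the phenomenology of cultured cortical networks on a
64-electrode array: homogeneous-Poisson background firing per electrode,
plus synchronized network bursts in which a tunable fraction of electrodes
each emit a short high-frequency spike cluster around a common onset.  An
inhibition perturbation (random spike thinning during an interval, with an
optional ramped recovery) stands in for the operational effect of
chemogenetic silencing on recorded activity.

Every planted event is recorded in :class:`GroundTruth`, so detectors and
metrics can be validated with known answers.  A fixed seed gives
byte-identical output; per-electrode background streams are spawned
hierarchically from the global seed so that adding electrodes does not
perturb existing trains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .spike_io import Recording, SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "GroundTruth",
    "PlantedEvent",
    "simulate",
    "apply_inhibition",
    "scenario",
    "SCENARIOS",
]

_REFRACTORY_FLOOR = 0.001  # s; truncates intra-burst exponential ISIs


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated recording.

    Rates are per second; ``participation`` is the fraction of electrodes
    recruited into each network burst; ``inhibition_factor`` multiplies the
    background and network-burst rates inside ``inhibition_interval``, with
    ``recovery_ramp_s`` linearly restoring the multiplier toward 1 after the
    interval ends.
    """

    n_electrodes: int = 64
    duration: float = 600.0  # s
    bg_rate: float = 0.5  # Hz per electrode
    nb_rate: float = 0.05  # network bursts per second
    participation: float = 0.8
    onset_jitter_sd: float = 0.005  # s
    spikes_per_burst_mean: float = 12.0
    intra_burst_isi_mean: float = 0.004  # s
    inhibition_factor: float = 1.0
    inhibition_interval: tuple[float, float] | None = None
    recovery_ramp_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("bg_rate", "nb_rate", "spikes_per_burst_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must be in [0, 1]")
        if not 0 <= self.inhibition_factor <= 1:
            raise ValueError("inhibition_factor must be in [0, 1]")

    @property
    def expected_burst_span(self) -> float:
        return self.spikes_per_burst_mean * self.intra_burst_isi_mean


@dataclass(frozen=True)
class PlantedEvent:
    start_s: float
    end_s: float
    electrodes: tuple[str, ...]
    n_spikes: int

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


@dataclass
class GroundTruth:
    """Intervals of every planted network burst and per-electrode burst."""

    network_bursts: list[PlantedEvent] = field(default_factory=list)
    electrode_bursts: list[tuple[str, float, float, int]] = field(
        default_factory=list
    )


def _electrode_id(i: int) -> str:
    return f"E{i:02d}"


def _rate_multiplier(t: np.ndarray, params: SimParams) -> np.ndarray:
    """Time-varying rate multiplier for the inhibition/recovery profile."""
    if params.inhibition_interval is None or params.inhibition_factor == 1.0:
        return np.ones_like(t)
    lo, hi = params.inhibition_interval
    m = np.ones_like(t)
    m[(t >= lo) & (t < hi)] = params.inhibition_factor
    if params.recovery_ramp_s > 0:
        ramp = (t >= hi) & (t < hi + params.recovery_ramp_s)
        frac = (t[ramp] - hi) / params.recovery_ramp_s
        m[ramp] = params.inhibition_factor + (1 - params.inhibition_factor) * frac
    return m


def _thin_by_multiplier(
    times: np.ndarray, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Keep each spike with probability equal to the local rate multiplier."""
    if params.inhibition_interval is None or params.inhibition_factor == 1.0:
        return times
    keep = rng.random(times.size) < _rate_multiplier(times, params)
    return times[keep]


def simulate(params: SimParams) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus the ground truth of its planted events.

    Background spikes are homogeneous Poisson per electrode.  Network-burst
    onsets form a Poisson process thinned to a minimum spacing of twice the
    expected burst span, so planted events never merge ambiguously.  Each
    onset recruits ``ceil(participation * n_electrodes)`` electrodes uniformly
    without replacement; each recruited electrode emits a cluster of
    Poisson-many spikes (floor 1) with exponential intra-burst ISIs
    (refractory floor 1 ms) starting at onset plus Gaussian jitter.
    """
    min_spacing = 2 * params.expected_burst_span
    if params.nb_rate > 0 and min_spacing * params.nb_rate > 0.5:
        warnings.warn(
            "network-burst rate is high relative to burst span; "
            "events may be thinned heavily to keep spacing",
            stacklevel=2,
        )

    root = np.random.SeedSequence(params.seed)
    # one child stream per electrode for background, one for network events,
    # one for inhibition thinning
    children = root.spawn(params.n_electrodes + 2)
    event_rng = np.random.default_rng(children[params.n_electrodes])
    thin_rng = np.random.default_rng(children[params.n_electrodes + 1])

    per_electrode: dict[str, list[np.ndarray]] = {
        _electrode_id(i): [] for i in range(params.n_electrodes)
    }

    # background firing
    for i in range(params.n_electrodes):
        rng = np.random.default_rng(children[i])
        n_bg = rng.poisson(params.bg_rate * params.duration)
        bg = np.sort(rng.random(n_bg) * params.duration)
        per_electrode[_electrode_id(i)].append(bg)

    truth = GroundTruth()

    # network-burst onsets: Poisson process with enforced minimum spacing
    if params.nb_rate > 0 and params.participation > 0:
        n_onsets = event_rng.poisson(params.nb_rate * params.duration)
        onsets = np.sort(event_rng.random(n_onsets) * params.duration)
        kept = []
        last = -np.inf
        for o in onsets:
            if o - last >= min_spacing:
                kept.append(o)
                last = o
        n_part = int(np.ceil(params.participation * params.n_electrodes))
        for onset in kept:
            elecs = event_rng.choice(
                params.n_electrodes, size=n_part, replace=False
            )
            ev_spikes: list[float] = []
            ev_elecs: list[str] = []
            for e in np.sort(elecs):
                eid = _electrode_id(int(e))
                jitter = event_rng.normal(0.0, params.onset_jitter_sd)
                n_sp = max(1, int(event_rng.poisson(params.spikes_per_burst_mean)))
                isis = np.maximum(
                    event_rng.exponential(params.intra_burst_isi_mean, n_sp),
                    _REFRACTORY_FLOOR,
                )
                t = onset + jitter + np.cumsum(isis)
                t = t[(t >= 0) & (t < params.duration)]
                if t.size == 0:
                    continue
                per_electrode[eid].append(t)
                ev_spikes.extend(t.tolist())
                ev_elecs.append(eid)
                truth.electrode_bursts.append(
                    (eid, float(t[0]), float(t[-1]), int(t.size))
                )
            if ev_spikes:
                truth.network_bursts.append(
                    PlantedEvent(
                        start_s=float(min(ev_spikes)),
                        end_s=float(max(ev_spikes)),
                        electrodes=tuple(ev_elecs),
                        n_spikes=len(ev_spikes),
                    )
                )

    trains: dict[str, SpikeTrain] = {}
    for eid, chunks in per_electrode.items():
        t = np.sort(np.concatenate(chunks)) if chunks else np.empty(0)
        t = _thin_by_multiplier(t, params, thin_rng)
        t = np.unique(t)  # strictly increasing invariant
        trains[eid] = SpikeTrain(eid, t)

    meta = {"simulated": True, "seed": params.seed}
    rec = Recording(trains=trains, duration=params.duration, metadata=meta)
    return rec, truth


def apply_inhibition(
    recording: Recording,
    interval: tuple[float, float],
    keep_prob: float,
    seed: int = 0,
) -> Recording:
    """Thin spikes inside ``interval``, keeping each with ``keep_prob``.

    Models the recorded effect of chemogenetic silencing as random spike
    deletion; spikes outside the interval are untouched.
    """
    if not 0 <= keep_prob <= 1:
        raise ValueError("keep_prob must be in [0, 1]")
    lo, hi = interval
    rng = np.random.default_rng(seed)
    trains = {}
    for eid in recording.electrode_ids:
        t = recording.trains[eid].times
        inside = (t >= lo) & (t < hi)
        keep = ~inside | (rng.random(t.size) < keep_prob)
        trains[eid] = SpikeTrain(eid, t[keep])
    meta = dict(recording.metadata)
    meta["inhibition"] = {"interval": (lo, hi), "keep_prob": keep_prob}
    return Recording(trains=trains, duration=recording.duration, metadata=meta)


# Presets spanning the activity regimes seen across in vitro development:
# uncorrelated tonic firing, sparse early bursting (small network bursts of
# a few tens of pooled spikes, the regime typical of baseline recordings
# before perturbation), mature network bursting, and hypersynchronous
# bursting with near-total electrode recruitment.
SCENARIOS: dict[str, SimParams] = {
    "asynchronous-tonic": SimParams(
        bg_rate=1.0,
        nb_rate=0.0,
        participation=0.0,
    ),
    "sparse-bursting": SimParams(
        bg_rate=0.3,
        nb_rate=0.05,
        participation=0.25,
        spikes_per_burst_mean=3.0,
    ),
    "mature-bursting": SimParams(
        bg_rate=0.5,
        nb_rate=0.05,
        participation=0.6,
        spikes_per_burst_mean=10.0,
    ),
    "hypersynchronous": SimParams(
        bg_rate=0.2,
        nb_rate=0.15,
        participation=0.95,
        spikes_per_burst_mean=15.0,
    ),
}


def scenario(name: str, **overrides) -> SimParams:
    """Return a documented preset parameter set, optionally overridden."""
    try:
        base = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
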