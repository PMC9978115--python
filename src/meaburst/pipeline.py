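"""Experiment orchestration: many recordings -> metric table -> statistics.

A manifest row describes one recording: where it comes from (a spike-table
CSV path or a ``scenario:<name>`` simulation preset), its condition group
(e.g. CTRL / PBS / DCZ), its day in vitro, its protocol phase and its
replicate index.  ``run`` loads or simulates each row, splits treatment
recordings into their 20-min phases, detects bursts and network bursts
(re-estimating the adaptive threshold for every phase), computes the metric
vector, and finally runs the gated pairwise statistics per metric and
timepoint.  All randomness derives from the single manifest-level seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_metrics import compute_summary
from .burst_detection import (
    BurstParams,
    NetBurstParams,
    adaptive_isi_n_threshold,
    detect_bursts,
    detect_network_bursts,
)
from .group_stats import compare_table
from .spike_io import (
    PhasePlan,
    Recording,
    flatten,
    read_spike_table,
    segment,
    write_results,
)
from .synthetic_data import SimParams, scenario, simulate

logger = logging.getLogger(__name__)

__all__ = ["ExperimentManifest", "run", "analyze_recording", "summarize"]

MANIFEST_COLUMNS = ["source", "condition", "div", "phase", "replicate"]
PHASE_LEN_S = 1200.0  # one protocol phase = 20 min
TREATMENT_ORDINALS = ["1st", "2nd", "3rd"]


@dataclass
class ExperimentManifest:
    """Rows of recordings plus shared parameters and the global seed."""

    rows: pd.DataFrame
    burst_params: BurstParams = field(default_factory=BurstParams)
    net_params: NetBurstParams = field(default_factory=NetBurstParams)
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        key = self.rows[["condition", "div", "phase", "replicate"]]
        if key.duplicated().any():
            raise ValueError(
                "manifest (condition, div, phase, replicate) rows not unique"
            )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ExperimentManifest":
        return cls(rows=pd.read_csv(path), **kwargs)


def _row_seed(manifest_seed: int, row_index: int) -> int:
    """Stable per-row sub-seed below 2**31."""
    return int(
        np.random.SeedSequence([manifest_seed, row_index]).generate_state(1)[0]
        % (2**31)
    )


def _load_row(row: pd.Series, seed: int) -> Recording:
    source = str(row["source"])
    if source.startswith("scenario:"):
        name = source.split(":", 1)[1]
        params = scenario(name, seed=seed)
        rec, _ = simulate(params)
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"manifest source not readable: {source}")
        rec = read_spike_table(path)
    rec.metadata.update(
        condition=str(row["condition"]),
        div=int(row["div"]),
        phase=str(row["phase"]),
        replicate=int(row["replicate"]),
    )
    return rec


def _phase_recordings(rec: Recording) -> list[Recording]:
    """Split a treatment recording into its 20-min phases, else pass through."""
    phase = rec.metadata.get("phase", "")
    n_phases = int(round(rec.duration / PHASE_LEN_S))
    if phase == "treatment" and n_phases > 1:
        labels = [
            f"treatment_{TREATMENT_ORDINALS[i]}" for i in range(n_phases)
        ]
        plan = PhasePlan.equal_phases(labels, rec.duration)
        return segment(rec, plan)
    return [rec]


def analyze_recording(
    rec: Recording,
    burst_params: BurstParams = BurstParams(),
    net_params: NetBurstParams = NetBurstParams(),
) -> tuple[dict, dict]:
    """Detect bursts and network bursts, compute the metric vector.

    Returns (metrics dict, provenance dict with the adaptive threshold and
    fallback flag).
    """
    bursts = []
    for eid in rec.electrode_ids:
        bursts.extend(detect_bursts(rec.trains[eid], burst_params))

    provenance: dict = {"n_spikes": rec.n_spikes}
    if rec.n_spikes >= net_params.n_consecutive:
        pooled = flatten(rec)
        diag = adaptive_isi_n_threshold(pooled, net_params)
        nbs = detect_network_bursts(pooled, net_params, diag.threshold)
        provenance.update(
            adaptive_threshold_s=diag.threshold,
            fallback_used=diag.fallback_used,
        )
    else:
        nbs = []
        provenance.update(adaptive_threshold_s=None, fallback_used=None)

    summary = compute_summary(rec, bursts, nbs)
    metrics = summary.as_dict()
    return metrics, provenance


def run(manifest: ExperimentManifest, out_dir: str | Path) -> Path:
    """Execute the full experiment described by a manifest.

    Writes ``metric_table.csv`` (long format), ``summary.csv`` (mean +- SEM
    per group/timepoint/metric), ``comparisons.csv`` and ``run_log.json``
    into ``out_dir``; returns ``out_dir``.
    """
    out_dir = Path(out_dir)
    unreadable = [
        str(r["source"])
        for _, r in manifest.rows.iterrows()
        if not str(r["source"]).startswith("scenario:")
        and not Path(str(r["source"])).exists()
    ]
    if unreadable:
        raise FileNotFoundError(
            "unreadable manifest sources: " + ", ".join(unreadable)
        )

    metric_rows = []
    run_log = {"version": __version__, "seed": manifest.seed, "recordings": []}
    for idx, row in manifest.rows.reset_index(drop=True).iterrows():
        seed = _row_seed(manifest.seed, int(idx))
        rec = _load_row(row, seed)
        for phase_rec in _phase_recordings(rec):
            metrics, provenance = analyze_recording(
                phase_rec, manifest.burst_params, manifest.net_params
            )
            rec_id = (
                f"{row['condition']}-div{row['div']}-r{row['replicate']}"
            )
            timepoint = f"div{row['div']}:{phase_rec.metadata['phase']}"
            for metric, value in metrics.items():
                metric_rows.append(
                    {
                        "recording_id": rec_id,
                        "group": str(row["condition"]),
                        "timepoint": timepoint,
                        "metric": metric,
                        "value": value,
                    }
                )
            run_log["recordings"].append(
                {
                    "recording_id": rec_id,
                    "timepoint": timepoint,
                    "source": str(row["source"]),
                    "row_seed": seed,
                    **{
                        k: v
                        for k, v in provenance.items()
                        if not isinstance(v, np.ndarray)
                    },
                }
            )

    metric_table = pd.DataFrame(
        metric_rows,
        columns=["recording_id", "group", "timepoint", "metric", "value"],
    )
    tables = {
        "metric_table": metric_table,
        "summary": summarize(metric_table),
        "comparisons": compare_table(metric_table),
    }
    write_results(tables, out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=float)
    return out_dir


def summarize(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM (SD / sqrt(n)) per (group, timepoint, metric).

    SEM is undefined (NaN) for a single observation.
    """
    if metric_table.empty:
        return pd.DataFrame(
            columns=["group", "timepoint", "metric", "mean", "sem", "n"]
        )
    grouped = (
        metric_table.dropna(subset=["value"])
        .groupby(["group", "timepoint", "metric"], sort=True)["value"]
    )
    out = grouped.agg(
        mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="count",
    ).reset_index()
    return out
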