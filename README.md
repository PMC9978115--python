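# meaburst

Burst and network-burst analysis for multi-electrode array (MEA) spike
trains from cultured neuronal networks, with a synthetic recording
generator and the group-comparison statistics used in small-n
electrophysiology studies.

Cultured cortical networks develop from uncorrelated tonic firing into
coordinated network bursts — episodes of near-simultaneous bursting across
many electrodes.  Quantifying how bursting dynamics change across
development or under perturbation (e.g. chemogenetic silencing of
excitatory transmission) requires a reproducible pipeline from raw spike
times to per-recording metrics to between-group statistics.  `meaburst`
provides that pipeline for anyone working with spike-time exports from MEA
systems: experimentalists comparing conditions across days in vitro, and
methodologists who need planted-ground-truth recordings to validate burst
detectors.

## Methods at a glance

* **Bursts** (per electrode): maximal runs of ≥ 4 spikes with every
  inter-spike interval ISI < 100 ms.
* **Network bursts** (pooled train): the span of six consecutive pooled
  spikes, ISI₆(i) = t[i+5] − t[i], is histogrammed on a log scale; the
  bimodal histogram's two peaks (intra-burst and background modes) are
  centred on the log scale — threshold = √(p₁·p₂) — and clamped to
  [12, 300] ms.  Spikes with ISI₆ below the threshold seed network bursts
  (minimum 6 spikes).
* **Rates**: channel rate f = (spikes − 1)/Δt; instantaneous rate
  f_w = spikes/(n·Δt) on a 1 s window stepped by 0.1 s over the n active
  electrodes.
* **Burstiness index**: fraction of total activity in the 15% most active
  windows, rescaled to [0, 1]; **coherence index**: SD/mean of the
  instantaneous-rate series.
* **Statistics**: Shapiro–Wilk normality gate per group, then Welch's
  t-test (all groups normal) or the Conover–Iman rank test, Bonferroni
  corrected over the pairwise family.
* **Generator**: Poisson background per electrode plus planted network
  bursts with tunable participation, jitter and intra-burst ISI; inhibition
  as seeded spike thinning.  Every planted event is recorded as ground
  truth.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```python
from meaburst import (scenario, simulate, flatten, detect_bursts,
                      adaptive_isi_n_threshold, detect_network_bursts,
                      compute_summary)

rec, truth = simulate(scenario("mature-bursting", seed=42))
bursts = [b for eid in rec.electrode_ids
          for b in detect_bursts(rec.trains[eid])]
pooled = flatten(rec)
diag = adaptive_isi_n_threshold(pooled)
nbs = detect_network_bursts(pooled, threshold=diag.threshold)
s = compute_summary(rec, bursts, nbs)
print(f"adaptive threshold: {diag.threshold*1000:.1f} ms")
print(f"bursts: {len(bursts)}, network bursts: {len(nbs)}")
print(f"burstiness index: {s.burstiness_index:.3f}")
print(f"coherence index: {s.coherence_index:.3f}")
```

Output:

```
adaptive threshold: 12.0 ms
bursts: 1142, network bursts: 32
burstiness index: 0.403
coherence index: 1.692
```

The simulated 64-electrode, 10-min recording planted 30 synchronized
events; the adaptive ISI₆ threshold lands on the 12 ms clamp floor (the
intra-burst and background modes are far apart, so their log-centre falls
below the floor), and the detector reports 32 network bursts covering the
30 planted events plus two residual background coincidences.  A burstiness
index of 0.40 and coherence index of 1.69 are typical of a moderately
synchronized bursting culture; a pure-Poisson recording scores under 0.05
and about 0.12 on the same indices.

## Command line

```bash
meaburst simulate --scenario hypersynchronous --seed 1 --out sim/
meaburst detect sim/spikes.csv --duration 600 --out det/
meaburst metrics sim/spikes.csv --duration 600 --out metrics.json
meaburst run manifest.csv --seed 1 --out results/
```

`run` takes a manifest CSV (`source,condition,div,phase,replicate`) where
`source` is a spike-table path or `scenario:<preset>`, splits 1-h treatment
recordings into three 20-min phases, computes all metrics per phase, and
writes the metric table, group mean ± SEM summary, pairwise comparison
table and a provenance log.

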