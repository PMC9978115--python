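# Methods

## Scope and data model

`meaburst` analyses spike-time tables from multi-electrode array (MEA)
recordings of cultured neuronal networks.  The unit of analysis is a
`Recording`: a set of per-electrode spike trains (seconds, strictly
increasing) with a known duration and condition metadata.  All times are
stored in SI seconds; thresholds quoted in milliseconds in the burst
literature are converted at the parameter boundary only.  Raw-voltage spike
detection and spike sorting are upstream of this package and out of scope —
the input is the spike-time table a recording system exports.

Boundary conventions that the data model fixes (they matter for the
conservation properties the tests assert):

* Phase windows are half-open `[start, end)`; a spike exactly on a boundary
  belongs to the later phase.  Segmenting a recording into phases conserves
  total spike count over the planned span.
* Duplicate timestamps on one electrode are collapsed on read (one electrode
  cannot physically report two spikes at one instant); simultaneous spikes
  on different electrodes are kept, ordered stably by electrode id in the
  pooled train.
* When a table carries no duration, the last spike time is used and the
  recording is flagged `duration_inferred`, so rate denominators remain
  auditable.

## Burst detection

**Single-electrode bursts** are maximal runs of at least 4 spikes whose
every inter-spike interval is strictly below 100 ms (`BurstParams`,
configurable).  Burst boundaries are the first and last member spike times.
The detector is exact: tests compare it against an independent O(n²)
enumeration of all maximal qualifying runs on randomized trains.

**Network bursts** are detected on the flattened (pooled, time-sorted)
train.  The span of six consecutive pooled spikes, ISI₆(i) = t[i+5] − t[i],
is histogrammed on a log₁₀ scale (10 bins per decade, padded past the
smoothing reach, 3-bin moving-average smoothing).  In a bursting network
this histogram is bimodal: a low mode from intra-burst spacing and a high
mode from background spacing.  The lowest-ISI peak is paired with the
tallest peak at strictly larger ISI, and the threshold is their geometric
mean (the centre on the log scale), clamped to [12, 300] ms.  Peaks are
strict local maxima with prominence ≥ 5% of the tallest bin.  If fewer than
two peaks exist (unimodal activity), a fixed 100 ms fallback is used and
flagged in the diagnostics rather than failing the recording.

Spikes i…i+5 are marked in-burst wherever ISI₆(i) is below the threshold;
maximal unions of overlapping marked blocks form candidates.  Because the
ISI₆ criterion picks out dense burst *cores*, one synchronized episode can
fragment into a core plus small trailing clusters as slower electrodes
finish.  Network bursts are collective sequences of synchronized bursts
lying within the detected ISI threshold of one another, so candidate blocks
separated by a quiescent gap shorter than the threshold are merged (the
standard choice in the log-ISI burst-detection literature; it can be
disabled via `merge_within_threshold=False`).  Candidates with at least 6
spikes are reported with their distinct-electrode counts.

ISI₆ windows are evaluated at every spike index (overlapping), not at
disjoint strides.  The span convention (5 gaps) makes the 12–300 ms clamp
dimensionally sensible for pooled 64-electrode trains.

## Activity metrics

* **Channel firing rate**: f = (spikes − 1)/Δt with Δt the first-to-last
  spike span of that channel; undefined (excluded, not zeroed) below two
  spikes.  The recording-level mean averages per-electrode rates over
  electrodes with ≥ 2 spikes.
* **Instantaneous rate**: pooled spike counts on a 1 s moving window
  stepped by 0.1 s, divided by (n_active × width).  An electrode is
  *active* when its overall rate is ≥ 0.1 Hz (≥ 6 spikes/min,
  configurable); the denominator is fixed per recording, not per window.
* **Burstiness index**: the fraction f15 of total windowed activity carried
  by the ⌈15%⌉ most active windows.  f15 is bounded below by 0.15 (the top
  15% always carry at least their proportional share), so the headline
  index is rescaled to (f15 − 0.15)/0.85 ∈ [0, 1]; the raw f15 is always
  reported alongside.
* **Coherence index**: population SD divided by mean of the
  instantaneous-rate series (a coefficient of variation).  A recording is
  one fixed series, not a sample, hence population SD; at the ~6000-window
  scale of a 10-min recording the distinction is negligible anyway.
* **Composition statistics**: mean burst duration; mean inter-burst
  interval computed within each electrode (over electrodes with ≥ 2 bursts)
  then averaged across electrodes, so high-burst electrodes do not
  dominate; network IBI analogous on the pooled detections; fractions of
  spikes inside (closed) burst intervals of their own electrode and inside
  network-burst intervals; and the spikes-per-burst occurrence histogram.
  Undefined means are reported as absent (`None`/NaN), never as 0.

## Synthetic recordings

The generator produces MEA-like recordings with known ground truth so every
detector and metric is testable without external data.  Background firing
is homogeneous Poisson per electrode.  Network-burst onsets form a Poisson
process thinned to a minimum spacing of twice the expected burst span, so
planted events never merge ambiguously.  Each onset recruits
⌈participation × n⌉ electrodes uniformly without replacement; each recruited
electrode emits Poisson-many spikes (floor 1) with exponential intra-burst
ISIs truncated at a 1 ms refractory floor, starting at onset plus Gaussian
jitter.  Per-electrode background streams are spawned hierarchically from
the one seed, so adding electrodes never perturbs existing trains; a fixed
seed gives byte-identical output.

Chemogenetic inhibition is modelled operationally as spike thinning — each
spike inside the treatment interval is kept with probability `keep_prob` —
not as membrane-level silencing.  `SimParams.inhibition_factor` provides the
generative variant (rate suppression with an optional linear recovery
ramp).

Presets (defaults chosen once as representative regimes, in order of
increasing synchrony):

| preset | bg rate | NB rate | participation | spikes/electrode |
|---|---|---|---|---|
| asynchronous-tonic | 1.0 Hz | 0 | 0 | — |
| sparse-bursting | 0.3 Hz | 0.05/s | 0.25 | 3 |
| mature-bursting | 0.5 Hz | 0.05/s | 0.6 | 10 |
| hypersynchronous | 0.2 Hz | 0.15/s | 0.95 | 15 |

All presets use 64 electrodes, 600 s, 5 ms onset jitter and 4 ms intra-burst
ISI.  `sparse-bursting` emulates the early-baseline regime in which network
bursts carry only a few tens of pooled spikes; it is the right substrate for
the inhibition experiment, because 90% spike deletion pushes such events
below detectability (dense mature bursts of several hundred spikes survive
thinning as detectable — thinning reduces their size, not their count).

What the generator does **not** emulate: biophysical neuron/synapse
dynamics, developmental GABA switching, electrode-specific noise or drift,
spatial structure on the array, and burst-internal rate profiles
(accelerando/decelerando).  Passing tests therefore demonstrate correctness
of the detection and statistics machinery on well-posed synthetic ground
truth, not biological fidelity of any particular parameter set.

## Group statistics

Each metric at each timepoint is compared across condition groups.  Every
group is first screened with the Shapiro–Wilk test; only if *all* groups
have p ≥ 0.05 (the conservative reading) is the parametric branch used.
Parametric: Welch's unequal-variance t-test.  Non-parametric: the
Conover–Iman pairwise test on joint ranks with the tie-corrected
Kruskal–Wallis statistic, t-distributed with N − k degrees of freedom
(implemented directly; tests verify it against a 10 000-shuffle permutation
null).  Groups of n < 3 cannot be screened and fall to the rank branch with
a warning.  Raw p-values are Bonferroni corrected; the default family is
all pairwise comparisons within one metric-timepoint (m = 3 for three
groups), with `family="all"` additionally multiplying by the number of
timepoints of that metric.  No continuity corrections are added: at the
n = 5–6 networks per group typical of these experiments the standard
definitions are used as-is.

A calibration harness (`type_i_calibration`) simulates identical groups and
measures the family-wise false-rejection rate; under the three-group,
n = 6 null it stays at or below the nominal α = 0.05 plus Monte-Carlo error.

## Pipeline

`pipeline.run` executes an experiment manifest: each row is loaded (CSV) or
simulated (preset), treatment recordings are split into their three 20-min
phases (phases are first-class analysis rows, and the adaptive ISI₆
threshold is re-estimated for every phase), detection and metrics run per
phase, and the long-format metric table feeds the group statistics.  Every
output row is traceable to a `run_log.json` entry recording the parameters,
the adaptive threshold chosen and any fallback flags.  All per-row seeds
derive from the manifest seed, so a rerun is byte-identical.

## Numerical and sizing choices

* Ties at exactly a threshold never join a burst (strict `<`), matching the
  "lower than a threshold" rule.
* Histogram peaks on plateaus resolve to the plateau centre; thresholds are
  therefore accurate to about one histogram bin (a factor of 10^0.1 ≈ 1.26).
* Interval matching for planted-event recovery is greedy one-to-one by
  descending Jaccard overlap with a 0.5 floor; with zero detections,
  precision is reported as 1 by convention.
* Validation problem sizes were chosen to exercise the asymptotics while
  keeping the whole suite fast: 10 simulation seeds for recovery and
  ordering properties, 20 for the Poisson burstiness control, 2000
  replicates for the Type-I calibration, 10 000 shuffles for the
  permutation oracle, 1000 random trains for the brute-force equivalence.

## Known limitations

* The adaptive threshold assumes an identifiable bimodal ISI₆ histogram;
  strongly multimodal activity (mixed burst scales) pairs the lowest mode
  with the tallest remaining mode, which may not be the intended background
  mode in pathological cases.  Diagnostics expose all detected peaks.
* The burstiness index depends on the active-electrode rule through the
  window series; recordings with many near-threshold electrodes can move
  between denominators.
* `mean_firing_rate` averages per-electrode rates; a network-level pooled
  rate is not what is reported, and the two differ when electrode activity
  is heterogeneous.
* The thinning model of inhibition preserves dense network bursts by
  construction; only their spike content shrinks.  Conclusions about burst
  ablation require the sparse-bursting regime or the generative
  `inhibition_factor`.
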