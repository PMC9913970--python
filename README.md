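# ctltrack

Analysis of intratumoral CD8⁺ T-cell (CTL) motility from 3D cell tracks,
together with a calibrated synthetic-track generator, for studies of how
cytokine-receptor signaling (IL-1R, IL-18R) shapes T-cell migration and
target engagement in pancreatic tumors and tumor spheroids.

## The problem

Intravital two-photon imaging of a tumor in a dorsal skinfold chamber — or of
a Matrigel tumor spheroid — yields xyzt tracks of fluorescently labelled
CTLs, sampled every Δt = 30 s over 30 min in a 509 × 509 × 60 µm volume.
From these tracks the questions are: how fast do the cells move, how far do
they get, how often and how long do they stop (a stop is a surrogate for a
cytotoxic contact with a target cell), and does this behaviour differ
between cells inside the tumor, near its surface, and in the periphery —
and between wild-type and receptor-deficient T cells?

`ctltrack` implements the full analysis chain:

- **Track model** (`ctltrack.tracks`) — tidy and Imaris-position CSV
  dialects, gap-aware `Track`/`TrackSet` containers, and greedy
  mutual-nearest-neighbour spot linking for unlinked detections.
- **Compartments** (`ctltrack.compartments`) — signed distance to an
  analytic sphere or a watertight triangle mesh; per-spot and
  time-majority per-track classification into **infiltrating** (d ≤ 0),
  **approaching** (0 < d < 10 µm) and **peripheral** (d ≥ 10 µm);
  median-based drift correction.
- **Motility metrics** (`ctltrack.metrics`) — instantaneous velocity
  v_i = ‖p_i − p_{i−1}‖/Δt (µm/min); mean track speed (path/duration);
  track displacement length ‖p_n − p_0‖; pausing phases (maximal runs of
  intervals with v_i < threshold, ≥ 30 s); and the arrest coefficient
  (fraction of intervals below threshold). Thresholds: 4 µm/min in vivo,
  2 µm/min in spheroids.
- **Rejection kinetics** (`ctltrack.kinetics`) — relative spheroid volume
  100 · V(18 h)/V(4 h) per spheroid, summarized per condition.
- **Group inference** (`ctltrack.inference`) — pooled track-level
  two-sample Kolmogorov–Smirnov tests and per-experiment-mean Welch
  t-tests, both two-tailed at α = 0.05.
- **Synthetic data** (`ctltrack.simulate`) — a two-state (motile/arrested)
  hidden-Markov correlated random walk with measurement noise, calibrated
  so cohorts reproduce published group statistics; scenario presets and
  YAML configs.
- **CLI** (`ctltrack.cli`) — `ctltrack simulate|link|classify|metrics|
  kinetics|compare|run` with a provenance manifest per run.

## Worked example

```python
from ctltrack import (scenario_presets, generate_cohort, drift_correct,
                      summarize_cohort, compare_metric)

sc = scenario_presets()["dsfc_pancova"]          # in vivo PancOVA scenario
ts, truth = generate_cohort(sc, seed=1)          # 900 tracks, 61 frames
ts = drift_correct(ts)
summary = summarize_cohort(ts, sc.surface, threshold=sc.pause_threshold)

inf = summary[summary.compartment == "infiltrating"]
print(inf.groupby("group").mean_track_speed.mean().round(2))
print(compare_metric(summary, "Il18r_ko", "WT", mode="pooled"))
```

Output:

```
group
Il18r_ko    8.24
Il1r_ko     4.85
WT          4.75
Name: mean_track_speed, dtype: float64
ComparisonResult(test='ks_2samp_asymp', statistic=0.46,
                 p_value=1.4710231686679953e-29, n_a=300, n_b=300)
```

IL-18R-deficient CTLs inside the tumor move at ≈ 8 µm/min versus ≈ 4.8
µm/min for wild-type and IL-1R-deficient cells (single-seed cohort means;
the calibration targets are 8.05 / 4.85 / 4.83), and the pooled KS test
flags the speed distribution shift as highly significant.

The same pipeline runs from the shell:

```bash
ctltrack run --scenario dsfc_pancova --seed 1 --out-dir out/ --plots
ctltrack run --scenario rejection_kinetics --seed 1 --out-dir out_kin/
```

writing per-track summaries, compartment counts, comparison JSON, and a
manifest with input/output hashes.

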