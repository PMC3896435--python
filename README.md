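# blockfc

Block-wise windowed functional connectivity and activation measures for
fMRI block designs, with a fully simulated bimanual finger-tapping testbed.

## The problem

Neurofeedback and single-trial decoding need brain measures that can be read
out from *one* task block rather than averaged over a session.  For a
block-design motor task (unimanual and bimanual finger tapping at several
speeds), two families of single-block measures are of interest:

* **windowed functional connectivity** — the Pearson correlation r between
  the time courses of two regions of interest (ROIs), computed inside a short
  window anchored to each block onset, and variance-stabilised with the
  Fisher transform z = atanh(r);
* **activation level** — the percent signal change
  100·(task mean − rest mean)/rest mean of a single ROI, comparing a block's
  BOLD plateau against its preceding rest period.

Three windows are used per block (TR = 1 s, half-open convention): a 26-s
*full task* window [+2 s, +28 s) spanning the rise and decline of the BOLD
response, a 12-s *steady state* window [+10 s, +22 s) covering only the
plateau, and a 12-s *rest* window [−12 s, 0 s).

`blockfc` implements the complete analysis path — behavioral scoring of
button-press logs, temporal preprocessing (leading-volume discard, Fourier
basis high-pass, motion/white-matter/ventricle nuisance regression),
localizer-based ROI definition (top-20 voxels of the suprathreshold cluster
nearest a seed coordinate), block-wise measures, and the fixed-effects
inferential layer (polynomial-contrast GLMs, midpoint-threshold
classification with sensitivity/specificity, brain–behavior criterion
validity, and the measure × speed × coordination comparison ANOVA).

Because raw data of this kind are rarely shareable, the package ships a
first-class simulator: a counterbalanced 16-condition session (4 tapping
sequences of increasing bimanual coordination demand × 4 right-finger speeds,
20-s task / 20-s rest, 8 repetitions per condition = 128 task blocks over 8
runs), with boxcar ⊗ two-gamma-HRF evoked responses, coupling-controlled
shared signals, nuisance traces, AR(1) noise, jittered tapping logs with
rule-matched error injection, and small 4D localizer volumes.  Every injected
parameter is recorded, so recovery can be asserted exactly.

## Worked example

```python
import blockfc as b

cfg = b.SimulationConfig(seed=1)                      # 128 blocks, 16 conditions
design, log, tcs, truth = b.simulate_session(cfg)
clean, shifted = b.preprocess_session(tcs, design)    # discard 5 vols, high-pass,
behavior = b.score_log(log, shifted)                  #   nuisance regression
table = b.build_block_measure_table(clean, shifted,
                                    pairs=[("left_M1", "right_M1")],
                                    behavior=behavior)

print(table.groupby("sequence")["left_M1-right_M1__steady_state__z"].mean().round(2))
res = b.threshold_classify(table, "left_M1-right_M1__full_task__z")
print(f"sensitivity {res.sensitivity:.1f}%, specificity {res.specificity:.1f}%")
con = b.contrast_glm(table, "left_M1-right_M1__steady_state__z", "coordination")
print(f"coordination linear contrast: F = {con.F:.1f}, p = {con.p:.2g}")
```

prints

```
sequence
alternating    1.83
synchronous    1.23
unbalanced     2.33
unimanual      0.67
Name: left_M1-right_M1__steady_state__z, dtype: float64
sensitivity 96.9%, specificity 96.9%
coordination linear contrast: F = 321.2, p = 3.2e-36
```

Reading: the mean steady-state connectivity between left and right primary
motor cortex rises with bimanual coordination demand (unimanual lowest,
unbalanced highest — the injected coupling ordering); a simple midpoint
threshold on the single-block full-task z detects whether a block was
bimanual with ~97% sensitivity and specificity; and the linear contrast over
coordination demand is strongly positive.

## Command line

```bash
blockfc run --out runs/demo --seed 1          # full pipeline, default config
blockfc report --out runs/demo                # print the statistics report
```

A run directory holds stage-numbered subfolders (`01_simulate` …
`05_stats`), a provenance manifest (config hash, seed, stage status), and a
`config.yaml` that reproduces the run.  Stages are cached by config hash, so
deleting one stage and re-running resumes from the others.  Subcommands
`simulate`, `preprocess`, `roi`, `connect`, and `stats` run the pipeline up
to the named stage.

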