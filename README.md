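# attnmod

ROI-based fMRI analysis of **endogenous** (voluntary) versus **exogenous**
(involuntary) covert spatial attention in human visual cortex, packaged as a
tested, fully simulatable pipeline.

The scientific question: when a spatial cue orients attention before
(*pre-cue*) or after (*post-cue*) a brief grating stimulus, how does the
cue-validity effect on stimulus-evoked BOLD activity change across the visual
hierarchy (V1 → V2 → V3 → V3A → hV4 → LO1)?  The package implements the full
analysis chain used to answer it — and a synthetic-data generator with known
ground truth so every stage can be validated without any scan data:

1. **Trial design** — sessions of event-related runs (40 trials each) mixing
   40% pre-cue, 40% post-cue, 10% cue-only and 10% blank trials; cue→stimulus
   SOA 117 ms (exogenous) or 317 ms (endogenous); cue validity 50% / 75%.
2. **Behavior** — a simulated 2-AFC orientation-discrimination observer with
   a cumulative-Gaussian psychometric function, titrated to ~80% correct by a
   3-down-1-up staircase; d′ and median RT per condition and the three-way
   repeated-measures ANOVA.
3. **BOLD synthesis** — event-related runs (TR 1.75 s) built from
   condition-amplitude × HRF responses plus drift and AR(1) noise, and
   block-design localizer runs (16 cycles of 17.5 s).
4. **Localizer voxel selection** — per-voxel sinusoid fit at the cycle
   frequency; keep voxels with response phase in (0, π) and coherence > 0.2.
5. **Event-related GLM** — discard 8 volumes, percent-signal-change
   conversion, linear detrend + 0.01 Hz DCT high-pass, then OLS with twelve
   regressors (8 cue-side × validity × epoch conditions, 2 cue-only, blank,
   eye-movement) on the voxel-averaged ROI time course.
6. **Inference** — the Attentional Modulation Index

   AMI = (V꜀ + c) / mean(V꜀ + c, I꜀ + c, Vᵢ + c, Iᵢ + c),   c = 0.2,

   where V꜀/I꜀ are contralateral valid/invalid amplitudes and Vᵢ/Iᵢ the
   ipsilateral (distractor) ones; AMI = 1 means no modulation.  Group tests:
   AMI-vs-1, per-ROI one-tailed valid > invalid t-tests, OLS regression of
   the group-mean valid−invalid difference on hierarchy rank, and linear
   mixed models of the difference on rank × attention system with
   by-participant random intercepts and slopes (likelihood-ratio p-values).

## Worked example

```python
from attnmod.pipeline import demo_config, run_pipeline

res = run_pipeline(demo_config(seed=0))
one = res.ami_vs_one
print(f"AMI vs 1 (all conditions/ROIs): t({one.df}) = {one.t:.2f}, "
      f"p = {one.p:.4f}, d = {one.cohens_d:.2f}")
for (a, e), h in res.hierarchy.items():
    print(f"{a:10s} {e:4s}-cue hierarchy regression: slope = {h.slope:+.4f}, "
          f"F(1,4) = {h.F:.2f}, p = {h.p:.4f}, R2 = {h.r2:.2f}")
```

prints (demo scale: 5 participants, 2 runs/session, 12 voxels per ROI):

```
AMI vs 1 (all conditions/ROIs): t(4) = 34.91, p = 0.0000, d = 15.61
endogenous pre -cue hierarchy regression: slope = +0.0598, F(1,4) = 133.38, p = 0.0003, R2 = 0.97
endogenous post-cue hierarchy regression: slope = +0.0032, F(1,4) = 0.14, p = 0.7258, R2 = 0.03
exogenous  pre -cue hierarchy regression: slope = -0.0038, F(1,4) = 0.42, p = 0.5530, R2 = 0.09
exogenous  post-cue hierarchy regression: slope = -0.0088, F(1,4) = 3.09, p = 0.1535, R2 = 0.44
```

Read: the AMI exceeds 1 everywhere (attentional orienting boosts the
stimulus-evoked response), and only the *endogenous pre-cue* validity effect
grows along the hierarchy — the simulated regimes are endogenous-pre
increasing, exogenous-pre flat, endogenous-post flat, exogenous-post null,
and the inference chain recovers exactly that qualitative pattern.

The same pipeline is scriptable from the shell:

```bash
attnmod run-all --seed 0 --out results/demo
attnmod simulate --seed 0 --out ws && attnmod localize --workspace ws \
    --attention endogenous --out sel.csv
```

Externally estimated condition-amplitude tables (e.g. a published data
deposit) can be analyzed directly with
`attnmod import-amplitudes` / `attnmod.pipeline.import_amplitude_table`,
after a documented column mapping.

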