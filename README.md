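# videba

Video-based **dynamic body acceleration** as a proxy for metabolic rate in
small fish.

Attaching an accelerometer logger to a 7-gram damselfish is not an option:
the smallest DBA loggers weigh more than the animal tolerates.  `videba`
implements the alternative: track body points in synchronized video from
two cameras, reconstruct the 3D path of the eye, differentiate it into
**VeDBA** (the vectorial magnitude of dynamic body acceleration,
√(a_x² + a_y² + a_z²), in g), and calibrate VeDBA against oxygen
consumption measured simultaneously by intermittent-flow respirometry.
Because the video frame is the Earth frame, no gravity subtraction is
needed — raw trajectory acceleration *is* DBA.

The package covers the full chain for a swim-flume calibration
experiment:

| stage | module | what it does |
| --- | --- | --- |
| I/O | `videba.io_formats` | pose tables (DLC-style or long CSV), DLT coefficient files, oxygen logs, cycle schedules, fish metadata |
| track QC | `videba.trajectory_qc` | likelihood cutoff → cubic-spline refill → Hampel outlier removal (window 29, median±1 s.d.) → refill → 5-sample running mean |
| 3D | `videba.dlt` | 11-coefficient DLT calibration, projection, linear triangulation |
| kinematics | `videba.vedba` | forward finite-difference acceleration, VeDBA, interval means with 0.001–1 g exclusion bounds, replicate pairing |
| respirometry | `videba.respirometry` | last-15-min oxygen slopes, background correction, Ṁ_O2 = −S·V_resp/M_b |
| statistics | `videba.calibration` | power fit Ṁ_O2 = a + b·U^c (SMR = a), net cost, random-intercept mixed model with Satterthwaite tests, marginal/conditional R², boundary-aware LRT, prediction intervals |
| synthetic | `videba.synthetic` | a ground-truthed virtual flume: C² fish motion, two-camera rig with tracker defects, oxygen sawtooth traces |
| orchestration | `videba.pipeline`, `videba.cli` | `run_all` over a study directory; `videba` command-line front-end |

## Worked example

Generate a synthetic 5-fish study (6 flow speeds from 5–30 cm/s, two
replicate cycles each) and run the whole pipeline:

```python
from videba.pipeline import RunConfig, run_all
from videba.synthetic import make_study

make_study("study/", seed=0)
res = run_all(RunConfig(study_dir="study/", out_dir="out/"))
```

which prints nothing itself; `examples/05_full_calibration.py` formats the
results and, at seed 0, reports:

```
pooled power fit: MO2 = 155.67 + 0.437*U^1.74  (SMR = 155.7)
mixed model: MO2 = 158.4 + 268.8*VeDBA + u_i  (slope se 10.6, ddf 24.0, p = 8e-19)
R2 marginal 0.84 (fixed effect), conditional 0.96 (fixed + individual intercepts)
random-intercept LRT: chi2 = 24.1, p = 9e-07
true slope kappa = 250.0
predicted MO2 at VeDBA = 0.2 g for fish A: 180.3 [151.0, 209.6] mg O2/kg/h
```

Reading this: oxygen consumption rises from a standard metabolic rate of
~156 mg O₂ kg⁻¹ h⁻¹ as a power of flow speed; per gram of VeDBA,
Ṁ_O2 rises by ≈269 mg O₂ kg⁻¹ h⁻¹ (the generator's true coupling is
250, within two standard errors); individual identity matters (the
random-intercept LRT is decisive, and conditional R² exceeds marginal
R²); and the fitted model predicts the metabolic rate of a new
observation with a 95% prediction interval.

The other scripts in `examples/` each demonstrate one capability — study
simulation, QC + 3D reconstruction, the VeDBA closed-form check, and
single-cycle respirometry — and print what the numbers mean.

The same chain is available from the shell:

```bash
videba simulate --out study/ --seed 0
videba run-all --study study/ --out out/
```

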