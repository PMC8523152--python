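# reachkin

Analysis pipeline for 2D center-out reaching kinematics, built for
studies of artificial-arm (prosthesis) motor control: it segments raw
manipulandum trajectories into reaches, decomposes endpoint error into
systematic **bias** and stochastic **noise**, measures feedforward
planning quality via the **initial directional error**, runs the
matching group statistics (covariate-adjusted ANCOVA, circular tests,
default Bayes factors), and scores daily prosthesis usage from
questionnaire data. A generative reach simulator with known parameters
makes every stage testable end to end.

It is aimed at motor-control and rehabilitation researchers who have
trial-level 2D trajectories (here: reaches by people with congenital or
acquired upper-limb differences and matched controls) and want a
reproducible, scripted path from raw samples to group inference.

## The measures

For a reach from home **h** = (0,0) to target **g**, with endpoint **e**
at the end of the first submovement (first local speed minimum below 50%
of peak speed, after 8 Hz zero-phase low-pass filtering and a 3.5 cm/s
onset threshold):

* absolute error ‖**e** − **g**‖;
* over a participant's trials, error vectors **eᵢ** − **gᵢ** are
  overlaid on a single notional target and split into
  bias = ‖mean error vector‖ and
  noise = √(Σ‖εᵢ − ε̄‖² / (n−1)) (spatial SD about the centroid,
  pooled over x and y);
  with population divisors, mean‖ε‖² = bias² + variance — an identity
  the code verifies on every decomposition;
* initial directional error = ∠(**p**(t_peak) − **h**, **g** − **h**),
  the angle of the reach direction at peak speed away from the target
  direction (a feedforward-plan proxy); the corrective angle compares
  the direction at peak speed with the direction at movement end.

Group comparisons follow the between-subject ANCOVA design
`artificial-arm measure ~ intact-arm measure + group` (Type III,
sum-to-zero coding) with Tukey HSD post hocs and partial η²; bias
angles use the Watson-Williams circular test; evidence for null results
uses JZS Bayes factors (Cauchy prior on effect size) and Jeffreys
correlation Bayes factors. Prosthesis usage = z(weekly wear time) +
z(PAL score), where PAL is a 27-item activity log scored 0–2 per item
over a 54-point maximum.

## Worked example

Simulate three groups (8 participants each, both arms, 60 reaches per
arm), segment, measure, summarize and test — from Python:

```python
from reachkin import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo", seed=7, n_per_group=8)
res = run_pipeline(cfg)
print(res["stats"][res["stats"]["test"].str.startswith("ancova_group")])
```

or equivalently `reachkin all --seed 7 --out-dir demo` from a shell.
With seed 7 this prints:

```
                              test  statistic   df        p  effect_size
   ancova_group:abs_error_mean_log  13.333951 2,20 0.000209     0.571440
             ancova_group:noise_sd  12.380439 2,20 0.000317     0.553181
             ancova_group:bias_mag   0.304754 2,20 0.740668     0.029574
    ancova_group:init_dir_err_mean  13.239031 2,20 0.000218     0.569689
ancova_group:corrective_angle_mean   7.771976 2,20 0.003182     0.437316
```

The congenital preset inflates planning and execution noise ~1.7×, and
the pipeline recovers exactly that pattern: strong group effects on
absolute error, endpoint noise and initial directional error, no effect
on bias. Mean recovered noise per group (artificial arm): congenital
2.17 cm vs acquired 1.27 cm and control 1.41 cm, against intact-arm
values near 1.15 cm for all groups.

The packaged participant table reproduces the cohort-level results
directly (`reachkin cohort` or `run_cohort_analyses()`):

```
included counts: {'acquired': 14, 'congenital': 18, 'control': 19}
usage-score recomputation r = 1.0000
experience years (acquired vs congenital): t(30) = -7.860, p = 9.02e-09; means 16.05 vs 45.30
usage score: t(30) = -0.250, p = 0.805
```

i.e. the congenital group has accumulated ~29 more years of
artificial-arm experience, yet daily usage does not differ between the
groups.

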