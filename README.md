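# fcage — brain age from functional connectivity

`fcage` predicts a person's chronological age, and their age group, from
resting-state functional connectivity, and explains the predictions at the
level of connectome edges and regions. It is aimed at researchers studying
functional brain aging who work with parcellated BOLD time series (e.g.
100-region Schaefer-style or 64-region BASC-style atlases).

The pipeline:

1. **sFC extraction** — per subject, the static functional connectivity
   matrix of pairwise Pearson correlations r_ij between regional time
   courses; optionally vectorized to the p(p−1)/2 lower-triangle edges.
2. **Models** — small attention-augmented CNNs (`vgg5`, `resnet5`) on the
   p×p matrix: a 4-way softmax head classifies subjects into young
   [20–40], adult [41–55], middle-old [56–69] and old [70–88] bins; a
   linear head regresses age in years. Attention blocks at layers 3 and 4
   learn a softmax weighting λ over spatial positions from projected
   pairwise features and a global descriptor.
3. **Interpretability** — integrated gradients along the straight path
   from an all-zero baseline, IG_i ≈ (x_i − x′_i)·(1/m)Σ_k ∂F/∂x_i,
   aggregated to signed per-ROI node strengths, thresholded edge tables,
   and per-ROI age-trajectory labels (decreasing / inverted-U / flat).
4. **Synthetic cohorts** — a generator that plants decreasing, inverted-U
   and age-constant correlation trajectories into multivariate-normal time
   series, so the entire pipeline is testable without access to any real
   imaging repository.

The neural-network core (convolutions, attention, backprop, integrated
gradients) runs on a compact numpy reverse-mode autodiff engine included
in the package — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from fcage import GeneratorConfig, generate_cohort
from fcage.pipeline import run_end_to_end, attribution_analysis

cohort = generate_cohort(GeneratorConfig(n_subjects=600, seed=1))  # p=32, T=200
res = run_end_to_end(cohort, seed=1, epochs=20)                    # resnet5 + attention

print(round(res["classification"]["report"].accuracy, 1))
print(round(res["regression"]["report"].mae, 2),
      round(res["regression"]["report"].r2, 3))

ana = attribution_analysis(cohort, res["classification"]["model"], res["scaler"])
print(round(ana["localization_ratio"], 1), ana["trajectory_recovery"])
```

Output:

```
80.7
4.97 0.906
73.2 1.0
```

Reading: on a 600-subject synthetic cohort with planted age-dependent
connectivity, the attention ResNet classifies the four age groups at 80.7%
held-out accuracy (chance is 25%) and regresses age with a mean absolute
error of 4.97 years (r² 0.906). Integrated-gradient attributions
concentrate on the planted age-sensitive edges — their median attribution
magnitude is 73× that of uninformative edges — and the node-strength
trajectories recover the planted decreasing/inverted-U labels for all ROIs
incident to planted edges.

The same stages are scriptable from the shell:

```sh
fcage simulate --n 600 --p 32 --t 200 --seed 1 --out data/
fcage extract-fc --timeseries-dir data/timeseries --out data/fc
fcage train --data-dir data/ --task classify --arch resnet5 --seed 1 --out run/
fcage attribute --checkpoint run/checkpoint.npz --data-dir data/ --out attr/
```

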