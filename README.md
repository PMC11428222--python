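# tdslice

Slice-stack classification with **Student-t slice attention** and a
**penalty-weight loss**, for exams that arrive as ordered stacks of 2-D
grayscale slices — the motivating case is knee MRI read for anterior
cruciate ligament (ACL) tears, where the diagnostically relevant slices
cluster in the middle of each series and the first and last few slices are
mostly noise.

The package is aimed at researchers who want the two mechanisms as reusable,
tested components, plus a reproducible training/evaluation/ablation pipeline
and a synthetic phantom generator so everything can be exercised without the
permission-gated clinical data.

## The method

**Slice attention.**  Per-slice backbone features `M ∈ R^{S×C'×H'×W'}` are
pooled into average/max descriptors `X̄, X̃ ∈ R^{S×C'}`; cross-similarities
`S1 = softmax(X̄X̃ᵀ)` and `S2 = softmax(X̃X̄ᵀ)` are averaged into `D` and
reduced to initial per-slice weights `ω` (column sums, normalised).  A
unit-scale Student-t is fitted over slice positions — location
`μ = Σ_s ω_s·s`, degrees of freedom `ν` moment-matched from the weighted
position variance — and the final attention weights are

    W_i = T(x_i; μ, ν) / Σ_j T(x_j; μ, ν),   x_i = 1..S,

applied multiplicatively to the feature maps.  Central slices are
up-weighted, noisy end slices suppressed; the fit adds no learned
parameters and is treated as a constant during backpropagation.

**Penalty-weight loss.**  A cost matrix `W` (unit diagonal, off-diagonal
costs growing with `|i−j|`) defines the objective
`loss = Σ_i W'_ij p_i` with `W'_ii = 0`, `W'_ij = W_ij + 1` — the expected
misclassification cost under the softmax output, a drop-in replacement for
cross-entropy that prices errors by severity and supports asymmetric
overrides (e.g. a missed tear costing more than a false alarm).

**Classifier.**  slices → small CNN trunk → optional attention re-weighting
→ per-slice global avg‖max descriptors → coordinatewise max over slices →
dense head → class probabilities.  Implemented in a compact NumPy layer
library with explicit backward passes and Adam; model gradients are verified
against finite differences in the test suite.

## Worked example

```python
import numpy as np
from tdslice import (SyntheticSpec, generate_dataset, TrainConfig,
                     ablate, ablation_table)

spec = SyntheticSpec(n_exams=250, slice_count_range=(8, 16), seed=1)
stacks = generate_dataset(spec)                 # ~20% positive prevalence
cfg = TrainConfig(max_epochs=10, seed=1)        # tiny backbone, 8:1:1 split
records = ablate(cfg, stacks)                   # 2x2 attention x loss grid
print(ablation_table(records))
```

which prints (numbers from this exact configuration):

```
Model	AUC	ACC	Precision	Recall	Specificity	F1
tiny-CE	0.5500	0.8000	0.0000	0.0000	1.0000	0.0000
tiny-Slice-CE	0.8600	0.9600	1.0000	0.8000	1.0000	0.8889
tiny-Weight	0.6000	0.8000	0.0000	0.0000	1.0000	0.0000
tiny-Slice-Weight	0.7800	0.7200	0.3750	0.6000	0.7500	0.4615
```

Each row is one variant trained with identical seed and splits on the same
synthetic cohort; AUC is threshold-free ranking quality on the 25-exam test
split, the other metrics use the accuracy-maximising threshold fitted on
validation only.  The cohort's end slices carry bright lesion-like
distractors that only differ from true lesions by position, so the
max-fusion baselines hit a false-positive ceiling (here they degenerate to
"predict healthy": precision/recall 0) while the slice-attention variants
filter the ends and rank cleanly.  Single-seed AUCs on 25 exams are coarse
— the package's acceptance experiment averages over five seeds before
comparing variants (five-seed means at this setting: baseline 0.62,
slice 0.89, slice+weight 0.75).

The same workflow is available from a shell:

```bash
tdslice generate --n-exams 250 --out data/
tdslice split --data data/ --out split.json
tdslice train --data data/ --split split.json --max-epochs 10 --out run/
tdslice evaluate --checkpoint run/checkpoint.npz --data data/ --split split.json --out eval/
tdslice ablate --data data/ --split split.json --max-epochs 10 --out ablation/
```

See `examples/` for short narrative scripts covering each capability
(attention weights, penalty loss, synthetic cohorts, training, ablation).

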