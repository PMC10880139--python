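# climat

Forecasting ordinal disease-severity trajectories from multimodal baseline
data — one medical image plus scalar clinical variables — with a
multi-agent transformer and a calibrated multi-task loss.

Degenerative disorders such as knee osteoarthritis or Alzheimer's disease
are graded on ordinal scales, and the clinically useful question is not
only "what grade is this patient at today?" but "what grade will they be at
in one, two, four years?".  This package treats that question as T+1
simultaneous classification tasks predicted in a single forward pass, the
way a clinical consult works: a *radiologist* block (CNN + transformer)
reads the image and produces both a baseline diagnosis and a report-like
state sequence; a *context* block encodes the clinical variables into a
single context vector; a *general practitioner* block fuses the two and
forecasts the severity grade at every horizon through K learnable [CLS]
tokens.  It is aimed at researchers who want a CPU-scale, fully testable
implementation of this architecture and its loss, together with a synthetic
cohort generator that plants a known severity signal so every claim can be
checked end to end.

## The CLUB loss

For a task with logits f, true class c and g = exp(f), the
temperature-scaled cross-entropy at inverse temperature τ ∈ (0, 1] is CE
evaluated on τ·f.  The reverse Hölder inequality bounds it from above by
the **C**alibrated **L**oss based on **U**pper **B**ound:

    L_CLUB = τ · L_CE + (1 − τ) · log Nc,        τ ∈ [0, 1],

a convex combination of the cross-entropy and the log class count, with
equality iff τ = 1.  Since ∂L_CLUB/∂θ = τ · ∂L_CE/∂θ and ∂L_CLUB/∂τ =
L_CE − log Nc, each τ_t is a learnable per-task weight that trades
sharpness against calibration.  The τ_t derive from noise parameters σ_t
through ρ_t = 1/(σ_t² + ε), ρ̃ = softmax(ρ), τ_t = ρ̃_t / max(ρ̃), which
keeps every τ in (0, 1] with max(τ) = 1.  Training minimizes

    L = L_prog + λ · L_cons,

where L_prog averages the per-task CLUB terms over *observed* targets only
(missing follow-up labels are masked out) and L_cons = ‖f0R − f0‖₁ keeps
the radiologist's and practitioner's baseline diagnoses consistent
(λ = 0.5 by default).

The neural network layer (`climat.nn`) is a compact reverse-mode autodiff
engine on numpy — tensors, fused softmax/layer-norm/GELU, im2col 2D/3D
convolutions, Adam — sized for CPU-scale experiments in float64.

## Worked example

```python
import numpy as np
from climat import ClimatForecaster, TrajectoryConfig, generate_cohort, split_cohort

cfg = TrajectoryConfig(n_subjects=400, T=2, n_classes_per_task=(2, 2, 2),
                       noise_sd=0.0, covariate_effect=0.6, seed=7)
records = generate_cohort(cfg)
train_idx, test_idx = split_cohort(records, k=4, seed=7)[0]

model = ClimatForecaster(epochs=30, lr=1e-3, depth_p=2,
                         n_classes_per_task=(2, 2, 2), seed=0)
model.fit([records[i] for i in train_idx])

report = model.evaluate([records[i] for i in test_idx])
for t, (ba, ece) in enumerate(zip(report.ba, report.ece)):
    print(f"horizon {t}: balanced accuracy {ba:.3f}, ECE {ece:.3f}")
print("final temperatures:", np.round(model.log_[-1]["tau"], 3))
```

prints (a minute or so on one core):

```
horizon 0: balanced accuracy 1.000, ECE 0.037
horizon 1: balanced accuracy 0.853, ECE 0.075
horizon 2: balanced accuracy 0.792, ECE 0.071
final temperatures: [0.999 0.999 1.   ]
```

The generator renders images whose band gap encodes the baseline grade and
lets one covariate (BMI) drive the progression rate, so these numbers mean:
the model reads the baseline grade off the image perfectly, forecasts the
two follow-ups well above the ~0.5 chance level of a permuted-label
control, stays calibrated (ECE a few percent), and the temperature
constraint holds (max τ = 1).  `model.attention(record, t)` returns the
imaging attention folded onto the feature grid and the per-variable
clinical attention weights (each renormalized to sum to 1).

The same workflow is available from the shell:

```bash
climat generate --config cohort.yaml --out cohort/ --seed 7
climat train    --cohort cohort/ --config run.yaml --out model.npz --seed 0
climat evaluate --checkpoint model.npz --cohort cohort/ --out metrics.json
climat attend   --checkpoint model.npz --cohort cohort/ --subject subj_00000 \
                --horizon 1 --out attn
```

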