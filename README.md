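# mcatnet

Small-sample multimodal lesion classification: a double-branch,
modality-contribution-aware network for predicting microvascular invasion
(MVI) of hepatocellular carcinoma from segmented multi-phase CT and
multi-sequence MRI, with the training machinery that makes ~100-lesion
cohorts workable and a synthetic cohort generator with a known planted
signal so every claim is testable without patient data.

The package is aimed at researchers studying attention-based multimodal
fusion and small-sample training strategies in medical imaging, and at
anyone who needs a fully inspectable (pure numpy) reference implementation
of this model family.

## The model

Each modality gets a *branch*: an input **modality-channel gate** — a
squeeze-and-excitation unit over the raw channels whose logits carry an
additive radiologist prior `log(p_c / p̄)` (the default CT prior upweights
the arterial phase) — followed by a small residual backbone with SE stage
attention, ending in an L2-normalised embedding and a linear evaluation
head. Branches train in two stages on augmented data:

1. **embedding pretraining** with the triplet margin loss
   `max(0, ‖e_a−e_p‖² − ‖e_a−e_n‖² + m)`,
2. **fine-tuning** of the head with cross-entropy at a reduced embedding
   rate,

and the CT and MRI branches are late-fused, `p = w_ct·p_ct + w_mr·p_mr`,
then jointly updated on lesions that have both modalities. Prediction
routes by availability (CT-only, MRI-only, or fused). Evaluation follows a
stratified 5-fold protocol with accuracy/sensitivity/precision/F1 at the
50% threshold, Mann–Whitney AUC, and Hanley–McNeil Z comparison of AUCs.
Baselines (plain CNN, ResNet-18, SENet-18, ECANet-18) are included.

The synthetic cohort mirrors a 121-lesion clinical composition (49 CT-only,
32 MRI-only, 40 with both; 44 MVI-positive overall) and plants a
standardized per-channel effect `d_c` whose optimal-readout AUC is the
closed form `Φ(√(Σd_c²)/√2)` — the generator is calibrated, so attention
recovery, pretraining benefit, and fusion benefit are measurable against
ground truth. See `docs/methods.md` for the full model and design account.

## Worked example

```python
from mcatnet.cohort import CohortSpec, generate_cohort, planted_bayes_auc
from mcatnet.evaluation import ExperimentSpec, run_cv_experiment
from mcatnet.studies import desk_harness

spec = CohortSpec(side=32)          # default 121-lesion composition
records = generate_cohort(spec)
print(f"{len(records)} lesions, "
      f"{sum(r.label for r in records)} MVI-positive, "
      f"oracle AUC (both modalities) {planted_bayes_auc(spec, 'both'):.3f}")

grid = [ExperimentSpec("CT", "mcat", "two_stage"),
        ExperimentSpec("MRI", "mcat", "two_stage"),
        ExperimentSpec("double", "mcat", "two_stage")]
report = run_cv_experiment(records, grid, seed=1, cfg=desk_harness())
for exp in grid:
    print(f"{exp.descriptor}: mean CV AUC "
          f"{report.mean(exp.descriptor, 'auc'):.3f}")
```

Output from this exact snippet (seed 1, one CPU core, ~4 min):

```
121 lesions, 44 MVI-positive, oracle AUC (both modalities) 0.933
CT/mcat/two_stage: mean CV AUC 0.449
MRI/mcat/two_stage: mean CV AUC 0.520
double/mcat/two_stage: mean CV AUC 0.577
```

The oracle AUC (0.933) is the information ceiling of the generator; the
branch AUCs are what a small CNN extracts from roughly 90 training lesions
per fold, and the fused double branch sits above each single branch — the
directional claim the package is built to demonstrate. Individual numbers
move with the seed; the shipped studies repeat such runs over three seeds
and report majorities.

The same pipeline is scriptable from the shell:

```bash
mcatnet full --config config.yaml --seed 1 --out runs/demo
```

which writes the cohort (PNG + manifest CSV), the per-fold metric table
(`cv_metrics.csv`), a Table-style summary (`cv_summary.md`), and the
resolved config for reproducibility.

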