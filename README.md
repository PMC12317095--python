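# duetmil

Dual-modality transformer multiple-instance learning (MIL) for whole-slide
biomarker prediction — and everything around it: synthetic paired-slide
cohorts, cross-validated training, screening trade-off analysis, attention
explainability, and survival stratification of the predictions.

## The problem

Predictive cancer biomarkers such as microsatellite instability (MSI),
mismatch-repair deficiency (MMRd) and PD-L1 status gate access to
immunotherapy, but their assessment (sequencing locus counts, IHC scoring)
is slow and partly subjective. A slide-level classifier that reads the
routinely available hematoxylin & eosin (H&E) *and* immunohistochemistry
(IHC) whole-slide images can pre-screen patients, and its probability
threshold can be tuned to a clinic's false-negative budget.

A whole-slide image is represented as a *bag* of 224 px tiles at x10
magnification, each encoded to a 768-dimensional embedding. The aggregator
is a transformer (linear projection, class token, two pre-norm
self-attention layers, MLP head) applied as **two parameter-shared
branches** — one per stain — whose class-token features are concatenated
into the head:

    logit = MLP([ f_trunk(HE bag) ; f_trunk(IHC bag) ])

During training, *branch dropout* omits one branch with probability 0.3,
so the same checkpoint also serves H&E-only or IHC-only inference. There
are no positional encodings: predictions are invariant to tile order. The
transformer and its training loop (AdamW, BCE, batch size one, five-fold
6:2:2 cross-validation, max 500 sampled tiles per slide per epoch,
validation-AUROC checkpoint selection) are implemented in NumPy with
hand-written, finite-difference-verified gradients.

Because no public paired H&E/IHC dataset exists, the package ships a
synthetic cohort generator whose labels come from the actual clinical
scoring rules (MSI-high at >= 116 altered loci, equivocal at 113-115;
Combined Positive Score = 100 x positive cells / viable tumor cells, capped
at 100, positive at CPS >= 10), with class signal planted in disjoint
embedding subspaces per modality — so the duet model has provably more
information than either single-stain model — plus claims-style outcome
trails (time-on-treatment, overall survival with a 100-day presumed-death
gap rule and 21-day minimum-TOT filter) for Kaplan-Meier / log-rank / Cox
analysis via lifelines. See `docs/methods.md` for the full model and
generator description.

## Worked example

```python
import numpy as np
from duetmil.experiments import (complementary_cohort, desk_scale_model_config,
                                 desk_scale_train_config)
from duetmil.trainer import cross_validate
from duetmil.evalmetrics import mean_auroc_ci, tradeoff_curve, pick_operating_point

cfg, cohort = complementary_cohort(n_cases=300, seed=42)
cv = cross_validate(cohort, desk_scale_model_config(),
                    desk_scale_train_config(seed=42), mode="DUET", k=5)
mean, (lo, hi) = mean_auroc_ci(cv.fold_aurocs)
print(f"duet test AUROC {mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")
pt = pick_operating_point(tradeoff_curve(cv.predictions), target_fn_pct=1.0)
print(f"screening: sensitivity {pt.sensitivity:.3f}, "
      f"TN {pt.tn_pct:.1f}% of cohort at FN <= 1%")
```

prints

```
duet test AUROC 0.960 (95% CI 0.943-0.976)
screening: sensitivity 0.943, TN 66.0% of cohort at FN <= 1%
```

i.e. five-fold cross-validation of the duet model on a 300-case synthetic
cohort ranks held-out cases with AUROC ~0.96, and a screening threshold
chosen under a 1% false-negative budget would clear two thirds of the
cohort as biomarker-negative while catching 94% of positives. Training the same
cohort with `mode="HE_ONLY"` or `mode="IHC_ONLY"` gives lower AUROC — the
planted signal is split across the modalities, and only the duet model
sees all of it.

The command line mirrors the library:

```bash
duetmil all --out runs/demo --seed 0          # simulate -> train -> evaluate
duetmil simulate --out runs/sim --seed 1      # cohort CSV + HDF5 bags only
duetmil preprocess slide.png --out runs/prep  # tissue mask + tile boxes
```

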