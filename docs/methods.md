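# Methods

`duetmil` implements a dual-modality multiple-instance-learning (MIL)
pipeline for predicting slide-level biomarker status from paired H&E and
IHC whole-slide images, together with everything needed to exercise it at
desk scale: a synthetic cohort generator, screening trade-off analysis,
attention-based explainability, and claims-derived survival analysis of the
predictions.

## The model

A slide is a bag of 224 x 224-pixel tiles at x10 magnification (~1 micron
per pixel). Each tile is encoded to a fixed-width embedding (default
d = 768); the encoder is a pluggable contract, and the shipped default is a
deterministic handcrafted-feature encoder (channel histograms, moments,
gradient and Laplacian energy, projected to width d by a fixed seeded
matrix) so the pipeline runs without pretrained weights. Any external
histopathology foundation encoder with the same `encode -> (N, d)` contract
drops in.

The aggregator is a transformer over the bag:

* linear projection d -> D (default D = 512) and a learned class token;
* two pre-norm transformer layers (multi-head self-attention, 8 heads by
  default, followed by a GELU feed-forward block), no positional encodings
  — a bag is a set, so the output is tile-order invariant;
* the final class-token state is the branch feature.

One **parameter-shared trunk** serves both modalities: the H&E bag and the
IHC bag each pass through the same weights, and the two branch features are
concatenated (H&E block first) into the MLP head, which emits a single
biomarker logit with a logistic link. A missing or dropped branch
contributes a zero feature block, keeping the head input width fixed at 2D.

**Branch dropout.** During duet training, with probability p = 0.3 per step
one branch (chosen uniformly) is omitted. This trains the head to tolerate
a zeroed block, which is what makes single-stain inference with the same
checkpoint possible. `p` is interpreted as the probability that *some*
branch is dropped (the event reading), not per-branch.

The model and its training loop are implemented in NumPy with explicit
reverse-mode gradients for every operation; a finite-difference gradient
check in the test suite pins the analytic gradients to ~1e-9 relative
error. This keeps the model dependency-light and bit-reproducible on CPU.

## Training and evaluation protocol

Five-fold cross-validation with a 6:2:2 train/validation/test split: the
five outer test sets partition the cohort; within each fold the remaining
80% splits 3:1. Splits can be stratified by label so low-prevalence cohorts
keep positives in every subset. Training uses AdamW (defaults: learning
rate 1e-5, weight decay 5e-4), binary cross-entropy, batch size one, 10
epochs, at most 500 randomly sampled tiles per slide per epoch during
training and validation, validation AUROC evaluated every 500 iterations
(and at the end of training), and checkpoint selection by best validation
AUROC with the earliest iteration winning ties. Test-time inference uses
all tiles and no dropout. AUROC is the tie-aware Mann-Whitney concordance;
fold means carry a Student-t 95% CI.

The trade-off analysis sweeps every distinct predicted probability as a
screening threshold (positive iff probability >= threshold) and reports,
per threshold, the false-negative percentage FN/total x 100, the
true-negative percentage TN/total x 100 (the fraction of the cohort a
pre-screen could clear without confirmatory testing), and sensitivity. An
operating point is chosen as the maximal TN% subject to an FN% budget.

## Explainability

Three per-tile channels are produced for a trained model:

* **attention** — attention rollout: per layer, heads are averaged into one
  row-stochastic matrix; layer matrices are multiplied in order and the
  class-token row, restricted to tile columns and renormalized, is the
  score. The default uses the canonical residual-corrected form
  (0.5 A + 0.5 I per layer): the bare product is also available, but in a
  residual architecture the near-uniform token mixing of early layers
  provably smears the informative class rows of later layers, and we
  measured the bare product at chance-level localization where the
  corrected form localizes well.
* **classification** — each tile alone is run through the model; the
  output probability scores the tile.
* **contribution** — the elementwise product attention x classification.

For display, each channel is min-max normalized to [0, 1] after clipping at
the 1st/99th percentile (the clipping percentile is a documented free
parameter); constant channels normalize to zeros and are flagged rather
than producing NaNs. Degenerate identity attention falls back to uniform
scores with a warning. Heatmaps paint tile boxes under a perceptually
uniform purple-low/yellow-high colormap.

## Label-generating rules

The synthetic cohorts derive labels through the clinical scoring rules, so
the rules themselves are first-class, tested code:

* **Microsatellite status from locus counts**: >= 116 altered loci is
  MSI-H, 113-115 equivocal (excluded before modeling, generated at a
  configurable rate, default 0), <= 112 MSS.
* **PD-L1 Combined Positive Score**: CPS = 100 x (PD-L1-positive tumor +
  immune cells) / viable tumor cells. Because the numerator includes immune
  cells the raw ratio can exceed 1; the score is capped at 100, the
  clinical convention. Positive iff CPS >= 10.

Measurements are drawn from status-conditional over-dispersed distributions
(negative-binomial locus counts with means 60 / 150; Poisson cell-count
pairs) and rejection-sampled onto the correct side of the cut, so the
rule-derived label equals the latent status for every generated case.

## Claims-derived endpoints

Time-on-treatment (TOT) is last minus first administration day. Overall
survival runs from treatment start; an explicit death date takes
precedence, otherwise silence of **more than 100 days** between the last
claim and the data refresh is read as a presumed death, imputed at the last
claim day (the latest evidence of being alive — the imputation date is a
package choice; the rule's source does not state one). Contact within 100
days of the refresh censors at the last claim. Records with TOT < 21 days
are excluded from survival analyses. Kaplan-Meier curves, the log-rank
test, and Cox proportional hazards (Breslow ties by default, Efron behind a
flag; Wald CI on the log scale; biomarker-negative group as reference) are
computed through lifelines; non-convergence (e.g. monotone likelihood)
raises rather than returning a silent estimate. Survival stratification by
*predicted* status thresholds the pooled cross-fold test probabilities at
0.5 by default, with a trade-off operating point as the alternative.

## The synthetic cohort generator

Each case draws a latent binary status at the configured prevalence
(default 0.17). Both modality bags share tile count (8-32 per slide) and
signal-tile indices (the same tissue regions carry the phenotype in both
stains), with i.i.d. N(0, 1) background embeddings. Positive cases have a
fraction (default 0.35) of tiles mean-shifted in a modality-specific block
of 8 coordinates — coordinates 0-7 for H&E, 8-15 for IHC — by a
per-coordinate effect (default 1.5). Because the blocks are disjoint, each
single-stain model can at best exploit half the planted separation while
the duet model sees all of it: the synthetic analogue of complementary
morphological and immunohistochemical information. Scanner and site enter
as additive constant offset vectors (norm 0.2), and an optional per-site
noise multiplier lets stratified evaluation detect performance differences.
Outcomes follow exponential two-arm hazards (negative-arm rate 1/300 per
day, true log-HR ln 0.5, censoring rate 1/600) and are emitted as claims
trails — administration days, last claim, refresh date, and a death date
that is explicitly recorded only half the time, the other half left to the
presumed-death gap rule.

Effect sizes are free parameters of the generator, not estimates of any
real cohort. The defaults were fixed by a learnability analysis: at 0.5 per
coordinate the signal is present (an oracle linear probe restricted to the
true blocks reaches AUROC 0.90 single / 0.98 duet) but not recoverable from
768 dimensions at n = 300; at 2.0 every model saturates; 1.5 is the regime
where trained single-stain models sit clearly off ceiling and the duet
approaches it. A second configuration, the *focal-signal cohort* (signal
fraction 0.10, effect 3.0), is used for explainability validation:
attention localization is only a meaningful readout when a minority of
tiles is discriminative — with diffuse signal, uniform attention is already
near-optimal for the bag feature and "signal tiles out-attend background"
is not the expected behaviour of even a perfect model.

What the generator does **not** emulate: real histology texture statistics,
stain variation, spatial correlation between neighbouring tiles, batch
effects beyond additive offsets, or informative censoring. Passing tests
therefore demonstrate that the machinery recovers planted structure under
its stated noise model, not clinical performance.

## Desk-scale experiment configuration

The synthetic experiments run five-fold cross-validation on 300-case
cohorts with a reduced aggregator (D = 64, 4 heads, hidden 64) and learning
rate 1e-3, because the published defaults (D = 512, lr 1e-5) are an
operating point for ~2 x 10^5 optimizer steps on a pretrained encoder's
embeddings; at ~1.8 x 10^3 steps from random initialization that learning
rate moves nothing measurable. Architecture and trainer *defaults* remain
the published values; only the experiment harness overrides them. The
duet-vs-single comparison repeats the full CV over five replicate cohorts.
Cox recovery simulates 200 replicates of 500 patients with true HR 0.5
through the full claims path and checks 95% CI coverage.

## Numerical choices and edge cases

* Layer norm epsilon 1e-5; softmax computed with max subtraction; BCE via
  `logaddexp`. All model math in float64.
* Attention-rollout inputs are validated row-stochastic to 1e-4; the
  product is re-validated (stochasticity is preserved by construction).
* Tessellation keeps a tile iff masked-pixel fraction >= min_coverage
  (default 0.5, configurable; grid origin (0,0), stride = tile size,
  partial edge tiles dropped). Tile coordinates are 0-based, half-open.
* Tie-breaks: checkpoint selection takes the earliest best iteration;
  `sample_tiles` returns sorted indices; fold construction is deterministic
  in (seed, fold index) via hashed seed fan-out, so adding a stage never
  perturbs another stage's draws.
* Degenerate inputs raise: empty bags, single-class AUROC/trade-off inputs,
  non-finite embeddings, out-of-bounds exclusion regions, zero-epoch
  training.

## Known limitations

* The toy encoder separates synthetic textures but carries no histological
  knowledge; results with it say nothing about real slides.
* The identical-tile multiplicity of a bag slightly influences the
  prediction through the class token's self-attention weight (a ~1/N
  effect); exact multiplicity invariance would require excluding the class
  token from the attention keys.
* Survival analysis is univariable (the biomarker group only), with no
  proportional-hazards diagnostics.
* The pipeline's default path feeds generator-emitted embedding bags
  directly to the aggregator; the image path (render -> segment ->
  tessellate -> encode) is exercised by its stage functions and tests but
  is not part of the default end-to-end run.
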