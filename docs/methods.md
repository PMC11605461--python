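# Methods

This document records the modelling choices in `pathdx`, the reasoning behind
their default parameters, and the known limits of the synthetic-data
framework. The API reference lives in the docstrings; this is the "why".

## 1. Problem framing

`pathdx` studies *pathways to diagnosis*: the temporally ordered sequence of
curated clinical codes recorded for a patient in primary care over the 36
months before an index date, used to predict whether that pathway ends in a
lung-cancer diagnosis. The framing is a nested case–control design:

* **Cases** — index date is the date of the patient's first lung-cancer
  diagnostic code (lung takes precedence if several cancer codes share a
  date).
* **Controls** — index date is the date of the first other-cancer code
  (other-cancer stratum) or the most recent diagnostic code (respiratory and
  other strata).
* The **pathway** is the ordered curated-code sequence in the half-open
  window `[index − lookback, index − trim)`, with calendar-month arithmetic
  (`dateutil.relativedelta`). Default lookback is 36 months; default trim is
  1 month, removing codes entered around the diagnostic work-up itself
  (post-diagnosis coding bias). Pathways with fewer than 10 codes are
  excluded; label-revealing diagnosis codes are stripped before modelling.

A note on windowing: calendar-month arithmetic means window boundaries move
by up to ~3 days when all events are shifted by a fixed number of days
(month lengths differ). We accept this in exchange for month-defined
trimming and lookback semantics; the property tests therefore check
translation invariance only for events clear of the boundary band.

## 2. Code curation

Raw terminology codes are mapped up to ~450 curated clinical groups; purely
administrative codes are dropped. The package ships a demonstration code map
(`pathdx.curation.demo_code_map_path()`) with named clinical groups (symptoms,
tests, procedures, medications, diagnoses) plus generic filler groups to
reach the full vocabulary size. The model vocabulary is the sorted set of
non-administrative group ids plus four specials:
`[PAD]=0, [UNK]=1, [CLS]=2, [MASK]=3`.

Unknown raw codes are either dropped or mapped to `[UNK]` (policy flag);
conflicting duplicate rows in a code map are an error, exact duplicates are
tolerated.

## 3. Sequence model

The classifier is a transformer encoder with the parameter-sharing devices
of ALBERT:

* **Factorised embedding** — a `V×E` token embedding followed by an `E×H`
  projection (`E < H`), cutting embedding parameters at large `V`.
* **Cross-layer parameter sharing** — one set of block weights applied at
  every layer (configurable off).
* Learned positions, post-layer-norm residual blocks, GELU activations.
* **MLM head** — dense `H→E` + GELU + layer norm, decoded against the
  *tied* token embedding plus an output bias.
* **Classification head** — logistic regression on the final-layer `[CLS]`
  vector trained with binary cross-entropy.

Two presets:

| preset | layers | heads | H | E | max_len |
|--------|--------|-------|----|----|---------|
| default | 6 | 12 | 768 | 128 | 512 |
| desk | 2 | 4 | 64 | 32 | 128 |

The default mirrors the published architecture; the desk preset preserves
every architectural device (sharing, factorisation, tied decoder, heads) at
a size that trains in seconds per epoch on one CPU, and is what the test
suite uses. Sequences longer than `max_len − 1` keep the most recent codes
(the informative end of a pathway) plus the prepended `[CLS]`.

Because no tensor/autodiff library is available in the target environment,
the model runs on a small reverse-mode autodiff tape over NumPy
(`pathdx.model.autodiff`) with fused softmax, layer-norm, GELU and loss
kernels. Gradient correctness is tested against central finite differences.
Padding positions receive a −1e9 additive attention bias; model outputs are
invariant (to float tolerance) to the amount of padding, which is also
tested.

## 4. Training

* **Pretraining (MLM)** — 15% of maskable positions (ids ≥ 4; `[CLS]` and
  `[PAD]` are never maskable) are selected per sequence; of those, 80%
  become `[MASK]`, 10% a uniformly random non-special code, 10% unchanged.
  Marginally this is 12% `[MASK]` and 1.5% random replacement — measured at
  scale by `scripts/acceptance.py`. Loss is cross-entropy at selected
  positions only.
* **Fine-tuning** — binary cross-entropy on the `[CLS]` logistic head, with
  `restarts` random reinitialisations of the classifier head (the encoder
  restarts from the pretrained weights each time); the restart with the best
  held-out AUROC wins. This follows the published recipe of selecting over
  repeated fine-tuning runs.
* **Optimiser** — Adam with linear warmup (10% of steps by default).
* Paper-scale plans (`default_pretrain_plan`: batch 2, 60 epochs;
  fine-tune batch 8) reproduce the published step arithmetic; desk plans
  (`desk_pretrain_plan`: batch 32, 6 epochs, lr 1e-3;
  `desk_finetune_plan`: batch 32, 8 epochs, lr 5e-4, 2 restarts) are sized
  so that the full pipeline runs in minutes on one CPU while still clearly
  learning planted signal in the test designs.
* **Baseline** — bag-of-codes logistic regression over per-group counts
  (optionally binary flags), with either a fixed `C` or cross-validated
  regularisation. This is the comparator that, by construction, cannot see
  code order.

## 5. Synthetic cohorts

Real primary-care extracts cannot be shipped, so `pathdx.synthetic`
generates cohorts with known ground truth that emulate the structure the
pipeline cares about: per-patient event streams over a 36-month window, a
curated vocabulary, control strata (respiratory / other-cancer / other),
latent utilisation subgroups, and an ordered progression motif whose hazard
rises toward the index date.

Key design points:

* **Background** — homogeneous Poisson process with a Zipf-flavoured token
  distribution, re-weighted per subgroup (`boost` concentrates mass on the
  subgroup's token set). Diagnosis-category groups are never background
  tokens: they are emitted per stratum (endpoint code at index; optional
  earlier "monitoring" copies for chronic-condition controls,
  `control_monitoring_mean`).
* **Motifs** — inhomogeneous emission hazard per month (entry 35 = month
  before index); tokens are assigned to time-sorted emissions cyclically in
  motif order.
* **Arms are background-matched** — motif expectations are subtracted from
  *everyone's* background mean, so the case/control difference is exactly
  the planted motif, not a compensating background-rate difference. This
  matters for trimming studies: if case background were thinned to equalise
  total length, trimming away a final-month motif would leave cases with
  systematically shorter pathways — a length artefact masquerading as
  residual signal. `mean_pathway_length` therefore pins the motif-carrying
  arm's expected total.
* **Signal regimes** —
  * `marginal_shift`: cases receive the motif emissions, controls do not.
    Both a bag-of-codes model and a sequence model can detect this.
  * `order_only`: both arms draw background *and* motif emissions from
    identical processes; cases assign motif tokens to the time-sorted
    emission slots in canonical order, controls in shuffled order. Code
    marginals are then identical in distribution (verified by a chi-square
    homogeneity test) and only ordering carries label signal — isolating
    what a sequence model can learn that a bag-of-codes model cannot.
    Order-only analyses run untrimmed: trimming an ordered stream
    preferentially removes late-cycle motif tokens from cases, itself
    re-introducing a small marginal difference.
* **Scope and limits** — the generator is a study-design instrument, not a
  clinical simulator. It makes no attempt at realistic comorbidity
  structure, code co-occurrence grammar, seasonal effects, or care-seeking
  behaviour beyond the utilisation subgroups; demographic fields are
  decorative (age differs by arm, sex/ethnicity are independent noise).
  Conclusions about *models* transfer only in the qualitative sense the
  acceptance designs test (order-signal recovery, trimming direction,
  subgroup recovery); absolute AUROCs on synthetic cohorts say nothing
  about clinical performance.

## 6. Evaluation

* AUROC via the Mann–Whitney statistic (ties counted ½).
* Confidence intervals by percentile bootstrap (degenerate single-class
  resamples are redrawn and logged).
* Model comparison by DeLong's test on paired predictions (structural
  components), checked in the tests against a paired-bootstrap oracle.
* Threshold sweep over 0.40–0.70 in steps of 0.05, with 0.4 as the default
  operating point (chosen against the fast-track referral convention that a
  triage tool should exceed ~3% PPV).
* Sensitivity grid over lookback × trim (3×3), with small-cell flagging.
* Subgroup panels (age band / sex / ethnicity) report per-group metrics
  with minimum-size flags and no multiplicity adjustment — they are
  descriptive.

## 7. Interpretation

* **Attention profiles** — final-layer, head-averaged attention from `[CLS]`
  to each pathway position, renormalised after dropping `[CLS]` itself.
* **Clustering** — k-means (n_init 10) on final-layer `[CLS]` embeddings,
  with an inertia/silhouette scan over k. 2-D views by t-SNE (PCA init,
  perplexity clamped for small n).
* **Design note on `[CLS]` clustering** — `[CLS]` receives no MLM loss (it
  is never maskable), so after pretraining alone its geometry is shaped by
  the attention mixture over the pathway rather than by any explicit
  objective; pathway length and utilisation dominate. Subgroup-recovery
  studies therefore contrast subgroups along axes such a representation can
  express — disjoint background token sets, distinct monitoring motifs,
  different utilisation levels — and use pathways long enough (relative to
  `max_len`) to stabilise the attention mixture. These are the same axes
  (monitoring-heavy vs sparse-attendance profiles) that published pathway
  clusterings surface.

## 8. Numerical choices

* float32 parameters by default (float64 available for gradient checks).
* Stable fused kernels: max-subtracted softmax, log-sum-exp cross-entropy,
  sign-split BCE-with-logits.
* All stochastic components take explicit seeds (`numpy.random.default_rng`);
  pipeline stages record seeds, config hash and input hashes in per-stage
  manifests, and a rerun of the same config byte-reproduces evaluation
  outputs (tested).
* Non-finite training losses abort with a diagnostic rather than continuing.

## 9. Limitations

* The desk-scale model is a faithful miniature, not the published model; the
  paper-scale preset exists and follows the same code path but is not
  exercised end-to-end in the test suite (CPU budget).
* The synthetic generator's limits in §5 bound what any experiment here can
  claim.
* DeLong and bootstrap machinery assume exchangeable test patients; no
  clustering by practice/site is modelled.
* Subgroup evaluation panels are descriptive only.
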