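"""Masked-code pretraining, supervised fine-tuning, and the bag-of-codes
logistic-regression comparator.

Pretraining corrupts each pathway with the BERT recipe re-expressed to match
the reported marginals: 15% of maskable positions are selected, of which 80%
become [MASK] (a 12% marginal), 10% become a uniformly random group code (a
1.5% marginal) and 10% are left unchanged; the model predicts the original
codes at selected positions. Fine-tuning trains the classification head (and
the whole encoder) with binary cross-entropy, running several random restarts
that differ in data shuffling and classifier initialisation and keeping the
restart with the best evaluation-set AUROC — fine-tuning small transformers is
known to be unstable.

The comparator destroys order information: each pathway becomes a vector of
per-group code counts fed to an L2-penalised logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from pathdx.model import SequenceModel, SequenceModelConfig
from pathdx.model import autodiff as ad
from pathdx.model.optim import Adam
from pathdx.pathways import CLS_ID, MASK_ID, N_SPECIAL, PAD_ID, Pathway, Vocabulary
from pathdx.evaluation import auroc

#: fraction of maskable positions selected for the MLM objective
MLM_SELECT_PROB = 0.15
#: of the selected positions: replaced by [MASK] / by a random code / kept
MLM_MASK_FRAC, MLM_RANDOM_FRAC = 0.8, 0.1


@dataclass
class MLMExample:
    """A corrupted input with its reconstruction targets."""

    input_ids: np.ndarray
    target_ids: np.ndarray
    selection_mask: np.ndarray  # True at positions contributing to the loss


def make_mlm_example(
    token_ids: Sequence[int], rng: np.random.Generator, vocab_size: int
) -> MLMExample:
    """Corrupt one id sequence for masked-code pretraining.

    Maskable positions are the non-special tokens (ids >= 4); [CLS] and [PAD]
    are never selected. A sequence with no maskable positions yields an empty
    selection.
    """
    ids = np.asarray(token_ids, dtype=np.int64)
    maskable = ids >= N_SPECIAL
    selected = maskable & (rng.random(ids.shape) < MLM_SELECT_PROB)
    inputs = ids.copy()
    u = rng.random(ids.shape)
    to_mask = selected & (u < MLM_MASK_FRAC)
    to_random = selected & (u >= MLM_MASK_FRAC) & (u < MLM_MASK_FRAC + MLM_RANDOM_FRAC)
    inputs[to_mask] = MASK_ID
    n_rand = int(to_random.sum())
    if n_rand:
        inputs[to_random] = rng.integers(N_SPECIAL, vocab_size, size=n_rand)
    return MLMExample(input_ids=inputs, target_ids=ids, selection_mask=selected)


def plan_steps(n_examples: int, epochs: int, batch_size: int) -> int:
    """Number of optimisation steps: floor(n_examples * epochs / batch_size)."""
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    if n_examples <= 0 or epochs <= 0:
        raise ValueError("n_examples and epochs must be positive")
    return (n_examples * epochs) // batch_size


@dataclass
class TrainPlan:
    """Hyperparameters of one training stage."""

    batch_size: int = 8
    epochs: int = 4
    learning_rate: float = 2e-5
    seed: int = 0
    restarts: int = 5
    warmup_fraction: float = 0.1

    def planned_steps(self, n_examples: int) -> int:
        return plan_steps(n_examples, self.epochs, self.batch_size)


def default_pretrain_plan(**overrides) -> TrainPlan:
    kw = dict(batch_size=2, epochs=60, learning_rate=1e-4, restarts=1)
    kw.update(overrides)
    return TrainPlan(**kw)


def desk_pretrain_plan(**overrides) -> TrainPlan:
    """CPU-scale pretraining: bigger batches and a larger learning rate than
    the full-scale schedule, matched to the few thousand steps actually run."""
    kw = dict(batch_size=32, epochs=6, learning_rate=1e-3, restarts=1)
    kw.update(overrides)
    return TrainPlan(**kw)


def desk_finetune_plan(**overrides) -> TrainPlan:
    kw = dict(batch_size=32, epochs=8, learning_rate=5e-4, restarts=2)
    kw.update(overrides)
    return TrainPlan(**kw)


def _pad_batch(seqs: list[np.ndarray]) -> np.ndarray:
    n = max(len(s) for s in seqs)
    out = np.full((len(seqs), n), PAD_ID, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def encode_pathways(
    pathways: Sequence[Pathway],
    vocabulary: Vocabulary,
    max_len: int,
    endpoints: dict[str, str] | None = None,
) -> list[np.ndarray]:
    """Tokenize pathways; ``endpoints`` optionally appends each patient's
    diagnostic endpoint code (pretraining keeps pathways ending in their
    diagnostic code; fine-tuning strips diagnostic codes instead)."""
    from pathdx.pathways import tokenize

    out = []
    for p in pathways:
        tokens = list(p.tokens)
        if endpoints is not None and p.patient_id in endpoints:
            tokens.append(endpoints[p.patient_id])
        out.append(np.asarray(tokenize(tokens, vocabulary, max_len), dtype=np.int64))
    return out


@dataclass
class PretrainResult:
    model: SequenceModel
    loss_trace: list[float]
    smoothed_trace: list[float] = field(default_factory=list)


def _smooth(xs: list[float], w: int = 25) -> list[float]:
    out = []
    for i in range(len(xs)):
        lo = max(0, i - w + 1)
        out.append(float(np.mean(xs[lo : i + 1])))
    return out


def pretrain(
    sequences: Sequence[np.ndarray],
    config: SequenceModelConfig,
    plan: TrainPlan,
    model: SequenceModel | None = None,
) -> PretrainResult:
    """Masked-code pretraining; returns the model and its loss trace."""
    rng = np.random.default_rng(plan.seed)
    if model is None:
        model = SequenceModel(config, seed=plan.seed)
    n = len(sequences)
    total_steps = plan.planned_steps(n)
    opt = Adam(
        model.params,
        lr=plan.learning_rate,
        warmup_steps=max(1, int(plan.warmup_fraction * total_steps)),
    )
    trace: list[float] = []
    for _ in range(plan.epochs):
        order = rng.permutation(n)
        for start in range(0, n - plan.batch_size + 1, plan.batch_size):
            batch = [sequences[i] for i in order[start : start + plan.batch_size]]
            examples = [make_mlm_example(s, rng, config.vocab_size) for s in batch]
            ids = _pad_batch([e.input_ids for e in examples])
            targets = _pad_batch([e.target_ids for e in examples])
            sel = np.zeros(ids.shape, dtype=bool)
            for i, e in enumerate(examples):
                sel[i, : len(e.selection_mask)] = e.selection_mask
            out = model.forward(ids, train=True, rng=rng)
            logits = model.mlm_logits(out)
            loss = ad.cross_entropy(
                logits.reshape(-1, config.vocab_size),
                targets.reshape(-1),
                weights=sel.reshape(-1).astype(logits.data.dtype),
            )
            if not math.isfinite(float(loss.data)):
                raise RuntimeError(
                    f"non-finite MLM loss at step {opt.t}: {float(loss.data)!r}; "
                    f"lr={plan.learning_rate}, batch={plan.batch_size}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
    return PretrainResult(model=model, loss_trace=trace, smoothed_trace=_smooth(trace))


def _clone(model: SequenceModel) -> SequenceModel:
    clone = SequenceModel(model.config)
    for k, t in model.params.items():
        clone.params[k].data = t.data.copy()
    return clone


def predict_scores(model: SequenceModel, sequences: Sequence[np.ndarray], batch_size: int = 64) -> np.ndarray:
    scores = []
    for start in range(0, len(sequences), batch_size):
        ids = _pad_batch(list(sequences[start : start + batch_size]))
        scores.append(model.predict_proba(ids))
    return np.concatenate(scores)


@dataclass
class FinetuneResult:
    model: SequenceModel
    best_restart: int
    report: list[dict]  # per restart: seed, eval AUROC, final loss, plan


def finetune(
    sequences: Sequence[np.ndarray],
    labels: Sequence[int],
    pretrained: SequenceModel,
    plan: TrainPlan,
    eval_sequences: Sequence[np.ndarray],
    eval_labels: Sequence[int],
) -> FinetuneResult:
    """Jointly fine-tune encoder + classification head with BCE.

    Runs ``plan.restarts`` restarts from the same pretrained checkpoint with
    different shuffling and classifier initialisation; returns the restart
    with the highest evaluation AUROC.
    """
    y = np.asarray(labels, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("fine-tuning needs both classes in the training set")
    y_eval = np.asarray(eval_labels, dtype=int)
    n = len(sequences)
    reports: list[dict] = []
    best: tuple[float, SequenceModel | None, int] = (-np.inf, None, -1)
    for r in range(plan.restarts):
        rng = np.random.default_rng((plan.seed, r))
        model = _clone(pretrained)
        model.reinit_classifier(rng)
        total_steps = plan.planned_steps(n)
        opt = Adam(
            model.params,
            lr=plan.learning_rate,
            warmup_steps=max(1, int(plan.warmup_fraction * total_steps)),
        )
        last_loss = math.nan
        for _ in range(plan.epochs):
            order = rng.permutation(n)
            for start in range(0, n - plan.batch_size + 1, plan.batch_size):
                take = order[start : start + plan.batch_size]
                ids = _pad_batch([sequences[i] for i in take])
                out = model.forward(ids, train=True, rng=rng)
                loss = ad.bce_with_logits(model.classify_logits(out), y[take])
                if not math.isfinite(float(loss.data)):
                    raise RuntimeError(f"non-finite fine-tuning loss at step {opt.t}")
                model.zero_grad()
                loss.backward()
                opt.step()
                last_loss = float(loss.data)
        eval_scores = predict_scores(model, eval_sequences)
        eval_auc = auroc(eval_scores, y_eval)
        reports.append(
            {
                "restart": r,
                "eval_auroc": eval_auc,
                "final_loss": last_loss,
                "batch_size": plan.batch_size,
                "epochs": plan.epochs,
                "learning_rate": plan.learning_rate,
                "seed": plan.seed,
            }
        )
        if eval_auc > best[0]:
            best = (eval_auc, model, r)
    assert best[1] is not None
    return FinetuneResult(model=best[1], best_restart=best[2], report=reports)


# --- bag-of-codes comparator -------------------------------------------------


def featurize_counts(
    pathway: Pathway | Sequence[str], vocabulary: Vocabulary, binary: bool = False
) -> np.ndarray:
    """Order-destroying count vector over the group vocabulary."""
    tokens = pathway.tokens if isinstance(pathway, Pathway) else pathway
    vec = np.zeros(len(vocabulary) - N_SPECIAL, dtype=float)
    for t in tokens:
        idx = vocabulary.id_of(t)
        if idx >= N_SPECIAL:
            vec[idx - N_SPECIAL] += 1.0
    if binary:
        vec = (vec > 0).astype(float)
    return vec


def featurize_matrix(
    pathways: Sequence[Pathway], vocabulary: Vocabulary, binary: bool = False
) -> np.ndarray:
    return np.vstack([featurize_counts(p, vocabulary, binary) for p in pathways])


def train_lr_baseline(
    features: np.ndarray,
    labels: Sequence[int],
    cv_folds: int = 5,
    seed: int = 0,
    C: float | None = None,
):
    """L2-penalised logistic regression on code-count features.

    The penalty strength is chosen by ``cv_folds``-fold cross-validation
    unless a fixed ``C`` is given.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("need both classes")
    X = np.asarray(features, dtype=float)
    if X.std() == 0:
        raise ValueError("degenerate (constant) feature matrix")
    if C is not None:
        clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    else:
        clf = LogisticRegressionCV(
            Cs=np.logspace(-3, 2, 8),
            cv=cv_folds,
            l1_ratios=(0.0,),
            scoring="roc_auc",
            use_legacy_attributes=False,
            max_iter=2000,
            random_state=seed,
            n_jobs=1,
        )
    clf.fit(X, y)
    return clf
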