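"""High-level experiment harnesses over the library stages.

These functions assemble the common study designs — derive pathways from a
(synthetic) cohort using its ground truth, then train and score the sequence
model and the bag-of-codes comparator on a train/test split — so experiments,
tests and reproduction scripts share one code path.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from pathdx.curation import curate_events
from pathdx.evaluation import auroc
from pathdx.model import SequenceModelConfig
from pathdx.pathways import (
    Pathway,
    Vocabulary,
    derive_pathway,
    filter_min_codes,
    strip_label_codes,
)
from pathdx.synthetic import Cohort
from pathdx.training import (
    TrainPlan,
    desk_finetune_plan,
    desk_pretrain_plan,
    encode_pathways,
    featurize_matrix,
    finetune,
    predict_scores,
    pretrain,
    train_lr_baseline,
)
from pathdx.vocab_spec import LUNG_DX, OTHER_CANCER_DX


def cohort_pathways(
    cohort: Cohort,
    lookback_months: int = 36,
    trim_months: int = 0,
    min_codes: int = 10,
    strip_diagnoses: bool = True,
) -> list[Pathway]:
    """Curate a cohort's events and derive one pathway per patient.

    Index dates, labels and strata come from the cohort's ground truth (the
    pipeline stages re-derive them from code lists instead). Pathways are
    returned sorted by patient id.
    """
    curated = curate_events(cohort.events, cohort.code_map)
    by_pid: dict[str, list] = defaultdict(list)
    for e in curated:
        by_pid[e.patient_id].append(e)
    lung, cancer = {LUNG_DX}, set(OTHER_CANCER_DX)
    out = []
    for pid in sorted(by_pid):
        t = cohort.truth[pid]
        p = derive_pathway(
            by_pid[pid], t.index_date, t.label, t.stratum, pid,
            lookback_months=lookback_months, trim_months=trim_months,
        )
        if strip_diagnoses:
            p = strip_label_codes(p, lung, cancer)
        out.append(p)
    return filter_min_codes(out, min_codes)


def split_pathways(
    pathways: list[Pathway], n_train: int, seed: int
) -> tuple[list[Pathway], list[Pathway]]:
    """Seeded random train/test split of a pathway list."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pathways))
    train = [pathways[i] for i in perm[:n_train]]
    test = [pathways[i] for i in perm[n_train:]]
    return train, test


@dataclass
class ModelComparison:
    """Held-out AUROCs of the sequence model and the count-based comparator."""

    sequence_auroc: float
    baseline_auroc: float
    sequence_scores: np.ndarray
    baseline_scores: np.ndarray
    labels: np.ndarray

    @property
    def margin(self) -> float:
        return self.sequence_auroc - self.baseline_auroc


def train_sequence_model(
    train: list[Pathway],
    vocabulary: Vocabulary,
    model_config: SequenceModelConfig | None = None,
    pretrain_plan: TrainPlan | None = None,
    finetune_plan: TrainPlan | None = None,
    eval_fraction: float = 0.15,
    seed: int = 0,
):
    """Pretrain (MLM) then fine-tune on the training pathways.

    A random ``eval_fraction`` of the training set is held out for restart
    selection (it still participates in pretraining, which is unsupervised).
    """
    cfg = model_config or SequenceModelConfig.desk(vocab_size=len(vocabulary))
    ppl = pretrain_plan or desk_pretrain_plan(seed=seed)
    fpl = finetune_plan or desk_finetune_plan(seed=seed + 1)
    seqs = encode_pathways(train, vocabulary, cfg.max_len)
    labels = np.array([p.label for p in train])
    pre = pretrain(seqs, cfg, ppl)
    rng = np.random.default_rng(seed + 2)
    n_eval = max(int(eval_fraction * len(train)), 20)
    eval_idx = set(rng.choice(len(train), size=n_eval, replace=False).tolist())
    tr_idx = [i for i in range(len(train)) if i not in eval_idx]
    ev_idx = sorted(eval_idx)
    result = finetune(
        [seqs[i] for i in tr_idx], labels[tr_idx], pre.model, fpl,
        [seqs[i] for i in ev_idx], labels[ev_idx],
    )
    return result.model


def compare_models(
    train: list[Pathway],
    test: list[Pathway],
    vocabulary: Vocabulary,
    model_config: SequenceModelConfig | None = None,
    pretrain_plan: TrainPlan | None = None,
    finetune_plan: TrainPlan | None = None,
    lr_C: float | None = 1.0,
    seed: int = 0,
) -> ModelComparison:
    """Train both models on ``train`` and compare held-out AUROC on ``test``."""
    cfg = model_config or SequenceModelConfig.desk(vocab_size=len(vocabulary))
    y_test = np.array([p.label for p in test])
    clf = train_lr_baseline(
        featurize_matrix(train, vocabulary),
        [p.label for p in train],
        seed=seed,
        C=lr_C,
    )
    lr_scores = clf.predict_proba(featurize_matrix(test, vocabulary))[:, 1]
    model = train_sequence_model(
        train, vocabulary, cfg, pretrain_plan, finetune_plan, seed=seed
    )
    seq_scores = predict_scores(model, encode_pathways(test, vocabulary, cfg.max_len))
    return ModelComparison(
        sequence_auroc=auroc(seq_scores, y_test),
        baseline_auroc=auroc(lr_scores, y_test),
        sequence_scores=seq_scores,
        baseline_scores=lr_scores,
        labels=y_test,
    )
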