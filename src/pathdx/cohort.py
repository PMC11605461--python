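"""Nested case-control cohort construction.

The population is split at patient level into training and validation arms
(default 70/30). Within the training arm a balanced case-control set is built:
all eligible lung-cancer cases plus controls over-sampled by stratum
(other cancers / chronic respiratory / other) so the model learns to separate
pathways that superficially resemble each other. A small evaluation subset is
carved from the training set for model selection, and a fixed-size random
sample of the validation arm is used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from pathdx.pathways import Pathway

#: Control-strata proportions of the combined case-control set, used to derive
#: default quotas: respiratory 22.5%, other cancers 15.6%, other 17.5%.
DEFAULT_STRATUM_PROPORTIONS = {
    "respiratory": 0.225,
    "other_cancer": 0.156,
    "other": 0.175,
}


@dataclass
class CohortSplit:
    """Patient-id partition for training/validation plus nested subsets."""

    training: list[str]
    validation: list[str]
    evaluation: list[str] = field(default_factory=list)
    validation_sample: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.training) & set(self.validation)
        if overlap:
            raise ValueError(f"training/validation overlap: {sorted(overlap)[:5]}")


def split_population(
    patient_ids: Sequence[str], train_fraction: float = 0.7, seed: int = 0
) -> CohortSplit:
    """Randomly partition patient ids; |training| = round(train_fraction * N).

    Ids are sorted before shuffling so the split depends only on the id set
    and the seed, not on input order.
    """
    ids = sorted(set(patient_ids))
    if len(ids) != len(patient_ids):
        raise ValueError("patient ids must be unique")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = sorted(ids[i] for i in perm[:n_train])
    valid = sorted(ids[i] for i in perm[n_train:])
    return CohortSplit(training=train, validation=valid)


def sample_ids(ids: Sequence[str], k: int, seed: int) -> list[str]:
    """Seeded order-invariant sample without replacement (canonical id sort)."""
    pool = sorted(ids)
    if k > len(pool):
        raise ValueError(f"cannot sample {k} from {len(pool)} ids")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(pool), size=k, replace=False)
    return sorted(pool[i] for i in take)


@dataclass
class CaseControlSet:
    """Labelled training set plus its composition report."""

    pathways: list[Pathway]
    composition: dict[str, dict[str, float]]  # stratum -> {count, fraction}

    @property
    def case_fraction(self) -> float:
        return self.composition["lung"]["fraction"]


def default_quotas(n_cases: int) -> dict[str, int]:
    """Absolute control quotas implied by the default strata proportions.

    Solves for quotas such that each control stratum makes up its default
    fraction of the combined (cases + controls) set.
    """
    control_frac = sum(DEFAULT_STRATUM_PROPORTIONS.values())
    total = n_cases / (1.0 - control_frac)
    return {s: int(round(total * f)) for s, f in DEFAULT_STRATUM_PROPORTIONS.items()}


def build_case_control(
    pathways: Sequence[Pathway],
    stratum_quotas: Mapping[str, int] | None = None,
    seed: int = 0,
) -> CaseControlSet:
    """Assemble the nested case-control training set.

    Includes every lung-cancer case; samples each control stratum without
    replacement to its quota. Raises if a quota exceeds the stratum. With
    ``stratum_quotas=None`` every available control is kept (the input is
    assumed to already carry the intended over-selected composition); use
    :func:`default_quotas` to subsample to the default stratum proportions.
    """
    by_stratum: dict[str, list[Pathway]] = {}
    for p in pathways:
        by_stratum.setdefault(p.stratum, []).append(p)
    cases = by_stratum.get("lung", [])
    if not cases:
        raise ValueError("no lung-cancer cases in input")

    rng = np.random.default_rng(seed)
    selected: list[Pathway] = list(cases)
    for stratum in ("other_cancer", "respiratory", "other"):
        if stratum_quotas is None:
            quota = len(by_stratum.get(stratum, []))
        else:
            quota = int(stratum_quotas.get(stratum, 0))
        pool = sorted(by_stratum.get(stratum, []), key=lambda p: p.patient_id)
        if quota > len(pool):
            raise ValueError(
                f"quota {quota} exceeds available size {len(pool)} "
                f"for stratum {stratum!r}"
            )
        take = rng.choice(len(pool), size=quota, replace=False) if quota else []
        selected.extend(pool[i] for i in sorted(take))

    total = len(selected)
    composition = {}
    for stratum in ("lung", "other_cancer", "respiratory", "other"):
        count = sum(1 for p in selected if p.stratum == stratum)
        composition[stratum] = {"count": count, "fraction": count / total}
    return CaseControlSet(pathways=selected, composition=composition)
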