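"""Construction of patient-level pathways to diagnosis.

A *pathway* is the temporally ordered sequence of curated code groups a
patient accrued over a lookback window (default 36 months) ending at an
*index date*. For patients diagnosed with lung cancer the index date is the
date of the first lung-cancer diagnostic code, and lung cancer takes
precedence over any other cancer; for other-cancer controls it is the date of
the first such cancer code; for the remaining controls it is the date of
their most recent diagnostic code. An optional *trim* removes the months
immediately preceding the index date to guard against post-diagnosis coding
bias.

Window convention: events with date in ``[index - lookback_months,
index - trim_months)`` are retained — closed below, open above, with
calendar-month arithmetic (same day-of-month, clamped to month end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from dateutil.relativedelta import relativedelta

from pathdx.curation import CuratedEvent

#: Strata of the nested case-control design.
STRATA = ("lung", "other_cancer", "respiratory", "other")

PAD_TOKEN, UNK_TOKEN, CLS_TOKEN, MASK_TOKEN = "[PAD]", "[UNK]", "[CLS]", "[MASK]"
PAD_ID, UNK_ID, CLS_ID, MASK_ID = 0, 1, 2, 3
SPECIAL_TOKENS = (PAD_TOKEN, UNK_TOKEN, CLS_TOKEN, MASK_TOKEN)
N_SPECIAL = len(SPECIAL_TOKENS)


class NoIndexDate(ValueError):
    """Raised when a patient has no diagnostic code to anchor a pathway."""


@dataclass
class Pathway:
    """One patient's ordered curated-token sequence."""

    patient_id: str
    tokens: list[str]
    index_date: date
    label: int  # 1 = lung cancer, 0 = non-lung
    stratum: str  # one of STRATA

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Vocabulary:
    """Bidirectional token <-> contiguous-integer map with fixed specials.

    Ids 0..3 are [PAD], [UNK], [CLS], [MASK]; group tokens follow in sorted
    order, so the default 450-group vocabulary has total size 454.
    """

    token_to_id: dict[str, int] = field(default_factory=dict)
    id_to_token: list[str] = field(default_factory=list)

    @classmethod
    def from_groups(cls, groups: Iterable[str]) -> "Vocabulary":
        tokens = list(SPECIAL_TOKENS) + sorted(set(groups) - set(SPECIAL_TOKENS))
        return cls({t: i for i, t in enumerate(tokens)}, tokens)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def token_of(self, idx: int) -> str:
        return self.id_to_token[idx]

    @property
    def group_ids(self) -> range:
        """Integer ids of the non-special (group) tokens."""
        return range(N_SPECIAL, len(self.id_to_token))


def months_before(day: date, months: int) -> date:
    """Same day-of-month ``months`` earlier, clamped to month end."""
    return day - relativedelta(months=months)


def select_index_date(
    events: Sequence[CuratedEvent],
    lung_codes: set[str],
    cancer_codes: set[str],
    diagnostic_codes: set[str] | None = None,
    respiratory_codes: set[str] | None = None,
) -> tuple[date, str]:
    """Pick a patient's pathway endpoint and case-control stratum.

    Lung cancer takes precedence over other cancers: any lung code makes the
    patient a case with index at the *first* lung code. Otherwise the first
    other-cancer code anchors an ``other_cancer`` control. Otherwise the
    *most recent* diagnostic code anchors a ``respiratory`` or ``other``
    control according to code-list membership.

    ``diagnostic_codes`` defaults to all codes in ``events`` (any code may
    serve as a control endpoint); ``respiratory_codes`` classifies the
    residual stratum.
    """
    respiratory_codes = respiratory_codes or set()
    lung_dates = [e.event_date for e in events if e.group_id in lung_codes]
    if lung_dates:
        return min(lung_dates), "lung"
    cancer_dates = [e.event_date for e in events if e.group_id in cancer_codes]
    if cancer_dates:
        return min(cancer_dates), "other_cancer"
    if diagnostic_codes is None:
        candidates = list(events)
    else:
        candidates = [e for e in events if e.group_id in diagnostic_codes]
    if not candidates:
        raise NoIndexDate("patient has no diagnostic code")
    last = max(candidates, key=lambda e: e.event_date)
    stratum = "respiratory" if any(
        e.group_id in respiratory_codes for e in events
    ) else "other"
    return last.event_date, stratum


def derive_pathway(
    events: Sequence[CuratedEvent],
    index_date: date,
    label: int,
    stratum: str,
    patient_id: str,
    lookback_months: int = 36,
    trim_months: int = 0,
) -> Pathway:
    """Window and order a patient's curated events into a Pathway.

    Retains events dated in ``[index - lookback, index - trim)``; orders by
    (event_date, group_id, input position) so output is deterministic under
    same-day ties. Duplicate codes are kept: repeat presentations carry
    signal.
    """
    if trim_months >= lookback_months:
        raise ValueError(
            f"trim_months={trim_months} must be < lookback_months={lookback_months}"
        )
    lo = months_before(index_date, lookback_months)
    hi = months_before(index_date, trim_months)
    keyed = [
        (e.event_date, e.group_id, i)
        for i, e in enumerate(events)
        if lo <= e.event_date < hi
    ]
    keyed.sort()
    return Pathway(
        patient_id=patient_id,
        tokens=[g for _, g, _ in keyed],
        index_date=index_date,
        label=label,
        stratum=stratum,
    )


def filter_min_codes(pathways: Iterable[Pathway], min_codes: int = 10) -> list[Pathway]:
    """Drop pathways with fewer than ``min_codes`` curated tokens.

    The boundary is inclusive on retention: a 10-token pathway survives the
    default filter, a 9-token one does not.
    """
    return [p for p in pathways if len(p.tokens) >= min_codes]


def strip_label_codes(
    pathway: Pathway, lung_codes: set[str], other_cancer_codes: set[str]
) -> Pathway:
    """Remove diagnostic (label-revealing) tokens, preserving order."""
    banned = lung_codes | other_cancer_codes
    return Pathway(
        patient_id=pathway.patient_id,
        tokens=[t for t in pathway.tokens if t not in banned],
        index_date=pathway.index_date,
        label=pathway.label,
        stratum=pathway.stratum,
    )


def tokenize(
    pathway: Pathway | Sequence[str], vocabulary: Vocabulary, max_len: int = 512
) -> list[int]:
    """Encode tokens as ``[CLS] + ids``, truncated to ``max_len``.

    Truncation keeps the most recent ``max_len - 1`` tokens: late events are
    the most predictive of the diagnosis at the index date.
    """
    tokens = pathway.tokens if isinstance(pathway, Pathway) else list(pathway)
    kept = tokens[-(max_len - 1):] if len(tokens) > max_len - 1 else tokens
    return [CLS_ID] + [vocabulary.id_of(t) for t in kept]
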