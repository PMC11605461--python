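"""Curation of raw terminology codes into higher-level clinical groups.

Real primary-care records use tens of thousands of distinct raw codes; a
clinically guided mapping collapses these onto a few hundred curated groups
(symptoms, diagnoses, medications, procedures, sites of encounter, tests) and
drops purely administrative terms. The mapping itself is *input data*: this
module handles the mapping format and its application, and the repository
ships a synthetic 450-group demo map (``pathdx/data/demo_codemap.csv``) so the
stage is exercisable end to end.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from pathdx.io import EventRecord, SchemaError

CATEGORIES = ("symptom", "diagnosis", "medication", "procedure", "encounter_site", "test")

CODEMAP_COLUMNS = ("raw_code", "group_id", "group_label", "category", "is_administrative")

UnknownPolicy = Literal["drop", "map_to_unknown_token"]

#: group token used when unknown raw codes are retained
UNKNOWN_GROUP = "[UNK]"


@dataclass(frozen=True)
class CodeGroup:
    group_id: str
    group_label: str
    category: str
    is_administrative: bool


@dataclass
class CodeMap:
    """Function from raw code to curated group.

    ``mapping`` is raw_code -> CodeGroup; the curated vocabulary is the set of
    distinct non-administrative group ids.
    """

    mapping: dict[str, CodeGroup] = field(default_factory=dict)

    def __contains__(self, raw_code: str) -> bool:
        return raw_code in self.mapping

    def __getitem__(self, raw_code: str) -> CodeGroup:
        return self.mapping[raw_code]

    @property
    def vocabulary(self) -> list[str]:
        """Sorted distinct non-administrative group ids."""
        return sorted(
            {g.group_id for g in self.mapping.values() if not g.is_administrative}
        )

    @property
    def vocabulary_size(self) -> int:
        return len(self.vocabulary)

    def groups_in_category(self, category: str) -> list[str]:
        return sorted(
            {
                g.group_id
                for g in self.mapping.values()
                if g.category == category and not g.is_administrative
            }
        )


@dataclass(frozen=True)
class CuratedEvent:
    """An event whose raw code has been replaced by its curated group."""

    patient_id: str
    event_date: date
    group_id: str


_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def _parse_flag(text: str, row: int) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise SchemaError(f"is_administrative flag {text!r} not boolean", row=row)


def load_code_map(path: str | Path) -> CodeMap:
    """Load ``codemap.csv``.

    Duplicate raw_code rows are tolerated when they agree exactly and are an
    error when they conflict.
    """
    path = Path(path)
    mapping: dict[str, CodeGroup] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in CODEMAP_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        for i, row in enumerate(reader):
            raw = row["raw_code"].strip()
            if not raw:
                raise SchemaError("empty raw_code", row=i)
            group = CodeGroup(
                group_id=row["group_id"].strip(),
                group_label=row["group_label"].strip(),
                category=row["category"].strip(),
                is_administrative=_parse_flag(row["is_administrative"], i),
            )
            if raw in mapping and mapping[raw] != group:
                raise SchemaError(
                    f"conflicting duplicate mapping for raw_code {raw!r}", row=i
                )
            mapping[raw] = group
    return CodeMap(mapping)


def demo_code_map_path() -> Path:
    """Path of the bundled synthetic 450-group demo mapping."""
    return Path(str(resources.files("pathdx").joinpath("data/demo_codemap.csv")))


def load_demo_code_map() -> CodeMap:
    return load_code_map(demo_code_map_path())


def demo_code_list_paths() -> dict[str, Path]:
    """Bundled diagnosis-definition code lists (lung / other cancer /
    respiratory), as group-id-per-line files."""
    data = resources.files("pathdx").joinpath("data")
    return {
        "lung": Path(str(data.joinpath("lung_cancer_codes.txt"))),
        "other_cancer": Path(str(data.joinpath("other_cancer_codes.txt"))),
        "respiratory": Path(str(data.joinpath("respiratory_codes.txt"))),
    }


def curate_events(
    events: Iterable[EventRecord],
    code_map: CodeMap,
    unknown_policy: UnknownPolicy = "drop",
) -> list[CuratedEvent]:
    """Map raw codes to curated groups, dropping administrative events.

    Input order is preserved. Unmapped raw codes are dropped or mapped to
    :data:`UNKNOWN_GROUP` according to ``unknown_policy``.
    """
    if unknown_policy not in ("drop", "map_to_unknown_token"):
        raise ValueError(f"unknown_policy {unknown_policy!r}")
    out: list[CuratedEvent] = []
    for e in events:
        group = code_map.mapping.get(e.raw_code)
        if group is None:
            if unknown_policy == "drop":
                continue
            gid = UNKNOWN_GROUP
        elif group.is_administrative:
            continue
        else:
            gid = group.group_id
        out.append(CuratedEvent(e.patient_id, e.event_date, gid))
    return out


def write_code_map(path: str | Path, code_map: CodeMap) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CODEMAP_COLUMNS)
        for raw in sorted(code_map.mapping):
            g = code_map.mapping[raw]
            w.writerow(
                [raw, g.group_id, g.group_label, g.category, int(g.is_administrative)]
            )


def build_code_map(rows: Sequence[tuple[str, str, str, str, bool]]) -> CodeMap:
    """Build a CodeMap from (raw, group_id, label, category, is_admin) tuples."""
    mapping = {}
    for raw, gid, label, cat, admin in rows:
        mapping[raw] = CodeGroup(gid, label, cat, admin)
    return CodeMap(mapping)
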