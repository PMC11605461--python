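"""Synthetic coded-EHR cohort generator with known ground truth.

Real primary-care extracts cannot be shared, so every downstream stage is
exercised on generated cohorts that emulate the relevant structure: ~3-year
event histories ending at an index date, a curated vocabulary of ~450 groups,
a mean of ~170 curated codes per case pathway, case pathways containing an ordered
progression motif whose emission hazard rises toward the index date, control
strata (other cancers / chronic respiratory / other), and latent patient
subgroups with distinct background code usage.

Two signal regimes are supported:

* ``marginal_shift`` — cases receive the progression-motif emissions on top of
  background; controls do not. Both a bag-of-codes model and a sequence model
  can detect this. The background process itself is identical across arms, so
  removing the motif events (e.g. by trimming a window the hazard is
  concentrated in) leaves the arms indistinguishable.
* ``order_only`` — cases and controls draw background tokens and motif
  emission times from *identical* processes (same background distribution,
  same motif hazard, same expected counts); the only difference is that cases
  assign motif tokens to their time-sorted emissions in canonical motif order
  while controls assign them in random order. Case and control code marginals
  are then identical in distribution and only the within-pathway ordering
  carries label signal — isolating what a sequence model can learn that a
  bag-of-codes model cannot. (Trimming an ordered stream re-introduces a
  slight marginal difference — late-cycle motif tokens are preferentially
  removed from cases — so order-only analyses are run untrimmed.)

Emission model: background events are a homogeneous Poisson process over the
36-month window with a per-subgroup categorical token distribution; motif
tokens are an inhomogeneous process whose monthly hazard profile is part of
the configuration (entry 0 = earliest month, entry 35 = the month immediately
before index).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from pathdx import vocab_spec
from pathdx.curation import CodeMap
from pathdx.io import EventRecord, PatientRecord, write_events, write_patients
from pathdx.pathways import months_before
from pathdx.vocab_spec import (
    LUNG_DX,
    OTHER_CANCER_DX,
    OTHER_DX,
    RESPIRATORY_DX,
)


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class Motif:
    """An ordered token subsequence planted in case pathways.

    ``hazard[m]`` is the expected number of motif-token emissions in month
    ``m`` of the 36-month window (m=0 earliest, m=35 adjacent to the index
    date). Emission times are drawn per month; tokens are assigned to the
    time-sorted emissions cyclically in motif order.
    """

    tokens: tuple[str, ...]
    hazard: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.hazard):
            raise ConfigurationError("motif hazard must be non-negative")
        if not self.tokens:
            raise ConfigurationError("motif needs at least one token")

    @property
    def expected_emissions(self) -> float:
        return float(sum(self.hazard))


@dataclass(frozen=True)
class Subgroup:
    """A latent patient subgroup: a background token-usage profile.

    ``boost`` is the fraction of background probability mass concentrated
    uniformly on ``boosted_tokens`` (the first of which acts as the
    subgroup's anchor code); the rest follows the shared base distribution.
    An optional ``motif`` (e.g. a chronic-condition monitoring cycle) is
    emitted in order for every patient of the subgroup, in both arms.
    ``case_motif`` plants a subgroup-specific progression pattern in the
    subgroup's *cases only* (distinct pathways to the same diagnosis), in
    addition to any cohort-wide motifs.
    """

    label: str
    boosted_tokens: tuple[str, ...] = ()
    boost: float = 0.0
    motif: "Motif | None" = None
    case_motif: "Motif | None" = None
    #: multiplier on the subgroup's background event rate (utilisation level)
    length_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.boost <= 0.9:
            raise ConfigurationError("subgroup boost must be in [0, 0.9]")
        if self.length_factor <= 0:
            raise ConfigurationError("length_factor must be positive")
        if self.boost > 0 and not self.boosted_tokens:
            raise ConfigurationError("boost > 0 requires boosted_tokens")


def default_motifs() -> list[Motif]:
    """Lung-cancer progression motif: escalating respiratory presentation
    over the final year, from cough through imaging to haemoptysis."""
    ramp = [0.1] * 24 + [0.2 + 1.6 * i / 11 for i in range(12)]
    return [
        Motif(
            tokens=(
                "cough",
                "chest_infection",
                "antibiotic_rx",
                "dyspnoea",
                "chest_xray",
                "haemoptysis",
            ),
            hazard=tuple(ramp),
        )
    ]


def default_subgroups() -> list[Subgroup]:
    return [
        Subgroup(
            "copd",
            (
                "copd_monitoring",
                "salbutamol_rx",
                "steroid_inhaler_rx",
                "spirometry",
                "wheeze",
                "smoking_cessation_advice",
            ),
            boost=0.35,
        ),
        Subgroup(
            "diabetes",
            (
                "diabetes_review",
                "metformin_rx",
                "hba1c_test",
                "blood_pressure_check",
                "statin_rx",
                "medication_review",
            ),
            boost=0.35,
        ),
        Subgroup("general", (), 0.0),
    ]


#: control composition of the combined case-control set used as weights
#: within the control arm (respiratory-heavy over-selection).
DEFAULT_CONTROL_WEIGHTS = {
    "respiratory": 0.405,
    "other_cancer": 0.280,
    "other": 0.315,
}


@dataclass
class SynthConfig:
    """Study conditions of a synthetic cohort."""

    n_patients: int = 2000
    case_fraction: float = 0.444
    control_strata_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_WEIGHTS)
    )
    vocab_size: int = 450
    mean_pathway_length: float = 170.0
    motifs: list[Motif] = field(default_factory=default_motifs)
    subgroups: list[Subgroup] = field(default_factory=default_subgroups)
    signal_mode: Literal["marginal_shift", "order_only"] = "marginal_shift"
    lookback_months: int = 36
    observation_end: date = date(2020, 12, 31)
    admin_event_mean: float = 6.0
    #: mean number of earlier in-window copies of a control's chronic
    #: diagnosis code (monitoring); 0 disables them
    control_monitoring_mean: float = 1.5
    seed: int = 0

    def validate(self, code_map: CodeMap) -> None:
        if self.n_patients * self.case_fraction < 1:
            raise ConfigurationError(
                "n_patients * case_fraction < 1: no cases would be generated"
            )
        if not 0 < self.case_fraction < 1:
            raise ConfigurationError("case_fraction must be in (0,1)")
        w = self.control_strata_weights
        if set(w) != {"respiratory", "other_cancer", "other"} or any(
            v < 0 for v in w.values()
        ) or sum(w.values()) <= 0:
            raise ConfigurationError("invalid control_strata_weights")
        vocab = set(code_map.vocabulary)
        referenced = {t for m in self.motifs for t in m.tokens} | {
            t for s in self.subgroups for t in s.boosted_tokens
        } | {
            t for s in self.subgroups if s.motif for t in s.motif.tokens
        } | {
            t for s in self.subgroups if s.case_motif for t in s.case_motif.tokens
        }
        missing = referenced - vocab
        if missing:
            raise ConfigurationError(
                f"vocab_size={self.vocab_size} too small: motif/subgroup tokens "
                f"not in vocabulary: {sorted(missing)}"
            )
        dx = {
            g.group_id for g in code_map.mapping.values()
            if g.category == "diagnosis" and not g.is_administrative
        }
        bad = {t for s in self.subgroups for t in s.boosted_tokens} & dx
        if bad:
            raise ConfigurationError(
                "subgroup boosted_tokens must be non-diagnosis groups "
                f"(diagnosis codes are emitted per stratum): {sorted(bad)}"
            )
        sub_motifs = [s.motif for s in self.subgroups if s.motif is not None]
        sub_motifs += [s.case_motif for s in self.subgroups if s.case_motif is not None]
        for m in list(self.motifs) + sub_motifs:
            if len(m.hazard) != self.lookback_months:
                raise ConfigurationError(
                    f"motif hazard length {len(m.hazard)} != lookback "
                    f"{self.lookback_months}"
                )


@dataclass(frozen=True)
class TruthEntry:
    patient_id: str
    label: int
    stratum: str
    subgroup: str
    index_date: date


@dataclass
class GroundTruth:
    entries: dict[str, TruthEntry]

    def __getitem__(self, pid: str) -> TruthEntry:
        return self.entries[pid]

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "label", "stratum", "subgroup", "index_date"])
            for pid in sorted(self.entries):
                e = self.entries[pid]
                w.writerow([pid, e.label, e.stratum, e.subgroup, e.index_date.isoformat()])

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        entries = {}
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[row["patient_id"]] = TruthEntry(
                    row["patient_id"],
                    int(row["label"]),
                    row["stratum"],
                    row["subgroup"],
                    date.fromisoformat(row["index_date"]),
                )
        return cls(entries)


@dataclass
class Cohort:
    patients: list[PatientRecord]
    events: list[EventRecord]
    code_map: CodeMap
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        from pathdx.curation import write_code_map

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_patients(outdir / "patients.csv", self.patients)
        write_events(outdir / "events.csv", self.events)
        write_code_map(outdir / "codemap.csv", self.code_map)
        self.truth.write(outdir / "ground_truth.csv")


# --- internal helpers -------------------------------------------------------


def _background_distribution(
    groups: Sequence[str], subgroup: Subgroup
) -> np.ndarray:
    """Zipf-flavoured base usage, re-weighted by the subgroup's boost."""
    base = 1.0 / (np.arange(len(groups)) + 30.0)
    base /= base.sum()
    if subgroup.boost > 0:
        idx = {g: i for i, g in enumerate(groups)}
        boosted = np.zeros(len(groups))
        for t in subgroup.boosted_tokens:
            boosted[idx[t]] = 1.0
        boosted /= boosted.sum()
        base = (1.0 - subgroup.boost) * base + subgroup.boost * boosted
    return base


def _month_spans(index_date: date, lookback: int) -> list[tuple[date, date]]:
    """Half-open [start, end) spans of each month in the window, earliest first."""
    edges = [months_before(index_date, lookback - m) for m in range(lookback + 1)]
    return list(zip(edges[:-1], edges[1:]))


def _uniform_day(rng: np.random.Generator, lo: date, hi: date) -> date:
    """A uniform day in [lo, hi)."""
    span = (hi - lo).days
    return lo + timedelta(days=int(rng.integers(0, max(span, 1))))


def _draw_motif_times(
    rng: np.random.Generator, motif: Motif, spans: list[tuple[date, date]]
) -> list[date]:
    times: list[date] = []
    for h, (lo, hi) in zip(motif.hazard, spans):
        for _ in range(rng.poisson(h)):
            times.append(_uniform_day(rng, lo, hi))
    times.sort()
    return times


def _assign_motif_tokens(
    rng: np.random.Generator, motif: Motif, times: list[date], ordered: bool
) -> list[tuple[date, str]]:
    tokens = [motif.tokens[i % len(motif.tokens)] for i in range(len(times))]
    if not ordered:
        tokens = list(rng.permutation(tokens))
    return list(zip(times, tokens))


@dataclass
class _Stream:
    """Internal per-patient curated token stream before raw-code emission."""

    pid: str
    stratum: str
    subgroup: str
    index_date: date
    dated_tokens: list[tuple[date, str]]
    background_tokens: list[str]
    motif_counts: list[int]


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate (patients, events, code map, ground truth) for ``config``.

    Deterministic: identical (config, seed) reproduce identical output.
    """
    code_map = vocab_spec.make_code_map(config.vocab_size)
    config.validate(code_map)
    rng = np.random.default_rng(config.seed)

    groups = code_map.vocabulary
    dx_groups = set(code_map.groups_in_category("diagnosis"))
    background_groups = [g for g in groups if g not in dx_groups]
    bg_index = {g: i for i, g in enumerate(background_groups)}
    bg_dists = {
        s.label: _background_distribution(background_groups, s)
        for s in config.subgroups
    }

    other_dx_pool = [g for g in OTHER_DX if g in set(groups)]
    resp_dx_pool = [g for g in RESPIRATORY_DX if g in set(groups)]
    cancer_dx_pool = [g for g in OTHER_CANCER_DX if g in set(groups)]

    e_motif = sum(m.expected_emissions for m in config.motifs)
    sub_by_label = {s.label: s for s in config.subgroups}
    e_sub_motif = {
        s.label: (s.motif.expected_emissions if s.motif else 0.0)
        for s in config.subgroups
    }
    e_case_motif = {
        s.label: (s.case_motif.expected_emissions if s.case_motif else 0.0)
        for s in config.subgroups
    }

    n_cases = int(round(config.n_patients * config.case_fraction))
    n_controls = config.n_patients - n_cases
    strata = ["lung"] * n_cases
    w = config.control_strata_weights
    names = ["respiratory", "other_cancer", "other"]
    probs = np.array([w[n] for n in names], dtype=float)
    probs /= probs.sum()
    strata += [names[i] for i in rng.choice(3, size=n_controls, p=probs)]

    subgroup_labels = [s.label for s in config.subgroups]

    def draw_background(sub: str, mean_n: float) -> list[str]:
        n_bg = rng.poisson(max(mean_n, 0.0))
        dist = bg_dists[sub]
        picks = rng.choice(len(background_groups), size=n_bg, p=dist)
        return [background_groups[i] for i in picks]

    def place_background(tokens: list[str], lo: date, hi: date) -> list[tuple[date, str]]:
        return [(_uniform_day(rng, lo, hi), t) for t in tokens]

    # pass 1: token streams
    streams: list[_Stream] = []
    year_start = months_before(config.observation_end, 12)
    for i, stratum in enumerate(strata):
        pid = f"P{i:06d}"
        sub = subgroup_labels[int(rng.integers(0, len(subgroup_labels)))]
        index_date = _uniform_day(rng, year_start, config.observation_end + timedelta(days=1))
        lo = months_before(index_date, config.lookback_months)
        spans = _month_spans(index_date, config.lookback_months)
        is_case = stratum == "lung"

        # in order-only mode everyone carries the motif emissions; only the
        # token-to-time assignment order differs between cases and controls
        carries_motif = is_case or config.signal_mode == "order_only"
        # the background process is identical across arms (motif expectations
        # are subtracted for everyone), so the case/control difference is the
        # planted motif itself — not a compensating background-rate shift that
        # would survive trimming as a length artefact. mean_pathway_length
        # therefore pins the motif-carrying arm's total.
        mean_bg = (
            config.mean_pathway_length - 1
            - e_motif
            - e_sub_motif[sub]
            - e_case_motif[sub]
        ) * sub_by_label[sub].length_factor
        bg_tokens = draw_background(sub, mean_bg)

        dated: list[tuple[date, str]] = [(lo, "gp_surgery_visit")]
        dated += place_background(bg_tokens, lo, index_date)
        motif_counts: list[int] = []
        if carries_motif:
            for m in config.motifs:
                times = _draw_motif_times(rng, m, spans)
                motif_counts.append(len(times))
                dated += _assign_motif_tokens(rng, m, times, ordered=is_case)
        sub_motif = sub_by_label[sub].motif
        if sub_motif is not None:
            times = _draw_motif_times(rng, sub_motif, spans)
            dated += _assign_motif_tokens(rng, sub_motif, times, ordered=True)
        case_motif = sub_by_label[sub].case_motif
        if is_case and case_motif is not None:
            times = _draw_motif_times(rng, case_motif, spans)
            dated += _assign_motif_tokens(rng, case_motif, times, ordered=True)

        streams.append(_Stream(pid, stratum, sub, index_date, dated, bg_tokens, motif_counts))

    # pass 2: endpoint diagnostic codes, admin noise, raw-code emission
    patients: list[PatientRecord] = []
    events: list[EventRecord] = []
    entries: dict[str, TruthEntry] = {}
    ethnicities = ["white_british", "white_other", "indian", "black_african",
                   "caribbean", "other"]
    eth_p = np.array([0.33, 0.22, 0.15, 0.08, 0.07, 0.15])
    for s in streams:
        lo = months_before(s.index_date, config.lookback_months)
        dated = list(s.dated_tokens)
        if s.stratum == "lung":
            dated.append((s.index_date, LUNG_DX))
            label = 1
        elif s.stratum == "other_cancer":
            dated.append((s.index_date, cancer_dx_pool[int(rng.integers(0, len(cancer_dx_pool)))]))
            label = 0
        else:
            pool = resp_dx_pool if s.stratum == "respiratory" else other_dx_pool
            dx = pool[int(rng.integers(0, len(pool)))]
            dated.append((s.index_date, dx))
            if config.signal_mode != "order_only":
                # earlier monitoring copies of the chronic diagnosis; omitted in
                # order-only mode where in-window marginals must match cases
                for _ in range(rng.poisson(config.control_monitoring_mean)):
                    dated.append((_uniform_day(rng, lo, s.index_date), dx))
            label = 0

        for _ in range(rng.poisson(config.admin_event_mean)):
            g = vocab_spec.ADMIN_GROUPS[int(rng.integers(0, len(vocab_spec.ADMIN_GROUPS)))]
            dated.append((_uniform_day(rng, lo, s.index_date), g))

        for d, g in dated:
            raws = vocab_spec.raw_codes_for(g)
            events.append(EventRecord(s.pid, d, raws[int(rng.integers(0, len(raws)))]))

        age_mean, age_sd = (71.0, 10.0) if label == 1 else (58.0, 13.0)
        age = float(np.clip(rng.normal(age_mean, age_sd), 25.0, 95.0))
        birth = s.index_date - timedelta(days=int(age * 365.25))
        patients.append(
            PatientRecord(
                s.pid,
                birth,
                "M" if rng.random() < 0.5 else "F",
                ethnicities[int(rng.choice(len(ethnicities), p=eth_p))],
            )
        )
        entries[s.pid] = TruthEntry(s.pid, label, s.stratum, s.subgroup, s.index_date)

    events.sort(key=lambda e: (e.patient_id, e.event_date, e.raw_code))
    return Cohort(patients, events, code_map, GroundTruth(entries))


def utilisation_subgroups() -> list[Subgroup]:
    """Three strongly contrasted latent subgroups for subtype-recovery studies.

    The subgroups differ in background code profile (70% of background mass on
    disjoint token sets), in monitoring motifs, and in consultation intensity
    (length factors 1.5 / 1.0 / 0.55) — emulating the kinds of cluster axes a
    pathway model surfaces in practice (chronic-condition monitoring versus
    sparse attendance).
    """
    flat = tuple([14 / 36.0] * 36)
    return [
        Subgroup(
            "copd_monitored",
            ("copd_monitoring", "salbutamol_rx", "steroid_inhaler_rx",
             "spirometry", "wheeze", "smoking_cessation_advice",
             "peak_flow", "oxygen_saturation"),
            boost=0.7,
            motif=Motif(("copd_monitoring", "spirometry", "salbutamol_rx",
                         "peak_flow"), flat),
            length_factor=1.5,
        ),
        Subgroup(
            "diabetes_monitored",
            ("diabetes_review", "metformin_rx", "hba1c_test",
             "blood_pressure_check", "statin_rx", "medication_review",
             "flu_vaccination", "renal_function_test"),
            boost=0.7,
            motif=Motif(("diabetes_review", "hba1c_test", "metformin_rx",
                         "blood_pressure_check"), flat),
            length_factor=1.0,
        ),
        Subgroup(
            "low_attender",
            ("joint_pain", "back_pain", "simple_analgesic_rx",
             "insomnia", "headache", "dizziness", "rash", "abdominal_pain"),
            boost=0.7,
            length_factor=0.55,
        ),
    ]


def desk_config(**overrides) -> SynthConfig:
    """Reduced-scale study conditions for tests and examples.

    Shorter pathways (mean 40 curated codes) and a compressed motif hazard
    keep transformer training tractable on one CPU while preserving the
    qualitative structure of the full-scale generator.
    """
    ramp = [0.05] * 24 + [0.1 + 0.9 * i / 11 for i in range(12)]
    cfg = SynthConfig(
        n_patients=1000,
        mean_pathway_length=40.0,
        motifs=[
            Motif(
                tokens=(
                    "cough",
                    "chest_infection",
                    "antibiotic_rx",
                    "dyspnoea",
                    "chest_xray",
                    "haemoptysis",
                ),
                hazard=tuple(ramp),
            )
        ],
    )
    return replace(cfg, **overrides)
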