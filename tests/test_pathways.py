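from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathdx.curation import CuratedEvent
from pathdx.pathways import (
    CLS_ID,
    NoIndexDate,
    Pathway,
    Vocabulary,
    derive_pathway,
    filter_min_codes,
    months_before,
    select_index_date,
    strip_label_codes,
    tokenize,
)


def cev(group, y, m, d):
    return CuratedEvent("p", date(y, m, d), group)


LUNG = {"lungCa"}
CANCER = {"breastCa"}


class TestSelectIndexDate:
    def test_first_lung_code_is_endpoint(self):
        events = [
            cev("cough", 2018, 1, 1),
            cev("lungCa", 2019, 5, 2),
            cev("lungCa", 2020, 1, 1),
        ]
        index, stratum = select_index_date(events, LUNG, CANCER)
        assert (index, stratum) == (date(2019, 5, 2), "lung")

    def test_lung_precedence_over_earlier_other_cancer(self):
        events = [cev("breastCa", 2019, 3, 3), cev("lungCa", 2018, 1, 1)]
        index, stratum = select_index_date(events, LUNG, CANCER)
        assert (index, stratum) == (date(2018, 1, 1), "lung")

    def test_control_uses_most_recent_diagnostic_code(self):
        events = [cev("copd_dx", 2017, 2, 1), cev("copd_dx", 2019, 9, 9)]
        index, stratum = select_index_date(
            events, LUNG, CANCER,
            diagnostic_codes={"copd_dx"}, respiratory_codes={"copd_dx"},
        )
        assert (index, stratum) == (date(2019, 9, 9), "respiratory")

    def test_other_cancer_uses_first_cancer_code(self):
        events = [cev("breastCa", 2019, 3, 3), cev("breastCa", 2017, 1, 1)]
        index, stratum = select_index_date(events, LUNG, CANCER)
        assert (index, stratum) == (date(2017, 1, 1), "other_cancer")

    def test_no_diagnostic_code_raises(self):
        with pytest.raises(NoIndexDate):
            select_index_date(
                [cev("cough", 2020, 1, 1)], LUNG, CANCER, diagnostic_codes={"copd_dx"}
            )


class TestDeriveWindow:
    def test_trim_boundary_is_half_open(self):
        index = date(2020, 6, 15)
        inside = cev("a", 2020, 5, 14)
        outside = cev("b", 2020, 5, 15)
        p = derive_pathway([inside, outside], index, 1, "lung", "p", trim_months=1)
        assert p.tokens == ["a"]

    def test_trim_zero_excludes_index_date_itself(self):
        index = date(2020, 6, 15)
        events = [cev("a", 2020, 6, 14), cev("b", 2020, 6, 15)]
        p = derive_pathway(events, index, 0, "other", "p", trim_months=0)
        assert p.tokens == ["a"]

    def test_lower_bound_closed(self):
        index = date(2020, 6, 15)
        events = [cev("a", 2017, 6, 15), cev("b", 2017, 6, 14)]
        p = derive_pathway(events, index, 0, "other", "p")
        assert p.tokens == ["a"]

    def test_trim_not_less_than_lookback_errors(self):
        with pytest.raises(ValueError):
            derive_pathway([], date(2020, 1, 1), 0, "other", "p",
                           lookback_months=36, trim_months=36)

    def test_retained_set_matches_brute_force_window_oracle(self, rng):
        index = date(2020, 6, 15)
        events = [
            cev(f"g{i:03d}", 2016 + int(rng.integers(0, 5)),
                int(rng.integers(1, 13)), int(rng.integers(1, 29)))
            for i in range(100)
        ]
        p = derive_pathway(events, index, 0, "other", "p",
                           lookback_months=36, trim_months=1)
        lo, hi = months_before(index, 36), months_before(index, 1)
        expected = sorted(
            e.group_id for e in events if lo <= e.event_date < hi
        )
        assert sorted(p.tokens) == expected

    def test_tokens_sorted_by_date_then_group(self):
        index = date(2020, 6, 15)
        events = [cev("b", 2020, 1, 1), cev("a", 2020, 1, 1), cev("c", 2019, 1, 1)]
        p = derive_pathway(events, index, 0, "other", "p")
        assert p.tokens == ["c", "a", "b"]

    @given(shift=st.integers(min_value=-400, max_value=400))
    @settings(max_examples=25, deadline=None)
    def test_windowing_translation_invariant(self, shift):
        # calendar-month boundaries move by up to ~3 days under a day shift,
        # so the invariant is tested with events clear of the boundary band
        index = date(2019, 6, 15)
        offsets = [-1200, -1000, -700, -400, -100, -45, -15, -1]
        events = [
            CuratedEvent("p", index + timedelta(days=o), f"g{i}")
            for i, o in enumerate(offsets)
        ]
        base = derive_pathway(events, index, 0, "other", "p", trim_months=1).tokens
        moved = [
            CuratedEvent("p", e.event_date + timedelta(days=shift), e.group_id)
            for e in events
        ]
        shifted = derive_pathway(
            moved, index + timedelta(days=shift), 0, "other", "p", trim_months=1
        ).tokens
        assert base == shifted

    @given(t1=st.integers(0, 6), t2=st.integers(0, 6))
    @settings(max_examples=25, deadline=None)
    def test_monotone_trimming(self, t1, t2):
        if t1 > t2:
            t1, t2 = t2, t1
        index = date(2020, 6, 15)
        events = [
            CuratedEvent("p", index - timedelta(days=int(d)), f"g{i}")
            for i, d in enumerate(range(1, 1000, 37))
        ]
        wide = derive_pathway(events, index, 0, "other", "p", trim_months=t1).tokens
        narrow = derive_pathway(events, index, 0, "other", "p", trim_months=t2).tokens
        assert set(narrow) <= set(wide)


def test_month_arithmetic_clamps_to_month_end():
    assert months_before(date(2020, 3, 31), 1) == date(2020, 2, 29)
    assert months_before(date(2019, 3, 31), 1) == date(2019, 2, 28)
    assert months_before(date(2020, 6, 15), 36) == date(2017, 6, 15)


class TestMinCodesFilter:
    def _pathway(self, n):
        return Pathway("p", [f"g{i}" for i in range(n)], date(2020, 1, 1), 0, "other")

    def test_nine_tokens_removed_ten_retained(self):
        kept = filter_min_codes([self._pathway(9), self._pathway(10)])
        assert [len(p) for p in kept] == [10]

    def test_all_long_pathways_pass_through(self):
        paths = [self._pathway(n) for n in (10, 15, 200)]
        assert filter_min_codes(paths) == paths


class TestStripLabelCodes:
    def test_diagnostic_tokens_removed_order_preserved(self):
        p = Pathway("p", ["cough", "lungCa", "dyspnoea"], date(2020, 1, 1), 1, "lung")
        out = strip_label_codes(p, LUNG, CANCER)
        assert out.tokens == ["cough", "dyspnoea"]

    def test_no_diagnostic_tokens_unchanged(self):
        p = Pathway("p", ["cough", "wheeze"], date(2020, 1, 1), 0, "other")
        assert strip_label_codes(p, LUNG, CANCER).tokens == p.tokens

    def test_matches_membership_oracle(self, rng):
        tokens = [f"g{int(i)}" for i in rng.integers(0, 20, size=200)]
        tokens += ["lungCa", "breastCa"] * 5
        rng.shuffle(tokens)
        p = Pathway("p", list(tokens), date(2020, 1, 1), 1, "lung")
        out = strip_label_codes(p, LUNG, CANCER)
        assert out.tokens == [t for t in tokens if t not in LUNG | CANCER]


class TestTokenize:
    def test_cls_prepended(self):
        vocab = Vocabulary.from_groups(["A", "B"])
        assert tokenize(["A", "B"], vocab) == [CLS_ID, 4, 5]

    def test_truncation_keeps_most_recent(self):
        vocab = Vocabulary.from_groups([f"g{i:03d}" for i in range(700)])
        tokens = [f"g{i:03d}" for i in range(600)]
        out = tokenize(tokens, vocab, max_len=512)
        assert len(out) == 512
        assert out[0] == CLS_ID
        assert out[1:] == [vocab.id_of(t) for t in tokens[-511:]]

    def test_empty_pathway_is_just_cls(self):
        vocab = Vocabulary.from_groups(["A"])
        assert tokenize([], vocab) == [CLS_ID]

    def test_unknown_tokens_map_to_unk(self):
        vocab = Vocabulary.from_groups(["A"])
        assert tokenize(["A", "nope"], vocab) == [CLS_ID, 4, 1]


def test_vocabulary_layout_and_size():
    vocab = Vocabulary.from_groups([f"g{i}" for i in range(450)])
    assert len(vocab) == 454
    assert [vocab.id_of(t) for t in ("[PAD]", "[UNK]", "[CLS]", "[MASK]")] == [0, 1, 2, 3]
    assert list(vocab.group_ids) == list(range(4, 454))
    assert vocab.token_of(vocab.id_of("g7")) == "g7"
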