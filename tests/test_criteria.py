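"""Declarative criterion engine: loading, scoring, binarization, oracles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhrisk import criteria
from fhrisk.cohort import derive_flags
from fhrisk.criteria import (CRITERION_NAMES, CriterionConfigError, binarize,
                             evaluate_predicate, load_builtin, load_criterion,
                             score)
from tests.conftest import make_record, record_with_flags


def brute_force_points(defn, record, flags):
    """Independent oracle: fire every predicate, take the max per group, sum."""
    fired = {}
    for item in defn.items:
        if evaluate_predicate(item.when, record, flags):
            key = item.group or item.id
            fired.setdefault(key, []).append(item.points)
    return sum(max(pts) for pts in fired.values())


class TestLoading:
    def test_all_builtin_load(self):
        defs = criteria.load_all_builtin()
        assert set(defs) == set(CRITERION_NAMES)

    def test_dlcn_shape(self):
        dlcn = load_builtin("DLCN")
        assert dlcn.mode == "points"
        assert dlcn.levels == ("unlikely", "possible", "probable", "definite")
        ldl_points = [it.points for it in dlcn.items if it.group == "ldl"]
        assert max(ldl_points) == 8

    def test_ldlc_tc_is_lab_only_two_level(self):
        defn = load_builtin("LDLC_TC")
        assert defn.mode == "rules" and defn.n_levels == 2
        fields = {p["field"] for it in defn.items for p in _leaves(it.when)}
        assert fields <= {"ldl_untreated", "tc"}

    def test_overlapping_thresholds_rejected(self):
        cfg = {"name": "BAD", "mode": "points", "levels": ["low", "high"],
               "level_thresholds": {"low": [None, 5], "high": [5, None]},
               "items": [{"id": "a", "points": 5,
                          "when": {"field": "ldl_untreated", "ge": 5}}]}
        with pytest.raises(CriterionConfigError, match="overlap"):
            load_criterion(cfg)

    def test_duplicate_item_ids_rejected(self):
        cfg = {"name": "BAD", "mode": "rules", "levels": ["low", "high"],
               "items": [{"id": "a", "when": {"field": "tc", "ge": 5}},
                         {"id": "a", "when": {"field": "tc", "ge": 6}}],
               "rules": {"high": {"any_of": ["a"]}}}
        with pytest.raises(CriterionConfigError, match="duplicate"):
            load_criterion(cfg)

    def test_unknown_field_rejected(self):
        cfg = {"name": "BAD", "mode": "rules", "levels": ["low", "high"],
               "items": [{"id": "a", "when": {"field": "chakra", "ge": 5}}],
               "rules": {"high": {"any_of": ["a"]}}}
        with pytest.raises(CriterionConfigError, match="unknown field"):
            load_criterion(cfg)


def _leaves(pred):
    if "all" in pred:
        for p in pred["all"]:
            yield from _leaves(p)
    elif "any" in pred:
        for p in pred["any"]:
            yield from _leaves(p)
    elif "not" in pred:
        yield from _leaves(pred["not"])
    else:
        yield pred


class TestScoring:
    def test_all_negative_adult_is_unlikely(self):
        rec, flags = record_with_flags(ldl_c=2.0)
        res = score(load_builtin("DLCN"), rec, flags)
        assert res.points == 0 and res.level == "unlikely"

    def test_isolated_ldl_9_scores_the_8_point_band(self):
        # untreated LDL 9.0 fires the top LDL band under DLCN and mDLCN
        rec, flags = record_with_flags(ldl_c=9.0, tc=10.5)
        for name in ("DLCN", "MDLCN"):
            res = score(load_builtin(name), rec, flags)
            assert res.points == 8
            assert res.level == "probable"  # 6-8 band without other findings

    def test_possible_fh_ldl_thresholds(self):
        # LDL-C >= 5.0 is possible FH under DLCN and TW; >= 3.5 under mDLCN
        rec, flags = record_with_flags(ldl_c=5.2, tc=6.8)
        assert score(load_builtin("DLCN"), rec, flags).level == "possible"
        assert score(load_builtin("TW"), rec, flags).level == "possible"
        rec, flags = record_with_flags(ldl_c=3.6, tc=5.2)
        assert score(load_builtin("MDLCN"), rec, flags).level == "possible"
        assert score(load_builtin("DLCN"), rec, flags).level == "unlikely"

    def test_tw_uses_strict_premature_ages(self):
        rec, flags = record_with_flags(age=70, chd_onset_age=50)  # male
        dlcn = score(load_builtin("DLCN"), rec, flags)
        tw = score(load_builtin("TW"), rec, flags)
        assert "premature_chd" in dlcn.fired_items
        assert "premature_chd_tw" not in tw.fired_items

    def test_scoring_uses_untreated_ldl(self):
        rec, flags = record_with_flags(ldl_c=3.0, tc=5.0, therapy_level="high")
        assert flags.ldl_untreated == pytest.approx(6.0)
        res = score(load_builtin("MDLCN"), rec, flags)
        assert "ldl_ge_6_0" in res.fired_items

    @given(ldl=st.floats(0.5, 14.0), pchd=st.booleans(),
           xanth=st.booleans(), fh=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_points_match_brute_force_oracle(self, ldl, pchd, xanth, fh):
        rec = make_record(
            age=58, ldl_c=ldl, tc=ldl + 1.5, tendon_xanthomata=xanth,
            chd_onset_age=44 if pchd else None,
            fh_chd_onset_age=50 if fh else None,
            fh_chd_relative_sex="male" if fh else None)
        flags = derive_flags(rec)
        for name in ("DLCN", "MDLCN", "TW", "LPA_DLCN"):
            defn = load_builtin(name)
            assert score(defn, rec, flags).points == \
                brute_force_points(defn, rec, flags)

    @given(lo=st.floats(0.5, 12.0), hi=st.floats(0.5, 12.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_untreated_ldl(self, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        r_lo, f_lo = record_with_flags(ldl_c=lo, tc=lo + 1.5)
        r_hi, f_hi = record_with_flags(ldl_c=hi, tc=hi + 1.5)
        for name in ("DLCN", "MDLCN", "TW"):
            defn = load_builtin(name)
            assert score(defn, r_hi, f_hi).points >= score(defn, r_lo, f_lo).points
            assert score(defn, r_hi, f_hi).level_index >= \
                score(defn, r_lo, f_lo).level_index

    @given(ldl=st.floats(0.5, 14.0), xanth=st.booleans(),
           genetic=st.sampled_from(["negative", "not_done"]), fh=st.booleans())
    @settings(max_examples=100, deadline=None)
    def test_jfhmc_needs_genetic_confirmation(self, ldl, xanth, genetic, fh):
        rec = make_record(ldl_c=ldl, tc=ldl + 1.5, tendon_xanthomata=xanth,
                          genetic_test=genetic,
                          fh_chd_onset_age=40 if fh else None,
                          fh_chd_relative_sex="female" if fh else None)
        res = score(load_builtin("JFHMC"), rec, derive_flags(rec))
        assert res.level_index == 0

    def test_jfhmc_fires_with_positive_test(self):
        rec, flags = record_with_flags(ldl_c=6.0, tc=7.5, genetic_test="positive")
        assert score(load_builtin("JFHMC"), rec, flags).level == "definite"


class TestBinarize:
    def _res(self, idx):
        return criteria.CriterionResult(criterion="DLCN", level_index=idx,
                                        level="x", points=None, fired_items=())

    def test_probable_is_risky_under_top2(self):
        assert binarize(self._res(2), 4, "top2")

    def test_possible_splits_top2_vs_top3(self):
        assert not binarize(self._res(1), 4, "top2")
        assert binarize(self._res(1), 4, "top3")

    @pytest.mark.parametrize("n_levels,scheme", [(2, "top1"), (3, "top2"), (4, "top3")])
    def test_lowest_level_never_risky(self, n_levels, scheme):
        assert not binarize(self._res(0), n_levels, scheme)

    def test_scheme_deeper_than_levels_rejected(self):
        with pytest.raises(ValueError):
            binarize(self._res(0), 2, "top2")

    def test_nested_in_scheme_depth_and_level(self):
        # deeper schemes flag supersets: top1 => top2 => top3
        for idx in range(4):
            flags = [binarize(self._res(idx), 4, s)
                     for s in ("top1", "top2", "top3")]
            for shallower, deeper in zip(flags, flags[1:]):
                assert deeper or not shallower
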