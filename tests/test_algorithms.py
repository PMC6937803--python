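"""Rule grid semantics: eligibility, application, nesting, stratification."""

import datetime as dt
import itertools

import pytest

import sclerotype as st
from sclerotype.algorithms import (
    AlgorithmSpec,
    apply_algorithm,
    exclude_by_code,
    flagged_set,
    is_eligible,
    specs_from_json,
    specs_to_json,
    stratify_by_first_code_date,
    published_grid,
)
from sclerotype.features import FeatureVector
from sclerotype.model import CodeSystem


def fv(icd9=0, icd10=0, any10=None, ana="negative", rp=False, sid="X"):
    if any10 is None:
        any10 = icd10 > 0
    return FeatureVector(sid, icd9, icd10, any10, ana, rp, 1.0)


class TestGrid:
    def test_grid_has_32_specs(self):
        grid = published_grid()
        assert len(grid) == 32
        assert len({s.name for s in grid}) == 32

    def test_first_spec_is_one_count_icd9(self):
        first = published_grid()[0]
        assert first.code_logic == "icd9_only"
        assert first.icd9_min == 1
        assert first.ana_clause == "absent" and first.rp_clause == "absent"

    def test_icd10_and_rp_family_absent(self):
        # too few ICD-10-era subjects with note data to evaluate it
        for spec in published_grid():
            assert not (spec.uses_icd10 and spec.uses_rp)

    def test_eight_families_by_four_thresholds(self):
        grid = published_grid()
        families = {}
        for s in grid:
            key = (s.code_logic, s.ana_clause, s.rp_clause)
            families.setdefault(key, []).append(s)
        assert len(families) == 8
        assert all(len(v) == 4 for v in families.values())

    def test_json_round_trip(self, tmp_path):
        grid = published_grid()
        specs_to_json(grid, tmp_path / "grid.json")
        assert specs_from_json(tmp_path / "grid.json") == grid


class TestSpecValidation:
    def test_threshold_required(self):
        with pytest.raises(ValueError):
            AlgorithmSpec("bad", "icd9_only")

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            AlgorithmSpec("bad", "icd9_only", icd9_min=0)


class TestEligibility:
    def test_icd10_spec_requires_icd10_era(self):
        spec = AlgorithmSpec("s", "icd10_only", icd10_min=1)
        ok, reason = is_eligible(fv(icd9=5, icd10=0, any10=False), spec)
        assert not ok and "ICD-10" in reason

    def test_ana_spec_requires_tested_ana(self):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=1, ana_clause="and")
        ok, reason = is_eligible(fv(icd9=5, ana="missing"), spec)
        assert not ok and "ANA" in reason

    def test_ana_or_rp_spec_also_requires_ana(self):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=1, rp_clause="or_with_ana")
        ok, _ = is_eligible(fv(icd9=5, ana="missing"), spec)
        assert not ok

    def test_icd9_only_spec_is_universally_eligible(self):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=4)
        assert is_eligible(fv(icd9=0, ana="missing", any10=False), spec) == (True, None)

    def test_apply_on_ineligible_subject_raises(self):
        spec = AlgorithmSpec("s", "icd10_only", icd10_min=1)
        with pytest.raises(ValueError, match="ineligible"):
            apply_algorithm(fv(icd9=5, icd10=0, any10=False), spec)


class TestApplication:
    def test_and_ana_conjunction(self):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=4, ana_clause="and")
        assert apply_algorithm(fv(icd9=4, ana="positive"), spec)
        assert not apply_algorithm(fv(icd9=4, ana="negative"), spec)
        assert not apply_algorithm(fv(icd9=3, ana="positive"), spec)

    def test_either_count_reading_of_or_logic(self):
        spec = AlgorithmSpec("s", "icd9_or_icd10", icd9_min=3, icd10_min=3)
        # counts 2 and 2: neither system meets 3, so not flagged
        assert not apply_algorithm(fv(icd9=2, icd10=2), spec)
        assert apply_algorithm(fv(icd9=3, icd10=0, any10=True), spec)
        assert apply_algorithm(fv(icd9=0, icd10=3), spec)

    def test_summed_count_reading_behind_flag(self):
        spec = AlgorithmSpec("s", "icd9_or_icd10", icd9_min=3, icd10_min=3, count_mode="sum")
        assert apply_algorithm(fv(icd9=2, icd10=2), spec)
        assert not apply_algorithm(fv(icd9=1, icd10=1), spec)

    def test_ana_or_rp_grouping(self):
        """'count AND ANA OR RP' parses as count AND (ANA OR RP)."""
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=2, rp_clause="or_with_ana")
        assert apply_algorithm(fv(icd9=2, ana="positive", rp=False), spec)
        assert apply_algorithm(fv(icd9=2, ana="negative", rp=True), spec)
        assert not apply_algorithm(fv(icd9=2, ana="negative", rp=False), spec)
        assert not apply_algorithm(fv(icd9=1, ana="positive", rp=True), spec)

    def test_truth_table_oracle_over_all_combinations(self):
        """Every spec agrees with a brute-force predicate on the full
        2-valued ANA x RP x small-count product."""
        def oracle(fv_, s):
            if s.code_logic == "icd9_only":
                counts = fv_.icd9_ssc_days >= s.icd9_min
            elif s.code_logic == "icd10_only":
                counts = fv_.icd10_ssc_days >= s.icd10_min
            elif s.count_mode == "sum":
                counts = fv_.icd9_ssc_days + fv_.icd10_ssc_days >= s.icd9_min
            else:
                counts = fv_.icd9_ssc_days >= s.icd9_min or fv_.icd10_ssc_days >= s.icd10_min
            ana_ok = fv_.ana == "positive"
            if s.rp_clause == "or_with_ana":
                return counts and (ana_ok or fv_.rp_keyword)
            out = counts
            if s.ana_clause == "and":
                out = out and ana_ok
            if s.rp_clause == "and":
                out = out and fv_.rp_keyword
            return out

        for spec in published_grid() + [
            AlgorithmSpec("sum", "icd9_or_icd10", icd9_min=3, icd10_min=3, count_mode="sum")
        ]:
            for icd9, icd10, ana, rp in itertools.product(
                range(6), range(6), ("positive", "negative"), (False, True)
            ):
                v = fv(icd9=icd9, icd10=icd10, any10=True, ana=ana, rp=rp)
                assert apply_algorithm(v, spec) == oracle(v, spec), spec.name


class TestNestingInvariants:
    def test_flagged_sets_nest_as_thresholds_rise(self, small_features):
        grid = published_grid()
        families = {}
        for s in grid:
            families.setdefault((s.code_logic, s.ana_clause, s.rp_clause), []).append(s)
        for specs in families.values():
            sets = [flagged_set(small_features, s) for s in specs]
            for lower, higher in zip(sets, sets[1:]):
                assert higher <= lower

    def test_and_clause_never_enlarges_flagged_set(self, small_features):
        eligible_ana = {
            sid: f for sid, f in small_features.items() if f.ana != "missing"
        }
        for k in range(1, 5):
            base = AlgorithmSpec("b", "icd9_only", icd9_min=k)
            plus_ana = AlgorithmSpec("a", "icd9_only", icd9_min=k, ana_clause="and")
            plus_both = AlgorithmSpec(
                "ab", "icd9_only", icd9_min=k, ana_clause="and", rp_clause="and"
            )
            or_spec = AlgorithmSpec("o", "icd9_only", icd9_min=k, rp_clause="or_with_ana")
            assert flagged_set(eligible_ana, plus_ana) <= flagged_set(eligible_ana, base)
            assert flagged_set(eligible_ana, plus_both) <= flagged_set(eligible_ana, plus_ana)
            # AND (ANA OR RP) can only add subjects relative to AND ANA
            assert flagged_set(eligible_ana, plus_ana) <= flagged_set(eligible_ana, or_spec)


class TestStratification:
    def test_first_code_year_assignment(self, small_cohort, small_features):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=1)
        strata = stratify_by_first_code_date(
            small_cohort, small_features, spec, [1995, 2000, 2005, 2010, 2015]
        )
        assert set(strata) == {(1995, 2000), (2000, 2005), (2005, 2010), (2010, 2015)}
        all_flagged = set().union(*strata.values())
        assert all_flagged <= flagged_set(small_features, spec)

    def test_single_stratum_equals_unstratified(self, small_cohort, small_features):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=2)
        strata = stratify_by_first_code_date(
            small_cohort, small_features, spec, [1900, 2100]
        )
        expected = {
            sid
            for sid in flagged_set(small_features, spec)
            if any(st.SSC_MATCHER.matches(e) for e in small_cohort.events[sid])
        }
        assert strata[(1900, 2100)] == expected

    def test_example_year_in_stratum(self, toy_events):
        cohort = st.Cohort(
            labels={"T1": st.ChartLabel("T1", st.ChartStatus.CASE)},
            events={"T1": [toy_events("710.1", "ICD9", 2003, 6, 1)]},
        )
        feats = st.extract_features(cohort)
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=1)
        strata = stratify_by_first_code_date(cohort, feats, spec, [1995, 2000, 2005, 2010])
        assert strata[(2000, 2005)] == {"T1"}
        assert strata[(1995, 2000)] == set()

    def test_unsorted_breakpoints_rejected(self, small_cohort, small_features):
        spec = AlgorithmSpec("s", "icd9_only", icd9_min=1)
        with pytest.raises(ValueError):
            stratify_by_first_code_date(small_cohort, small_features, spec, [2010, 1995])


class TestCodeExclusion:
    def _cohort(self):
        d = dt.date
        labels = {
            "both": st.ChartLabel("both", st.ChartStatus.NOT_CASE),
            "ssc": st.ChartLabel("ssc", st.ChartStatus.CASE),
        }
        events = {
            "both": [
                st.DiagnosisEvent("both", "710.0", CodeSystem.ICD9, d(2012, 1, 1)),
                st.DiagnosisEvent("both", "710.1", CodeSystem.ICD9, d(2012, 2, 1)),
            ],
            "ssc": [st.DiagnosisEvent("ssc", "710.1", CodeSystem.ICD9, d(2012, 1, 1))],
        }
        return st.Cohort(labels=labels, events=events)

    def test_subject_with_lupus_code_removed(self):
        reduced = exclude_by_code(self._cohort())
        assert set(reduced.labels) == {"ssc"}

    def test_icd10_lupus_prefix_also_excludes(self):
        cohort = self._cohort()
        cohort.events["ssc"].append(
            st.DiagnosisEvent("ssc", "M32.9", CodeSystem.ICD10CM, dt.date(2016, 1, 1))
        )
        assert len(exclude_by_code(cohort)) == 0

    def test_nonmatching_exclusion_is_identity(self):
        cohort = self._cohort()
        matcher = st.CodeMatcher(icd9_exact=frozenset({"9999"}), icd10_prefixes=frozenset({"Z99"}))
        assert set(exclude_by_code(cohort, matcher).labels) == set(cohort.labels)
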