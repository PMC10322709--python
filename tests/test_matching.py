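"""Case-control and timepoint matching: constraints, optimality, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from matchrank.io import MetadataTable
from matchrank.matching import (
    MatchedPairs,
    match_case_control,
    match_timepoints,
    select_first_timepoint,
)


def _meta(rows, timepoint_order=None):
    return MetadataTable(pd.DataFrame(rows), timepoint_order=timepoint_order)


def _row(sid, group, age, sex="F", cohort="c1", subject=None, tp=None):
    return {"sample_id": sid, "subject_id": subject or sid, "cohort_id": cohort,
            "group": group, "age": age, "sex": sex, "timepoint": tp}


def brute_force_optimum(cases, controls, max_gap, same_sex):
    """Exhaustive search: max cardinality, then min total age gap."""
    def feasible(ci, cj):
        ok = abs(ci[1] - cj[1]) <= max_gap + 1e-12
        return ok and (not same_sex or ci[2] == cj[2])

    best = (0, 0.0)
    n = len(cases)
    for k in range(min(n, len(controls)), -1, -1):
        best_gap = None
        for csub in itertools.combinations(range(n), k):
            for perm in itertools.permutations(range(len(controls)), k):
                if all(feasible(cases[i], controls[j]) for i, j in zip(csub, perm)):
                    gap = sum(abs(cases[i][1] - controls[j][1]) for i, j in zip(csub, perm))
                    best_gap = gap if best_gap is None else min(best_gap, gap)
        if best_gap is not None:
            return k, best_gap
    return 0, 0.0


class TestCaseControl:
    def test_sex_constraint_forces_pairing(self):
        md = _meta([_row("A", "case", 5.0, "F"), _row("B", "control", 5.2, "F"),
                    _row("C", "control", 5.0, "M")])
        m = match_case_control(md, max_age_gap=0.5)
        assert m.pairs == [(0, "A", "B")]
        assert m.unmatched == ["C"]

    def test_minimum_total_gap_among_perfect_matchings(self):
        md = _meta([_row("A", "case", 4.0), _row("B", "case", 6.0),
                    _row("C", "control", 4.1), _row("D", "control", 5.9)])
        m = match_case_control(md, max_age_gap=0.5)
        assert {(c, x) for _, c, x in m.pairs} == {("A", "C"), ("B", "D")}

    def test_unmatchable_case_excluded(self):
        md = _meta([_row("A", "case", 5.0), _row("B", "control", 7.0)])
        m = match_case_control(md, max_age_gap=0.5)
        assert len(m) == 0 and set(m.unmatched) == {"A", "B"}

    def test_within_cohort_only(self):
        md = _meta([_row("A", "case", 5.0, cohort="c1"), _row("B", "control", 5.0, cohort="c2")])
        m = match_case_control(md, max_age_gap=0.5)
        assert len(m) == 0

    def test_empty_control_cohort_warns_not_raises(self, caplog):
        md = _meta([_row("A", "case", 5.0)])
        m = match_case_control(md)
        assert len(m) == 0 and m.unmatched == ["A"]

    def test_duplicate_sample_in_pairs_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            MatchedPairs(pairs=[(0, "a", "b"), (1, "a", "c")])

    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        n_case = data.draw(st.integers(1, 5))
        n_ctrl = data.draw(st.integers(1, 5))
        ages = st.floats(0.0, 10.0, allow_nan=False, width=32)
        sexes = st.sampled_from(["M", "F"])
        cases = [(f"A{i}", data.draw(ages), data.draw(sexes)) for i in range(n_case)]
        ctrls = [(f"B{i}", data.draw(ages), data.draw(sexes)) for i in range(n_ctrl)]
        same_sex = data.draw(st.booleans())
        gap = data.draw(st.sampled_from([0.5, 1.0, 3.0]))
        md = _meta([_row(s, "case", a, x) for s, a, x in cases]
                   + [_row(s, "control", a, x) for s, a, x in ctrls])
        m = match_case_control(md, max_age_gap=gap, require_same_sex=same_sex)
        k_opt, gap_opt = brute_force_optimum(cases, ctrls, gap, same_sex)
        assert len(m) == k_opt
        ages_by_id = {s: a for s, a, _ in cases + ctrls}
        total = sum(abs(ages_by_id[c] - ages_by_id[x]) for _, c, x in m.pairs)
        assert total <= gap_opt + 1e-6

    @given(st.randoms(use_true_random=False))
    def test_row_permutation_invariance(self, rnd):
        rows = [_row("A", "case", 5.0), _row("B", "case", 6.1), _row("C", "control", 5.2),
                _row("D", "control", 6.0), _row("E", "control", 6.05, "M")]
        rnd.shuffle(rows)
        m = match_case_control(_meta(rows), max_age_gap=0.5)
        assert {(c, x) for _, c, x in m.pairs} == {("A", "C"), ("B", "D")}


class TestTimepoints:
    def _long(self):
        rows = []
        for i, tps in enumerate([("week0", "week10"), ("week0", "week10"), ("week0",)]):
            for tp in tps:
                rows.append(_row(f"S{i}_{tp}", "case", 5.0, subject=f"S{i}", tp=tp))
        return _meta(rows, timepoint_order=["week0", "week10"])

    def test_pairs_and_exclusions(self):
        m = match_timepoints(self._long(), ("week0", "week10"))
        assert len(m) == 2
        assert m.unmatched == ["S2_week0"]
        # later timepoint plays the case role
        assert all(c.endswith("week10") and x.endswith("week0") for _, c, x in m.pairs)

    def test_reversed_interval_swaps_roles(self):
        fwd = match_timepoints(self._long(), ("week0", "week10"))
        rev = match_timepoints(self._long(), ("week10", "week0"))
        assert {(c, x) for _, c, x in fwd.pairs} == {(x, c) for _, c, x in rev.pairs}

    def test_full_cohort(self):
        rows = [_row(f"S{i}_{tp}", "case", 7.0, subject=f"S{i}", tp=tp)
                for i in range(18) for tp in ("week0", "week18")]
        m = match_timepoints(_meta(rows, ["week0", "week18"]), ("week0", "week18"))
        assert len(m) == 18

    def test_duplicate_subject_timepoint_rejected(self):
        rows = [_row("a", "case", 5.0, subject="S", tp="week0"),
                _row("b", "case", 5.0, subject="S", tp="week0")]
        with pytest.raises(ValueError, match="duplicate"):
            match_timepoints(_meta(rows, ["week0"]), ("week0", "week10"))


class TestFirstTimepoint:
    def test_earliest_kept(self):
        rows = [_row(f"s_{tp}", "case", 5.0, subject="S", tp=tp)
                for tp in ("year2", "week0", "week10")]
        md = _meta(rows, timepoint_order=["week0", "week10", "year2"])
        out = select_first_timepoint(md)
        assert out.sample_ids == ["s_week0"]

    def test_cross_sectional_identity(self):
        md = _meta([_row("a", "case", 5.0), _row("b", "control", 5.0)])
        assert select_first_timepoint(md).sample_ids == ["a", "b"]

    def test_mixed_table_one_row_per_subject(self):
        rows = [_row("a", "case", 5.0, subject="S1"), _row("b", "control", 5.0, subject="S2"),
                _row("c", "case", 5.0, subject="S3"), *[
                    _row(f"L{i}_{tp}", "control", 6.0, subject=f"L{i}", tp=tp)
                    for i in range(2) for tp in ("t0", "t1")]]
        md = _meta(rows, timepoint_order=["t0", "t1"])
        out = select_first_timepoint(md)
        assert len(out) == 5

    def test_duplicate_earliest_rejected(self):
        rows = [_row("a", "case", 5.0, subject="S", tp="t0"),
                _row("b", "case", 5.0, subject="S", tp="t0")]
        with pytest.raises(ValueError, match="duplicated earliest"):
            select_first_timepoint(_meta(rows, ["t0"]))
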