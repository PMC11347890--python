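"""Single-case and group tests: hand-computed values, scipy cross-checks,
degenerate inputs, and the full study evaluation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from triadic_attention.policy import InterventionRecommendation, NormativeReference
from triadic_attention.profiles import SessionProfile
from triadic_attention.stats import (
    DegenerateDataError,
    InsufficientDataError,
    ParticipantData,
    crawford_howell,
    evaluate_study,
    improvement_direction,
    independent_t,
    paired_t,
)


class TestCrawfordHowell:
    def test_case_at_control_mean(self):
        r = crawford_howell(2.0, [1.0, 2.0, 3.0], "decrease")
        assert r.statistic_t == pytest.approx(0.0)
        assert r.p_value == pytest.approx(0.5)

    def test_hand_computed_example(self):
        # controls {1,2,3}: mean 2, sd 1, n 3 -> t = 2 / sqrt(4/3)
        r = crawford_howell(4.0, [1.0, 2.0, 3.0], "increase")
        assert r.statistic_t == pytest.approx(2 / math.sqrt(4 / 3))
        assert r.df == 2
        assert r.p_value == pytest.approx(0.1127, abs=5e-4)

    def test_equals_two_sample_t_with_singleton_group(self):
        """The single-case statistic equals a pooled two-sample t with n1=1."""
        rng = np.random.default_rng(5)
        controls = rng.normal(10, 2, size=12)
        case = 14.2
        ours = crawford_howell(case, controls, "increase")
        ref_t, ref_p = sps.ttest_ind([case], controls, equal_var=True,
                                     alternative="greater")
        assert ours.statistic_t == pytest.approx(float(ref_t))
        assert ours.p_value == pytest.approx(float(ref_p))
        assert ours.df == 11

    def test_converges_to_z_score_for_large_controls(self):
        rng = np.random.default_rng(11)
        controls = rng.normal(0.0, 1.0, size=10_000)
        case = 1.5
        r = crawford_howell(case, controls, "increase")
        z = (case - controls.mean()) / controls.std(ddof=1)
        assert r.statistic_t == pytest.approx(z, rel=1e-2)
        assert r.p_value == pytest.approx(sps.norm.sf(z), rel=1e-2)

    def test_p_decreases_with_improvement(self):
        controls = [0.0, 1.0, -1.0, 0.5, -0.5]
        ps = [crawford_howell(delta, controls, "decrease").p_value
              for delta in (0.0, -1.0, -2.0, -4.0)]
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_and_insufficient(self):
        with pytest.raises(DegenerateDataError):
            crawford_howell(1.0, [5.0, 5.0, 5.0], "decrease")
        with pytest.raises(InsufficientDataError):
            crawford_howell(1.0, [5.0], "decrease")


class TestIndependentT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        r = independent_t(g, g, tails="two")
        assert r.statistic_t == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2,df", [(8, 12, 18), (6, 12, 16)])
    def test_degrees_of_freedom(self, n1, n2, df):
        rng = np.random.default_rng(n1)
        r = independent_t(rng.normal(size=n1), rng.normal(size=n2), tails="two")
        assert r.df == df

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(3)
        g1, g2 = rng.normal(0, 1, 8), rng.normal(0.8, 1, 12)
        ours = independent_t(g1, g2, tails="two")
        ref = sps.ttest_ind(g1, g2, equal_var=True)
        assert ours.statistic_t == pytest.approx(float(ref.statistic))
        assert ours.p_value == pytest.approx(float(ref.pvalue))
        one = independent_t(g1, g2, tails="one", improvement_direction="decrease")
        ref_one = sps.ttest_ind(g1, g2, equal_var=True, alternative="less")
        assert one.p_value == pytest.approx(float(ref_one.pvalue))

    def test_degenerate_pooled_variance(self):
        with pytest.raises(DegenerateDataError):
            independent_t([1.0, 1.0], [1.0, 1.0])


class TestPairedT:
    def test_no_change_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="no change"):
            paired_t([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    def test_constant_shift_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])

    def test_hand_computed_differences(self):
        # diffs {1,0,1,1}: mean .75, sd .5 -> t = .75 / (.5/2) = 3
        r = paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 4.0, 5.0])
        assert r.statistic_t == pytest.approx(3.0)
        assert r.df == 3
        assert r.p_value == pytest.approx(float(sps.ttest_rel(
            [2.0, 2.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0]).pvalue))


def test_improvement_directions_mirror_flag_directions():
    assert improvement_direction("AvgCon", "high") == "decrease"
    assert improvement_direction("AvgCon", "low") == "increase"
    assert improvement_direction("NumCon", "low") == "increase"
    for dom in ("AvgNoCon", "MaxExc", "ExcPct"):
        assert improvement_direction(dom, "high") == "decrease"


def _profile(**kw):
    defaults = dict(avg_con=6.0, avg_no_con=30.0, num_con=2.0, max_exc=10.0,
                    exc_pct=3.0, n_contacts=20, n_exclusions=1, session_frames=800)
    defaults.update(kw)
    return SessionProfile(**defaults)


def _participant(pid, s1_vals, s2_vals, recs=()):
    return ParticipantData(pid, _profile(**s1_vals), _profile(**s2_vals), tuple(recs))


class TestEvaluateStudy:
    def make_groups(self, rng, n=12, case_shift=0.0):
        control = []
        for i in range(n):
            v1 = rng.normal(20, 3)
            v2 = rng.normal(20, 3)
            control.append(_participant(f"C{i}", {"max_exc": v1}, {"max_exc": v2}))
        rec = InterventionRecommendation("MaxExc", "high", 25.0, 21.16, 2.65)
        test = []
        for i in range(n):
            v1 = rng.normal(25, 3)
            v2 = v1 + case_shift + rng.normal(0, 1)
            test.append(_participant(f"T{i}", {"max_exc": v1}, {"max_exc": v2}, [rec]))
        return test, control

    def test_cloned_control_group_shows_nothing(self):
        rng = np.random.default_rng(0)
        control = [
            _participant(f"C{i}", {"max_exc": rng.normal(20, 3)},
                         {"max_exc": rng.normal(20, 3)})
            for i in range(12)
        ]
        clones = [ParticipantData(f"T{i}", p.session1, p.session2, ())
                  for i, p in enumerate(control)]
        report = evaluate_study(clones, control)
        assert report.n_interventions == 0
        assert report.n_significant == 0
        # identical groups: baseline t = 0, two-tailed p = 1 where defined
        assert report.baseline_tests["MaxExc"].p_value == pytest.approx(1.0)

    def test_strong_improvement_detected(self):
        rng = np.random.default_rng(42)
        test, control = self.make_groups(rng, case_shift=-12.0)
        report = evaluate_study(test, control)
        assert report.n_interventions == 12
        assert report.n_significant >= 10
        assert "MaxExc:high" in report.group_tests
        assert report.group_tests["MaxExc:high"].p_value < 0.01
        assert report.group_tests["MaxExc:high"].df == 22

    def test_case_at_control_mean_delta_not_significant(self):
        rng = np.random.default_rng(1)
        control = [
            _participant(f"C{i}", {"max_exc": 20.0}, {"max_exc": 20.0 + d})
            for i, d in enumerate(rng.normal(0, 2, size=12))
        ]
        mean_delta = float(np.mean([p.session2.max_exc - p.session1.max_exc
                                    for p in control]))
        rec = InterventionRecommendation("MaxExc", "high", 25.0, 21.16, 2.65)
        test = [_participant("T0", {"max_exc": 25.0}, {"max_exc": 25.0 + mean_delta}, [rec])]
        report = evaluate_study(test, control)
        case = report.case_results[0]
        assert case.test.p_value == pytest.approx(0.5)
        assert not case.significant

    def test_moved_inside_requires_both(self):
        rng = np.random.default_rng(7)
        test, control = self.make_groups(rng, case_shift=-12.0)
        report = evaluate_study(test, control)
        for case in report.case_results:
            if case.moved_inside and case.significant:
                participant = next(p for p in test if p.participant == case.participant)
                assert participant.session2.max_exc < 21.16
        assert report.n_moved_inside <= report.n_significant

    def test_group_test_needs_six_recipients(self):
        rng = np.random.default_rng(9)
        test, control = self.make_groups(rng, case_shift=-12.0)
        report = evaluate_study(test[:5], control)
        assert report.group_tests == {}

    def test_json_rendering_round_trip(self):
        rng = np.random.default_rng(3)
        test, control = self.make_groups(rng, case_shift=-12.0)
        report = evaluate_study(test, control)
        d = report.to_dict()
        assert d["summary"]["interventions_given"] == report.n_interventions
        assert len(d["case_results"]) == len(report.case_results)
        md = report.to_markdown()
        assert "Crawford-Howell" in md

    def test_empty_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            evaluate_study([], [])
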