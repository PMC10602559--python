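"""Rescue index, efficacy score, hit calling and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfheart.cardiometrics import AxisPair, CardiacParams
from zfheart.screening import (PARAMETERS, ScreenResult, call_hits,
                               efficacy_score, group_means, rank_compounds,
                               rescue_index, run_screen, score_compound)


def _larva(**overrides):
    base = dict(EDA=600.0, ESA=340.0, FAC=43.0, FS=25.0, SV=9000.0, HR=150.0,
                edema=1)
    base.update(overrides)
    return CardiacParams(EDA=base["EDA"], ESA=base["ESA"],
                         ED_axes=AxisPair(40, 24), ES_axes=AxisPair(30, 20),
                         FAC=base["FAC"], FS=base["FS"], SV=base["SV"],
                         HR=base["HR"], edema=base["edema"], n_cycles=5)


class TestGroupMeans:
    def test_single_larva(self):
        m = group_means([_larva()])
        assert m["HR"] == 150.0 and m["edema"] == 1.0

    def test_edema_fraction_normal(self):
        larvae = [_larva(edema=e) for e in (1, 1, 0, 1)]
        assert group_means(larvae)["edema"] == 0.75

    def test_numeric_mean(self):
        assert group_means([_larva(HR=100), _larva(HR=120)])["HR"] == 110.0

    def test_all_missing_parameter_is_nan(self):
        larvae = [_larva(FAC=float("nan"))] * 2
        assert np.isnan(group_means(larvae)["FAC"])


class TestRescueIndex:
    def test_full_rescue(self):
        assert rescue_index(100.0, 50.0, 100.0) == 1.0

    def test_no_rescue(self):
        assert rescue_index(50.0, 50.0, 100.0) == 0.0

    def test_half_rescue(self):
        assert rescue_index(75.0, 50.0, 100.0) == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            rescue_index(75.0, 100.0, 100.0)

    def test_unclamped_by_default_clamped_on_request(self):
        assert rescue_index(120.0, 50.0, 100.0) == pytest.approx(1.4)
        assert rescue_index(120.0, 50.0, 100.0, clamp=True) == 1.0
        assert rescue_index(30.0, 50.0, 100.0, clamp=True) == 0.0

    @given(xd=st.floats(-1e3, 1e3), xm=st.floats(-1e3, 1e3),
           xc=st.floats(-1e3, 1e3),
           scale=st.floats(0.01, 100.0), shift=st.floats(-1e3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, xd, xm, xc, scale, shift):
        """Rescue index is invariant to common affine rescaling."""
        if abs(xc - xm) < 1e-6:
            return
        a = rescue_index(xd, xm, xc)
        b = rescue_index(xd * scale + shift, xm * scale + shift,
                         xc * scale + shift)
        assert b == pytest.approx(a, rel=1e-5, abs=1e-6)


class TestEfficacyScore:
    def test_all_ones(self):
        assert efficacy_score([1.0] * 7) == 1.0

    def test_mean_of_two(self):
        assert efficacy_score([1.0, 0.0]) == 0.5

    def test_seven_parameter_hand_computation(self):
        vals = [1.0, 0.8, 0.6, 0.4, 0.2, 0.0, 1.0]
        assert efficacy_score(vals) == pytest.approx(4.0 / 7.0, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            efficacy_score([])

    def test_permutation_invariance(self):
        vals = [0.9, 0.1, 0.5, 0.7]
        assert efficacy_score(vals) == efficacy_score(list(reversed(vals)))


class TestHitCallingAndRanking:
    def _result(self, name, score):
        return ScreenResult(compound=name, rescue_indices={},
                            efficacy_score=score, n_parameters=7)

    def test_strictly_above_threshold(self):
        results = call_hits([self._result("a", 0.71), self._result("b", 0.70),
                             self._result("c", 0.69)], threshold=0.7)
        assert [r.is_hit for r in results] == [True, False, False]

    def test_exactly_one_hit(self):
        results = call_hits([self._result(c, s) for c, s in
                             zip("abc", (0.9, 0.7, 0.3))])
        assert sum(r.is_hit for r in results) == 1

    def test_rank_descending(self):
        ranked = rank_compounds([self._result(c, s) for c, s in
                                 zip("abc", (0.2, 0.9, 0.5))])
        assert [r.efficacy_score for r in ranked] == [0.9, 0.5, 0.2]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_broken_lexicographically(self):
        ranked = rank_compounds([self._result("zeta", 0.5),
                                 self._result("alpha", 0.5)])
        assert [r.compound for r in ranked] == ["alpha", "zeta"]


class TestRunScreen:
    def _groups(self):
        ctrl = [_larva() for _ in range(5)]
        model = [_larva(EDA=800, ESA=650, FAC=19, FS=10, SV=4000, HR=100,
                        edema=0) for _ in range(5)]
        return ctrl, model

    def test_control_scores_one_model_scores_zero(self):
        ctrl, model = self._groups()
        groups = {"control": ctrl, "model": model,
                  "self_ctrl": list(ctrl), "self_model": list(model)}
        results = {r.compound: r for r in run_screen(groups)}
        assert results["self_ctrl"].efficacy_score == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert results["self_model"].efficacy_score == pytest.approx(0.0,
                                                                     abs=1e-12)
        assert results["self_ctrl"].n_parameters == 7

    def test_degenerate_parameter_dropped(self):
        ctrl, model = self._groups()
        model = [_larva(HR=150.0, EDA=800, ESA=650, FAC=19, FS=10, SV=4000,
                        edema=0) for _ in range(5)]  # HR same as control
        res = score_compound("x", group_means(ctrl), group_means(model),
                             group_means(ctrl))
        assert res.n_parameters == 6 and "HR" not in res.rescue_indices

    def test_missing_groups_rejected(self):
        with pytest.raises(ValueError):
            run_screen({"control": [_larva()]})
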