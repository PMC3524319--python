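"""Priming feature extraction, verdict clauses, and mechanism rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primescreen.features import (
    MechanismLabel,
    PrimingFeatures,
    PrimingThresholds,
    classify_mechanism,
    evaluate_priming,
    extract_features,
)
from primescreen.motifs import SignedGraph
from primescreen.protocols import StimulusProtocol, TimeCourse, TimeCourseSet


def _make_features(ld, hd, ldhd, dss=None, dmax_hd=None, dmax_ldhd=None):
    dss = dss or {"x1": 0.0, "x2": 0.0}
    return PrimingFeatures(
        dss_ld=dss,
        dmax_hd=dmax_hd or {k: 0.0 for k in dss},
        dmax_ldhd=dmax_ldhd or {k: 0.0 for k in dss},
        readout_max_ld=ld,
        readout_max_hd=hd,
        readout_max_ldhd=ldhd,
    )


def _flat_tcs(level=0.4, names=("x1", "x2", "x3")):
    t = np.linspace(0, 100, 51)
    courses = {}
    for lab in ("untreated", "LD", "HD", "LD_HD"):
        vals = np.full((len(names), t.size), level)
        courses[lab] = TimeCourse(t, vals, names)
    return TimeCourseSet(courses)


class TestExtractFeatures:
    def test_identical_flat_arms_give_zero_features(self):
        feats = extract_features(
            _flat_tcs(), "x3", ld_period=(0, 50), hd_period=(50, 100)
        )
        assert feats.dss_ld == {"x1": 0.0, "x2": 0.0}
        assert feats.dmax_hd == {"x1": 0.0, "x2": 0.0}
        assert feats.dmax_ldhd == {"x1": 0.0, "x2": 0.0}

    def test_dss_is_level_at_ld_end_minus_baseline(self):
        t = np.linspace(0, 100, 101)
        base = np.full((2, t.size), 0.4)
        courses = {
            lab: TimeCourse(t, base.copy(), ("x1", "x3"))
            for lab in ("untreated", "HD", "LD_HD")
        }
        ld_vals = base.copy()
        ld_vals[0] = np.linspace(0.4, 0.1, t.size)  # x1 decays to 0.1 at t=100
        # at the LD-period end (t=50) x1 is 0.25
        courses["LD"] = TimeCourse(t, ld_vals, ("x1", "x3"))
        feats = extract_features(
            TimeCourseSet(courses), "x3", ld_period=(0, 50), hd_period=(50, 100)
        )
        assert feats.dss_ld["x1"] == pytest.approx(0.25 - 0.4)

    def test_missing_arm_is_named_in_error(self):
        tcs = _flat_tcs()
        del tcs.courses["HD"]
        with pytest.raises(KeyError, match="HD"):
            extract_features(tcs, "x3", (0, 50), (50, 100))

    def test_period_outside_grid_raises(self):
        with pytest.raises(ValueError, match="outside grid"):
            extract_features(_flat_tcs(), "x3", (0, 50), (50, 200))

    def test_scale_consistency_features_linear_in_levels(self):
        """Multiplying all trajectories by c scales every Delta by c."""
        t = np.linspace(0, 100, 101)
        rng = np.random.default_rng(0)
        base = 0.2 + 0.1 * rng.random((3, t.size)).cumsum(axis=1) / t.size
        courses = {}
        for i, lab in enumerate(("untreated", "LD", "HD", "LD_HD")):
            vals = base * (1 + 0.2 * i)
            vals[:, 0] = base[:, 0]  # shared baseline at t=0
            courses[lab] = TimeCourse(t, vals, ("x1", "x2", "x3"))
        f1 = extract_features(TimeCourseSet(courses), "x3", (0, 50), (50, 100))
        scaled = {
            lab: TimeCourse(t, tc.values * 3.0, tc.names)
            for lab, tc in courses.items()
        }
        f3 = extract_features(TimeCourseSet(scaled), "x3", (0, 50), (50, 100))
        for v in ("x1", "x2"):
            assert f3.dss_ld[v] == pytest.approx(3 * f1.dss_ld[v])
            assert f3.dmax_hd[v] == pytest.approx(3 * f1.dmax_hd[v])
            assert f3.dmax_ldhd[v] == pytest.approx(3 * f1.dmax_ldhd[v])


class TestEvaluatePriming:
    @pytest.mark.parametrize(
        "ld,hd,ldhd,primed,reason_key",
        [
            (0.05, 0.40, 0.65, True, "all"),      # 0.65 >= 1.5 x 0.40
            (0.05, 0.40, 0.55, False, "ratio"),   # 0.55 < 0.60
            (0.20, 0.40, 0.90, False, "LD"),      # LD response too high
            (0.05, 0.05, 0.90, False, "HD"),      # HD fails to activate
        ],
    )
    def test_clause_truth_table(self, ld, hd, ldhd, primed, reason_key):
        verdict = evaluate_priming(_make_features(ld, hd, ldhd))
        assert verdict["primed"] is primed
        assert reason_key in verdict["reason"]

    def test_boundary_is_inclusive_for_hd_and_ratio(self):
        v = evaluate_priming(_make_features(0.05, 0.10, 0.15))
        assert v["primed"]

    @given(
        ld=st.floats(0, 0.3), hd=st.floats(0, 1),
        ldhd=st.floats(0, 1), bump=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_ldhd_response(self, ld, hd, ldhd, bump):
        """Raising the LD+HD maximum never flips primed -> not primed."""
        v1 = evaluate_priming(_make_features(ld, hd, ldhd))
        v2 = evaluate_priming(_make_features(ld, hd, ldhd + bump))
        assert not (v1["primed"] and not v2["primed"])


class TestClassifyMechanism:
    PRIMED = dict(ld=0.05, hd=0.3, ldhd=0.6)

    def _cls(self, dss, diffs=None, graph=None):
        diffs = diffs or {k: 0.0 for k in dss}
        feats = _make_features(
            **self.PRIMED,
            dss=dss,
            dmax_hd={k: 0.2 for k in dss},
            dmax_ldhd={k: 0.2 + diffs[k] for k in dss},
        )
        return classify_mechanism(feats, graph=graph)

    def test_suppressor_drop_gives_sd(self):
        assert self._cls({"x1": -0.3, "x2": 0.0}).label == "SD"

    def test_ld_induced_with_boosted_max_gives_ps(self):
        lab = self._cls({"x1": 0.0, "x2": 0.25}, {"x1": 0.0, "x2": 0.30})
        assert lab.label == "PS"

    def test_ld_induced_with_flat_max_gives_ai(self):
        lab = self._cls({"x1": 0.0, "x2": 0.25}, {"x1": 0.0, "x2": 0.02})
        assert lab.label == "AI"

    def test_not_primed_returns_none(self):
        feats = _make_features(0.5, 0.3, 0.6, dss={"x1": -0.3, "x2": 0.0})
        assert classify_mechanism(feats).label == "none"

    def test_precedence_sd_over_ps_keeps_all_evidence(self):
        lab = self._cls({"x1": -0.3, "x2": 0.25}, {"x1": 0.0, "x2": 0.30})
        assert lab.label == "SD"
        assert any(e.startswith("PS") for e in lab.evidence)

    def test_graph_sign_vetoes_mismatched_mechanism(self):
        g = SignedGraph()
        g.add_edge("x1", "x3", 1)  # x1 activates the readout
        g.add_edge("x2", "x3", 1)
        feats = _make_features(
            **self.PRIMED, dss={"x1": -0.3, "x2": 0.0},
            dmax_hd={"x1": 0.2, "x2": 0.2},
            dmax_ldhd={"x1": 0.2, "x2": 0.2},
        )
        # SD requires an inhibiting path; x1 activates, so no SD call
        assert classify_mechanism(feats, graph=g).label == "none"

    def test_graph_missing_readout_raises(self):
        g = SignedGraph()
        g.add_edge("a", "b", 1)
        feats = _make_features(**self.PRIMED, dss={"x1": -0.3})
        with pytest.raises(KeyError, match="x3"):
            classify_mechanism(feats, graph=g)

    @given(
        d1=st.floats(-0.5, 0.5), d2=st.floats(-0.5, 0.5),
        diff=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_single_regulator_beyond_delta_fires_at_most_one_rule(
        self, d1, d2, diff
    ):
        """Region exclusivity for one out-of-band regulator.

        An LD-lowered regulator always classifies SD; an LD-raised one
        classifies PS or AI depending on the Delta-max difference (or
        none when the LD+HD maximum dropped by more than delta, a case
        outside all three templates); never more than one rule.
        """
        delta = 0.1
        beyond = [abs(d) > delta for d in (d1, d2)]
        if sum(beyond) != 1:
            return
        lab = self._cls({"x1": d1, "x2": d2}, {"x1": diff, "x2": diff})
        mechs = {e.split(":")[0] for e in lab.evidence}
        assert len(mechs) <= 1
        low = d1 < -delta or d2 < -delta
        if low:
            assert lab.label == "SD"
        elif diff > delta:
            assert lab.label == "PS"
        elif abs(diff) <= delta:
            assert lab.label == "AI"
        else:
            assert lab.label == "none"


class TestValidation:
    def test_label_requires_evidence(self):
        with pytest.raises(ValueError):
            MechanismLabel("PS", [])

    def test_thresholds_reject_negative(self):
        with pytest.raises(ValueError):
            PrimingThresholds(tau_ld=-0.1)

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            _make_features(float("nan"), 0.1, 0.2)


class TestProtocols:
    def test_ld_hd_ordering_enforced(self):
        with pytest.raises(ValueError, match="LD segment strictly before"):
            StimulusProtocol(((50.0, 1.0), (50.0, 0.03)), "LD_HD")

    def test_wash_segment_allowed(self):
        p = StimulusProtocol(((50.0, 0.03), (5.0, 0.0), (50.0, 1.0)), "LD_HD")
        assert p.dose_at(52.0) == 0.0
        assert p.dose_at(60.0) == 1.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(((0.0, 1.0),), "HD")
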