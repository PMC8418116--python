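import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import smartffr as sf
from smartffr.errors import InvalidArgumentError, UnsupportedTopologyError
from smartffr.hemodynamics import BIFURCATION_TOTAL_FLOWS

from conftest import make_symmetric_tree


class TestViscousCoefficient:
    def test_poiseuille_closed_form(self, straight_vessel):
        # 128*mu*L/(pi*D^4) for a 3 mm x 30 mm tube at blood viscosity
        assert sf.viscous_coefficient(straight_vessel) == pytest.approx(0.3962, rel=1e-3)

    def test_linear_in_length(self):
        f1 = sf.viscous_coefficient(sf.make_straight_vessel(3.0, 30.0, 201))
        f2 = sf.viscous_coefficient(sf.make_straight_vessel(3.0, 60.0, 401))
        assert f2 == pytest.approx(2.0 * f1, rel=1e-9)

    def test_inverse_fourth_power_of_diameter(self):
        f1 = sf.viscous_coefficient(sf.make_straight_vessel(3.0, 30.0, 201))
        f2 = sf.viscous_coefficient(sf.make_straight_vessel(1.5, 30.0, 201))
        assert f2 == pytest.approx(16.0 * f1, rel=1e-9)


class TestSeparationCoefficient:
    def test_healthy_vessel_has_no_separation_loss(self, straight_vessel):
        assert sf.separation_coefficient(straight_vessel) == 0.0

    def test_young_tsai_value_at_70_percent_area_stenosis(self, stenosed_vessel):
        assert sf.separation_coefficient(stenosed_vessel) == pytest.approx(0.6522, rel=1e-3)

    def test_invariant_under_added_healthy_length(self, stenosed_vessel):
        s_short = sf.separation_coefficient(stenosed_vessel)
        extended = sf.VesselSegment(
            "ext",
            np.concatenate([stenosed_vessel.arc_mm, [45.0, 60.0]]),
            np.concatenate([stenosed_vessel.radius_mm, [1.5, 1.5]]),
        )
        assert sf.separation_coefficient(extended) == pytest.approx(s_short, rel=1e-12)


class TestFitPressureDrop:
    def test_exact_recovery_from_model_class(self, quadratic_samples):
        model = sf.fit_pressure_drop(quadratic_samples)
        assert model.f == pytest.approx(2.0, abs=1e-9)
        assert model.s == pytest.approx(1.0, abs=1e-9)

    def test_zero_drop_gives_zero_coefficients(self):
        samples = [sf.PressureFlowSample(q, 100.0, 100.0) for q in (1.0, 2.0, 3.0)]
        model = sf.fit_pressure_drop(samples)
        assert model.f == 0.0 and model.s == 0.0

    def test_noisy_fit_matches_grid_search(self):
        rng = np.random.default_rng(42)
        true = sf.PressureDropModel(1.5, 0.8)
        q = np.array([1.0, 2.0, 3.0, 4.0])
        dp = true.pressure_drop(q) + rng.normal(0.0, 0.4, q.size)
        samples = [sf.PressureFlowSample(qi, 100.0, 100.0 - d) for qi, d in zip(q, dp)]
        fitted = sf.fit_pressure_drop(samples)

        # independent oracle: exhaustive search on a fine (f, s) grid
        fg, sg = np.meshgrid(np.linspace(0, 4, 801), np.linspace(0, 2, 401))
        resid = ((fg[..., None] * q + sg[..., None] * q**2 - dp) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(resid), resid.shape)
        assert fitted.f == pytest.approx(fg[i, j], abs=0.01)
        assert fitted.s == pytest.approx(sg[i, j], abs=0.01)

    def test_requires_two_distinct_positive_flows(self):
        samples = [sf.PressureFlowSample(2.0, 100.0, 98.0)] * 3
        with pytest.raises(InvalidArgumentError):
            sf.fit_pressure_drop(samples)


class TestMurraySplit:
    def test_symmetric_branches_split_evenly(self):
        split = sf.murray_split(3.0, 3.0)
        assert split.fraction_1 == split.fraction_2 == 0.5

    def test_cubic_flow_ratio(self):
        split = sf.murray_split(1.0, 2.0)
        assert split.fraction_2 / split.fraction_1 == pytest.approx(8.0, rel=1e-12)

    def test_three_versus_two_millimetres(self):
        split = sf.murray_split(3.0, 2.0)
        assert split.fraction_1 == pytest.approx(27.0 / 35.0, rel=1e-12)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sf.murray_split(0.0, 2.0)

    @given(st.floats(0.5, 6.0), st.floats(0.5, 6.0))
    def test_relabeling_symmetry_and_normalisation(self, d1, d2):
        a = sf.murray_split(d1, d2)
        b = sf.murray_split(d2, d1)
        assert a.fraction_1 == pytest.approx(b.fraction_2, rel=1e-12)
        assert a.fraction_1 + a.fraction_2 == pytest.approx(1.0, abs=1e-12)


class TestSingleVesselProtocol:
    def test_healthy_vessel_keeps_unity_ratio(self, straight_vessel):
        samples = sf.run_single_vessel_protocol(straight_vessel)
        # viscous drop of the healthy tube itself is the only loss
        f = sf.viscous_coefficient(straight_vessel)
        for s in samples:
            assert s.ratio == pytest.approx(1.0 - f * s.flow / 100.0, abs=1e-12)

    def test_engine_matches_quadratic_law_exactly(self, stenosed_vessel):
        model = sf.pressure_drop_model(stenosed_vessel)
        for s in sf.run_single_vessel_protocol(stenosed_vessel):
            assert s.pa - s.pd == pytest.approx(model.pressure_drop(s.flow), abs=1e-12)

    def test_distal_pressure_floored_at_zero(self):
        severe = sf.apply_stenosis(
            sf.make_straight_vessel(1.5, 60.0, 301), sf.StenosisSpec(30.0, 20.0, 0.95)
        )
        samples = sf.run_single_vessel_protocol(severe)
        assert sf.pressure_drop_model(severe).pressure_drop(4.0) > 100.0
        assert samples[-1].pd == 0.0 and samples[-1].ratio == 0.0

    @given(
        sa1=st.floats(0.1, 0.85),
        sa2=st.floats(0.1, 0.85),
        q=st.floats(0.5, 4.0),
    )
    def test_pressure_drop_monotone_in_severity(self, sa1, sa2, q):
        lo, hi = sorted((sa1, sa2))
        base = sf.make_straight_vessel(3.0, 30.0, 151)
        mild = sf.pressure_drop_model(sf.apply_stenosis(base, sf.StenosisSpec(15.0, 12.0, lo)))
        severe = sf.pressure_drop_model(sf.apply_stenosis(base, sf.StenosisSpec(15.0, 12.0, hi)))
        assert severe.pressure_drop(q) >= mild.pressure_drop(q) - 1e-12
        # and monotone in flow along each model
        assert severe.pressure_drop(q) >= severe.pressure_drop(q / 2.0)

    @given(length=st.floats(10.0, 50.0))
    def test_pressure_drop_monotone_in_length(self, length):
        short = sf.pressure_drop_model(sf.make_straight_vessel(3.0, length, 101))
        longer = sf.pressure_drop_model(sf.make_straight_vessel(3.0, length + 10.0, 101))
        assert longer.pressure_drop(3.0) >= short.pressure_drop(3.0)


class TestBifurcationProtocol:
    def test_symmetric_branches_get_unit_staged_flows(self):
        branch_samples = sf.run_bifurcation_protocol(make_symmetric_tree())
        for samples in branch_samples.values():
            assert [s.flow for s in samples] == [1.0, 2.0, 3.0, 4.0]

    def test_flow_conservation_and_pressure_continuity(self):
        tree = make_symmetric_tree(branch_sa=0.6)
        parent_model = sf.pressure_drop_model(tree.segments["LM"])
        branch_samples = sf.run_bifurcation_protocol(tree)
        for i, q_tot in enumerate(BIFURCATION_TOTAL_FLOWS):
            lad, lcx = branch_samples["LAD"][i], branch_samples["LCX"][i]
            assert lad.flow + lcx.flow == pytest.approx(q_tot, abs=1e-12)
            expected_pa = 100.0 - parent_model.pressure_drop(q_tot)
            assert lad.pa == pytest.approx(expected_pa, abs=1e-12)
            assert lcx.pa == pytest.approx(expected_pa, abs=1e-12)

    def test_asymmetric_murray_flows(self):
        parent = sf.make_straight_vessel(4.0, 10.0, 51, segment_id="LM")
        b1 = sf.make_straight_vessel(3.0, 30.0, 201, segment_id="LAD")
        b2 = sf.make_straight_vessel(2.0, 30.0, 201, segment_id="LCX")
        tree = sf.CoronaryTree(
            segments={"LM": parent, "LAD": b1, "LCX": b2}, root="LM", children={"LM": ["LAD", "LCX"]}
        )
        branch_samples = sf.run_bifurcation_protocol(tree)
        assert branch_samples["LAD"][-1].flow == pytest.approx(8.0 * 27.0 / 35.0, rel=1e-12)
        assert branch_samples["LCX"][-1].flow == pytest.approx(8.0 * 8.0 / 35.0, rel=1e-12)

    def test_single_child_root_rejected(self):
        segs = {
            "a": sf.make_straight_vessel(3.0, 20.0, 11, segment_id="a"),
            "b": sf.make_straight_vessel(3.0, 20.0, 11, segment_id="b"),
        }
        tree = sf.CoronaryTree(segments=segs, root="a", children={"a": ["b"]})
        with pytest.raises(UnsupportedTopologyError):
            sf.run_bifurcation_protocol(tree)
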