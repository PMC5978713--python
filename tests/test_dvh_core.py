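"""DVH data model: interpolation queries, normalization, hotspot screen, CSV I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jawsearch.dvh_core import (
    DVHCurve,
    DVHError,
    DegeneratePlanError,
    PlanDose,
    curves_equal,
    dose_at_volume,
    is_hotspot_unacceptable,
    max_dose,
    normalize_to_prescription,
    read_dvh_csv,
    resample,
    volume_at_dose,
    write_dvh_csv,
)
from tests.conftest import dvh_curves


def curve(points, sid="s"):
    d, v = zip(*points)
    return DVHCurve(sid, np.array(d, float), np.array(v, float))


class TestInvariants:
    @pytest.mark.parametrize(
        "points",
        [
            [(0, 90), (10, 0)],          # does not start at 100 %
            [(0, 100), (10, 50), (5, 0)],  # dose grid not increasing
            [(0, 100), (10, 110)],       # volume above 100 / increasing
            [(1, 100), (10, 0)],         # grid does not start at 0
        ],
    )
    def test_invalid_curves_rejected(self, points):
        with pytest.raises(DVHError):
            curve(points)

    def test_empty_curve_rejected(self):
        with pytest.raises(DVHError):
            DVHCurve("s", np.array([]), np.array([]))


class TestResample:
    def test_midpoint_interpolation(self):
        c = resample(curve([(0, 100), (10, 0)]), 5.0)
        assert np.allclose(c.dose_gy, [0, 5, 10])
        assert np.allclose(c.volume_pct, [100, 50, 0])

    def test_identity_on_aligned_grid(self):
        c = resample(curve([(0, 100), (10, 100), (20, 0)]), 10.0)
        assert np.allclose(c.dose_gy, [0, 10, 20])
        assert np.allclose(c.volume_pct, [100, 100, 0])

    def test_hand_interpolation_oracle(self):
        # between (0,100) and (8,25): at 4 Gy -> 100 + 4/8*(25-100) = 62.5
        c = resample(curve([(0, 100), (8, 25), (16, 5)]), 4.0)
        assert c.volume_pct[1] == pytest.approx(62.5)

    def test_bad_bin_width(self):
        with pytest.raises(DVHError):
            resample(curve([(0, 100), (10, 0)]), 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(dvh_curves())
    def test_refinement_error_bound(self, c):
        """Resampled nodes are exact; a finer grid stays within the coarse
        grid's interpolation error bound (the largest per-cell volume drop)."""
        coarse = resample(c, 1.0)
        fine = resample(c, 0.25)
        for rc in (coarse, fine):
            for d in rc.dose_gy[::3]:
                assert volume_at_dose(rc, float(d)) == pytest.approx(
                    volume_at_dose(c, float(d)), abs=1e-9
                )
        bound = float(np.max(-np.diff(coarse.volume_pct), initial=0.0)) + 1e-9
        for d in np.linspace(0, float(c.dose_gy[-1]), 7):
            assert abs(volume_at_dose(fine, d) - volume_at_dose(c, d)) <= bound


class TestQueries:
    @pytest.mark.parametrize(
        "points,v,expected",
        [
            ([(0, 100), (10, 0)], 50, 5.0),
            ([(0, 100), (10, 100), (20, 0)], 100, 10.0),  # far edge of the plateau
            ([(0, 100), (10, 0)], 0, 10.0),
            ([(0, 100), (10, 0)], 100, 0.0),
        ],
    )
    def test_dose_at_volume(self, points, v, expected):
        assert dose_at_volume(curve(points), v) == pytest.approx(expected)

    def test_dose_at_volume_matches_brute_force_scan(self):
        c = curve([(0, 100), (10, 100), (20, 0)])
        grid = np.arange(0, 20.001, 0.001)
        vols = np.interp(grid, c.dose_gy, c.volume_pct)
        brute = grid[vols >= 100].max()
        assert dose_at_volume(c, 100) == pytest.approx(brute, abs=1e-3)

    @pytest.mark.parametrize(
        "points,d,expected",
        [
            ([(0, 100), (10, 0)], 2.5, 75.0),
            ([(0, 100), (10, 0)], 0.0, 100.0),
            ([(0, 100), (30, 100), (40, 50), (50, 0)], 45, 25.0),
            ([(0, 100), (10, 0)], 99.0, 0.0),  # beyond the last sample
        ],
    )
    def test_volume_at_dose(self, points, d, expected):
        assert volume_at_dose(curve(points), d) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 100), (10, 0)], 10.0),
            ([(0, 100), (50, 1), (55, 0)], 55.0),
            ([(0, 100), (10, 0), (20, 0)], 10.0),  # trailing zeros ignored
        ],
    )
    def test_max_dose(self, points, expected):
        assert max_dose(curve(points)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(dvh_curves(), st.floats(0.1, 5.0))
    def test_dose_scaling_homogeneity(self, c, s):
        """Scaling doses by s scales D_v and Dmax by s, leaves V(d*s) fixed."""
        cs = c.scaled(s)
        assert max_dose(cs) == pytest.approx(s * max_dose(c), rel=1e-12)
        for v in (0.0, 30.0, 95.0, 100.0):
            assert dose_at_volume(cs, v) == pytest.approx(s * dose_at_volume(c, v), rel=1e-12)
        for d in (0.0, 5.0, 20.0):
            assert volume_at_dose(cs, d * s) == pytest.approx(volume_at_dose(c, d), abs=1e-9)


def two_structure_plan(d95=47.5):
    # target with D95 = d95: plateau to d95 at 95 %, falloff to d95*1.1
    target = curve([(0, 100), (0.5 * d95, 100), (d95, 95), (1.1 * d95, 0)], "ptv")
    oar = curve([(0, 100), (30, 20), (40, 0)], "oar")
    return PlanDose("p1", {"ptv": target, "oar": oar})


class TestNormalization:
    def test_closed_form_scale(self):
        plan = two_structure_plan(d95=47.5)
        out = normalize_to_prescription(plan, "ptv", 50.0, 95.0)
        s = 50.0 / 47.5
        assert out.scale_applied == pytest.approx(s)
        assert dose_at_volume(out.curve("ptv"), 95.0) == pytest.approx(50.0)
        # OAR doses scale by the same factor, volumes unchanged
        assert np.allclose(out.curve("oar").dose_gy, plan.curve("oar").dose_gy * s)
        assert np.array_equal(out.curve("oar").volume_pct, plan.curve("oar").volume_pct)

    def test_identity_when_already_at_prescription(self):
        plan = two_structure_plan(d95=50.0)
        out = normalize_to_prescription(plan, "ptv", 50.0, 95.0)
        assert out.scale_applied == pytest.approx(1.0)
        assert curves_equal(out.curve("ptv"), plan.curve("ptv"))

    def test_idempotent(self):
        plan = two_structure_plan(d95=43.0)
        once = normalize_to_prescription(plan, "ptv", 50.0, 95.0)
        twice = normalize_to_prescription(once, "ptv", 50.0, 95.0)
        assert twice.scale_applied == pytest.approx(once.scale_applied)
        assert np.allclose(twice.curve("ptv").dose_gy, once.curve("ptv").dose_gy)

    def test_degenerate_plan_raises(self):
        target = curve([(0, 100), (1, 0)], "ptv")
        plan = PlanDose("dead", {"ptv": target})
        # D95 of a curve that drops immediately: dose at 95 % is ~0.05 -- fine;
        # a target that is all zero dose beyond the origin is the degenerate case
        zero = curve([(0, 100)], "ptv")
        with pytest.raises(DegeneratePlanError):
            normalize_to_prescription(PlanDose("z", {"ptv": zero}), "ptv", 50.0, 95.0)
        assert normalize_to_prescription(plan, "ptv", 50.0, 95.0).scale_applied > 1


class TestHotspotScreen:
    @pytest.mark.parametrize(
        "dmax,unacceptable",
        [
            (53.5, False),   # exactly 107 % of 50 Gy: kept (strict inequality)
            (53.6, True),
            (50.0, False),
            (54.0, True),    # 108 %
        ],
    )
    def test_strict_107_boundary(self, dmax, unacceptable):
        target = curve([(0, 100), (0.9 * dmax, 95), (dmax, 0)], "ptv")
        plan = PlanDose("p", {"ptv": target})
        assert is_hotspot_unacceptable(plan, "ptv", 50.0, 107.0) is unacceptable


class TestCsvRoundTrip:
    def test_bit_exact_round_trip(self):
        rng = np.random.default_rng(7)
        plans = []
        for pid in ("a", "b"):
            d = np.concatenate([[0.0], np.cumsum(rng.uniform(0.1, 3.0, 9))])
            v = 100.0 - np.concatenate([[0.0], np.cumsum(rng.uniform(0, 11, 9))])
            v = np.clip(v, 0, 100)
            plans.append(PlanDose(pid, {"s": DVHCurve("s", d, v)}))
        buf = io.StringIO()
        write_dvh_csv(plans, buf)
        text1 = buf.getvalue()
        back = read_dvh_csv(io.StringIO(text1))
        assert [p.plan_id for p in back] == ["a", "b"]
        for orig, rt in zip(plans, back):
            assert curves_equal(orig.curve("s"), rt.curve("s"))
        buf2 = io.StringIO()
        write_dvh_csv(back, buf2)
        assert buf2.getvalue() == text1

    def test_bad_header_rejected(self):
        with pytest.raises(DVHError):
            read_dvh_csv(io.StringIO("plan,structure,dose,vol\n"))
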