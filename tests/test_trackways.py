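import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleogait.fixtures import BATRACHOTOMUS
from paleogait.synthetic import SyntheticTrackwaySpec, make_trackway
from paleogait.trackways import (
    Footprint,
    Trackway,
    analytic_track_phase,
    estimate_speed,
    extend_caudal_point,
    gad_from_trot,
    ipd_to_midpoint_distance,
    limb_phase_candidates,
    manus_pes_distances,
    midpoint,
    print_length,
    stride_vectors,
    summarize,
    summary_from_means,
    track_phase,
    trailing_manus_distance,
)


def fp(pid, limb, side, tip, caudal):
    return Footprint(pid, limb, side, np.array(tip, float), np.array(caudal, float))


class TestPrintGeometry:
    @pytest.mark.parametrize("tip,caudal,expected", [
        ((1, 0), (0, 0), 1.0),
        ((0.3, 0.4), (0, 0), 0.5),
    ])
    def test_print_length(self, tip, caudal, expected):
        assert print_length(fp(1, "pes", "left", tip, caudal)) == pytest.approx(expected)

    def test_midpoint(self):
        assert midpoint(fp(1, "pes", "left", (0, 0), (2, 0))) == pytest.approx((1, 0))
        assert midpoint(fp(1, "pes", "left", (1, 1), (1, 3))) == pytest.approx((1, 2))

    def test_midpoint_translation_equivariance(self):
        a = fp(1, "pes", "left", (0.3, 0.1), (0.0, 0.0))
        b = fp(1, "pes", "left", (5.3, 5.1), (5.0, 5.0))
        assert midpoint(b) - midpoint(a) == pytest.approx((5, 5))

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError):
            fp(1, "pes", "left", (1, 1), (1, 1))


class TestStrides:
    def test_two_left_pes_prints(self):
        tw = Trackway("t", [
            fp(1, "pes", "left", (0.1, 0), (-0.1, 0)),
            fp(2, "pes", "left", (1.6, 0), (1.4, 0)),
        ])
        vecs = stride_vectors(tw)
        assert vecs.shape == (1, 2)
        assert vecs[0] == pytest.approx((1.5, 0))

    def test_exclusion_ranges_reduce_count(self):
        prints = [fp(i, "pes", "left", (i * 1.0 + 0.1, 0), (i * 1.0 - 0.1, 0))
                  for i in range(4)]
        tw = Trackway("t", prints, exclusion_ranges=[(0, 0)])
        assert len(stride_vectors(tw)) == 2  # pairs (1,2) and (2,3)

    def test_no_pair_warns_and_returns_empty(self):
        tw = Trackway("t", [fp(1, "pes", "left", (0.1, 0), (-0.1, 0))])
        with pytest.warns(UserWarning):
            assert len(stride_vectors(tw)) == 0


class TestManusPes:
    def _trackway(self, lateral=0.0):
        prints = []
        pid = 1
        for k in range(3):
            x = k * 1.68
            prints.append(fp(pid, "pes", "left", (x + 0.17, 0), (x - 0.17, 0)))
            pid += 1
            prints.append(fp(pid, "manus", "left",
                             (x + 0.24 + 0.06, lateral), (x + 0.24 - 0.06, lateral)))
            pid += 1
        return Trackway("t", prints)

    def test_projected_distance_matches_construction(self):
        d = manus_pes_distances(self._trackway())
        assert d == pytest.approx([0.24, 0.24, 0.24])

    def test_lateral_offset_does_not_change_projection(self):
        d = manus_pes_distances(self._trackway(lateral=0.1))
        assert d == pytest.approx([0.24, 0.24, 0.24])

    def test_absolute_mode_includes_lateral_offset(self):
        d = manus_pes_distances(self._trackway(lateral=0.1), mode="absolute")
        assert d == pytest.approx([np.hypot(0.24, 0.1)] * 3)

    def test_purely_lateral_manus_projects_to_zero(self):
        prints = [
            fp(1, "pes", "left", (0.1, 0), (-0.1, 0)),
            fp(2, "manus", "left", (0.05, 0.3), (-0.05, 0.3)),
            fp(3, "pes", "left", (1.3, 0), (1.1, 0)),
        ]
        d = manus_pes_distances(Trackway("t", prints))
        assert d == pytest.approx([0.0], abs=1e-12)


class TestTrailingManus:
    def test_subtraction_from_stride(self):
        tw = Trackway("t", [
            fp(1, "manus", "left", (0.06, 0), (-0.06, 0)),
            fp(2, "pes", "left", (0.9, 0), (0.56, 0)),
        ])
        # manus midpoint at 0, pes midpoint at 0.73
        assert trailing_manus_distance(tw, 1, 2, 1.29) == pytest.approx(0.56)

    def test_coincident_manus_gives_full_stride(self):
        tw = Trackway("t", [
            fp(1, "manus", "left", (0.06, 0), (-0.06, 0)),
            fp(2, "pes", "left", (0.17, 0), (-0.17, 0)),
        ])
        assert trailing_manus_distance(tw, 1, 2, 1.29) == pytest.approx(1.29)

    def test_distance_beyond_stride_rejected(self):
        tw = Trackway("t", [
            fp(1, "manus", "left", (0.06, 0), (-0.06, 0)),
            fp(2, "pes", "left", (2.1, 0), (1.9, 0)),
        ])
        with pytest.raises(ValueError):
            trailing_manus_distance(tw, 1, 2, 1.29)


class TestScalarRelations:
    @pytest.mark.parametrize("ipd,pes,manus,expected", [
        (0.0, 0.3, 0.1, 0.2),
        (0.01, 0.34, 0.12, 0.24),
        (0.05, 0.22, 0.10, 0.21),
    ])
    def test_ipd_conversion(self, ipd, pes, manus, expected):
        assert ipd_to_midpoint_distance(ipd, pes, manus) == pytest.approx(expected)

    @pytest.mark.parametrize("d,D,expected", [
        (0.24, 1.68, 0.14), (0.13, 1.19, 0.11), (0.0, 2.0, 0.0),
    ])
    def test_track_phase(self, d, D, expected):
        assert round(track_phase(d, D), 2) == expected

    def test_estimate_speed_table_values(self):
        H12 = 0.34 * 0.76 / 0.26
        assert round(estimate_speed(1.68, H12), 2) == 0.60
        Hcd = 0.12 * 0.76 / 0.26
        assert round(estimate_speed(1.19, Hcd), 2) == 1.92
        assert estimate_speed(0.0, 1.0) == 0.0

    def test_analytic_track_phase_examples(self):
        assert analytic_track_phase(0.5, 0.705, 0.91) == pytest.approx(
            0.25 / 0.91, abs=1e-12)
        assert analytic_track_phase(0.0, 1.48, 1.48) == pytest.approx(0.0)
        assert analytic_track_phase(0.5, 0.74, 1.48) == pytest.approx(0.0)

    def test_limb_phase_candidates_inverts(self):
        for phi_L, LBx, D in [(0.5, 0.705, 0.91), (0.0, 1.48, 1.48), (0.3, 0.7, 1.2)]:
            phi_T = analytic_track_phase(phi_L, LBx, D)
            assert limb_phase_candidates(phi_T, LBx, D) == pytest.approx(
                phi_L % 1.0, abs=1e-12)

    def test_gad_from_trot(self):
        assert gad_from_trot(0.25, 0.91) == pytest.approx(0.705)
        assert gad_from_trot(0.0, 2.0) == pytest.approx(1.0)
        assert gad_from_trot(0.56, 1.29) == pytest.approx(1.205)


@settings(max_examples=200, deadline=None)
@given(d=st.floats(0.01, 2.0), D=st.floats(0.05, 3.0))
def test_trot_gad_and_track_phase_are_mutually_consistent(d, D):
    """A trot's quadruple-stance GAD estimate, fed back through the analytic
    track-phase relation at phi_L = 0.5, recovers d/D exactly."""
    a = analytic_track_phase(0.5, gad_from_trot(d, D), D)
    b = (d / D) % 1.0
    assert min(abs(a - b), 1.0 - abs(a - b)) < 1e-12  # equal modulo 1


class TestSummaries:
    def test_table_row_pipeline(self):
        s = summary_from_means("12", 0.34, 0.12, 0.24, 1.68, BATRACHOTOMUS)
        assert round(s.track_phase, 2) == 0.14
        assert round(s.speed, 2) == 0.60

    def test_rigid_motion_invariance(self):
        spec = SyntheticTrackwaySpec(phi_L=0.3, D=1.1, LBx=0.7,
                                     landmark_noise_sd=0.005, seed=4)
        tw, _ = make_trackway(spec)
        base = summarize(tw, BATRACHOTOMUS)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([13.0, -4.0])
        moved = Trackway(tw.name, [
            Footprint(f.print_id, f.limb, f.side, R @ f.tip + shift,
                      R @ f.caudal + shift) for f in tw.prints])
        rotated = summarize(moved, BATRACHOTOMUS)
        assert rotated.track_phase == pytest.approx(base.track_phase, abs=1e-9)
        assert rotated.stride.mean == pytest.approx(base.stride.mean, abs=1e-9)
        assert rotated.mp_distance.mean == pytest.approx(
            base.mp_distance.mean, abs=1e-9)

    def test_missing_manus_gives_partial_summary(self):
        prints = [fp(i, "pes", "left", (i * 1.2 + 0.13, 0), (i * 1.2 - 0.13, 0))
                  for i in range(3)]
        s = summarize(Trackway("no-manus", prints), BATRACHOTOMUS)
        assert s.mp_distance is None and s.track_phase is None
        assert s.stride.mean == pytest.approx(1.2)
        assert s.speed is not None

    def test_single_manus_has_no_sd(self):
        prints = [fp(i, "pes", "left", (i * 1.2 + 0.13, 0), (i * 1.2 - 0.13, 0))
                  for i in range(3)]
        prints.append(fp(10, "manus", "left", (0.3, 0), (0.2, 0)))
        s = summarize(Trackway("one-manus", prints), BATRACHOTOMUS)
        assert s.mp_distance.n == 1 and s.mp_distance.sd is None

    def test_manus_only_stride_fallback(self):
        prints = []
        for k in range(3):
            prints.append(fp(k + 1, "manus", "left",
                             (k * 1.3 + 0.05, 0), (k * 1.3 - 0.05, 0)))
        prints.append(fp(9, "pes", "left", (0.5, 0), (0.24, 0)))
        s = summarize(Trackway("manus-stride", prints), BATRACHOTOMUS)
        assert s.stride_source == "manus"
        assert s.stride.mean == pytest.approx(1.3)


def test_extend_caudal_point_restores_length():
    cropped = fp(6, "pes", "left", (0.28, 0.0), (0.15, 0.0))
    fixed = extend_caudal_point(cropped, 0.28)
    assert print_length(fixed) == pytest.approx(0.28)
    assert fixed.tip == pytest.approx(cropped.tip)
    assert "extended" in fixed.notes
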