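import numpy as np
import pytest

from conftest import make_circle_pair
from modiolus.curvature import _point_polyline_distance
from modiolus.insertion import (
    ELECTRODES,
    GeometryInfeasibleError,
    TangentialTransition,
    eid_ia_surface,
    offset_trajectory,
    tangential_transition,
    tune_doff,
)
from modiolus.spiral import resample

RHO = 2.5  # offset-path radius of the worked phantom (2.0 + 0.5)
D = 4.5  # entry distance
L_STR = np.sqrt(D**2 - RHO**2)
IA_STR = np.degrees(np.arccos(RHO / D))


@pytest.fixture(scope="module")
def traj(circle_phantom):
    modiolar, lateral = circle_phantom
    return offset_trajectory(modiolar, lateral, 0.5)


class TestCirclePhantom:
    """Closed-form checks on the concentric-circle anatomy."""

    def test_curved_segment_radius(self, traj):
        r = np.hypot(traj.curved_points[:, 0], traj.curved_points[:, 1])
        assert np.allclose(r, RHO, rtol=1e-3)

    def test_tangential_transition_closed_form(self, traj):
        tr = traj.transition
        assert tr.l_str == pytest.approx(L_STR, rel=1e-3)
        assert tr.IA_str == pytest.approx(IA_STR, rel=1e-3)
        assert tr.l_crit == pytest.approx(2 * L_STR, rel=1e-3)

    def test_full_turn_arc_length(self, traj):
        s0 = traj.eid_of_ia(traj.transition.IA_str)
        s1 = traj.eid_of_ia(traj.transition.IA_str + 360.0)
        assert s1 - s0 == pytest.approx(2 * np.pi * RHO, rel=1e-3)

    def test_eid_linear_in_angle_on_curved_part(self, traj):
        tr = traj.transition
        for ia in (100.0, 250.0, 500.0):
            expected = tr.l_str + RHO * np.radians(ia - tr.IA_str)
            assert traj.eid_of_ia(ia) == pytest.approx(expected, rel=1e-3)

    def test_transition_point_maps_to_l_str(self, traj):
        assert traj.eid_of_ia(traj.transition.IA_str) == pytest.approx(
            traj.transition.l_str, rel=1e-3
        )

    def test_inverse_round_trip(self, traj):
        rng = np.random.default_rng(7)
        lo, hi = traj.theta_range
        ias = rng.uniform(lo, hi, size=100)
        back = np.array([traj.ia_of_eid(traj.eid_of_ia(a)) for a in ias])
        assert np.allclose(back, ias, atol=1e-9)

    def test_out_of_range_queries(self, traj):
        with pytest.raises(ValueError, match="valid interval"):
            traj.eid_of_ia(10000.0)
        with pytest.raises(ValueError, match="valid interval"):
            traj.ia_of_eid(-1.0)


class TestOffsetGeometry:
    def test_zero_offset_coincides_with_modiolar_wall(self, circle_phantom):
        modiolar, lateral = circle_phantom
        traj = offset_trajectory(modiolar, lateral, 0.0)
        r = np.hypot(traj.curved_points[:, 0], traj.curved_points[:, 1])
        assert np.allclose(r, 2.0, atol=1e-9)

    def test_offset_distance_conserved_on_mean_anatomy(self, mean_walls):
        """Every curved-segment sample sits d_off off the local modiolar wall.

        The distance is taken to the wall stretch of the same turn
        (±90°): in planar projection consecutive turns overlap, so a
        global minimum would jump windings.
        """
        modiolar, lateral = mean_walls
        d_off = 0.5
        traj = offset_trajectory(modiolar, lateral, d_off)
        wall = resample(modiolar, 0.1)
        for k in range(0, len(traj.curved_points), 40):
            theta = traj.curved_theta_deg[k]
            win = np.abs(wall.theta_deg - theta) <= 90.0
            dist = _point_polyline_distance(
                traj.curved_points[k, :2], wall.points[win, :2]
            )
            assert dist == pytest.approx(d_off, rel=0.01)

    def test_straight_segment_has_zero_curvature(self, mean_walls):
        modiolar, lateral = mean_walls
        traj = offset_trajectory(modiolar, lateral, 0.8)
        p = traj.straight_points
        chords = np.linalg.norm(p[-1] - p[0])
        summed = np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))
        assert summed == pytest.approx(chords, rel=1e-12)

    def test_entry_on_offset_curve_degenerates(self):
        modiolar, lateral = make_circle_pair(2.0, 2.5)
        tr = tangential_transition(modiolar, lateral, 0.5)
        assert tr.l_str == pytest.approx(0.0, abs=1e-9)
        assert tr.IA_str == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_offset_names_theta(self, circle_phantom):
        modiolar, lateral = circle_phantom
        with pytest.raises(GeometryInfeasibleError, match="theta"):
            offset_trajectory(modiolar, lateral, 3.0)

    def test_negative_offset_rejected(self, circle_phantom):
        modiolar, lateral = circle_phantom
        with pytest.raises(ValueError):
            offset_trajectory(modiolar, lateral, -0.1)


class TestMonotonicity:
    def test_eid_strictly_increasing_in_ia(self, mean_walls):
        modiolar, lateral = mean_walls
        traj = offset_trajectory(modiolar, lateral, 0.8)
        assert np.all(np.diff(traj.arclength_mm) > 0)

    def test_eid_increases_with_d_off_at_fixed_ia(self, mean_walls):
        modiolar, lateral = mean_walls
        eids = [
            offset_trajectory(modiolar, lateral, d, theta_max=250.0,
                              truncate=True).eid_of_ia(240.0)
            for d in np.arange(0.0, 1.51, 0.1)
        ]
        assert np.all(np.diff(eids) > 0)

    def test_transition_quantities_decrease_with_d_off(self, mean_walls):
        """l_str, IA_str and l_crit are largest for the most modiolar array."""
        modiolar, lateral = mean_walls
        trs = [tangential_transition(modiolar, lateral, d) for d in (0.3, 0.8, 1.0)]
        for attr in ("l_str", "IA_str", "l_crit"):
            vals = [getattr(t, attr) for t in trs]
            assert vals[0] > vals[1] > vals[2]


class TestTuneDoff:
    def test_self_consistency(self, mean_walls):
        modiolar, lateral = mean_walls
        traj = offset_trajectory(modiolar, lateral, 0.6)
        anchor = (traj.eid_of_ia(360.0), 360.0)
        assert tune_doff((modiolar, lateral), anchor) == pytest.approx(0.6)

    def test_refinement(self, mean_walls):
        modiolar, lateral = mean_walls
        traj = offset_trajectory(modiolar, lateral, 0.65)
        anchor = (traj.eid_of_ia(350.0), 350.0)
        d = tune_doff((modiolar, lateral), anchor, refine_to=0.01)
        assert d == pytest.approx(0.65, abs=0.01)

    def test_empty_grid_rejected(self, mean_walls):
        with pytest.raises(ValueError):
            tune_doff(mean_walls, (16.0, 348.0), grid=[])

    def test_unreachable_anchor_rejected(self, mean_walls):
        with pytest.raises(ValueError):
            tune_doff(mean_walls, (50.0, 2000.0))


class TestSurface:
    def test_single_phantom_matches_closed_form(self, circle_phantom):
        modiolar, lateral = circle_phantom
        table, counts = eid_ia_surface([(modiolar, lateral)], [0.5], [180.0, 360.0])
        tr = tangential_transition(modiolar, lateral, 0.5)
        for ia in (180.0, 360.0):
            expected = tr.l_str + RHO * np.radians(ia - tr.IA_str)
            assert table.loc[0.5, ia] == pytest.approx(expected, rel=1e-3)
        assert (counts.to_numpy() == 1).all()

    def test_identical_cohort_zero_variance(self, circle_phantom):
        modiolar, lateral = circle_phantom
        single, _ = eid_ia_surface([(modiolar, lateral)], [0.2, 0.5], [180.0, 300.0])
        triple, _ = eid_ia_surface([(modiolar, lateral)] * 3, [0.2, 0.5], [180.0, 300.0])
        assert np.allclose(triple.to_numpy(), single.to_numpy())

    def test_monotone_in_both_axes(self, mean_walls):
        table, _ = eid_ia_surface(
            [mean_walls], [0.0, 0.4, 0.8], [120.0, 240.0, 330.0]
        )
        arr = table.to_numpy()
        assert np.all(np.diff(arr, axis=0) > 0)  # in d_off
        assert np.all(np.diff(arr, axis=1) > 0)  # in IA

    def test_short_anatomy_excluded_from_mean(self):
        short = make_circle_pair(2.0, 4.5, theta_max=300.0)
        table, counts = eid_ia_surface([short], [0.5], [200.0, 500.0])
        assert counts.loc[0.5, 200.0] == 1
        assert counts.loc[0.5, 500.0] == 0
        assert np.isnan(table.loc[0.5, 500.0])

    def test_empty_inputs_rejected(self, circle_phantom):
        with pytest.raises(ValueError):
            eid_ia_surface([], [0.5], [180.0])


class TestSpecsAndValidation:
    def test_electrode_specs_offsets(self):
        assert ELECTRODES["contour_advance"].d_off == 0.8
        assert ELECTRODES["mid_scala"].d_off == 1.0
        assert ELECTRODES["slim_modiolar"].d_off == 0.3

    def test_transition_invariants_enforced(self):
        with pytest.raises(ValueError):
            TangentialTransition(l_str=5.0, IA_str=30.0, l_crit=4.0)
        with pytest.raises(ValueError):
            TangentialTransition(l_str=1.0, IA_str=95.0, l_crit=2.0)
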