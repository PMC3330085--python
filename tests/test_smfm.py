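"""Distances, dihedrals, rotamers, ring tilt, RMSD, smoothing, lock state, events."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrtraj.exceptions import ConfigurationError, ParameterError, SelectionError
from gpcrtraj.fitting import dihedral
from gpcrtraj.model import AtomTable, Frame, TimeSeries, Trajectory, select
from gpcrtraj.smfm import (
    DEFAULT_EVENT_RULES,
    LOCK_CLOSE_RULE,
    activation_metrics,
    backbone_rmsd,
    ca_distance,
    chi_angles,
    classify_rotamer,
    detect_activation_events,
    lock_state,
    min_distance,
    ring_tilt,
    running_average,
)
from gpcrtraj.synth import BundleSpec, make_bundle
from tests.conftest import AGONIST_EVENT_FRAMES


def _point_traj(points_per_frame, names=None):
    """Trajectory of bare points for distance-operation tests."""
    arr = np.asarray(points_per_frame, float)
    n = arr.shape[1]
    table = AtomTable(
        name=names or [f"X{i}" for i in range(n)],
        res_name=["UNK"] * n,
        res_seq=list(range(1, n + 1)),
        chain=["A"] * n,
    )
    return Trajectory(table, arr)


class TestCaDistance:
    def test_same_residue_is_zero(self, bundle):
        frame, bw_map = bundle
        traj = Trajectory(frame.table, frame.coords[None])
        ts = ca_distance(traj, bw_map, "6.48", "6.48")
        assert np.allclose(ts.values, 0.0)

    def test_three_four_five_triangle(self):
        table = AtomTable(["CA", "CA"], ["GLY", "GLY"], [350, 630], ["A", "A"])
        coords = np.array([[[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]])
        traj = Trajectory(table, coords)
        from gpcrtraj.bwmap import BWMap

        bw = BWMap(anchors={3: ("A", 350), 6: ("A", 650)})
        ts = ca_distance(traj, bw, "3.50", "6.30")
        assert ts.values[0] == pytest.approx(5.0)

    def test_translation_and_rotation_invariance(self, agonist_run):
        traj, gt = agonist_run
        bw_map = gt["bw_map"]
        ref = ca_distance(traj, bw_map, "3.50", "6.30").values
        rot = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        moved = Trajectory(traj.table, traj.coords @ rot.T + 7.5, times=traj.times)
        assert np.allclose(ca_distance(moved, bw_map, "3.50", "6.30").values, ref, atol=1e-9)


class TestMinDistance:
    def test_singletons_equal_pair_distance(self):
        traj = _point_traj([[[0, 0, 0], [3, 4, 0]]])
        a = select(traj, "name X0")
        b = select(traj, "name X1")
        assert min_distance(traj, a, b).values[0] == pytest.approx(5.0)

    def test_two_against_one_analytic(self):
        traj = _point_traj([[[0, 0, 0], [10, 0, 0], [4, 0, 0]]])
        a = select(traj, "name X0 X1")
        b = select(traj, "name X2")
        assert min_distance(traj, a, b).values[0] == pytest.approx(4.0)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.normal(scale=8.0, size=(20, 50, 3))
        traj = _point_traj(coords)
        a = select(traj, "resid 1-20")
        b = select(traj, "resid 21-50")
        fast = min_distance(traj, a, b).values
        for k in range(traj.n_frames):
            best = min(
                np.linalg.norm(coords[k, i] - coords[k, j])
                for i in a.indices
                for j in b.indices
            )
            assert abs(fast[k] - best) < 1e-9


class TestChiAndRotamers:
    def test_dihedral_construction_60_degrees(self):
        p0 = np.array([1.0, 0.0, -1.0])
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 1.0])
        ang = np.radians(60.0)
        p3 = np.array([np.cos(ang), np.sin(ang), 2.0])
        assert dihedral(p0, p1, p2, p3) == pytest.approx(60.0, abs=1e-9)
        assert classify_rotamer(60.0).label == "g+"

    def test_dihedral_sign_matches_mdanalysis(self, rng):
        """IUPAC convention cross-checked against an independent implementation."""
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(20):
            pts = rng.normal(scale=3.0, size=(4, 3))
            ours = dihedral(*pts)
            theirs = np.degrees(
                calc_dihedrals(pts[0][None], pts[1][None], pts[2][None], pts[3][None])[0]
            )
            assert ours == pytest.approx(theirs, abs=1e-3)  # MDAnalysis uses float32

    @pytest.mark.parametrize(
        "chi1,label",
        [(-65.0, "g-"), (-119.9, "g-"), (60.0, "g+"), (0.0, "g+"), (180.0, "trans"),
         (-150.0, "trans"), (130.0, "trans")],
    )
    def test_rotamer_bins(self, chi1, label):
        assert classify_rotamer(chi1).label == label

    def test_built_chi_angles_recovered_exactly(self):
        frame, bw_map = make_bundle(BundleSpec(chi1={(6, 48): -77.0}))
        traj = Trajectory(frame.table, frame.coords[None])
        chi1, chi2 = chi_angles(traj, bw_map, "6.48")
        assert chi1.values[0] == pytest.approx(-77.0, abs=1e-6)
        assert chi2.values[0] == pytest.approx(90.0, abs=1e-6)

    def test_scripted_flip_changes_classification_at_exact_frame(self, agonist_run):
        traj, gt = agonist_run
        chi1, _ = chi_angles(traj, gt["bw_map"], "6.48")
        labels = [classify_rotamer(v).label for v in chi1.values]
        flip = AGONIST_EVENT_FRAMES[3]
        assert labels[flip - 1] == "g-"
        assert labels[flip] == "trans"

    def test_missing_atom_raises(self, bundle):
        frame, bw_map = bundle
        traj = Trajectory(frame.table, frame.coords[None])
        with pytest.raises(SelectionError):
            chi_angles(traj, bw_map, "6.50")  # proline carries no gamma atom here


def _hexagon_frame(rotation=None):
    ang = np.radians(np.arange(6) * 60.0)
    pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    if rotation is not None:
        pts = pts @ rotation.T
    table = AtomTable(
        name=["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        res_name=["TRP"] * 6,
        res_seq=[648] * 6,
        chain=["A"] * 6,
    )
    return Trajectory(table, pts[None])


class TestRingTilt:
    @pytest.fixture()
    def hex_map(self):
        from gpcrtraj.bwmap import BWMap

        return BWMap(anchors={6: ("A", 650)})

    def test_flat_hexagon_parallel_to_membrane(self, hex_map):
        ts = ring_tilt(_hexagon_frame(), hex_map, "6.48", [0, 0, 1])
        assert ts.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_hexagon(self, hex_map):
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], float)  # 90 deg about x
        ts = ring_tilt(_hexagon_frame(rot), hex_map, "6.48", [0, 0, 1])
        assert ts.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_scripted_37_degree_rotation(self, hex_map):
        a = np.radians(37.0)
        rot = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        ts = ring_tilt(_hexagon_frame(rot), hex_map, "6.48", [0, 0, 1])
        assert ts.values[0] == pytest.approx(37.0, abs=0.1)


class TestBackboneRmsd:
    def test_reference_against_itself_is_zero(self, bundle):
        frame, _ = bundle
        traj = Trajectory(frame.table, frame.coords[None])
        sel = select(traj, "name CA")
        assert backbone_rmsd(traj, frame, sel).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed_by_superposition(self, bundle):
        frame, _ = bundle
        rot = np.linalg.qr(np.random.default_rng(3).normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        moved = Trajectory(frame.table, (frame.coords @ rot.T + [1.0, -2.0, 3.0])[None])
        sel = select(moved, "name CA")
        assert backbone_rmsd(moved, frame, sel).values[0] < 1e-6

    def test_matches_quaternion_oracle_for_single_displacement(self, bundle):
        """One atom displaced by 3 Å: equals the quaternion-method optimal RMSD."""
        frame, _ = bundle
        sel_idx = select(frame, "name CA").indices[:40]
        ref = frame.coords[sel_idx]
        moved = ref.copy()
        moved[7] += [3.0, 0.0, 0.0]

        def quaternion_rmsd(p, q):
            p = p - p.mean(axis=0)
            q = q - q.mean(axis=0)
            m = p.T @ q
            sxx, sxy, sxz = m[0]
            syx, syy, syz = m[1]
            szx, szy, szz = m[2]
            k = np.array(
                [
                    [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
                    [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
                    [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
                    [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
                ]
            )
            lam = np.linalg.eigvalsh(k).max()
            e0 = (p**2).sum() + (q**2).sum()
            return np.sqrt(max(e0 - 2.0 * lam, 0.0) / p.shape[0])

        table = AtomTable(
            [f"C{i}" for i in range(40)], ["ALA"] * 40, list(range(1, 41)), ["A"] * 40
        )
        traj = Trajectory(table, moved[None])
        sel = select(traj, "all")
        got = backbone_rmsd(traj, Frame(table, ref), sel).values[0]
        assert got == pytest.approx(quaternion_rmsd(moved, ref), abs=1e-9)


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        ts = TimeSeries("c", np.arange(20.0), np.full(20, 3.3))
        out = running_average(ts, 10)
        assert np.allclose(out.values, 3.3)
        assert len(out) == 11

    def test_one_to_ten_single_window(self):
        ts = TimeSeries("x", np.arange(10.0), np.arange(1.0, 11.0))
        out = running_average(ts, 10)
        assert len(out) == 1
        assert out.values[0] == pytest.approx(5.5)
        assert out.times[0] == 9.0

    def test_matches_explicit_loop(self, rng):
        vals = rng.normal(size=57)
        ts = TimeSeries("r", np.arange(57.0), vals)
        out = running_average(ts, 10)
        loop = [vals[i - 9 : i + 1].mean() for i in range(9, 57)]
        assert np.allclose(out.values, loop, atol=1e-12)

    def test_window_larger_than_series_raises(self):
        ts = TimeSeries("x", np.arange(5.0), np.arange(5.0))
        with pytest.raises(ParameterError):
            running_average(ts, 6)


class TestLockState:
    def _series(self, values):
        return TimeSeries("lock", np.arange(float(len(values))), np.asarray(values, float))

    def test_all_below_threshold_closed(self):
        states = lock_state(self._series([8.5] * 20))
        assert all(s.label == "closed" for s in states)

    def test_all_above_threshold_open(self):
        states = lock_state(self._series([9.5] * 20))
        assert all(s.label == "open" for s in states)

    def test_tie_value_is_closed(self):
        states = lock_state(self._series([9.0] * 5), dwell=1)
        assert all(s.label == "closed" for s in states)

    def test_short_flicker_suppressed_by_dwell(self):
        vals = [8.0] * 10 + [10.0] * 2 + [8.0] * 10
        states = lock_state(self._series(vals), dwell=5)
        assert all(s.label == "closed" for s in states)

    def test_sustained_transition_accepted(self):
        vals = [8.0] * 10 + [10.0] * 8
        states = lock_state(self._series(vals), dwell=5)
        assert [s.label for s in states[-8:]] == ["open"] * 8

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(5.0, 13.0), min_size=6, max_size=40))
    def test_monotone_in_threshold(self, values):
        """Raising the threshold never converts closed -> open at fixed distance."""
        lo = lock_state(self._series(values), threshold=8.5, dwell=1)
        hi = lock_state(self._series(values), threshold=10.0, dwell=1)
        for a, b in zip(lo, hi):
            if a.label == "closed":
                assert b.label == "closed"


class TestEventDetection:
    def test_scripted_six_events_recovered_in_order(self, agonist_run):
        traj, gt = agonist_run
        metrics = activation_metrics(traj, gt["bw_map"])
        timeline = detect_activation_events(metrics, DEFAULT_EVENT_RULES)
        assert timeline.event_ids() == [1, 2, 3, 4, 5, 6]
        onsets_frames = [int(round(e.onset_ns / traj.stride)) for e in timeline.events]
        for got, scripted in zip(onsets_frames, AGONIST_EVENT_FRAMES):
            assert abs(got - scripted) <= 5

    def test_flat_trajectory_yields_empty_timeline(self, membrane_run_noisy):
        traj, gt = membrane_run_noisy
        metrics = activation_metrics(traj, gt["bw_map"])
        timeline = detect_activation_events(metrics, DEFAULT_EVENT_RULES)
        assert len(timeline) == 0

    def test_inverse_scenario_contains_lock_close_only(self, inverse_run):
        traj, gt = inverse_run
        metrics = activation_metrics(traj, gt["bw_map"])
        rules = DEFAULT_EVENT_RULES + (LOCK_CLOSE_RULE,)
        timeline = detect_activation_events(metrics, rules)
        assert [e.rule for e in timeline.events] == ["ionic lock closes"]
        final = lock_state(metrics["d_3.50_6.30"])[-20:]
        assert all(s.label == "closed" for s in final)

    def test_missing_series_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            detect_activation_events({}, DEFAULT_EVENT_RULES)
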