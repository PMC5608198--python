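import numpy as np
import pytest

from emtqa.io_formats import MOVE_OUT, STOP, SensorRecording
from emtqa.mds_registration import (
    DegenerateGeometryError,
    DwellPositionSet,
    align_and_deviate,
    extract_dwell_positions,
    mds_embed,
)
from emtqa.synthetic_phantom import generate_plan


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _point_set(positions, catheter_of=None):
    M = len(positions)
    catheter_of = catheter_of or (lambda i: 1)
    keys = []
    counts = {}
    for i in range(M):
        c = catheter_of(i)
        counts[c] = counts.get(c, 0) + 1
        keys.append((c, counts[c]))
    return DwellPositionSet(keys=tuple(keys), positions=np.asarray(positions, float),
                            n_samples=np.ones(M, dtype=int))


def _grid_points(n=3):
    g = np.arange(n, dtype=float)
    return np.array([[x, y, z] for x in g for y in g for z in g])


class TestExtractDwellPositions:
    def _recording(self, solenoid, command, dwell, cath):
        T = len(solenoid)
        return SensorRecording(
            t=np.arange(T) / 40.0, solenoid=np.asarray(solenoid, float),
            fiducials=np.zeros((3, T, 3)),
            command=np.array(command, dtype=object),
            dwell_index=np.asarray(dwell, int), catheter_id=np.asarray(cath, int),
        )

    def test_constant_stop_run_yields_its_value(self):
        rec = self._recording(np.tile([1.0, 2.0, 3.0], (40, 1)),
                              [STOP] * 40, [1] * 40, [1] * 40)
        out = extract_dwell_positions(rec)
        assert out.keys == ((1, 1),)
        assert np.allclose(out.positions[0], [1, 2, 3])
        assert out.n_samples[0] == 40

    def test_mean_of_two_samples(self):
        rec = self._recording([[0, 0, 0], [0, 0, 2]], [STOP, STOP], [1, 1], [1, 1])
        out = extract_dwell_positions(rec)
        assert np.allclose(out.positions[0], [0, 0, 1])

    def test_full_traversal_yields_one_entry_per_plan_point(self, small_phantom):
        plan, rec, _ = small_phantom
        out = extract_dwell_positions(rec)
        assert len(out) == plan.n_dwell_points
        assert set(out.keys) == {
            (c.catheter_id, dp.dwell_index)
            for c in plan.catheters for dp in c.dwell_points
        }

    def test_no_stop_samples_rejected(self):
        rec = self._recording([[0, 0, 0]] * 3, [MOVE_OUT] * 3, [0] * 3, [1] * 3)
        with pytest.raises(ValueError, match="STOP"):
            extract_dwell_positions(rec)


class TestMDSEmbed:
    def test_grid_distances_reproduced(self):
        pts = _grid_points(3)
        emb = mds_embed(_point_set(pts))
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1)
        assert np.allclose(d_out, d_in, atol=1e-6)

    def test_rigid_motion_preserves_eigenvalue_spectrum(self):
        pts = _grid_points(3)
        moved = pts @ _rotation([1, 2, 3], 0.8).T + np.array([5.0, -2.0, 7.0])
        a = mds_embed(_point_set(pts)).eigenvalues
        b = mds_embed(_point_set(moved)).eigenvalues
        assert np.allclose(a, b, atol=1e-6)

    def test_unit_tetrahedron_distances(self):
        pts = np.array([
            [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]
        ]) / np.sqrt(8)
        emb = mds_embed(_point_set(pts))
        d = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1)
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(DegenerateGeometryError):
            mds_embed(_point_set(pts))

    def test_dissimilarity_matrix_is_minus_half_squared_distance(self):
        pts = _grid_points(2)
        emb = mds_embed(_point_set(pts))
        d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
        assert np.allclose(emb.dissimilarity, -0.5 * d2)
        assert np.allclose(np.diag(emb.dissimilarity), 0.0)


class TestAlignAndDeviate:
    def _two_catheter_sets(self):
        rng = np.random.default_rng(0)
        pts = _grid_points(3) * 5.0 + rng.normal(0, 0.01, (27, 3))
        catheter_of = lambda i: 1 + (i % 3)
        return _point_set(pts, catheter_of), pts, catheter_of

    def test_identical_sets_give_zero_deviations(self):
        plan, pts, catheter_of = self._two_catheter_sets()
        measured = _point_set(pts.copy(), catheter_of)
        report = align_and_deviate(plan, measured)
        assert report.global_mean < 1e-6

    @pytest.mark.parametrize("method", ["separate", "direct"])
    def test_rigid_motion_gives_zero_deviations(self, method):
        plan, pts, catheter_of = self._two_catheter_sets()
        moved = pts @ _rotation([0, 1, 1], 1.1).T + np.array([10.0, 3.0, -4.0])
        report = align_and_deviate(plan, _point_set(moved, catheter_of),
                                   method=method)
        assert report.global_mean < 1e-6

    def test_reflected_set_still_aligns_when_reflection_allowed(self):
        plan, pts, catheter_of = self._two_catheter_sets()
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        report = align_and_deviate(plan, _point_set(mirrored, catheter_of),
                                   method="direct")
        assert report.global_mean < 1e-6

    def test_single_catheter_shift_localises_to_that_catheter(self, small_phantom):
        plan, _, _ = small_phantom
        plan_set = DwellPositionSet.from_plan(plan)
        shifted = plan_set.positions.copy()
        mask = np.array([k[0] == 2 for k in plan_set.keys])
        shifted[mask] += np.array([0.0, 2.0, 0.0])
        measured = DwellPositionSet(
            keys=plan_set.keys, positions=shifted,
            n_samples=plan_set.n_samples)

        # oracle: orthogonal Procrustes fitted on the untouched catheters
        # recovers the identity, so the shifted catheter deviates by the
        # full 2 mm and the others by ~0
        from scipy.linalg import orthogonal_procrustes
        src, dst = shifted[~mask], plan_set.positions[~mask]
        mu_s, mu_d = src.mean(0), dst.mean(0)
        R, _ = orthogonal_procrustes(src - mu_s, dst - mu_d)
        aligned = (shifted - mu_s) @ R + mu_d
        oracle_dev = np.linalg.norm(aligned - plan_set.positions, axis=1)
        assert np.allclose(oracle_dev[mask], 2.0, atol=1e-6)
        assert np.allclose(oracle_dev[~mask], 0.0, atol=1e-6)

        # the all-pairs alignment absorbs part of the shift into the fitted
        # rotation/translation, but the shifted catheter still ranks first
        report = align_and_deviate(plan_set, measured, method="direct")
        per = report.per_catheter_mean()
        assert all(per[2] > m for c, m in per.items() if c != 2)
        assert per[2] == pytest.approx(2.0, abs=0.8)

    def test_global_mean_monotone_in_injected_shift(self, small_phantom):
        plan, _, _ = small_phantom
        plan_set = DwellPositionSet.from_plan(plan)
        mask = np.array([k[0] == 1 for k in plan_set.keys])
        means = []
        for shift in (0.0, 1.0, 2.5, 5.0):
            shifted = plan_set.positions.copy()
            shifted[mask] += np.array([shift, 0.0, 0.0])
            measured = DwellPositionSet(keys=plan_set.keys, positions=shifted,
                                        n_samples=plan_set.n_samples)
            means.append(align_and_deviate(plan_set, measured,
                                           method="direct").global_mean)
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_unmatched_plan_keys_reported_and_excluded(self):
        plan, pts, catheter_of = self._two_catheter_sets()
        keep = np.arange(len(pts) - 3)
        measured = DwellPositionSet(
            keys=tuple(plan.keys[i] for i in keep),
            positions=pts[keep], n_samples=np.ones(len(keep), dtype=int))
        report = align_and_deviate(plan, measured)
        assert len(report.unmatched) == 3
        assert len(report.deviations) == len(keep)

    def test_too_few_matches_rejected(self):
        pts = _grid_points(2)[:4]
        plan = _point_set(pts)
        measured = DwellPositionSet(keys=(plan.keys[0], plan.keys[1]),
                                    positions=pts[:2],
                                    n_samples=np.ones(2, dtype=int))
        with pytest.raises(ValueError, match="matched"):
            align_and_deviate(plan, measured)


def test_plan_point_set_keys_follow_plan_order(small_scenario):
    plan = generate_plan(small_scenario)
    ps = DwellPositionSet.from_plan(plan)
    assert ps.keys[0] == (1, 1)
    assert len(ps) == plan.n_dwell_points
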