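"""TPS bending energy, tangent-frame estimation, semilandmark sliding."""

import numpy as np
import pytest

import morphorec as mr
from morphorec.errors import DegenerateShapeError
from morphorec.io import FIXED, SEMILANDMARK, LandmarkDataset, LandmarkConfiguration
from morphorec.sliding import _estimate_frames_batch, _slide_one


class TestBendingEnergyMatrix:
    def test_affine_fields_have_zero_energy(self, template):
        bem = mr.bending_energy_matrix(template)
        rng = np.random.default_rng(1)
        for _ in range(5):
            A = rng.standard_normal((3, 3))
            t = rng.standard_normal(3)
            V = template @ A + t  # affine displacement field
            assert bem.energy(V) < 1e-8

    def test_quadratic_scaling(self, template):
        bem = mr.bending_energy_matrix(template)
        rng = np.random.default_rng(2)
        V = rng.standard_normal(template.shape)
        e1, e2 = bem.energy(V), bem.energy(2 * V)
        assert e2 == pytest.approx(4 * e1, rel=1e-10)

    def test_positive_semidefinite(self, template):
        bem = mr.bending_energy_matrix(template)
        eigvals = np.linalg.eigvalsh(bem.matrix)
        assert eigvals.min() > -1e-9 * max(eigvals.max(), 1.0)
        np.testing.assert_allclose(bem.matrix, bem.matrix.T, atol=1e-10)

    def test_duplicate_landmarks_rejected(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]
        )
        with pytest.raises(DegenerateShapeError, match="2 and 3"):
            mr.bending_energy_matrix(pts)

    def test_energy_matches_bordered_system_solve(self):
        # independent evaluation: interpolate the displacement field with
        # the full bordered TPS system and evaluate the functional as
        # w^T K w per axis
        ref = np.array(
            [
                [0, 0, 0],
                [2, 0, 0.3],
                [0, 2, 0.1],
                [2, 2, 0.5],
                [1, 1, 1.0],
            ]
        )
        bem = mr.bending_energy_matrix(ref)
        k = 5
        from scipy.spatial.distance import cdist

        K = cdist(ref, ref)
        Q = np.hstack([np.ones((k, 1)), ref])
        L = np.block([[K, Q], [Q.T, np.zeros((4, 4))]])
        for j in range(k):
            V = np.zeros((k, 3))
            V[j, 0] = 1.0  # unit displacement of one landmark along x
            direct = bem.energy(V)
            rhs = np.concatenate([V[:, 0], np.zeros(4)])
            w = np.linalg.solve(L, rhs)[:k]
            independent = abs(float(w @ K @ w))
            assert direct == pytest.approx(independent, rel=1e-8, abs=1e-12)


class TestTangentFrames:
    def test_planar_cloud_spans_plane(self):
        rng = np.random.default_rng(3)
        coords = np.column_stack(
            [rng.uniform(0, 10, 20), rng.uniform(0, 10, 20), np.zeros(20)]
        )
        roles = (FIXED,) * 5 + (SEMILANDMARK,) * 15
        frames = mr.estimate_tangent_frames(coords, roles, neighbors=8)
        assert np.abs(frames.vectors[:, :, 2]).max() < 1e-9

    def test_orthonormal_by_construction(self, aligned_small):
        frames = mr.estimate_tangent_frames(
            aligned_small.aligned[0], aligned_small.roles
        )
        v = frames.vectors
        np.testing.assert_allclose(
            np.einsum("qta,qta->qt", v, v), 1.0, atol=1e-9
        )
        assert np.abs(np.einsum("qa,qa->q", v[:, 0], v[:, 1])).max() < 1e-9

    def test_sphere_patch_matches_analytic_tangents(self):
        # landmarks on a sphere: analytic tangent plane is orthogonal to
        # the radial direction
        rng = np.random.default_rng(4)
        R = 50.0
        theta = rng.uniform(0.6, 1.0, 80)
        phi = rng.uniform(0.3, 0.7, 80)
        pts = R * np.column_stack(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ]
        )
        roles = (FIXED,) * 7 + (SEMILANDMARK,) * 73
        frames = mr.estimate_tangent_frames(pts, roles, neighbors=8)
        normals = pts[frames.semilandmark_indices] / R
        angles = []
        for row in range(len(normals)):
            est_normal = np.cross(frames.vectors[row, 0], frames.vectors[row, 1])
            cosang = abs(float(est_normal @ normals[row]))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        assert np.median(angles) < 5.0

    def test_batch_matches_single(self, aligned_small):
        batch = _estimate_frames_batch(
            aligned_small.aligned[:4], aligned_small.roles, neighbors=8
        )
        for i in range(4):
            single = mr.estimate_tangent_frames(
                aligned_small.aligned[i], aligned_small.roles, neighbors=8
            )
            # same plane: spans agree up to in-plane rotation/sign
            for q in range(len(single.semilandmark_indices)):
                n1 = np.cross(single.vectors[q, 0], single.vectors[q, 1])
                n2 = np.cross(batch[i].vectors[q, 0], batch[i].vectors[q, 1])
                assert abs(abs(float(n1 @ n2)) - 1) < 1e-9


class TestSliding:
    def test_identical_shapes_do_not_move(self, template):
        rng = np.random.default_rng(5)
        from conftest import apply_similarity, random_similarity

        shapes = [
            apply_similarity(template, *random_similarity(rng)) for _ in range(5)
        ]
        ds = LandmarkDataset(
            tuple(
                LandmarkConfiguration(f"s{i}", c) for i, c in enumerate(shapes)
            )
        )
        res = mr.gpa(ds)
        slid = mr.slide_semilandmarks(res)
        assert np.abs(slid.aligned - res.aligned).max() < 1e-9

    def test_energy_trace_non_increasing(self, small_dataset):
        slid = mr.slide_semilandmarks(mr.gpa(small_dataset), iterations=5)
        trace = slid.sliding_energy
        assert trace is not None and len(trace) >= 1
        for a, b in zip(trace, trace[1:]):
            assert b <= a * (1 + 1e-9)

    def test_slide_step_leaves_fixed_landmarks_bit_identical(self, aligned_small):
        bem = mr.bending_energy_matrix(aligned_small.consensus)
        frames = mr.estimate_tangent_frames(
            aligned_small.aligned[0], aligned_small.roles
        )
        slid = _slide_one(
            aligned_small.aligned[0],
            aligned_small.consensus,
            bem.matrix,
            frames,
            ridge=1e-10,
        )
        fixed_rows = [i for i, r in enumerate(aligned_small.roles) if r == FIXED]
        assert (
            slid[fixed_rows] == aligned_small.aligned[0][fixed_rows]
        ).all()  # bit-identical
        semi_rows = [
            i for i, r in enumerate(aligned_small.roles) if r == SEMILANDMARK
        ]
        assert np.abs(slid[semi_rows] - aligned_small.aligned[0][semi_rows]).max() > 0

    def test_tangent_offset_fully_corrected(self, template):
        # two specimens: the template and a copy whose semilandmarks are
        # offset strictly inside their estimated tangent planes; one slide
        # iteration must remove essentially all bending energy
        roles = (FIXED,) * 7 + (SEMILANDMARK,) * 23
        frames = mr.estimate_tangent_frames(template, roles, neighbors=8)
        rng = np.random.default_rng(6)
        offset = template.copy()
        size = mr.centroid_size(template)
        amps = 1e-4 * size * rng.standard_normal((23, 2))
        offset[frames.semilandmark_indices] += np.einsum(
            "qt,qta->qa", amps, frames.vectors
        )
        ds = LandmarkDataset(
            (
                LandmarkConfiguration("ref", template),
                LandmarkConfiguration("off", offset),
            )
        )
        res = mr.gpa(ds)
        bem = mr.bending_energy_matrix(res.consensus)
        pre = sum(bem.energy(s - res.consensus) for s in res.aligned)
        slid = mr.slide_semilandmarks(res, iterations=1)
        assert slid.sliding_energy[0] < 1e-6 * pre

    def test_sliding_is_idempotent_at_convergence(self, small_dataset):
        first = mr.slide_semilandmarks(mr.gpa(small_dataset), iterations=6)
        again = mr.slide_semilandmarks(first, iterations=1)
        e_prev = first.sliding_energy[-1]
        e_next = again.sliding_energy[-1] if again.sliding_energy else e_prev
        assert abs(e_next - e_prev) < 1e-2 * e_prev
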