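"""Synthetic-data generator: template geometry, factor model, sampling."""

import numpy as np
import pytest

import morphorec as mr
from morphorec.errors import DatasetError, MorphorecError
from morphorec.io import FIXED
from morphorec.synthetic import (
    BODY_BLOCK_LANDMARKS,
    PROCESS_TIP_LANDMARKS,
    template_diameter,
)

from conftest import apply_similarity, random_similarity


class TestTemplate:
    def test_counts_and_roles(self, template):
        assert template.shape == (30, 3)
        roles = mr.LandmarkConfiguration("t", template).roles
        assert sum(r == FIXED for r in roles) == 7
        assert roles[:7] == (FIXED,) * 7

    def test_positive_centroid_size(self, template):
        assert mr.centroid_size(template) > 0

    def test_case_regions_are_spatial_clusters(self, template):
        def d(i, j):  # 1-based
            return np.linalg.norm(template[i - 1] - template[j - 1])

        assert d(16, 17) < d(16, 1)
        # each damage region is tighter than its distance to the others
        for region in [PROCESS_TIP_LANDMARKS, (4, 5, 7), BODY_BLOCK_LANDMARKS]:
            inside = max(
                d(i, j) for i in region for j in region if i != j
            )
            outside = min(
                d(i, j)
                for i in region
                for j in range(1, 31)
                if j not in region
            )
            assert inside < 2.5 * outside  # compact, contiguous blocks


class TestSpatialFactorModel:
    def test_long_length_scale_gives_translation_mode(self, template):
        L = mr.spatial_factor_model(template, m=3, length_scale=1e9)
        mode = L[0::3, 0]  # x-axis profile of the first factor
        mode = mode / np.linalg.norm(mode)
        uniform = np.ones_like(mode) / np.sqrt(len(mode))
        assert abs(float(mode @ uniform)) > 1 - 1e-6

    def test_short_length_scale_decorrelates(self, template):
        L = mr.spatial_factor_model(template, m=3, length_scale=1e-6)
        # kernel ~ identity: each eigenmode concentrates on one landmark
        profile = np.abs(L[0::3, 0])
        assert profile.max() > 0.99

    def test_m_too_large(self, template):
        with pytest.raises(MorphorecError):
            mr.spatial_factor_model(template, m=91, length_scale=10.0)

    def test_monte_carlo_covariance_matches_implied(self, template):
        L = mr.spatial_factor_model(
            template, m=6, length_scale=0.3 * template_diameter(template)
        )
        sd = 2.0 * 0.8 ** np.arange(6)
        model = mr.PopulationModel(
            mean_shape=template,
            factor_loadings=L,
            factor_sd=sd,
            noise_sd=0.1,
        )
        rng = np.random.default_rng(123)
        z = rng.standard_normal((20000, 6))
        draws = z @ (L * sd).T + 0.1 * rng.standard_normal((20000, 90))
        emp = np.cov(draws, rowvar=False)
        implied = model.implied_covariance()
        rel = np.linalg.norm(emp - implied) / np.linalg.norm(implied)
        assert rel < 0.05


class TestGenerateDataset:
    def test_degenerate_model_reproduces_mean(self, template):
        model = mr.PopulationModel(
            mean_shape=template,
            factor_loadings=np.eye(90)[:, :2],
            factor_sd=np.zeros(2),
            noise_sd=0.0,
        )
        ds = mr.generate_dataset(model, {"only": 5}, nuisance=False, seed=1)
        for c in ds:
            np.testing.assert_array_equal(c.coords, template)

    def test_seed_reproducibility(self, default_model):
        a = mr.generate_dataset(default_model, {"Italian": 10}, seed=5)
        b = mr.generate_dataset(default_model, {"Italian": 10}, seed=5)
        c = mr.generate_dataset(default_model, {"Italian": 10}, seed=6)
        np.testing.assert_array_equal(a.coords_array(), b.coords_array())
        assert not np.array_equal(a.coords_array(), c.coords_array())

    def test_unknown_population_rejected(self, default_model):
        with pytest.raises(DatasetError, match="Martian"):
            mr.generate_dataset(default_model, {"Martian": 5})

    def test_default_design_matches_study_sample(self, default_dataset):
        assert len(default_dataset) == 150
        pops = [c.population for c in default_dataset]
        assert pops.count("Italian") == 119
        assert pops.count("AfricanAmerican") == 20
        assert pops.count("Spanish") == 11

    def test_gpa_recovers_generating_mean(self, template):
        # noise-only model: the consensus should sit within the heuristic
        # noise bound 3 * noise_sd * sqrt(k) / sqrt(n) of the true mean
        cs = mr.centroid_size(template)
        noise_sd = 0.005 * cs
        model = mr.PopulationModel(
            mean_shape=template,
            factor_loadings=np.eye(90)[:, :2],
            factor_sd=np.zeros(2),
            noise_sd=noise_sd,
        )
        bound = 3 * (noise_sd / cs) * np.sqrt(30) / np.sqrt(150)
        for rep in range(10):
            ds = mr.generate_dataset(model, {"a": 75, "b": 75}, seed=100 + rep)
            res = mr.gpa(ds)
            assert mr.procrustes_distance(res.consensus, template) < bound

    def test_nuisance_invariance_end_to_end(self, default_model):
        # the same underlying shapes, with and without nuisance transforms,
        # give identical aligned inter-specimen distances after GPA
        clean = mr.generate_dataset(
            default_model, {"Italian": 25}, nuisance=False, seed=9
        )
        rng = np.random.default_rng(99)
        moved = np.stack(
            [apply_similarity(c.coords, *random_similarity(rng)) for c in clean]
        )
        g0, g1 = mr.gpa(clean.coords_array()), mr.gpa(moved)
        iu = np.triu_indices(len(clean), 1)
        d0 = np.linalg.norm(g0.aligned[iu[0]] - g0.aligned[iu[1]], axis=(1, 2))
        d1 = np.linalg.norm(g1.aligned[iu[0]] - g1.aligned[iu[1]], axis=(1, 2))
        assert np.abs(d0 - d1).max() < 1e-8

    def test_aligned_covariance_converges_to_implied(self, template):
        # at n=4000 the covariance of GPA-aligned shapes matches the
        # model's implied covariance projected onto the tangent space of
        # the mean (similarity directions removed), up to the unit-size
        # rescaling
        L = mr.spatial_factor_model(
            template, m=5, length_scale=0.3 * template_diameter(template)
        )
        cs = mr.centroid_size(template)
        model = mr.PopulationModel(
            mean_shape=template,
            factor_loadings=L,
            factor_sd=0.02 * cs * 0.8 ** np.arange(5),
            noise_sd=0.004 * cs,
        )
        ds = mr.generate_dataset(model, {"a": 4000}, nuisance=True, seed=77)
        res = mr.gpa(ds)
        # the aligned frame inherits the (random) orientation of the first
        # specimen; rotate everything onto the template frame before
        # comparing covariances
        mu0 = template - template.mean(axis=0)
        mu0 = mu0 / np.linalg.norm(mu0)
        R = mr.opa_superimpose(res.consensus, mu0, allow_scale=False).rotation
        flat = np.einsum("nka,ba->nkb", res.aligned, R).reshape(res.n, -1)
        emp = np.cov(flat, rowvar=False)
        # tangent projector at the unit-scaled mean
        mu = template - template.mean(axis=0)
        mu = (mu / np.linalg.norm(mu)).reshape(-1)
        basis = [np.tile(np.eye(3)[a], 30) / np.sqrt(30) for a in range(3)]
        basis.append(mu)
        for A in (
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]]),
            np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]]),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]]),
        ):
            v = (mu.reshape(30, 3) @ A.T).reshape(-1)
            basis.append(v / np.linalg.norm(v))
        Q = np.linalg.qr(np.array(basis).T)[0]
        P = np.eye(90) - Q @ Q.T
        implied = P @ (model.implied_covariance() / cs**2) @ P
        rel = np.linalg.norm(P @ emp @ P - implied) / np.linalg.norm(implied)
        assert rel < 0.15
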