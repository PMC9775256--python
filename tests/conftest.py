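"""Shared fixtures: synthetic datasets at the default study conditions and
small helpers used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import morphorec as mr


@pytest.fixture(scope="session")
def template():
    return mr.default_zygomatic_template()


@pytest.fixture(scope="session")
def default_model():
    return mr.default_population_model(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_model):
    """The full 150-specimen default study sample."""
    return mr.generate_dataset(default_model, seed=0)


@pytest.fixture(scope="session")
def small_dataset(default_model):
    """A 40-specimen single-population sample for cheaper tests."""
    return mr.generate_dataset(default_model, {"Italian": 40}, seed=3)


@pytest.fixture(scope="session")
def aligned_small(small_dataset):
    return mr.slide_semilandmarks(mr.gpa(small_dataset))


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """One full study run at the default design (3 cases x 30 targets)."""
    return mr.DamageStudy(default_dataset).run(seed=0)


def fake_gpa_result(shapes, ids=None):
    """Wrap raw (n, k, 3) shapes as an aligned reference without running
    GPA, for regression tests that need full control of the design."""
    shapes = np.asarray(shapes, dtype=float)
    consensus = shapes.mean(axis=0)
    consensus = consensus - consensus.mean(axis=0)
    consensus = consensus / np.linalg.norm(consensus)
    return mr.GPAResult(
        aligned=shapes,
        centroid_sizes=np.ones(len(shapes)),
        consensus=consensus,
        iterations=1,
        final_change=0.0,
        converged=True,
        specimen_ids=tuple(ids or (f"s{i}" for i in range(len(shapes)))),
    )


def random_similarity(rng, scale_range=(0.5, 2.0), translation_scale=100.0):
    """A random proper rotation, scale and translation."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    s = rng.uniform(*scale_range)
    t = translation_scale * rng.standard_normal(3)
    return Q, s, t


def apply_similarity(coords, Q, s, t):
    return s * coords @ Q.T + t


def brute_force_opa_residual(source, target, allow_scale=True, n_starts=24, seed=0):
    """Independent superimposition residual by direct minimization over
    rotation vectors (multi-start Nelder-Mead), never touching the SVD
    solution path."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    src = source - source.mean(axis=0)
    tgt = target - target.mean(axis=0)

    def residual(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        rotated = src @ R.T
        if allow_scale:
            s = max(float((rotated * tgt).sum()) / float((src**2).sum()), 0.0)
        else:
            s = 1.0
        return float(np.linalg.norm(s * rotated - tgt))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=rng).as_rotvec() for _ in range(n_starts)
    ]
    for x0 in starts:
        res = minimize(
            residual, x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        best = min(best, res.fun)
    return best
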