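"""Sliding of surface semilandmarks by thin-plate-spline bending energy.

Surface semilandmarks carry no point-wise homology; during alignment they
are allowed to move within their local tangent planes so as to minimize
the bending energy of the thin-plate-spline deformation from the consensus
to each specimen.  Because the package works from landmark clouds (no
meshes), tangent planes are estimated per specimen from the nearest
neighboring landmarks, and sliding is tangent-plane only, without
re-projection onto a surface.

The 3D TPS kernel is U(r) = r.  The bending-energy matrix is the upper
k x k block of the inverse of the bordered system [[K, Q], [Q^T, 0]] with
Q = [1 | p]; its sign convention is fixed so the quadratic form is
positive semidefinite, and affine displacement fields lie in its null
space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateShapeError, MorphorecError
from .io import SEMILANDMARK
from .procrustes import GPAResult, gpa


@dataclass(frozen=True)
class BendingEnergyMatrix:
    """PSD quadratic form measuring non-affine deformation of a reference."""

    reference_shape: np.ndarray  # (k, 3)
    matrix: np.ndarray  # (k, k), symmetric PSD

    def energy(self, displacement: np.ndarray) -> float:
        """Bending energy of a (k, 3) displacement field (summed over axes)."""
        v = np.asarray(displacement, dtype=float)
        return float(np.einsum("ka,kl,la->", v, self.matrix, v))


def bending_energy_matrix(reference: np.ndarray) -> BendingEnergyMatrix:
    """Build the TPS bending-energy matrix on a 3D reference configuration."""
    p = np.asarray(reference, dtype=float)
    k = p.shape[0]
    if p.ndim != 2 or p.shape[1] != 3 or k < 5:
        raise DegenerateShapeError(
            f"reference must be (k>=5, 3), got {p.shape}"
        )
    dist = cdist(p, p)
    close = np.argwhere((dist < 1e-9) & ~np.eye(k, dtype=bool))
    if len(close):
        i, j = close[0]
        raise DegenerateShapeError(
            f"duplicate landmarks {i + 1} and {j + 1}: TPS system singular"
        )
    K = dist  # 3D kernel U(r) = r
    Q = np.hstack([np.ones((k, 1)), p])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError(f"singular TPS system: {exc}") from None
    B = Linv[:k, :k]
    B = 0.5 * (B + B.T)
    eigvals = np.linalg.eigvalsh(B)
    # with U(r) = r the inverse block is negative semidefinite; flip sign so
    # the energy form is PSD
    if abs(eigvals[0]) > abs(eigvals[-1]):
        B = -B
        eigvals = -eigvals[::-1]
    scale = max(abs(eigvals[-1]), 1e-300)
    if eigvals[0] < -1e-9 * scale:
        raise MorphorecError(
            f"bending-energy form not PSD (min eigenvalue {eigvals[0]:.3e})"
        )
    return BendingEnergyMatrix(reference_shape=p, matrix=B)


@dataclass(frozen=True)
class TangentFrames:
    """Two orthonormal tangent vectors per surface semilandmark."""

    semilandmark_indices: np.ndarray  # 0-based positions within the configuration
    vectors: np.ndarray  # (n_semi, 2, 3), rows orthonormal


def estimate_tangent_frames(
    coords: np.ndarray,
    roles: tuple[str, ...],
    neighbors: int = 8,
) -> TangentFrames:
    """Estimate local tangent planes from the landmark cloud.

    For each surface semilandmark, a plane is fitted (total least squares
    through the neighborhood centroid) to the landmark itself plus its
    ``neighbors`` nearest landmarks; the two leading principal directions
    span the tangent plane.  Collinear neighborhoods fall back to a larger
    neighborhood before failing.
    """
    coords = np.asarray(coords, dtype=float)
    k = coords.shape[0]
    if neighbors < 4:
        raise ValueError("neighbors must be >= 4")
    semi_idx = np.array([i for i, r in enumerate(roles) if r == SEMILANDMARK])
    if semi_idx.size == 0:
        raise MorphorecError("no surface semilandmarks in configuration")
    order = np.argsort(cdist(coords[semi_idx], coords), axis=1)
    vectors = np.empty((semi_idx.size, 2, 3))
    for row, j in enumerate(semi_idx):
        for m in (neighbors, min(2 * neighbors, k - 1)):
            hood = coords[order[row, : m + 1]]  # nearest m others + the point
            centered = hood - hood.mean(axis=0)
            _, s, Vt = np.linalg.svd(centered, full_matrices=False)
            if s[1] > 1e-9 * max(s[0], 1.0):
                vectors[row] = Vt[:2]
                break
        else:
            raise DegenerateShapeError(
                f"collinear neighborhood around landmark {j + 1}; cannot "
                "estimate a tangent plane"
            )
    return TangentFrames(semilandmark_indices=semi_idx, vectors=vectors)


def _estimate_frames_batch(
    shapes: np.ndarray, roles: tuple[str, ...], neighbors: int
) -> list[TangentFrames]:
    """Vectorized tangent-frame estimation for a stack of (n, k, 3) shapes.

    Equivalent to calling :func:`estimate_tangent_frames` per specimen;
    specimens whose first-pass neighborhood is degenerate fall back to the
    per-specimen routine (which enlarges the neighborhood).
    """
    n, k, _ = shapes.shape
    semi_idx = np.array([i for i, r in enumerate(roles) if r == SEMILANDMARK])
    q = semi_idx.size
    diff = shapes[:, semi_idx, None, :] - shapes[:, None, :, :]
    d2 = np.einsum("nqka,nqka->nqk", diff, diff)
    order = np.argsort(d2, axis=2)[:, :, : neighbors + 1]  # self + m nearest
    hoods = np.take_along_axis(
        shapes[:, None, :, :].repeat(q, axis=1), order[..., None], axis=2
    )
    centered = hoods - hoods.mean(axis=2, keepdims=True)
    _, s, Vt = np.linalg.svd(centered.reshape(n * q, neighbors + 1, 3), full_matrices=False)
    ok = (s[:, 1] > 1e-9 * np.maximum(s[:, 0], 1.0)).reshape(n, q)
    vectors = Vt[:, :2, :].reshape(n, q, 2, 3)
    frames = []
    for i in range(n):
        if ok[i].all():
            frames.append(TangentFrames(semi_idx, vectors[i]))
        else:
            frames.append(estimate_tangent_frames(shapes[i], roles, neighbors))
    return frames


def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    B: np.ndarray,
    frames: TangentFrames,
    ridge: float,
) -> np.ndarray:
    """Minimize bending energy over tangent-plane offsets of one specimen.

    Solves t = -(U^T Bt U)^{-1} U^T Bt y for the stacked tangent
    coefficients, where Bt applies B per coordinate axis and y is the
    displacement from the consensus.  The structure of U (one 3-vector per
    semilandmark and tangent direction) gives the closed forms
    ``M[(j,t),(l,s)] = B[j,l] (u_jt . u_ls)`` and
    ``rhs[(j,t)] = u_jt . (B y)[j]``.
    """
    idx = frames.semilandmark_indices
    U = frames.vectors  # (q, 2, 3)
    y = shape - consensus
    G = B @ y  # (k, 3)
    rhs = -np.einsum("qta,qa->qt", U, G[idx]).reshape(-1)
    dots = np.einsum("qta,lsa->qtls", U, U)
    M = (B[np.ix_(idx, idx)][:, None, :, None] * dots).reshape(
        2 * len(idx), 2 * len(idx)
    )
    try:
        t = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"singular tangent system; ridge-regularizing with eps={ridge}",
            stacklevel=2,
        )
        t = np.linalg.solve(M + ridge * np.eye(M.shape[0]), rhs)
    correction = np.einsum("qt,qta->qa", t.reshape(-1, 2), U)
    slid = shape.copy()
    slid[idx] += correction
    return slid


def slide_semilandmarks(
    gpa_result: GPAResult,
    iterations: int = 3,
    neighbors: int = 8,
    ridge: float = 1e-10,
    energy_tol: float = 1e-6,
    gpa_tol: float = 1e-10,
) -> GPAResult:
    """Slide surface semilandmarks to minimize total bending energy.

    Each iteration: (1) build the bending-energy matrix on the current
    consensus; (2) slide every specimen within its tangent planes (exact
    minimizer of its quadratic energy, so the per-iteration slide never
    increases energy); (3) re-run GPA.  Tangent frames are estimated per
    iteration on each specimen's own aligned coordinates (realignment
    rotates specimens, so frames must follow).  Because the consensus (and
    with it the energy form) is recomputed between iterations, a safeguard
    reverts and stops if a full iteration would raise total energy, keeping
    the recorded energy trace non-increasing.  Stops early when relative
    energy change falls below ``energy_tol``.

    Fixed landmarks are never displaced by the slide step itself; the
    closing GPA applies only common similarity transforms.
    """
    if not gpa_result.roles:
        raise MorphorecError("GPA result carries no landmark roles; cannot slide")
    if SEMILANDMARK not in gpa_result.roles:
        return gpa_result
    current = gpa_result
    trace: list[float] = []
    for _ in range(iterations):
        frames = _estimate_frames_batch(current.aligned, current.roles, neighbors)
        bem = bending_energy_matrix(current.consensus)
        slid = np.stack(
            [
                _slide_one(shape, current.consensus, bem.matrix, fr, ridge)
                for shape, fr in zip(current.aligned, frames)
            ]
        )
        energy = float(
            sum(bem.energy(s - current.consensus) for s in slid)
        )
        if trace and energy > trace[-1] * (1 + 1e-12):
            break  # revert: keep `current` from the previous iteration
        realigned = gpa(slid, tol=gpa_tol)
        current = replace(
            realigned,
            centroid_sizes=gpa_result.centroid_sizes,
            specimen_ids=gpa_result.specimen_ids,
            roles=gpa_result.roles,
            labels=gpa_result.labels,
        )
        prev = trace[-1] if trace else None
        trace.append(energy)
        if prev is not None and abs(prev - energy) <= energy_tol * max(prev, 1e-300):
            break
    return replace(current, sliding_energy=tuple(trace))
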