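"""Shape-space machinery: centroid size, ordinary and generalized
Procrustes analysis, and Procrustes distance.

GPA standardizes location (centering), scale (unit centroid size) and
rotation (iterative least-squares alignment onto a consensus).  Rotations
are proper (determinant +1): reflections are never applied here, antimeres
are handled by explicit reflection at the I/O stage.

The distance used throughout reporting is the *partial* Procrustes
distance: both configurations scaled to unit centroid size, optimally
rotated, root-sum-of-squares of the residual.  A ``common_space`` mode
skips the pairwise fit and measures already-aligned coordinates directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceWarning, DegenerateShapeError, DegenerateShapeWarning
from .io import LandmarkDataset


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark deviations from the centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise DegenerateShapeError("centroid_size needs at least 2 landmarks")
    if not np.isfinite(coords).all():
        raise DegenerateShapeError("non-finite coordinates")
    size = float(np.linalg.norm(coords - coords.mean(axis=0)))
    if size == 0.0:
        warnings.warn(
            "all landmarks coincide; centroid size is 0",
            DegenerateShapeWarning,
            stacklevel=2,
        )
    return size


def _check_rank(centered: np.ndarray, name: str) -> None:
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size < 2 or s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateShapeError(
            f"configuration {name!r} is degenerate (rank < 2); cannot "
            "superimpose"
        )


@dataclass(frozen=True)
class OPAResult:
    """Least-squares superimposition of source onto target."""

    transformed: np.ndarray  # source after similarity transform
    rotation: np.ndarray  # 3x3 proper rotation R
    scale: float
    translation: np.ndarray  # 3-vector t: x -> scale * x @ R.T + t
    residual: float  # sqrt(sum of squared landmark residuals)


def _optimal_rotation(source_c: np.ndarray, target_c: np.ndarray) -> tuple[np.ndarray, float]:
    """Proper rotation R maximizing trace(R H), H = source_c.T @ target_c.

    Returns (R, trace(R H)); applied as ``source_c @ R.T``.
    """
    H = source_c.T @ target_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.array([1.0, 1.0, d])
    R = (Vt.T * D) @ U.T
    return R, float((S * D).sum())


def opa_superimpose(
    source: np.ndarray,
    target: np.ndarray,
    allow_scale: bool = True,
    source_name: str = "source",
    target_name: str = "target",
) -> OPAResult:
    """Least-squares rigid (plus optional scale) superimposition via SVD.

    Minimizes ``sum ||s * R source_i + t - target_i||^2`` over proper
    rotations R (no reflection), translation t and, if ``allow_scale``,
    scale s > 0.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(
            f"source and target must both be (k, 3); got {source.shape} and "
            f"{target.shape}"
        )
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    src_c = source - mu_s
    tgt_c = target - mu_t
    _check_rank(src_c, source_name)
    _check_rank(tgt_c, target_name)
    R, trace = _optimal_rotation(src_c, tgt_c)
    if allow_scale:
        scale = trace / float((src_c**2).sum())
    else:
        scale = 1.0
    transformed_c = scale * (src_c @ R.T)
    translation = mu_t - scale * (mu_s @ R.T)
    transformed = transformed_c + mu_t
    residual = float(np.linalg.norm(transformed_c - tgt_c))
    return OPAResult(
        transformed=transformed,
        rotation=R,
        scale=float(scale),
        translation=translation,
        residual=residual,
    )


@dataclass(frozen=True)
class GPAResult:
    """Generalized Procrustes alignment of a sample of configurations.

    ``aligned`` holds unit-centroid-size, centered, rotated shapes;
    ``consensus`` is their renormalized coordinate-wise mean; original
    scales are kept in ``centroid_sizes``.
    """

    aligned: np.ndarray  # (n, k, 3)
    consensus: np.ndarray  # (k, 3), unit centroid size
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    final_change: float
    converged: bool
    specimen_ids: tuple[str, ...] = ()
    roles: tuple[str, ...] = ()
    labels: tuple[str, ...] = ()
    sliding_energy: tuple[float, ...] | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def aligned_flat(self) -> np.ndarray:
        """Aligned shapes flattened to (n, 3k), row-major per landmark."""
        return self.aligned.reshape(self.n, -1)


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size == 0.0:
        raise DegenerateShapeError("degenerate configuration: zero centroid size")
    return centered / size, size


def _rotate_all_onto(shapes: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Batched rotation-only OPA of unit-size centered shapes onto consensus."""
    H = np.einsum("nka,kb->nab", shapes, consensus)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nab,nbc->nac", np.transpose(Vt, (0, 2, 1)), np.transpose(U, (0, 2, 1))))
    D = np.ones((shapes.shape[0], 3))
    D[:, 2] = np.sign(det)
    R = np.einsum("nab,nb,ncb->nac", np.transpose(Vt, (0, 2, 1)), D, U)
    return np.einsum("nka,nba->nkb", shapes, R)


def gpa(
    data: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes analysis.

    All configurations are centered and scaled to unit centroid size, then
    iteratively rotated onto the running consensus (initialized as the
    first specimen) until the consensus moves by less than ``tol`` in
    root-sum-of-squares, or ``max_iter`` is reached (warned, flagged).
    """
    if isinstance(data, LandmarkDataset):
        arr = data.coords_array()
        ids = data.specimen_ids
        roles = data.roles
        labels = data.landmark_labels
    else:
        arr = np.asarray(data, dtype=float)
        ids, roles, labels = (), (), ()
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (n, k, 3) array, got {arr.shape}")
    n = arr.shape[0]
    if n < 2:
        raise DegenerateShapeError("GPA needs at least 2 configurations")
    shapes = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        try:
            shapes[i], sizes[i] = _center_and_scale(arr[i])
        except DegenerateShapeError as exc:
            name = ids[i] if ids else str(i)
            raise DegenerateShapeError(f"specimen {name!r}: {exc}") from None
    consensus = shapes[0].copy()
    iterations = 0
    change = np.inf
    converged = False
    for iterations in range(1, max_iter + 1):
        shapes = _rotate_all_onto(shapes, consensus)
        new_consensus, _ = _center_and_scale(shapes.mean(axis=0))
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last change {change:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    # final rotation pass so aligned shapes match the reported consensus
    shapes = _rotate_all_onto(shapes, consensus)
    return GPAResult(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        final_change=change,
        converged=converged,
        specimen_ids=ids,
        roles=roles,
        labels=labels,
    )


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, mode: str = "pairwise_opa"
) -> float:
    """Partial Procrustes distance between two configurations.

    ``pairwise_opa``: both are centered, scaled to unit centroid size, and
    optimally rotated (no re-scaling in the fit); the root-sum-of-squares
    residual is returned.  ``common_space``: plain root-sum-of-squares of
    already-aligned coordinates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mode == "common_space":
        return float(np.linalg.norm(a - b))
    if mode != "pairwise_opa":
        raise ValueError(f"unknown mode {mode!r}")
    ua, _ = _center_and_scale(a)
    ub, _ = _center_and_scale(b)
    _check_rank(ua, "a")
    _check_rank(ub, "b")
    R, _ = _optimal_rotation(ua, ub)
    return float(np.linalg.norm(ua @ R.T - ub))
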