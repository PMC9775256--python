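"""Regression-based imputation of missing landmarks (the RM method).

Each missing landmark's coordinates are regressed, by ordinary least
squares with intercept, on the coordinates of all present landmarks across
a complete, Procrustes-aligned (and slid) reference sample.  A damaged
specimen is completed by superimposing its present landmarks onto the
matching subset of the reference consensus (full similarity fit — the
specimen's size is nuisance), feeding the aligned present coordinates to
the regression, and inserting the predictions.

Exposed statsmodels-style: :class:`MissingLandmarkModel` is built from a
reference :class:`~morphorec.procrustes.GPAResult` and a missing-landmark
set; ``fit()`` returns a :class:`MissingLandmarkResults` carrying the
coefficients, fit diagnostics and ``impute``/``summary`` methods.  The
functional aliases :func:`fit_rm` and :func:`impute` wrap them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .errors import DegenerateShapeError, MorphorecError
from .io import LandmarkConfiguration
from .procrustes import GPAResult, opa_superimpose

_MIN_REFERENCE = 10  # documented floor on reference sample size


def _validate_indices(missing: Iterable[int], k: int) -> tuple[int, ...]:
    idx = tuple(sorted(set(int(i) for i in missing)))
    if not idx:
        raise MorphorecError("missing-landmark set is empty")
    if idx[0] < 1 or idx[-1] > k:
        raise MorphorecError(f"missing indices must lie in 1..{k}, got {idx}")
    if len(idx) >= k - 2:
        raise MorphorecError(
            "missing set leaves fewer than 3 present landmarks"
        )
    return idx


@dataclass(frozen=True)
class DamagedConfiguration:
    """A specimen with some landmark coordinates unknown.

    ``base`` keeps the full coordinate block; rows listed in
    ``missing_indices`` (1-based) are treated as unknown and ignored.
    """

    base: LandmarkConfiguration
    missing_indices: tuple[int, ...]

    def __post_init__(self):
        idx = _validate_indices(self.missing_indices, self.base.k)
        object.__setattr__(self, "missing_indices", idx)
        present = self.present_coords()
        centered = present - present.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-12 * max(s[0], 1.0):
            raise DegenerateShapeError(
                f"specimen {self.base.specimen_id!r}: present landmarks are "
                "collinear; superimposition impossible"
            )

    @property
    def present_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i in range(1, self.base.k + 1) if i not in self.missing_indices
        )

    def present_coords(self) -> np.ndarray:
        idx = np.array(self.present_indices) - 1
        return self.base.coords[idx]


@dataclass(frozen=True)
class AlignmentRecord:
    """Similarity transform mapping original specimen space to consensus
    space: ``x_aligned = scale * x @ R.T + translation``."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * coords @ self.rotation.T + self.translation

    def invert(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.translation) @ self.rotation / self.scale


class MissingLandmarkModel:
    """OLS model of missing-landmark coordinates given present ones.

    Parameters
    ----------
    reference : GPAResult
        Aligned (and normally slid) complete reference sample.
    missing_indices : iterable of int
        1-based landmarks to be treated as missing.
    pca_variance, max_condition :
        When the design would have at least as many columns as reference
        specimens, or its condition number exceeds ``max_condition``,
        predictors are first reduced to principal-component scores
        retaining ``min(n - 2, components explaining pca_variance)``.
    """

    def __init__(
        self,
        reference: GPAResult,
        missing_indices: Iterable[int],
        pca_variance: float = 0.99,
        max_condition: float = 100.0,
    ):
        self.reference = reference
        self.missing_indices = _validate_indices(missing_indices, reference.k)
        self.present_indices = tuple(
            i for i in range(1, reference.k + 1) if i not in self.missing_indices
        )
        self.pca_variance = pca_variance
        self.max_condition = max_condition
        if reference.n < _MIN_REFERENCE:
            raise MorphorecError(
                f"reference sample too small: n={reference.n} < {_MIN_REFERENCE}"
            )

    def _coord_cols(self, indices: tuple[int, ...]) -> np.ndarray:
        idx = np.array(indices) - 1
        return (3 * idx[:, None] + np.arange(3)).reshape(-1)

    def fit(self) -> "MissingLandmarkResults":
        flat = self.reference.aligned_flat()
        X = flat[:, self._coord_cols(self.present_indices)]
        Y = flat[:, self._coord_cols(self.missing_indices)]
        n, p = X.shape
        x_mean = X.mean(axis=0)
        Xc = X - x_mean
        s, Vt = np.linalg.svd(Xc, full_matrices=False)[1:]
        # Procrustes alignment (and sliding) leaves the predictor block
        # nearly degenerate along the linearized centering/rotation/scale
        # constraints — with exactly two landmarks missing one dependency
        # is even exact.  OLS coefficients along such directions are
        # unstable and are excited by the subset-aligned damaged specimen,
        # so predictors are reduced to principal-component scores whenever
        # the design is wide (p + 1 >= n) or ill-conditioned.
        # tolerance floored at unit scale: aligned shapes are unit-size, so
        # spectra entirely below ~1e-13 mean a (numerically) constant
        # reference and an intercept-only model
        tol = max(n, p) * np.finfo(float).eps * max(s[0], 1.0)
        rank = int((s > tol).sum())
        components = None
        reduce = p + 1 >= n or rank < p or s[-1] < s[0] / self.max_condition
        if reduce:
            if rank == 0:  # zero-variance reference: intercept-only model
                n_components = 0
            else:
                frac = np.cumsum(s**2) / (s**2).sum()
                by_variance = int(np.searchsorted(frac, self.pca_variance) + 1)
                n_components = min(n - 2, by_variance, rank)
            components = Vt[:n_components]
            Z = Xc @ components.T
        else:
            n_components = 0
            Z = Xc
        design = np.column_stack([np.ones(n), Z])
        coef, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
        if rank < design.shape[1]:
            raise MorphorecError(
                f"rank-deficient regression design (rank {rank} < "
                f"{design.shape[1]}) even after predictor reduction"
            )
        fitted = design @ coef
        resid = Y - fitted
        dof = max(n - design.shape[1], 1)
        resid_sd = np.sqrt((resid**2).sum(axis=0) / dof)
        ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1 - (resid**2).sum(axis=0) / ss_tot, 1.0)
        return MissingLandmarkResults(
            model=self,
            intercept=coef[0],
            coefficients=coef[1:],
            predictor_mean=x_mean,
            components=components,
            predictor_reduction=(
                f"pca({n_components})" if components is not None else "none"
            ),
            residual_sd=resid_sd,
            r_squared=np.asarray(r2, dtype=float),
        )


@dataclass(frozen=True)
class MissingLandmarkResults:
    """Fitted RM regression: linear map from present to missing coordinates."""

    model: MissingLandmarkModel
    intercept: np.ndarray  # (3*k_missing,)
    coefficients: np.ndarray  # (p_eff, 3*k_missing)
    predictor_mean: np.ndarray  # (3*k_present,)
    components: np.ndarray | None  # (n_components, 3*k_present) or None
    predictor_reduction: str
    residual_sd: np.ndarray  # per missing coordinate
    r_squared: np.ndarray  # per missing coordinate

    @property
    def reference_consensus(self) -> np.ndarray:
        return self.model.reference.consensus

    @property
    def missing_indices(self) -> tuple[int, ...]:
        return self.model.missing_indices

    @property
    def present_indices(self) -> tuple[int, ...]:
        return self.model.present_indices

    def predict_from_present(self, present_flat: np.ndarray) -> np.ndarray:
        """Predict flattened missing coordinates from aligned present ones."""
        xc = np.atleast_2d(present_flat) - self.predictor_mean
        z = xc @ self.components.T if self.components is not None else xc
        out = self.intercept + z @ self.coefficients
        return out[0] if np.ndim(present_flat) == 1 else out

    def impute(
        self, damaged: DamagedConfiguration
    ) -> tuple[LandmarkConfiguration, AlignmentRecord]:
        """Complete a damaged specimen.

        Returns the completed configuration in reference-consensus space
        together with the similarity transform used, so the completion can
        be mapped back to original specimen space via
        ``AlignmentRecord.invert``.
        """
        if damaged.missing_indices != self.missing_indices:
            raise MorphorecError(
                f"damaged specimen misses {damaged.missing_indices}, model "
                f"was fitted for {self.missing_indices}"
            )
        present_idx0 = np.array(self.present_indices) - 1
        missing_idx0 = np.array(self.missing_indices) - 1
        target = self.reference_consensus[present_idx0]
        fit = opa_superimpose(
            damaged.present_coords(),
            target,
            allow_scale=True,
            source_name=damaged.base.specimen_id,
            target_name="reference consensus (present subset)",
        )
        record = AlignmentRecord(
            rotation=fit.rotation, scale=fit.scale, translation=fit.translation
        )
        predicted = self.predict_from_present(fit.transformed.reshape(-1))
        completed = np.empty((self.model.reference.k, 3))
        completed[present_idx0] = fit.transformed
        completed[missing_idx0] = predicted.reshape(-1, 3)
        return (
            replace(damaged.base, coords=completed),
            record,
        )

    def summary(self) -> str:
        lines = [
            "Missing-landmark regression (RM)",
            f"  reference sample size : {self.model.reference.n}",
            f"  missing landmarks     : {list(self.missing_indices)}",
            f"  present landmarks     : {len(self.present_indices)}",
            f"  predictor reduction   : {self.predictor_reduction}",
            f"  residual sd (mean)    : {self.residual_sd.mean():.6g}",
            f"  R^2 (min/mean/max)    : {self.r_squared.min():.4f} / "
            f"{self.r_squared.mean():.4f} / {self.r_squared.max():.4f}",
        ]
        return "\n".join(lines)


def fit_rm(
    reference: GPAResult, missing_indices: Iterable[int], **kwargs
) -> MissingLandmarkResults:
    """Fit the RM regression on an aligned reference sample."""
    return MissingLandmarkModel(reference, missing_indices, **kwargs).fit()


def impute(
    results: MissingLandmarkResults, damaged: DamagedConfiguration
) -> tuple[LandmarkConfiguration, AlignmentRecord]:
    """Complete a damaged configuration with a fitted RM model."""
    return results.impute(damaged)
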