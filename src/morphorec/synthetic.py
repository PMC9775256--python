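"""Synthetic zygomatic landmark datasets.

Generates 3D landmark samples with the statistical structure the
reconstruction analysis assumes: a common mean configuration, low-rank
spatially smooth covariance (nearby landmarks co-vary, so regressing one
landmark on the rest has genuine signal), small population-level mean
offsets, per-specimen rigid-motion + scale nuisance, and iid digitization
noise.

The default template is a deterministic 30-point layout on a smooth curved
quadrilateral patch mimicking the zygomatic scheme: fixed landmarks 1-7 at
suture corners (1,2 on the temporal process; 4,5,7 around the orbit) and
23 surface semilandmarks (8-30), with 16-21 a tight block on the body of
the bone.

The default covariance mixes three components, mirroring how regional
anatomy varies:

* six smooth global eigenmodes of a distance-decay kernel on the template
  (overall shape variation; recoverable from any large present subset),
* three local modes on the process tip (landmarks 1-2), emulating the
  population-variable projection of the zygomatic process,
* three larger local modes on the body block (landmarks 16-21), emulating
  the variable masseter-attachment surface.

Local modes load on single regions only, so their variance is genuinely
unpredictable when that whole region is missing; this is what makes
reconstruction error depend on damage location and extent rather than on
landmark count alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DatasetError, MorphorecError
from .io import (
    FIXED,
    SEMILANDMARK,
    LandmarkConfiguration,
    LandmarkDataset,
    default_labels,
    default_roles,
)
from .procrustes import centroid_size

# (u, v) layout of the 30 landmarks on the unit patch; order is landmark 1..30
_TEMPLATE_UV = np.array(
    [
        # fixed landmarks 1-7
        (0.06, 0.10),  # 1 inferior zygotemporale   (process tip)
        (0.10, 0.22),  # 2 superior zygotemporale   (process tip)
        (0.30, 0.88),  # 3 frontomalare temporale
        (0.52, 0.93),  # 4 frontomalare orbitale    (orbit)
        (0.60, 0.86),  # 5 zygomaxillare orbitale   (orbit)
        (0.85, 0.18),  # 6 inferior zygomaxillare
        (0.56, 0.80),  # 7 inferior zygosphenoid    (orbit)
        # surface semilandmarks 8-30
        (0.18, 0.14),  # 8
        (0.20, 0.34),  # 9
        (0.30, 0.24),  # 10
        (0.32, 0.44),  # 11
        (0.26, 0.60),  # 12
        (0.38, 0.70),  # 13
        (0.52, 0.68),  # 14
        (0.66, 0.66),  # 15
        (0.44, 0.46),  # 16  body block
        (0.52, 0.46),  # 17
        (0.60, 0.46),  # 18
        (0.44, 0.56),  # 19
        (0.52, 0.56),  # 20
        (0.60, 0.56),  # 21
        (0.74, 0.54),  # 22
        (0.80, 0.40),  # 23
        (0.72, 0.30),  # 24
        (0.58, 0.28),  # 25
        (0.44, 0.30),  # 26
        (0.58, 0.14),  # 27
        (0.72, 0.14),  # 28
        (0.86, 0.40),  # 29
        (0.88, 0.62),  # 30
    ]
)

#: Landmarks (1-based) carrying the local variance modes of the default model.
PROCESS_TIP_LANDMARKS = (1, 2)
BODY_BLOCK_LANDMARKS = (16, 17, 18, 19, 20, 21)

_PATCH_SIZE_MM = 50.0
_PATCH_DOME_MM = 12.0


def default_zygomatic_template() -> np.ndarray:
    """Deterministic 30-point template on a smooth curved patch (mm units)."""
    u, v = _TEMPLATE_UV[:, 0], _TEMPLATE_UV[:, 1]
    x = _PATCH_SIZE_MM * u
    y = _PATCH_SIZE_MM * v
    z = _PATCH_DOME_MM * np.sin(np.pi * u) * np.sin(np.pi * v)
    return np.column_stack([x, y, z])


def template_diameter(template: np.ndarray) -> float:
    """Maximum inter-landmark distance."""
    return float(cdist(template, template).max())


def spatial_factor_model(
    template: np.ndarray, m: int, length_scale: float
) -> np.ndarray:
    """Smooth spatial factor loadings from a distance-decay kernel.

    Builds the kernel ``exp(-d^2 / length_scale^2)`` on the template,
    takes its leading eigenvectors, and assigns them cyclically to the
    x/y/z axes: factor j displaces all landmarks along axis ``j % 3`` with
    the spatial profile of eigenvector ``j // 3``.  Columns are unit-norm,
    so a factor's standard deviation is the norm of the displacement field
    it generates.  Neighboring landmarks therefore always co-displace.
    """
    template = np.asarray(template, dtype=float)
    k = template.shape[0]
    if m < 1 or m > 3 * k:
        raise MorphorecError(f"m must be in 1..{3 * k}, got {m}")
    if length_scale <= 0:
        raise MorphorecError("length_scale must be positive")
    d = cdist(template, template)
    kernel = np.exp(-((d / length_scale) ** 2))
    eigvals, eigvecs = np.linalg.eigh(kernel)
    eigvecs = eigvecs[:, ::-1]  # descending
    loadings = np.zeros((3 * k, m))
    for j in range(m):
        mode = eigvecs[:, j // 3]
        # deterministic sign: largest-magnitude entry positive
        mode = mode * np.sign(mode[np.argmax(np.abs(mode))])
        loadings[j % 3 :: 3, j] = mode
    return loadings


def regional_displacement_modes(
    k: int, landmarks: tuple[int, ...]
) -> np.ndarray:
    """Three unit-norm loading columns displacing a landmark region rigidly
    along x, y and z (landmark indices 1-based)."""
    idx = np.asarray(landmarks, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= k:
        raise MorphorecError(f"landmark indices out of range 1..{k}")
    cols = np.zeros((3 * k, 3))
    w = 1.0 / np.sqrt(len(idx))
    for axis in range(3):
        cols[3 * idx + axis, axis] = w
    return cols


@dataclass(frozen=True)
class PopulationModel:
    """Generative model for one landmark scheme across named populations.

    A specimen of population p is drawn as::

        shape = mean_shape + offset_p + loadings @ (factor_sd * z) + noise

    (flattened k*3 coordinates, z standard normal, noise iid
    N(0, noise_sd^2) per coordinate), then optionally hit with a uniform
    random rotation, a translation, and a lognormal scale
    exp(N(0, size_log_sd^2)).
    """

    mean_shape: np.ndarray  # (k, 3)
    factor_loadings: np.ndarray  # (3k, m), unit-norm columns
    factor_sd: np.ndarray  # (m,)
    noise_sd: float
    population_offsets: Mapping[str, np.ndarray] = field(default_factory=dict)
    size_log_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        mean = np.asarray(self.mean_shape, dtype=float)
        L = np.asarray(self.factor_loadings, dtype=float)
        sd = np.asarray(self.factor_sd, dtype=float)
        k = mean.shape[0]
        if mean.ndim != 2 or mean.shape[1] != 3:
            raise DatasetError(f"mean_shape must be (k, 3), got {mean.shape}")
        if L.shape[0] != 3 * k or L.ndim != 2:
            raise DatasetError(
                f"factor_loadings must be ({3 * k}, m), got {L.shape}"
            )
        if L.shape[1] < 1:
            raise DatasetError("need at least one factor")
        norms = np.linalg.norm(L, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise DatasetError("factor_loadings columns must be unit-norm")
        if sd.shape != (L.shape[1],) or (sd < 0).any():
            raise DatasetError("factor_sd must be nonnegative, one per factor")
        if self.noise_sd < 0:
            raise DatasetError("noise_sd must be >= 0")
        cs = centroid_size(mean)
        offsets = {}
        for name, off in self.population_offsets.items():
            off = np.asarray(off, dtype=float).reshape(-1)
            if off.shape != (3 * k,):
                raise DatasetError(
                    f"offset for {name!r} must have {3 * k} entries"
                )
            if np.linalg.norm(off) >= 0.2 * cs:
                raise DatasetError(
                    f"offset for {name!r} is not small (norm >= 20% of mean "
                    "centroid size)"
                )
            offsets[name] = off
        object.__setattr__(self, "mean_shape", mean)
        object.__setattr__(self, "factor_loadings", L)
        object.__setattr__(self, "factor_sd", sd)
        object.__setattr__(self, "population_offsets", offsets)

    @property
    def k(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def n_factors(self) -> int:
        return self.factor_loadings.shape[1]

    def implied_covariance(self) -> np.ndarray:
        """Implied (3k, 3k) shape covariance L diag(sd^2) L^T + noise_sd^2 I."""
        L = self.factor_loadings
        return (L * self.factor_sd**2) @ L.T + self.noise_sd**2 * np.eye(
            L.shape[0]
        )


#: Sample composition of the default study design (150 specimens).
DEFAULT_SAMPLE = {"Italian": 119, "AfricanAmerican": 20, "Spanish": 11}


def default_population_model(seed: int = 0) -> PopulationModel:
    """The default zygomatic generative model.

    Scales are set relative to the template centroid size CS:
    digitization noise 0.5% CS per coordinate; six global modes with
    geometrically declining sd (ratio 0.75) from 5.5% CS at kernel length
    scale 0.3 x template diameter; process-tip modes at 1x noise sd and
    body modes at 3x noise sd (see docs for the variance calculus);
    population offsets ~2% CS along the leading smooth modes; 5% lognormal
    size dispersion.
    """
    template = default_zygomatic_template()
    cs = centroid_size(template)
    noise_sd = 0.005 * cs
    global_loadings = spatial_factor_model(
        template, m=6, length_scale=0.3 * template_diameter(template)
    )
    global_sd = 0.055 * cs * 0.75 ** np.arange(6)
    tip = regional_displacement_modes(30, PROCESS_TIP_LANDMARKS)
    body = regional_displacement_modes(30, BODY_BLOCK_LANDMARKS)
    loadings = np.hstack([global_loadings, tip, body])
    factor_sd = np.concatenate(
        [global_sd, np.full(3, 1.0 * noise_sd), np.full(3, 3.0 * noise_sd)]
    )
    # deterministic small mean offsets along the two leading smooth modes
    offsets = {
        "Italian": 0.02 * cs * global_loadings[:, 0],
        "AfricanAmerican": (
            -0.015 * cs * global_loadings[:, 0]
            + 0.012 * cs * global_loadings[:, 1]
        ),
        "Spanish": -0.012 * cs * global_loadings[:, 1],
    }
    return PopulationModel(
        mean_shape=template,
        factor_loadings=loadings,
        factor_sd=factor_sd,
        noise_sd=noise_sd,
        population_offsets=offsets,
        size_log_sd=0.05,
        seed=seed,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation (QR of a Gaussian matrix, det forced +1)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def generate_dataset(
    model: PopulationModel,
    n_per_population: Mapping[str, int] | None = None,
    nuisance: bool = True,
    seed: int | None = None,
) -> LandmarkDataset:
    """Draw a seeded, fully reproducible dataset from a population model.

    ``n_per_population`` maps population name to sample size (default: the
    150-specimen study composition).  Populations must have offsets in the
    model unless the model defines none at all (single-population use).
    With ``nuisance`` on, each specimen receives a uniform random rotation,
    a translation, and a lognormal scale, which downstream GPA must remove.
    """
    if n_per_population is None:
        n_per_population = DEFAULT_SAMPLE
    for name, n in n_per_population.items():
        if n < 1:
            raise DatasetError(f"n for population {name!r} must be >= 1")
        if model.population_offsets and name not in model.population_offsets:
            raise DatasetError(f"unknown population {name!r} (no offset defined)")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    k = model.k
    cs = centroid_size(model.mean_shape)
    mean_flat = model.mean_shape.reshape(-1)
    configs = []
    for name in n_per_population:
        offset = model.population_offsets.get(name, np.zeros(3 * k))
        for i in range(n_per_population[name]):
            z = rng.standard_normal(model.n_factors)
            noise = model.noise_sd * rng.standard_normal(3 * k)
            flat = mean_flat + offset + model.factor_loadings @ (model.factor_sd * z) + noise
            coords = flat.reshape(k, 3)
            if nuisance:
                R = _random_rotation(rng)
                scale = float(np.exp(model.size_log_sd * rng.standard_normal()))
                translation = 0.25 * cs * rng.standard_normal(3)
                coords = scale * coords @ R.T + translation
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{name}_{i + 1:03d}",
                    coords=coords,
                    roles=default_roles(k),
                    population=name,
                    sex="M" if rng.random() < 0.5 else "F",
                    side="left",
                )
            )
    return LandmarkDataset(tuple(configs), default_labels(k))
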