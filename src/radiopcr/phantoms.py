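"""Seeded two-class synthetic lesion cohorts.

No public imaging archive backs this pipeline, so the study conditions are
emulated by texture phantoms: ellipsoidal "lesions" filled with a Gaussian
random field whose correlation length and intensity-distribution shape
differ between responders (pCR) and non-responders. Smoothing length drives
GLCM/fractal texture, the monotone intensity transform drives first-order
skew/kurtosis, so every feature family can carry genuine class signal
without modelling MR physics. Setting both class parameter sets equal
defines an exact null cohort.

A fast mode (:func:`generate_feature_table`) skips the imaging stack and
draws a case x feature matrix directly, for exercising the selection and
modelling stages at realistic cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import VolumeWithMask
from .table import FeatureTable

__all__ = ["ClassTexture", "PhantomSpec", "SyntheticCohort", "generate_cohort", "generate_feature_table"]

#: cohort defaults mirror the study: 183 cases, 74 of them pCR
DEFAULT_N_CASES = 183
DEFAULT_PREVALENCE = 74 / 183


@dataclass(frozen=True)
class ClassTexture:
    """Texture parameters of one outcome class.

    ``correlation_length_mm`` is the Gaussian smoothing length of the random
    field (larger = coarser, more homogeneous texture);
    ``intensity_shape`` controls the monotone transform exp(shape * z) of the
    standardised field (0 = symmetric, larger = more right-skewed, heavier
    tails), i.e. first-order skewness/kurtosis.
    """

    correlation_length_mm: float = 1.5
    intensity_shape: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort; equal spec => equal voxels."""

    n_cases: int = DEFAULT_N_CASES
    prevalence_positive: float = DEFAULT_PREVALENCE
    grid_shape: tuple[int, int, int] = (64, 64, 7)
    voxel_spacing_mm: tuple[float, float, float] = (0.548, 0.548, 3.0)
    lesion_radius_mm: float = 7.0
    texture_negative: ClassTexture = field(default_factory=lambda: ClassTexture(1.5, 0.0))
    texture_positive: ClassTexture = field(default_factory=lambda: ClassTexture(3.0, 0.8))
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0.0 < self.prevalence_positive < 1.0:
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        # the lesion must be fully interior to the grid along every axis
        for n, s in zip(self.grid_shape, self.voxel_spacing_mm):
            if 2 * self.lesion_radius_mm >= (n - 2) * s:
                raise ValueError(
                    "lesion does not fit inside the grid at the given spacing"
                )

    def null(self) -> "PhantomSpec":
        """A copy with identical class parameters (no class signal)."""
        return replace(self, texture_positive=self.texture_negative)


@dataclass
class SyntheticCohort:
    cases: list[VolumeWithMask]
    labels: np.ndarray
    spec: PhantomSpec


def _labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(spec.n_cases * spec.prevalence_positive))
    labels = np.zeros(spec.n_cases, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    return labels


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    center = [(n - 1) / 2.0 for n in shape]
    axes = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(
        ((ax - c) * s / spec.lesion_radius_mm) ** 2
        for ax, c, s in zip(axes, center, spec.voxel_spacing_mm)
    )
    return r2 <= 1.0


def _textured_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    texture: ClassTexture,
    rng: np.random.Generator,
) -> np.ndarray:
    white = rng.standard_normal(shape)
    sigma_vox = [texture.correlation_length_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    z = smooth / sd if sd > 0 else smooth
    if texture.intensity_shape != 0.0:
        a = texture.intensity_shape
        z = (np.exp(a * z) - 1.0) / a  # monotone; skew grows with |a|
        z = (z - z.mean()) / z.std()
    return z


def generate_cohort(spec: PhantomSpec) -> SyntheticCohort:
    """Generate a seeded cohort of lesion phantoms.

    Each case is a darker constant background plus an ellipsoidal lesion
    whose interior carries the class's textured random field, with additive
    Gaussian noise everywhere. All randomness flows from ``spec.seed``
    through one named generator, so equal specs reproduce identical voxels.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec, rng)
    mask = _ellipsoid_mask(spec)
    background, lesion_mean, lesion_contrast = 0.2, 0.6, 0.15
    cases = []
    for lab in labels:
        texture = spec.texture_positive if lab == 1 else spec.texture_negative
        field_ = _textured_field(spec.grid_shape, spec.voxel_spacing_mm, texture, rng)
        vol = np.full(spec.grid_shape, background)
        vol[mask] = lesion_mean + lesion_contrast * field_[mask]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        cases.append(VolumeWithMask(vol, spec.voxel_spacing_mm, mask.copy()))
    return SyntheticCohort(cases, labels, spec)


def generate_feature_table(
    n_cases: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    prevalence: float = DEFAULT_PREVALENCE,
    seed: int = 0,
    n_duplicate_pairs: int = 0,
    block_rho: float = 0.0,
) -> FeatureTable:
    """Draw a two-class feature table directly (fast mode).

    The first ``n_informative`` columns differ between classes by
    ``effect_size`` standardised mean difference; the rest are
    class-independent N(0, 1) noise. ``n_duplicate_pairs`` appends exact
    copies of the first informative columns and ``block_rho`` correlates the
    informative block, to exercise Pearson pruning. Column names mark
    informative columns (``inf_*``) so recovery can be scored.
    """
    if n_cases <= 0 or n_features <= 0:
        raise ValueError("n_cases and n_features must be positive")
    if n_informative < 0 or n_informative > n_features:
        raise ValueError("need 0 <= n_informative <= n_features")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_cases * prevalence))
    labels = np.zeros(n_cases, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    X = rng.standard_normal((n_cases, n_features))
    if n_informative and block_rho:
        shared = rng.standard_normal((n_cases, 1))
        X[:, :n_informative] = (
            np.sqrt(block_rho) * shared
            + np.sqrt(1.0 - block_rho) * X[:, :n_informative]
        )
    X[:, :n_informative] += effect_size * labels[:, None]
    names = [
        f"inf_{i:04d}" if i < n_informative else f"noise_{i:04d}"
        for i in range(n_features)
    ]
    if n_duplicate_pairs:
        k = min(n_duplicate_pairs, max(n_informative, 1))
        X = np.hstack([X, X[:, :k]])
        names += [f"dup_{names[i]}" for i in range(k)]
    return FeatureTable(X, names, labels)
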