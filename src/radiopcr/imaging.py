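"""Image preprocessing: planar resampling and the two radiomic filter banks.

The pipeline mirrors a T2-weighted MRI radiomics protocol: every volume is
first resampled to a common in-plane resolution (0.548 x 0.548 mm^2 by
default), then passed through

* a Laplacian-of-Gaussian (LoG) filter bank with 13 widths sigma = 0, 0.35,
  ..., 4.2 mm (sigma = 0 means "no filtering", i.e. the raw image), feeding
  the first-order feature family; and
* an intensity-based (IB) filter: intensities inside the ROI are linearly
  normalised between the 1st and 99th percentile of the ROI histogram, and
  voxel subpopulations are carved out by all 55 ordered pairs of threshold
  levels drawn from 0%..100% in 10% steps.

All filtering and resampling is planar (2D, per axial slice): slice thickness
varies across acquisition protocols and is deliberately left untouched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeWithMask",
    "LogBank",
    "IbThresholdPair",
    "DegenerateNormalisationError",
    "resample_planar",
    "log_kernel",
    "log_filter",
    "sigma_grid",
    "ib_normalize",
    "ib_threshold_pairs",
    "subpopulation_mask",
]

DEFAULT_TARGET_SPACING_MM = 0.548


class DegenerateNormalisationError(ValueError):
    """ROI intensities are constant; percentile normalisation is undefined."""


@dataclass
class VolumeWithMask:
    """A 3D intensity volume with voxel spacing and an aligned binary ROI.

    ``intensities`` is indexed (row, col, slice); ``spacing_mm`` gives the
    physical voxel size along each of those axes.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask shape must equal intensity shape")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three strictly positive values")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def roi_values(self) -> np.ndarray:
        """Intensities of the ROI voxels as a flat array."""
        return self.intensities[self.mask]

    def copy(self) -> "VolumeWithMask":
        return VolumeWithMask(
            self.intensities.copy(), self.spacing_mm, self.mask.copy()
        )


@dataclass(frozen=True)
class LogBank:
    """LoG filter widths in mm; default 13 steps from 0 to 4.2 by 0.35."""

    sigma_max_mm: float = 4.2
    sigma_step_mm: float = 0.35

    sigmas_mm: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        n = int(round(self.sigma_max_mm / self.sigma_step_mm)) + 1
        object.__setattr__(
            self,
            "sigmas_mm",
            tuple(round(i * self.sigma_step_mm, 10) for i in range(n)),
        )


@dataclass(frozen=True)
class IbThresholdPair:
    """Lower/upper intensity levels, in percent of the normalised maximum."""

    lower_pct: int
    upper_pct: int

    def __post_init__(self) -> None:
        allowed = set(range(0, 101, 10))
        if self.lower_pct not in allowed or self.upper_pct not in allowed:
            raise ValueError("threshold levels must be multiples of 10 in 0..100")
        if not self.lower_pct < self.upper_pct:
            raise ValueError("lower level must be strictly below upper level")


def sigma_grid(bank: LogBank | None = None) -> list[float]:
    """Return the LoG sigma grid in mm ([0, 0.35, ..., 4.2] by default)."""
    return list((bank or LogBank()).sigmas_mm)


def resample_planar(v: VolumeWithMask, target_mm: float = DEFAULT_TARGET_SPACING_MM) -> VolumeWithMask:
    """Resample each axial plane to ``target_mm`` isotropic in-plane spacing.

    The slice axis is untouched. Intensities are linearly interpolated; the
    mask is linearly interpolated then re-binarised at 0.5.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    nr, nc, _ = v.intensities.shape
    if nr < 2 or nc < 2:
        raise ValueError("cannot resample a degenerate (single-voxel) plane")
    sr, sc, ss = v.spacing_mm
    if np.isclose(sr, target_mm) and np.isclose(sc, target_mm):
        return v.copy()
    new_nr = max(int(round(nr * sr / target_mm)), 2)
    new_nc = max(int(round(nc * sc / target_mm)), 2)
    zoom = (new_nr / nr, new_nc / nc, 1.0)
    intensities = ndimage.zoom(v.intensities, zoom, order=1, mode="nearest", grid_mode=True)
    mask = ndimage.zoom(v.mask.astype(float), zoom, order=1, mode="nearest", grid_mode=True)
    return VolumeWithMask(intensities, (target_mm, target_mm, ss), mask >= 0.5)


def log_kernel(
    sigma_mm: float, spacing_mm: tuple[float, float], truncate: float = 4.0
) -> np.ndarray:
    """Discrete 2D LoG kernel at width ``sigma_mm``, zero-normalised.

    Sigma is converted to pixels per axis via the planar spacing. The
    truncated sampled kernel is shifted to sum exactly to zero, so a
    constant image produces a (numerically) zero response.
    """
    if sigma_mm <= 0:
        raise ValueError("kernel needs a positive sigma")
    sr = sigma_mm / spacing_mm[0]
    sc = sigma_mm / spacing_mm[1]
    rr = int(truncate * sr + 0.5)
    rc = int(truncate * sc + 0.5)
    delta = np.zeros((4 * rr + 1, 4 * rc + 1))
    delta[2 * rr, 2 * rc] = 1.0
    full = ndimage.gaussian_laplace(delta, sigma=(sr, sc), mode="constant")
    k = full[rr : 3 * rr + 1, rc : 3 * rc + 1].copy()
    k -= k.sum() / k.size
    return k


def log_filter(v: VolumeWithMask, sigma_mm: float) -> VolumeWithMask:
    """Planar Laplacian-of-Gaussian response at width ``sigma_mm``.

    Each axial slice is convolved with the zero-normalised discrete LoG
    kernel of :func:`log_kernel` (nearest-neighbour boundary extension).
    ``sigma_mm == 0`` returns the raw image unchanged.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma_mm == 0:
        return v.copy()
    kernel = log_kernel(sigma_mm, v.spacing_mm[:2])
    out = np.empty_like(v.intensities)
    for k in range(v.intensities.shape[2]):
        out[:, :, k] = ndimage.convolve(v.intensities[:, :, k], kernel, mode="nearest")
    return VolumeWithMask(out, v.spacing_mm, v.mask.copy())


def ib_normalize(v: VolumeWithMask) -> VolumeWithMask:
    """Normalise ROI intensities between the 1st and 99th ROI percentiles.

    Inside the ROI the linear map sends the 1st percentile to 0 and the 99th
    to 1, then clips to [0, 1]. Voxels outside the ROI are left unchanged
    (downstream features only read the ROI).
    """
    roi = v.roi_values
    if np.unique(roi).size < 2:
        raise DegenerateNormalisationError("ROI intensities are constant")
    lo, hi = np.percentile(roi, [1, 99])
    if hi <= lo:
        raise DegenerateNormalisationError("degenerate ROI percentile range")
    out = v.intensities.copy()
    out[v.mask] = np.clip((roi - lo) / (hi - lo), 0.0, 1.0)
    return VolumeWithMask(out, v.spacing_mm, v.mask.copy())


def ib_threshold_pairs(step_pct: int = 10) -> list[IbThresholdPair]:
    """All ordered level pairs (l < u) from 0..100 by ``step_pct`` (55 by default)."""
    levels = range(0, 101, step_pct)
    return [
        IbThresholdPair(l, u) for l, u in itertools.combinations(levels, 2)
    ]


def subpopulation_mask(normed: VolumeWithMask, pair: IbThresholdPair) -> np.ndarray:
    """ROI voxels whose normalised intensity lies in [lower, upper] (closed).

    Boundary voxels belong to both adjacent pairs; the result may be empty
    (downstream features then return a missing sentinel).
    """
    lo = pair.lower_pct / 100.0
    hi = pair.upper_pct / 100.0
    vals = normed.intensities
    return normed.mask & (vals >= lo) & (vals <= hi)
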