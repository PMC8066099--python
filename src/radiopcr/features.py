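"""Radiomic feature families and per-case feature-bank extraction.

Four families are computed over the ROI of each (already resampled) volume:

* first-order intensity statistics on every LoG-filtered image (13 sigmas);
* grey-level co-occurrence (GLCM) texture statistics, box-counting fractal
  dimension and morphology on every intensity-based subpopulation (55
  threshold pairs).

Feature identifiers are fully qualified (filter, filter parameters, family,
feature name) and round-trip through their string form, so a feature table
column can always be traced back to the exact image operation that produced
it. Empty or too-small subpopulations yield NaN sentinels, never an abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import stats
from skimage.measure import label as cc_label

from .imaging import (
    DegenerateNormalisationError,
    IbThresholdPair,
    LogBank,
    VolumeWithMask,
    ib_normalize,
    ib_threshold_pairs,
    log_filter,
    sigma_grid,
    subpopulation_mask,
)

__all__ = [
    "FeatureId",
    "BankConfig",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "FRACTAL_NAMES",
    "MORPHOLOGY_NAMES",
    "first_order_features",
    "glcm_features",
    "glcm_matrix",
    "fractal_features",
    "box_counting_dimension",
    "morphology_features",
    "extract_bank",
    "bank_feature_ids",
]

MISSING = float("nan")

FIRST_ORDER_NAMES = (
    "mean",
    "variance",
    "sd",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "minimum",
    "maximum",
    "median",
    "p10",
    "p90",
    "iqr",
    "range",
    "mad",
    "robust_mad",
    "rms",
    "uniformity",
)

GLCM_NAMES = (
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "entropy",
    "cluster_shade",
    "cluster_prominence",
)

FRACTAL_NAMES = ("fd_mean", "fd_sd", "fd_max")

MORPHOLOGY_NAMES = (
    "volume_mm3",
    "surface_mm2",
    "sphericity",
    "max_planar_diameter_mm",
    "n_components",
)


@dataclass(frozen=True)
class FeatureId:
    """Structured identifier: filter, filter parameters, family, name.

    String form: ``log|s0.35|first_order|mean`` or
    ``ib|20-60|glcm|cluster_shade``; parseable back via :meth:`from_string`.
    """

    filter: str  # "log" | "ib"
    filter_params: tuple  # (sigma_mm,) or (lower_pct, upper_pct)
    family: str  # "first_order" | "glcm" | "fractal" | "morphology"
    name: str

    def __post_init__(self) -> None:
        if self.filter == "log" and self.family != "first_order":
            raise ValueError("LoG images carry only first-order features")
        if self.filter == "ib" and self.family not in ("glcm", "fractal", "morphology"):
            raise ValueError("IB subpopulations carry glcm/fractal/morphology features")

    def __str__(self) -> str:
        if self.filter == "log":
            params = f"s{self.filter_params[0]:g}"
        else:
            params = f"{self.filter_params[0]:d}-{self.filter_params[1]:d}"
        return f"{self.filter}|{params}|{self.family}|{self.name}"

    @classmethod
    def from_string(cls, s: str) -> "FeatureId":
        filt, params, family, name = s.split("|")
        if filt == "log":
            fp: tuple = (float(params[1:]),)
        else:
            lo, hi = params.split("-")
            fp = (int(lo), int(hi))
        return cls(filt, fp, family, name)


@dataclass(frozen=True)
class BankConfig:
    """Configuration of the extracted feature bank.

    Defaults follow the protocol skeleton (13 LoG sigmas x first-order +
    55 IB pairs x {glcm, fractal, morphology}); the GLCM discretisation
    (32 fixed bins, distance 1, four planar directions summed) and the
    minimum subpopulation size are package defaults, exposed here.
    """

    log_bank: LogBank = field(default_factory=LogBank)
    ib_step_pct: int = 10
    glcm_bins: int = 32
    glcm_distance: int = 1
    min_subpop_voxels: int = 8

    @property
    def census(self) -> int:
        n_pairs = len(ib_threshold_pairs(self.ib_step_pct))
        return len(self.log_bank.sigmas_mm) * len(FIRST_ORDER_NAMES) + n_pairs * (
            len(GLCM_NAMES) + len(FRACTAL_NAMES) + len(MORPHOLOGY_NAMES)
        )


# ---------------------------------------------------------------------------
# first-order


def first_order_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """First-order statistics of the ROI intensity multiset.

    Kurtosis uses the Pearson convention (a normal distribution scores 3).
    Entropy and uniformity use a fixed-bin-number histogram (``n_bins`` bins
    over the observed range).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        return {name: MISSING for name in FIRST_ORDER_NAMES}
    mean = float(np.mean(x))
    var = float(np.var(x))  # population convention
    sd = math.sqrt(var)
    if sd > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi > lo:
        hist, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        hist = np.array([x.size])
    p = hist[hist > 0] / x.size
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "mean": mean,
        "variance": var,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(x**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "minimum": lo,
        "maximum": hi,
        "median": float(np.median(x)),
        "p10": float(p10),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "range": hi - lo,
        "mad": float(np.mean(np.abs(x - mean))),
        "robust_mad": float(np.mean(np.abs(robust - np.mean(robust))))
        if robust.size
        else 0.0,
        "rms": float(np.sqrt(np.mean(x**2))),
        "uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM

_PLANAR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_matrix(
    img: np.ndarray, mask: np.ndarray, n_bins: int, distance: int = 1
) -> np.ndarray | None:
    """Symmetric, normalised grey-level co-occurrence matrix of a masked volume.

    Grey levels are discretised to ``n_bins`` equal-width bins over the
    masked intensity range; co-occurrences are accumulated per axial slice
    over the four planar directions at the given distance, summed across
    slices and directions, then normalised to probabilities. Returns None
    when no valid voxel pair exists.
    """
    vals = img[mask]
    if vals.size < 2:
        return None
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        binned = np.floor((img - lo) / (hi - lo) * n_bins).astype(int)
        binned = np.clip(binned, 0, n_bins - 1)
    else:
        binned = np.zeros(img.shape, dtype=int)
    binned = np.where(mask, binned, -1)
    counts = np.zeros((n_bins, n_bins), dtype=float)
    for k in range(img.shape[2]):
        sl = binned[:, :, k]
        h, w = sl.shape
        for dr, dc in _PLANAR_OFFSETS:
            off_r, off_c = distance * dr, distance * dc
            r0, r1 = max(0, -off_r), min(h, h - off_r)
            c0, c1 = max(0, -off_c), min(w, w - off_c)
            if r0 >= r1 or c0 >= c1:
                continue
            a = sl[r0:r1, c0:c1]
            b = sl[r0 + off_r : r1 + off_r, c0 + off_c : c1 + off_c]
            valid = (a >= 0) & (b >= 0)
            np.add.at(counts, (a[valid], b[valid]), 1.0)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def glcm_features(
    img: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    distance: int = 1,
) -> dict[str, float]:
    """GLCM texture statistics (contrast, correlation, energy, homogeneity,
    entropy, cluster shade, cluster prominence) from the planar co-occurrence
    matrix of the masked voxels."""
    p = glcm_matrix(img, mask, n_bins=n_bins, distance=distance)
    if p is None:
        return {name: MISSING for name in GLCM_NAMES}
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i > 0 and var_j > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))
    else:
        corr = 0.0
    nz = p[p > 0]
    dev = i + j - mu_i - mu_j
    return {
        "contrast": float(np.sum((i - j) ** 2 * p)),
        "correlation": corr,
        "energy": float(np.sum(p**2)),
        "homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "entropy": float(-np.sum(nz * np.log2(nz))),
        "cluster_shade": float(np.sum(dev**3 * p)),
        "cluster_prominence": float(np.sum(dev**4 * p)),
    }


# ---------------------------------------------------------------------------
# fractal


def box_counting_dimension(slice_mask: np.ndarray) -> float:
    """Box-counting dimension of a 2D binary mask.

    Least-squares slope of log N(eps) against log(1/eps) over dyadic box
    sizes spanning the mask's bounding box. A single pixel (N(eps) = 1 for
    all eps) has dimension 0.
    """
    rows, cols = np.nonzero(slice_mask)
    if rows.size == 0:
        return MISSING
    sub = slice_mask[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    max_dim = max(sub.shape)
    sizes = []
    s = 1
    while s <= max_dim:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0
    log_n, log_inv_eps = [], []
    for s in sizes:
        pr = (-sub.shape[0]) % s
        pc = (-sub.shape[1]) % s
        padded = np.pad(sub, ((0, pr), (0, pc)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        n_boxes = int(blocks.any(axis=(1, 3)).sum())
        log_n.append(math.log(n_boxes))
        log_inv_eps.append(math.log(1.0 / s))
    slope = np.polyfit(log_inv_eps, log_n, 1)[0]
    return float(slope)


def fractal_features(mask: np.ndarray) -> dict[str, float]:
    """Mean, SD and maximum of the per-axial-slice box-counting dimensions."""
    dims = []
    for k in range(mask.shape[2]):
        if mask[:, :, k].any():
            dims.append(box_counting_dimension(mask[:, :, k]))
    if not dims:
        return {name: MISSING for name in FRACTAL_NAMES}
    dims = np.asarray(dims)
    return {
        "fd_mean": float(dims.mean()),
        "fd_sd": float(dims.std(ddof=1)) if dims.size > 1 else 0.0,
        "fd_max": float(dims.max()),
    }


# ---------------------------------------------------------------------------
# morphology


def _max_planar_diameter(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    sr, sc, _ = spacing
    best = 0.0
    for k in range(mask.shape[2]):
        rows, cols = np.nonzero(mask[:, :, k])
        if rows.size == 0:
            continue
        pts = np.column_stack([rows * sr, cols * sc])
        if pts.shape[0] > 3:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass  # collinear points; brute-force below
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        best = max(best, float(np.sqrt(d2.max())))
    return best


def morphology_features(
    mask: np.ndarray, spacing_mm: tuple[float, float, float]
) -> dict[str, float]:
    """Shape descriptors of a binary subpopulation mask.

    Surface area is the voxel-face proxy (exposed faces weighted by their
    physical area); sphericity compares that surface with the surface of the
    equal-volume sphere; components are 8-connected per axial slice, summed
    over slices.
    """
    if not mask.any():
        return {name: MISSING for name in MORPHOLOGY_NAMES}
    sr, sc, ss = spacing_mm
    n_vox = int(mask.sum())
    volume = n_vox * sr * sc * ss
    m = mask.astype(np.int8)
    face_areas = (sc * ss, sr * ss, sr * sc)  # faces normal to row/col/slice
    surface = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        surface += float(np.abs(np.diff(padded, axis=axis)).sum()) * area
    sphericity = (math.pi ** (1 / 3)) * ((6.0 * volume) ** (2 / 3)) / surface
    n_comp = 0
    for k in range(mask.shape[2]):
        if mask[:, :, k].any():
            n_comp += int(cc_label(mask[:, :, k], connectivity=2).max())
    return {
        "volume_mm3": volume,
        "surface_mm2": surface,
        "sphericity": sphericity,
        "max_planar_diameter_mm": _max_planar_diameter(mask, spacing_mm),
        "n_components": float(n_comp),
    }


# ---------------------------------------------------------------------------
# bank assembly


def bank_feature_ids(config: BankConfig | None = None) -> list[FeatureId]:
    """The ordered FeatureId roster determined by a bank configuration."""
    config = config or BankConfig()
    ids: list[FeatureId] = []
    for sigma in config.log_bank.sigmas_mm:
        for name in FIRST_ORDER_NAMES:
            ids.append(FeatureId("log", (sigma,), "first_order", name))
    for pair in ib_threshold_pairs(config.ib_step_pct):
        fp = (pair.lower_pct, pair.upper_pct)
        for name in GLCM_NAMES:
            ids.append(FeatureId("ib", fp, "glcm", name))
        for name in FRACTAL_NAMES:
            ids.append(FeatureId("ib", fp, "fractal", name))
        for name in MORPHOLOGY_NAMES:
            ids.append(FeatureId("ib", fp, "morphology", name))
    return ids


def extract_bank(
    case: VolumeWithMask, config: BankConfig | None = None
) -> dict[FeatureId, float]:
    """Extract the full feature bank from one (resampled) case.

    First-order features are computed on each LoG-filtered image over the
    whole ROI; GLCM, fractal and morphology features on each IB threshold
    subpopulation. Subpopulations below ``config.min_subpop_voxels`` (or a
    constant ROI that defeats percentile normalisation) produce NaN
    sentinels; extraction never aborts on them.
    """
    config = config or BankConfig()
    out: dict[FeatureId, float] = {}
    for sigma in config.log_bank.sigmas_mm:
        filtered = log_filter(case, sigma)
        fo = first_order_features(filtered.roi_values)
        for name in FIRST_ORDER_NAMES:
            out[FeatureId("log", (sigma,), "first_order", name)] = fo[name]
    try:
        normed = ib_normalize(case)
    except DegenerateNormalisationError:
        normed = None
    for pair in ib_threshold_pairs(config.ib_step_pct):
        fp = (pair.lower_pct, pair.upper_pct)
        if normed is None:
            sub = np.zeros(case.mask.shape, dtype=bool)
        else:
            sub = subpopulation_mask(normed, pair)
        if normed is not None and sub.sum() >= config.min_subpop_voxels:
            gl = glcm_features(
                normed.intensities, sub, n_bins=config.glcm_bins, distance=config.glcm_distance
            )
            fr = fractal_features(sub)
        else:
            gl = {name: MISSING for name in GLCM_NAMES}
            fr = {name: MISSING for name in FRACTAL_NAMES}
        mo = morphology_features(sub, case.spacing_mm)
        for name in GLCM_NAMES:
            out[FeatureId("ib", fp, "glcm", name)] = gl[name]
        for name in FRACTAL_NAMES:
            out[FeatureId("ib", fp, "fractal", name)] = fr[name]
        for name in MORPHOLOGY_NAMES:
            out[FeatureId("ib", fp, "morphology", name)] = mo[name]
    return out
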