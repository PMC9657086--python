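"""Astrocyte process morphometry from GFAP-stained volumes.

The segmentation is two-step: an intensity-based hysteresis threshold at 3
and 5 noise standard deviations above background selects stain-positive
voxels, and a multiscale Frangi vesselness contrast then refines the
selection and splits it into thin (scales 0.1–0.6 μm) and thick (> 0.6 μm)
processes.  Summary metrics are volume fractions and medial-axis skeleton
sizes per class.  An independent intensity-only separation via 3-level Otsu
thresholding is also provided (background / dim thin / bright thick).

All spatial scales are specified in micrometres and converted per axis using
the voxel calibration, so anisotropic stacks are handled natively.  Scales
that are unresolvable along z fall back to an in-plane (2D) Hessian; scales
unresolvable even in-plane are skipped with a warning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .stack import ImageStack3D

__all__ = [
    "NoiseEstimate",
    "HysteresisConfig",
    "FrangiConfig",
    "RefineConfig",
    "ProcessSegmentation",
    "MorphometrySummary",
    "IntensityClassMap",
    "estimate_noise_sd",
    "estimate_background",
    "hysteresis_segment",
    "frangi_response",
    "scale_split_contrast",
    "refine_segmentation",
    "morphometry_summary",
    "otsu3_thresholds",
    "otsu3_labels",
    "run_gfap_pipeline",
]

logger = logging.getLogger(__name__)

_FULL_CONN = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class NoiseEstimate:
    sigma: float
    method: str = "mad_first_diff"
    degenerate: bool = False  # set when the stack was constant

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class HysteresisConfig:
    """Low/high thresholds as multiples of the noise SD above background."""

    low_k: float = 3.0
    high_k: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.low_k <= self.high_k):
            raise ValueError(f"need 0 < low_k <= high_k, got {self.low_k}, {self.high_k}")


def _default_scales() -> list[float]:
    # 6 geometric steps spanning 0.1–1.2 μm; 0.6 μm separates thin from thick
    return list(np.geomspace(0.1, 1.2, 6))


@dataclass
class FrangiConfig:
    """Scale ladder and sensitivity parameters for the vesselness filter."""

    scales: list[float] = field(default_factory=_default_scales)
    boundary: float = 0.6  # μm; thin: sigma <= boundary, thick: sigma > boundary
    alpha: float = 0.5  # plate-vs-line sensitivity (3D only)
    beta: float = 0.5  # blob-vs-line sensitivity
    c: float | None = None  # structureness scale; None = half the max Hessian norm across scales
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        s = list(self.scales)
        if s != sorted(s) or any(x <= 0 for x in s):
            raise ValueError("scales must be sorted ascending and positive")
        if not (min(s) <= self.boundary < max(s)):
            raise ValueError(
                f"boundary={self.boundary} must lie within [min(scales), max(scales))"
            )
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        self.scales = s


@dataclass
class ProcessSegmentation:
    """Disjoint thick/thin masks inside the intensity-based foreground."""

    thick_mask: np.ndarray
    thin_mask: np.ndarray
    intensity_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.thick_mask.shape == self.thin_mask.shape == self.intensity_mask.shape):
            raise ValueError("masks must share one shape")
        if np.any(self.thick_mask & ~self.intensity_mask) or np.any(
            self.thin_mask & ~self.intensity_mask
        ):
            raise ValueError("thick/thin masks must lie within the intensity mask")
        if np.any(self.thick_mask & self.thin_mask):
            raise ValueError("thick and thin masks must be disjoint")


@dataclass
class MorphometrySummary:
    vf_thick: float
    vf_thin: float
    skeleton_size_thick: float  # μm (skeleton voxel count × mean in-plane pitch)
    skeleton_size_thin: float
    skeleton_voxels_thick: int
    skeleton_voxels_thin: int


@dataclass
class IntensityClassMap:
    """Per-voxel labels: 0 background, 1 dim/thin, 2 bright/thick."""

    labels: np.ndarray
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        t1, t2 = self.thresholds
        if not t1 < t2:
            raise ValueError("thresholds must be strictly increasing")


# --------------------------------------------------------------------------
# noise and background
# --------------------------------------------------------------------------

def estimate_noise_sd(stack: ImageStack3D) -> NoiseEstimate:
    """Robust noise SD from first differences along the fastest (x) axis.

    For i.i.d. noise the first difference has variance 2σ², and the median
    absolute deviation ignores the sparse structured voxels, so
    σ ≈ 1.4826·MAD(Δx) / √2.
    """
    data = np.asarray(stack.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty stack")
    d = np.diff(data, axis=-1).ravel()
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.482602218505602 * mad / math.sqrt(2.0)
    if sigma == 0:
        warnings.warn("stack appears constant; noise sigma estimated as 0")
        return NoiseEstimate(0.0, degenerate=True)
    return NoiseEstimate(float(sigma))


def estimate_background(stack: ImageStack3D, nbins: int = 256) -> float:
    """Background level as the mode of the intensity histogram."""
    counts, edges = np.histogram(stack.data, bins=nbins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


# --------------------------------------------------------------------------
# hysteresis segmentation
# --------------------------------------------------------------------------

def hysteresis_segment(
    stack: ImageStack3D,
    noise: NoiseEstimate | None = None,
    cfg: HysteresisConfig | None = None,
    background: float | None = None,
    thresholds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Foreground voxels above ``low_k·σ`` that 26-connect to a voxel above
    ``high_k·σ`` (both measured above the background level).

    Pass absolute ``thresholds=(low, high)`` to bypass the noise model, e.g.
    for a degenerate noise estimate.
    """
    data = np.asarray(stack.data, dtype=float)
    cfg = cfg or HysteresisConfig()
    if thresholds is None:
        if noise is None or noise.sigma <= 0:
            raise ValueError(
                "noise sigma is zero or missing; pass explicit thresholds=(low, high)"
            )
        bg = estimate_background(stack) if background is None else float(background)
        low = bg + cfg.low_k * noise.sigma
        high = bg + cfg.high_k * noise.sigma
    else:
        low, high = (float(t) for t in thresholds)
        if low > high:
            raise ValueError("low threshold must not exceed high threshold")

    low_mask = data >= low
    high_mask = data >= high
    if not high_mask.any():
        return np.zeros_like(low_mask)
    labels, _ = ndimage.label(low_mask, structure=_FULL_CONN)
    keep = np.unique(labels[high_mask])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


# --------------------------------------------------------------------------
# Frangi vesselness
# --------------------------------------------------------------------------

def _hessian(data: np.ndarray, sigma_vox: np.ndarray, voxel_size: np.ndarray, axes: tuple[int, ...]):
    """Scale-space Hessian entries in physical (μm⁻²) units over ``axes``."""
    H = {}
    for ii, a in enumerate(axes):
        for b in axes[ii:]:
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            deriv = ndimage.gaussian_filter(data, sigma=sigma_vox, order=tuple(order), mode="nearest")
            H[(a, b)] = deriv / (voxel_size[a] * voxel_size[b])
    return H


def _vesselness_from_eigs(eigs: np.ndarray, alpha: float, beta: float, c: float) -> np.ndarray:
    """Frangi response from |λ|-sorted Hessian eigenvalues (last axis)."""
    ndim_eff = eigs.shape[-1]
    l1 = eigs[..., 0]
    l2 = eigs[..., 1]
    S2 = np.sum(eigs**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if ndim_eff == 3:
            l3 = eigs[..., 2]
            ra2 = (l2 / l3) ** 2
            rb2 = l1**2 / np.abs(l2 * l3)
            v = (
                (1.0 - np.exp(-ra2 / (2 * alpha**2)))
                * np.exp(-rb2 / (2 * beta**2))
                * (1.0 - np.exp(-S2 / (2 * c**2)))
            )
            v = np.where((l2 < 0) & (l3 < 0), v, 0.0)
        else:
            rb2 = (l1 / l2) ** 2
            v = np.exp(-rb2 / (2 * beta**2)) * (1.0 - np.exp(-S2 / (2 * c**2)))
            v = np.where(l2 < 0, v, 0.0)
    return np.nan_to_num(v, nan=0.0, posinf=0.0, neginf=0.0)


def _sort_by_abs(*lams: np.ndarray) -> np.ndarray:
    stackd = np.stack(lams, axis=-1)
    order = np.argsort(np.abs(stackd), axis=-1)
    return np.take_along_axis(stackd, order, axis=-1)


def frangi_response(stack: ImageStack3D, cfg: FrangiConfig | None = None) -> dict[float, np.ndarray]:
    """Per-scale vesselness volumes, keyed by scale σ in μm.

    The Hessian is computed from a Gaussian-smoothed volume with per-axis
    sigmas ``σ/voxel_size`` and normalised by σ² (γ = 2) so responses are
    comparable across scales.  A scale below half the z voxel falls back to
    an in-plane 2D Hessian; a scale below half the in-plane pitch is skipped.
    """
    cfg = cfg or FrangiConfig()
    data = np.asarray(stack.data, dtype=float)
    if not cfg.bright_on_dark:
        data = -data
    vs = np.asarray(stack.voxel_size, dtype=float)
    eigs_by_scale: dict[float, np.ndarray] = {}
    for sigma in cfg.scales:
        if sigma < 0.5 * max(vs[1], vs[2]):
            logger.warning("scale %.3f μm below in-plane resolution %s; skipped", sigma, vs[1:])
            continue
        use_2d = sigma < 0.5 * vs[0]
        if use_2d:
            logger.warning(
                "scale %.3f μm below z resolution %.3f μm; using in-plane Hessian", sigma, vs[0]
            )
            sigma_vox = np.array([0.0, sigma / vs[1], sigma / vs[2]])
            H = _hessian(data, sigma_vox, vs, axes=(1, 2))
            hyy, hyx, hxx = H[(1, 1)], H[(1, 2)], H[(2, 2)]
            tr = hyy + hxx
            det = hyy * hxx - hyx**2
            disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
            eigs = _sort_by_abs(tr / 2 - disc, tr / 2 + disc)
        else:
            sigma_vox = sigma / vs
            H = _hessian(data, sigma_vox, vs, axes=(0, 1, 2))
            Hm = np.zeros(data.shape + (3, 3))
            for (a, b), val in H.items():
                Hm[..., a, b] = val
                Hm[..., b, a] = val
            lam = np.linalg.eigvalsh(Hm)
            eigs = _sort_by_abs(lam[..., 0], lam[..., 1], lam[..., 2])
        eigs *= sigma**2  # gamma-normalisation
        eigs_by_scale[sigma] = eigs
    if not eigs_by_scale:
        raise ValueError("no resolvable scales in the configured ladder")
    # the structureness scale c must be shared across scales, otherwise each
    # scale's response saturates relative to its own strongest structure and
    # the scale ladder loses its selectivity
    smax = math.sqrt(max(float((e**2).sum(axis=-1).max()) for e in eigs_by_scale.values()))
    ptp = float(np.ptp(data))
    if ptp == 0.0 or smax <= 1e-8 * ptp:
        # constant (or numerically constant) stack: zero Hessian everywhere
        return {s: np.zeros(data.shape) for s in eigs_by_scale}
    c = cfg.c if cfg.c is not None else 0.5 * smax
    return {
        s: _vesselness_from_eigs(e, cfg.alpha, cfg.beta, c)
        for s, e in eigs_by_scale.items()
    }


def scale_split_contrast(
    responses: dict[float, np.ndarray], cfg: FrangiConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise maximum projections over the thin and thick scale ranges.

    Thin: σ ≤ boundary; thick: σ > boundary.
    """
    cfg = cfg or FrangiConfig()
    thin_scales = [s for s in responses if s <= cfg.boundary]
    thick_scales = [s for s in responses if s > cfg.boundary]
    if not thin_scales:
        raise ValueError(f"no computed scales <= boundary {cfg.boundary} μm (thin range empty)")
    if not thick_scales:
        raise ValueError(f"no computed scales > boundary {cfg.boundary} μm (thick range empty)")
    thin = np.maximum.reduce([responses[s] for s in thin_scales])
    thick = np.maximum.reduce([responses[s] for s in thick_scales])
    return thin, thick


@dataclass
class RefineConfig:
    """How the vesselness contrasts binarise and split the intensity mask.

    Vesselness is a centreline detector: its response decays towards the
    tube surface, so an Otsu-style cut keeps only the core and halves the
    measured volume.  A low *support* threshold (fraction of the maximum
    response inside the region considered) marks the full cross-section
    instead.  ``exclusion_margin_um`` is the guard zone around the thick
    mask inside which no voxel may be called thin: bright thick-process
    rims produce spurious small-scale (edge) responses within roughly one
    PSF halo of the surface.
    """

    support_fraction: float = 0.05
    exclusion_margin_um: tuple[float, float, float] = (0.5, 0.4, 0.4)  # (z, y, x)

    def __post_init__(self) -> None:
        if not (0.0 < self.support_fraction < 1.0):
            raise ValueError("support_fraction must lie in (0, 1)")


def refine_segmentation(
    stack: ImageStack3D,
    intensity_mask: np.ndarray,
    thin_contrast: np.ndarray,
    thick_contrast: np.ndarray,
    cfg: RefineConfig | None = None,
) -> ProcessSegmentation:
    """Split the intensity mask into thick and thin processes.

    Thick: intensity-mask voxels with thick-range vesselness support.
    Thin: intensity-mask voxels outside a guard zone around the thick mask
    with thin-range vesselness support.  Thick wins everywhere inside the
    guard zone, so the masks are disjoint by construction.
    """
    cfg = cfg or RefineConfig()
    if not (intensity_mask.shape == thin_contrast.shape == thick_contrast.shape == stack.shape):
        raise ValueError("stack, mask and contrast volumes must share one shape")
    if not intensity_mask.any():
        warnings.warn("empty intensity mask; returning empty segmentation")
        empty = np.zeros_like(intensity_mask)
        return ProcessSegmentation(empty, empty.copy(), intensity_mask)
    thick_vals = thick_contrast[intensity_mask]
    thick_mask = intensity_mask & (
        thick_contrast >= cfg.support_fraction * thick_vals.max()
    ) if thick_vals.max() > 0 else np.zeros_like(intensity_mask)

    margin_vox = [
        2 * max(1, int(round(m / v))) + 1
        for m, v in zip(cfg.exclusion_margin_um, stack.voxel_size)
    ]
    guard = ndimage.binary_dilation(thick_mask, structure=np.ones(margin_vox, dtype=bool))
    roi = intensity_mask & ~guard
    thin_vals = thin_contrast[roi]
    if thin_vals.size and thin_vals.max() > 0:
        thin_mask = roi & (thin_contrast >= cfg.support_fraction * thin_vals.max())
    else:
        thin_mask = np.zeros_like(intensity_mask)
    return ProcessSegmentation(thick_mask, thin_mask, intensity_mask)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def _skeleton_voxels(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    return int(skeletonize(mask).sum())


def morphometry_summary(
    seg: ProcessSegmentation, voxel_size: tuple[float, float, float]
) -> MorphometrySummary:
    """Volume fractions and 3D medial-axis skeleton sizes (μm) per class."""
    total = float(seg.intensity_mask.size)
    pitch = 0.5 * (voxel_size[1] + voxel_size[2])
    sk_thick = _skeleton_voxels(seg.thick_mask)
    sk_thin = _skeleton_voxels(seg.thin_mask)
    return MorphometrySummary(
        vf_thick=float(seg.thick_mask.sum()) / total,
        vf_thin=float(seg.thin_mask.sum()) / total,
        skeleton_size_thick=sk_thick * pitch,
        skeleton_size_thin=sk_thin * pitch,
        skeleton_voxels_thick=sk_thick,
        skeleton_voxels_thin=sk_thin,
    )


def otsu3_thresholds(counts: np.ndarray, centers: np.ndarray) -> tuple[int, int]:
    """Exact 3-class Otsu on a histogram: exhaustive two-threshold search.

    Returns cut indices ``(i, j)``: class 0 = bins [0, i), class 1 = [i, j),
    class 2 = [j, nbins).  The pair maximising the between-class variance
    (equivalently Σ w_k μ_k², the total mean being fixed) is found by
    evaluating every admissible pair, vectorised via cumulative sums.
    """
    nbins = counts.size
    p = counts.astype(float) / counts.sum()
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * centers)])

    def term(a, b):  # w·μ² of bins [a, b) for index arrays a, b
        w = cw[b] - cw[a]
        m = cm[b] - cm[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(w > 0, m * m / np.maximum(w, 1e-300), 0.0)

    ii, jj = np.meshgrid(np.arange(1, nbins - 1), np.arange(2, nbins), indexing="ij")
    valid = jj > ii
    obj = term(np.zeros_like(ii), ii) + term(ii, jj) + term(jj, np.full_like(jj, nbins))
    obj = np.where(valid, obj, -np.inf)
    k = int(np.argmax(obj))
    return int(ii.ravel()[k]), int(jj.ravel()[k])


def otsu3_labels(stack: ImageStack3D, nbins: int = 256) -> IntensityClassMap:
    """Three-class Otsu split: background / dim thin / bright thick.

    Two thresholds maximise the between-class variance of the intensity
    histogram (exhaustive search over all threshold pairs); labels follow
    the threshold intervals.  Thresholds are reported as the bin edges at
    the cuts, and the label map is invariant to affine rescaling of the
    intensities.
    """
    data = np.asarray(stack.data, dtype=float)
    if np.unique(data).size < 3:
        raise ValueError("need at least 3 distinct intensity values for a 3-level Otsu")
    counts, edges = np.histogram(data, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    i, j = otsu3_thresholds(counts, centers)
    t1, t2 = float(edges[i]), float(edges[j])
    labels = np.digitize(data, [t1, t2]).astype(np.uint8)
    return IntensityClassMap(labels=labels, thresholds=(t1, t2))


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------

def run_gfap_pipeline(
    stack: ImageStack3D,
    hcfg: HysteresisConfig | None = None,
    fcfg: FrangiConfig | None = None,
    rcfg: RefineConfig | None = None,
) -> tuple[ProcessSegmentation, MorphometrySummary, dict]:
    """Full GFAP morphometry: noise → hysteresis → Frangi refine → summary.

    Returns the segmentation, the summary metrics, and a dict with the
    resolved intermediate quantities (noise sigma, background, thresholds).
    """
    hcfg = hcfg or HysteresisConfig()
    fcfg = fcfg or FrangiConfig()
    noise = estimate_noise_sd(stack)
    bg = estimate_background(stack)
    intensity_mask = hysteresis_segment(stack, noise, hcfg, background=bg)
    responses = frangi_response(stack, fcfg)
    thin_c, thick_c = scale_split_contrast(responses, fcfg)
    seg = refine_segmentation(stack, intensity_mask, thin_c, thick_c, rcfg)
    summary = morphometry_summary(seg, stack.voxel_size)
    details = {
        "noise_sigma": noise.sigma,
        "background": bg,
        "low_threshold": bg + hcfg.low_k * noise.sigma,
        "high_threshold": bg + hcfg.high_k * noise.sigma,
        "scales_um": list(responses.keys()),
    }
    return seg, summary, details
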