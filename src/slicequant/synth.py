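"""Ground-truthed synthetic data generators.

Three kinds of inputs are emulated, each with the statistical structure the
corresponding analysis stage assumes:

* GFAP-like stacks: filamentous astrocyte arbors with distinct thick
  (> 0.6 μm radius) and thin (0.1–0.6 μm) processes, rendered as capsules in
  physical μm space, blurred by a separable Gaussian PSF and degraded with
  additive Gaussian noise (optionally Poisson shot noise).
* EAAT2-like stacks: fields of roughly isotropic bright puncta ("clusters")
  of controlled diameter and areal density, a fraction of which are strung
  into contiguous chains that read out as ridges in curvature-based texture
  analysis.
* fPSP sweep series: paired-pulse field responses every 20 s with a
  controllable 20–80% rising slope, paired-pulse ratio, post-HFS
  potentiation factor, drift and noise.

Every generator is deterministic given its seed and returns the ground truth
alongside the data, so parameter recovery can be tested end to end.

Conventions: voxel indices are 0-based ``(z, y, x)``; the physical position
of voxel ``i`` along an axis with pitch ``d`` is ``i * d`` μm (voxel-center
coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack import ImageStack3D
from .sweeps import ProtocolSpec, Sweep, SweepSeries

__all__ = [
    "AstroSynthParams",
    "PunctaSynthParams",
    "FpspSynthParams",
    "GroundTruth",
    "gen_gfap_stack",
    "gen_eaat2_stack",
    "gen_fpsp_sweeps",
    "gen_group_values",
    "LOG_SIGMA_FACTOR",
]

# A Gaussian blob of standard deviation s is detected by a
# scale-normalised Laplacian-of-Gaussian at sigma = s, and its reported
# diameter is 2*sqrt(2)*sigma; blob "diameter" in this package always means
# that quantity, so the rendered Gaussian sd is diameter / LOG_SIGMA_FACTOR.
LOG_SIGMA_FACTOR = 2.0 * math.sqrt(2.0)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class AstroSynthParams:
    """Conditions for a synthetic GFAP-stained astrocyte arbor stack.

    Defaults emulate a high-NA confocal acquisition of the hippocampal
    neuropil: 0.1 μm in-plane pixels, 0.25 μm z-steps, lateral PSF sigma
    ~0.09 μm and axial ~0.25 μm, bright thick trunks and dimmer fine
    processes over a low background.
    """

    stack_shape: tuple[int, int, int] = (24, 160, 160)
    voxel_size: tuple[float, float, float] = (0.25, 0.1, 0.1)
    n_cells: int = 2
    thick_radius: float = 1.2  # μm, must exceed the 0.6 μm scale boundary
    thin_radius: float = 0.25  # μm, within (0, 0.6]
    n_thick_per_cell: int = 3
    n_thin_per_thick: int = 2
    thick_length: float = 5.0  # μm
    thin_length: float = 4.0  # μm
    psf_sigma: tuple[float, float, float] = (0.25, 0.09, 0.09)  # μm (z, y, x)
    noise_sd: float = 6.0
    background: float = 10.0
    fg_intensity_thick: float = 120.0
    fg_intensity_thin: float = 70.0
    poisson_gain: float | None = None  # photons per intensity unit; None = no shot noise
    seed: int = 0

    def validate(self) -> None:
        if len(self.stack_shape) != 3 or any(s < 8 for s in self.stack_shape):
            raise ValueError(f"stack_shape entries must all be >= 8, got {self.stack_shape}")
        if not (self.thick_radius > 0.6):
            raise ValueError(f"thick_radius must exceed 0.6 μm, got {self.thick_radius}")
        if not (0.0 < self.thin_radius <= 0.6):
            raise ValueError(f"thin_radius must lie in (0, 0.6] μm, got {self.thin_radius}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for r, name in ((self.thick_radius, "thick_radius"), (self.thin_radius, "thin_radius")):
            bad = [ax for ax, d in zip("zyx", self.voxel_size) if r < d]
            if bad:
                raise ValueError(
                    f"{name}={r} μm is below one voxel along axis(es) {','.join(bad)} "
                    f"(voxel_size={self.voxel_size}); the structure would be unresolvable"
                )


@dataclass
class PunctaSynthParams:
    """Conditions for a synthetic EAAT2-like punctate stack.

    Puncta are rendered as 2D Gaussians assigned to individual XY planes
    (matching the per-plane analysis), with diameters drawn from a truncated
    normal.  ``ridge_fraction`` of the blob budget is laid out as chains of
    overlapping puncta that form stringy ridge aggregates.
    """

    stack_shape: tuple[int, int, int] = (8, 256, 256)
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)
    cluster_density: float = 6.0  # clusters per 100 μm² per plane
    diameter_mean: float = 1.0  # μm
    diameter_sd: float = 0.1  # μm
    ridge_fraction: float = 0.0
    chain_length: int = 5  # puncta per ridge chain
    psf_sigma: tuple[float, float, float] = (0.0, 0.1, 0.1)  # μm
    noise_sd: float = 5.0
    background: float = 10.0
    fg_intensity: float = 100.0  # peak amplitude of a punctum before PSF blur
    isolation_factor: float = 2.0  # min centre distance = factor * (r_i + r_j)
    seed: int = 0

    def validate(self) -> None:
        if len(self.stack_shape) != 3 or any(s < 8 for s in self.stack_shape):
            raise ValueError(f"stack_shape entries must all be >= 8, got {self.stack_shape}")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be > 0")
        if self.cluster_density < 0:
            raise ValueError("cluster_density must be >= 0")
        if not (0.0 <= self.ridge_fraction <= 1.0):
            raise ValueError("ridge_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class FpspSynthParams:
    """Conditions for a synthetic paired-pulse fPSP recording session.

    Paired stimuli 50 ms apart every 20 s; a 20-min baseline, an HFS episode
    (3 × 100 pulses at 100 Hz, 20 s apart), then 60 min of potentiated
    responses.  The fPSP is a negative-going dual-exponential (1 ms rise,
    8 ms decay) whose amplitude is set so that the 20–80% chord slope of the
    rising phase equals ``baseline_slope``.
    """

    sampling_rate: float = 10_000.0  # Hz
    sweep_period: float = 20.0  # s
    isi: float = 50.0  # ms
    pulse_width: float = 0.1  # ms
    baseline_slope: float = 0.15  # mV/ms, magnitude of the negative rising slope
    ppr_true: float = 1.42
    potentiation: float = 1.5
    hfs_time: float = 20.0  # min from recording start, onset of first train
    record_pre: float = 20.0  # min
    record_post: float = 60.0  # min
    noise_sd: float = 0.01  # mV
    drift_per_min: float = 0.0  # fractional slope drift per minute
    tau_rise: float = 1.0  # ms
    tau_decay: float = 8.0  # ms
    onset_latency: float = 2.0  # ms from stimulus to response onset
    sweep_duration: float = 0.3  # s
    stim1_time: float = 0.05  # s within sweep
    artifact_amp: float = 5.0  # mV
    seed: int = 0

    def validate(self) -> None:
        if self.potentiation <= 0:
            raise ValueError("potentiation must be > 0")
        if self.record_pre < 10:
            raise ValueError("record_pre must be >= 10 min so the baseline window fits")
        if self.isi <= 0:
            raise ValueError("isi must be > 0")
        if self.hfs_time > self.record_pre or self.hfs_time < 0:
            raise ValueError(
                f"hfs_time={self.hfs_time} min is outside the recorded pre-HFS span "
                f"(0–{self.record_pre} min)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    thick_mask: np.ndarray | None = None
    thin_mask: np.ndarray | None = None
    true_vf_thick: float | None = None
    true_vf_thin: float | None = None
    # blobs: rows of (plane_index, y_um, x_um, diameter_um, is_chain_member)
    blob_list: list[tuple[int, float, float, float, bool]] = field(default_factory=list)
    true_mean_diameter: float | None = None
    true_density: float | None = None  # per 100 μm² per plane
    true_ltp: float | None = None
    true_ppr: float | None = None


# --------------------------------------------------------------------------
# GFAP arbor stacks
# --------------------------------------------------------------------------

def _rasterize_capsule(
    mask: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
    voxel_size: Sequence[float],
) -> None:
    """Set voxels whose centre lies within ``radius`` μm of segment p0–p1."""
    vs = np.asarray(voxel_size, dtype=float)
    lo_um = np.minimum(p0, p1) - radius
    hi_um = np.maximum(p0, p1) + radius
    lo = np.maximum(np.floor(lo_um / vs).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / vs).astype(int) + 1, np.asarray(mask.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(lo[a], hi[a]) * vs[a] for a in range(3)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)  # (...,3) voxel centres in μm
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
        nearest = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - nearest, axis=-1)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= dist <= radius


def _unit_vector(rng: np.random.Generator, z_damp: float = 0.3) -> np.ndarray:
    """Random direction with the z component damped (thin optical sections)."""
    v = rng.standard_normal(3)
    v[0] *= z_damp
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([0.0, 1.0, 0.0])
    return v / n


def _apply_noise(
    img: np.ndarray, noise_sd: float, poisson_gain: float | None, rng: np.random.Generator
) -> np.ndarray:
    if poisson_gain is not None and poisson_gain > 0:
        img = rng.poisson(np.maximum(img, 0.0) * poisson_gain) / poisson_gain
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def gen_gfap_stack(params: AstroSynthParams) -> tuple[ImageStack3D, GroundTruth]:
    """Render a synthetic astrocyte-arbor stack plus its ground-truth masks.

    Each cell contributes ``n_thick_per_cell`` thick trunks radiating from a
    soma point and ``n_thin_per_thick`` thin branches continuing from each
    trunk tip.  Masks are the pre-blur capsule rasterisations; where thick
    and thin overlap (junctions) the voxel counts as thick.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.stack_shape)
    vs = np.asarray(params.voxel_size, dtype=float)
    extent = (np.asarray(shape) - 1) * vs  # physical span, μm

    thick = np.zeros(shape, dtype=bool)
    thin = np.zeros(shape, dtype=bool)
    for _ in range(params.n_cells):
        soma = rng.uniform(0.2, 0.8, size=3) * extent
        for _ in range(params.n_thick_per_cell):
            d0 = _unit_vector(rng)
            length = params.thick_length * rng.uniform(0.8, 1.2)
            tip = soma + d0 * length
            _rasterize_capsule(thick, soma, tip, params.thick_radius, vs)
            for _ in range(params.n_thin_per_thick):
                # deflect the trunk direction by 20–70 degrees
                ang = np.deg2rad(rng.uniform(20, 70))
                perp = np.cross(d0, _unit_vector(rng, z_damp=1.0))
                nperp = np.linalg.norm(perp)
                perp = perp / nperp if nperp > 0 else np.array([0.0, 0.0, 1.0])
                d1 = d0 * np.cos(ang) + perp * np.sin(ang)
                d1[0] *= 0.3  # keep branches mostly in-plane
                d1 /= np.linalg.norm(d1)
                tlen = params.thin_length * rng.uniform(0.8, 1.2)
                _rasterize_capsule(thin, tip, tip + d1 * tlen, params.thin_radius, vs)
    thin &= ~thick

    img = np.full(shape, float(params.background))
    img[thin] = params.fg_intensity_thin
    img[thick] = params.fg_intensity_thick
    sigma_vox = np.asarray(params.psf_sigma) / vs
    if np.any(sigma_vox > 0):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    img = _apply_noise(img, params.noise_sd, params.poisson_gain, rng)

    total = float(np.prod(shape))
    truth = GroundTruth(
        thick_mask=thick,
        thin_mask=thin,
        true_vf_thick=float(thick.sum()) / total,
        true_vf_thin=float(thin.sum()) / total,
    )
    stack = ImageStack3D(img, tuple(vs), channel_label="GFAP-synthetic")
    return stack, truth


# --------------------------------------------------------------------------
# EAAT2 puncta stacks
# --------------------------------------------------------------------------

def gen_eaat2_stack(params: PunctaSynthParams) -> tuple[ImageStack3D, GroundTruth]:
    """Render a synthetic punctate stack plus per-blob ground truth.

    Isolated puncta are rejection-sampled so that no two centres in a plane
    are closer than ``isolation_factor * (r_i + r_j)``.  Chain puncta (ridge
    aggregates) are spaced 0.7 diameters apart along a random direction and
    exempt from the isolation rule within their own chain.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.stack_shape
    dz, dy, dx = params.voxel_size
    width_um, height_um = nx * dx, ny * dy
    plane_area = width_um * height_um
    n_per_plane = int(round(params.cluster_density * plane_area / 100.0))

    margin = params.diameter_mean  # keep blobs off the image edge
    img = np.full(params.stack_shape, float(params.background))
    blobs: list[tuple[int, float, float, float, bool]] = []

    feasible_max = 100.0 * 0.25 / max(
        (params.isolation_factor * params.diameter_mean) ** 2, 1e-12
    )
    for z in range(nz):
        n_chain = int(round(params.ridge_fraction * n_per_plane))
        n_chains = n_chain // max(params.chain_length, 1)
        n_iso = n_per_plane - n_chains * params.chain_length
        placed: list[tuple[float, float, float]] = []  # (y, x, r)

        def _ok(y: float, x: float, r: float) -> bool:
            return all(
                math.hypot(y - py, x - px) >= params.isolation_factor * (r + pr)
                for py, px, pr in placed
            )

        def _draw_diameter() -> float:
            while True:
                d = rng.normal(params.diameter_mean, params.diameter_sd)
                if d > 0:
                    return d

        for _ in range(n_iso):
            diam = _draw_diameter()
            for attempt in range(400):
                y = rng.uniform(margin, height_um - margin)
                x = rng.uniform(margin, width_um - margin)
                if _ok(y, x, diam / 2):
                    break
            else:
                raise ValueError(
                    f"cluster_density={params.cluster_density}/100 μm² is too high to "
                    f"place non-overlapping isolated puncta; feasible maximum is about "
                    f"{feasible_max:.1f}/100 μm² at diameter {params.diameter_mean} μm"
                )
            placed.append((y, x, diam / 2))
            blobs.append((z, y, x, diam, False))
        for _ in range(n_chains):
            diam = _draw_diameter()
            step = 0.7 * diam
            span = step * (params.chain_length - 1)
            for attempt in range(400):
                y0 = rng.uniform(margin + span, height_um - margin - span)
                x0 = rng.uniform(margin + span, width_um - margin - span)
                theta = rng.uniform(0, 2 * np.pi)
                pts = [
                    (y0 + k * step * math.sin(theta), x0 + k * step * math.cos(theta))
                    for k in range(params.chain_length)
                ]
                # the whole chain must clear previously placed structures
                if all(_ok(y, x, diam / 2) for y, x in pts):
                    break
            else:
                raise ValueError(
                    f"cluster_density={params.cluster_density}/100 μm² with "
                    f"ridge_fraction={params.ridge_fraction} is too crowded for "
                    f"non-overlapping chains; feasible maximum is about "
                    f"{feasible_max:.1f}/100 μm²"
                )
            for y, x in pts:
                placed.append((y, x, diam / 2))
                blobs.append((z, y, x, diam, True))

    # render: 2D Gaussian per punctum in its own plane
    yy = np.arange(ny) * dy
    xx = np.arange(nx) * dx
    for z, y, x, diam, _chain in blobs:
        s = diam / LOG_SIGMA_FACTOR
        half = 4.0 * s
        iy0, iy1 = max(int((y - half) / dy), 0), min(int((y + half) / dy) + 2, ny)
        ix0, ix1 = max(int((x - half) / dx), 0), min(int((x + half) / dx) + 2, nx)
        gy = np.exp(-((yy[iy0:iy1] - y) ** 2) / (2 * s * s))
        gx = np.exp(-((xx[ix0:ix1] - x) ** 2) / (2 * s * s))
        img[z, iy0:iy1, ix0:ix1] += params.fg_intensity * np.outer(gy, gx)

    sz, sy, sx = np.asarray(params.psf_sigma) / np.asarray(params.voxel_size)
    if sy > 0 or sx > 0:
        for z in range(nz):
            img[z] = ndimage.gaussian_filter(img[z], sigma=(sy, sx), mode="nearest")
    if sz > 0:
        img = ndimage.gaussian_filter1d(img, sigma=sz, axis=0, mode="nearest")
    img = _apply_noise(img, params.noise_sd, None, rng)

    diams = [b[3] for b in blobs]
    truth = GroundTruth(
        blob_list=blobs,
        true_mean_diameter=float(np.mean(diams)) if diams else None,
        true_density=len(blobs) / (nz * plane_area) * 100.0,
    )
    stack = ImageStack3D(img, tuple(params.voxel_size), channel_label="EAAT2-synthetic")
    return stack, truth


# --------------------------------------------------------------------------
# fPSP sweep series
# --------------------------------------------------------------------------

def _dual_exp_unit(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Dual-exponential synaptic waveform, peak-normalised to 1, zero for t<0."""
    w = np.where(
        t_ms >= 0,
        np.exp(-np.maximum(t_ms, 0.0) / tau_decay) - np.exp(-np.maximum(t_ms, 0.0) / tau_rise),
        0.0,
    )
    t_peak = (
        tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    )
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return w / peak


def _chord_slope_unit(params: FpspSynthParams) -> float:
    """20–80% chord slope (1/ms) of the unit waveform's rising phase."""
    dt_ms = 1e3 / params.sampling_rate
    t = np.arange(0.0, 6.0 * params.tau_decay, dt_ms)
    w = _dual_exp_unit(t, params.tau_rise, params.tau_decay)
    ipk = int(np.argmax(w))
    rise = w[: ipk + 1]
    t20 = np.interp(0.2, rise, t[: ipk + 1])
    t80 = np.interp(0.8, rise, t[: ipk + 1])
    return 0.6 / (t80 - t20)


def gen_fpsp_sweeps(params: FpspSynthParams) -> tuple[SweepSeries, GroundTruth]:
    """Simulate a full LTP session of paired-pulse sweeps.

    Sweeps are emitted every ``sweep_period`` s during the baseline and the
    post-HFS hour; no test sweeps are emitted while the HFS trains run.
    Post-HFS responses are scaled by ``potentiation``; the second pulse of
    every pair is scaled by ``ppr_true``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    proto = ProtocolSpec()
    n_samp = int(round(params.sweep_duration * params.sampling_rate))
    t_ms = np.arange(n_samp) * 1e3 / params.sampling_rate  # ms within sweep
    stim1_ms = params.stim1_time * 1e3
    stim2_ms = stim1_ms + params.isi

    chord = _chord_slope_unit(params)  # 1/ms for the unit waveform
    amp = params.baseline_slope / chord  # mV; waveform applied negative-going

    resp1 = _dual_exp_unit(t_ms - stim1_ms - params.onset_latency, params.tau_rise, params.tau_decay)
    resp2 = _dual_exp_unit(t_ms - stim2_ms - params.onset_latency, params.tau_rise, params.tau_decay)
    artifact = np.zeros(n_samp)
    for s_ms in (stim1_ms, stim2_ms):
        i0 = int(round(s_ms * params.sampling_rate / 1e3))
        i1 = max(i0 + 1, int(round((s_ms + params.pulse_width) * params.sampling_rate / 1e3)))
        artifact[i0:i1] = params.artifact_amp
        if i1 < n_samp:
            artifact[i1] = -0.4 * params.artifact_amp

    hfs_start = params.hfs_time * 60.0
    hfs_end = hfs_start + proto.total_duration
    t0s = [t for t in np.arange(0.0, hfs_start - params.sweep_duration, params.sweep_period)]
    first_post = math.ceil(hfs_end / params.sweep_period) * params.sweep_period
    t0s += list(np.arange(first_post, hfs_end + params.record_post * 60.0, params.sweep_period))

    sweeps = []
    for t0 in t0s:
        scale = params.potentiation if t0 >= hfs_end else 1.0
        scale *= 1.0 + params.drift_per_min * (t0 / 60.0)
        v = artifact - amp * scale * (resp1 + params.ppr_true * resp2)
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=n_samp)
        sweeps.append(
            Sweep(
                samples=v,
                sampling_rate=params.sampling_rate,
                t0=float(t0),
                stim_times=(params.stim1_time, params.stim1_time + params.isi / 1e3),
                isi=params.isi,
                pulse_width=params.pulse_width,
            )
        )
    series = SweepSeries(sweeps, hfs_time=hfs_start, protocol=proto)
    truth = GroundTruth(true_ltp=params.potentiation, true_ppr=params.ppr_true)
    return series, truth


# --------------------------------------------------------------------------
# summary-statistic group fixtures
# --------------------------------------------------------------------------

def gen_group_values(
    mean: float, sem: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` values from N(mean, (sem·√n)²), i.e. with population SEM ``sem``."""
    if n < 2:
        raise ValueError(f"need n >= 2 values, got n={n}")
    if sem < 0:
        raise ValueError("sem must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(mean, sem * math.sqrt(n), size=n)
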