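# Methods

This note documents the models, estimators and numerical choices behind each
pipeline, what the synthetic generators do and do not emulate, and the known
limitations.

## GFAP astrocyte morphometry (`slicequant.gfap`)

**Noise floor.** The acquisition noise SD is estimated as
σ = 1.4826·MAD(Δx)/√2, the scaled median absolute deviation of first
differences along the fastest axis. First differences cancel smooth
structure; the MAD ignores the sparse bright voxels, so the estimate is
robust to a few percent of structured signal (tested against a trimmed-SD
reference with 1% of voxels at 50σ). A constant stack yields σ = 0 with a
degenerate flag; segmentation then requires explicit thresholds.

**Background.** The histogram mode of the stack (256 bins). Thresholds are
applied above background, since stains sit on a nonzero offset and the
3σ/5σ rule is only meaningful relative to the noise floor around it.

**Intensity segmentation.** Hysteresis thresholding: a voxel is foreground
iff it is ≥ background + 3σ and 26-connected through such voxels to at least
one voxel ≥ background + 5σ. Implemented by full-connectivity component
labelling; equivalence with a breadth-first flood fill from the ≥5σ seeds is
asserted exhaustively on randomized small volumes in the test suite.

**Vesselness refinement.** Frangi vesselness is computed per scale σ (in μm)
from the Hessian of the Gaussian-smoothed volume, with per-axis smoothing
sigmas σ/voxel_size so anisotropic calibrations are handled natively, and
γ = 2 scale normalisation (eigenvalues multiplied by σ²). Sensitivity
parameters: α = 0.5, β = 0.5, c = half the maximum Hessian norm per scale,
bright-on-dark polarity. The scale ladder is 6 geometric steps over
0.1–1.2 μm; responses are max-projected within the thin (≤ 0.6 μm) and thick
(> 0.6 μm) ranges. Scales below half the z voxel fall back to an in-plane 2D
Hessian (logged); scales below half the in-plane pitch are skipped (logged).
Note the matched scale of a solid tube of radius r is ≈ r/√3 (flat-top
profiles read as narrower Gaussians), so the 0.6 μm boundary separates
processes of radius roughly above/below 1 μm.

**Class assignment.** Vesselness is a centreline detector: its response
decays towards the tube surface, so binarising it at an Otsu-style cut keeps
only the core and systematically halves the measured volume. Instead, each
contrast is binarised at a low *support* threshold (5% of its maximum within
the region considered), which marks the full cross-section, and the masks
are formed as:

* thick = intensity mask ∧ thick-range support;
* thin = intensity mask ∧ thin-range support, excluding a guard zone
  (thick mask dilated by ~one PSF halo: 0.5 μm axially, 0.4 μm in-plane).

The guard zone exists because bright thick-process rims produce spurious
small-scale (edge) responses: without it, thin volume is overestimated
3–6-fold on synthetic arbors. Both parameters are exposed in `RefineConfig`.
With the defaults, synthetic arbors at realistic SNR recover vf_thick within
±7% and vf_thin within ±18% relative error across seeds.

**Summaries.** Volume fraction = mask voxels / total voxels. Skeleton size =
3D medial-axis (Lee) skeleton voxel count × mean in-plane pitch, with the raw
voxel count also reported; on straight tubes the μm length matches the
centreline length within 15%.

**Three-level Otsu.** The two thresholds maximise the between-class variance
of the 256-bin intensity histogram, found by exhaustive vectorised search
over all threshold pairs (the search is exact by construction; the label map
is invariant to affine intensity rescaling). Classes read as background /
dim thin / bright thick, exploiting the correlation of process calibre with
stain brightness.

## EAAT2 texture analysis (`slicequant.eaat2`)

All analysis is strictly per XY plane; transporter clusters have no
resolvable 3D morphology at these scales.

**Cluster detection.** Scale-normalised LoG: R(σ) = −σ²∇²(G_σ ∗ I),
assembled from per-axis second derivatives so anisotropic pixels are
supported. Detections are strict 3×3×3 local maxima of the (σ, y, x) cube
above `rel_threshold` (default 0.15) of the cube maximum, pruned so that no
two detections lie closer than the mean radius of the pair (stronger wins).
The ladder is 16 geometric steps over σ = 0.2–2.0 μm; the reported scale is
refined between ladder steps by log-parabolic interpolation of the response
(positions stay on the pixel grid, preserving exact equivalence with a
discrete grid argmax, which the tests assert). Cluster diameter = 2√2·σ_opt,
the diameter at which a Gaussian blob of sd σ maximises the response.
Diameters carry a small positive bias of order (PSF/σ)² (~4% at 1 μm
clusters with a 0.1 μm lateral PSF); it is common-mode across conditions and
does not affect group contrasts, and no deconvolution is attempted.

**Shape index.** SI = (2/π)·arctan2(κ₁+κ₂, κ₁−κ₂) from eigenvalues
κ₁ ≥ κ₂ of the negated Hessian of the smoothed plane (default smoothing
0.2 μm), fixing the sign convention so a bright peak maps to +1, a bright
straight ridge crest to +1/2 and a saddle to 0 (this matches
`skimage.feature.shape_index`). Pixels whose Hessian Frobenius norm is below
10⁻⁶ of the plane's intensity range are flagged undefined rather than
reported as 0. Derivative kernels use an 8σ truncation: the default
truncated second-derivative kernel does not sum exactly to zero, which
otherwise shifts SI off its analytic values on flat axes.

**Classification and summaries.** Within the stain-positive foreground
(per-plane 2D hysteresis with the same 3σ/5σ rule), caps are SI ∈ [7/8, 1]
and ridges SI ∈ [3/8, 5/8] — the canonical shape-index category bounds,
config-exposed. Cluster density (per 100 μm², averaged over planes) counts
detections whose centre lies on the foreground; relative brightness and
relative area are normalised to foreground pixels, not the whole plane, so
empty-field fraction does not dilute them. The ends of a punctum chain are
genuinely cap-shaped (curvature along the chain does not vanish there), so
classification quality is asserted on chain interiors.

## Field-potential quantification (`slicequant.ephys`)

**Waveform model (generator).** fPSPs are negative-going dual exponentials
(τ_rise = 1 ms, τ_decay = 8 ms, 2 ms onset latency) whose amplitude is set so
the 20–80% chord slope of the rising phase equals the requested slope;
paired stimuli 50 ms apart every 20 s, a brief rectangular stimulus
artifact, optional additive Gaussian noise and linear drift. The default
noise of 0.01 mV against a ~0.2 mV response (SNR ≈ 20) reflects a clean
extracellular recording.

**Slope.** After 1.5 ms artifact blanking, the response extremum within
20 ms of the stimulus is located on a 0.3 ms Gaussian-smoothed copy of the
trace; its amplitude is the mean over ±0.3 ms around the extremum (the raw
maximum of a noisy trace is biased away from zero). The fit window is the
contiguous run of rising-phase samples, ending at the peak, whose smoothed
value lies between 20% and 80% of the amplitude; the slope is the least
squares line through the *raw* samples in that window. Band membership was
chosen over first-crossing times because crossing estimates are
noise-biased: with crossing-based windows the recovered LTP ratio was
inflated ~9% at 10% noise, versus ≤1.5% with the band (and both are exact on
noiseless input, since every step is linear or window-selection and windows
are scale-invariant). Sweeps with no peak above 5× the pre-stimulus SD raise
an error and are logged and excluded downstream, never imputed.

**Paired-pulse ratio.** Amplitude₂/amplitude₁, after subtracting the
extrapolated single-exponential decay of response 1 (log-linear fit over the
20 ms tail preceding pulse 2, applied only when an un-decayed tail is
actually present). The correction is switchable; the ratio is invariant to
scaling the sweep by any positive constant.

**LTP.** Slopes are normalised by the mean magnitude over the final 10 min
before HFS onset (so the baseline-window mean is exactly 1); sweeps
overlapping the trains (3 × 100 pulses at 100 Hz, 20 s apart) are excluded;
post-HFS times are measured from the end of the last train. The LTP value is
the mean normalised slope over [50, 60) min. At least 10 baseline minutes
and 60 post-HFS minutes are required, else an error names the missing span.

## Statistics (`slicequant.stats`)

**Dixon's Q.** Classic r10 ratio, two-sided: Q = max(gap at either extreme)
/ range, the suspect being the extreme with the larger gap; one value at
most is flagged per call (single-pass convention), for 3 ≤ n ≤ 30. Critical
values are *not* transcribed from published tables: they are the empirical
confidence-level quantile of Q over 2×10⁵ seeded standard-normal Monte-Carlo
samples per (n, confidence), cached per process. By construction the null
flag rate equals 1 − confidence up to Monte-Carlo error (verified at 10% ±
1% for n ∈ {4, 6, 8}); independent seeds reproduce the critical values
within 0.005.

**Summary t.** t = (m₁ − m₂)/√(sem₁² + sem₂²) with Welch–Satterthwaite
degrees of freedom (the unpooled form; the pooled Student form is available
and coincides for equal n). Published t values are reproducible only up to
the rounding of the printed means/SEMs, so the acceptance check brackets the
achievable t interval under half-ulp input perturbations.

## Synthetic generators (`slicequant.synth`)

What they emulate: capsule-rasterised arbors with distinct thick
(default radius 1.2 μm — thick enough that the matched vesselness scale
exceeds the 0.6 μm boundary, and realistic for primary processes) and thin
(0.25 μm) processes; separable Gaussian PSF (0.25 μm axial, 0.09 μm lateral
by default) with additive Gaussian noise and optional Poisson shot noise;
punctate fields with truncated-normal diameters, rejection-sampled isolation
and optional chains of overlapping puncta; full LTP sessions with HFS
bookkeeping. Coordinates are voxel-centre μm, (z, y, x), 0-based.

What they do not emulate: realistic arbor branching statistics, spectral
bleed-through, depth-dependent attenuation, detector offset drift, Airy-disk
side lobes, or axial placement of puncta between planes (each punctum
belongs to exactly one plane, matching the strictly per-plane analysis).
Passing recovery tests therefore demonstrates correctness of the estimators
under a controlled forward model, not robustness to every acquisition
artifact of real microscopes and rigs.

Problem sizes used by the test and acceptance runs — 24×160×160 voxel
arbor stacks, 8×256×256 puncta stacks, 240-sweep sessions, 10⁵-sample null
simulations — were chosen so a full run completes comfortably on a single
CPU while leaving every estimator in its intended operating regime.

## Known limitations

* Volume fractions inherit the PSF halo of the 3σ intensity cut (~+25% on
  raw masks); the vesselness support threshold compensates on tubes but the
  guard zone slightly truncates thin branches at junctions (thin vf biased
  a few percent low).
* The LoG diameter is the scale-space optimum for Gaussian-shaped clusters;
  irregular or hollow clusters will read differently.
* The shape-index bins are the canonical ones; histology with different
  contrast statistics may warrant retuning `cap_lo`/`ridge_lo`/`ridge_hi`.
* Dixon critical values assume normality of the null sample, as the test
  itself does.
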