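"""Field-potential quantification: fPSP slope, paired-pulse ratio, LTP.

A session is paired-pulse sweeps every 20 s around one high-frequency
stimulation (HFS).  Per sweep, the initial slope of the (negative-going)
field response is the linear least-squares fit over the 20–80% span of its
rising phase; the paired-pulse ratio (PPR) is the second amplitude over the
first, after subtracting the extrapolated single-exponential decay of the
first response.  The LTP timecourse normalises slopes by the mean over the
final 10 baseline minutes, and the LTP value is the mean normalised slope
50–60 min after the end of the HFS trains.

Sweeps where no response can be measured (noise-only, peak missing within
20 ms of the stimulus) raise :class:`SweepMeasurementError`; the timecourse
logs and excludes them rather than imputing values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sweeps import Sweep, SweepSeries

__all__ = [
    "SlopeConfig",
    "SlopeResult",
    "TimecourseResult",
    "SweepMeasurementError",
    "measure_fpsp_slope",
    "paired_pulse_ratio",
    "ltp_timecourse",
    "ltp_value",
]

logger = logging.getLogger(__name__)


class SweepMeasurementError(RuntimeError):
    """Raised when a sweep has no measurable response."""


def _smooth(x: np.ndarray, sigma_samples: float) -> np.ndarray:
    if sigma_samples <= 0:
        return x
    return ndimage.gaussian_filter1d(x, sigma_samples, mode="nearest")


@dataclass
class SlopeConfig:
    blank_ms: float = 1.5  # stimulus-artifact blanking after each pulse
    smooth_ms: float = 0.3  # Gaussian smoothing used only to locate peak/onset/fit window
    search_ms: float = 20.0  # peak must occur within this window post-stimulus
    lo_frac: float = 0.2  # rising-phase fit window, fractions of peak
    hi_frac: float = 0.8
    baseline_ms: float = 10.0  # pre-stimulus segment used for baseline and SD
    onset_k: float = 3.0  # onset = first sustained excursion > onset_k × pre-stim SD
    min_peak_k: float = 5.0  # peak must exceed this × pre-stim SD to count
    decay_correction: bool = True  # subtract response-1 decay under response 2
    decay_fit_ms: float = 20.0  # tail window fitted before pulse 2


@dataclass
class SlopeResult:
    """Signed slope (mV/ms) plus fit diagnostics; ``magnitude`` is reported."""

    slope: float
    t20_ms: float
    t80_ms: float
    n_fit: int
    peak_mv: float  # signed, baseline-subtracted

    @property
    def magnitude(self) -> float:
        return abs(self.slope)


def _baseline_stats(sweep: Sweep, cfg: SlopeConfig) -> tuple[float, float]:
    """Mean and SD of the pre-stimulus segment (before the first pulse)."""
    i_stim = int(round(sweep.stim_times[0] * sweep.sampling_rate))
    i0 = max(0, i_stim - int(round(cfg.baseline_ms * 1e-3 * sweep.sampling_rate)))
    i1 = max(i0 + 1, i_stim - 1)
    seg = sweep.samples[i0:i1]
    return float(seg.mean()), float(seg.std())


def _response_window(sweep: Sweep, stim_index: int, cfg: SlopeConfig) -> tuple[int, int]:
    fs = sweep.sampling_rate
    t_stim = sweep.stim_times[stim_index]
    i0 = int(round((t_stim + cfg.blank_ms * 1e-3) * fs))
    t_end = t_stim + cfg.search_ms * 1e-3
    if stim_index + 1 < len(sweep.stim_times):
        t_end = min(t_end, sweep.stim_times[stim_index + 1])
    i1 = min(int(round(t_end * fs)), sweep.samples.size)
    if i1 - i0 < 4:
        raise SweepMeasurementError("response window after blanking is too short")
    return i0, i1


def measure_fpsp_slope(
    sweep: Sweep, stim_index: int = 0, cfg: SlopeConfig | None = None
) -> SlopeResult:
    """Slope of the fPSP rising phase after the given stimulus.

    The extremum within 20 ms of the stimulus (after 1.5 ms artifact
    blanking) defines the peak; the fit covers samples between the 20% and
    80% crossings of the rising phase, with crossing times interpolated.
    """
    cfg = cfg or SlopeConfig()
    fs = sweep.sampling_rate
    base, sd = _baseline_stats(sweep, cfg)
    i0, i1 = _response_window(sweep, stim_index, cfg)
    sig = sweep.samples[i0:i1] - base
    # peak, onset and fit window are located on a lightly smoothed copy so
    # that single noisy samples do not steer the measurement; the fit itself
    # uses the raw samples
    det = _smooth(sig, cfg.smooth_ms * 1e-3 * fs)
    ipk = int(np.argmax(np.abs(det)))
    vpk = _peak_amplitude(det, ipk, fs)
    if abs(vpk) <= max(cfg.min_peak_k * sd, 1e-12):
        raise SweepMeasurementError(
            f"no response peak above {cfg.min_peak_k}× the pre-stimulus SD within "
            f"{cfg.search_ms} ms of stimulus {stim_index}"
        )
    # fit window: the contiguous run of rising-phase samples, ending at the
    # peak, whose smoothed value lies in the 20-80% amplitude band.  Band
    # membership is far less noise-sensitive than first-crossing times.
    sgn = math.copysign(1.0, vpk)
    excur = sgn * det[: ipk + 1]
    lo, hi = cfg.lo_frac * abs(vpk), cfg.hi_frac * abs(vpk)
    band = np.nonzero((excur >= lo) & (excur <= hi))[0]
    if band.size == 0:
        raise SweepMeasurementError("rising phase never spans the fit band")
    splits = np.nonzero(np.diff(band) > 1)[0]
    if splits.size:  # keep the run adjacent to the peak
        band = band[splits[-1] + 1 :]
    dt_ms = 1e3 / fs
    if band.size >= 2:
        t_ms = band * dt_ms
        slope = float(np.polyfit(t_ms, sig[band], 1)[0])
        n_fit = int(band.size)
    else:  # band narrower than one sample: chord across it on the smoothed trace
        j = band[0]
        j0 = max(0, j - 1)
        slope = float(det[j] - det[j0]) / ((j - j0) * dt_ms) if j > j0 else 0.0
        if slope == 0.0:
            raise SweepMeasurementError("rising phase too short to fit a slope")
        n_fit = 1
    return SlopeResult(
        slope=slope,
        t20_ms=(i0 + band[0]) * dt_ms - sweep.stim_times[stim_index] * 1e3,
        t80_ms=(i0 + band[-1]) * dt_ms - sweep.stim_times[stim_index] * 1e3,
        n_fit=n_fit,
        peak_mv=vpk,
    )


def _peak_amplitude(det: np.ndarray, ipk: int, fs: float, half_ms: float = 0.3) -> float:
    """Amplitude as the mean around the extremum, not the single max sample.

    The maximum of a noisy trace is biased away from zero; averaging ±0.3 ms
    around the located extremum removes most of that selection bias.
    """
    h = max(1, int(round(half_ms * 1e-3 * fs)))
    lo, hi = max(0, ipk - h), min(det.size, ipk + h + 1)
    return float(det[lo:hi].mean())


def _amplitude(sig: np.ndarray, fs: float) -> tuple[float, int]:
    i = int(np.argmax(np.abs(sig)))
    return _peak_amplitude(sig, i, fs), i


def paired_pulse_ratio(sweep: Sweep, cfg: SlopeConfig | None = None) -> float:
    """Amplitude ratio (second / first) of a paired-pulse sweep.

    The second amplitude is measured after subtracting the extrapolated
    single-exponential decay of the first response, fitted over the
    ``decay_fit_ms`` tail preceding the second pulse.  Disable with
    ``cfg.decay_correction = False``.
    """
    cfg = cfg or SlopeConfig()
    if len(sweep.stim_times) < 2:
        raise ValueError("paired-pulse ratio requires two stimuli in the sweep")
    fs = sweep.sampling_rate
    base, sd = _baseline_stats(sweep, cfg)
    sig = sweep.samples - base

    det = _smooth(sig, cfg.smooth_ms * 1e-3 * fs)
    a0, b0 = _response_window(sweep, 0, cfg)
    amp1, ipk1 = _amplitude(det[a0:b0], fs)
    if abs(amp1) <= max(cfg.min_peak_k * sd, 1e-12):
        raise SweepMeasurementError("first response amplitude is indistinguishable from 0")

    a1, b1 = _response_window(sweep, 1, cfg)
    sig2 = det[a1:b1].copy()
    if cfg.decay_correction:
        i_stim2 = int(round(sweep.stim_times[1] * fs))
        j0 = max(a0 + ipk1 + 1, i_stim2 - int(round(cfg.decay_fit_ms * 1e-3 * fs)))
        j1 = i_stim2 - 1
        tail = det[j0:j1]
        sgn = math.copysign(1.0, amp1)
        y = sgn * tail
        good = y > max(3.0 * sd, 1e-3 * abs(amp1))
        if good.sum() >= 4:  # enough un-decayed tail to matter and to fit
            t = np.arange(j0, j1)[good] / fs * 1e3  # ms
            coef = np.polyfit(t, np.log(y[good]), 1)
            k, logA = coef[0], coef[1]
            if k < 0:  # only subtract a genuine decay
                t2 = np.arange(a1, b1) / fs * 1e3
                sig2 = sig2 - sgn * np.exp(logA + k * t2)
    amp2, _ = _amplitude(sig2, fs)
    return abs(amp2) / abs(amp1)


@dataclass
class TimecourseResult:
    """Normalised slope timecourse around one HFS induction."""

    times: np.ndarray  # min; < 0 relative to HFS onset, >= 0 relative to train end
    norm_slopes: np.ndarray
    ppr_series: np.ndarray  # NaN where the PPR could not be measured
    baseline_window: tuple[float, float] = (-10.0, 0.0)
    ltp_window: tuple[float, float] = (50.0, 60.0)
    baseline_slope: float = float("nan")  # mV/ms, mean magnitude over the baseline window
    n_excluded: int = 0

    @property
    def ltp_value(self) -> float:
        return ltp_value(self)


def ltp_timecourse(series: SweepSeries, cfg: SlopeConfig | None = None) -> TimecourseResult:
    """Per-sweep normalised slopes and PPRs for an LTP session.

    Requires at least 10 min of baseline before the HFS onset and 60 min of
    recording after the trains end.  Sweeps overlapping the trains are
    excluded; so are sweeps whose slope cannot be measured (logged).  Slopes
    are normalised by the mean magnitude over the final 10 baseline minutes,
    so the baseline-window mean of the normalised series is 1 by construction.
    """
    cfg = cfg or SlopeConfig()
    hfs_start, hfs_end = series.hfs_time, series.hfs_end
    t0s = np.array([s.t0 for s in series.sweeps])
    pre_span = (hfs_start - t0s.min()) / 60.0
    post_span = (t0s.max() - hfs_end) / 60.0
    if pre_span < 10.0 - 1e-9:
        raise ValueError(f"only {pre_span:.1f} min of baseline before HFS; need >= 10 min")
    if post_span < 59.0:
        raise ValueError(f"only {post_span:.1f} min recorded after HFS; need >= 60 min")

    times, slopes, pprs = [], [], []
    n_excluded = 0
    for sw in series.sweeps:
        if hfs_start - sw.samples.size / sw.sampling_rate < sw.t0 < hfs_end:
            n_excluded += 1
            continue
        try:
            res = measure_fpsp_slope(sw, 0, cfg)
        except SweepMeasurementError as e:
            logger.info("sweep at t0=%.1f s excluded: %s", sw.t0, e)
            n_excluded += 1
            continue
        if sw.t0 < hfs_start:
            times.append((sw.t0 - hfs_start) / 60.0)
        else:
            times.append((sw.t0 - hfs_end) / 60.0)
        slopes.append(res.magnitude)
        try:
            pprs.append(paired_pulse_ratio(sw, cfg))
        except (SweepMeasurementError, ValueError):
            pprs.append(float("nan"))

    times_arr = np.array(times)
    slopes_arr = np.array(slopes)
    base_sel = (times_arr >= -10.0) & (times_arr < 0.0)
    if not base_sel.any():
        raise ValueError("no measurable sweeps in the 10-min baseline window")
    base_mean = float(slopes_arr[base_sel].mean())
    return TimecourseResult(
        times=times_arr,
        norm_slopes=slopes_arr / base_mean,
        ppr_series=np.array(pprs),
        baseline_slope=base_mean,
        n_excluded=n_excluded,
    )


def ltp_value(tc: TimecourseResult) -> float:
    """Mean normalised slope over the LTP window (50–60 min post-HFS)."""
    lo, hi = tc.ltp_window
    sel = (tc.times >= lo) & (tc.times < hi)
    if not sel.any():
        raise ValueError(f"no sweeps in the LTP window [{lo}, {hi}) min")
    return float(tc.norm_slopes[sel].mean())
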