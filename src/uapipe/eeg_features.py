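"""EEG-derived signatures.

Implements the full signature set consumed by the group-level analyses:
Morlet time-frequency power, pre-response ramp slope/threshold on
centro-parietal channels, contralateral motor-band (8-25 Hz) slope,
spectrally normalized 30 Hz entrained amplitude, time-resolved sample
entropy over discontinuous trial segments, and the aperiodic (1/f)
spectral exponent via iterative peak-excluding fits.

All temporal filters are zero-phase (forward-backward Butterworth).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .task_synth import EpochedSignal

try:  # numba accelerates the O(N^2) entropy pair counting when present
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "SpectralMap",
    "SlopeEstimate",
    "EntropyTimecourse",
    "AperiodicFit",
    "morlet_power",
    "cpp_slope",
    "mubeta_slope",
    "ssvep_amplitude",
    "sample_entropy_timeresolved",
    "sample_entropy_counts",
    "spectral_psd",
    "aperiodic_fit",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SpectralMap:
    """channel x frequency x time power (optionally trial-resolved)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    log10: bool
    valid: np.ndarray  # frequency x time, False where edge-contaminated
    n_cycles: float
    step: float


@dataclass
class SlopeEstimate:
    value: float
    threshold: float
    window: tuple[float, float]
    channels: tuple[str, ...]
    baseline: tuple[float, float] | None = None
    trace: np.ndarray | None = None
    times: np.ndarray | None = None


@dataclass
class EntropyTimecourse:
    entropy: np.ndarray      # channel x window
    times: np.ndarray        # window centers (s)
    undefined: np.ndarray    # channel x window boolean
    m: int
    r: float
    window: float
    step: float
    channels: tuple[str, ...] = ()


@dataclass
class AperiodicFit:
    offset: float
    exponent: float
    freq_range: tuple[float, float]
    peaks: list[dict] = field(default_factory=list)
    residual_rms: float = float("nan")
    n_points: int = 0


# ---------------------------------------------------------------------------
# Morlet time-frequency power
# ---------------------------------------------------------------------------

def _morlet_wavelet(freq: float, srate: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wav = env * np.exp(2j * np.pi * freq * t)
    # normalize so a unit-amplitude sinusoid at `freq` yields |conv| ~ 1
    return wav / (env.sum() / 2.0)


def morlet_power(
    epochs: EpochedSignal,
    freqs: np.ndarray,
    n_cycles: float = 7.0,
    step: float = 0.05,
    log_transform: bool = True,
    average: bool = True,
) -> SpectralMap:
    """Complex Morlet wavelet power.

    Power is computed per trial; when ``log_transform`` is set, log10 is
    applied at the single-trial level *before* any averaging.  Samples
    closer to an epoch edge than the wavelet half-width are marked
    invalid in ``valid``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= epochs.srate / 2:
        raise ConfigurationError("max frequency must be below Nyquist")
    n_ch, n_t, n_tr = epochs.data.shape
    stride = max(int(round(step * epochs.srate)), 1)
    out_idx = np.arange(0, n_t, stride)
    times = epochs.times[out_idx]

    flat = epochs.data.transpose(0, 2, 1).reshape(n_ch * n_tr, n_t)
    power = np.empty((n_ch, freqs.size, out_idx.size, n_tr))
    valid = np.ones((freqs.size, out_idx.size), dtype=bool)
    for fi, f in enumerate(freqs):
        wav = _morlet_wavelet(f, epochs.srate, n_cycles)
        half = (len(wav) - 1) // 2
        if len(wav) > n_t:
            raise ConfigurationError(
                f"epoch too short for a {n_cycles}-cycle wavelet at {f} Hz")
        conv = sps.fftconvolve(flat, wav[None, :], mode="same", axes=1)
        p = np.abs(conv[:, out_idx]) ** 2
        if log_transform:
            p = np.log10(np.maximum(p, 1e-300))
        power[:, fi] = p.reshape(n_ch, n_tr, out_idx.size).transpose(0, 2, 1)
        valid[fi] = (out_idx >= half) & (out_idx < n_t - half)

    if average:
        power = power.mean(axis=3)
    return SpectralMap(power=power, freqs=freqs, times=times, log10=log_transform,
                       valid=valid, n_cycles=n_cycles, step=step)


# ---------------------------------------------------------------------------
# pre-response ramp slope (centro-parietal) and threshold
# ---------------------------------------------------------------------------

def _window_slice(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ConfigurationError(
            f"window {window} outside epoch bounds ({times[0]:.3f}, {times[-1]:.3f})")
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def _zero_phase_lowpass(data: np.ndarray, srate: float, cutoff: float,
                        order: int = 6, axis: int = -1) -> np.ndarray:
    sos = sps.butter(order // 2, cutoff, btype="low", fs=srate, output="sos")
    return sps.sosfiltfilt(sos, data, axis=axis)


def cpp_slope(
    epochs: EpochedSignal,
    channels: tuple[str, ...] = ("Cz", "Pz", "CP3", "CP4"),
    slope_window: tuple[float, float] = (-0.25, -0.10),
    threshold_window: tuple[float, float] = (-0.05, 0.05),
    lowpass: float | None = 8.0,
    baseline: tuple[float, float] | None = None,
) -> SlopeEstimate:
    """Ramp slope (OLS on the trial-averaged trace) and threshold amplitude.

    ``epochs`` must be response-aligned.  The trace is low-pass filtered
    (6th-order zero-phase) before averaging; ``baseline`` optionally
    subtracts the mean over a window of the same epoch.
    """
    data = epochs.pick(channels)
    if lowpass is not None:
        data = _zero_phase_lowpass(data, epochs.srate, lowpass, axis=1)
    trace = data.mean(axis=(0, 2))
    if baseline is not None:
        trace = trace - trace[_window_slice(epochs.times, baseline)].mean()
    sl = _window_slice(epochs.times, slope_window)
    slope = float(np.polyfit(epochs.times[sl], trace[sl], 1)[0])
    th = float(trace[_window_slice(epochs.times, threshold_window)].mean())
    return SlopeEstimate(value=slope, threshold=th, window=slope_window,
                         channels=tuple(channels), baseline=baseline,
                         trace=trace, times=epochs.times)


def mubeta_slope(
    epochs: EpochedSignal,
    response_side: np.ndarray,
    left_channels: tuple[str, ...] = ("C3", "CP3"),
    right_channels: tuple[str, ...] = ("C4", "CP4"),
    freq_range: tuple[float, float] = (8.0, 25.0),
    n_cycles: float = 7.0,
    step: float = 0.05,
    slope_window: tuple[float, float] = (-0.25, -0.05),
    threshold_window: tuple[float, float] = (-0.05, 0.05),
    baseline: tuple[float, float] | None = None,
) -> tuple[SlopeEstimate, dict[str, np.ndarray]]:
    """Contralateral motor-band power slope and threshold.

    Channels are re-mapped per trial to contra/ipsilateral given the
    response side; trials with missing side are dropped with a warning.
    Returns the contralateral slope estimate plus the contra/ipsi power
    time courses.
    """
    side = np.asarray(response_side, dtype=object)
    known = np.array([s in ("left", "right") for s in side])
    if not known.all():
        warnings.warn(f"dropping {int((~known).sum())} trials with missing response side",
                      stacklevel=2)
    if not known.any():
        raise ConfigurationError("no trials with a known response side")

    sub = EpochedSignal(epochs.data[:, :, known], srate=epochs.srate,
                        times=epochs.times, alignment=epochs.alignment,
                        channels=epochs.channels, neighbors=epochs.neighbors)
    side = side[known]
    freqs = np.arange(freq_range[0], freq_range[1] + 0.5, 1.0)
    tf = morlet_power(sub, freqs, n_cycles=n_cycles, step=step,
                      log_transform=False, average=False)
    li = [epochs.channels.index(c) for c in left_channels]
    ri = [epochs.channels.index(c) for c in right_channels]
    band = tf.power.mean(axis=1)  # channel x time x trial
    lpow, rpow = band[li].mean(axis=0), band[ri].mean(axis=0)
    is_left = np.array([s == "left" for s in side])
    contra = np.where(is_left[None, :], rpow, lpow).mean(axis=1)
    ipsi = np.where(is_left[None, :], lpow, rpow).mean(axis=1)
    if baseline is not None:
        bsl = _window_slice(tf.times, baseline)
        contra = contra - contra[bsl].mean()
        ipsi = ipsi - ipsi[bsl].mean()
    sl = _window_slice(tf.times, slope_window)
    slope = float(np.polyfit(tf.times[sl], contra[sl], 1)[0])
    th = float(contra[_window_slice(tf.times, threshold_window)].mean())
    est = SlopeEstimate(value=slope, threshold=th, window=slope_window,
                        channels=tuple(left_channels) + tuple(right_channels),
                        baseline=baseline, trace=contra, times=tf.times)
    return est, {"contra": contra, "ipsi": ipsi, "times": tf.times}


# ---------------------------------------------------------------------------
# entrained 30 Hz amplitude
# ---------------------------------------------------------------------------

def ssvep_amplitude(
    epochs: EpochedSignal,
    f0: float = 30.0,
    sidebands: tuple[float, float] = (28.0, 32.0),
    window: float = 1.0,
    step: float = 0.1,
    baseline: tuple[float, float] | None = (-0.7, -0.1),
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window entrained power, sideband- and baseline-normalized.

    Returns ``(times, value)`` with ``value`` of shape channel x window.
    Each 1 s segment is Hann-tapered; power at ``f0`` minus the plain
    mean of the two sideband estimates removes broadband background, and
    the temporal baseline (window centers within ``baseline``) is then
    subtracted.
    """
    if max(f0, *sidebands) >= epochs.srate / 2:
        raise ConfigurationError("f0 and sidebands must be below Nyquist")
    n_ch, n_t, n_tr = epochs.data.shape
    wlen = int(round(window * epochs.srate))
    stride = max(int(round(step * epochs.srate)), 1)
    starts = np.arange(0, n_t - wlen + 1, stride)
    if starts.size == 0:
        raise ConfigurationError("epoch shorter than the FFT window")
    centers = epochs.times[starts] + window / 2.0
    taper = np.hanning(wlen)
    fft_freqs = np.fft.rfftfreq(wlen, d=1.0 / epochs.srate)
    bins = [int(np.argmin(np.abs(fft_freqs - f))) for f in (f0, *sidebands)]

    value = np.empty((n_ch, starts.size))
    for wi, s in enumerate(starts):
        seg = epochs.data[:, s:s + wlen, :] * taper[None, :, None]
        spec = np.fft.rfft(seg, axis=1)
        pow_ = (np.abs(spec[:, bins, :]) ** 2).mean(axis=2)  # channel x 3
        value[:, wi] = pow_[:, 0] - pow_[:, 1:].mean(axis=1)
    if baseline is not None:
        bsl = (centers >= baseline[0] - 1e-9) & (centers <= baseline[1] + 1e-9)
        if not bsl.any():
            raise ConfigurationError("no window centers fall in the baseline range")
        value = value - value[:, bsl].mean(axis=1, keepdims=True)
    return centers, value


# ---------------------------------------------------------------------------
# time-resolved sample entropy (discontinuous segments)
# ---------------------------------------------------------------------------

@_njit(cache=True)
def _count_matches(x: np.ndarray, pos: np.ndarray, m: int, r: float):  # pragma: no cover
    """Pairwise template matches: B over length m, A over length m+1."""
    n = pos.size
    a = 0
    b = 0
    for i in range(n - 1):
        pi = pos[i]
        for j in range(i + 1, n):
            pj = pos[j]
            ok = True
            for k in range(m):
                if abs(x[pi + k] - x[pj + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[pi + m] - x[pj + m]) <= r:
                    a += 1
    return a, b


def _count_matches_numpy(x: np.ndarray, pos: np.ndarray, m: int, r: float):
    """Vectorized fallback used when numba is unavailable."""
    templ = np.stack([x[pos + k] for k in range(m + 1)], axis=1)
    a = b = 0
    chunk = 512
    for i0 in range(0, len(pos), chunk):
        ti = templ[i0:i0 + chunk]
        # pairs (i, j) with j > i
        dist_m = np.max(np.abs(ti[:, None, :m] - templ[None, :, :m]), axis=2)
        match_m = dist_m <= r
        match_a = match_m & (np.abs(ti[:, None, m] - templ[None, :, m]) <= r)
        for row in range(ti.shape[0]):
            gi = i0 + row
            b += int(match_m[row, gi + 1:].sum())
            a += int(match_a[row, gi + 1:].sum())
    return a, b


def sample_entropy_counts(segments: list[np.ndarray], m: int, r: float) -> tuple[int, int]:
    """(A, B) template-match counts pooled across discontinuous segments.

    Templates never span a segment boundary; matches are counted across
    all template pairs (within and between segments).  ``r`` is an
    absolute tolerance here.
    """
    data = []
    pos = []
    offset = 0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.size >= m + 1:
            data.append(seg)
            pos.append(offset + np.arange(seg.size - m))
            offset += seg.size
    if not pos:
        return 0, 0
    x = np.concatenate(data)
    p = np.concatenate(pos)
    if _HAVE_NUMBA:
        return _count_matches(x, p, m, float(r))
    return _count_matches_numpy(x, p, m, float(r))


def sample_entropy_timeresolved(
    epochs: EpochedSignal,
    channels: tuple[str, ...] | None = None,
    m: int = 2,
    r: float = 0.5,
    window: float = 0.5,
    step: float = 0.15,
    alpha_notch: tuple[float, float] | None = (8.0, 15.0),
    t_range: tuple[float, float] | None = None,
) -> EntropyTimecourse:
    """Windowed sample entropy pooled across trials.

    For every window, each trial contributes one discontinuous segment;
    the tolerance is ``r`` times the pooled SD of all samples entering
    the estimate, recomputed per window.  Windows with no length-m+1
    matches (or zero variance) are flagged undefined, never zeroed.
    """
    chans = tuple(channels) if channels is not None else tuple(epochs.channels)
    data = epochs.pick(chans)
    if alpha_notch is not None:
        sos = sps.butter(3, alpha_notch, btype="bandstop", fs=epochs.srate, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=1)

    wlen = int(round(window * epochs.srate))
    stride = max(int(round(step * epochs.srate)), 1)
    t_lo = epochs.times[0] if t_range is None else t_range[0]
    t_hi = epochs.times[-1] if t_range is None else t_range[1]
    start_lo = int(np.searchsorted(epochs.times, t_lo - 1e-9))
    start_hi = int(np.searchsorted(epochs.times, t_hi - window + 1e-9, side="right"))
    starts = np.arange(start_lo, max(start_hi, start_lo), stride)
    starts = starts[starts + wlen <= data.shape[1]]
    if starts.size == 0:
        raise ConfigurationError("no entropy windows fit in the requested range")
    centers = epochs.times[starts] + window / 2.0

    n_ch = len(chans)
    ent = np.full((n_ch, starts.size), np.nan)
    undef = np.zeros((n_ch, starts.size), dtype=bool)
    for ci in range(n_ch):
        for wi, s in enumerate(starts):
            chunk = data[ci, s:s + wlen, :]
            sd = float(chunk.std())
            if sd == 0.0:
                undef[ci, wi] = True
                continue
            segs = [chunk[:, t] for t in range(chunk.shape[1])]
            a, b = sample_entropy_counts(segs, m, r * sd)
            if a == 0 or b == 0:
                undef[ci, wi] = True
                continue
            ent[ci, wi] = -np.log(a / b)
    return EntropyTimecourse(entropy=ent, times=centers, undefined=undef,
                             m=m, r=r, window=window, step=step, channels=chans)


# ---------------------------------------------------------------------------
# aperiodic (1/f) fit
# ---------------------------------------------------------------------------

def spectral_psd(
    data: np.ndarray,
    srate: float,
    fmin: float = 2.0,
    fmax: float = 80.0,
    fstep: float = 0.5,
    pad_seconds: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, zero-padded PSD on a linear frequency grid.

    ``data`` may have any leading shape with time last; spectra are
    averaged over all leading axes.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    nfft = max(int(round(pad_seconds * srate)), n)
    taper = np.hanning(n)
    seg = (data - data.mean(axis=-1, keepdims=True)) * taper
    spec = np.abs(np.fft.rfft(seg, n=nfft, axis=-1)) ** 2
    spec = spec.reshape(-1, spec.shape[-1]).mean(axis=0)
    fft_freqs = np.fft.rfftfreq(nfft, d=1.0 / srate)
    grid = np.arange(fmin, fmax + fstep / 2, fstep)
    idx = np.searchsorted(fft_freqs, grid)
    idx = np.clip(idx, 0, fft_freqs.size - 1)
    return grid, spec[idx]


def aperiodic_fit(
    freqs: np.ndarray,
    psd: np.ndarray,
    max_iter: int = 20,
    peak_z: float = 2.0,
    min_points: int = 10,
) -> AperiodicFit:
    """Aperiodic exponent/offset from an iterative peak-excluding line fit.

    A line is fit to log10(power) vs log10(frequency); points with high
    *positive* residuals (oscillatory peaks) are flagged and the line is
    refit on the remainder until the flag set is stable.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.shape != psd.shape or freqs.ndim != 1:
        raise ConfigurationError("freqs and psd must be matching 1-D arrays")
    if (psd <= 0).any() or (freqs <= 0).any():
        raise ConfigurationError("PSD and frequencies must be positive on the fit range")
    lf, lp = np.log10(freqs), np.log10(psd)
    keep = np.ones(freqs.size, dtype=bool)
    coef = np.polyfit(lf, lp, 1)
    for _ in range(max_iter):
        coef = np.polyfit(lf[keep], lp[keep], 1)
        resid = lp - np.polyval(coef, lf)
        sd = resid[keep].std()
        new_keep = resid <= peak_z * max(sd, 1e-12)
        if new_keep.sum() < min_points:
            raise ConfigurationError(
                f"fewer than {min_points} non-peak points remain in the aperiodic fit")
        if (new_keep == keep).all():
            keep = new_keep
            break
        keep = new_keep
    resid = lp - np.polyval(coef, lf)

    peaks: list[dict] = []
    flagged = ~keep
    if flagged.any():
        edges = np.flatnonzero(np.diff(np.r_[0, flagged.astype(int), 0]))
        for lo, hi in zip(edges[::2], edges[1::2]):
            seg = slice(lo, hi)
            k = lo + int(np.argmax(resid[seg]))
            peaks.append({
                "center": float(freqs[k]),
                "height": float(resid[k]),
                "width": float(freqs[hi - 1] - freqs[lo] + (freqs[1] - freqs[0])),
            })
    return AperiodicFit(offset=float(coef[1]), exponent=float(-coef[0]),
                        freq_range=(float(freqs[0]), float(freqs[-1])),
                        peaks=peaks,
                        residual_rms=float(np.sqrt(np.mean(resid[keep] ** 2))),
                        n_points=int(keep.sum()))
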