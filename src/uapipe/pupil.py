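"""Pupil preprocessing and the first-derivative arousal signature.

Cleaning removes blink- and gaze-artifact samples (with a symmetric pad)
and linearly interpolates interior gaps; edge gaps are never
extrapolated and stay flagged as missing.  The signature is the rate of
change of the cleaned trace, decimated to 100 Hz with an anti-alias
filter and smoothed with a 300 ms moving median.  Missing flags
propagate: any output window touching a missing sample is missing.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .task_synth import PupilTrace

__all__ = ["PupilDerivative", "TraceRejected", "preprocess_pupil", "derivative_signature"]


class TraceRejected(ConfigurationError):
    """Raised when more than the tolerated fraction of samples is flagged."""


@dataclass
class PupilDerivative:
    """Rate-of-change samples at the signature rate (units/s)."""

    samples: np.ndarray
    srate: float
    t0: float
    missing: np.ndarray
    smoothing_window: float = 0.3

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.srate


def _artifact_mask(trace: PupilTrace, z_thresh: float, pad: float,
                   use_gaze: bool) -> np.ndarray:
    n = trace.samples.size
    mask = np.zeros(n, dtype=bool)
    for start, end in trace.blinks:
        lo = int(np.floor(start * trace.srate))
        hi = int(np.ceil(end * trace.srate))
        mask[max(lo, 0):min(hi, n)] = True
    if use_gaze and trace.gaze_y is not None:
        dg = np.diff(trace.gaze_y, prepend=trace.gaze_y[0])
        sd = dg.std()
        if sd > 0:
            mask |= np.abs((dg - dg.mean()) / sd) >= z_thresh
    if mask.any() and pad > 0:
        w = int(round(pad * trace.srate))
        idx = np.flatnonzero(mask)
        padded = np.zeros(n, dtype=bool)
        for i in idx:
            padded[max(i - w, 0):min(i + w + 1, n)] = True
        mask = padded
    return mask


def preprocess_pupil(
    trace: PupilTrace,
    z_thresh: float = 3.0,
    pad: float = 0.15,
    reject_fraction: float = 0.5,
    use_gaze: bool = True,
) -> PupilTrace:
    """Remove flagged samples and linearly interpolate interior gaps.

    Samples are flagged by blink annotations and, when a gaze channel is
    present, by |z| >= ``z_thresh`` of the gaze derivative; flags are
    padded by ``pad`` seconds on both sides.  Traces with more than
    ``reject_fraction`` flagged samples are rejected.
    """
    mask = _artifact_mask(trace, z_thresh, pad, use_gaze)
    frac = mask.mean()
    if frac > reject_fraction:
        raise TraceRejected(
            f"{frac:.0%} of samples flagged (> {reject_fraction:.0%}); trace rejected")
    samples = trace.samples.astype(float).copy()
    missing = np.zeros(samples.size, dtype=bool)
    if mask.any():
        good = np.flatnonzero(~mask)
        bad = np.flatnonzero(mask)
        # interior gaps only: edges carry missing flags, never extrapolated
        interior = (bad > good[0]) & (bad < good[-1])
        samples[bad[interior]] = np.interp(bad[interior], good, samples[good])
        edge = bad[~interior]
        samples[edge] = np.nan
        missing[edge] = True
    return replace(trace, samples=samples, missing=missing)


def _moving_median(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving median; edge windows shrink to the available span."""
    n = x.size
    out = np.empty(n)
    half = w // 2
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        out[i] = np.median(x[lo:hi])
    return out


def derivative_signature(
    trace: PupilTrace,
    out_srate: float = 100.0,
    smooth: float = 0.3,
) -> PupilDerivative:
    """First derivative, decimated to ``out_srate``, moving-median smoothed.

    The derivative is taken at the native rate (first difference times
    srate) before decimation to minimize aliasing of artifact remnants.
    """
    n = trace.samples.size
    if n / trace.srate < smooth:
        raise ConfigurationError("trace shorter than the smoothing window")
    missing = trace.missing if trace.missing is not None else np.isnan(trace.samples)
    x = trace.samples.astype(float).copy()
    had_missing = missing.any()
    if had_missing:
        good = np.flatnonzero(~missing)
        if good.size < 2:
            raise ConfigurationError("trace almost entirely missing")
        x[missing] = np.interp(np.flatnonzero(missing), good, x[good])

    deriv = np.gradient(x) * trace.srate
    dmiss = missing | np.r_[missing[1:], False] | np.r_[False, missing[:-1]]

    factor = trace.srate / out_srate
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(
            f"native rate {trace.srate} Hz is not an integer multiple of {out_srate} Hz")
    factor = int(round(factor))
    if factor > 1:
        deriv_ds = sps.decimate(deriv, factor, ftype="fir", zero_phase=True)
        miss_ds = np.add.reduceat(dmiss, np.arange(0, n, factor)) > 0
        miss_ds = miss_ds[: deriv_ds.size]
    else:
        deriv_ds, miss_ds = deriv, dmiss

    w = max(int(round(smooth * out_srate)), 1)
    smoothed = _moving_median(np.where(miss_ds, np.nan, deriv_ds), w)
    # a window containing any missing sample is missing
    out_missing = np.isnan(smoothed)
    return PupilDerivative(samples=smoothed, srate=out_srate, t0=trace.t0,
                           missing=out_missing, smoothing_window=smooth)
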