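"""Simplified first-level GLM for BOLD-like time series.

Boxcar regressors per condition are convolved with a canonical
double-gamma HRF (plus its temporal derivative as a nuisance term);
mean-centered parametric modulators are convolved likewise.  Estimation
is per-voxel OLS; run-wise betas are averaged per condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ConfigurationError

__all__ = [
    "EventTable",
    "DesignMatrix",
    "BetaMap",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "average_run_betas",
]


@dataclass
class EventTable:
    """Event onsets/durations with condition labels and optional modulators."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: np.ndarray
    modulators: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if np.any(np.diff(self.onsets) < 0):
            raise ConfigurationError("event onsets must be non-decreasing")
        if np.any(self.durations <= 0):
            raise ConfigurationError("event durations must be > 0")
        for name, vals in self.modulators.items():
            self.modulators[name] = np.asarray(vals, dtype=float)
            if self.modulators[name].size != self.onsets.size:
                raise ConfigurationError(f"modulator {name!r} does not match events")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventTable":
        mods = {c: frame[c].to_numpy() for c in frame.columns
                if c not in ("onset", "duration", "trial_type")}
        return cls(onsets=frame["onset"].to_numpy(),
                   durations=frame["duration"].to_numpy(),
                   conditions=frame["trial_type"].to_numpy(),
                   modulators=mods)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"onset": self.onsets, "duration": self.durations,
                           "trial_type": self.conditions})
        for name, vals in self.modulators.items():
            df[name] = vals
        return df


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list[str]
    tr: float

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ConfigurationError("regressor names do not match columns")


@dataclass
class BetaMap:
    betas: np.ndarray              # voxel x regressor
    residual_variance: np.ndarray  # voxel
    names: list[str]


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Double-gamma HRF (peak ~5 s, undershoot ~15 s), zero for t < 0."""
    t = np.asarray(t, dtype=float)
    h = sstats.gamma.pdf(t, a=6.0) - sstats.gamma.pdf(t, a=16.0) / 6.0
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design(
    events: EventTable,
    tr: float,
    n_volumes: int,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
    oversample: int = 16,
    add_derivative: bool = True,
) -> DesignMatrix:
    """Convolved design matrix on the volume grid.

    Each condition gets a boxcar convolved with the canonical HRF (and
    its temporal derivative when ``add_derivative``); each modulator is
    mean-centered within condition, multiplied into the boxcar, and
    convolved likewise.  Arbitrary nuisance columns are appended last.
    A rank-deficient result raises, listing the collinear columns.
    """
    scan_end = n_volumes * tr
    if np.any(events.onsets + events.durations > scan_end + 1e-9):
        raise ConfigurationError("events extend beyond the scan duration")
    dt = tr / oversample
    n_fine = n_volumes * oversample
    t_fine = np.arange(n_fine) * dt
    hrf = canonical_hrf(np.arange(0, 32, dt))
    dhrf = np.gradient(hrf, dt)

    cols, names = [], []
    for cond in pd.unique(events.conditions):
        sel = events.conditions == cond
        box = np.zeros(n_fine)
        for onset, dur in zip(events.onsets[sel], events.durations[sel]):
            lo = int(round(onset / dt))
            hi = int(round((onset + dur) / dt))
            box[lo:hi] = 1.0
        for kernel, suffix in ((hrf, ""), (dhrf, "_derivative")) if add_derivative \
                else ((hrf, ""),):
            conv = np.convolve(box, kernel)[:n_fine] * dt
            cols.append(conv[::oversample])
            names.append(f"{cond}{suffix}")
        for mod_name, mod_vals in events.modulators.items():
            vals = mod_vals[sel]
            if np.all(np.isnan(vals)):
                continue
            centered = vals - np.nanmean(vals)
            pbox = np.zeros(n_fine)
            for onset, dur, v in zip(events.onsets[sel], events.durations[sel], centered):
                if np.isnan(v):
                    continue
                lo = int(round(onset / dt))
                hi = int(round((onset + dur) / dt))
                pbox[lo:hi] = v
            conv = np.convolve(pbox, hrf)[:n_fine] * dt
            cols.append(conv[::oversample])
            names.append(f"{cond}_x_{mod_name}")

    X = np.column_stack(cols)
    # drop all-zero modulator columns (constant modulators center to zero)
    keep = ~np.all(X == 0, axis=0)
    X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        X = np.column_stack([X, nuisance])
        names = names + (nuisance_names or
                         [f"nuisance_{i}" for i in range(nuisance.shape[1])])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns greedily
        bad, kept_idx = [], []
        for j in range(X.shape[1]):
            trial = X[:, kept_idx + [j]]
            if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
                kept_idx.append(j)
            else:
                bad.append(names[j])
        raise ConfigurationError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(matrix=X, names=names, tr=tr)


def fit_glm(timeseries: np.ndarray, design: DesignMatrix) -> BetaMap:
    """Per-voxel OLS fit of ``timeseries`` (voxel x time) to the design."""
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if not np.isfinite(Y).all():
        raise ConfigurationError("time series contain non-finite values")
    X = design.matrix
    if Y.shape[1] != X.shape[0]:
        raise ConfigurationError("time axis does not match the design")
    betas, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ betas
    dof = max(X.shape[0] - X.shape[1], 1)
    return BetaMap(betas=betas.T, residual_variance=(resid**2).sum(axis=0) / dof,
                   names=design.names)


def average_run_betas(maps: list[BetaMap], conditions: list[str]) -> np.ndarray:
    """Average per-condition betas across runs -> voxel x condition."""
    if not maps:
        raise ConfigurationError("no runs to average")
    out = []
    for cond in conditions:
        per_run = []
        for m in maps:
            if cond not in m.names:
                raise ConfigurationError(f"condition {cond!r} missing from a run")
            per_run.append(m.betas[:, m.names.index(cond)])
        out.append(np.mean(per_run, axis=0))
    return np.column_stack(out)
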