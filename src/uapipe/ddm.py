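"""Drift-diffusion model: simulation, first-passage densities, ML fitting.

The decision process is a one-dimensional Wiener process with unit
diffusion, drift ``v`` (signed toward the correct bound), boundary
separation ``a`` and relative start point ``w`` (fixed at 0.5 for
accuracy-coded data).  Fitting maximizes a mixture likelihood of the
first-passage density with a uniform outlier component; trials faster
than 250 ms are excluded before fitting.

The density evaluation uses the classic small-time / large-time series
split, selecting per time point whichever expansion needs fewer terms
for the requested truncation error (``_SERIES_EPS``).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, FitError

__all__ = [
    "DDMParams",
    "BehavioralTrial",
    "DDMFitResult",
    "ModelComparison",
    "VARIANTS",
    "simulate_ddm_trials",
    "first_passage_density",
    "absorption_probability",
    "mean_decision_time",
    "fit_ddm",
    "compare_models",
    "trials_to_frame",
    "frame_to_trials",
]

#: Truncation error bound for the density series (per evaluation point).
_SERIES_EPS = 1e-10

#: Minimum RT retained for fitting (premature-response exclusion), seconds.
RT_EXCLUSION_S = 0.25

VARIANTS = ("full", "drift", "drift+threshold", "drift+ndt", "null")


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a single-condition diffusion process."""

    v: float
    a: float
    t0: float
    w: float = 0.5
    p_outlier: float = 0.05
    condition: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite([self.v, self.a, self.t0, self.w]).all():
            raise ConfigurationError("DDM parameters must be finite")
        if self.a <= 0:
            raise ConfigurationError(f"boundary separation must be > 0, got {self.a}")
        if not 0 < self.w < 1:
            raise ConfigurationError(f"start fraction must lie in (0, 1), got {self.w}")
        if self.t0 < 0:
            raise ConfigurationError(f"non-decision time must be >= 0, got {self.t0}")
        if not 0 <= self.p_outlier < 1:
            raise ConfigurationError(f"p_outlier must lie in [0, 1), got {self.p_outlier}")


@dataclass
class BehavioralTrial:
    """One behavioral observation (RT in seconds, accuracy-coded)."""

    subject: str
    group: str
    load: int
    feature: str
    rt: float
    correct: int
    excluded: bool = False

    def __post_init__(self) -> None:
        self.excluded = bool(self.rt < RT_EXCLUSION_S)


@dataclass
class DDMFitResult:
    """Per-subject maximum-likelihood fit across conditions."""

    variant: str
    params: dict[int, DDMParams]
    log_likelihood: float
    n_params: int
    n_trials: int
    criterion: str
    ic: float
    converged: bool
    conditions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.conditions = tuple(sorted(self.params))


@dataclass
class ModelComparison:
    """Ranking of fitted variants by information criterion (lower wins)."""

    ranking: list[tuple[str, float]]
    best: str
    criterion: str


# ---------------------------------------------------------------------------
# closed forms (used as internal checks and by callers as oracles)
# ---------------------------------------------------------------------------

def absorption_probability(params: DDMParams, boundary: str = "correct") -> float:
    """Probability of absorption at ``boundary`` ('correct' = upper)."""
    v, a, w = params.v, params.a, params.w
    z = w * a
    if abs(v) < 1e-12:
        p_upper = z / a
    else:
        p_upper = (1.0 - math.exp(-2.0 * v * z)) / (1.0 - math.exp(-2.0 * v * a))
    return p_upper if boundary == "correct" else 1.0 - p_upper


def mean_decision_time(params: DDMParams) -> float:
    """Mean first-passage time (over both boundaries), w = 0.5 only."""
    if abs(params.w - 0.5) > 1e-12:
        raise ConfigurationError("mean_decision_time implemented for w = 0.5 only")
    v, a = params.v, params.a
    if abs(v) < 1e-12:
        return a**2 / 4.0  # E[T] = z(a-z) for the driftless process
    return (a / (2.0 * v)) * math.tanh(v * a / 2.0)


# ---------------------------------------------------------------------------
# first-passage density
# ---------------------------------------------------------------------------

def _f0_lower(tau: np.ndarray, w: float) -> np.ndarray:
    """Density (v=0, a=1) of hitting the lower bound at normalized time tau."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]
    eps = _SERIES_EPS

    # number of terms required by either expansion, from the standard
    # truncation-error bounds for the two series
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = np.where(
            2.0 * np.sqrt(2.0 * np.pi * t) * eps < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * t)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        kl = np.where(
            np.pi * t * eps < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * eps), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    val = np.empty_like(t)

    if use_small.any():
        ts = t[use_small]
        kmax = int(np.ceil((ks[use_small].max() - 1.0) / 2.0))
        acc = np.zeros_like(ts)
        for k in range(-kmax, kmax + 1):
            acc += (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * ts))
        val[use_small] = acc / np.sqrt(2.0 * np.pi * ts**3)

    if (~use_small).any():
        tl = t[~use_small]
        kmax = int(np.ceil(kl[~use_small].max()))
        acc = np.zeros_like(tl)
        for k in range(1, kmax + 1):
            acc += k * np.exp(-(k**2) * np.pi**2 * tl / 2.0) * np.sin(k * np.pi * w)
        val[~use_small] = acc * np.pi

    out[pos] = np.maximum(val, 0.0)
    return out


def first_passage_density(
    t: np.ndarray | float,
    boundary: str,
    params: DDMParams,
    *,
    decision_time: bool = True,
) -> np.ndarray:
    """First-passage density (1/s) at the requested boundary.

    Parameters
    ----------
    t
        Times at which to evaluate.  Interpreted as decision time when
        ``decision_time`` is true, otherwise as observed RT (``t0`` is
        subtracted first).
    boundary
        ``'correct'`` (upper bound) or ``'error'`` (lower bound).
    """
    if boundary not in ("correct", "error"):
        raise ValueError(f"boundary must be 'correct' or 'error', got {boundary!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    td = t if decision_time else t - params.t0
    v, a, w = params.v, params.a, params.w
    if boundary == "correct":
        # upper-bound density == lower-bound density under reflection
        v, w = -v, 1.0 - w
    out = np.zeros_like(td)
    pos = td > 0
    if pos.any():
        tp = td[pos]
        tau = tp / a**2
        out[pos] = (1.0 / a**2) * np.exp(-v * a * w - v**2 * tp / 2.0) * _f0_lower(tau, w)
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_ddm_trials(
    params: DDMParams,
    n: int,
    seed: int | np.random.Generator = 0,
    dt: float = 1e-3,
    *,
    max_t: float = 10.0,
    subject: str = "sim",
    group: str = "young",
    feature: str = "color",
) -> list[BehavioralTrial]:
    """Draw ``n`` choices/RTs from the first-passage process (Euler scheme).

    A fraction ``params.p_outlier`` of trials is replaced by uniform-RT
    outliers with random accuracy, mirroring the fitted mixture.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if dt > 1e-3 + 1e-12:
        warnings.warn(f"dt = {dt} s is coarser than the 1 ms contract", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    v, a, w = params.v, params.a, params.w
    x = np.full(n, w * a)
    rt_dec = np.full(n, max_t)
    correct = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    sqrt_dt = math.sqrt(dt)
    n_steps = int(round(max_t / dt))
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x_old = x[idx].copy()
        x[idx] += v * dt + sqrt_dt * rng.standard_normal(idx.size)
        x_new = x[idx]
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        # Brownian-bridge correction: probability of an unobserved
        # within-step crossing, removing the O(sqrt(dt)) overshoot bias.
        interior = ~(hit_up | hit_lo)
        if interior.any():
            u = rng.random(idx.size)
            p_up = np.exp(-2.0 * np.maximum(a - x_old, 0.0) * np.maximum(a - x_new, 0.0) / dt)
            p_lo = np.exp(-2.0 * np.maximum(x_old, 0.0) * np.maximum(x_new, 0.0) / dt)
            hit_up |= interior & (u < p_up)
            hit_lo |= interior & ~hit_up & (u < p_up + p_lo)
        done = hit_up | hit_lo
        if done.any():
            d = idx[done]
            rt_dec[d] = step * dt
            correct[d] = hit_up[done].astype(int)
            alive[d] = False
    if alive.any():  # force-classify stragglers by current position
        correct[alive] = (x[alive] >= a / 2.0).astype(int)

    rt = rt_dec + params.t0
    if params.p_outlier > 0:
        out_mask = rng.random(n) < params.p_outlier
        if out_mask.any():
            hi = max(float(rt.max()), RT_EXCLUSION_S + 0.5)
            rt[out_mask] = rng.uniform(RT_EXCLUSION_S, hi, out_mask.sum())
            correct[out_mask] = rng.integers(0, 2, out_mask.sum())

    load = params.condition if params.condition is not None else 1
    return [
        BehavioralTrial(subject=subject, group=group, load=int(load), feature=feature,
                        rt=float(rt[i]), correct=int(correct[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def trials_to_frame(trials: list[BehavioralTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [t.subject for t in trials],
            "group": [t.group for t in trials],
            "load": [t.load for t in trials],
            "feature": [t.feature for t in trials],
            "rt": [t.rt for t in trials],
            "correct": [t.correct for t in trials],
            "excluded": [t.excluded for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[BehavioralTrial]:
    return [
        BehavioralTrial(subject=str(r.subject), group=str(r.group), load=int(r.load),
                        feature=str(r.feature), rt=float(r.rt), correct=int(r.correct))
        for r in frame.itertuples()
    ]


def _ez_start(rt: np.ndarray, correct: np.ndarray) -> tuple[float, float, float]:
    """Closed-form method-of-moments starting values (EZ-style, s = 1)."""
    pc = float(np.clip(correct.mean(), 0.02, 0.98))
    if abs(pc - 0.5) < 1e-3:
        pc = 0.51
    mrt = float(rt.mean())
    vrt = float(np.var(rt[correct == 1])) if (correct == 1).sum() > 2 else float(np.var(rt))
    vrt = max(vrt, 1e-4)
    logit = math.log(pc / (1 - pc))
    x = logit * (logit * pc**2 - logit * pc + pc - 0.5) / vrt
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    v = float(np.clip(v, -5.0, 5.0))
    if abs(v) < 0.05:
        v = math.copysign(0.05, v)
    a = float(np.clip(logit / v, 0.5, 4.0))
    mdt = (a / (2 * v)) * (1 - math.exp(-v * a)) / (1 + math.exp(-v * a))
    t0 = float(np.clip(mrt - mdt, 0.05, max(0.05, rt.min() - 0.02)))
    return v, a, t0


_VARIANT_FREE = {
    "full": {"v", "a", "t0"},
    "drift": {"v"},
    "drift+threshold": {"v", "a"},
    "drift+ndt": {"v", "t0"},
    "null": set(),
}


def _pack_spec(variant: str, conditions: list[int]) -> list[tuple[str, int | None]]:
    """Ordered parameter layout: (name, condition) with None = shared."""
    free = _VARIANT_FREE[variant]
    spec: list[tuple[str, int | None]] = []
    for name in ("v", "a", "t0"):
        if name in free:
            spec.extend((name, c) for c in conditions)
        else:
            spec.append((name, None))
    return spec


def _unpack(theta: np.ndarray, spec: list[tuple[str, int | None]],
            conditions: list[int]) -> dict[int, dict[str, float]]:
    per_cond: dict[int, dict[str, float]] = {c: {} for c in conditions}
    for value, (name, cond) in zip(theta, spec):
        if cond is None:
            for c in conditions:
                per_cond[c][name] = float(value)
        else:
            per_cond[cond][name] = float(value)
    return per_cond


def fit_ddm(
    trials: list[BehavioralTrial] | pd.DataFrame,
    variant: str = "full",
    p_outlier: float = 0.05,
    criterion: str = "aic",
) -> DDMFitResult:
    """Maximum-likelihood fit of one subject's trials.

    The likelihood of each retained trial is the mixture
    ``(1 - p_outlier) * wfpt(rt - t0) + p_outlier * uniform`` with the
    uniform component spanning [0.25 s, max observed RT].  The ``variant``
    fixes which of v/a/t0 vary across load conditions.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    kept = frame.loc[frame["rt"] >= RT_EXCLUSION_S].reset_index(drop=True)
    if len(kept) == 0:
        raise FitError("no trials remain after the 250 ms exclusion")
    conditions = sorted(kept["load"].unique().tolist())

    rt_max = float(kept["rt"].max())
    unif = 1.0 / max(rt_max - RT_EXCLUSION_S, 1e-3)

    rts = {c: kept.loc[kept["load"] == c, "rt"].to_numpy() for c in conditions}
    cors = {c: kept.loc[kept["load"] == c, "correct"].to_numpy() for c in conditions}

    spec = _pack_spec(variant, conditions)

    def nll(theta: np.ndarray) -> float:
        per_cond = _unpack(theta, spec, conditions)
        total = 0.0
        for c in conditions:
            p = per_cond[c]
            try:
                params = DDMParams(v=p["v"], a=p["a"], t0=p["t0"], p_outlier=p_outlier)
            except ConfigurationError:
                return 1e12
            rt, cor = rts[c], cors[c]
            td = rt - p["t0"]
            dens = np.zeros_like(rt)
            ok = td > 1e-5
            if ok.any():
                up = first_passage_density(td[ok], "correct", params)
                lo = first_passage_density(td[ok], "error", params)
                dens[ok] = np.where(cor[ok] == 1, up, lo)
            lik = (1.0 - p_outlier) * dens + p_outlier * unif
            total -= float(np.log(np.maximum(lik, 1e-300)).sum())
        return total

    # starting values from per-condition moment estimates
    starts = {c: _ez_start(rts[c], cors[c]) for c in conditions}
    theta0, lb, ub = [], [], []
    for name, cond in spec:
        pool = [cond] if cond is not None else conditions
        idx = {"v": 0, "a": 1, "t0": 2}[name]
        theta0.append(float(np.mean([starts[c][idx] for c in pool])))
        if name == "v":
            lb.append(-10.0), ub.append(10.0)
        elif name == "a":
            lb.append(0.2), ub.append(6.0)
        else:
            min_rt = min(float(rts[c].min()) for c in pool)
            lb.append(1e-3), ub.append(max(2e-3, min_rt - 1e-3))
    theta0 = np.clip(np.asarray(theta0), np.asarray(lb), np.asarray(ub))

    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            bounds=list(zip(lb, ub)),
                            options={"maxiter": 500})
    best = res
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 2000, "fatol": 1e-8})
        if res2.fun <= res.fun:
            best = res2

    per_cond = _unpack(best.x, spec, conditions)
    params = {
        c: DDMParams(v=per_cond[c]["v"], a=per_cond[c]["a"], t0=per_cond[c]["t0"],
                     p_outlier=p_outlier, condition=c)
        for c in conditions
    }
    k = len(spec)
    ll = -float(best.fun)
    n = len(kept)
    if criterion == "aic":
        ic = 2.0 * k - 2.0 * ll
    elif criterion == "bic":
        ic = k * math.log(n) - 2.0 * ll
    else:
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    return DDMFitResult(variant=variant, params=params, log_likelihood=ll,
                        n_params=k, n_trials=n, criterion=criterion, ic=ic,
                        converged=bool(best.success or abs(best.fun) < 1e11))


def compare_models(fits: dict[str, DDMFitResult] | list[DDMFitResult]) -> ModelComparison:
    """Rank fitted variants by information criterion (lower = better)."""
    if isinstance(fits, list):
        fits = {f.variant: f for f in fits}
    if not fits:
        raise ConfigurationError("no fits to compare")
    n_trials = {f.n_trials for f in fits.values()}
    criteria = {f.criterion for f in fits.values()}
    if len(n_trials) != 1:
        raise ConfigurationError("variants were fitted on different trial sets")
    if len(criteria) != 1:
        raise ConfigurationError("variants use different information criteria")
    ranking = sorted(((v, f.ic) for v, f in fits.items()), key=lambda x: x[1])
    return ModelComparison(ranking=ranking, best=ranking[0][0], criterion=criteria.pop())
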