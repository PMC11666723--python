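"""Group-level statistical utilities.

Linear load slopes (per-subject OLS over the 1-4 load regressor), MAD
winsorization, within-subject centering for repeated-measures display,
cluster-based permutation tests with a minimum-channel rule, and
random-intercept mixed models (delegated to statsmodels with a
two-stage fallback).
"""
from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._rng import child_rng
from .errors import ConfigurationError

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "MixedModelResult",
    "linear_load_slope",
    "slope_group_tests",
    "mad_winsorize",
    "within_subject_center",
    "cluster_permutation_test",
    "random_intercept_model",
]

MAD_SCALE = 1.4826  # consistency constant for normal data


# ---------------------------------------------------------------------------
# linear load slopes
# ---------------------------------------------------------------------------

def linear_load_slope(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Per-subject OLS slope (and intercept) of ``value`` over load.

    ``table`` must hold one row per subject x condition with columns
    subject, group, load, and the value column.
    """
    required = {"subject", "group", "load", value}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    rows = []
    for (subj, grp), sub in table.groupby(["subject", "group"], sort=True):
        loads = sub["load"].to_numpy(dtype=float)
        if np.unique(loads).size < 2:
            raise ConfigurationError(
                f"subject {subj!r} has a single load level; slope undefined")
        beta, intercept = np.polyfit(loads, sub[value].to_numpy(dtype=float), 1)
        rows.append({"subject": subj, "group": grp,
                     "beta": float(beta), "intercept": float(intercept)})
    return pd.DataFrame(rows)


def slope_group_tests(slopes: pd.DataFrame) -> dict:
    """Two-sided within-group one-sample t and between-group two-sample t."""
    out: dict = {"within": {}, "between": None}
    for grp, sub in slopes.groupby("group"):
        t, p = sstats.ttest_1samp(sub["beta"], 0.0)
        out["within"][grp] = {"t": float(t), "p": float(p),
                              "mean": float(sub["beta"].mean()), "n": len(sub)}
    groups = list(out["within"])
    if len(groups) == 2:
        a = slopes.loc[slopes["group"] == groups[0], "beta"]
        b = slopes.loc[slopes["group"] == groups[1], "beta"]
        t, p = sstats.ttest_ind(a, b)
        out["between"] = {"groups": groups, "t": float(t), "p": float(p),
                          "mean_diff": float(a.mean() - b.mean())}
    return out


# ---------------------------------------------------------------------------
# MAD winsorization
# ---------------------------------------------------------------------------

def mad_winsorize(values: np.ndarray, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Clip values beyond median +/- k scaled-MAD; returns (clipped, flags).

    The scaled MAD is ``1.4826 * median(|x - median|)``.  Call per group.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ConfigurationError("need >= 4 values per group for MAD winsorization")
    med = float(np.median(values))
    mad = MAD_SCALE * float(np.median(np.abs(values - med)))
    if mad == 0.0:
        if np.ptp(values) > 0:
            warnings.warn("degenerate MAD = 0 with spread present; nothing winsorized",
                          stacklevel=2)
        return values.copy(), np.zeros(values.size, dtype=bool)
    lo, hi = med - k * mad, med + k * mad
    flags = (values < lo) | (values > hi)
    return np.clip(values, lo, hi), flags


# ---------------------------------------------------------------------------
# within-subject centering
# ---------------------------------------------------------------------------

def within_subject_center(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Remove each subject's cross-condition mean and restore the group mean.

    Condition means are preserved exactly; between-subject mean variance
    is removed (for repeated-measures error bars / display).
    """
    required = {"subject", "group", "load", value}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    counts = table.groupby(["subject"])["load"].nunique()
    if counts.nunique() > 1:
        raise ConfigurationError("incomplete subject x condition cells")
    out = table.copy()
    subj_mean = out.groupby("subject")[value].transform("mean")
    group_mean = out.groupby("group")[value].transform("mean")
    out[value] = out[value] - subj_mean + group_mean
    return out


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    points: list[tuple[int, int]]   # (channel, time) indices
    mass: float
    p: float = float("nan")
    sign: int = 0

    @property
    def channels(self) -> set[int]:
        return {c for c, _ in self.points}


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    entry_p: float
    n_permutations: int
    sig_p: float
    tmap: np.ndarray = field(default=None, repr=False)

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.sig_p]


def _find_clusters(tmap: np.ndarray, supra: np.ndarray,
                   adjacency: np.ndarray | None) -> list[Cluster]:
    """Same-sign connected components over (channel, time).

    Adjacent time points on the same channel are neighbors; simultaneous
    points on neighboring channels are neighbors when ``adjacency`` is
    given.
    """
    n_ch, n_t = tmap.shape
    visited = np.zeros((n_ch, n_t), dtype=bool)
    clusters = []
    for c0 in range(n_ch):
        for t0 in range(n_t):
            if not supra[c0, t0] or visited[c0, t0]:
                continue
            sign = int(np.sign(tmap[c0, t0]))
            comp = []
            queue = deque([(c0, t0)])
            visited[c0, t0] = True
            while queue:
                c, t = queue.popleft()
                comp.append((c, t))
                neigh = [(c, t - 1), (c, t + 1)]
                if adjacency is not None:
                    neigh.extend((c2, t) for c2 in np.flatnonzero(adjacency[c]))
                for c2, t2 in neigh:
                    if (0 <= c2 < n_ch and 0 <= t2 < n_t and supra[c2, t2]
                            and not visited[c2, t2]
                            and np.sign(tmap[c2, t2]) == sign):
                        visited[c2, t2] = True
                        queue.append((c2, t2))
            clusters.append(Cluster(points=comp,
                                    mass=float(sum(tmap[c, t] for c, t in comp)),
                                    sign=sign))
    return clusters


def _max_cluster_mass(tmap: np.ndarray, tcrit: float, adjacency: np.ndarray | None,
                      min_channels: int) -> float:
    supra = np.abs(tmap) > tcrit
    best = 0.0
    for cl in _find_clusters(tmap, supra, adjacency):
        if adjacency is not None and len(cl.channels) < min_channels:
            continue
        best = max(best, abs(cl.mass))
    return best


def cluster_permutation_test(
    data: np.ndarray,
    adjacency: np.ndarray | None = None,
    entry_p: float = 0.05,
    n_perm: int = 1000,
    sig_p: float = 0.025,
    min_channels: int = 3,
    seed: int = 0,
) -> ClusterTestResult:
    """One-sample (or paired-difference) cluster permutation test.

    Parameters
    ----------
    data
        subject x channel x time (or subject x time, treated as a single
        channel without the spatial minimum rule).  For paired designs
        pass the within-subject condition differences.
    adjacency
        channel x channel boolean neighbor matrix; spatial clusters must
        then span at least ``min_channels`` channels.
    """
    data = np.asarray(data, dtype=float)
    squeeze_ch = data.ndim == 2
    if squeeze_ch:
        data = data[:, None, :]
    if data.ndim != 3:
        raise ConfigurationError("data must be subject x [channel x] time")
    n_sub, n_ch, n_t = data.shape
    if adjacency is not None:
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.shape != (n_ch, n_ch):
            raise ConfigurationError("adjacency must be channel x channel")
    use_spatial_rule = adjacency is not None

    tcrit = sstats.t.ppf(1.0 - entry_p / 2.0, df=n_sub - 1)

    def tmap_of(x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(n_sub)
        return np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)

    tmap = tmap_of(data)
    supra = np.abs(tmap) > tcrit
    clusters = _find_clusters(tmap, supra, adjacency)
    if use_spatial_rule:
        clusters = [c for c in clusters if len(c.channels) >= min_channels]

    if clusters:
        rng = child_rng(seed, "stats")
        null = np.empty(n_perm)
        for i in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=n_sub)
            null[i] = _max_cluster_mass(tmap_of(data * flips[:, None, None]),
                                        tcrit, adjacency, min_channels)
        for cl in clusters:
            cl.p = float((1 + (null >= abs(cl.mass)).sum()) / (n_perm + 1))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(clusters=clusters, entry_p=entry_p,
                             n_permutations=n_perm, sig_p=sig_p, tmap=tmap)


# ---------------------------------------------------------------------------
# random-intercept mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    fixed_effects: dict[str, dict]
    converged: bool
    method: str                    # 'mixed' or 'two-stage'
    interaction_dropped: bool = False


def _two_stage(table: pd.DataFrame, value: str) -> MixedModelResult:
    slopes = linear_load_slope(table, value=value)
    tests = slope_group_tests(slopes)
    fx = {"load": {"estimate": float(slopes["beta"].mean()),
                   "t": tests["within"][list(tests["within"])[0]]["t"]
                   if len(tests["within"]) == 1 else float("nan"),
                   "p": float(sstats.ttest_1samp(slopes["beta"], 0.0).pvalue)}}
    if tests["between"] is not None:
        subj_means = table.groupby(["subject", "group"])[value].mean().reset_index()
        groups = tests["between"]["groups"]
        a = subj_means.loc[subj_means["group"] == groups[0], value]
        b = subj_means.loc[subj_means["group"] == groups[1], value]
        t, p = sstats.ttest_ind(b, a)
        fx["group"] = {"estimate": float(b.mean() - a.mean()), "t": float(t), "p": float(p)}
    return MixedModelResult(fixed_effects=fx, converged=True, method="two-stage")


def random_intercept_model(
    table: pd.DataFrame,
    value: str = "value",
    interaction: bool = True,
    drop_ns_interaction: bool = True,
    alpha: float = 0.05,
) -> MixedModelResult:
    """Mixed model with random intercepts and fixed load + age-group effects.

    The interaction term is dropped when non-significant (the standard
    two-step procedure); on non-convergence the estimator falls back to
    the two-stage per-subject slope analysis with a warning.
    """
    required = {"subject", "group", "load", value}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"missing columns: {sorted(missing)}")
    if table.groupby("subject").size().min() < 2:
        raise ConfigurationError("need >= 2 observations per subject")
    import statsmodels.formula.api as smf

    df = table.rename(columns={value: "y"}).copy()
    df["load"] = df["load"].astype(float)
    two_groups = df["group"].nunique() == 2

    def _fit(formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject"])
            return model.fit(reml=True, method=["lbfgs", "powell"])

    base = "y ~ load + C(group)" if two_groups else "y ~ load"
    dropped = False
    try:
        if interaction and two_groups:
            fit = _fit("y ~ load * C(group)")
            inter_terms = [t for t in fit.params.index if "load:" in t]
            if drop_ns_interaction and inter_terms and all(
                    fit.pvalues[t] > alpha for t in inter_terms):
                fit = _fit(base)
                dropped = True
        else:
            fit = _fit(base)
        if not fit.converged:
            raise RuntimeError("mixed model did not converge")
        fx = {}
        for term in fit.params.index:
            if term == "Group Var":
                continue
            key = ("load" if term == "load"
                   else "group" if term.startswith("C(group)")
                   else "interaction" if "load:" in term
                   else term)
            fx[key] = {"estimate": float(fit.params[term]),
                       "t": float(fit.tvalues[term]),
                       "p": float(fit.pvalues[term])}
        return MixedModelResult(fixed_effects=fx, converged=True, method="mixed",
                                interaction_dropped=dropped)
    except Exception as exc:  # non-convergence or singular fit
        warnings.warn(f"mixed model failed ({exc}); falling back to two-stage estimates",
                      stacklevel=2)
        res = _two_stage(df.rename(columns={"y": value}), value)
        res.converged = False
        return res
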