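"""Task and behavioral partial least squares with resampling inference.

Task PLS decomposes the (group-mean-removed) condition-mean matrix by
SVD; behavioral PLS decomposes the between-subject correlation matrix
between a behavioral block and a neural block.  Latent-variable
significance comes from permutation of the singular values; salience
reliability from bootstrap ratios (salience / bootstrap SE) with
Procrustes alignment of resampled singular vectors.

Sign convention: within each latent variable the largest-magnitude
element of the neural salience vector is positive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import ConfigurationError

__all__ = [
    "DataMatrix",
    "PLSResult",
    "task_pls",
    "behavioral_pls",
    "permutation_test",
    "bootstrap_bsr",
]


@dataclass
class DataMatrix:
    """Subject(-condition) rows by neural-variable columns with metadata."""

    values: np.ndarray
    subjects: np.ndarray
    groups: np.ndarray
    conditions: np.ndarray | None = None
    columns: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.groups = np.asarray(self.groups)
        n = self.values.shape[0]
        if self.subjects.size != n or self.groups.size != n:
            raise ConfigurationError("row metadata does not match the data rows")
        if self.conditions is not None:
            self.conditions = np.asarray(self.conditions)
            if self.conditions.size != n:
                raise ConfigurationError("condition metadata does not match the data rows")
        if not np.isfinite(self.values).all():
            raise ConfigurationError("data matrix contains missing cells; impute upstream")


@dataclass
class PLSResult:
    kind: str                      # 'task' | 'behavioral'
    U: np.ndarray                  # condition/behavior saliences
    S: np.ndarray                  # singular values, descending
    V: np.ndarray                  # neural saliences
    row_meta: pd.DataFrame         # metadata of the decomposed rows (U rows)
    brainscores: pd.DataFrame      # subject(-condition) scores per LV
    matrix: np.ndarray | None = None   # the decomposed matrix (COV/CORR rows)
    perm_p: np.ndarray | None = None
    bsr: np.ndarray | None = None
    bsr_threshold: float | None = None
    _data: DataMatrix | None = field(default=None, repr=False)
    _behavior: np.ndarray | None = field(default=None, repr=False)
    _remove_group_means: bool = field(default=True, repr=False)

    @property
    def n_lv(self) -> int:
        return self.S.size

    def reliable_mask(self) -> np.ndarray:
        if self.bsr is None or self.bsr_threshold is None:
            raise ConfigurationError("run bootstrap_bsr first")
        return np.abs(self.bsr) >= self.bsr_threshold


def _fix_signs(U: np.ndarray, S: np.ndarray, V: np.ndarray):
    for k in range(S.size):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    return U, S, V


# ---------------------------------------------------------------------------
# task PLS
# ---------------------------------------------------------------------------

def _task_matrix(values: np.ndarray, subjects: np.ndarray, groups: np.ndarray,
                 conditions: np.ndarray, remove_group_means: bool):
    glabels = pd.unique(groups)
    clabels = np.sort(pd.unique(conditions))
    rows, meta = [], []
    for g in glabels:
        gmask = groups == g
        cond_means = []
        for c in clabels:
            sel = gmask & (conditions == c)
            if not sel.any():
                raise ConfigurationError(f"no rows for group {g!r}, condition {c!r}")
            cond_means.append(values[sel].mean(axis=0))
            meta.append({"group": g, "condition": c})
        cond_means = np.asarray(cond_means)
        if remove_group_means:
            cond_means = cond_means - cond_means.mean(axis=0, keepdims=True)
        rows.append(cond_means)
    return np.vstack(rows), pd.DataFrame(meta)


def task_pls(data: DataMatrix, remove_group_means: bool = True) -> PLSResult:
    """Mean-centered task PLS over subject-condition rows.

    Condition means are computed per group, group means removed (when
    requested) to emphasize condition and condition-by-group effects,
    and the stacked matrix is decomposed by SVD.
    """
    if data.conditions is None:
        raise ConfigurationError("task PLS requires condition labels per row")
    clabels = pd.unique(data.conditions)
    if clabels.size < 2:
        raise ConfigurationError("task PLS requires >= 2 conditions")
    for g in pd.unique(data.groups):
        if pd.unique(data.subjects[data.groups == g]).size < 2:
            raise ConfigurationError(f"group {g!r} has < 2 subjects")

    M, meta = _task_matrix(data.values, data.subjects, data.groups,
                           data.conditions, remove_group_means)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.linalg.matrix_rank(M))
    if rank < S.size:
        warnings.warn(f"rank-deficient input: keeping {rank} of {S.size} LVs",
                      stacklevel=2)
        U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    V = Vt.T
    U, S, V = _fix_signs(U.copy(), S, V.copy())

    scores = data.values @ V
    bs = pd.DataFrame({"subject": data.subjects, "group": data.groups,
                       "condition": data.conditions})
    for k in range(S.size):
        bs[f"lv{k + 1}"] = scores[:, k]
    return PLSResult(kind="task", U=U, S=S, V=V, row_meta=meta, brainscores=bs,
                     matrix=M, _data=data, _remove_group_means=remove_group_means)


# ---------------------------------------------------------------------------
# behavioral PLS
# ---------------------------------------------------------------------------

def _zscore_cols(x: np.ndarray, what: str, names=None) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ConfigurationError(f"zero-variance {what} variable: {label}")
    return (x - x.mean(axis=0)) / sd


def _behavioral_corr(neural: np.ndarray, behavior: np.ndarray,
                     behavior_names=None, columns=None) -> np.ndarray:
    xz = _zscore_cols(neural, "neural", columns)
    bz = _zscore_cols(behavior, "behavioral", behavior_names)
    return bz.T @ xz / (neural.shape[0] - 1)


def behavioral_pls(
    neural: DataMatrix,
    behavior: np.ndarray,
    behavior_names: list[str] | None = None,
) -> PLSResult:
    """Brain-behavior PLS on the column-wise correlation matrix.

    ``neural`` rows are one per subject; ``behavior`` is subject x
    variable.  U holds behavioral saliences, V neural saliences;
    brainscores are projections of the z-scored neural rows onto V.
    """
    behavior = np.atleast_2d(np.asarray(behavior, dtype=float))
    if behavior.shape[0] != neural.values.shape[0]:
        raise ConfigurationError("behavior rows must match neural rows (same subjects)")
    if behavior.shape[1] < 2:
        raise ConfigurationError("behavioral PLS requires >= 2 behavioral variables")
    corr = _behavioral_corr(neural.values, behavior, behavior_names, neural.columns)
    U, S, Vt = np.linalg.svd(corr, full_matrices=False)
    V = Vt.T
    U, S, V = _fix_signs(U.copy(), S, V.copy())

    scores = _zscore_cols(neural.values, "neural", neural.columns) @ V
    bs = pd.DataFrame({"subject": neural.subjects, "group": neural.groups})
    for k in range(S.size):
        bs[f"lv{k + 1}"] = scores[:, k]
    meta = pd.DataFrame({"behavior": behavior_names
                         if behavior_names is not None
                         else [f"b{i}" for i in range(behavior.shape[1])]})
    return PLSResult(kind="behavioral", U=U, S=S, V=V, row_meta=meta,
                     brainscores=bs, matrix=corr, _data=neural, _behavior=behavior)


# ---------------------------------------------------------------------------
# permutation and bootstrap
# ---------------------------------------------------------------------------

def _task_singvals(data: DataMatrix, conditions: np.ndarray,
                   remove_group_means: bool, k: int) -> np.ndarray:
    M, _ = _task_matrix(data.values, data.subjects, data.groups, conditions,
                        remove_group_means)
    s = np.linalg.svd(M, compute_uv=False)
    return s[:k]


def permutation_test(model: PLSResult, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Permutation p per LV (rank-matched singular values).

    Task PLS shuffles condition labels within each subject; behavioral
    PLS shuffles the subject correspondence of the behavior block.
    """
    rng = child_rng(seed, "pls", 0)
    k = model.n_lv
    exceed = np.zeros(k)
    if model.kind == "task":
        data = model._data
        conditions = data.conditions.copy()
        for _ in range(n_perm):
            perm = conditions.copy()
            for s in pd.unique(data.subjects):
                idx = np.flatnonzero(data.subjects == s)
                perm[idx] = perm[rng.permutation(idx)]
            s_perm = _task_singvals(data, perm, model._remove_group_means, k)
            exceed += s_perm >= model.S
    else:
        neural, behavior = model._data, model._behavior
        n = behavior.shape[0]
        for _ in range(n_perm):
            corr = _behavioral_corr(neural.values, behavior[rng.permutation(n)],
                                    columns=neural.columns)
            s_perm = np.linalg.svd(corr, compute_uv=False)[:k]
            exceed += s_perm >= model.S
    p = (exceed + 1.0) / (n_perm + 1.0)
    model.perm_p = p
    return p


def _procrustes_align(V_boot: np.ndarray, V_ref: np.ndarray) -> np.ndarray:
    M = V_boot.T @ V_ref
    P, _, Qt = np.linalg.svd(M)
    return V_boot @ (P @ Qt)


def bootstrap_bsr(model: PLSResult, n_boot: int = 1000, threshold: float = 3.0,
                  seed: int = 0, max_redraws: int = 100) -> np.ndarray:
    """Bootstrap ratios of the neural saliences.

    Subjects are resampled with replacement within group; resampled V
    matrices are Procrustes-aligned to the observed solution before the
    element-wise SE is computed.  Degenerate resamples (zero-variance
    columns) are redrawn and counted.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    rng = child_rng(seed, "pls", 1)
    data = model._data
    subjects = pd.unique(data.subjects)
    subj_group = {s: data.groups[data.subjects == s][0] for s in subjects}
    by_group = {g: [s for s in subjects if subj_group[s] == g]
                for g in pd.unique(data.groups)}
    rows_of = {s: np.flatnonzero(data.subjects == s) for s in subjects}

    boots = np.empty((n_boot, *model.V.shape))
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(max_redraws):
            draw = []
            for g, members in by_group.items():
                draw.extend(rng.choice(members, size=len(members), replace=True))
            rows = np.concatenate([rows_of[s] for s in draw])
            try:
                if model.kind == "task":
                    resampled = DataMatrix(values=data.values[rows],
                                           subjects=np.repeat(np.arange(len(draw)),
                                                              [rows_of[s].size for s in draw]),
                                           groups=data.groups[rows],
                                           conditions=data.conditions[rows])
                    M, _ = _task_matrix(resampled.values, resampled.subjects,
                                        resampled.groups, resampled.conditions,
                                        model._remove_group_means)
                    _, _, Vt = np.linalg.svd(M, full_matrices=False)
                    Vb = Vt.T[:, :model.n_lv]
                else:
                    beh_rows = np.array([rows_of[s][0] for s in draw])
                    corr = _behavioral_corr(data.values[beh_rows],
                                            model._behavior[beh_rows],
                                            columns=data.columns)
                    _, _, Vt = np.linalg.svd(corr, full_matrices=False)
                    Vb = Vt.T[:, :model.n_lv]
            except ConfigurationError:
                n_redrawn += 1
                continue
            boots[b] = _procrustes_align(Vb, model.V)
            break
        else:
            raise ConfigurationError("could not draw a non-degenerate bootstrap sample")
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap samples", stacklevel=2)

    se = boots.std(axis=0, ddof=1)
    bsr = np.where(se > 0, model.V / np.where(se > 0, se, 1.0), np.inf * np.sign(model.V))
    model.bsr = bsr
    model.bsr_threshold = threshold
    return bsr
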