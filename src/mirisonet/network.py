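"""Weighted co-expression network: adjacency, topological overlap,
module detection, eigengenes, module–trait correlation, kME and hubs.

The workflow follows the WGCNA recipe: soft-threshold the feature
correlation matrix into an adjacency, convert to a topological overlap
similarity, cluster on 1 − TOM with average linkage, cut the tree at a
static height, discard clusters below the minimum module size to an
unassigned 'grey' pool, and iteratively merge modules whose eigengenes
are closer than the merge threshold.  Hub features are the top members
of each module by own-module kME.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import ExpressionMatrix

GREY = "grey"
#: WGCNA-style module colours assigned to surviving modules by size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

DEFAULT_BETA = 6
DEFAULT_MIN_MODULE_SIZE = 600
DEFAULT_MERGE_THRESHOLD = 0.5
DEFAULT_CUT_HEIGHT = 0.99
HUB_COUNT = 150


def adjacency(
    expr: np.ndarray | pd.DataFrame, beta: float = DEFAULT_BETA, signed: bool = False
) -> np.ndarray:
    """Soft-thresholded co-expression adjacency (features x features).

    ``expr`` is features x samples.  Unsigned: |cor|^beta; signed:
    ((1 + cor)/2)^beta.  Diagonal is 1.
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need >= 2 features and >= 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    sd = X.std(axis=1)
    if (sd == 0).any():
        idx = int(np.argmax(sd == 0))
        raise ValueError(f"zero-variance feature at index {idx}; pre-filter first")
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    a = np.abs(cor) ** beta if not signed else ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_power(
    expr: np.ndarray,
    betas: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_min: float = 0.8,
    signed: bool = False,
) -> int:
    """Smallest beta whose degree distribution fits a scale-free law with
    R^2 >= r2_min on the log-log regression; falls back to the default."""
    for beta in betas:
        a = adjacency(expr, beta=beta, signed=signed)
        k = a.sum(axis=0) - 1.0
        hist, edges = np.histogram(k, bins=10)
        mids = (edges[:-1] + edges[1:]) / 2
        ok = (hist > 0) & (mids > 0)
        if ok.sum() < 3:
            continue
        x, y = np.log10(mids[ok]), np.log10(hist[ok])
        r = stats.pearsonr(x, y)[0]
        if r**2 >= r2_min:
            return beta
    return DEFAULT_BETA


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a symmetric [0,1] adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) for i != j, with
    L_ij = sum_u!=i,j a_iu a_uj and k_i = sum_u!=i a_iu; TOM_ii = 1.
    """
    A = np.asarray(adj, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    k = B.sum(axis=1)
    L = B @ B  # L[i,j] includes u != i,j automatically since diag(B)=0
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + B) / (kmin + 1.0 - B)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(expr: np.ndarray) -> np.ndarray:
    """First principal component across samples of z-scored member rows.

    Returns a unit-variance-free PC score vector of length n_samples,
    sign-oriented so the mean member correlation is positive.
    """
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("eigengene needs a members x samples matrix with >= 2 samples")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    # PC1 over samples: right singular vector of Z
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    cors = np.array([_safe_cor(row, eig) for row in Z])
    if np.nanmean(cors) < 0:
        eig = -eig
    return eig


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ModuleAssignment:
    labels: pd.Series                  # feature -> module colour ('grey' = none)
    eigengenes: pd.DataFrame | None = None   # module x sample
    kme: pd.DataFrame | None = None          # feature x module
    hubs: dict[str, list[str]] = field(default_factory=dict)
    module_trait_r: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    beta: float = DEFAULT_BETA
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> ModuleAssignment:
    """Assign features to colour-named modules from a TOM.

    ``expr`` (features x samples, same order as ``tom``) supplies the
    profiles for eigengene-based merging.  Clusters below
    ``min_module_size`` go to grey; module pairs with eigengene
    dissimilarity (1 − cor) below ``merge_threshold`` are merged
    iteratively, largest-module-first colour naming at the end.
    """
    features = list(expr.index)
    n = len(features)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match expression matrix")
    if min_module_size > n:
        import warnings

        warnings.warn("min_module_size exceeds feature count; all features grey")
        return ModuleAssignment(
            labels=pd.Series(GREY, index=features),
            min_module_size=min_module_size,
            merge_threshold=merge_threshold,
        )
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    X = expr.to_numpy(dtype=float)
    clusters: dict[int, list[int]] = {}
    for idx, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(idx)
    groups = [idxs for idxs in clusters.values() if len(idxs) >= min_module_size]

    # iterative eigengene merging
    merged = True
    while merged and len(groups) > 1:
        merged = False
        eigs = [module_eigengene(X[idxs]) for idxs in groups]
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = 1.0 - _safe_cor(eigs[i], eigs[j])
                if d < merge_threshold and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is not None:
            _, i, j = best
            groups[i] = groups[i] + groups[j]
            del groups[j]
            merged = True

    groups.sort(key=len, reverse=True)
    labels = pd.Series(GREY, index=features, dtype=object)
    for color, idxs in zip(MODULE_COLORS, groups):
        labels.iloc[idxs] = color
    if len(groups) > len(MODULE_COLORS):
        for extra, idxs in enumerate(groups[len(MODULE_COLORS):]):
            labels.iloc[idxs] = f"module{extra + len(MODULE_COLORS)}"
    return ModuleAssignment(
        labels=labels,
        min_module_size=min_module_size,
        merge_threshold=merge_threshold,
    )


def module_trait_and_kme(
    assignment: ModuleAssignment,
    expr: ExpressionMatrix,
    hub_count: int = HUB_COUNT,
) -> ModuleAssignment:
    """Fill in eigengenes, module–trait correlations, kME and hub sets.

    Traits are one-hot tissue indicators over samples; r is the Pearson
    correlation of each module eigengene with each indicator, p from the
    t-distribution with n − 2 degrees of freedom.  Hubs are the top
    ``hub_count`` members of each module by own-module kME (ties broken
    by feature id).
    """
    samples = expr.sample_ids
    if len(samples) < 3:
        raise ValueError("module-trait correlation needs >= 3 samples")
    X = expr.values
    modules = sorted(assignment.modules, key=lambda m: -len(assignment.members(m)))
    eig_rows = {}
    for m in modules:
        members = assignment.members(m)
        eig_rows[m] = module_eigengene(X.loc[members].to_numpy())
    eigengenes = pd.DataFrame(eig_rows, index=samples).T

    tissues = expr.tissues
    n = len(samples)
    r_tab = pd.DataFrame(index=modules, columns=tissues, dtype=float)
    p_tab = pd.DataFrame(index=modules, columns=tissues, dtype=float)
    for t in tissues:
        indicator = np.array([1.0 if expr.design[s] == t else 0.0 for s in samples])
        for m in modules:
            r = _safe_cor(eigengenes.loc[m].to_numpy(), indicator)
            r_tab.at[m, t] = r
            if abs(r) >= 1.0:
                p_tab.at[m, t] = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
                p_tab.at[m, t] = 2.0 * stats.t.sf(abs(tstat), df=n - 2)

    features = list(assignment.labels.index)
    kme = pd.DataFrame(index=features, columns=modules, dtype=float)
    Xv = X.loc[features].to_numpy(dtype=float)
    for m in modules:
        eig = eigengenes.loc[m].to_numpy()
        kme[m] = [_safe_cor(row, eig) for row in Xv]

    hubs = {}
    for m in modules:
        members = assignment.members(m)
        ranked = sorted(members, key=lambda f: (-kme.at[f, m], f))
        hubs[m] = ranked[: min(hub_count, len(members))]

    assignment.eigengenes = eigengenes
    assignment.kme = kme
    assignment.hubs = hubs
    assignment.module_trait_r = r_tab
    assignment.module_trait_p = p_tab
    return assignment


def build_network(
    expr: ExpressionMatrix,
    beta: float = DEFAULT_BETA,
    signed: bool = False,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    hub_count: int = HUB_COUNT,
) -> ModuleAssignment:
    """End-to-end: adjacency -> TOM -> modules -> eigengenes/kME/hubs."""
    a = adjacency(expr.values.to_numpy(dtype=float), beta=beta, signed=signed)
    tom = tom_similarity(a)
    assignment = detect_modules(
        tom,
        expr.values,
        min_module_size=min_module_size,
        merge_threshold=merge_threshold,
        cut_height=cut_height,
    )
    assignment.beta = beta
    if assignment.modules:
        module_trait_and_kme(assignment, expr, hub_count=hub_count)
    return assignment
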