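"""Differential co-expression: adjacency differences, topological overlap,
module detection, hub genes, and condition-wise correlation comparison.

Between two conditions (e.g. tumour and normal) with Spearman correlation
matrices C_case and C_control, the adjacency-difference matrix is

    d_ij = ( 1/2 * | sign(c_case) c_case^2 - sign(c_control) c_control^2 | )^beta

with integer beta chosen from a grid so that clustering yields the fewest
modules with the smallest largest module. Genes with shared correlation
changes are grouped by clustering the topological-overlap dissimilarity

    t_ij = 1 - ( sum_{k != i,j} d_ik d_kj + d_ij )
               / ( min(sum_{k != i} d_ik, sum_{k != j} d_kj) + 1 - d_ij )

Hub genes use the signed weighted-network convention: within-module
adjacency ((1 + cor)/2)^power (power 2), hub = largest row sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "correlation_matrix",
    "adjacency_difference",
    "tom_dissimilarity",
    "select_beta",
    "detect_modules",
    "hub_gene",
    "compare_focal_networks",
    "NetworkComparison",
]

UNASSIGNED = "grey"


def correlation_matrix(x: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Gene x gene correlation of a samples x genes table.

    Constant genes have no defined correlation; their off-diagonal entries
    are set to 0 with a warning, diagonal stays 1.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 samples for correlations, got {x.shape[0]}")
    # contiguous copy: the BLAS path behind corrcoef must not depend on the
    # caller's memory layout, or identical inputs yield 1-ulp different output
    values = np.ascontiguousarray(x.to_numpy(dtype=float))
    constant = values.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant genes: correlations set to 0", stacklevel=2
        )
    if method == "spearman":
        data = stats.rankdata(values, axis=0)
    else:
        data = values
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return pd.DataFrame(corr, index=x.columns, columns=x.columns)


def _as_matrix(c) -> np.ndarray:
    m = c.to_numpy(dtype=float) if isinstance(c, pd.DataFrame) else np.asarray(c, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation input must be a square matrix")
    if np.any(np.abs(m) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    return np.clip(m, -1.0, 1.0)


def adjacency_difference(c_case, c_control, beta: int = 1):
    """d_ij = (1/2 |sign(c_case) c_case^2 - sign(c_control) c_control^2|)^beta."""
    case = _as_matrix(c_case)
    control = _as_matrix(c_control)
    if case.shape != control.shape:
        raise ValueError("case and control correlation matrices differ in shape")
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    d = (0.5 * np.abs(np.sign(case) * case**2 - np.sign(control) * control**2)) ** beta
    np.fill_diagonal(d, 0.0)
    if isinstance(c_case, pd.DataFrame):
        return pd.DataFrame(d, index=c_case.index, columns=c_case.columns)
    return d


def tom_dissimilarity(d):
    """Topological-overlap dissimilarity of an adjacency(-difference) matrix.

    The k-sum excludes i and j (the zero diagonal makes this automatic in
    the matrix product); t_ii = 0 by convention.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or np.any(dm < 0) or np.any(dm > 1):
        raise ValueError("adjacency entries must be a square matrix in [0, 1]")
    if np.any(np.diag(dm) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.allclose(dm, dm.T):
        raise ValueError("adjacency matrix must be symmetric")
    shared = dm @ dm  # diagonal of d is zero, so k = i and k = j drop out
    conn = dm.sum(axis=1)
    denom = np.minimum.outer(conn, conn) + 1.0 - dm
    t = 1.0 - (shared + dm) / denom
    np.fill_diagonal(t, 0.0)
    t = np.clip(t, 0.0, 1.0)
    if isinstance(d, pd.DataFrame):
        return pd.DataFrame(t, index=d.index, columns=d.columns)
    return t


def detect_modules(t, min_module_size: int = 5, cut_height: float | str = 0.99) -> pd.Series:
    """Average-linkage clustering of the TOM dissimilarity.

    ``cut_height`` is either a static dendrogram cut or ``"gap"``: candidate
    cuts are placed in every gap between consecutive merge heights and the
    one assigning the most genes to modules of at least
    ``min_module_size`` wins (ties: fewer modules, then the lower cut).
    This adapts to high beta values, which compress all dissimilarities
    towards 1 so that no fixed cut separates them. Clusters below
    ``min_module_size`` are labelled ``grey`` (unassigned); the rest are
    renamed M1, M2, ... in decreasing size.
    """
    genes = list(t.index) if isinstance(t, pd.DataFrame) else [f"g{j}" for j in range(len(t))]
    tm = t.to_numpy(dtype=float) if isinstance(t, pd.DataFrame) else np.asarray(t, dtype=float)
    tm = (tm + tm.T) / 2.0
    np.fill_diagonal(tm, 0.0)
    linkage = average(squareform(tm, checks=False))
    if cut_height == "gap":
        heights = np.sort(linkage[:, 2])
        midpoints = [
            (a + b) / 2.0 for a, b in zip(heights, heights[1:]) if b - a > 1e-12
        ] or [heights[0] / 2.0 if len(heights) else 0.99]
        best = None
        for cut in midpoints:
            labels = fcluster(linkage, t=cut, criterion="distance")
            sizes = np.bincount(labels)
            assigned = int(sizes[sizes >= min_module_size].sum())
            n_modules = int((sizes[1:] >= min_module_size).sum())
            key = (-assigned, n_modules, cut)
            if best is None or key < best[0]:
                best = (key, labels)
        raw = best[1]
    else:
        raw = fcluster(linkage, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    rename = {c: f"M{r + 1}" for r, c in enumerate(ordered)}
    labels = [rename.get(c, UNASSIGNED) for c in raw]
    return pd.Series(labels, index=genes, name="module")


def select_beta(
    c_case,
    c_control,
    grid=range(5, 11),
    min_module_size: int = 5,
    cut_height: float | str = "gap",
) -> int:
    """Pick beta minimising (module count, largest-module size) lexicographically.

    Grid values yielding no module at all are ineligible; ties go to the
    smallest beta.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("beta grid is empty")
    best = None
    for beta in grid:
        try:
            t = tom_dissimilarity(adjacency_difference(c_case, c_control, beta))
            modules = detect_modules(t, min_module_size, cut_height)
        except Exception:
            continue
        sizes = modules[modules != UNASSIGNED].value_counts()
        if sizes.empty:
            continue
        key = (len(sizes), int(sizes.max()), beta)
        if best is None or key < best:
            best = key
    if best is None:
        raise RuntimeError("module detection produced no modules for any beta in the grid")
    return best[2]


def hub_gene(x: pd.DataFrame, modules: pd.Series, power: int = 2) -> dict:
    """Most-connected gene per module in a signed weighted network.

    Adjacency within a module is ((1 + pearson_cor)/2)^power; the hub is
    the gene with the largest adjacency row sum, ties broken
    lexicographically. Singleton and unassigned groups are skipped.
    """
    hubs: dict[str, str] = {}
    for label in sorted(set(modules) - {UNASSIGNED}):
        members = list(modules.index[modules == label])
        if len(members) < 2:
            warnings.warn(f"module {label} has fewer than 2 genes; skipped", stacklevel=2)
            continue
        corr = correlation_matrix(x[members], method="pearson").to_numpy()
        adj = ((1.0 + corr) / 2.0) ** power
        np.fill_diagonal(adj, 0.0)
        connectivity = adj.sum(axis=1)
        # deterministic tiebreak: highest connectivity, then lexicographic id
        order = sorted(range(len(members)), key=lambda j: (-connectivity[j], members[j]))
        hubs[label] = members[order[0]]
    return hubs


@dataclass(frozen=True)
class NetworkComparison:
    """Correlation profiles of one focal gene in two conditions plus a KS test."""

    focal_gene: str
    other_genes: tuple[str, ...]
    correlations_case: np.ndarray
    correlations_control: np.ndarray
    ks_statistic: float
    ks_p: float


def compare_focal_networks(x_case: pd.DataFrame, x_control: pd.DataFrame, focal: str, others) -> NetworkComparison:
    """Pearson correlations of a focal gene against partner genes in each
    condition, compared with a two-sample Kolmogorov-Smirnov test."""
    others = list(others)
    if focal in others:
        raise ValueError("focal gene must not appear among the partner genes")
    for frame, name in ((x_case, "case"), (x_control, "control")):
        if frame.shape[0] < 3:
            raise ValueError(f"{name} condition has fewer than 3 samples")
        missing = [g for g in [focal, *others] if g not in frame.columns]
        if missing:
            raise KeyError(f"{name} matrix lacks genes {missing[:5]}")

    def profile(frame: pd.DataFrame) -> np.ndarray:
        corr = correlation_matrix(frame[[focal, *others]], method="pearson")
        return corr.loc[focal, others].to_numpy(dtype=float)

    case = profile(x_case)
    control = profile(x_control)
    if np.array_equal(case, control):
        ks_stat, ks_p = 0.0, 1.0
    else:
        res = stats.ks_2samp(case, control, method="asymp")
        ks_stat, ks_p = float(res.statistic), float(res.pvalue)
    return NetworkComparison(
        focal_gene=focal,
        other_genes=tuple(others),
        correlations_case=case,
        correlations_control=control,
        ks_statistic=ks_stat,
        ks_p=min(ks_p, 1.0),
    )
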