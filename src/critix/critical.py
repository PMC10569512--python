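"""Critical indexes: aggregating Shapley attributions into per-gene scores.

A gene's contribution to latent variable ``h`` is summarised by the mean
absolute attribution over samples,

    SV_{h,i} = (1/n) * sum_s |phi_{i,h,s}|

and the critical index weights those summaries by each surrogate's R^2:

    WSV_i = sum_h w_h * SV_{h,i}.

Critical genes are the top ceil(fraction * G) by WSV (default 1%), the
ceiling making the cut inclusive when fraction * G is not an integer
(e.g. 20 genes at 1% -> 1 gene, 180 genes -> 2 genes).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .explain import ShapTensor

__all__ = [
    "per_latent_mean_abs",
    "critical_index",
    "select_top",
    "critical_table",
]

NONZERO_TOL = 1e-12  # "non-zero critical index" threshold for enrichment queries


def per_latent_mean_abs(tensor: ShapTensor) -> pd.DataFrame:
    """SV matrix (genes x latent): mean |attribution| over samples."""
    if tensor.values.shape[2] < 1:
        raise ValueError("need at least one sample")
    sv = np.abs(tensor.values).mean(axis=2)  # (G, H)
    return pd.DataFrame(
        sv, index=list(tensor.gene_ids), columns=[f"SV_{h}" for h in range(tensor.n_latent)]
    )


def critical_index(sv: pd.DataFrame | np.ndarray, weights: np.ndarray) -> pd.Series | np.ndarray:
    """WSV_i = sum_h w_h * SV_{h,i}; weights must be non-negative."""
    weights = np.asarray(weights, dtype=float)
    values = sv.to_numpy() if isinstance(sv, pd.DataFrame) else np.asarray(sv, dtype=float)
    if values.shape[1] != weights.shape[0]:
        raise ValueError(f"SV has {values.shape[1]} latent columns but got {weights.shape[0]} weights")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative (clamp surrogate R^2 upstream)")
    wsv = values @ weights
    if isinstance(sv, pd.DataFrame):
        return pd.Series(wsv, index=sv.index, name="WSV")
    return wsv


def select_top(wsv: pd.Series, fraction: float = 0.01) -> list[str]:
    """The ceil(fraction * G) genes with the largest critical index.

    Ties are broken by descending WSV then lexicographic gene id, so the
    selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(wsv))
    order = sorted(wsv.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gene for gene, _ in order[:k]]


def critical_table(tensor: ShapTensor, fraction: float = 0.01) -> pd.DataFrame:
    """Full per-gene summary: SV columns, WSV, rank and selection flag."""
    sv = per_latent_mean_abs(tensor)
    wsv = critical_index(sv, tensor.weights)
    table = sv.copy()
    table["WSV"] = wsv
    order = sorted(wsv.items(), key=lambda kv: (-kv[1], kv[0]))
    rank = {gene: r + 1 for r, (gene, _) in enumerate(order)}
    table["rank"] = [rank[g] for g in table.index]
    selected = set(select_top(wsv, fraction))
    table["is_critical"] = [g in selected for g in table.index]
    table.index.name = "gene_id"
    return table
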