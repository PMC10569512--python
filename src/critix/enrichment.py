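"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list of n genes drawn from a background of N annotated genes,
the upper-tail hypergeometric p-value for a set with M members and k
overlapping query genes is

    p = P(X >= k),  X ~ Hypergeometric(N, M, n)

evaluated through scipy's log-space survival function. By default the
background is the union of all annotated genes and p-values are adjusted
by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "hypergeom_p", "run_ora"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the annotation background (their union by default)."""

    sets: dict
    descriptions: dict
    background: frozenset

    @classmethod
    def from_sets(cls, sets: dict, descriptions: dict | None = None, background=None) -> "GeneSetCollection":
        clean = {name: tuple(dict.fromkeys(members)) for name, members in sets.items()}
        union = set().union(*(set(m) for m in clean.values())) if clean else set()
        bg = frozenset(background) if background is not None else frozenset(union)
        if not union <= bg:
            raise ValueError("background must contain every annotated gene")
        return cls(sets=clean, descriptions=dict(descriptions or {}), background=bg)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets, descs = {}, {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT rows need name, description, >=1 gene")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
            sets[name] = members
            descs[name] = desc
    return GeneSetCollection.from_sets(sets, descs)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def hypergeom_p(N: int, n: int, M: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    N: background size, n: query size, M: set size, k: overlap.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(n, M)):
        raise ValueError(f"inconsistent counts N={N}, n={n}, M={M}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def run_ora(query, collection: GeneSetCollection, adjust: str = "BH") -> pd.DataFrame:
    """Over-representation of a query gene list in each annotated set.

    Query genes outside the background are dropped (with a warning); the
    result has one row per set, sorted by ascending p-value, with the
    chosen multiple-testing adjustment ("BH", "bonferroni" or "none").
    """
    query = list(dict.fromkeys(query))
    if not query:
        raise ValueError("query gene list is empty")
    in_bg = [g for g in query if g in collection.background]
    dropped = [g for g in query if g not in collection.background]
    if not in_bg:
        raise ValueError(
            f"no query gene found in the annotation background; e.g. {dropped[:5]}"
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the annotation background were "
            f"dropped (e.g. {dropped[:3]})",
            stacklevel=2,
        )
    N = len(collection.background)
    n = len(in_bg)
    query_set = set(in_bg)
    rows = []
    for name, members in collection.sets.items():
        M = len(members)
        k = len(query_set & set(members))
        rows.append(
            {
                "gene_set": name,
                "description": collection.descriptions.get(name, ""),
                "N": N,
                "n": n,
                "M": M,
                "k": k,
                "p_value": hypergeom_p(N, n, M, k),
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "BH":
        table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    elif adjust == "bonferroni":
        table["adjusted_p"] = multipletests(table["p_value"], method="bonferroni")[1]
    elif adjust == "none":
        table["adjusted_p"] = table["p_value"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
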