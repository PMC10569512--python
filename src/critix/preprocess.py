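"""Expression-matrix loading, filtering, transformation and splitting.

The training protocol expects TPM-like non-negative expression values that
pass through a fixed pipeline before reaching the autoencoder:

    raw -> filtered (median > threshold) -> log2(v + pseudocount) -> min-max [0, 1]

Each stage is recorded on the :class:`ExpressionMatrix` so out-of-order
application raises instead of silently producing garbage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SplitIndex",
    "load_expression",
    "filter_by_median",
    "log2_transform",
    "minmax_scale",
    "inverse_minmax",
    "split_train_test",
]

_STAGES = ("raw", "filtered", "log2", "scaled")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes expression table with pipeline-stage bookkeeping.

    Parameters
    ----------
    values
        2-D float array, one row per sample, one column per gene.
    gene_ids, sample_ids
        Unique ordered identifiers matching the array axes.
    stage
        One of ``raw``, ``filtered``, ``log2``, ``scaled``.
    scale_min, scale_max
        Per-gene minima/maxima retained by :func:`minmax_scale` so the
        transform can be inverted; ``None`` before scaling.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    stage: str = "raw"
    scale_min: np.ndarray | None = field(default=None, compare=False)
    scale_max: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples x genes)")
        if values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values contain non-finite entries")
        if self.stage in ("raw", "filtered", "log2") and np.any(values < 0):
            raise ValueError(f"negative expression values at stage {self.stage!r}")
        if self.stage == "scaled" and (np.any(values < -1e-12) or np.any(values > 1 + 1e-12)):
            raise ValueError("scaled expression values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.gene_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stage: str = "raw") -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=tuple(str(g) for g in frame.columns),
            sample_ids=tuple(str(s) for s in frame.index),
            stage=stage,
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to the given genes (order as given), keeping the stage."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [index[g] for g in gene_ids]
        return replace(
            self,
            values=self.values[:, cols],
            gene_ids=tuple(gene_ids),
            scale_min=None if self.scale_min is None else self.scale_min[cols],
            scale_max=None if self.scale_max is None else self.scale_max[cols],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return replace(self, values=self.values[rows], sample_ids=tuple(sample_ids))


@dataclass(frozen=True)
class SplitIndex:
    """Train/test partition of sample identifiers produced by a seeded shuffle."""

    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_sample_ids", tuple(self.train_sample_ids))
        object.__setattr__(self, "test_sample_ids", tuple(self.test_sample_ids))
        overlap = set(self.train_sample_ids) & set(self.test_sample_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {kind} identifier {name!r}")
        seen.add(name)


def _require_stage(m: ExpressionMatrix, expected: str, op: str) -> None:
    if m.stage != expected:
        raise ValueError(
            f"{op} expects a matrix at stage {expected!r}, got {m.stage!r}; "
            f"the pipeline order is {' -> '.join(_STAGES)}"
        )


def load_expression(path, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read a TSV/CSV expression table into a samples x genes matrix.

    ``orientation`` names the layout *on disk*; either way the result is
    internally samples x genes. gzip-compressed files are accepted
    (pandas infers compression from the filename).
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    for axis, kind in ((frame.index, "gene" if orientation == "genes_by_samples" else "sample"),
                       (frame.columns, "sample" if orientation == "genes_by_samples" else "gene")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {kind} identifier {dup[0]!r} in {path}")
    non_numeric = frame.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = non_numeric.isna() & frame.notna()
    if bad.any().any() or frame.isna().any().any():
        mask = bad | frame.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise ValueError(
            f"non-numeric or missing cell at row {row!r}, column {col!r} "
            f"(value {frame.loc[row, col]!r}) in {path}"
        )
    if orientation == "genes_by_samples":
        non_numeric = non_numeric.T
    return ExpressionMatrix.from_frame(non_numeric.astype(float), stage="raw")


def filter_by_median(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose median expression across samples is strictly above
    ``threshold`` (default 1.0, the low-expression cut for TPM input)."""
    _require_stage(m, "raw", "filter_by_median")
    medians = np.median(m.values, axis=0)
    keep = medians > threshold
    if not keep.any():
        raise ValueError(
            f"median filter at threshold {threshold} removed every gene; "
            "lower the threshold or check the input units"
        )
    return ExpressionMatrix(
        values=m.values[:, keep],
        gene_ids=tuple(g for g, k in zip(m.gene_ids, keep) if k),
        sample_ids=m.sample_ids,
        stage="filtered",
    )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """v -> log2(v + pseudocount). TPM matrices contain zeros, hence the
    pseudocount (default 1, the usual log2(TPM+1) convention)."""
    _require_stage(m, "filtered", "log2_transform")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return replace(m, values=np.log2(m.values + pseudocount), stage="log2")


def minmax_scale(m: ExpressionMatrix, fit_sample_ids=None) -> ExpressionMatrix:
    """Rescale each gene to [0, 1] to match a sigmoid output layer.

    ``fit_sample_ids`` optionally restricts the min/max estimation to a
    subset (typically the training split); the transform is then applied
    to all samples and clipped into [0, 1]. Constant genes map to 0.
    The per-gene minima/maxima are retained for :func:`inverse_minmax`.
    """
    _require_stage(m, "log2", "minmax_scale")
    if fit_sample_ids is None:
        fit_values = m.values
    else:
        rows = [m.sample_ids.index(s) for s in fit_sample_ids]
        fit_values = m.values[rows]
    lo = fit_values.min(axis=0)
    hi = fit_values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (m.values - lo) / safe_span
    scaled[:, constant] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return replace(m, values=scaled, stage="scaled", scale_min=lo, scale_max=hi)


def inverse_minmax(m: ExpressionMatrix) -> ExpressionMatrix:
    """Undo :func:`minmax_scale`, returning a stage-``log2`` matrix."""
    _require_stage(m, "scaled", "inverse_minmax")
    if m.scale_min is None or m.scale_max is None:
        raise ValueError("matrix carries no scaling parameters to invert")
    span = m.scale_max - m.scale_min
    values = m.values * np.where(span == 0, 1.0, span) + m.scale_min
    return replace(m, values=values, stage="log2", scale_min=None, scale_max=None)


def split_train_test(m: ExpressionMatrix, train_frac: float = 0.8, seed: int = 0) -> SplitIndex:
    """Seeded uniform 8:2 (by default) split of samples, |train| = round(frac * n)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n = m.n_samples
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [m.sample_ids[i] for i in sorted(order[:n_train])]
    test = [m.sample_ids[i] for i in sorted(order[n_train:])]
    return SplitIndex(train_sample_ids=tuple(train), test_sample_ids=tuple(test), seed=seed)
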