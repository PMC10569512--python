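"""Model/Results front end tying the pipeline together.

:class:`CriticalGeneModel` is constructed from a raw expression matrix and
``fit()`` runs the full analysis: median filtering, log2, per-gene [0, 1]
scaling (parameters estimated on the training split), autoencoder
training, per-latent gradient-boosted surrogates, tree-Shapley
attributions for every [gene, latent, sample] triple, and aggregation into
critical indexes. The returned :class:`CriticalGeneResults` carries the
fitted components, the per-gene table and a ``summary()``.

:class:`DiffCoExModel` does the same for the differential co-expression
analysis of a case/control pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autoencoder as ae_mod
from . import critical as crit_mod
from . import diffcoex as dc_mod
from . import explain as ex_mod
from . import preprocess as pp_mod

__all__ = [
    "CriticalGeneModel",
    "CriticalGeneResults",
    "DiffCoExModel",
    "DiffCoExResults",
]


def _as_expression(data, stage: str = "raw") -> pp_mod.ExpressionMatrix:
    if isinstance(data, pp_mod.ExpressionMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return pp_mod.ExpressionMatrix.from_frame(data, stage=stage)
    raise TypeError("expected an ExpressionMatrix or a samples x genes DataFrame")


class CriticalGeneModel:
    """End-to-end critical-gene analysis of one expression matrix.

    Parameters
    ----------
    data
        Raw non-negative expression, samples x genes (``ExpressionMatrix``
        or DataFrame).
    mode
        ``"transcriptome"`` (L=5, H=32) or ``"pathway"`` (H=8, L=2 below
        100 genes else L=3); ignored when ``config`` is given.
    config
        Full :class:`~critix.autoencoder.AEConfig` override.
    median_threshold, pseudocount
        Preprocessing parameters (median filter cut, log2 pseudocount).
    fraction
        Critical-gene cutoff as a fraction of genes (ceiling rule).
    surrogate_params
        Keyword overrides for :func:`critix.explain.fit_surrogates`.
    explain_on
        ``"all"`` (default) or ``"train"``: which samples receive
        attributions.
    """

    def __init__(
        self,
        data,
        mode: str = "pathway",
        config: ae_mod.AEConfig | None = None,
        median_threshold: float = 1.0,
        pseudocount: float = 1.0,
        train_frac: float = 0.8,
        fraction: float = 0.01,
        surrogate_params: dict | None = None,
        explain_on: str = "all",
        skip_median_filter: bool = False,
        seed: int = 0,
    ):
        self.raw = _as_expression(data)
        self.mode = mode
        self.config = config
        self.median_threshold = median_threshold
        self.pseudocount = pseudocount
        self.train_frac = train_frac
        self.fraction = fraction
        self.surrogate_params = dict(surrogate_params or {})
        if explain_on not in ("all", "train"):
            raise ValueError("explain_on must be 'all' or 'train'")
        self.explain_on = explain_on
        self.skip_median_filter = skip_median_filter
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CriticalGeneModel":
        return cls(frame, **kwargs)

    def fit(self) -> "CriticalGeneResults":
        filtered = (
            pp_mod.ExpressionMatrix(
                self.raw.values, self.raw.gene_ids, self.raw.sample_ids, stage="filtered"
            )
            if self.skip_median_filter
            else pp_mod.filter_by_median(self.raw, self.median_threshold)
        )
        logged = pp_mod.log2_transform(filtered, self.pseudocount)
        split = pp_mod.split_train_test(logged, self.train_frac, seed=self.seed)
        scaled = pp_mod.minmax_scale(logged, fit_sample_ids=split.train_sample_ids)

        cfg = self.config
        if cfg is None:
            cfg = ae_mod.default_config(self.mode, scaled.n_genes, seed=self.seed)
        elif cfg.seed != self.seed:
            from dataclasses import replace

            cfg = replace(cfg, seed=self.seed)
        ae = ae_mod.train(scaled, split, cfg)

        train_matrix = scaled.subset_samples(list(split.train_sample_ids))
        z_train = ae_mod.encode(ae, train_matrix)
        surrogates = ex_mod.fit_surrogates(
            train_matrix.to_frame(), z_train, seed=self.seed, **self.surrogate_params
        )
        explained = train_matrix if self.explain_on == "train" else scaled
        tensor = ex_mod.tree_shap(surrogates, explained.to_frame())
        table = crit_mod.critical_table(tensor, fraction=self.fraction)
        return CriticalGeneResults(
            model=self,
            scaled=scaled,
            split=split,
            autoencoder=ae,
            surrogates=surrogates,
            shap_tensor=tensor,
            table=table,
        )


@dataclass
class CriticalGeneResults:
    """Fitted critical-gene analysis: components, per-gene table, summaries."""

    model: CriticalGeneModel
    scaled: pp_mod.ExpressionMatrix
    split: pp_mod.SplitIndex
    autoencoder: ae_mod.TrainedAutoencoder
    surrogates: ex_mod.SurrogateSet
    shap_tensor: ex_mod.ShapTensor
    table: pd.DataFrame = field(repr=False)

    @property
    def critical_genes(self) -> list[str]:
        sel = self.table[self.table["is_critical"]]
        return list(sel.sort_values("rank").index)

    @property
    def nonzero_genes(self) -> list[str]:
        """Genes with a non-negligible critical index (enrichment query set)."""
        return list(self.table.index[self.table["WSV"] > crit_mod.NONZERO_TOL])

    @property
    def test_r2(self) -> float:
        return self.autoencoder.final_test_r2

    def rank_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "rank"])

    def summary(self) -> str:
        cfg = self.autoencoder.config
        w = self.surrogates.weights
        lines = [
            "Critical-gene analysis",
            "=" * 58,
            f"samples (train/test):   {len(self.split.train_sample_ids)}/"
            f"{len(self.split.test_sample_ids)}",
            f"genes after filtering:  {self.scaled.n_genes}",
            f"architecture:           widths {self.autoencoder.layer_widths} "
            f"(L={cfg.n_coding_layers}, H={cfg.n_latent})",
            f"epochs trained:         {len(self.autoencoder.history)}",
            f"test reconstruction R2: {self.test_r2:.4f}",
            f"surrogate R2 (w_h):     min {w.min():.3f}, median {np.median(w):.3f}, "
            f"max {w.max():.3f}",
            f"critical fraction:      {self.model.fraction:.2%} "
            f"-> {int(self.table['is_critical'].sum())} genes",
            "-" * 58,
            "top critical genes (gene, WSV, rank):",
        ]
        top = self.table[self.table["is_critical"]].sort_values("rank")
        for gene, row in top.iterrows():
            lines.append(f"  {gene:<16} {row['WSV']:.6f}  {int(row['rank'])}")
        return "\n".join(lines)

    def plot_critical_indexes(self, top: int = 30, ax=None):
        """Horizontal bar chart of the largest critical indexes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(2, top * 0.25)))
        head = self.table.sort_values("rank").head(top).iloc[::-1]
        ax.barh(head.index, head["WSV"])
        ax.set_xlabel("critical index (WSV)")
        ax.set_title(f"Top {top} critical indexes")
        return ax


class DiffCoExModel:
    """Differential co-expression of a case/control expression pair.

    ``fit()`` computes Spearman correlation matrices, selects beta on the
    grid, builds the adjacency-difference and TOM-dissimilarity matrices,
    clusters modules and nominates hub genes.
    """

    def __init__(
        self,
        x_case,
        x_control,
        beta_grid=range(5, 11),
        beta: int | None = None,
        min_module_size: int = 5,
        cut_height: float | str = "gap",
        hub_power: int = 2,
    ):
        case = _as_expression(x_case)
        control = _as_expression(x_control)
        if case.gene_ids != control.gene_ids:
            raise ValueError("case and control matrices must share the same genes in order")
        self.x_case = case.to_frame()
        self.x_control = control.to_frame()
        self.beta_grid = list(beta_grid)
        self.beta = beta
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.hub_power = hub_power

    def fit(self) -> "DiffCoExResults":
        c_case = dc_mod.correlation_matrix(self.x_case, "spearman")
        c_control = dc_mod.correlation_matrix(self.x_control, "spearman")
        beta = self.beta
        if beta is None:
            beta = dc_mod.select_beta(
                c_case, c_control, self.beta_grid, self.min_module_size, self.cut_height
            )
        d = dc_mod.adjacency_difference(c_case, c_control, beta)
        t = dc_mod.tom_dissimilarity(d)
        modules = dc_mod.detect_modules(t, self.min_module_size, self.cut_height)
        hubs = dc_mod.hub_gene(
            pd.concat([self.x_case, self.x_control]), modules, self.hub_power
        )
        return DiffCoExResults(
            model=self, c_case=c_case, c_control=c_control, beta=int(beta),
            d=d, tom=t, modules=modules, hubs=hubs,
        )


@dataclass
class DiffCoExResults:
    """Fitted differential co-expression network."""

    model: DiffCoExModel
    c_case: pd.DataFrame = field(repr=False)
    c_control: pd.DataFrame = field(repr=False)
    beta: int
    d: pd.DataFrame = field(repr=False)
    tom: pd.DataFrame = field(repr=False)
    modules: pd.Series = field(repr=False)
    hubs: dict = field(default_factory=dict)

    def module_table(self) -> pd.DataFrame:
        out = self.modules.to_frame()
        out["is_hub"] = [self.hubs.get(m) == g for g, m in self.modules.items()]
        out.index.name = "gene_id"
        return out

    def compare_focal(self, focal: str, others=None) -> dc_mod.NetworkComparison:
        """KS comparison of the focal gene's correlation profile across
        conditions (defaults to all other genes)."""
        if others is None:
            others = [g for g in self.c_case.index if g != focal]
        return dc_mod.compare_focal_networks(
            self.model.x_case, self.model.x_control, focal, others
        )

    def summary(self) -> str:
        sizes = self.modules[self.modules != dc_mod.UNASSIGNED].value_counts()
        lines = [
            "Differential co-expression analysis",
            "=" * 58,
            f"genes:              {self.d.shape[0]}",
            f"selected beta:      {self.beta}",
            f"modules:            {len(sizes)} "
            f"(largest {int(sizes.max()) if len(sizes) else 0} genes; "
            f"{int((self.modules == dc_mod.UNASSIGNED).sum())} unassigned)",
            "-" * 58,
            "module  size  hub",
        ]
        for label, size in sizes.items():
            lines.append(f"  {label:<6} {size:>4}  {self.hubs.get(label, '-')}")
        return "\n".join(lines)
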