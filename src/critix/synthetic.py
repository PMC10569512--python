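"""Synthetic expression data with known latent structure.

Two generators cover the statistical structure the analysis assumes:

``simulate_factor_expression``
    A linear factor model X = Z Lambda^T + noise with K standard-normal
    factors. A few *planted* genes carry large loadings (one factor each,
    round-robin) while background genes carry weak loadings, so the
    planted genes are the ground-truth signal carriers that a critical-
    index analysis should recover.

``simulate_condition_pair``
    Case/control matrices with block-structured co-expression (equi-
    correlated Gaussian blocks at correlation ``within_block_rho``). In
    the case condition a fraction of each block's genes is decoupled
    (their pairwise correlations drop to 0), emulating tumour rewiring of
    co-expression networks.

Both map the Gaussian draws to non-negative TPM-like values with a
per-gene monotone transform (``expm1`` of the min-shifted values by
default), which preserves rank correlations exactly, so Spearman-based
targets are unaffected. All randomness flows from the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .preprocess import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "simulate_factor_expression",
    "simulate_condition_pair",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators.

    ``loading_scale`` is the planted-gene loading magnitude;
    ``background_loading_sd`` the standard deviation of the weak loadings
    every other gene carries (weak co-expression with the factors);
    ``noise_sd`` the observation noise. ``nonneg`` selects the mapping to
    non-negative expression: ``expm1`` (log-normal-like, exact zero at the
    per-gene minimum) or ``shift`` (subtract the per-gene minimum, keeping
    the centred matrix exactly rank K).
    """

    n_samples: int = 200
    n_genes: int = 100
    n_factors: int = 4
    planted_gene_count: int = 4
    loading_scale: float = 3.0
    background_loading_sd: float = 0.05
    noise_sd: float = 0.1
    block_sizes: tuple[int, ...] = (20, 20, 20)
    within_block_rho: float = 0.8
    rewire_fraction: float = 1.0
    nonneg: str = "expm1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors > self.n_genes:
            raise ValueError("n_factors must not exceed n_genes")
        if self.planted_gene_count > self.n_genes:
            raise ValueError("planted_gene_count must not exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must lie in [0, 1)")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise ValueError("rewire_fraction must lie in [0, 1]")
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes exceed n_genes")
        if self.nonneg not in ("expm1", "shift"):
            raise ValueError(f"unknown nonneg mapping {self.nonneg!r}")


def _to_nonneg(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "shift":
        return x - x.min(axis=0, keepdims=True)
    # standardise per gene, then a monotone log-normal-like map; medians land
    # well above 1 so the default TPM median filter keeps every gene
    sd = x.std(axis=0, keepdims=True)
    z = (x - x.mean(axis=0, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    return np.expm1(z - z.min(axis=0, keepdims=True))


def _gene_ids(n: int) -> tuple[str, ...]:
    return tuple(f"G{j:04d}" for j in range(n))


def _sample_ids(n: int, prefix: str = "S") -> tuple[str, ...]:
    return tuple(f"{prefix}{i:04d}" for i in range(n))


def simulate_factor_expression(spec: SyntheticSpec):
    """Draw a factor-structured expression matrix and its ground truth.

    Returns ``(matrix, truth)`` where ``truth`` has the planted gene ids,
    the factor scores and the loading matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n, G, K = spec.n_samples, spec.n_genes, spec.n_factors
    z = rng.standard_normal((n, K))
    # every background gene carries one weak loading of fixed magnitude and
    # random sign (round-robin over factors): collectively the factors drive
    # most genes, but no single background gene rivals a planted gene
    loadings = np.zeros((G, K))
    loadings[np.arange(G), np.arange(G) % K] = spec.background_loading_sd * rng.choice(
        [-1.0, 1.0], size=G
    )
    planted = rng.choice(G, size=spec.planted_gene_count, replace=False)
    planted = np.sort(planted)
    for j, gene in enumerate(planted):
        loadings[gene] = 0.0
        loadings[gene, j % K] = spec.loading_scale
    x = z @ loadings.T + rng.normal(0.0, spec.noise_sd, size=(n, G))
    values = _to_nonneg(x, spec.nonneg)
    genes = _gene_ids(G)
    matrix = ExpressionMatrix(
        values=values, gene_ids=genes, sample_ids=_sample_ids(n), stage="raw"
    )
    truth = {
        "planted_genes": [genes[g] for g in planted],
        "factor_scores": z,
        "loadings": loadings,
        "spec": asdict(spec),
    }
    return matrix, truth


def simulate_condition_pair(spec: SyntheticSpec):
    """Draw case/control matrices with block co-expression and rewiring.

    Control genes in block b follow sqrt(rho) * f_b + sqrt(1-rho) * eps
    (pairwise correlation rho within the block). In the case condition a
    seeded ``rewire_fraction`` of each block's genes is decoupled from the
    block factor, zeroing their correlations. Genes beyond the blocks are
    independent noise in both conditions. Returns
    ``(x_case, x_control, truth)`` with block membership and the rewired
    gene ids in ``truth``.
    """
    rng = np.random.default_rng(spec.seed)
    n, G = spec.n_samples, spec.n_genes
    rho = spec.within_block_rho
    genes = _gene_ids(G)

    block_of = np.full(G, -1)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        block_of[start:start + size] = b
        start += size

    rewired = np.zeros(G, dtype=bool)
    for b in range(len(spec.block_sizes)):
        members = np.flatnonzero(block_of == b)
        n_rewire = int(round(spec.rewire_fraction * len(members)))
        if n_rewire:
            rewired[rng.choice(members, size=n_rewire, replace=False)] = True

    def draw(decouple: np.ndarray, prefix: str) -> ExpressionMatrix:
        factors = rng.standard_normal((n, len(spec.block_sizes)))
        eps = rng.standard_normal((n, G))
        x = np.empty((n, G))
        for j in range(G):
            b = block_of[j]
            if b < 0 or decouple[j]:
                x[:, j] = eps[:, j]
            else:
                x[:, j] = np.sqrt(rho) * factors[:, b] + np.sqrt(1.0 - rho) * eps[:, j]
        return ExpressionMatrix(
            values=_to_nonneg(x, spec.nonneg),
            gene_ids=genes,
            sample_ids=_sample_ids(n, prefix),
            stage="raw",
        )

    x_control = draw(np.zeros(G, dtype=bool), "N")
    x_case = draw(rewired, "T")
    truth = {
        "blocks": {f"B{b + 1}": [genes[j] for j in np.flatnonzero(block_of == b)]
                   for b in range(len(spec.block_sizes))},
        "rewired_genes": [genes[j] for j in np.flatnonzero(rewired)],
        "spec": asdict(spec),
    }
    return x_case, x_control, truth


def save_ground_truth(truth: dict, path) -> None:
    """JSON-serialise a ground-truth record (arrays become nested lists)."""
    encoded = {
        k: v.tolist() if isinstance(v, np.ndarray) else v for k, v in truth.items()
    }
    with open(path, "w") as fh:
        json.dump(encoded, fh, indent=1)


def load_ground_truth(path) -> dict:
    with open(path) as fh:
        truth = json.load(fh)
    for key in ("factor_scores", "loadings"):
        if key in truth:
            truth[key] = np.asarray(truth[key], dtype=float)
    return truth
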