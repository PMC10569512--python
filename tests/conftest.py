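"""Shared fixtures: random tree ensembles and small expression matrices."""

from __future__ import annotations

import numpy as np
import pytest

from critix.explain import Tree, TreeEnsemble
from critix.preprocess import ExpressionMatrix


def random_tree(rng: np.random.Generator, n_features: int, depth: int) -> Tree:
    """Full binary tree with random splits, covers and leaf values.

    Covers halve by a random fraction at each split so every internal node
    keeps positive cover, as in a trained ensemble.
    """
    feature, threshold, left, right, value, cover = [], [], [], [], [], []

    def build(level: int, node_cover: float) -> int:
        idx = len(feature)
        if level == depth:
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(float(rng.standard_normal()))
            cover.append(node_cover)
            return idx
        feature.append(int(rng.integers(n_features)))
        threshold.append(float(rng.uniform(0.2, 0.8)))
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        cover.append(node_cover)
        frac = float(rng.uniform(0.2, 0.8))
        left[idx] = build(level + 1, node_cover * frac)
        right[idx] = build(level + 1, node_cover * (1.0 - frac))
        return idx

    build(0, 100.0)
    return Tree(
        np.array(feature), np.array(threshold), np.array(left), np.array(right),
        np.array(value), np.array(cover),
    )


def random_ensemble(
    rng: np.random.Generator, n_features: int, n_trees: int, depth: int
) -> TreeEnsemble:
    trees = [random_tree(rng, n_features, int(rng.integers(1, depth + 1))) for _ in range(n_trees)]
    return TreeEnsemble(trees=tuple(trees), n_features=n_features,
                        base_score=float(rng.standard_normal()))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = np.array(
        [
            [0.5, 2.0, 3.0, 1.0],
            [0.5, 2.0, 7.0, 1.0],
            [3.0, 2.0, 0.0, 1.0],
        ]
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=("gA", "gB", "gC", "gD"),
        sample_ids=("s1", "s2", "s3"),
        stage="raw",
    )
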