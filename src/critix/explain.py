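"""Per-latent tree-ensemble surrogates and Shapley attributions.

The encoder of a trained autoencoder is a black box; to attribute each
latent variable back to input genes, one gradient-boosted regression-tree
ensemble is fitted per latent variable (gene expression in, latent value
out) and Shapley values of the surrogate are computed for every
[gene, latent, sample] triple.

Attributions use the path-dependent tree-Shapley value function: the payoff
of a feature subset S is the tree-traversal conditional expectation in
which splits on features outside S average both children weighted by their
training cover. Two routes are provided:

``tree_shap``
    Exact path-dependent attributions computed leaf by leaf. The game
    restricted to a single leaf depends only on the (at most ``depth``)
    distinct features on that leaf's path, so its Shapley values can be
    obtained by enumerating the 2^d subsets of those features; features
    off the path are dummies and receive zero from that leaf. Summing over
    leaves and trees is exact and polynomial in practice (cost
    O(leaves * 2^depth) per tree, vectorised over samples).

``exact_shapley``
    Brute-force global subset enumeration straight from the Shapley
    definition, tractable for <= 12 features. Used as an independent
    oracle for ``tree_shap``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TreeEnsemble",
    "SurrogateSet",
    "ShapTensor",
    "fit_surrogates",
    "tree_shap",
    "exact_shapley",
]


@dataclass(frozen=True)
class Tree:
    """One binary regression tree in array form.

    ``feature[i] < 0`` marks a leaf, in which case ``value[i]`` is the leaf
    prediction. Internal nodes route ``x[feature] < threshold`` to
    ``left``, else ``right``. ``cover`` is the training weight that reached
    each node and defines the conditional-expectation value function.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    def __post_init__(self) -> None:
        for name in ("feature", "left", "right"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("threshold", "value", "cover"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        internal = self.feature >= 0
        if np.any(self.cover[internal] <= 0):
            raise ValueError("internal nodes must have positive cover")

    def leaf_of(self, x: np.ndarray) -> int:
        node = 0
        while self.feature[node] >= 0:
            node = self.left[node] if x[self.feature[node]] < self.threshold[node] else self.right[node]
        return int(node)

    def expectation(self) -> float:
        """Cover-weighted mean prediction (the empty-coalition payoff)."""
        return _cond_exp(self, np.empty(0), 0)  # no conditioning features


@dataclass(frozen=True)
class TreeEnsemble:
    """Additive ensemble: prediction = base_score + sum of tree outputs."""

    trees: tuple[Tree, ...]
    n_features: int
    base_score: float = 0.0
    input_dtype: type = np.float64  # xgboost compares in float32

    def __post_init__(self) -> None:
        object.__setattr__(self, "trees", tuple(self.trees))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.input_dtype)
        out = np.full(X.shape[0], self.base_score, dtype=np.float64)
        for tree in self.trees:
            for i in range(X.shape[0]):
                out[i] += tree.value[tree.leaf_of(X[i])]
        return out

    def expected_value(self) -> float:
        return self.base_score + sum(t.expectation() for t in self.trees)

    @classmethod
    def from_xgboost(cls, model) -> "TreeEnsemble":
        """Convert a fitted XGBoost regressor (sklearn wrapper or Booster)."""
        booster = model.get_booster() if hasattr(model, "get_booster") else model
        cfg = json.loads(booster.save_config())
        base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        names = booster.feature_names
        if names is None:
            names = [f"f{j}" for j in range(booster.num_features())]
        name_to_idx = {name: j for j, name in enumerate(names)}
        frame = booster.trees_to_dataframe()
        trees = []
        for _, tdf in frame.groupby("Tree", sort=True):
            tdf = tdf.sort_values("Node")
            id_to_node = {nid: k for k, nid in enumerate(tdf["ID"])}
            is_leaf = (tdf["Feature"] == "Leaf").to_numpy()
            feature = np.where(
                is_leaf, -1, tdf["Feature"].map(lambda f: name_to_idx.get(f, -1)).to_numpy()
            )
            # Split values print as 9-digit decimals; round-trip through
            # float32 to recover the exact thresholds xgboost compares with
            threshold = np.where(
                is_leaf, 0.0, tdf["Split"].fillna(0.0).to_numpy(dtype=np.float32)
            )
            left = np.array([-1 if l else id_to_node[y] for l, y in zip(is_leaf, tdf["Yes"])])
            right = np.array([-1 if l else id_to_node[n] for l, n in zip(is_leaf, tdf["No"])])
            value = np.where(is_leaf, tdf["Gain"].to_numpy(dtype=float), 0.0)
            cover = tdf["Cover"].to_numpy(dtype=float)
            trees.append(Tree(feature, threshold, left, right, value, cover))
        return cls(
            trees=tuple(trees),
            n_features=len(names),
            base_score=base_score,
            input_dtype=np.float32,
        )


def _shapley_weights(d: int) -> np.ndarray:
    """w[r] = r!(d-1-r)!/d! for a game on d players."""
    fact = [math.factorial(k) for k in range(d + 1)]
    return np.array([fact[r] * fact[d - 1 - r] / fact[d] for r in range(d)])


def _accumulate_tree(tree: Tree, X: np.ndarray, phi: np.ndarray) -> float:
    """Add one tree's path-dependent Shapley values into ``phi`` (n x F).

    Returns the tree's expected value (its contribution to the base value).
    Recurses over the tree keeping, per distinct feature on the current
    path, the indicator that each sample follows the path (in-coalition
    factor) and the product of cover fractions (out-of-coalition factor).
    """
    n = X.shape[0]
    base = 0.0
    # path state: parallel lists of feature id, indicator (n,), cover fraction
    feats: list[int] = []
    inds: list[np.ndarray] = []
    fracs: list[float] = []

    def recurse(node: int) -> None:
        nonlocal base
        f = int(tree.feature[node])
        if f < 0:
            base += _leaf_contrib(tree.value[node], feats, inds, fracs, phi)
            return
        thr = tree.threshold[node]
        goes_left = X[:, f] < thr
        parent_cover = tree.cover[node]
        for child, ind in ((int(tree.left[node]), goes_left), (int(tree.right[node]), ~goes_left)):
            frac = tree.cover[child] / parent_cover
            if f in feats:
                j = feats.index(f)
                old_ind, old_frac = inds[j], fracs[j]
                inds[j] = old_ind * ind
                fracs[j] = old_frac * frac
                recurse(child)
                inds[j], fracs[j] = old_ind, old_frac
            else:
                feats.append(f)
                inds.append(ind.astype(np.float64))
                fracs.append(frac)
                recurse(child)
                feats.pop()
                inds.pop()
                fracs.pop()

    recurse(0)
    return base


def _leaf_contrib(value: float, feats, inds, fracs, phi: np.ndarray) -> float:
    """Shapley contribution of one leaf to every path feature, all samples."""
    d = len(feats)
    if d == 0:  # stump-less tree: a single leaf
        return float(value)
    n = phi.shape[0]
    n_masks = 1 << d
    # in-coalition products over subsets, shared-prefix dynamic programme
    p_in = np.empty((n_masks, n))
    p_in[0] = 1.0
    for mask in range(1, n_masks):
        low = mask & -mask
        p_in[mask] = p_in[mask ^ low] * inds[low.bit_length() - 1]
    # out-of-coalition cover products over complements
    p_out = np.empty(n_masks)
    for mask in range(n_masks):
        prod = 1.0
        for j in range(d):
            if not mask & (1 << j):
                prod *= fracs[j]
        p_out[mask] = prod
    weights = _shapley_weights(d)
    popcount = np.array([bin(m).count("1") for m in range(n_masks)])
    for j in range(d):
        bit = 1 << j
        acc = np.zeros(n)
        for mask in range(n_masks):
            if mask & bit:
                continue
            delta = p_in[mask | bit] * p_out[mask | bit] - p_in[mask] * p_out[mask]
            acc += weights[popcount[mask]] * delta
        phi[:, feats[j]] += value * acc
    return float(value) * p_out[0]


def _ensemble_tree_shap(ens: TreeEnsemble, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Attributions (n x F) and base value for one ensemble."""
    X = np.asarray(X, dtype=ens.input_dtype)
    if X.shape[1] != ens.n_features:
        raise ValueError(f"expected {ens.n_features} features, got {X.shape[1]}")
    phi = np.zeros((X.shape[0], ens.n_features))
    base = ens.base_score
    for tree in ens.trees:
        base += _accumulate_tree(tree, X, phi)
    return phi, base


def _cond_exp(tree: Tree, x: np.ndarray, node: int, in_coalition=None) -> float:
    """Tree-traversal conditional expectation given the coalition's features."""
    f = int(tree.feature[node])
    if f < 0:
        return float(tree.value[node])
    if in_coalition is not None and in_coalition[f]:
        child = tree.left[node] if x[f] < tree.threshold[node] else tree.right[node]
        return _cond_exp(tree, x, int(child), in_coalition)
    lc, rc = int(tree.left[node]), int(tree.right[node])
    wl = tree.cover[lc] / tree.cover[node]
    wr = tree.cover[rc] / tree.cover[node]
    return wl * _cond_exp(tree, x, lc, in_coalition) + wr * _cond_exp(tree, x, rc, in_coalition)


def exact_shapley(ens: TreeEnsemble, x: np.ndarray, max_features: int = 12) -> tuple[np.ndarray, float]:
    """Brute-force Shapley values for a single sample by subset enumeration.

    phi_i = sum over S not containing i of |S|!(F-|S|-1)!/F! * [v(S+i)-v(S)]
    with v(S) the cover-weighted tree-traversal conditional expectation.
    Exponential in the feature count, hence the ``max_features`` guard;
    use :func:`tree_shap` for real problems.
    """
    F = ens.n_features
    if F > max_features:
        raise ValueError(
            f"{F} features exceeds the brute-force limit ({max_features}); "
            "use tree_shap for exact attributions at scale"
        )
    x = np.asarray(x, dtype=ens.input_dtype)
    payoff = np.empty(1 << F)
    for mask in range(1 << F):
        members = np.array([(mask >> j) & 1 for j in range(F)], dtype=bool)
        payoff[mask] = sum(_cond_exp(t, x, 0, members) for t in ens.trees)
    weights = _shapley_weights(F)
    phi = np.zeros(F)
    for i in range(F):
        bit = 1 << i
        for mask in range(1 << F):
            if mask & bit:
                continue
            r = bin(mask).count("1")
            phi[i] += weights[r] * (payoff[mask | bit] - payoff[mask])
    return phi, float(payoff[0] + ens.base_score)


@dataclass(frozen=True)
class SurrogateSet:
    """One gradient-boosted surrogate per latent variable.

    ``r2`` holds the raw coefficient of determination of each surrogate on
    its fitting samples; ``weights`` clamps negatives to zero so a
    poorly-predicted latent variable cannot flip attribution signs when
    critical indexes are aggregated downstream.
    """

    models: tuple
    ensembles: tuple[TreeEnsemble, ...]
    r2: np.ndarray
    gene_ids: tuple[str, ...]
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    @property
    def n_latent(self) -> int:
        return len(self.models)

    @property
    def weights(self) -> np.ndarray:
        return np.clip(self.r2, 0.0, None)


@dataclass(frozen=True)
class ShapTensor:
    """Attributions indexed [gene, latent, sample] plus per-latent metadata."""

    values: np.ndarray  # (G, H, n)
    base_values: np.ndarray  # (H,)
    weights: np.ndarray  # (H,), surrogate R^2 clamped at 0
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        G, H, n = self.values.shape
        if G != len(self.gene_ids) or n != len(self.sample_ids) or H != len(self.base_values):
            raise ValueError("ShapTensor axes do not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attributions contain non-finite values")

    @property
    def n_latent(self) -> int:
        return self.values.shape[1]


def fit_surrogates(
    x: np.ndarray | pd.DataFrame,
    z: np.ndarray | pd.DataFrame,
    gene_ids=None,
    n_estimators: int = 100,
    max_depth: int = 6,
    learning_rate: float = 0.3,
    seed: int = 0,
) -> SurrogateSet:
    """Fit one XGBoost regressor per latent column of ``z`` from genes ``x``.

    The per-latent weight is the surrogate's R^2 on the fitting samples; a
    constant latent column yields weight 0 with the model retained.
    Single-threaded and seeded for reproducibility.
    """
    from xgboost import XGBRegressor

    if isinstance(x, pd.DataFrame):
        gene_ids = tuple(map(str, x.columns)) if gene_ids is None else tuple(gene_ids)
        x = x.to_numpy(dtype=float)
    elif gene_ids is None:
        gene_ids = tuple(f"g{j}" for j in range(np.asarray(x).shape[1]))
    z = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if x.shape[0] != z.shape[0]:
        raise ValueError(f"x has {x.shape[0]} samples but z has {z.shape[0]}")

    hyper = dict(n_estimators=n_estimators, max_depth=max_depth, learning_rate=learning_rate)
    models, ensembles, r2s = [], [], []
    for h in range(z.shape[1]):
        target = z[:, h]
        model = XGBRegressor(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            n_jobs=1,
            random_state=seed + h,
            tree_method="hist",
        )
        model.fit(x, target)
        pred = model.predict(x)
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum((target - pred) ** 2)) / ss_tot
        models.append(model)
        ensembles.append(TreeEnsemble.from_xgboost(model))
        r2s.append(r2)
    return SurrogateSet(
        models=tuple(models),
        ensembles=tuple(ensembles),
        r2=np.array(r2s),
        gene_ids=gene_ids,
        seed=seed,
        hyperparameters=hyper,
    )


def tree_shap(ss: SurrogateSet, x: np.ndarray | pd.DataFrame, sample_ids=None) -> ShapTensor:
    """Path-dependent tree-Shapley attributions for every latent variable.

    Returns a tensor with ``values[i, h, s]`` the attribution of gene ``i``
    to latent ``h`` for sample ``s``; for each (h, s) the attributions plus
    the latent's base value reproduce the surrogate prediction (local
    accuracy).
    """
    if isinstance(x, pd.DataFrame):
        if tuple(map(str, x.columns)) != ss.gene_ids:
            raise ValueError("gene columns do not match the surrogate fitting genes")
        sample_ids = tuple(map(str, x.index)) if sample_ids is None else tuple(sample_ids)
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if sample_ids is None:
            sample_ids = tuple(f"s{i}" for i in range(x.shape[0]))
    if x.shape[1] != len(ss.gene_ids):
        raise ValueError(f"expected {len(ss.gene_ids)} genes, got {x.shape[1]}")

    n, G = x.shape
    H = ss.n_latent
    values = np.empty((G, H, n))
    bases = np.empty(H)
    for h, ens in enumerate(ss.ensembles):
        phi, base = _ensemble_tree_shap(ens, x)
        values[:, h, :] = phi.T
        bases[h] = base
    return ShapTensor(
        values=values,
        base_values=bases,
        weights=ss.weights,
        gene_ids=ss.gene_ids,
        sample_ids=tuple(sample_ids),
    )


def local_accuracy_error(ss: SurrogateSet, tensor: ShapTensor, x: np.ndarray) -> float:
    """Largest |sum_i phi_i + base - prediction| over all (latent, sample)."""
    x = np.asarray(x, dtype=float)
    worst = 0.0
    for h, ens in enumerate(ss.ensembles):
        pred = ens.predict(x)
        total = tensor.values[:, h, :].sum(axis=0) + tensor.base_values[h]
        worst = max(worst, float(np.max(np.abs(total - pred))))
    return worst
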