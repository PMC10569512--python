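"""Symmetric fully connected autoencoder for expression matrices.

The model compresses a samples x genes matrix (scaled to [0, 1]) through a
bottleneck of ``H`` latent variables using ``L`` coding layers on each side,
sigmoid activations throughout, and reconstructs the input. Training
minimises

    MSE(x, r) + lambda * mean(|h|)

with Adam, full-batch gradients (the batch size is the sample size), a step
learning-rate decay, and early stopping on held-out reconstruction R^2:
training halts once the best test R^2 has failed to improve by more than
``min_r2_gain`` for ``patience_epochs`` consecutive epochs, or at
``max_epochs``.

The implementation is plain numpy: the networks involved are small (at most
a few thousand units) and full-batch, so hand-written backpropagation is
both fast and exactly reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, SplitIndex

__all__ = [
    "AEConfig",
    "TrainedAutoencoder",
    "plan_layer_widths",
    "default_config",
    "train",
    "encode",
    "reconstruction_r2",
    "compression_ratio",
    "save_autoencoder",
    "load_autoencoder",
]

_ACTIVATIONS = {
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    # derivative expressed in terms of the activation output a
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
}


@dataclass(frozen=True)
class AEConfig:
    """Hyperparameters of the autoencoder and its training schedule.

    Defaults follow the training protocol: Adam at 1e-3 with the rate
    multiplied by 0.8 every 100 epochs, full-batch updates, a hard cap of
    3000 epochs, and early stopping when held-out R^2 gains fall below
    0.0002 (0.02%) for 10 consecutive epochs.
    """

    n_coding_layers: int = 5
    n_latent: int = 32
    activation: str = "sigmoid"
    learning_rate: float = 1e-3
    lr_decay: float = 0.8
    decay_interval_epochs: int = 100
    l1_penalty: float = 1e-4
    max_epochs: int = 3000
    patience_epochs: int = 10
    min_r2_gain: float = 2e-4
    batch_size: int | str = "all"
    seed: int = 0
    layer_widths: tuple[int, ...] | None = None  # override the geometric plan
    # deep sigmoid stacks occasionally settle into poor optima (worst case:
    # the per-gene-mean predictor); train several seed-derived
    # initialisations and keep the best held-out R^2, as k-means does
    n_inits: int = 3

    def __post_init__(self) -> None:
        if self.n_coding_layers < 1:
            raise ValueError("need at least one coding layer")
        if self.n_latent < 1:
            raise ValueError("need at least one latent variable")
        if self.min_r2_gain < 0:
            raise ValueError("min_r2_gain must be non-negative")
        if self.l1_penalty < 0:
            raise ValueError("l1_penalty must be non-negative")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def plan_layer_widths(n_genes: int, L: int, H: int) -> list[int]:
    """Geometric width schedule from ``n_genes`` down to ``H`` in ``L`` steps.

    width_k = round(n_genes * (H / n_genes)^(k/L)); any ties introduced by
    rounding are broken by decrementing so the sequence is strictly
    decreasing.
    """
    if n_genes <= H:
        raise ValueError(f"bottleneck H={H} must be smaller than n_genes={n_genes}")
    if L < 1:
        raise ValueError("L must be >= 1")
    ratio = H / n_genes
    widths = [int(round(n_genes * ratio ** (k / L))) for k in range(L + 1)]
    widths[0], widths[-1] = n_genes, H
    for k in range(1, L + 1):  # enforce strict decrease after rounding
        if widths[k] >= widths[k - 1]:
            widths[k] = widths[k - 1] - 1
    if widths[-1] < 1:
        raise ValueError(f"cannot fit {L} strictly decreasing layers between {n_genes} and {H}")
    if widths[-1] != H:
        widths[-1] = H
        for k in range(L - 1, 0, -1):
            if widths[k] <= widths[k + 1]:
                widths[k] = widths[k + 1] + 1
    return widths


def default_config(mode: str, n_genes: int, seed: int = 0) -> AEConfig:
    """Preset architectures: transcriptome -> L=5/H=32; pathway -> H=8 with
    L=2 below 100 genes, L=3 otherwise."""
    if mode == "transcriptome":
        L, H = 5, 32
    elif mode == "pathway":
        H = 8
        L = 2 if n_genes < 100 else 3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n_genes <= H:
        raise ValueError(f"{mode} preset needs more than {H} genes, got {n_genes}")
    return AEConfig(n_coding_layers=L, n_latent=H, seed=seed)


def compression_ratio(n_genes: int, H: int) -> int:
    """How many input genes each latent variable summarises: floor(n_genes/H)."""
    if H < 1:
        raise ValueError("H must be >= 1")
    return n_genes // H


class _MLP:
    """Weights + forward/backward for a stack of dense sigmoid/tanh layers."""

    def __init__(self, widths: list[int], activation: str, rng: np.random.Generator):
        self.act, self.dact = _ACTIVATIONS[activation]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        # Glorot uniform; the classic 4x gain for sigmoid keeps activations
        # out of saturation in deeper stacks (without it, depth >= 3
        # collapses to predicting per-gene means)
        gain = 4.0 if activation == "sigmoid" else 1.0
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = gain * math.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for W, b in zip(self.weights, self.biases):
            acts.append(self.act(acts[-1] @ W + b))
        return acts

    def backward(self, acts: list[np.ndarray], grad_out: np.ndarray):
        """Given dL/d(output activation), return per-layer weight gradients
        and dL/d(input activation)."""
        grads_w, grads_b = [], []
        grad = grad_out
        for layer in range(len(self.weights) - 1, -1, -1):
            delta = grad * self.dact(acts[layer + 1])
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            grad = delta @ self.weights[layer].T
        return grads_w[::-1], grads_b[::-1], grad


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedAutoencoder:
    """Fitted encoder/decoder pair with its configuration and history."""

    config: AEConfig
    layer_widths: list[int]
    gene_ids: tuple[str, ...]
    encoder: _MLP = field(repr=False)
    decoder: _MLP = field(repr=False)
    history: pd.DataFrame = field(repr=False)  # epoch, train_mse, test_r2, lr
    final_test_r2: float = float("nan")

    @property
    def n_latent(self) -> int:
        return self.config.n_latent

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(np.asarray(x, dtype=float))[-1]

    def decode_array(self, h: np.ndarray) -> np.ndarray:
        return self.decoder.forward(np.asarray(h, dtype=float))[-1]

    def reconstruct_array(self, x: np.ndarray) -> np.ndarray:
        return self.decode_array(self.encode_array(x))


def _check_genes(ae: TrainedAutoencoder, m: ExpressionMatrix) -> None:
    if m.gene_ids != ae.gene_ids:
        missing = set(ae.gene_ids) - set(m.gene_ids)
        extra = set(m.gene_ids) - set(ae.gene_ids)
        raise ValueError(
            "gene set/order does not match training; "
            f"missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}, "
            f"order_mismatch={not missing and not extra}"
        )


def _pooled_r2(x: np.ndarray, r: np.ndarray) -> float:
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("evaluated entries have zero variance; R^2 undefined")
    ss_res = float(np.sum((x - r) ** 2))
    return 1.0 - ss_res / ss_tot


def reconstruction_r2(ae: TrainedAutoencoder, m: ExpressionMatrix, sample_ids=None) -> float:
    """Pooled reconstruction R^2 = 1 - SS_res/SS_tot over all (sample, gene)
    entries of the chosen samples, SS_tot about their grand mean."""
    _check_genes(ae, m)
    sub = m if sample_ids is None else m.subset_samples(list(sample_ids))
    return _pooled_r2(sub.values, ae.reconstruct_array(sub.values))


def encode(ae: TrainedAutoencoder, m: ExpressionMatrix) -> pd.DataFrame:
    """Latent representation (samples x H) of a matrix with the training genes."""
    _check_genes(ae, m)
    z = ae.encode_array(m.values)
    cols = [f"z{h}" for h in range(ae.n_latent)]
    return pd.DataFrame(z, index=list(m.sample_ids), columns=cols)


def train(m: ExpressionMatrix, split: SplitIndex, cfg: AEConfig) -> TrainedAutoencoder:
    """Train the autoencoder on the split's training samples.

    Deep sigmoid stacks occasionally settle into poor optima from an
    unlucky initialisation (worst case: the per-gene-mean predictor), so
    ``cfg.n_inits`` seed-derived initialisations are trained and the one
    with the best held-out R^2 is returned. Raises if the matrix is not at
    stage ``scaled`` or the loss diverges. Deterministic for a fixed
    config seed on a single thread.
    """
    best: TrainedAutoencoder | None = None
    for attempt in range(max(1, cfg.n_inits)):
        init_seed = (cfg.seed + attempt * 100_003) % 2**31
        candidate = _train_once(m, split, cfg, init_seed)
        if best is None or candidate.final_test_r2 > best.final_test_r2:
            best = candidate
    return best


def _train_once(
    m: ExpressionMatrix, split: SplitIndex, cfg: AEConfig, init_seed: int
) -> TrainedAutoencoder:
    if m.stage != "scaled":
        raise ValueError(f"training expects a scaled matrix, got stage {m.stage!r}")
    known = set(m.sample_ids)
    for s in (*split.train_sample_ids, *split.test_sample_ids):
        if s not in known:
            raise ValueError(f"split sample {s!r} not in matrix")
    if m.n_genes <= cfg.n_latent:
        raise ValueError(f"H={cfg.n_latent} must be smaller than n_genes={m.n_genes}")

    widths = (
        list(cfg.layer_widths)
        if cfg.layer_widths is not None
        else plan_layer_widths(m.n_genes, cfg.n_coding_layers, cfg.n_latent)
    )
    rng = np.random.default_rng(init_seed)
    encoder = _MLP(widths, cfg.activation, rng)
    decoder = _MLP(widths[::-1], cfg.activation, rng)

    x_train = m.subset_samples(list(split.train_sample_ids)).values
    x_test = m.subset_samples(list(split.test_sample_ids)).values
    n_train = x_train.shape[0]
    if cfg.batch_size == "all":
        batch = n_train
    else:
        batch = min(int(cfg.batch_size), n_train)

    params = encoder.weights + encoder.biases + decoder.weights + decoder.biases
    opt = _Adam(params, cfg.learning_rate)

    records = []
    best_r2 = -np.inf
    stall = 0
    best_state = [p.copy() for p in params]

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.decay_interval_epochs)
        if batch == n_train:
            batches = [np.arange(n_train)]
        else:
            order = rng.permutation(n_train)
            batches = [order[i:i + batch] for i in range(0, n_train, batch)]
        epoch_mse = 0.0
        for idx in batches:
            xb = x_train[idx]
            enc_acts = encoder.forward(xb)
            h = enc_acts[-1]
            dec_acts = decoder.forward(h)
            r = dec_acts[-1]
            resid = r - xb
            mse = float(np.mean(resid ** 2))
            epoch_mse += mse * len(idx) / n_train
            if not np.isfinite(mse):
                raise FloatingPointError(f"training loss diverged (NaN/inf) at epoch {epoch}")
            grad_r = 2.0 * resid / resid.size
            dec_gw, dec_gb, grad_h = decoder.backward(dec_acts, grad_r)
            if cfg.l1_penalty > 0:
                grad_h = grad_h + cfg.l1_penalty * np.sign(h) / h.size
            enc_gw, enc_gb, _ = encoder.backward(enc_acts, grad_h)
            grads = enc_gw + enc_gb + dec_gw + dec_gb
            opt.step(params, grads)
        test_r2 = _pooled_r2(x_test, decoder.forward(encoder.forward(x_test)[-1])[-1])
        records.append((epoch, epoch_mse, test_r2, opt.lr))
        if test_r2 > best_r2 + cfg.min_r2_gain:
            best_r2 = test_r2
            stall = 0
            best_state = [p.copy() for p in params]
        else:
            if test_r2 > best_r2:
                best_r2 = test_r2
                best_state = [p.copy() for p in params]
            stall += 1
            if stall >= cfg.patience_epochs:
                break

    for p, saved in zip(params, best_state):  # roll back to the best epoch
        p[...] = saved

    history = pd.DataFrame(records, columns=["epoch", "train_mse", "test_r2", "lr"])
    final = _pooled_r2(x_test, decoder.forward(encoder.forward(x_test)[-1])[-1])
    return TrainedAutoencoder(
        config=cfg,
        layer_widths=widths,
        gene_ids=m.gene_ids,
        encoder=encoder,
        decoder=decoder,
        history=history,
        final_test_r2=final,
    )


def save_autoencoder(ae: TrainedAutoencoder, directory) -> None:
    """Checkpoint: weights.npz + config.json + history.json in a directory."""
    import dataclasses
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for part, net in (("enc", ae.encoder), ("dec", ae.decoder)):
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"{part}_W{i}"] = W
            arrays[f"{part}_b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)
    cfg = dataclasses.asdict(ae.config)
    cfg["layer_widths_planned"] = list(ae.layer_widths)
    cfg["gene_ids"] = list(ae.gene_ids)
    cfg["final_test_r2"] = ae.final_test_r2
    with open(directory / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=1)
    with open(directory / "history.json", "w") as fh:
        json.dump(ae.history.to_dict(orient="list"), fh)


def load_autoencoder(directory) -> TrainedAutoencoder:
    import json
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "config.json") as fh:
        meta = json.load(fh)
    widths = [int(w) for w in meta.pop("layer_widths_planned")]
    gene_ids = tuple(meta.pop("gene_ids"))
    final = float(meta.pop("final_test_r2"))
    if meta.get("layer_widths") is not None:
        meta["layer_widths"] = tuple(meta["layer_widths"])
    cfg = AEConfig(**meta)
    rng = np.random.default_rng(0)
    encoder = _MLP(widths, cfg.activation, rng)
    decoder = _MLP(widths[::-1], cfg.activation, rng)
    with np.load(directory / "weights.npz") as arrays:
        for part, net in (("enc", encoder), ("dec", decoder)):
            for i in range(len(net.weights)):
                net.weights[i] = arrays[f"{part}_W{i}"]
                net.biases[i] = arrays[f"{part}_b{i}"]
    with open(directory / "history.json") as fh:
        history = pd.DataFrame(json.load(fh))
    return TrainedAutoencoder(
        config=cfg,
        layer_widths=widths,
        gene_ids=gene_ids,
        encoder=encoder,
        decoder=decoder,
        history=history,
        final_test_r2=final,
    )
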