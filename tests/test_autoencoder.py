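"""Autoencoder architecture planning, training, early stopping, R^2."""

import numpy as np
import pandas as pd
import pytest

from critix.autoencoder import (
    AEConfig,
    compression_ratio,
    default_config,
    encode,
    load_autoencoder,
    plan_layer_widths,
    reconstruction_r2,
    save_autoencoder,
    train,
)
from critix.preprocess import (
    filter_by_median,
    log2_transform,
    minmax_scale,
    split_train_test,
)
from critix.synthetic import SyntheticSpec, simulate_factor_expression

SMALL_CFG = dict(learning_rate=1e-2, patience_epochs=50)  # converges on small inputs


def scaled_split(spec, seed):
    m, truth = simulate_factor_expression(spec)
    logged = log2_transform(filter_by_median(m))
    split = split_train_test(logged, seed=seed)
    return minmax_scale(logged, fit_sample_ids=split.train_sample_ids), split, truth


class TestArchitecture:
    @pytest.mark.parametrize(
        "n_genes,L,H,expected",
        [(1000, 1, 512, [1000, 512]), (256, 3, 32, [256, 128, 64, 32])],
    )
    def test_geometric_schedule(self, n_genes, L, H, expected):
        assert plan_layer_widths(n_genes, L, H) == expected

    def test_strictly_decreasing_contract(self):
        widths = plan_layer_widths(100, 2, 8)
        assert widths[0] == 100 and widths[-1] == 8
        assert all(a > b for a, b in zip(widths, widths[1:]))

    @pytest.mark.parametrize(
        "mode,n_genes,L,H",
        [("pathway", 80, 2, 8), ("pathway", 250, 3, 8), ("transcriptome", 15000, 5, 32)],
    )
    def test_default_architectures(self, mode, n_genes, L, H):
        cfg = default_config(mode, n_genes)
        assert (cfg.n_coding_layers, cfg.n_latent) == (L, H)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            default_config("pathway", 8)

    @pytest.mark.parametrize("n,H,expected", [(15000, 32, 468), (15000, 512, 29), (7, 7, 1)])
    def test_compression_ratio(self, n, H, expected):
        assert compression_ratio(n, H) == expected

    def test_compression_ratio_of_presets_differ_16_fold(self):
        assert compression_ratio(15000, 32) // compression_ratio(15000, 512) == 16


class TestReconstructionR2:
    def _ae_identity_like(self):
        spec = SyntheticSpec(n_samples=40, n_genes=12, n_factors=2, planted_gene_count=2,
                             block_sizes=(4,), seed=5)
        s, split, _ = scaled_split(spec, 5)
        cfg = AEConfig(n_coding_layers=1, n_latent=4, max_epochs=5, seed=5, **SMALL_CFG)
        return train(s, split, cfg), s, split

    def test_perfect_reconstruction_gives_one(self):
        ae, s, split = self._ae_identity_like()
        ae.decoder.forward = lambda h: [h, s.values]  # force r == x
        assert reconstruction_r2(ae, s) == pytest.approx(1.0)

    def test_grand_mean_reconstruction_gives_zero(self):
        ae, s, split = self._ae_identity_like()
        mean = np.full_like(s.values, s.values.mean())
        ae.decoder.forward = lambda h: [h, mean]
        assert reconstruction_r2(ae, s) == pytest.approx(0.0)

    def test_hand_made_two_by_two(self):
        # x = [[0,1],[1,0]], r = 0.5 everywhere: SS_res = 4*(0.5)^2 = 1 = SS_tot
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        r = np.full((2, 2), 0.5)
        ss_tot = ((x - x.mean()) ** 2).sum()
        assert 1 - ((x - r) ** 2).sum() / ss_tot == pytest.approx(0.0)


class TestTraining:
    def test_noiseless_rank4_data_reconstructs_well(self):
        spec = SyntheticSpec(n_samples=200, n_genes=50, n_factors=4, planted_gene_count=4,
                             loading_scale=3.0, background_loading_sd=0.5, noise_sd=0.0,
                             block_sizes=(10, 10, 10), seed=2)
        s, split, _ = scaled_split(spec, 2)
        cfg = AEConfig(n_coding_layers=2, n_latent=8, patience_epochs=100,
                       learning_rate=1e-2, seed=2)
        ae = train(s, split, cfg)
        assert ae.final_test_r2 >= 0.95

    def test_beats_grand_mean_on_noisy_factor_data(self):
        spec = SyntheticSpec(n_samples=150, n_genes=60, n_factors=4, planted_gene_count=4,
                             background_loading_sd=0.3, noise_sd=0.05,
                             block_sizes=(10, 10), seed=3)
        s, split, _ = scaled_split(spec, 3)
        cfg = AEConfig(n_coding_layers=2, n_latent=8, seed=3, **SMALL_CFG)
        ae = train(s, split, cfg)
        # grand-mean predictor has pooled R^2 = 0 by construction
        assert ae.final_test_r2 >= 0.5

    def test_deterministic_history_for_fixed_seed(self):
        spec = SyntheticSpec(n_samples=60, n_genes=20, n_factors=2, planted_gene_count=2,
                             block_sizes=(5,), seed=4)
        s, split, _ = scaled_split(spec, 4)
        cfg = AEConfig(n_coding_layers=1, n_latent=4, max_epochs=40, seed=4, **SMALL_CFG)
        h1 = train(s, split, cfg).history
        h2 = train(s, split, cfg).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_early_stopping_rule_assertable_from_history(self):
        spec = SyntheticSpec(n_samples=80, n_genes=30, n_factors=2, planted_gene_count=2,
                             block_sizes=(6,), seed=6)
        s, split, _ = scaled_split(spec, 6)
        cfg = AEConfig(n_coding_layers=1, n_latent=4, seed=6, n_inits=1, **SMALL_CFG)
        ae = train(s, split, cfg)
        h = ae.history["test_r2"].to_numpy()
        assert len(h) <= cfg.max_epochs
        if len(h) < cfg.max_epochs:  # stopped early: last `patience` epochs stalled
            best = -np.inf
            stall = 0
            for r2 in h:
                if r2 > best + cfg.min_r2_gain:
                    best = r2
                    stall = 0
                else:
                    best = max(best, r2)
                    stall += 1
            assert stall >= cfg.patience_epochs

    def test_sparsity_pressure_reduces_latent_magnitude(self):
        spec = SyntheticSpec(n_samples=80, n_genes=30, n_factors=2, planted_gene_count=2,
                             block_sizes=(6,), seed=7)
        s, split, _ = scaled_split(spec, 7)
        means = []
        for lam in (1e-4, 1e-2):
            cfg = AEConfig(n_coding_layers=1, n_latent=4, l1_penalty=lam, max_epochs=300,
                           patience_epochs=300, learning_rate=1e-2, seed=7, n_inits=1)
            ae = train(s, split, cfg)
            tr = s.subset_samples(list(split.train_sample_ids))
            means.append(np.abs(ae.encode_array(tr.values)).mean())
        assert means[1] <= means[0]

    def test_encode_shape_and_gene_mismatch(self):
        spec = SyntheticSpec(n_samples=40, n_genes=12, n_factors=2, planted_gene_count=2,
                             block_sizes=(4,), seed=8)
        s, split, _ = scaled_split(spec, 8)
        cfg = AEConfig(n_coding_layers=1, n_latent=3, max_epochs=5, seed=8, **SMALL_CFG)
        ae = train(s, split, cfg)
        z = encode(ae, s)
        assert z.shape == (40, 3)
        one = encode(ae, s.subset_samples([s.sample_ids[0]]))
        assert one.shape == (1, 3)
        permuted = s.subset_genes(list(s.gene_ids[::-1]))
        with pytest.raises(ValueError, match="gene"):
            encode(ae, permuted)

    def test_checkpoint_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_samples=40, n_genes=12, n_factors=2, planted_gene_count=2,
                             block_sizes=(4,), seed=9)
        s, split, _ = scaled_split(spec, 9)
        cfg = AEConfig(n_coding_layers=1, n_latent=3, max_epochs=5, seed=9, **SMALL_CFG)
        ae = train(s, split, cfg)
        save_autoencoder(ae, tmp_path / "ckpt")
        back = load_autoencoder(tmp_path / "ckpt")
        np.testing.assert_allclose(back.encode_array(s.values), ae.encode_array(s.values))
        assert back.config == ae.config
        assert back.final_test_r2 == ae.final_test_r2
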