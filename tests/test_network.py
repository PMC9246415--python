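"""Pair fusion and the residual convolutional scorer."""

import numpy as np
import pytest

from epiconv.alleles import parse_allele
from epiconv.autodiff import Tensor
from epiconv.network import (
    BlockConvConfig,
    BlockConvNet,
    EncodedPair,
    PairScorer,
    ScorerConfig,
    conv1d,
    fuse_pair,
)

TINY = ScorerConfig(
    dim=16,
    blockconv=BlockConvConfig(n_blocks=1, channels=16, seed=0),
    seed=0,
)


def tiny_scorer(**overrides) -> PairScorer:
    cfg_kw = dict(
        dim=16, blockconv=BlockConvConfig(n_blocks=1, channels=16, seed=0),
        seed=0,
    )
    cfg_kw.update(overrides)
    alleles = [parse_allele(a) for a in ("DRB1*01:01", "DPB1*04:02")]
    return PairScorer(ScorerConfig(**cfg_kw), alleles=alleles)


class TestFusePair:
    def test_concat_yields_26_rows_head_first(self):
        head = Tensor(np.ones((2, 8)))
        pep = Tensor(np.zeros((2, 25, 8)))
        out = fuse_pair(head, pep)
        assert out.shape == (2, 26, 8)
        np.testing.assert_array_equal(out.data[:, 0, :], 1.0)
        np.testing.assert_array_equal(out.data[:, 1:, :], 0.0)

    def test_zero_inputs_zero_matrix(self):
        out = fuse_pair(Tensor(np.zeros((1, 8))), Tensor(np.zeros((1, 25, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_swapping_peptides_changes_only_peptide_rows(self):
        rng = np.random.default_rng(0)
        head = Tensor(rng.standard_normal((1, 8)))
        p1 = Tensor(rng.standard_normal((1, 25, 8)))
        p2 = Tensor(rng.standard_normal((1, 25, 8)))
        a = fuse_pair(head, p1).data
        b = fuse_pair(head, p2).data
        np.testing.assert_array_equal(a[:, 0, :], b[:, 0, :])
        assert not np.array_equal(a[:, 1:, :], b[:, 1:, :])

    def test_add_mode_keeps_25_rows(self):
        head = Tensor(np.full((1, 8), 2.0))
        pep = Tensor(np.ones((1, 25, 8)))
        out = fuse_pair(head, pep, mode="add")
        assert out.shape == (1, 25, 8)
        np.testing.assert_array_equal(out.data, 3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_pair(Tensor(np.zeros((1, 9))), Tensor(np.zeros((1, 25, 8))))


class TestConv1d:
    def test_delta_kernel_is_identity(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.standard_normal((1, 10, 4)))
        k = np.zeros((3, 4, 4))
        k[1] = np.eye(4)  # centre tap, channel-preserving
        out = conv1d(x, Tensor(k))
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_ones_kernel_on_constant_input(self):
        x = Tensor(np.ones((1, 10, 1)))
        k = Tensor(np.ones((3, 1, 1)))
        out = conv1d(x, k)
        np.testing.assert_allclose(out.data[0, 1:-1, 0], 3.0)
        np.testing.assert_allclose(out.data[0, 0, 0], 2.0)  # same-padding edge
        np.testing.assert_allclose(out.data[0, -1, 0], 2.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(7)
        B, L, Ci, Co, K = 2, 9, 3, 5, 3
        x = rng.standard_normal((B, L, Ci))
        k = rng.standard_normal((K, Ci, Co))
        b = rng.standard_normal(Co)
        out = conv1d(Tensor(x), Tensor(k), Tensor(b)).data
        expected = np.zeros((B, L, Co))
        for bi in range(B):
            for t in range(L):
                for o in range(Co):
                    acc = b[o]
                    for tap in range(K):
                        src = t + tap - K // 2
                        if 0 <= src < L:
                            for c in range(Ci):
                                acc += k[tap, c, o] * x[bi, src, c]
                    expected[bi, t, o] = acc
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conv1d(Tensor(np.zeros((1, 5, 3))), Tensor(np.zeros((3, 4, 2))))


class TestBlockConvNet:
    def test_residual_identity_with_zeroed_blocks(self):
        cfg = BlockConvConfig(n_blocks=2, channels=8, pooling="average", seed=0)
        net = BlockConvNet(cfg, in_channels=8)
        for c1, c2 in net.blocks:
            for p in c1.params() + c2.params():
                p.data[:] = 0.0
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 8, 8))
        out = net.forward(Tensor(x)).data
        # with blocks zeroed, the trunk is pooling + head of the raw input
        pooled = x
        for _ in range(2):
            B, L, C = pooled.shape
            n = (L + 1) // 2
            nxt = np.zeros((B, n, C))
            for j in range(n):
                nxt[:, j] = pooled[:, 2 * j : 2 * j + 2].mean(axis=1)
            pooled = nxt
        feat = pooled.mean(axis=1)
        logit = feat @ net.w_out.data + net.b_out.data
        expected = 1 / (1 + np.exp(-logit[:, 0]))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_zero_final_dense_gives_sigmoid_bias(self):
        cfg = BlockConvConfig(n_blocks=1, channels=8, seed=0)
        net = BlockConvNet(cfg, in_channels=8)
        net.w_out.data[:] = 0.0
        net.b_out.data[:] = 0.7
        out = net.forward(Tensor(np.random.default_rng(0)
                                 .standard_normal((3, 26, 8)))).data
        np.testing.assert_allclose(out, 1 / (1 + np.exp(-0.7)), atol=1e-12)

    def test_outputs_strictly_inside_unit_interval(self):
        sc = tiny_scorer()
        alleles = [parse_allele("DRB1*01:01")] * 4
        peptides = ["ACDEFGHIK", "WYYWYYWYW", "KKKKKKKKKKK", "AAAAAAAAA"]
        probs = sc.forward(alleles, peptides).data
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BlockConvConfig(n_blocks=0)
        with pytest.raises(ValueError):
            BlockConvConfig(kernel_size=2)
        with pytest.raises(ValueError):
            BlockConvConfig(pooling="median")


class TestDeterminismAndGradients:
    def test_inference_deterministic_and_batch_invariant(self):
        sc = tiny_scorer()
        alleles = [parse_allele(a) for a in
                   ("DRB1*01:01", "DPB1*04:02", "DRB1*01:01")]
        peptides = ["ACDEFGHIK", "WYYWYYWYWHH", "KLMNPQRST"]
        sc.train_mode(False)
        full = sc.forward(alleles, peptides).data
        again = sc.forward(alleles, peptides).data
        np.testing.assert_array_equal(full, again)
        solo = sc.forward(alleles[1:2], peptides[1:2]).data
        np.testing.assert_array_equal(full[1], solo[0])

    def test_batch_norm_couples_sample_to_batch_companions(self):
        # the first sample's score changes when its batch companion does —
        # the coupling that HLAN and layer norm are built to avoid
        a0, p0 = parse_allele("DRB1*01:01"), "ACDEFGHIK"
        sc = tiny_scorer(norm="batch")
        sc.train_mode(True)
        with_b = sc.forward(
            [a0, parse_allele("DPB1*04:02")], [p0, "WYYWYYWYW"]
        ).data[0]
        sc2 = tiny_scorer(norm="batch")
        sc2.train_mode(True)
        with_c = sc2.forward(
            [a0, parse_allele("DQB1*06:02")], [p0, "KKKKKKKKKKK"]
        ).data[0]
        assert not np.isclose(with_b, with_c)
        # whereas the per-sample scheme is companion-free
        sc3 = tiny_scorer(norm="hlan")
        sc3.train_mode(True)
        h_b = sc3.forward(
            [a0, parse_allele("DPB1*04:02")], [p0, "WYYWYYWYW"]
        ).data[0]
        h_c = sc3.forward(
            [a0, parse_allele("DQB1*06:02")], [p0, "KKKKKKKKKKK"]
        ).data[0]
        assert np.isclose(h_b, h_c)

    def test_gradients_match_finite_differences_on_tiny_model(self):
        # 1 block, 8 channels: every parameter, 1e-4 relative agreement
        cfg = ScorerConfig(
            dim=8, blockconv=BlockConvConfig(n_blocks=1, channels=8, seed=3),
            seed=3,
        )
        sc = PairScorer(cfg)
        alleles = [parse_allele("DRB1*01:01"), parse_allele("DQB1*06:02")]
        peptides = ["ACDEFGHIK", "WYYWYYWYWHH"]
        labels = np.array([1.0, 0.0])

        def loss_value():
            sc.train_mode(True)
            return sc.loss(sc.forward(alleles, peptides), labels)

        for p in sc.params():
            p.zero_grad()
        loss_value().backward()
        eps = 1e-5
        worst = 0.0
        for p in sc.params():
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.reshape(-1)
            idxs = np.linspace(0, flat.size - 1, min(6, flat.size)).astype(int)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                hi = float(loss_value().data)
                flat[i] = orig - eps
                lo = float(loss_value().data)
                flat[i] = orig
                num = (hi - lo) / (2 * eps)
                ana = grad.reshape(-1)[i]
                denom = max(abs(num), abs(ana), 1e-6)
                worst = max(worst, abs(num - ana) / denom)
        assert worst < 1e-4


class TestPredictBatch:
    def test_bad_records_isolated(self):
        sc = tiny_scorer()
        rows = sc.predict_batch([
            ("DRB1*01:01", "ACDEFGHIK"),
            ("HLA-DPA1*01:03", "ACDEFGHIK"),   # alpha chain
            ("DPB1*04:02", "ACDEFGH"),          # 7-mer
            ("DPB1*04:02", "KLMNPQRSTV"),
        ])
        assert len(rows) == 4
        assert rows[0]["error"] is None and rows[3]["error"] is None
        assert rows[1]["score"] is None and "alpha" in rows[1]["error"]
        assert rows[2]["score"] is None

    def test_order_preserved_across_batch_sizes(self):
        sc = tiny_scorer()
        recs = [("DRB1*01:01", p) for p in
                ("ACDEFGHIK", "KLMNPQRST", "WYYWYYWYW", "AAAAAAAAAAA")]
        s1 = [r["score"] for r in sc.predict_batch(recs, batch_size=1)]
        s4 = [r["score"] for r in sc.predict_batch(recs, batch_size=4)]
        np.testing.assert_allclose(s1, s4, atol=1e-12)


class TestCheckpoint:
    def test_save_load_roundtrip_scores_identical(self, tmp_path):
        sc = tiny_scorer()
        alleles = [parse_allele("DRB1*01:01")]
        peptides = ["ACDEFGHIK"]
        before = sc.forward(alleles, peptides).data
        sc.save(str(tmp_path / "ckpt"))
        assert (tmp_path / "ckpt.meta.json").exists()  # plain-text sidecar
        loaded = PairScorer.load(str(tmp_path / "ckpt"))
        after = loaded.forward(alleles, peptides).data
        np.testing.assert_array_equal(before, after)

    def test_encoded_pair_shape_contract(self):
        sc = tiny_scorer()
        pair = sc.encode_pair(parse_allele("DRB1*01:01"), "ACDEFGHIK")
        assert pair.matrix.shape == (26, 16)
        with pytest.raises(ValueError):
            EncodedPair(np.zeros((25, 16)), "DRB1*01:01", "ACDEFGHIK")
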