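import numpy as np
import pytest

from vpidet.carsnet import (CARSNet, EmbeddingPair, VowelNetConfig,
                            classify_vowel, contrastive_loss, cross_entropy,
                            predict_vowel, train_vowel_model)
from vpidet.signal_io import DualChannelSignal
from vpidet.spectrogram import make_spectrogram_pair
from vpidet.synth import VowelSourceFilterModel, gen_vowel

FS = 11025.0


def _vowel_pairs(n, seed=0, epochs_cfg=None):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        lab = "vpi" if i % 2 else "control"
        lam = rng.uniform(0.3, 0.7) if lab == "vpi" else rng.uniform(0, 0.05)
        sig = gen_vowel(VowelSourceFilterModel(leakage=lam,
                                               f0=rng.uniform(100, 220)),
                        seed=9000 + i)
        out.append((make_spectrogram_pair(sig), lab))
    return out


class TestSpectrogramPair:
    def test_shape_and_range(self):
        sig = gen_vowel(VowelSourceFilterModel(leakage=0.3, duration_s=0.5), seed=1)
        sp = make_spectrogram_pair(sig)
        assert sp.S_n.shape == sp.S_o.shape == (64, 64)
        for S in (sp.S_n, sp.S_o):
            assert S.min() >= 0.0 and S.max() <= 1.0

    def test_identical_channels_identical_images(self, rng):
        x = rng.standard_normal(5512)
        sp = make_spectrogram_pair(DualChannelSignal(x, x, fs=FS))
        np.testing.assert_array_equal(sp.S_n, sp.S_o)

    def test_pure_tone_row(self):
        t = np.arange(5512) / FS
        x = 0.5 * np.sin(2 * np.pi * 500.0 * t)
        sp = make_spectrogram_pair(DualChannelSignal(x, x, fs=FS))
        expected_row = round(500.0 * 128 / FS) - 1     # DC dropped
        assert np.all(np.argmax(sp.S_o, axis=0) == expected_row)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_spectrogram_pair(DualChannelSignal(np.ones(64), np.ones(64), fs=FS))


class TestBlocks:
    def test_shape_bookkeeping_small_stride2_block(self):
        net = CARSNet(VowelNetConfig.small(side=32, seed=0))
        rng = np.random.default_rng(1)
        xn = rng.random((1, 8, 16, 16))
        xo = rng.random((1, 8, 16, 16))
        yn, yo, cache = net.block_forward(xn, xo, "s1b0")   # 8 -> 16 channels
        assert yn.shape == yo.shape == (1, 16, 8, 8)
        assert net.params["s1b0_a_w"].shape == (16, 16)     # 2*Cin -> Cout
        assert cache["att"][2].shape == (1, 16)             # weight vector W_i

    def test_zeroed_attention_reduces_to_skip(self):
        net = CARSNet(VowelNetConfig.small(side=32, seed=0))
        net.params["s1b0_a_w"][:] = 0.0
        net.params["s1b0_a_b"][:] = 0.0
        rng = np.random.default_rng(2)
        xn = rng.random((2, 8, 16, 16))
        xo = rng.random((2, 8, 16, 16))
        yn, yo, cache = net.block_forward(xn, xo, "s1b0")
        from vpidet.carsnet import conv_forward
        skip, _ = conv_forward(xn, net.params["s1b0_p_w"],
                               net.params["s1b0_p_b"], 2, 0)
        np.testing.assert_allclose(yn, skip, atol=1e-12)

    def test_no_ca_equals_plain_residual_block(self):
        cfg_ca = VowelNetConfig.small(side=32, seed=5)
        cfg_plain = VowelNetConfig.small(side=32, seed=5, use_ca=False)
        net_ca, net_plain = CARSNet(cfg_ca), CARSNet(cfg_plain)
        # align the conv/proj weights, then force attention weights to 1
        for k, v in net_plain.params.items():
            net_ca.params[k] = v.copy()
        for name in [s[0] for s in net_ca._block_specs]:
            net_ca.params[name + "_a_w"][:] = 0.0
            net_ca.params[name + "_a_b"][:] = 1.0   # ReLU(1) = 1: no reweighting
        rng = np.random.default_rng(3)
        xn = rng.random((2, 8, 16, 16))
        xo = rng.random((2, 8, 16, 16))
        a = net_ca.block_forward(xn, xo, "s1b0")
        b = net_plain.block_forward(xn, xo, "s1b0")
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)

    def test_branch_symmetry_every_block(self):
        net = CARSNet(VowelNetConfig.small(side=32, seed=7))
        rng = np.random.default_rng(4)
        x = rng.random((1, 32, 32))
        fn, fo, _ = net.forward_features(x, x.copy())
        np.testing.assert_array_equal(fn, fo)


class TestDFE:
    def test_identical_inputs_zero_distance(self, rng):
        net = CARSNet(VowelNetConfig.small(side=32, seed=0))
        S = rng.random((32, 32))
        emb = net.embed(S, S.copy())
        assert emb.d == 0.0

    def test_default_final_shape(self):
        net = CARSNet(VowelNetConfig())
        assert net.final_shape == (512, 2, 2)
        assert net.flat_dim == 2048

    def test_small_preset_final_shape(self):
        net = CARSNet(VowelNetConfig.small(side=32))
        assert net.final_shape == (64, 1, 1)

    def test_widths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            VowelNetConfig(widths=(64, 64, 128, 256))


class TestClassifierHead:
    def test_zero_difference_gives_half(self):
        emb = EmbeddingPair(F_n_final=np.ones((2, 2, 2)),
                            F_o_final=np.ones((2, 2, 2)), d=0.0)
        p0, p1 = classify_vowel(emb, np.zeros((8, 2)), np.zeros(2))
        assert (p0, p1) == (0.5, 0.5)

    def test_closed_form_softmax(self):
        emb = EmbeddingPair(F_n_final=np.array([[[1.0]]]),
                            F_o_final=np.array([[[0.0]]]), d=1.0)
        w = np.array([[0.0, np.log(3.0)]])
        p0, p1 = classify_vowel(emb, w, np.zeros(2))
        assert p0 == pytest.approx(0.25)
        assert p1 == pytest.approx(0.75)

    def test_probabilities_normalized(self, rng):
        for _ in range(10):
            emb = EmbeddingPair(F_n_final=rng.random((2, 2, 2)),
                                F_o_final=rng.random((2, 2, 2)), d=1.0)
            p0, p1 = classify_vowel(emb, rng.normal(size=(8, 2)),
                                    rng.normal(size=2))
            assert 0 < p0 < 1 and 0 < p1 < 1
            assert p0 + p1 == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        emb = EmbeddingPair(F_n_final=np.ones((2, 2, 2)),
                            F_o_final=np.zeros((2, 2, 2)), d=1.0)
        with pytest.raises(ValueError, match="mismatch"):
            classify_vowel(emb, np.zeros((4, 2)), np.zeros(2))


class TestLosses:
    @pytest.mark.parametrize("d,y,want", [(0.0, 1, 0.0), (0.0, 0, 4.0),
                                          (3.0, 0, 0.0), (1.0, 1, 1.0),
                                          (0.5, 0, 2.25)])
    def test_contrastive_closed_forms(self, d, y, want):
        assert contrastive_loss(d, y, margin=2.0) == pytest.approx(want)

    def test_contrastive_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            contrastive_loss(-0.1, 1)

    @pytest.mark.parametrize("p,y,want", [(0.5, 0, 0.6931), (0.5, 1, 0.6931),
                                          (0.9, 0, 2.3026), (1 - 1e-12, 1, 0.0)])
    def test_cross_entropy_closed_forms(self, p, y, want):
        assert cross_entropy(p, y) == pytest.approx(want, abs=1e-4)

    def test_loss_decomposition(self, rng):
        net = CARSNet(VowelNetConfig.small(side=32, seed=0))
        Xn = rng.random((3, 32, 32))
        Xo = rng.random((3, 32, 32))
        lv, _ = net.loss_and_grads(Xn, Xo, np.array([1.0, 0.0, 1.0]))
        assert lv.total == lv.loss1 + lv.loss2
        assert lv.loss1 >= 0 and lv.loss2 >= 0


class TestGradients:
    def test_finite_difference_agreement(self):
        """Analytic gradients match central differences on the small preset."""
        net = CARSNet(VowelNetConfig.small(side=32, seed=3))
        rng = np.random.default_rng(0)
        Xn = rng.random((2, 32, 32))
        Xo = rng.random((2, 32, 32))
        y = np.array([1.0, 0.0])
        _, grads = net.loss_and_grads(Xn, Xo, y)
        names = ["stem_w", "s0b0_c1_w", "s0b0_a_w", "s1b0_p_w",
                 "s2b0_c2_b", "s3b0_a_b", "head_w", "head_b"]
        for name in names:
            p = net.params[name]
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in p.shape)
                h = 1e-6 * max(1.0, abs(p[ix]))
                orig = p[ix]
                p[ix] = orig + h
                lp, _ = net.loss_and_grads(Xn, Xo, y)
                p[ix] = orig - h
                lm, _ = net.loss_and_grads(Xn, Xo, y)
                p[ix] = orig
                num = (lp.total - lm.total) / (2 * h)
                ana = grads[name][ix]
                assert num == pytest.approx(ana, rel=1e-3, abs=1e-8), name


@pytest.fixture(scope="module")
def training_pairs():
    return _vowel_pairs(200)


class TestTraining:
    def test_separable_synthetic_task(self, training_pairs):
        cfg = VowelNetConfig.small(epochs=10, batch_size=16, seed=0)
        net, hist = train_vowel_model(training_pairs, cfg)
        assert hist.final()["train_acc"] >= 0.9

    def test_seeded_training_is_reproducible(self):
        pairs = _vowel_pairs(16, seed=4)
        cfg = VowelNetConfig.small(epochs=2, batch_size=8, seed=11)
        _, h1 = train_vowel_model(pairs, cfg)
        _, h2 = train_vowel_model(pairs, cfg)
        assert h1.final()["total"] == h2.final()["total"]

    def test_single_class_rejected(self):
        pairs = [(p, "vpi") for p, _ in _vowel_pairs(8)]
        with pytest.raises(ValueError, match="both classes"):
            train_vowel_model(pairs, VowelNetConfig.small(epochs=1))

    def test_ablations_train(self):
        pairs = _vowel_pairs(16, seed=5)
        for kw in ({"use_ca": False}, {"use_contrastive": False}):
            cfg = VowelNetConfig.small(epochs=1, batch_size=8, seed=0, **kw)
            net, hist = train_vowel_model(pairs, cfg)
            assert np.isfinite(hist.final()["total"])

    def test_contrastive_not_inferior(self, training_pairs):
        """Adding the contrastive term does not cost more than 5 accuracy
        points on the synthetic vowel task at fixed seed and epochs."""
        accs = {}
        for flag in (True, False):
            cfg = VowelNetConfig.small(epochs=10, batch_size=16, seed=1,
                                       use_contrastive=flag)
            _, hist = train_vowel_model(training_pairs, cfg)
            accs[flag] = hist.final()["train_acc"]
        assert accs[True] >= accs[False] - 0.05

    def test_predict_vowel_contracts(self):
        pairs = _vowel_pairs(16, seed=7)
        cfg = VowelNetConfig.small(epochs=2, batch_size=8, seed=2)
        net, _ = train_vowel_model(pairs, cfg)
        lab1, p1 = predict_vowel(net, pairs[0][0])
        lab2, p2 = predict_vowel(net, pairs[0][0])
        assert (lab1, p1) == (lab2, p2)
        assert 0.0 < p1 < 1.0

    def test_equal_channels_give_half_probability(self, rng):
        net = CARSNet(VowelNetConfig.small(side=32, seed=9))
        S = rng.random((32, 32))
        p = net.predict_proba(S[None], S[None].copy())[0]
        np.testing.assert_allclose(p, [0.5, 0.5])   # He init leaves biases 0
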