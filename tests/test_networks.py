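import numpy as np
import pytest
from scipy.special import expit

from midecode.autodiff import Tensor
from midecode.networks import (
    CNN,
    CNN_SHAPE_CHAIN,
    SSAE,
    BiLSTM,
    ConvLayer,
    FusionModel,
    LSTMCell,
    bilstm_forward,
    classification_loss,
    cnn_forward,
    conv_forward,
    domain_loss,
    lstm_step,
    parameter_count,
    softmax,
    ssae_forward,
    task_predict,
)

LN2 = np.log(2.0)
LN4 = np.log(4.0)


# --------------------------------------------------------------------- oracles
def naive_lstm_transcription(xs, W, U, b):
    """Straight-line transcription of the gate recurrences, scalar-style."""
    H = U["i"].shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    for x in xs:
        i = expit(W["i"] @ x + U["i"] @ h + b["i"])
        f = expit(W["f"] @ x + U["f"] @ h + b["f"])
        o = expit(W["o"] @ x + U["o"] @ h + b["o"])
        g = np.tanh(W["c"] @ x + U["c"] @ h + b["c"])
        c = f * c + i * g
        h = o * np.tanh(c)
    return h, c


def naive_conv2d(img, w, b, stride=(1, 1)):
    """Quadruple-loop valid convolution oracle: img (H,W,Cin), w (kh,kw,Cin,Cout)."""
    H, W_, Cin = img.shape
    kh, kw, _, Cout = w.shape
    sh, sw = stride
    Ho = (H - kh) // sh + 1
    Wo = (W_ - kw) // sw + 1
    out = np.zeros((Ho, Wo, Cout))
    for i in range(Ho):
        for j in range(Wo):
            for k in range(Cout):
                out[i, j, k] = np.sum(
                    img[i * sh : i * sh + kh, j * sw : j * sw + kw, :] * w[:, :, :, k]
                ) + b[k]
    return out


def naive_maxpool(img, pool):
    ph, pw = pool
    H, W_, C = img.shape
    Ho, Wo = H // ph, W_ // pw
    out = np.zeros((Ho, Wo, C))
    for i in range(Ho):
        for j in range(Wo):
            out[i, j] = img[i * ph : (i + 1) * ph, j * pw : (j + 1) * pw, :].max(axis=(0, 1))
    return out


# ------------------------------------------------------------------------ LSTM
class TestLSTMStep:
    def test_zero_params_zero_state(self, rng):
        cell = LSTMCell(3, 4, rng)
        for t in cell.parameters():
            t.data[...] = 0.0
        p = cell.gate_params()
        h, c = np.zeros(4), np.zeros(4)
        for t in range(5):
            h, c = lstm_step(np.ones(3), (h, c), p)
        # all gates sigmoid(0)=0.5, candidate tanh(0)=0 -> state stays zero
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(c, 0.0)

    def test_matches_transcription_oracle(self, rng):
        cell = LSTMCell(3, 4, rng)
        for t in cell.parameters():
            t.data[...] = rng.standard_normal(t.shape) * 0.4
        p = cell.gate_params()
        xs = rng.standard_normal((5, 3))
        h, c = np.zeros(4), np.zeros(4)
        for x in xs:
            h, c = lstm_step(x, (h, c), p)
        h_o, c_o = naive_lstm_transcription(xs, p.W, p.U, p.b)
        np.testing.assert_allclose(h, h_o, atol=1e-10)
        np.testing.assert_allclose(c, c_o, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        p = LSTMCell(3, 4, rng).gate_params()
        with pytest.raises(ValueError, match="mismatch"):
            lstm_step(np.ones(5), (np.zeros(4), np.zeros(4)), p)

    def test_gates_bounded(self, rng):
        # sigmoid gate outputs in (0,1): h bounded by |tanh| < 1
        cell = LSTMCell(3, 4, rng)
        p = cell.gate_params()
        h, c = np.zeros(4), np.zeros(4)
        h, c = lstm_step(1e3 * np.ones(3), (h, c), p)
        assert np.all(np.abs(h) < 1.0)


class TestBiLSTM:
    def test_fused_matches_reference(self, rng):
        net = BiLSTM(3, 5, rng=rng)
        seq = rng.standard_normal((7, 3))
        fused = net.forward(Tensor(seq[None])).data[0]
        ref = bilstm_forward(seq, net)
        np.testing.assert_allclose(fused, ref, atol=1e-10)

    def test_palindrome_shared_cells_hadamard_is_square(self, rng):
        net = BiLSTM(3, 4, merge_mode="hadamard", rng=rng)
        net.backward_cell = net.forward_cell  # shared params
        half = rng.standard_normal((4, 3))
        seq = np.concatenate([half, half[::-1]])  # palindromic
        out = bilstm_forward(seq, net)
        # forward and backward streams see the same sequence -> same final h
        gp = net.forward_cell.gate_params()
        h, c = np.zeros(4), np.zeros(4)
        for x in seq:
            h, c = lstm_step(x, (h, c), gp)
        np.testing.assert_allclose(out, h * h, atol=1e-12)

    def test_reversal_swaps_streams(self, rng):
        net = BiLSTM(3, 4, rng=rng)
        seq = rng.standard_normal((5, 3))
        fwd = bilstm_forward(seq, net)
        # swapping the two cells and reversing the input swaps the halves
        net.forward_cell, net.backward_cell = net.backward_cell, net.forward_cell
        rev = bilstm_forward(seq[::-1], net)
        np.testing.assert_allclose(rev, np.concatenate([fwd[4:], fwd[:4]]), atol=1e-10)

    def test_zero_params_zero_output(self, rng):
        net = BiLSTM(3, 4, rng=rng)
        for t in net.parameters():
            t.data[...] = 0.0
        out = bilstm_forward(rng.standard_normal((6, 3)), net)
        np.testing.assert_allclose(out, 0.0)

    def test_empty_sequence_rejected(self, rng):
        net = BiLSTM(3, 4, rng=rng)
        with pytest.raises(ValueError, match="empty"):
            bilstm_forward(np.zeros((0, 3)), net)

    def test_merge_dims(self, rng):
        assert BiLSTM(3, 8, merge_mode="concat", rng=rng).out_dim == 16
        assert BiLSTM(3, 8, merge_mode="hadamard", rng=rng).out_dim == 8


# ------------------------------------------------------------------------- CNN
class TestConvForward:
    def test_c1_output_shape(self, rng):
        cnn = CNN(rng=rng)
        out = conv_forward(rng.standard_normal((90, 90, 1)), cnn.c1)
        assert out.shape == (84, 84, 25)

    def test_c2_output_shape(self, rng):
        cnn = CNN(rng=rng)
        out = conv_forward(rng.standard_normal((42, 28, 25)), cnn.c2)
        assert out.shape == (38, 24, 50)

    def test_identity_kernel(self, rng):
        layer = ConvLayer(1, 1, (1, 1), batch_norm=False, rng=rng)
        layer.w.data[...] = 1.0
        layer.b.data[...] = 0.0
        img = rng.uniform(0.0, 1.0, (5, 5, 1))  # non-negative: ReLU is identity
        np.testing.assert_allclose(conv_forward(img, layer), img, atol=1e-12)

    def test_matches_naive_oracle(self, rng):
        layer = ConvLayer(2, 3, (3, 3), batch_norm=False, rng=rng)
        img = rng.standard_normal((7, 8, 2))
        ours = conv_forward(img, layer)
        oracle = np.maximum(
            naive_conv2d(img, layer.w.data, layer.b.data), 0.0
        )
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_kernel_too_large(self, rng):
        layer = ConvLayer(1, 1, (9, 9), batch_norm=False, rng=rng)
        with pytest.raises(ValueError, match="larger"):
            conv_forward(rng.standard_normal((5, 5, 1)), layer)


class TestCNN:
    def test_shape_chain_matches_contract(self, rng):
        cnn = CNN(rng=rng)
        assert cnn.shape_chain == CNN_SHAPE_CHAIN

    def test_forward_is_60_dim(self, rng, small_images):
        cnn = CNN(rng=rng)
        out = cnn_forward(small_images[0], cnn)
        assert out.shape == (60,)

    def test_flatten_length_5700(self, rng):
        assert CNN(rng=rng).shape_chain["F1"] == 5700

    def test_wrong_input_shape(self, rng):
        cnn = CNN(rng=rng)
        with pytest.raises(ValueError, match="90"):
            cnn_forward(np.zeros((80, 90)), cnn)

    def test_violating_chain_impossible(self):
        # constructing a chain that breaks the required shapes must raise:
        # shrink C1's kernel behind CNN.__init__'s back and watch it refuse
        import midecode.networks as nw

        orig = nw.ConvLayer
        try:
            class Bad(orig):
                def __init__(self, cin, cout, kernel, stride=(1, 1), batch_norm=True,
                             rng=None, dtype=np.float64):
                    super().__init__(cin, cout, (5, 5) if kernel == (7, 7) else kernel,
                                     stride, batch_norm, rng, dtype)

            nw.ConvLayer = Bad
            with pytest.raises(ValueError, match="violates"):
                nw.CNN(rng=np.random.default_rng(0))
        finally:
            nw.ConvLayer = orig

    def test_small_cnn_vs_naive_pipeline(self, rng):
        # full chain on one image vs loop-based conv/pool oracle (no BN)
        cnn = CNN(rng=rng, batch_norm=False)
        img = rng.standard_normal((90, 90))
        ours = cnn_forward(img, cnn)
        x = np.maximum(naive_conv2d(img[:, :, None], cnn.c1.w.data, cnn.c1.b.data), 0.0)
        x = naive_maxpool(x, (2, 3))
        x = np.maximum(naive_conv2d(x, cnn.c2.w.data, cnn.c2.b.data), 0.0)
        x = naive_maxpool(x, (2, 4))
        feat = x.reshape(-1) @ cnn.f2.w.data + cnn.f2.b.data
        np.testing.assert_allclose(ours, feat, atol=1e-8)


class TestParameterCount:
    def test_c1_1250(self, rng):
        assert parameter_count(CNN(rng=rng).c1) == 1250

    def test_f2_342060(self, rng):
        assert parameter_count(CNN(rng=rng).f2) == 342060

    def test_trivial_1x1(self, rng):
        assert parameter_count(ConvLayer(1, 1, (1, 1), rng=rng)) == 2

    def test_c2_counted_correctly(self, rng):
        # 5*5*25*50 + 50; a count that ignored the 25 input channels (1300)
        # would be wrong
        assert parameter_count(CNN(rng=rng).c2) == 31300

    def test_bn_reported_separately(self, rng):
        counts = CNN(rng=rng).parameter_counts()
        assert counts["BN"] == 2 * (25 + 50)
        assert counts["C1"] == 1250


# ------------------------------------------------------------------------ SSAE
class TestSSAE:
    def test_zero_input_zero_biases_code_is_half(self, rng):
        p = SSAE(6, (4, 3), rng=rng)
        for t in p.parameters():
            t.data[...] = 0.0
        code, recon = ssae_forward(np.zeros(6), p)
        np.testing.assert_allclose(code, 0.5)
        np.testing.assert_allclose(recon, 0.5)

    def test_degenerate_tied_stage_constant_reconstruction(self, rng):
        p = SSAE(1, (1,), rng=rng)
        for t in p.parameters():
            t.data[...] = 0.0
        for x in (-3.0, 0.0, 5.0):
            _, recon = ssae_forward(np.array([x]), p)
            np.testing.assert_allclose(recon, expit(0.0))

    def test_closed_form_single_stage(self, rng):
        p = SSAE(2, (2,), rng=rng)
        x = rng.standard_normal(2)
        code, recon = ssae_forward(x, p)
        h = expit(p.encoders[0].w.data.T @ x + p.encoders[0].b.data)
        np.testing.assert_allclose(code, h, atol=1e-12)
        np.testing.assert_allclose(
            recon, expit(p.decoders[0].w.data.T @ h + p.decoders[0].b.data), atol=1e-12
        )

    def test_dimension_mismatch(self, rng):
        p = SSAE(6, (4, 3), rng=rng)
        with pytest.raises(ValueError, match="6"):
            ssae_forward(np.zeros(5), p)

    def test_code_dim(self, rng):
        assert SSAE(10, (8, 5), rng=rng).code_dim == 5


# ------------------------------------------------------------- softmax, losses
class TestSoftmax:
    def test_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(4)), 0.25)

    def test_one_hot_score(self):
        p = softmax(np.array([1.0, 0.0, 0.0, 0.0]))
        assert p[0] == pytest.approx(np.e / (np.e + 3), abs=1e-12)

    def test_shift_invariance(self, rng):
        a = rng.standard_normal(6)
        np.testing.assert_allclose(softmax(a), softmax(a + 100.0), atol=1e-12)

    def test_sums_to_one_positive(self, rng):
        p = softmax(rng.standard_normal((5, 4)) * 50)
        assert np.all(p > 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestClassificationLoss:
    def test_perfect_prediction_zero(self):
        assert classification_loss(np.array([1.0, 0, 0, 0]), 0) == 0.0

    def test_uniform_is_ln4(self):
        assert classification_loss(np.full(4, 0.25), 2) == pytest.approx(LN4, abs=1e-9)

    def test_batch_mean(self):
        probs = np.array([[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25]])
        loss = classification_loss(probs, np.array([0, 1]))
        assert loss == pytest.approx(LN2, abs=1e-9)

    def test_zero_probability_clamped(self):
        loss = classification_loss(np.array([0.0, 1.0, 0, 0]), 0)
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))


class TestDomainLoss:
    def test_confident_correct_zero(self):
        assert domain_loss(1.0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_half_is_ln2(self):
        assert domain_loss(0.5, 1) == pytest.approx(LN2, abs=1e-9)

    def test_symmetry_at_half(self):
        assert domain_loss(0.5, 0) == pytest.approx(LN2, abs=1e-9)

    def test_invalid_probability(self):
        with pytest.raises(ValueError, match="invalid"):
            domain_loss(1.7, 1)

    def test_categorical_multidomain(self):
        p = np.array([0.5, 0.25, 0.25])
        assert domain_loss(p, 0) == pytest.approx(LN2, abs=1e-9)
        with pytest.raises(ValueError):
            domain_loss(np.array([0.5, 0.2]), 0)


# ----------------------------------------------------------------- full model
@pytest.fixture(scope="module")
def model():
    return FusionModel(n_domains=2, hidden_size=8, ssae_dims=(16, 9), seed=0)


class TestFusionModel:

    def test_probabilities_sum_to_one(self, model, small_session, small_images):
        probs = task_predict(model, small_session.trials[:4], small_images[:4])
        assert probs.shape == (4, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic(self, model, small_session, small_images):
        a = task_predict(model, small_session.trials[:2], small_images[:2])
        b = task_predict(model, small_session.trials[:2], small_images[:2])
        np.testing.assert_array_equal(a, b)

    def test_stage_mismatch_named(self, model):
        with pytest.raises(ValueError, match="feature-mapper"):
            task_predict(model, np.zeros((2, 5, 500)), np.zeros((2, 90, 90)))

    def test_finite_in_finite_out_and_finite_grads(self, small_session, small_images):
        model = FusionModel(n_domains=2, hidden_size=4, ssae_dims=(8, 5), seed=1,
                            dtype=np.float64)
        seqs = Tensor(small_session.trials[:3].transpose(0, 2, 1))
        imgs = Tensor(small_images[:3])
        code = model.encode(seqs, imgs, training=True)
        from midecode.networks import nll_from_logits

        loss = nll_from_logits(model.task_logits(code), small_session.labels[:3])
        loss.backward()
        for p in model.parameters():
            if p.grad is not None:
                assert np.all(np.isfinite(p.grad))
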