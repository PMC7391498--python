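"""Networks: architecture contracts, cell equations, training, prediction."""

import dataclasses
import math
from types import SimpleNamespace

import numpy as np
import pytest

from seedstage.errors import ConfigurationError
from seedstage.stagenet import (ConvLSTMWeights, LSTMWeights, NetworkSpec,
                                TrainingConfig, build_network,
                                chained_predict, convlstm_step, lstm_step,
                                predict_frames, train_model)
from seedstage.stagenet.train import softmax_cross_entropy


class TestBuildNetwork:
    def test_baseline_forward_is_a_probability_vector(self):
        model = build_network(NetworkSpec.baseline(), seed=0)
        x = np.random.default_rng(0).random((1, 89, 89, 3), dtype=np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (1, 4)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_baseline_conv_filter_counts(self):
        model = build_network(NetworkSpec.baseline(), seed=0)
        assert model.conv_filter_counts() == (64, 128, 256, 256)

    def test_parameter_count_matches_closed_form(self):
        spec = NetworkSpec.baseline()
        model = build_network(spec, seed=0)
        # conv stack: 3x3 kernels, chain 3 -> 64 -> 128 -> 256 -> 256
        conv = sum(3 * 3 * cin * cout + cout
                   for cin, cout in ((3, 64), (64, 128), (128, 256),
                                     (256, 256)))
        # after four 2x2 pools: 89 -> 44 -> 22 -> 11 -> 5; head 6400->512->4
        head = 5 * 5 * 256 * 512 + 512 + 512 * 4 + 4
        assert model.param_count() == conv + head

    def test_lstm_variant_adds_the_cell_parameters(self):
        base = build_network(NetworkSpec.baseline(), seed=0)
        lstm = build_network(NetworkSpec.baseline(temporal="lstm"),
                             seed=0)
        d, u = 6400, 128
        cell = 4 * d * u + 4 * u * u + 3 * u + 4 * u
        head_delta = (d * 512 + 512) - (u * 512 + 512)  # head input shrinks
        assert lstm.param_count() == base.param_count() + cell - head_delta

    def test_too_small_input_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkSpec(conv_filters=(8, 16, 32, 64, 64),
                        input_shape=(16, 16, 3))

    def test_same_seed_same_weights(self):
        a = build_network(NetworkSpec.small(), seed=5)
        b = build_network(NetworkSpec.small(), seed=5)
        for (_, la, ka), (_, lb, kb) in zip(a.parameters(), b.parameters()):
            assert (la.params[ka] == lb.params[kb]).all()


def scalar_lstm_oracle(x, h, c, w, peephole_prev=True):
    """Independent scalar evaluation of the peephole-LSTM step."""
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    i = sig(w["xi"] * x + w["hi"] * h + w["ci"] * c + w["bi"])
    f = sig(w["xf"] * x + w["hf"] * h + w["cf"] * c + w["bf"])
    c_new = f * c + i * math.tanh(w["xc"] * x + w["hc"] * h + w["bc"])
    c_peep = c if peephole_prev else c_new
    o = sig(w["xo"] * x + w["ho"] * h + w["co"] * c_peep + w["bo"])
    return o * math.tanh(c_new), c_new


def scalar_weights(vals):
    return LSTMWeights(
        w_xi=np.array([[vals["xi"]]]), w_hi=np.array([[vals["hi"]]]),
        w_ci=np.array([vals["ci"]]), b_i=np.array([vals["bi"]]),
        w_xf=np.array([[vals["xf"]]]), w_hf=np.array([[vals["hf"]]]),
        w_cf=np.array([vals["cf"]]), b_f=np.array([vals["bf"]]),
        w_xc=np.array([[vals["xc"]]]), w_hc=np.array([[vals["hc"]]]),
        b_c=np.array([vals["bc"]]),
        w_xo=np.array([[vals["xo"]]]), w_ho=np.array([[vals["ho"]]]),
        w_co=np.array([vals["co"]]), b_o=np.array([vals["bo"]]))


class TestLSTMStep:
    VALS = dict(xi=0.3, hi=-0.2, ci=0.1, bi=0.05, xf=-0.4, hf=0.25,
                cf=-0.15, bf=0.6, xc=0.7, hc=-0.5, bc=0.0, xo=0.2,
                ho=0.3, co=-0.25, bo=-0.1)

    def test_zero_everything_gives_zero_state(self):
        zeros = {k: 0.0 for k in self.VALS}
        w = scalar_weights(zeros)
        h, c = lstm_step(np.zeros(1), np.zeros(1), np.zeros(1), w)
        assert h[0] == 0.0 and c[0] == 0.0

    @pytest.mark.parametrize("peephole", ["prev", "new"])
    def test_single_unit_matches_scalar_oracle(self, peephole):
        w = scalar_weights(self.VALS)
        h, c = lstm_step(np.array([0.8]), np.array([-0.3]), np.array([0.5]),
                         w, output_peephole=peephole)
        ho, co = scalar_lstm_oracle(0.8, -0.3, 0.5, self.VALS,
                                    peephole_prev=(peephole == "prev"))
        assert h[0] == pytest.approx(ho, abs=1e-10)
        assert c[0] == pytest.approx(co, abs=1e-10)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        w = LSTMWeights.init(6, 4, rng)
        x = rng.normal(size=6)
        h, c = lstm_step(x, np.zeros(4), np.zeros(4), w)
        # h = o * tanh(c) with o strictly in (0,1): |h| < |tanh(c)| <= 1
        assert (np.abs(h) < 1.0).all()
        finite = np.isfinite(h).all() and np.isfinite(c).all()
        assert finite


class TestConvLSTMStep:
    def test_one_by_one_grid_reduces_to_lstm(self):
        rng = np.random.default_rng(0)
        d, u = 3, 4
        wl = LSTMWeights.init(d, u, rng)
        for name in ("w_ci", "w_cf", "w_co"):
            setattr(wl, name, rng.normal(0, 0.5, u))
        kw = {}
        for f in dataclasses.fields(wl):
            a = getattr(wl, f.name)
            if f.name.startswith("w_x"):
                kw[f.name] = a.reshape(1, 1, d, u)
            elif f.name.startswith("w_h"):
                kw[f.name] = a.reshape(1, 1, u, u)
            else:
                kw[f.name] = a
        wc = ConvLSTMWeights(**kw)
        x = rng.normal(size=d).astype(np.float32)
        h0 = rng.normal(size=u).astype(np.float32)
        c0 = rng.normal(size=u).astype(np.float32)
        h1, c1 = lstm_step(x, h0, c0, wl)
        H1, C1 = convlstm_step(x.reshape(1, 1, d), h0.reshape(1, 1, u),
                               c0.reshape(1, 1, u), wc)
        assert np.abs(H1.ravel() - h1).max() < 1e-6
        assert np.abs(C1.ravel() - c1).max() < 1e-6

    def test_zero_weights_give_zero_hidden_state(self):
        w = ConvLSTMWeights(
            **{f.name: np.zeros_like(getattr(
                ConvLSTMWeights.init(2, 3, 3, np.random.default_rng(0)),
                f.name))
               for f in dataclasses.fields(ConvLSTMWeights)})
        x = np.random.default_rng(1).normal(size=(5, 5, 2))
        H, C = convlstm_step(x, np.zeros((5, 5, 3)), np.zeros((5, 5, 3)), w)
        assert (H == 0).all() and (C == 0).all()

    def test_shift_equivariance_in_the_interior(self):
        # zero-padding breaks equivariance only within one kernel radius of
        # the border; the interior response must shift with the input
        rng = np.random.default_rng(2)
        w = ConvLSTMWeights.init(2, 3, 3, rng)
        x = rng.normal(size=(10, 10, 2)).astype(np.float32)
        H0 = np.zeros((10, 10, 3), dtype=np.float32)
        Ha, _ = convlstm_step(x, H0, H0.copy(), w)
        Hb, _ = convlstm_step(np.roll(x, 2, axis=1), H0, H0.copy(), w)
        assert np.abs(np.roll(Ha, 2, axis=1)[2:-2, 4:-2]
                      - Hb[2:-2, 4:-2]).max() < 1e-5


class TestTraining:
    def test_zero_epochs_is_a_noop(self):
        model = build_network(NetworkSpec.small(), seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((8, 32, 32, 3), dtype=np.float32)
        y = rng.integers(0, 4, 8)
        before = model.state_dict()
        probs0 = model.predict_proba(x)
        train_model(model, x, y, TrainingConfig(epochs=0, seed=0))
        for k, v in model.state_dict().items():
            assert (v == before[k]).all()
        assert (model.predict_proba(x) == probs0).all()

    def test_separable_binary_task_reaches_95_percent(self, easy_crops):
        # green blob vs bare soil, a task separable by construction
        x, y = easy_crops
        frames = x.reshape(-1, 32, 32, 3)
        labels = (y.reshape(-1) > 0).astype(np.int64)
        model = build_network(
            NetworkSpec.small(n_classes=2, class_pair=(0, 1)), seed=0)
        _, history = train_model(model, frames, labels,
                                 TrainingConfig(epochs=5, batch_size=32,
                                                seed=0))
        pred = model.predict_proba(frames.astype(np.float32) / 255.0)
        acc = (pred.argmax(1) == labels).mean()
        assert acc >= 0.95
        # mean epoch loss non-increasing over the first three epochs
        assert history[0] >= history[1] >= history[2]

    def test_identical_seed_identical_loss_history(self, easy_crops):
        x, y = easy_crops
        frames, labels = x.reshape(-1, 32, 32, 3), y.reshape(-1)
        histories = []
        for _ in range(2):
            model = build_network(NetworkSpec.small(), seed=3)
            _, h = train_model(model, frames, labels,
                               TrainingConfig(epochs=2, batch_size=32,
                                              seed=3))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_missing_class_warns(self):
        model = build_network(NetworkSpec.small(), seed=0)
        x = np.zeros((4, 32, 32, 3), dtype=np.float32)
        y = np.zeros(4, dtype=np.int64)      # only Soil present
        with pytest.warns(UserWarning, match="absent"):
            train_model(model, x, y, TrainingConfig(epochs=1, batch_size=4,
                                                    seed=0))


class TestPredictFrames:
    def test_memoryless_model_is_stateless(self):
        model = build_network(NetworkSpec.small(), seed=0)
        frame = np.random.default_rng(0).random((32, 32, 3),
                                                dtype=np.float32)
        seq = np.repeat(frame[None], 6, axis=0)
        trace = predict_frames(model, seq)
        assert np.abs(trace.probs - trace.probs[0]).max() < 1e-6

    def test_probabilities_normalised_per_frame(self, trained_small_lstm,
                                                easy_crops):
        model, _ = trained_small_lstm
        x, _ = easy_crops
        trace = predict_frames(model, x[0])
        assert len(trace) == x.shape[1]
        assert np.abs(trace.probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_trained_lstm_accurate_on_easy_sequences(self,
                                                     trained_small_lstm,
                                                     easy_crops):
        model, _ = trained_small_lstm
        x, y = easy_crops
        accs = [(predict_frames(model, x[i]).labels == y[i]).mean()
                for i in range(len(x))]
        assert np.mean(accs) >= 0.9

    def test_empty_sequence_rejected(self):
        model = build_network(NetworkSpec.small(), seed=0)
        with pytest.raises(ValueError):
            predict_frames(model, np.empty((0, 32, 32, 3)))


def stub_binary(pair, outputs):
    """A stand-in binary classifier emitting a fixed label sequence."""
    outputs = list(outputs)
    calls = []

    def predict_proba(x):
        probs = np.zeros((len(x), 2))
        for i in range(len(x)):
            label = outputs[len(calls)]
            calls.append(label)
            probs[i, int(label == pair[1])] = 1.0
        return probs

    return SimpleNamespace(spec=SimpleNamespace(n_classes=2,
                                                class_pair=pair),
                           is_temporal=False, predict_proba=predict_proba)


class TestChainedPredict:
    SEQ = np.zeros((8, 4, 4, 3), dtype=np.float32)

    def test_always_soil_never_switches(self):
        m1 = stub_binary((0, 1), [0] * 8)
        m2 = stub_binary((1, 2), [])   # must never be consulted per frame
        m3 = stub_binary((2, 3), [])
        trace = chained_predict(m1, m2, m3, self.SEQ)
        assert (trace.labels == 0).all()

    def test_switch_to_second_model_at_first_fa(self):
        m1 = stub_binary((0, 1), [0, 0, 0, 1, 1, 1, 1, 1])
        m2 = stub_binary((1, 2), [1] * 8)
        m3 = stub_binary((2, 3), [2] * 8)
        trace = chained_predict(m1, m2, m3, self.SEQ)
        assert trace.labels.tolist() == [0, 0, 0, 1, 1, 1, 1, 1]

    def test_output_non_decreasing_for_random_stubs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = 12
            m1 = stub_binary((0, 1), rng.integers(0, 2, t) * 1)
            m2 = stub_binary((1, 2), rng.integers(1, 3, t))
            m3 = stub_binary((2, 3), rng.integers(2, 4, t))
            trace = chained_predict(m1, m2, m3,
                                    np.zeros((t, 4, 4, 3),
                                             dtype=np.float32))
            assert (np.diff(trace.labels) >= 0).all()

    def test_wrong_pairing_rejected(self):
        m1 = stub_binary((0, 1), [0])
        m_bad = stub_binary((0, 1), [0])
        m3 = stub_binary((2, 3), [2])
        with pytest.raises(ConfigurationError):
            chained_predict(m1, m_bad, m3, self.SEQ)


class TestGradients:
    """Analytic gradients agree with central differences."""

    @pytest.mark.parametrize("kind", ["lstm", "convlstm"])
    def test_recurrent_layer_full_gradient(self, kind):
        from seedstage.stagenet.recurrent import ConvLSTMLayer, LSTMLayer

        rng = np.random.default_rng(0)
        if kind == "lstm":
            layer = LSTMLayer(3, 4, np.random.default_rng(1))
            x = rng.normal(size=(2, 5, 3))
        else:
            layer = ConvLSTMLayer(3, 4, 3, np.random.default_rng(1))
            x = rng.normal(size=(2, 4, 5, 5, 3))
        for key in ("w_ci", "w_cf", "w_co"):   # exercise the peepholes
            layer.params[key] = rng.normal(0, 0.5, 4).astype(np.float32)
        target = rng.normal(size=x.shape[:2] + layer.forward(x).shape[2:])

        def loss():
            return 0.5 * ((layer.forward(x).astype(np.float64)
                           - target) ** 2).sum()

        out = layer.forward(x).astype(np.float64)
        layer.forward(x)
        layer.backward((out - target).astype(np.float32))
        eps = 1e-3
        for key, p in layer.params.items():
            g = layer.grads[key].astype(np.float64)
            num = np.zeros_like(p, dtype=np.float64)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                l1 = loss()
                p[idx] = orig - eps
                l2 = loss()
                p[idx] = orig
                num[idx] = (l1 - l2) / (2 * eps)
            rel = np.abs(num - g).max() / (np.abs(num).max() + 1e-12)
            assert rel < 1e-2, key

    def test_full_model_gradient_check(self):
        # spot checks through conv/pool/dense/LSTM jointly; max-pool argmax
        # switches make the loss piecewise smooth, hence the mixed tolerance
        rng = np.random.default_rng(3)
        spec = NetworkSpec(conv_filters=(4,), dense_units=8, lstm_units=5,
                           temporal="lstm", n_classes=4,
                           input_shape=(8, 8, 3), dropout=0.0)
        model = build_network(spec, seed=1)
        x = (rng.normal(size=(2, 3, 8, 8, 3)) * 0.5).astype(np.float32)
        y = rng.integers(0, 4, size=(2, 3))
        logits = model.forward(x, train=True)
        _, dlogits = softmax_cross_entropy(logits, y)
        model.backward(dlogits)
        eps = 1e-3
        for name, layer, key in model.parameters():
            p, g = layer.params[key], layer.grads[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            l1, _ = softmax_cross_entropy(model.forward(x), y)
            p[idx] = orig - eps
            l2, _ = softmax_cross_entropy(model.forward(x), y)
            p[idx] = orig
            num = (l1 - l2) / (2 * eps)
            assert abs(num - g[idx]) < 1e-3 + 0.05 * (abs(num)
                                                      + abs(g[idx])), name
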