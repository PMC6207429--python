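"""Forward/backward contracts of the convolutional model and its readouts."""

import numpy as np
import pytest

from fsgm_attn import network as net
from fsgm_attn import stimuli as st

from conftest import CANVAS


def tiny_model(seed=0, **kwargs):
    arch = net.ArchitectureConfig(
        n_maps=kwargs.pop("n_maps", (4, 4, 4, 4)),
        pool_after=kwargs.pop("pool_after", (2,)),
        input_size=kwargs.pop("input_size", 16),
        **kwargs,
    )
    return net.NetworkModel(arch, np.random.default_rng(seed))


def rand_images(n, size=16, seed=1):
    return np.random.default_rng(seed).random((n, 3, size, size))


class TestForwardContract:
    def test_no_attention_equals_zero_attention_bitwise(self):
        m = tiny_model()
        x = rand_images(3)
        base = m.forward(x)
        zero = net.AttentionField(
            mode="multiplicative",
            values={l: np.zeros(4) for l in range(1, 5)},
        )
        res = m.forward(x, attention=zero)
        for a, b in zip(base.activations, res.activations):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(base.pooled, res.pooled)

    def test_gain_minus_one_silences_feature_map(self):
        m = tiny_model()
        x = rand_images(2)
        values = {2: np.zeros(4)}
        values[2][1] = -1.0
        res = m.forward(x, attention=net.AttentionField(values=values))
        assert np.all(res.activations[1][:, 1] == 0)
        # other maps untouched
        base = m.forward(x)
        np.testing.assert_array_equal(res.activations[1][:, 0], base.activations[1][:, 0])

    def test_single_unit_multiplicative_gain_hand_value(self):
        # one 1x1 feature map with pre-activation input I=2: gain (1+0.285)
        # must give exactly 2.57
        arch = net.ArchitectureConfig(
            n_maps=(1,), pool_after=(), input_size=1, input_mean=0.0
        )
        m = net.NetworkModel(arch)
        m.weights[0][:] = 0.0
        m.biases[0][:] = 2.0  # I = 2 regardless of pixel input
        x = np.zeros((1, 3, 1, 1))
        res = m.forward(x, attention=net.AttentionField(values={1: np.array([0.285])}))
        assert res.activations[0][0, 0, 0, 0] == pytest.approx(2.57, abs=1e-12)

    def test_attention_leaves_earlier_layers_unchanged(self):
        m = tiny_model()
        x = rand_images(2)
        base = m.forward(x)
        field = net.AttentionField(values={3: np.full(4, 0.7)})
        res = m.forward(x, attention=field)
        for layer in (0, 1):
            np.testing.assert_array_equal(base.activations[layer], res.activations[layer])

    def test_multiplicative_gain_scales_recorded_activity_exactly(self):
        m = tiny_model()
        x = rand_images(2)
        g = 0.6
        base = m.forward(x)
        res = m.forward(x, attention=net.AttentionField(values={2: np.full(4, g - 1)}))
        r_base = base.activations[1].mean(axis=(2, 3))
        r_att = res.activations[1].mean(axis=(2, 3))
        np.testing.assert_allclose(r_att, g * r_base, rtol=1e-12)

    def test_pooling_halves_spatial_dimensions(self):
        m = tiny_model(n_maps=(4, 4, 4, 4), pool_after=(1, 3), input_size=16)
        res = m.forward(rand_images(1))
        assert [a.shape[2] for a in res.activations] == [16, 8, 8, 4]

    def test_additive_attention_shifts_pre_rectification(self):
        m = tiny_model()
        m.layer_means = np.array([2.0, 2.0, 2.0, 2.0])
        x = rand_images(2)
        base = m.forward(x, keep_cache=True)
        field = net.AttentionField(mode="additive", values={4: np.full(4, 0.5)})
        res = m.forward(x, attention=field)
        # contract: x = [I + mu_l * m]_+ with I unchanged below the target layer
        np.testing.assert_allclose(
            res.activations[3],
            np.maximum(_preactivation(m, base, 3) + 2.0 * 0.5, 0.0),
            rtol=1e-12,
        )

    def test_unknown_attention_layer_rejected(self):
        m = tiny_model()
        with pytest.raises(net.ConfigurationError):
            m.forward(rand_images(1), attention=net.AttentionField(values={9: np.zeros(4)}))

    def test_wrong_map_count_rejected(self):
        m = tiny_model()
        with pytest.raises(net.ConfigurationError):
            m.forward(rand_images(1), attention=net.AttentionField(values={1: np.zeros(3)}))


def _preactivation(model, result, layer_index):
    """Recompute conv pre-activation of a layer from the cached inputs."""
    w = model.weights[layer_index]
    b = model.biases[layer_index]
    return net._conv2d(result.cache["inputs"][layer_index], w, b)


class TestBackward:
    def test_weight_gradients_match_finite_differences(self):
        m = tiny_model(n_maps=(3, 3, 3, 3), input_size=8)
        x = rand_images(2, size=8)
        rng = np.random.default_rng(4)
        d_pooled = rng.standard_normal((2, 3))
        res = m.forward(x, keep_cache=True)
        _, d_ws, d_bs = m.backward_activity_grads(res, d_pooled, weight_grads=True)
        eps = 1e-6
        for layer, (i, j, a, b) in [(0, (1, 2, 0, 1)), (2, (2, 1, 1, 2))]:
            w = m.weights[layer]
            w[i, j, a, b] += eps
            up = (m.forward(x).pooled * d_pooled).sum()
            w[i, j, a, b] -= 2 * eps
            dn = (m.forward(x).pooled * d_pooled).sum()
            w[i, j, a, b] += eps
            assert d_ws[layer][i, j, a, b] == pytest.approx((up - dn) / (2 * eps), rel=1e-5)

    def test_activity_gradients_flow_through_attention_gain(self):
        # with multiplicative gain g at a layer, dE/d(pre-relu) scales by g
        m = tiny_model()
        x = rand_images(1)
        d_pooled = np.ones((1, 4))
        base = m.forward(x, keep_cache=True)
        g = 1.5
        att = net.AttentionField(values={4: np.full(4, g - 1)})
        res = m.forward(x, attention=att, keep_cache=True)
        d_base = m.backward_activity_grads(base, d_pooled)
        d_att = m.backward_activity_grads(res, d_pooled)
        # gradient w.r.t. layer-3 activity gains the factor g via layer 4
        np.testing.assert_allclose(d_att[2], g * d_base[2], rtol=1e-12)


class TestRecordingUtilities:
    def test_spatial_average_hand_example(self):
        act = [np.array([[[[1.0, 2.0], [3.0, 4.0]]]])]
        out = net.record_spatially_averaged_activity(act)
        assert out[0][0, 0] == pytest.approx(2.5)

    def test_constant_and_zero_maps(self):
        act = [np.full((1, 2, 3, 3), 0.0)]
        act[0][0, 1] = 7.0
        out = net.record_spatially_averaged_activity(act)
        assert out[0][0, 0] == 0.0 and out[0][0, 1] == 7.0

    def test_layer_means_positive_and_homogeneous(self):
        m = tiny_model()
        x = rand_images(4)
        mu = net.compute_layer_means(m, x)
        assert np.all(mu > 0) and np.all(np.isfinite(mu))
        assert m.layer_means is mu

    def test_vgg_layer_means_constants_loadable(self):
        m = tiny_model()
        m.layer_means = np.asarray(net.VGG16_LAYER_MEANS, dtype=float)
        assert m.layer_means[0] == 20 and m.layer_means[-1] == 1


class TestFixtureTraining:
    def test_training_determinism_same_seed(self):
        arch = net.ArchitectureConfig(n_maps=(4, 4, 4, 4), pool_after=(2,), input_size=16)
        cfg = net.TrainingConfig(epochs=2, accuracy_floor=0.0)
        train = st.full_field_training_set(2, size=16, seed=9)
        m1 = net.train_fixture_network(train, arch, cfg, seed=5)
        m2 = net.train_fixture_network(train, arch, cfg, seed=5)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_allclose(w1, w2, rtol=1e-10)
        assert m1.holdout_accuracy == m2.holdout_accuracy

    def test_accuracy_floor_enforced(self):
        arch = net.ArchitectureConfig(n_maps=(4, 4, 4, 4), pool_after=(2,), input_size=16)
        cfg = net.TrainingConfig(epochs=1, accuracy_floor=1.01)
        train = st.full_field_training_set(2, size=16, seed=9)
        with pytest.raises(net.TrainingError, match="accuracy"):
            net.train_fixture_network(train, arch, cfg, seed=5)

    def test_too_shallow_architecture_rejected(self):
        arch = net.ArchitectureConfig(n_maps=(4, 4), pool_after=(), input_size=16)
        with pytest.raises(net.ConfigurationError):
            net.train_fixture_network(None, arch, seed=0)


class TestTrainedFixture:
    """Slower checks against the session-scoped trained network."""

    def test_holdout_accuracy_above_twice_chance(self, model):
        assert model.holdout_accuracy > 2 / 45

    def test_binary_readout_bank(self, model, train_set):
        assert set(model.binary_readouts) == set(st.ORIENTATIONS)
        # each detector beats chance on its own training stimuli
        x = st.stack_pixels(train_set)
        pooled = net._pooled_features(model, x)
        for ori in st.ORIENTATIONS:
            p = net.binary_probability(model, pooled, ori)
            truth = np.array([img.contains_orientation(ori) for img in train_set.items])
            acc = ((p >= 0.5) == truth).mean()
            assert acc > 0.5

    def test_two_grating_detection_between_chance_and_perfect(self, model, test_arrays):
        from fsgm_attn.evaluate import evaluate_detection

        perfs = []
        for ori, (x, pos) in test_arrays.items():
            perfs.append(evaluate_detection(model, x, pos, ori).performance)
        assert 0.5 < np.mean(perfs) < 1.0

    def test_color_readout_probabilities(self, model, train_set):
        x = st.stack_pixels(train_set)[:20]
        pooled = net._pooled_features(model, x)
        probs = net.color_probabilities(model, pooled)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-9)
        truth = [next(iter(img.labels)).color for img in train_set.items[:20]]
        acc = (probs.argmax(1) == [st.COLORS.index(c) for c in truth]).mean()
        assert acc > 1 / 5

    def test_attention_shifts_color_readout_toward_attended_grating(
        self, model, tuning_table
    ):
        # on two-grating images, attending one grating's orientation should on
        # average move the 5-way color readout toward that grating's color
        rng = np.random.default_rng(77)
        oris = list(st.ORIENTATIONS)
        from fsgm_attn.attention import AttentionConfig, build_attention_field

        shifts = []
        for _ in range(30):
            ori_a, ori_b = rng.choice(oris, size=2, replace=False)
            ca, cb = rng.choice(5, size=2, replace=False)
            img = st.make_two_grating_image(
                st.GratingSpec(ori_a, st.COLORS[ca], size=CANVAS),
                st.GratingSpec(ori_b, st.COLORS[cb], size=CANVAS),
                CANVAS, seed=rng,
            )
            x = st.stack_pixels([img])
            field = build_attention_field(
                AttentionConfig(source="tuning", layers=(5,), beta=0.75,
                                attended_condition=int(ori_a)),
                tuning_table, model,
            )
            p0 = net.color_probabilities(model, model.forward(x).pooled)[0, ca]
            p1 = net.color_probabilities(
                model, model.forward(x, attention=field).pooled
            )[0, ca]
            shifts.append(p1 - p0)
        assert np.mean(shifts) > 0

    def test_orientation_tuning_quality_rises_with_depth(self, tuning_table):
        from fsgm_attn.tuning import tuning_quality

        q = tuning_quality(tuning_table)
        means = [q[layer].mean() for layer in sorted(q)]
        assert means[-1] > means[0]

    def test_save_load_round_trip(self, model, tmp_path):
        model.save(tmp_path / "archive")
        clone = net.NetworkModel.load(tmp_path / "archive")
        x = rand_images(2, size=CANVAS, seed=8)
        a = model.forward(x)
        b = clone.forward(x)
        np.testing.assert_allclose(a.pooled, b.pooled, rtol=1e-6)
        np.testing.assert_allclose(a.probs, b.probs, rtol=1e-6)
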