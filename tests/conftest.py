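"""Shared fixtures: a small trained network and its stimulus/tuning context.

The session-scoped fixture network is deliberately small (32-pixel canvas,
6-8-8-12-24 feature maps) so the whole suite trains it once in well under a
minute; every directional claim about attention is tested against it.
"""

import numpy as np
import pytest
from hypothesis import settings

from fsgm_attn import network as net
from fsgm_attn import stimuli as st
from fsgm_attn import tuning as tn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

CANVAS = 32
ARCH = net.ArchitectureConfig(n_maps=(6, 8, 8, 12, 24), pool_after=(2, 4), input_size=CANVAS)
SEED = 20260921


@pytest.fixture(scope="session")
def train_set():
    """Full-field grating training set (random phase + block degradation)."""
    return st.full_field_training_set(8, size=CANVAS, seed=SEED)


@pytest.fixture(scope="session")
def model(train_set):
    """Trained fixture network with binary, color and softmax readouts."""
    m = net.train_fixture_network(
        train_set=train_set,
        arch=ARCH,
        config=net.TrainingConfig(epochs=30, accuracy_floor=0.10),
        seed=SEED,
    )
    net.attach_binary_readouts(m, list(st.ORIENTATIONS), train_set, seed=SEED)
    net.attach_color_readout(m, train_set, seed=SEED)
    net.compute_layer_means(m, st.stack_pixels(train_set))
    return m


@pytest.fixture(scope="session")
def activity_record(model, train_set):
    """Spatially averaged responses to the training gratings, labelled by orientation."""
    oris = list(st.ORIENTATIONS)
    labels = [oris.index(next(iter(img.labels)).orientation) for img in train_set.items]
    x = st.stack_pixels(train_set)
    return tn.record_responses(model, x, labels, oris)


@pytest.fixture(scope="session")
def tuning_table(activity_record):
    return tn.compute_tuning_values(activity_record)


@pytest.fixture(scope="session")
def test_sets():
    """Balanced two-grating detection sets, one per orientation."""
    rng = np.random.default_rng(SEED + 1)
    sets = {}
    for ori in st.ORIENTATIONS:
        recipe = st.two_grating_recipe(ori, CANVAS)
        sets[ori] = st.build_balanced_detection_set(ori, 40, recipe, seed=rng)
    return sets


@pytest.fixture(scope="session")
def test_arrays(test_sets):
    """Stacked pixel arrays and positive flags for each detection set."""
    return {
        ori: (st.stack_pixels(s), s.is_positive) for ori, s in test_sets.items()
    }


def make_toy_logistic_model(weights, bias, n_maps=2, size=4, seed=0):
    """One-conv-layer network with a hand-set binary logistic readout.

    The convolution weights stay random (the toy's substance is the readout);
    ``weights``/``bias`` define the logistic readout on pooled features.
    """
    arch = net.ArchitectureConfig(
        n_maps=(n_maps,), pool_after=(), input_size=size, input_mean=0.0
    )
    m = net.NetworkModel(arch, np.random.default_rng(seed))
    m.binary_readouts["toy"] = (np.asarray(weights, dtype=float), float(bias))
    return m
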