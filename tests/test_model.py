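"""Architecture family: exact parameter counts, weight sharing, checkpoints."""

import numpy as np
import pytest

from brainage2d import (ChannelTag, DEFAULT_CHANNELS, MEAN_CHANNELS, ModelSpec,
                        build_model, count_parameters, load_weights, save_weights)
from brainage2d.model import state_dict, load_state

STD_3 = tuple(ChannelTag(p, "std") for p in ("axial", "coronal", "sagittal"))

# The published trainable-parameter counts for the architecture family
# (3ch = one mean channel per plane, 6ch = mean+std per plane).
PUBLISHED_COUNTS = [
    (dict(depth=13, width=1.0, channels=MEAN_CHANNELS), 2_009_261),
    (dict(depth=13, width=1.0, channels=STD_3), 2_009_261),
    (dict(depth=13, width=1.0, channels=DEFAULT_CHANNELS), 2_009_369),
    (dict(depth=13, width=1.0, channels=DEFAULT_CHANNELS, iso=True), 827_841),
    (dict(depth=13, width=0.5, channels=MEAN_CHANNELS), 505_037),
    (dict(depth=13, width=0.5, channels=DEFAULT_CHANNELS), 505_091),
    (dict(depth=13, width=0.5, channels=DEFAULT_CHANNELS, iso=True), 209_167),
    (dict(depth=13, width=2.0, channels=MEAN_CHANNELS), 8_015_333),
    (dict(depth=13, width=2.0, channels=DEFAULT_CHANNELS), 8_015_549),
    (dict(depth=13, width=2.0, channels=DEFAULT_CHANNELS, iso=True), 3_293_773),
    (dict(depth=19, width=1.0, channels=MEAN_CHANNELS), 2_599_697),
    (dict(depth=19, width=1.0, channels=DEFAULT_CHANNELS), 2_599_805),
    (dict(depth=19, width=1.0, channels=DEFAULT_CHANNELS, iso=True), 1_024_653),
    (dict(depth=25, width=1.0, channels=DEFAULT_CHANNELS, iso=True), 1_221_465),
]


def small_spec(**kw):
    kw.setdefault("depth", 13)
    kw.setdefault("width", 0.5)
    return ModelSpec(**kw)


def tiny_batch(spec, n=2, h=17, w=13, seed=0):
    rng = np.random.default_rng(seed)
    return {p: rng.normal(size=(n, len(spec.plane_channels(p)), h, w)).astype(np.float32)
            for p in spec.planes}


class TestParameterCounts:
    @pytest.mark.parametrize("kw,expected", PUBLISHED_COUNTS,
                             ids=[f"d{c[0]['depth']}w{c[0]['width']}"
                                  f"c{len(c[0]['channels'])}{'iso' if c[0].get('iso') else ''}"
                                  for c in PUBLISHED_COUNTS])
    def test_published_counts_reproduced(self, kw, expected):
        net = build_model(ModelSpec(**kw))
        assert count_parameters(net).total == expected

    def test_six_vs_three_channel_delta_is_first_layer_kernels(self):
        """3 extra input channels x 4 first-layer filters x 3x3 kernel = 108."""
        six = count_parameters(build_model(ModelSpec(channels=DEFAULT_CHANNELS))).total
        three = count_parameters(build_model(ModelSpec(channels=MEAN_CHANNELS))).total
        assert six - three == 3 * 4 * 9

    def test_iso_identity_stack_plus_head(self):
        """non-iso total = 3 x stack + head; iso total = stack + head."""
        spec = ModelSpec(channels=DEFAULT_CHANNELS)
        pc = count_parameters(build_model(spec))
        pc_iso = count_parameters(build_model(ModelSpec(channels=DEFAULT_CHANNELS, iso=True)))
        stacks = set(pc.per_stack.values())
        assert len(stacks) == 1  # identical topology per plane
        stack = stacks.pop()
        assert pc.total == 3 * stack + pc.head
        assert pc_iso.total == stack + pc_iso.head
        assert pc.head == pc_iso.head

    def test_breakdown_sums_to_total(self):
        pc = count_parameters(build_model(small_spec()))
        assert pc.total == sum(pc.per_stack.values()) + pc.head
        assert pc.batchnorm > 0  # BN scale+shift counted as trainable


class TestSpecValidation:
    def test_unsupported_depth(self):
        with pytest.raises(ValueError, match="depth"):
            ModelSpec(depth=15)

    def test_unsupported_width(self):
        with pytest.raises(ValueError, match="width"):
            ModelSpec(width=0.75)

    def test_empty_channels(self):
        with pytest.raises(ValueError):
            ModelSpec(channels=())

    def test_iso_needs_equal_plane_channels(self):
        chans = (ChannelTag("axial", "mean"), ChannelTag("axial", "std"),
                 ChannelTag("coronal", "mean"))
        with pytest.raises(ValueError, match="iso"):
            ModelSpec(channels=chans, iso=True)

    def test_spec_json_round_trip(self):
        spec = ModelSpec(depth=19, width=2.0, iso=True)
        assert ModelSpec.from_json(spec.to_json()) == spec


class TestForward:
    def test_forward_returns_one_scalar_per_subject(self):
        spec = small_spec()
        net = build_model(spec, seed=1)
        out, _ = net.forward(tiny_batch(spec, n=3))
        assert out.shape == (3,)
        assert np.isfinite(out).all()

    def test_iso_stacks_produce_identical_features(self):
        """With shared weights, identical per-plane inputs give identical
        stack features, hence the same output as any plane permutation."""
        spec = small_spec(iso=True)
        net = build_model(spec, seed=1)
        rng = np.random.default_rng(3)
        img = rng.normal(size=(2, 16, 16, 2)).astype(np.float32)  # NHWC
        feats = {}
        for p in spec.planes:
            f, _ = net.stacks[p].forward(img, training=False)
            feats[p] = f
        for p in spec.planes[1:]:
            np.testing.assert_array_equal(feats[p], feats[spec.planes[0]])

    def test_missing_plane_rejected(self):
        spec = small_spec()
        net = build_model(spec)
        batch = tiny_batch(spec)
        del batch["axial"]
        with pytest.raises(ValueError, match="axial"):
            net.forward(batch)

    def test_wrong_channel_count_rejected(self):
        spec = small_spec()
        net = build_model(spec)
        batch = tiny_batch(spec)
        batch["coronal"] = batch["coronal"][:, :1]
        with pytest.raises(ValueError, match="coronal"):
            net.forward(batch)


class TestCheckpoint:
    def test_save_load_round_trip_exact(self, tmp_path):
        spec = small_spec()
        net = build_model(spec, seed=2)
        batch = tiny_batch(spec)
        before = net.predict(batch)
        path = save_weights(net, tmp_path / "m.ckpt")
        net2 = load_weights(path)
        np.testing.assert_array_equal(net2.predict(batch), before)

    def test_checkpoint_self_describes_spec(self, tmp_path):
        spec = small_spec(depth=19, iso=True)
        path = save_weights(build_model(spec), tmp_path / "m.ckpt")
        assert load_weights(path).spec == spec

    def test_load_with_mismatched_spec_rejected(self, tmp_path):
        path = save_weights(build_model(small_spec(depth=13)), tmp_path / "m.ckpt")
        with pytest.raises(ValueError, match="depth"):
            load_weights(path, spec=small_spec(depth=19))

    def test_state_dict_shape_mismatch_names_parameter(self):
        net = build_model(small_spec())
        state = state_dict(net)
        key = next(k for k in state if k.endswith("head.out.W"))
        state[key] = state[key][:3]
        with pytest.raises(ValueError, match="head.out.W"):
            load_state(net, state)
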