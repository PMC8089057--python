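"""Architecture contracts: building blocks, forward passes, checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

import contactattn as ca
from contactattn.network import (
    ModelConfig, ResidualStack, SqueezeExciteParams, build_model,
    ensemble_predict, load_model, maxout_reduce, save_model, squeeze_excite,
    symmetrize,
)
from contactattn.nn import Tensor, SqueezeExcite
from contactattn.features import ContactMap, FeatureSet, PlmTensor, Pssm


def make_fs(rng, L, channels=16):
    return FeatureSet(pssm=Pssm(values=rng.uniform(size=(L, 20))),
                      plm=PlmTensor(values=rng.normal(size=(L, L, channels))))


# ---------------------------------------------------------------------------
# Maxout

def test_maxout_examples(rng):
    assert maxout_reduce(np.array([[3.0, -1.0]]))[0, 0] == 3.0
    f = rng.normal(size=(4, 4, 128))
    out = maxout_reduce(f)
    assert out.shape == (4, 4, 64)
    for k in range(64):  # loop oracle over channel pairs
        assert np.array_equal(out[..., k], np.maximum(f[..., 2 * k], f[..., 2 * k + 1]))
    with pytest.raises(ValueError):
        maxout_reduce(np.zeros((2, 2, 5)))


# ---------------------------------------------------------------------------
# Squeeze-and-excitation

def test_squeeze_excite_gate_limits(rng):
    f = rng.normal(size=(5, 5, 4))
    big = 1e3
    # weights that force the gate to ~1 regardless of input
    p1 = SqueezeExciteParams(w1=np.zeros((4, 2)), b1=np.zeros(2),
                             w2=np.zeros((2, 4)), b2=np.full(4, big))
    assert np.abs(squeeze_excite(f, p1) - f).max() < 1e-9
    p0 = SqueezeExciteParams(w1=np.zeros((4, 2)), b1=np.zeros(2),
                             w2=np.zeros((2, 4)), b2=np.full(4, -big))
    assert np.abs(squeeze_excite(f, p0)).max() < 1e-9


def test_squeeze_excite_matches_loop_oracle(rng):
    f = rng.normal(size=(6, 6, 5))
    p = SqueezeExciteParams(w1=rng.normal(size=(5, 2)), b1=rng.normal(size=2),
                            w2=rng.normal(size=(2, 5)), b2=rng.normal(size=5))
    out = squeeze_excite(f, p)
    z = np.array([f[:, :, ch].mean() for ch in range(5)])
    hidden = np.maximum(z @ p.w1 + p.b1, 0.0)
    gate = 1.0 / (1.0 + np.exp(-(hidden @ p.w2 + p.b2)))
    for ch in range(5):
        assert np.abs(out[:, :, ch] - gate[ch] * f[:, :, ch]).max() < 1e-12


def test_squeeze_excite_layer_agrees_with_functional(rng):
    layer = SqueezeExcite(4, 2, rng)
    f = rng.normal(size=(5, 5, 4))
    p = SqueezeExciteParams(w1=layer.fc1.w.data, b1=layer.fc1.b.data,
                            w2=layer.fc2.w.data, b2=layer.fc2.b.data)
    assert np.abs(layer(Tensor(f)).data - squeeze_excite(f, p)).max() < 1e-12


# ---------------------------------------------------------------------------
# Residual trunk

@pytest.mark.parametrize("L", [8, 17, 33])
def test_residual_stack_preserves_spatial_shape(rng, L):
    stack = ResidualStack(c_in=6, width=8, repeats=(1, 1), se_ratio=2, rng=rng)
    out = stack(Tensor(rng.normal(size=(L, L, 6))))
    assert out.shape == (L, L, 8)


def test_trunk_convolution_count_full_scale():
    """Full-scale trunk: 3+4+6+3 main 3x3 convolutions plus 4 shortcuts."""
    cfg = ModelConfig.full_scale("sequence")
    model = build_model(cfg)
    main = sum(len(b.convs) for b in model.trunk.blocks)
    shortcuts = len(model.trunk.blocks)
    assert main == 3 + 4 + 6 + 3
    assert shortcuts == 4
    assert all(c.kernel == 3 for b in model.trunk.blocks for c in b.convs)
    assert all(b.shortcut.kernel == 1 for b in model.trunk.blocks)
    assert all(c.c_out == 64 for b in model.trunk.blocks for c in b.convs)


def test_zeroed_trunk_reduces_to_gated_shortcut(rng):
    """With main convolutions zeroed, each block is SE-gate * shortcut."""
    from contactattn.network import ResidualBlock
    block = ResidualBlock(c_in=3, width=4, repeats=2, se_ratio=2, rng=rng)
    for conv in block.convs:
        conv.w.data[:] = 0.0
        conv.b.data[:] = 0.0
    x = Tensor(rng.normal(size=(2, 2, 3)))
    shortcut = block.shortcut(x)
    gate = block.se.gate_values(shortcut)
    expected = shortcut.data * gate
    assert np.abs(block(x).data - expected).max() < 1e-12


def test_full_scale_preattention_width_is_32():
    cfg = ModelConfig.full_scale("regional")
    model = build_model(cfg)
    assert model.pre_attn_conv.c_out == 32
    assert cfg.region_n == 5 and cfg.n_heads == 4


# ---------------------------------------------------------------------------
# Module forward passes

@pytest.mark.parametrize("module", ["sequence", "regional"])
def test_forward_output_contract(rng, module):
    model = build_model(ModelConfig.tiny(module))
    fs = make_fs(rng, 12)
    out = model.predict(fs)
    assert out.contacts.values.shape == (12, 12)
    assert out.contacts.values.min() >= 0.0 and out.contacts.values.max() <= 1.0
    assert out.contacts.kind == "probability"


@pytest.mark.parametrize("module", ["sequence", "regional"])
def test_forward_deterministic_and_capture_side_effect_free(rng, module):
    model = build_model(ModelConfig.tiny(module))
    fs = make_fs(rng, 10)
    a = model.predict(fs, capture=False).contacts.values
    b = model.predict(fs, capture=True)
    c = model.predict(fs, capture=False).contacts.values
    assert np.array_equal(a, b.contacts.values)
    assert np.array_equal(a, c)
    assert b.attention is not None


def test_captured_weights_satisfy_invariants(rng):
    fs = make_fs(rng, 9)
    seq = build_model(ModelConfig.tiny("sequence")).predict(fs, capture=True)
    w = seq.attention.sequence
    assert np.abs(w.w_att.sum(axis=-1) - 1.0).max() < 1e-5
    reg = build_model(ModelConfig.tiny("regional")).predict(fs, capture=True)
    rw = reg.attention.regional
    assert np.abs(rw.weights.sum(axis=-1) - 1.0).max() < 1e-5


@pytest.mark.parametrize("module", ["sequence", "regional"])
def test_baseline_variant_produces_valid_maps(rng, module):
    model = build_model(ModelConfig.tiny(module, use_attention=False))
    assert model.config.variant == "baseline"
    out = model.predict(fs := make_fs(rng, 11), capture=True)
    assert out.contacts.values.shape == (11, 11)
    assert out.attention is None
    assert 0.0 <= out.contacts.values.min() <= out.contacts.values.max() <= 1.0


def test_parameter_counts_are_config_determined():
    """Regression: parameter counts are pure functions of the config."""
    assert build_model(ModelConfig.tiny("sequence")).n_parameters() == 19265
    assert build_model(ModelConfig.tiny("regional")).n_parameters() == 17425
    # independent of the initialization seed
    a = build_model(ModelConfig.tiny("sequence", init_seed=5)).n_parameters()
    assert a == 19265


def test_length_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        FeatureSet(pssm=Pssm(values=rng.uniform(size=(10, 20))),
                   plm=PlmTensor(values=rng.normal(size=(11, 11, 16))))


# ---------------------------------------------------------------------------
# Ensemble and symmetrization

def test_ensemble_properties(rng):
    L = 6
    v = rng.uniform(size=(L, L))
    a = ContactMap(values=v, kind="probability")
    assert np.array_equal(ensemble_predict(a, a).values, v)
    zero = ContactMap(values=np.zeros((L, L)), kind="probability")
    one = ContactMap(values=np.ones((L, L)), kind="probability")
    assert np.all(ensemble_predict(zero, one).values == 0.5)
    b = ContactMap(values=rng.uniform(size=(L, L)), kind="probability")
    e = ensemble_predict(a, b)
    assert e.values.min() >= 0.0 and e.values.max() <= 1.0


def test_symmetrize(rng):
    v = rng.uniform(size=(5, 5))
    m = symmetrize(ContactMap(values=v, kind="probability"))
    assert np.array_equal(m.values, m.values.T)
    assert m.values.min() >= 0.0 and m.values.max() <= 1.0
    sym = ContactMap(values=(v + v.T) / 2, kind="probability")
    assert np.array_equal(symmetrize(sym).values, sym.values)


# ---------------------------------------------------------------------------
# Checkpoints

@pytest.mark.parametrize("module", ["sequence", "regional"])
def test_checkpoint_round_trip(rng, tmp_path, module):
    model = build_model(ModelConfig.tiny(module))
    path = tmp_path / "m.npz"
    save_model(model, path)
    clone = load_model(path)
    fs = make_fs(rng, 9)
    assert np.array_equal(model.predict(fs).contacts.values,
                          clone.predict(fs).contacts.values)
    assert clone.config == model.config
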