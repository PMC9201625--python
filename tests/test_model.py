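"""Dual-branch assembly: projections, fusion, branch ablations, parameter
accounting, classification and encoder-weight transfer."""

import numpy as np
import pytest

from onet import nn
from onet.model import (BranchSettings, ONet, ONetClassifier, ONetConfig,
                        count_parameters, fuse_encoder_features,
                        project_grid_to_tokens, project_tokens_to_grid,
                        tiny_config, transfer_encoder_weights)
from onet.swin import TokenGrid


def cfg_with(**branches):
    base = dict(use_swin_encoder=True, use_cnn_encoder=True,
                use_swin_decoder=True, use_cnn_decoder=True)
    base.update(branches)
    return tiny_config(branches=BranchSettings(**base))


# -- projections --------------------------------------------------------------

def test_identity_projection_is_pure_reshape(rng):
    toks = rng.normal(size=(1, 12, 5))
    g = TokenGrid(nn.Tensor(toks), 3, 4)
    out = project_tokens_to_grid(g, np.eye(5)).data
    assert out.shape == (1, 5, 3, 4)
    np.testing.assert_array_equal(out[0, :, 1, 2], toks[0, 1 * 4 + 2])


def test_projection_round_trip_with_pseudo_inverse(rng):
    w = rng.normal(size=(5, 8))
    toks = rng.normal(size=(1, 12, 5))
    g = TokenGrid(nn.Tensor(toks), 3, 4)
    fmap = project_tokens_to_grid(g, w)
    back = project_grid_to_tokens(fmap, np.linalg.pinv(w))
    np.testing.assert_allclose(back.tokens.data, toks, atol=1e-5)
    assert (back.grid_height, back.grid_width) == (3, 4)


def test_grid_to_tokens_shapes(rng):
    fmap = nn.Tensor(rng.normal(size=(1, 40, 28, 28)))
    out = project_grid_to_tokens(fmap, rng.normal(size=(40, 6)))
    assert out.tokens.shape == (1, 784, 6)
    zero = project_grid_to_tokens(nn.Tensor(np.zeros((1, 40, 4, 4))),
                                  rng.normal(size=(40, 6)),
                                  bias=np.ones(6))
    np.testing.assert_allclose(zero.tokens.data, 1.0)


# -- fusion -------------------------------------------------------------------

def test_additive_fusion_identities(rng):
    x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)))
    zero = nn.Tensor(np.zeros((1, 4, 8, 8)))
    np.testing.assert_array_equal(fuse_encoder_features(x, zero).data, x.data)
    np.testing.assert_allclose(fuse_encoder_features(x, x).data, 2 * x.data)
    with pytest.raises(ValueError, match="mismatch"):
        fuse_encoder_features(x, nn.Tensor(np.zeros((1, 3, 8, 8))))


def test_concat_fusion_reduces_to_target_channels(rng):
    x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)))
    reducer = nn.Conv2d(8, 4, 1)
    out = fuse_encoder_features(x, x, mode="concat", reducer=reducer)
    assert out.shape == (1, 4, 8, 8)


# -- segmentation forward -----------------------------------------------------

def test_segmentation_logits_match_input_shape(rng):
    model = ONet(tiny_config())
    with nn.no_grad():
        out = model(nn.Tensor(rng.normal(size=(1, 1, 64, 64))))
    assert out.logits.shape == (1, 4, 64, 64)
    assert set(out.branch_logits) == {"swin", "cnn"}
    # non-divisible input is padded internally and cropped back
    with nn.no_grad():
        odd = model(nn.Tensor(rng.normal(size=(1, 1, 50, 42))))
    assert odd.logits.shape == (1, 4, 50, 42)


def test_all_nine_branch_combinations_run_forward_backward(rng):
    x = nn.Tensor(rng.normal(size=(1, 1, 32, 32)))
    target = np.zeros((1, 32, 32), dtype=int)
    for se, ce in ((1, 0), (0, 1), (1, 1)):
        for sd, cd in ((1, 0), (0, 1), (1, 1)):
            nn.manual_seed(1)
            model = ONet(cfg_with(use_swin_encoder=bool(se),
                                  use_cnn_encoder=bool(ce),
                                  use_swin_decoder=bool(sd),
                                  use_cnn_decoder=bool(cd)))
            out = model(x)
            assert out.logits.shape == (1, 4, 32, 32)
            loss = nn.cross_entropy_logits(out.logits, target)
            loss.backward()


def test_zero_branch_configs_rejected():
    with pytest.raises(ValueError, match="encoder"):
        cfg_with(use_swin_encoder=False, use_cnn_encoder=False)
    with pytest.raises(ValueError, match="decoder"):
        cfg_with(use_swin_decoder=False, use_cnn_decoder=False)


def test_disabling_a_branch_removes_exactly_its_parameters():
    nn.manual_seed(0)
    full = ONet(tiny_config())
    n_full = count_parameters(full)
    for branch in ("swin_encoder", "cnn_encoder", "swin_decoder", "cnn_decoder"):
        nn.manual_seed(0)
        sub = ONet(cfg_with(**{f"use_{branch}": False}))
        assert n_full - count_parameters(sub) == count_parameters(full, branch)
    # encoder + decoder scopes partition the total (fusion is parameter-free)
    assert count_parameters(full, "encoder") + count_parameters(full, "decoder") \
        == n_full


def test_single_branch_model_is_strict_subset_of_full():
    nn.manual_seed(0)
    full = ONet(tiny_config())
    sub = ONet(cfg_with(use_cnn_encoder=False, use_cnn_decoder=False))
    full_names = {n for n, _ in full.named_parameters()}
    sub_names = {n for n, _ in sub.named_parameters()}
    assert sub_names < full_names
    assert all(n.startswith(("swin_encoder.", "swin_decoder.")) for n in sub_names)


def test_gradient_reaches_every_parameter(rng):
    nn.manual_seed(3)
    model = ONet(tiny_config())
    out = model(nn.Tensor(rng.normal(size=(1, 1, 64, 64))))
    loss = nn.cross_entropy_logits(out.logits, rng.integers(0, 4, size=(1, 64, 64)))
    loss.backward()
    dead = [n for n, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert not dead, f"no gradient reached: {dead[:5]}"


def test_count_parameters_closed_form():
    lin = nn.Linear(10, 5)
    assert lin.num_parameters() == 55
    assert count_parameters(lin) == 55


# -- classification -----------------------------------------------------------

def test_classifier_output_and_pooling(rng):
    nn.manual_seed(2)
    cls = ONetClassifier(tiny_config(num_classification_classes=3))
    out = cls(nn.Tensor(rng.normal(size=(2, 1, 64, 64))))
    assert out.logits.shape == (2, 3)
    # global average pooling of a constant map is that constant per channel
    x = nn.Tensor(np.full((1, 6, 4, 4), 2.5))
    np.testing.assert_allclose(nn.global_avg_pool(x).data, 2.5)


def test_classifier_has_no_decoder_parameters():
    cls = ONetClassifier(tiny_config())
    names = [n for n, _ in cls.named_parameters()]
    assert not any(n.startswith(("swin_decoder.", "cnn_decoder.")) for n in names)
    assert count_parameters(cls, "decoder") == 0


def test_classification_invariant_to_segmentation_decoder_weights(rng):
    """Two segmentation models sharing encoder weights but with different
    decoder weights transfer to identical classifiers."""
    cfg = tiny_config()
    nn.manual_seed(10)
    seg_a = ONet(cfg)
    nn.manual_seed(11)
    seg_b = ONet(cfg)
    # align encoders, leave decoders different
    transfer_encoder_weights(seg_a, seg_b)
    nn.manual_seed(12)
    cls_a = ONetClassifier(cfg)
    nn.manual_seed(12)
    cls_b = ONetClassifier(cfg)
    transfer_encoder_weights(seg_a, cls_a)
    transfer_encoder_weights(seg_b, cls_b)
    x = nn.Tensor(rng.normal(size=(1, 1, 64, 64)))
    cls_a.eval(), cls_b.eval()
    np.testing.assert_array_equal(cls_a(x).logits.data, cls_b(x).logits.data)


# -- transfer -----------------------------------------------------------------

def test_transfer_is_bit_exact_and_leaves_head_fresh():
    cfg = tiny_config()
    nn.manual_seed(20)
    seg = ONet(cfg)
    nn.manual_seed(21)
    cls = ONetClassifier(cfg)
    head_before = cls.head.weight.data.copy()
    moved = transfer_encoder_weights(seg, cls)
    assert moved == count_parameters(seg, "encoder")
    seg_params = dict(seg.named_parameters())
    for name, p in cls.named_parameters():
        if name.startswith(("swin_encoder.", "cnn_encoder.")):
            assert np.abs(p.data - seg_params[name].data).max() == 0.0
    np.testing.assert_array_equal(cls.head.weight.data, head_before)


def test_transfer_rejects_mismatched_encoders():
    nn.manual_seed(0)
    seg = ONet(tiny_config())
    cls = ONetClassifier(tiny_config(branches=BranchSettings(
        use_swin_encoder=True, use_cnn_encoder=False,
        use_swin_decoder=True, use_cnn_decoder=True)))
    with pytest.raises(ValueError, match="cnn_encoder"):
        transfer_encoder_weights(seg, cls)


# -- config -------------------------------------------------------------------

def test_config_round_trips_through_dict():
    cfg = tiny_config(num_classes=5)
    cfg2 = ONetConfig.from_dict(cfg.to_dict())
    assert cfg2.to_dict() == cfg.to_dict()
    assert cfg2.stage_dims == [24, 48]
    assert cfg2.stage_strides == [4, 8]


def test_config_rejects_bad_values():
    with pytest.raises(ValueError, match="patch"):
        ONetConfig(swin=dict(patch=2))
    with pytest.raises(ValueError):
        ONetConfig(fusion=dict(encoder_mode="avg"))
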