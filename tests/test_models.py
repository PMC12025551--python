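"""Model builders: shape/range contracts, parameter counting against an
independent closed-form ledger, capacity ordering, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from fractalseg import nn
from fractalseg.models import (
    ARCH_NAMES,
    ArchitectureConfig,
    CalibrationError,
    build_att_fractalspinet,
    build_con_fractalunet,
    build_fractalspinet,
    build_model,
    build_unet,
    calibrate_capacity,
    count_parameters,
    default_config,
)

BUILDERS = {
    "unet": build_unet,
    "fractalspinet": build_fractalspinet,
    "att_fractalspinet": build_att_fractalspinet,
    "con_fractalunet": build_con_fractalunet,
}


def reduced_cfg(arch, **kw):
    base = dict(
        arch_name=arch,
        input_size=(64, 64, 1),
        depth=3,
        stage_widths=(8, 16, 32, 64),
        fractal_order=2,
        dropout_rate=0.5,
        attention=(arch == "att_fractalspinet"),
        seed=0,
    )
    base.update(kw)
    return ArchitectureConfig(**base)


# --------------------------------------------------------------------------
# independent closed-form parameter ledger
# --------------------------------------------------------------------------

def conv_params(cin, cout, k, bn=True, bias=True):
    return k * k * cin * cout + (cout if bias else 0) + (2 * cout if bn else 0)


def fractal_params(cin, w, order, bn=True):
    if order == 1:
        return conv_params(cin, w, 3, bn)
    return (
        conv_params(cin, w, 3, bn)
        + fractal_params(cin, w, order - 1, bn)
        + fractal_params(w, w, order - 1, bn)
    )


def ledger_count(cfg: ArchitectureConfig) -> int:
    """Closed-form per-layer sum, independent of the module introspection."""
    w = cfg.stage_widths
    d = cfg.depth
    bn = cfg.batch_norm
    C = cfg.fractal_order
    fractal_backbone = cfg.arch_name in ("fractalspinet", "att_fractalspinet")

    def stage(cin, width):
        if fractal_backbone:
            return fractal_params(cin, width, C, bn)
        return conv_params(cin, width, 3, bn) + conv_params(width, width, 3, bn)

    total = 0
    cin = cfg.input_size[2]
    for i in range(d):
        total += stage(cin if i == 0 else w[i - 1], w[i])
    total += stage(w[d - 1], w[d])  # bottleneck
    for i in range(d):
        total += conv_params(w[i + 1], w[i], 2, bn=False)  # upsampling conv
        total += stage(2 * w[i], w[i])  # decoder stage
    if cfg.arch_name == "con_fractalunet":
        for i in range(d):
            total += fractal_params(w[i], w[i], C, bn)
    if cfg.arch_name == "att_fractalspinet" or cfg.attention:
        for i in range(d):
            inter = max(w[i] // 2, 1)
            total += conv_params(w[i], inter, 1, bn=False)      # W_x
            total += conv_params(w[i + 1], inter, 1, bn=False)  # W_g
            total += conv_params(inter, 1, 1, bn=False)         # psi
    total += conv_params(w[0], 1, 1, bn=False)  # head
    return total


class TestBuilders:
    @pytest.mark.parametrize("arch", ARCH_NAMES)
    def test_forward_shape_and_sigmoid_range(self, arch):
        model = BUILDERS[arch](reduced_cfg(arch))
        x = np.random.default_rng(0).random((2, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            model.eval()
            out = model.forward(x)
        assert out.shape == (2, 1, 64, 64)
        assert out.data.min() > 0.0 and out.data.max() < 1.0

    @pytest.mark.parametrize("arch", ARCH_NAMES)
    @pytest.mark.parametrize("widths,order", [((8, 16, 32, 64), 2), ((4, 8, 8, 16), 3),
                                              ((6, 12, 24, 24), 1)])
    def test_count_matches_closed_form_ledger(self, arch, widths, order):
        cfg = reduced_cfg(arch, stage_widths=widths, fractal_order=order)
        model = build_model(cfg, init=False)
        assert count_parameters(model) == ledger_count(cfg)

    def test_classic_unet_counting_oracle(self):
        """The canonical width-(64..1024) U-Net without batch norm has the
        textbook total of 31,030,593 trainable parameters (the 2x2
        upsampling convolution has the same count as a 2x2 transposed
        convolution, making the closed-form sum directly comparable)."""
        cfg = ArchitectureConfig(arch_name="unet", batch_norm=False, dropout_rate=0.0)
        assert count_parameters(build_model(cfg, init=False)) == 31_030_593

    def test_capacity_ordering_at_equal_widths(self):
        counts = {
            arch: count_parameters(build_model(reduced_cfg(arch), init=False))
            for arch in ARCH_NAMES
        }
        assert (counts["unet"] < counts["con_fractalunet"]
                < counts["fractalspinet"] < counts["att_fractalspinet"])

    def test_fractal_c1_and_growth(self):
        c1 = count_parameters(build_model(reduced_cfg("fractalspinet", fractal_order=1),
                                          init=False))
        unet = count_parameters(build_model(reduced_cfg("unet"), init=False))
        c2 = count_parameters(build_model(reduced_cfg("fractalspinet"), init=False))
        assert c1 < unet < c2  # one conv unit/block < two < three

    def test_builders_reject_wrong_arch_name(self):
        with pytest.raises(ValueError):
            build_unet(reduced_cfg("fractalspinet"))

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            reduced_cfg("unet", input_size=(60, 64, 1))

    def test_determinism_same_seed_same_params_and_output(self):
        a = build_model(reduced_cfg("unet", seed=5))
        b = build_model(reduced_cfg("unet", seed=5))
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
        x = np.random.default_rng(1).random((1, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            a.eval(), b.eval()
            np.testing.assert_array_equal(a.forward(x).data, b.forward(x).data)

    def test_gradients_flow_to_every_parameter(self):
        from fractalseg.nn import bce_with_logits

        model = build_model(reduced_cfg("att_fractalspinet", dropout_rate=0.0))
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        y = (rng.random((2, 1, 64, 64)) > 0.5).astype(np.float32)
        loss = bce_with_logits(model.forward_logits(x), y)
        loss.backward(np.float32(1.0))
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert missing == []


class TestAttentionIdentityLimit:
    def test_forcing_gates_open_reproduces_fractalspinet(self):
        """With every attention weight map forced to 1, the attention
        variant computes exactly the plain fractal network's output at
        tied weights."""
        cfg_att = reduced_cfg("att_fractalspinet", dropout_rate=0.0)
        cfg_fra = replace(reduced_cfg("fractalspinet", dropout_rate=0.0), attention=False)
        att = build_model(cfg_att)
        fra = build_model(cfg_fra)
        # tie the shared weights (same traversal order for shared modules)
        fra_state = fra.state_dict()
        att_state = att.state_dict()
        for k, v in fra_state.items():
            assert k in att_state
            att_state[k] = v
        att.load_state_dict(att_state)
        for gate in att.gates:  # saturate psi -> alpha == 1
            gate.psi.weight.data[:] = 0.0
            gate.psi.bias.data[:] = 500.0
        x = np.random.default_rng(3).random((1, 1, 64, 64)).astype(np.float32)
        with nn.no_grad():
            att.eval(), fra.eval()
            np.testing.assert_allclose(att.forward(x).data, fra.forward(x).data,
                                       rtol=0, atol=1e-6)


class TestCalibration:
    def test_toy_solvable_target_returns_default_when_met(self):
        cfg = default_config("unet")
        out = calibrate_capacity("unet", 31.4, base_cfg=cfg)
        assert out == cfg  # already rounds to target

    def test_monotone_larger_target_larger_width(self):
        small = calibrate_capacity("unet", 30.0)
        large = calibrate_capacity("unet", 35.0)
        assert small.stage_widths[-1] < large.stage_widths[-1]

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_capacity("unet", 20000.0, w_max=1200)
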