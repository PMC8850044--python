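"""Numeric executor: forward contract and exact reverse-mode gradients."""

import numpy as np
import pytest

from wnetseg import nn
from wnetseg.architecture import build_wnet
from wnetseg.metrics import soft_dice_with_grad

ALL_VARIANTS = ("unet", "original_bridge", "modified_bridge", "compound")


def _loss(graph, params, x, t):
    probs, _ = nn.forward(graph, params, x, training=False)
    vals, _ = soft_dice_with_grad(probs, t, 1.0)
    return 1.0 - vals.mean()


class TestForwardContract:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    @pytest.mark.parametrize("base", [2, 4])
    def test_output_in_unit_interval_same_size(self, variant, base, rng):
        """Random [0,1] input -> finite output in (0,1) of identical spatial
        size for all variant x schedule combinations."""
        graph = build_wnet(variant, base_filters=base, input_size=32)
        params = nn.init_params(graph, rng)
        x = rng.random((2, 1, 32, 32), dtype=np.float32)
        probs, _ = nn.forward(graph, params, x)
        assert probs.shape == (2, 1, 32, 32)
        assert np.isfinite(probs).all()
        assert (probs > 0).all() and (probs < 1).all()

    def test_wrong_input_size_rejected(self, rng):
        graph = build_wnet("unet", base_filters=2, input_size=32)
        params = nn.init_params(graph, rng)
        with pytest.raises(ValueError):
            nn.forward(graph, params, rng.random((1, 1, 16, 16)))

    def test_param_count_matches_graph_annotation(self, rng):
        from wnetseg.architecture import count_parameters

        graph = build_wnet("compound", base_filters=3, input_size=16, levels=3)
        params = nn.init_params(graph, rng)
        assert nn.num_params(params) == count_parameters(graph)

    def test_dropout_only_active_in_training(self, rng):
        graph = build_wnet("unet", base_filters=2, input_size=16, levels=3)
        params = nn.init_params(graph, rng)
        x = rng.random((1, 1, 16, 16), dtype=np.float32)
        a, _ = nn.forward(graph, params, x)
        b, _ = nn.forward(graph, params, x)
        np.testing.assert_array_equal(a, b)  # eval mode is deterministic
        c, _ = nn.forward(graph, params, x, training=True,
                          rng=np.random.default_rng(0))
        d, _ = nn.forward(graph, params, x, training=True,
                          rng=np.random.default_rng(0))
        np.testing.assert_array_equal(c, d)  # seeded dropout reproduces
        assert nn.forward(graph, params, x, training=True,
                          rng=np.random.default_rng(1))[0] is not None

    def test_training_requires_rng(self, rng):
        graph = build_wnet("unet", base_filters=2, input_size=16, levels=3)
        params = nn.init_params(graph, rng)
        with pytest.raises(ValueError):
            nn.forward(graph, params, rng.random((1, 1, 16, 16)), training=True)


class TestGradients:
    @pytest.mark.parametrize("variant", ["unet", "compound"])
    def test_finite_difference_gradcheck(self, variant):
        """Every parameter's analytic gradient matches central differences on
        a tiny two-level model (float64)."""
        graph = build_wnet(variant, base_filters=2, input_size=8, levels=2)
        rng = np.random.default_rng(0)
        params = nn.init_params(graph, rng, dtype=np.float64)
        x = rng.random((2, 1, 8, 8))
        t = (rng.random((2, 1, 8, 8)) > 0.7).astype(float)
        probs, cache = nn.forward(graph, params, x, training=False)
        vals, grad = soft_dice_with_grad(probs, t, 1.0)
        grads = nn.backward(graph, params, cache, -grad / len(x))
        eps = 1e-6
        worst = 0.0
        for nid, pg in params.items():
            for key, arr in pg.items():
                flat = arr.reshape(-1)
                for i in range(flat.size):
                    old = flat[i]
                    flat[i] = old + eps
                    lp = _loss(graph, params, x, t)
                    flat[i] = old - eps
                    lm = _loss(graph, params, x, t)
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = grads[nid][key].reshape(-1)[i]
                    worst = max(worst,
                                abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
        assert worst < 1e-4

    def test_dropout_gradcheck_with_fixed_mask(self):
        """Gradients stay exact through active dropout when the same masks
        are replayed (identical rng stream)."""
        graph = build_wnet("unet", base_filters=2, input_size=8, levels=2,
                           dropout_contracting=0.5, dropout_expanding=0.4)
        rng = np.random.default_rng(0)
        params = nn.init_params(graph, rng, dtype=np.float64)
        x = np.random.default_rng(1).random((1, 1, 8, 8))
        t = (np.random.default_rng(2).random((1, 1, 8, 8)) > 0.7).astype(float)

        def loss_with_dropout():
            probs, cache = nn.forward(
                graph, params, x, training=True, rng=np.random.default_rng(9)
            )
            vals, grad = soft_dice_with_grad(probs, t, 1.0)
            return 1.0 - vals.mean(), cache, -grad

        base, cache, dprobs = loss_with_dropout()
        grads = nn.backward(graph, params, cache, dprobs)
        eps = 1e-6
        nid = next(iter(params))
        arr = params[nid]["W"].reshape(-1)
        for i in range(0, arr.size, 3):
            old = arr[i]
            arr[i] = old + eps
            lp, _, _ = loss_with_dropout()
            arr[i] = old - eps
            lm, _, _ = loss_with_dropout()
            arr[i] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[nid]["W"].reshape(-1)[i]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-10)


class TestAdam:
    def test_zero_lr_is_identity(self, rng):
        graph = build_wnet("unet", base_filters=2, input_size=16, levels=2)
        params = nn.init_params(graph, rng)
        before = {nid: {k: a.copy() for k, a in pg.items()}
                  for nid, pg in params.items()}
        opt = nn.Adam(learning_rate=0.0)
        fake = {nid: {k: np.ones_like(a) for k, a in pg.items()}
                for nid, pg in params.items()}
        opt.step(params, fake)
        for nid, pg in params.items():
            for k, a in pg.items():
                np.testing.assert_array_equal(a, before[nid][k])

    def test_step_magnitude_bounded_by_lr(self, rng):
        graph = build_wnet("unet", base_filters=2, input_size=16, levels=2)
        params = nn.init_params(graph, rng)
        before = {nid: {k: a.copy() for k, a in pg.items()}
                  for nid, pg in params.items()}
        opt = nn.Adam(learning_rate=1e-2)
        fake = {nid: {k: np.full_like(a, 0.5) for k, a in pg.items()}
                for nid, pg in params.items()}
        opt.step(params, fake)
        for nid, pg in params.items():
            for k, a in pg.items():
                delta = np.abs(a - before[nid][k])
                assert delta.max() <= 1e-2 * 1.001

    def test_negative_lr_rejected(self):
        with pytest.raises(ValueError):
            nn.Adam(learning_rate=-1.0)
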