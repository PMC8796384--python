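"""Convolution semantics and backprop correctness of the NumPy layers."""

import numpy as np
import pytest

from cyclicppb.featmap import build_feature_map
from cyclicppb.model import ModelConfig, build_model
from cyclicppb.nn import Conv1dSame, cyclic_conv1d


def wrap_padded_oracle(values, span, kernel):
    """Ordinary valid convolution on the span explicitly pre-padded with its
    own wrap-around columns — the independent reference for CyclicConv."""
    start, n = span
    c_out, c_in, k = kernel.shape
    h = k // 2
    block = values[:, start : start + n]
    padded = np.concatenate([block[:, n - h :], block, block[:, :h]], axis=1)
    out = np.zeros((c_out, values.shape[1]))
    for j in range(n):
        window = padded[:, j : j + k]
        out[:, start + j] = np.einsum("ck,ock->o", window, kernel)
    return out


class TestCyclicConv:
    def test_receptive_fields_wrap_for_three_residues(self):
        # residues A, B, C with k=3: fields are (C,A,B), (A,B,C), (B,C,A)
        a, b, c = 1.0, 10.0, 100.0
        fm = build_feature_map(np.array([[a], [b], [c]]))
        kernel = np.ones((1, 1, 3))
        out = cyclic_conv1d(fm.values, fm.span, kernel)
        s = fm.start
        total = a + b + c
        np.testing.assert_allclose(out[0, s : s + 3], [total, total, total])
        left = np.zeros((1, 1, 3)); left[0, 0, 0] = 1.0
        out_left = cyclic_conv1d(fm.values, fm.span, left)
        np.testing.assert_allclose(out_left[0, s : s + 3], [c, a, b])
        right = np.zeros((1, 1, 3)); right[0, 0, 2] = 1.0
        out_right = cyclic_conv1d(fm.values, fm.span, right)
        np.testing.assert_allclose(out_right[0, s : s + 3], [b, c, a])

    def test_identity_kernel_of_size_one_reproduces_input(self, rng):
        fm = build_feature_map(rng.normal(size=(6, 2)))
        kernel = np.zeros((2, 2, 1))
        kernel[0, 0, 0] = kernel[1, 1, 0] = 1.0
        out = cyclic_conv1d(fm.values, fm.span, kernel)
        np.testing.assert_allclose(out, fm.values)

    @pytest.mark.parametrize(
        "n,k", [(3, 3), (5, 3), (8, 3), (15, 3), (5, 5), (8, 5), (15, 5)]
    )
    def test_matches_wrap_padded_oracle(self, n, k, rng):
        for _ in range(10):
            fm = build_feature_map(rng.normal(size=(n, 2)))
            kernel = rng.normal(size=(3, 2, k))
            got = cyclic_conv1d(fm.values, fm.span, kernel)
            want = wrap_padded_oracle(fm.values, fm.span, kernel)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_kernel_larger_than_ring_raises(self, rng):
        fm = build_feature_map(rng.normal(size=(3, 1)))
        with pytest.raises(ValueError, match="kernel larger than ring"):
            cyclic_conv1d(fm.values, fm.span, np.ones((1, 1, 5)))

    def test_output_outside_span_stays_zero(self, rng):
        fm = build_feature_map(rng.normal(size=(5, 2)))
        out = cyclic_conv1d(fm.values, fm.span, rng.normal(size=(4, 2, 3)))
        outside = np.delete(out, np.arange(fm.start, fm.start + 5), axis=1)
        assert (outside == 0).all()


class TestBackprop:
    def _net_and_input(self, variant, seed=0):
        cfg = ModelConfig(
            variant=variant, n_descriptors=2, conv_channels=(4, 3),
            fc_widths=(5,), epochs=1, seed=seed,
        )
        net = build_model(cfg)
        rng = np.random.default_rng(seed + 10)
        fm = build_feature_map(rng.normal(size=(6, 2)))
        x = fm.values[None]
        spans = np.array([[fm.start, fm.n]], dtype=np.intp)
        # populate batch-norm running statistics
        for _ in range(5):
            net.forward(
                rng.normal(size=(8, 2, 15)),
                np.tile([[4, 6]], (8, 1)).astype(np.intp),
                train=True,
            )
        return net, x, spans

    @pytest.mark.parametrize("variant", ["baseline", "cyclicconv"])
    def test_input_gradient_matches_finite_differences(self, variant):
        net, x, spans = self._net_and_input(variant)
        net.forward(x, spans, train=False)
        grad = net.backward(np.ones((1, 1)))
        h = 1e-5
        for d in range(2):
            for l in range(3, 12, 2):
                xp, xm = x.copy(), x.copy()
                xp[0, d, l] += h
                xm[0, d, l] -= h
                num = (
                    net.forward(xp, spans, train=False)
                    - net.forward(xm, spans, train=False)
                )[0, 0] / (2 * h)
                assert grad[0, d, l] == pytest.approx(num, abs=1e-6, rel=1e-4)

    def test_parameter_gradients_match_finite_differences(self):
        net, x, spans = self._net_and_input("cyclicconv", seed=2)
        rng = np.random.default_rng(0)
        xb = rng.normal(size=(4, 2, 15))
        sb = np.tile([[4, 6]], (4, 1)).astype(np.intp)
        yb = rng.normal(size=4)

        def loss():
            p = net.forward(xb, sb, train=True)[:, 0]
            return float(np.mean((p - yb) ** 2))

        net.zero_grad()
        p = net.forward(xb, sb, train=True)[:, 0]
        net.backward((2 * (p - yb) / 4)[:, None])
        h = 1e-5
        for P, G in zip(net.parameters(), net.gradients()):
            flat, gflat = P.ravel(), G.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                lp = loss()
                flat[i] = orig - h
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * h)
                assert gflat[i] == pytest.approx(num, abs=1e-5, rel=1e-3)
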