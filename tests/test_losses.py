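"""Oracle and property tests of the metric-learning objectives.

Expected values on the worked feature triplets are hand-computed from the
squared-Euclidean definitions.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafshot.losses import (
    HardNegativeGenerator,
    MetricParams,
    daml_metric_loss,
    daml_total,
    generator_loss,
    triplet_loss,
)

A = np.array([[0.0, 0.0]])
P = np.array([[1.0, 0.0]])
N = np.array([[3.0, 0.0]])
G = np.array([[2.0, 0.0]])


class TestTripletLoss:
    @pytest.mark.parametrize(
        "a,p,n,m,expected",
        [
            ([0.0, 0.0], [0.0, 0.0], [2.0, 0.0], 1.0, 0.0),   # margin satisfied
            ([0.0, 0.0], [2.0, 0.0], [1.0, 0.0], 1.0, 4.0),   # 4 - 1 + 1
            ([1.0, 1.0], [1.0, 1.0], [1.0, 1.0], 1e-9, 1e-9),  # n == p boundary
        ],
    )
    def test_worked_examples(self, a, p, n, m, expected):
        val = triplet_loss(np.array([a]), np.array([p]), np.array([n]), m)
        assert val == pytest.approx(expected, abs=1e-9)

    def test_batch_mean(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0]])
        p = np.array([[2.0, 0.0], [0.0, 0.0]])
        n = np.array([[1.0, 0.0], [5.0, 0.0]])
        assert triplet_loss(a, p, n, 1.0) == pytest.approx(2.0, abs=1e-9)  # (4+0)/2

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_and_zero_iff_margin_met(self, seed):
        rng = np.random.default_rng(seed)
        a, p, n = rng.normal(size=(3, 4, 3))
        m = 0.5
        val = triplet_loss(a, p, n, m)
        assert val >= 0.0
        d_ap = ((a - p) ** 2).sum(1)
        d_an = ((a - n) ** 2).sum(1)
        if (d_an >= d_ap + m).all():
            assert val == 0.0
        else:
            assert val > 0.0

    def test_gradient_step_improves_triplet_geometry(self):
        """One gradient step on an active triplet shrinks
        D(a,p) - D(a,n)."""
        a = np.array([[0.0, 0.0]])
        p = np.array([[2.0, 0.0]])
        n = np.array([[1.0, 1.0]])
        loss, (ga, gp, gn) = triplet_loss(a, p, n, 1.0, with_grads=True)
        assert loss > 0
        lr = 0.05
        a2, p2, n2 = a - lr * ga, p - lr * gp, n - lr * gn
        gap = lambda x, y, z: (
            np.linalg.norm(x - y) - np.linalg.norm(x - z)
        )
        assert gap(a2, p2, n2) < gap(a, p, n)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            triplet_loss(np.zeros((1, 2)), np.zeros((1, 3)), np.zeros((1, 2)))


class TestGeneratorLoss:
    def test_all_terms_vanish_on_zero_features(self):
        z = np.zeros((1, 2))
        assert generator_loss(z, z, z, z, MetricParams()) == 0.0

    def test_worked_decomposition(self):
        # J_hard = |2-0|^2 = 4, J_reg = |2-3|^2 = 1,
        # J_adv = max(0, 4 - 1 - 0) = 3; total = 8 with unit weights
        params = MetricParams(m=1.0, alpha=0.0, lam=1.0, lam1=1.0, lam2=1.0)
        assert generator_loss(A, P, N, G, params) == pytest.approx(8.0, abs=1e-9)

    def test_term_isolation(self):
        params = MetricParams(lam1=0.0, lam2=0.0)
        val = generator_loss(A, P, N, G, params)
        assert val == pytest.approx(4.0, abs=1e-9)  # ||g - a||^2 only

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            MetricParams(lam1=-0.1)


class TestDamlLosses:
    def test_far_synthetic_negative_gives_zero(self):
        g_far = np.array([[10.0, 0.0]])
        assert daml_metric_loss(A, P, g_far, 1.0) == 0.0

    def test_worked_metric_value(self):
        # a=(0,0), p=(1,0), g=(1,0): max(0, 1 - 1 + 1) = 1
        g = np.array([[1.0, 0.0]])
        assert daml_metric_loss(A, P, g, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_reduces_to_triplet_when_generator_is_identity(self):
        rng = np.random.default_rng(0)
        a, p, n = rng.normal(size=(3, 5, 4))
        assert daml_metric_loss(a, p, n, 1.0) == pytest.approx(
            triplet_loss(a, p, n, 1.0), abs=1e-12
        )

    def test_total_composition(self):
        # generator loss 8 (worked example) + lam * max(0, 1 - 4 + 1) = 8
        params = MetricParams(m=1.0, alpha=0.0, lam=1.0, lam1=1.0, lam2=1.0)
        assert daml_total(A, P, N, G, params) == pytest.approx(8.0, abs=1e-9)

    def test_lambda_zero_equals_generator_loss(self):
        params = MetricParams(alpha=0.0, lam=0.0)
        assert daml_total(A, P, N, G, params) == pytest.approx(
            generator_loss(A, P, N, G, params), abs=1e-12
        )

    def test_zero_features_leave_only_metric_hinge(self):
        z = np.zeros((1, 3))
        params = MetricParams(m=1.0, alpha=0.5)
        assert daml_total(z, z, z, z, params) == pytest.approx(1.0, abs=1e-12)


class TestHardNegativeGenerator:
    def test_output_dimension_matches_feature_dim(self):
        gen = HardNegativeGenerator(dim=6, seed=0)
        rng = np.random.default_rng(1)
        a, p, n = rng.normal(size=(3, 4, 6))
        out = gen.generate(a, p, n)
        assert out.shape == (4, 6)

    def test_generator_step_reduces_its_objective(self):
        """A few gradient steps on a fixed triplet batch reduce the
        generator objective — the backward pass points downhill."""
        from leafshot import nn

        rng = np.random.default_rng(2)
        a, p, n = rng.normal(size=(3, 8, 6))
        gen = HardNegativeGenerator(dim=6, seed=3)
        params = MetricParams(alpha=0.1)
        opt = nn.Adam(gen.parameters(), lr=1e-2)
        first = None
        for _ in range(30):
            out = gen.generate(a, p, n)
            loss, dgen = generator_loss(a, p, n, out, params, with_grads=True)
            if first is None:
                first = loss
            gen.zero_grad()
            gen.backward(dgen)
            opt.step()
        final = generator_loss(a, p, n, gen.generate(a, p, n), params)
        assert final < first
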