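"""Network machinery and the adversarial imputer's contracts."""

import math

import numpy as np
import pytest

from gainimpute import (
    GainConfig,
    discriminator_loss,
    generator_loss,
    impute,
    multiple_impute,
    sample_hint,
    train,
)
from gainimpute._nn import MLP
from gainimpute.encoding import MixedEncoder


class TestGradients:
    """Analytic backprop vs central finite differences."""

    @pytest.mark.parametrize("batch_norm", [False, True])
    def test_mlp_param_gradients(self, batch_norm):
        rng = np.random.default_rng(0)
        net = MLP(4, 3, hidden_layers=1, neurons=5, activation="tanh",
                  rng=rng, batch_norm=batch_norm)
        x = rng.standard_normal((6, 4))
        R = rng.standard_normal((6, 3))  # loss = sum(y * R)

        def loss() -> float:
            return float((net.forward(x, train=True) * R).sum())

        loss()
        net.zero_grad()
        net.backward(R)
        eps = 1e-6
        for p in net.params:
            flat = p.data.ravel()
            grad = p.grad.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_mlp_input_gradient(self):
        rng = np.random.default_rng(1)
        net = MLP(3, 2, hidden_layers=1, neurons=4, activation="tanh", rng=rng)
        x = rng.standard_normal((5, 3))
        R = rng.standard_normal((5, 2))
        net.forward(x, train=True)
        net.zero_grad()
        gx = net.backward(R)
        eps = 1e-6
        for i in (0, 2):
            for j in range(3):
                x2 = x.copy()
                x2[i, j] += eps
                up = float((net.forward(x2, train=True) * R).sum())
                x2[i, j] -= 2 * eps
                down = float((net.forward(x2, train=True) * R).sum())
                fd = (up - down) / (2 * eps)
                assert gx[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestHint:
    def _blocks(self, widths):
        blocks, pos = [], 0
        for k, w in enumerate(widths):
            blocks.append((f"v{k}", pos, pos + w))
            pos += w
        return blocks

    def test_full_reveal(self):
        rng = np.random.default_rng(0)
        M = (rng.random((20, 4)) > 0.5).astype(float)
        H = sample_hint(M, 1.0, rng, self._blocks([1, 1, 2]))
        np.testing.assert_array_equal(H, M)

    def test_no_reveal(self):
        rng = np.random.default_rng(0)
        M = (rng.random((20, 4)) > 0.5).astype(float)
        H = sample_hint(M, 0.0, rng, self._blocks([1, 1, 2]))
        np.testing.assert_array_equal(H, np.full_like(M, 0.5))

    def test_reveal_fraction_monte_carlo(self):
        rng = np.random.default_rng(5)
        M = np.ones((50_000, 2))
        H = sample_hint(M, 0.9, rng, self._blocks([1, 1]))
        revealed = (H == 1.0).mean()
        assert revealed == pytest.approx(0.9, abs=0.01)

    def test_replicated_across_block(self):
        rng = np.random.default_rng(2)
        M = np.ones((100, 3))
        M[:, 1:] = 0.0  # one variable of width 2, missing
        H = sample_hint(M, 0.5, rng, self._blocks([1, 2]))
        np.testing.assert_array_equal(H[:, 1], H[:, 2])
        assert set(np.unique(H[:, 1])) <= {0.0, 0.5}


class TestLossFormulas:
    def test_uninformative_discriminator_gives_ln2(self):
        rng = np.random.default_rng(0)
        M = (rng.random((7, 5)) > 0.4).astype(float)
        p = np.full((7, 5), 0.5)
        assert discriminator_loss(p, M) == pytest.approx(math.log(2), abs=1e-10)

    def test_perfect_discriminator_near_zero(self):
        rng = np.random.default_rng(1)
        M = (rng.random((7, 5)) > 0.4).astype(float)
        assert discriminator_loss(M, M) == pytest.approx(0.0, abs=1e-7)

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            M = (rng.random((3, 2)) > 0.5).astype(float)
            p = rng.uniform(0.01, 0.99, (3, 2))
            expected = 0.0
            for i in range(3):
                for j in range(2):
                    expected -= M[i, j] * math.log(p[i, j]) + (
                        1 - M[i, j]
                    ) * math.log(1 - p[i, j])
            expected /= 6
            assert discriminator_loss(p, M) == pytest.approx(expected, abs=1e-10)

    def _random_instance(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        cont_cols = np.array([0, 1])
        cat_blocks = [(2, 4), (4, 7)]
        D = 7
        M = np.zeros((n, D))
        mvar = (rng.random((n, 4)) > 0.4).astype(float)
        M[:, 0] = mvar[:, 0]
        M[:, 1] = mvar[:, 1]
        M[:, 2:4] = mvar[:, 2:3]
        M[:, 4:7] = mvar[:, 3:4]
        p = rng.uniform(0.05, 0.95, (n, D))
        g = rng.uniform(0.01, 0.99, (n, D))
        for s, e in cat_blocks:
            g[:, s:e] /= g[:, s:e].sum(axis=1, keepdims=True)
        x = rng.uniform(0, 1, (n, D))
        for s, e in cat_blocks:
            x[:, s:e] = 0.0
            x[np.arange(n), s + rng.integers(0, e - s, n)] = 1.0
        return p, M, g, x, cont_cols, cat_blocks

    def test_generator_loss_matches_oracle(self):
        for seed in range(10):
            p, M, g, x, cont_cols, cat_blocks = self._random_instance(seed)
            adv = 0.0
            n_miss = 0
            for i in range(p.shape[0]):
                for j in range(p.shape[1]):
                    if M[i, j] == 0:
                        adv -= math.log(p[i, j])
                        n_miss += 1
            adv = adv / n_miss if n_miss else 0.0
            mse_sum, mse_n = 0.0, 0
            for i in range(p.shape[0]):
                for j in cont_cols:
                    if M[i, j] == 1:
                        mse_sum += (x[i, j] - g[i, j]) ** 2
                        mse_n += 1
            ce_sum, ce_n = 0.0, 0
            for i in range(p.shape[0]):
                for s, e in cat_blocks:
                    if M[i, s] == 1:
                        ce_sum -= sum(
                            x[i, c] * math.log(g[i, c]) for c in range(s, e)
                        )
                        ce_n += 1
            alpha, beta = 3.0, 7.0
            expected = (
                adv
                + alpha * (mse_sum / mse_n if mse_n else 0.0)
                + beta * (ce_sum / ce_n if ce_n else 0.0)
            )
            got = generator_loss(p, M, g, x, cont_cols, cat_blocks, alpha, beta)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_full_mask_reduces_to_reconstruction(self):
        p, M, g, x, cont_cols, cat_blocks = self._random_instance(3)
        M = np.ones_like(M)
        got = generator_loss(p, M, g, x, cont_cols, cat_blocks, 2.0, 5.0)
        mse = ((x[:, cont_cols] - g[:, cont_cols]) ** 2).mean()
        ce = 0.0
        for s, e in cat_blocks:
            ce += (-(x[:, s:e] * np.log(g[:, s:e])).sum(axis=1)).sum()
        ce /= x.shape[0] * len(cat_blocks)
        assert got == pytest.approx(2.0 * mse + 5.0 * ce, abs=1e-10)

    def test_alpha_beta_zero_leaves_adversarial_only(self):
        p, M, g, x, cont_cols, cat_blocks = self._random_instance(4)
        got = generator_loss(p, M, g, x, cont_cols, cat_blocks, 0.0, 0.0)
        miss = M == 0
        expected = float(-np.log(p[miss]).mean())
        assert got == pytest.approx(expected, abs=1e-10)

    def test_perfect_reconstruction_zeroes_those_terms(self):
        p, M, g, x, cont_cols, cat_blocks = self._random_instance(5)
        adv_only = generator_loss(p, M, g, x, cont_cols, cat_blocks, 0.0, 0.0)
        g2 = x.astype(float).copy()
        g2[g2 == 0] = 1e-300  # log(1)=0 terms only where x_c = 1
        got = generator_loss(p, M, g2, x, cont_cols, [], 9.0, 0.0)
        # continuous term vanishes when generated == target
        assert got == pytest.approx(
            generator_loss(p, M, g2, x, cont_cols, [], 0.0, 0.0), abs=1e-12
        )
        assert adv_only >= 0


class TestTraining:
    def test_zero_iterations_gives_empty_trace(self, demo_incomplete):
        model, trace = train(demo_incomplete, GainConfig(n_iterations=0, seed=0))
        assert len(trace) == 0
        assert model.generator is not None

    def test_bit_identical_under_fixed_seed(self, demo_incomplete):
        cfg = GainConfig(n_iterations=100, seed=12)
        m1, t1 = train(demo_incomplete, cfg)
        m2, t2 = train(demo_incomplete, cfg)
        for p1, p2 in zip(m1.generator.params, m2.generator.params):
            np.testing.assert_array_equal(p1.data, p2.data)
        np.testing.assert_array_equal(t1.g_loss, t2.g_loss)
        assert impute(m1, demo_incomplete).equals(impute(m2, demo_incomplete))

    def test_trace_length_equals_iterations(self, demo_incomplete):
        _, trace = train(demo_incomplete, GainConfig(n_iterations=37, seed=0))
        assert len(trace) == 37
        assert np.isfinite(trace.d_loss).all() and np.isfinite(trace.g_loss).all()

    def test_full_hint_lets_discriminator_win(self, demo_incomplete):
        """With p_hint=1 the hint reveals the mask, so the discriminator
        loss falls well below the uninformative ln 2 level."""
        cfg = GainConfig(
            n_iterations=800, p_hint=1.0, optimizer="adam",
            learning_rate=0.005, seed=1,
        )
        _, trace = train(demo_incomplete, cfg)
        assert trace.d_loss[-50:].mean() < 0.35

    @pytest.mark.parametrize("optimizer", ["sgd", "momentum", "adam"])
    def test_all_optimizers_run(self, demo_incomplete, optimizer):
        lr = 0.01 if optimizer != "adam" else 0.001
        cfg = GainConfig(
            n_iterations=30, optimizer=optimizer, learning_rate=lr, seed=0
        )
        _, trace = train(demo_incomplete, cfg)
        assert np.isfinite(trace.g_loss).all()

    def test_softmax_blocks_sum_to_one(self, demo_incomplete):
        model, _ = train(demo_incomplete, GainConfig(n_iterations=50, seed=0))
        enc = model.encoder
        X, M = enc.encode(demo_incomplete)
        from gainimpute.gain import _head_forward

        X_fill = X * M + (1 - M) * model.fill_means
        y = _head_forward(
            model.generator.forward(np.hstack([X_fill, M]), train=False),
            model.cont_cols,
            model.cat_blocks,
        )
        for s, e in model.cat_blocks:
            np.testing.assert_allclose(y[:, s:e].sum(axis=1), 1.0, atol=1e-6)


@pytest.fixture(scope="module")
def model(demo_incomplete):
    trained, _ = train(demo_incomplete, GainConfig(n_iterations=300, seed=3))
    return trained


class TestImpute:
    def test_observed_cells_preserved_exactly(self, model, demo_incomplete):
        out = impute(model, demo_incomplete)
        for j, v in enumerate(demo_incomplete.schema):
            obs = demo_incomplete.mask[:, j]
            a = out[v.name].to_numpy()[obs]
            b = demo_incomplete.values[v.name].to_numpy()[obs]
            np.testing.assert_array_equal(a, b)

    def test_complete_table_passes_through(self, demo_table):
        model, _ = train(demo_table, GainConfig(n_iterations=20, seed=0))
        out = impute(model, demo_table)
        for v in demo_table.schema:
            np.testing.assert_array_equal(
                out[v.name].to_numpy(), demo_table.values[v.name].to_numpy()
            )

    def test_imputed_categories_legal(self, model, demo_incomplete):
        out = impute(model, demo_incomplete)
        for v in demo_incomplete.schema:
            if v.is_categorical:
                assert set(out[v.name]) <= set(v.categories)

    def test_imputed_continuous_within_observed_range(self, model, demo_incomplete):
        enc = MixedEncoder(demo_incomplete.schema).fit(demo_incomplete)
        out = impute(model, demo_incomplete)
        for v in demo_incomplete.schema:
            if v.is_continuous:
                vals = out[v.name].to_numpy(float)
                assert vals.min() >= enc.mins_[v.name] - 1e-12
                assert vals.max() <= enc.maxs_[v.name] + 1e-12


class TestMultipleImpute:
    def test_m_one_matches_derived_single_run(self, demo_incomplete):
        from dataclasses import replace

        cfg = GainConfig(n_iterations=50, seed=21)
        outs = multiple_impute(demo_incomplete, cfg, m=1)
        seed = int(np.random.SeedSequence(21).generate_state(1)[0] % 2**31)
        model, _ = train(demo_incomplete, replace(cfg, seed=seed))
        assert outs[0].equals(impute(model, demo_incomplete))

    def test_repeats_differ_somewhere(self, demo_incomplete):
        cfg = GainConfig(n_iterations=50, seed=2)
        a, b = multiple_impute(demo_incomplete, cfg, m=2)
        assert not a.equals(b)

    def test_traces_returned_on_request(self, demo_incomplete):
        cfg = GainConfig(n_iterations=25, seed=2)
        imps, traces = multiple_impute(demo_incomplete, cfg, m=2,
                                       return_traces=True)
        assert len(imps) == 2 and len(traces) == 2
        assert all(len(t) == 25 for t in traces)
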