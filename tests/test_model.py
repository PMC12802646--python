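import warnings

import numpy as np
import pytest
from scipy import stats

from snscore.model import (FittedModel, ModelConfig, build_model,
                           count_parameters, denoise_counts, forward,
                           load_checkpoint, loss, objective_and_grads,
                           pearson, save_checkpoint, train, zinb_nll,
                           ZINBOutput)


def enumerate_layer_shapes(g, enc=32, bot=2, dec=32):
    """Independent parameter count from an explicit layer-shape list."""
    shapes = [
        (g, enc), (enc,),          # encoder
        (enc, bot), (bot,),        # bottleneck
        (bot, dec), (dec,),        # decoder
        (dec, g), (g,),            # dropout head
        (dec, g), (g,),            # mean head
        (dec, g), (g,),            # dispersion head
    ]
    return sum(int(np.prod(s)) for s in shapes)


class TestConstruction:
    @pytest.mark.parametrize("g", [2, 10, 39, 100])
    def test_parameter_count_matches_shape_enumeration(self, g):
        assert count_parameters(g) == enumerate_layer_shapes(g)
        assert build_model(g).n_parameters == enumerate_layer_shapes(g)

    def test_published_panel_size(self):
        assert count_parameters(39) == 5303
        assert count_parameters(10) == 1504

    def test_seeded_init_reproducible(self):
        a = build_model(12, ModelConfig(seed=42))
        b = build_model(12, ModelConfig(seed=42))
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            build_model(1)


class TestForward:
    def test_zero_weights_give_neutral_outputs(self):
        m = build_model(4)
        for k in m.weights:
            m.weights[k] = np.zeros_like(m.weights[k])
        h, out = forward(m, np.random.default_rng(0).normal(size=(6, 4)))
        assert h.shape == (6, 2)
        assert np.allclose(out.pi, 0.5)
        assert np.allclose(out.mu_prime, 1.0)
        assert np.allclose(out.theta, 1.0)

    def test_size_factor_scales_mu_only(self, rng):
        m = build_model(5, ModelConfig(seed=3))
        xp = rng.normal(size=(8, 5))
        sf = np.ones(8)
        sf2 = sf.copy()
        sf2[2] = 2.0
        h1, o1 = forward(m, xp, sf)
        h2, o2 = forward(m, xp, sf2)
        assert np.allclose(o2.mu[2], 2.0 * o1.mu[2])
        assert np.allclose(o2.pi, o1.pi)
        assert np.allclose(o2.theta, o1.theta)
        assert np.allclose(h1, h2)

    def test_shape_mismatch(self, rng):
        m = build_model(5)
        with pytest.raises(ValueError):
            forward(m, rng.normal(size=(4, 7)))


def oracle_zinb_nll(x, pi, mu, theta):
    """Independent formulation via scipy's NB pmf on the (n, p) scale."""
    p = theta / (theta + mu)
    nb = stats.nbinom.logpmf(x, theta, p)
    if x == 0:
        return -np.logaddexp(np.log(pi) if pi > 0 else -np.inf,
                             np.log1p(-pi) + nb)
    return -(np.log1p(-pi) + nb)


class TestZINBLikelihood:
    def test_point_mass_at_zero(self):
        assert zinb_nll(0, 1.0, 5.0, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_example(self):
        # x=0, pi=0.5, mu=theta=1: NB(0) = 0.5, density 0.75
        assert zinb_nll(0, 0.5, 1.0, 1.0) == pytest.approx(
            -np.log(0.75), abs=1e-10)

    def test_pi_zero_reduces_to_nb(self):
        x = np.arange(0, 15)
        ours = zinb_nll(x, 0.0, 3.0, 1.7)
        ref = -stats.nbinom.logpmf(x, 1.7, 1.7 / (1.7 + 3.0))
        assert np.allclose(ours, ref, atol=1e-10)

    def test_grid_against_independent_oracle(self):
        for x in range(0, 21, 4):
            for pi in (0.0, 0.2, 0.7, 0.99):
                for mu in (0.1, 1.0, 10.0, 100.0):
                    for theta in (0.1, 1.0, 10.0):
                        ours = float(zinb_nll(x, pi, mu, theta))
                        ref = oracle_zinb_nll(x, pi, mu, theta)
                        assert ours == pytest.approx(ref, abs=1e-8)

    def test_poisson_limit(self):
        x = np.arange(0, 20)
        ours = zinb_nll(x, 0.0, 4.0, 1e6)
        poisson = -stats.poisson.logpmf(x, 4.0)
        assert np.allclose(ours, poisson, atol=1e-3)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            zinb_nll(1, -0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            zinb_nll(1, 0.5, -1.0, 1.0)
        with pytest.raises(ValueError):
            zinb_nll(1, 0.5, 1.0, 0.0)


class TestLoss:
    def _toy(self, rng, n=2, g=2):
        x = rng.poisson(3, size=(n, g)).astype(float)
        out = ZINBOutput(
            pi=rng.uniform(0.1, 0.9, (n, g)),
            mu_prime=rng.uniform(0.5, 5.0, (n, g)),
            theta=rng.uniform(0.5, 5.0, (n, g)),
            mu=rng.uniform(0.5, 5.0, (n, g)),
        )
        return x, out

    def test_lambda_zero_is_pure_nll(self, rng):
        x, out = self._toy(rng)
        h = rng.normal(size=(2, 2))
        total, nll, pen = loss(x, out, h, lambda_penalty=0.0)
        assert pen == 0.0
        assert total == nll

    def test_collinear_bottleneck_penalty_is_lambda(self, rng):
        x, out = self._toy(rng, n=5)
        h1 = rng.normal(size=5)
        h = np.column_stack([h1, 2.0 * h1])
        _, _, pen = loss(x, out, h, lambda_penalty=3.0)
        assert pen == pytest.approx(3.0)

    def test_matches_brute_force_sum(self, rng):
        x, out = self._toy(rng)
        h = rng.normal(size=(2, 2))
        total, nll, pen = loss(x, out, h, lambda_penalty=1.0)
        brute = 0.0
        for i in range(2):
            for j in range(2):
                brute += oracle_zinb_nll(
                    int(x[i, j]), out.pi[i, j], out.mu[i, j], out.theta[i, j])
        brute /= 4.0
        rho = np.corrcoef(h[:, 0], h[:, 1])[0, 1]
        assert nll == pytest.approx(brute, abs=1e-10)
        assert total == pytest.approx(brute + rho ** 2, abs=1e-10)

    def test_constant_unit_warns_zero_penalty(self, rng):
        x, out = self._toy(rng, n=4)
        h = np.column_stack([np.ones(4), rng.normal(size=4)])
        with pytest.warns(UserWarning):
            _, _, pen = loss(x, out, h, 1.0)
        assert pen == 0.0


class TestGradients:
    def test_analytic_matches_finite_difference(self, rng):
        n, g = 3, 4
        x = rng.poisson(3.0, size=(n, g)).astype(float)
        xp = rng.normal(size=(n, g))
        sf = np.exp(rng.normal(0, 0.2, n))
        m = build_model(g, ModelConfig(encoder_width=5, decoder_width=5,
                                       seed=9))
        _, _, _, grads = objective_and_grads(m, x, xp, sf, 1.0)
        eps = 1e-6
        for k, W in m.weights.items():
            flat_idx = rng.choice(W.size, size=min(4, W.size), replace=False)
            for fi in flat_idx:
                ij = np.unravel_index(fi, W.shape)
                orig = W[ij]
                W[ij] = orig + eps
                up = objective_and_grads(m, x, xp, sf, 1.0)[0]
                W[ij] = orig - eps
                down = objective_and_grads(m, x, xp, sf, 1.0)[0]
                W[ij] = orig
                fd = (up - down) / (2 * eps)
                assert grads[k][ij] == pytest.approx(fd, abs=1e-4, rel=1e-4)


class TestTraining:
    def _data(self, n=60, g=8, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.poisson(4.0, size=(n, g)).astype(float)
        xp = (x - x.mean(0)) / np.maximum(x.std(0), 1e-6)
        return x, xp

    def test_deterministic_given_seed(self):
        x, xp = self._data()
        cfg = ModelConfig(epochs=30, seed=5)
        a = train(x, xp, config=cfg)
        b = train(x, xp, config=cfg)
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])
        assert np.array_equal(a.h_pre, b.h_pre)

    def test_best_validation_loss_non_increasing(self):
        x, xp = self._data(seed=3)
        fitted = train(x, xp, config=ModelConfig(epochs=40, seed=1))
        running_best = np.minimum.accumulate(fitted.history["val_loss"])
        assert (np.diff(running_best) <= 0).all()

    def test_too_few_cells_rejected(self):
        x, xp = self._data(n=10)
        with pytest.raises(ValueError):
            train(x, xp)

    def test_history_bounded_by_epochs(self):
        x, xp = self._data(seed=2)
        fitted = train(x, xp, config=ModelConfig(epochs=25, seed=0))
        assert len(fitted.history["val_loss"]) <= 25

    def test_learning_rate_halves_on_stagnation(self):
        x, xp = self._data(seed=4)
        fitted = train(x, xp, config=ModelConfig(epochs=300, seed=0))
        lrs = np.array(fitted.history["lr"])
        # once training runs long enough to stop early, the LR schedule
        # must have stepped down by factors of two only
        assert set(np.round(lrs[0] / np.unique(lrs), 6)) <= {1, 2, 4, 8, 16}


class TestDenoiser:
    def test_mean_recovery(self, rng):
        means = np.array([5.0, 20.0, 50.0])
        counts = rng.poisson(np.tile(means, (250, 1)))
        den = denoise_counts(counts, seed=1, epochs=120)
        rel = np.abs(den.mean(0) - counts.mean(0)) / counts.mean(0)
        assert rel.max() < 0.10
        assert (den >= 0).all()


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        x = rng.poisson(4.0, size=(40, 6)).astype(float)
        xp = (x - x.mean(0)) / np.maximum(x.std(0), 1e-6)
        fitted = train(x, xp, config=ModelConfig(epochs=15, seed=2),
                       panel_genes=np.array([f"g{j}" for j in range(6)]))
        path = tmp_path / "model.npz"
        save_checkpoint(fitted, path)
        back = load_checkpoint(path)
        for k in fitted.weights:
            assert np.array_equal(fitted.weights[k], back.weights[k])
        assert back.config == fitted.config
        assert list(back.panel_genes) == [f"g{j}" for j in range(6)]
        assert np.array_equal(back.h_pre, fitted.h_pre)
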