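"""Mixture-model maximum likelihood, grouped weights and the bootstrap."""

import itertools

import numpy as np
import pytest

from mtmisalign.genome import Breakpoint, BreakpointDataset, MtGenome
from mtmisalign.mixture import (
    bootstrap_sd,
    component_matrix,
    fit_mixture,
    group_weights,
    resample_dataset,
)
from mtmisalign.propensity import LengthGrid, PropensityEngine

from test_propensity import sterile_genome_with_repeat


def synthetic_components(rng, n, theta_true, n_sites=60, sharp=3.0):
    """Rows drawn from a K-component mixture over a finite site set.

    Builds K site-likelihood columns with equal totals (so the fitted
    unnormalized-likelihood mixture is well-specified), then samples sites
    from the joint theta_l f_l(x).
    """
    K = theta_true.size
    F = rng.gamma(1.0, 1.0, size=(n_sites, K)) ** sharp
    F /= F.sum(axis=0, keepdims=True)  # equal component masses
    joint = F * theta_true
    px = joint.sum(axis=1)
    xs = rng.choice(n_sites, size=n, p=px / px.sum())
    return F[xs]


class TestFitMixture:
    def test_k1_trivial(self):
        grid = LengthGrid((0,))
        fit = fit_mixture(np.full((5, 1), 0.0025), grid=grid)
        assert fit.theta.tolist() == [1.0]

    def test_flat_likelihood_returns_uniform(self):
        grid = LengthGrid((0, 5, 10))
        P = np.full((20, 3), 1.0 / 400)
        fit = fit_mixture(P, grid=grid)
        assert np.allclose(fit.theta, 1.0 / 3)
        assert fit.non_identifiable

    def test_matches_dense_grid_search_oracle(self):
        """EM log-likelihood matches a 0.01-step simplex grid search (K=3)."""
        rng = np.random.default_rng(7)
        theta_true = np.array([0.2, 0.5, 0.3])
        P = synthetic_components(rng, n=50, theta_true=theta_true)
        grid = LengthGrid((0, 5, 20))
        fit = fit_mixture(P, grid=grid)

        best = -np.inf
        for i, j in itertools.product(range(101), repeat=2):
            t0, t1 = i / 100, j / 100
            if t0 + t1 > 1.0 + 1e-12:
                continue
            theta = np.array([t0, t1, 1.0 - t0 - t1])
            ll = float(np.log(P @ theta).sum())
            best = max(best, ll)
        assert fit.loglik >= best - 1e-3

    def test_simplex_feasibility_and_convergence(self):
        rng = np.random.default_rng(11)
        P = rng.uniform(0.001, 0.1, size=(40, 5))
        fit = fit_mixture(P, grid=LengthGrid((0, 5, 10, 15, 20)))
        assert fit.converged
        assert np.all(fit.theta >= 0)
        assert fit.theta.sum() == pytest.approx(1.0, abs=1e-10)

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(13)
        P = rng.uniform(0.001, 0.1, size=(30, 4))
        grid = LengthGrid((0, 5, 10, 20))
        base = fit_mixture(P, grid=grid)
        P2 = P.copy()
        P2[::3] *= 37.5  # scaling whole rows cannot change the optimum
        again = fit_mixture(P2, grid=grid)
        assert np.allclose(base.theta, again.theta, atol=1e-6)

    def test_multistart_agrees_with_uniform_start(self):
        rng = np.random.default_rng(17)
        P = synthetic_components(rng, 100, np.array([0.3, 0.3, 0.4]))
        grid = LengthGrid((0, 10, 50))
        single = fit_mixture(P, grid=grid)
        multi = fit_mixture(P, grid=grid, n_starts=5, seed=0)
        assert multi.loglik == pytest.approx(single.loglik, abs=1e-6)

    def test_parameter_recovery_synthetic(self):
        """n=2000 rows from a known well-specified mixture: recovery <= 0.05."""
        rng = np.random.default_rng(23)
        theta_true = np.array([0.5, 0.3, 0.2])
        P = synthetic_components(rng, 2000, theta_true)
        fit = fit_mixture(P, grid=LengthGrid((0, 5, 20)))
        assert np.max(np.abs(fit.theta - theta_true)) <= 0.05

    def test_estimator_sd_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(29)
        theta_true = np.array([0.5, 0.3, 0.2])
        grid = LengthGrid((0, 5, 20))
        sds = {}
        for n in (50, 800):
            est = [
                fit_mixture(
                    synthetic_components(rng, n, theta_true), grid=grid
                ).theta[0]
                for _ in range(40)
            ]
            sds[n] = np.std(est)
        ratio = sds[50] / sds[800]
        assert 2.0 < ratio < 8.0  # expect ~ sqrt(800/50) = 4

    def test_rejects_bad_input(self):
        grid = LengthGrid((0, 5))
        with pytest.raises(ValueError):
            fit_mixture(np.array([[0.1, np.nan]]), grid=grid)
        with pytest.raises(ValueError):
            fit_mixture(np.ones((3, 4)), grid=grid)


class TestGroupWeights:
    def test_uniform_theta(self):
        grid = LengthGrid()
        g = group_weights(np.full(9, 1 / 9), grid)
        assert g["short"] == pytest.approx(2 / 9)
        assert g["medium"] == pytest.approx(4 / 9)
        assert g["long"] == pytest.approx(3 / 9)

    def test_concentrated_on_5(self):
        grid = LengthGrid()
        theta = np.zeros(9)
        theta[1] = 1.0  # l = 5
        assert group_weights(theta, grid) == {"short": 1.0, "medium": 0.0, "long": 0.0}

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        grid = LengthGrid()
        for _ in range(10):
            theta = rng.dirichlet(np.ones(9))
            assert sum(group_weights(theta, grid).values()) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_setup(random_genome, params):
    grid = LengthGrid((0, 5, 10, 20))
    engine = PropensityEngine(random_genome, params, grid=grid)
    bps = [Breakpoint(800, 2200), Breakpoint(820, 2240), Breakpoint(860, 2210)]
    ds = BreakpointDataset("toy", random_genome, bps)
    return ds, engine


class TestComponentMatrix:

    def test_shape_and_uniform_column(self, small_setup):
        ds, engine = small_setup
        P = component_matrix(ds, engine)
        assert P.P.shape == (3, 4)
        assert np.allclose(P.P[:, 0], 1.0 / 400)

    def test_row_permutation(self, random_genome, params, small_setup):
        ds, engine = small_setup
        P = component_matrix(ds, engine).P
        ds_rev = BreakpointDataset("rev", random_genome, ds.breakpoints[::-1])
        P_rev = component_matrix(ds_rev, engine).P
        assert np.allclose(P_rev, P[::-1])

    def test_planted_column_dominates(self, params):
        g = sterile_genome_with_repeat(5)
        grid = LengthGrid((0, 5, 10, 20))
        engine = PropensityEngine(g, params, grid=grid)
        ds = BreakpointDataset("planted", g, [Breakpoint(800, 2200)])
        P = component_matrix(ds, engine)
        assert P.P[0].argmax() == grid.lengths.index(5)
        assert P.P[0, grid.lengths.index(5)] > 50 / 400

    def test_empty_dataset(self, random_genome, params):
        ds = BreakpointDataset("empty", random_genome)
        engine = PropensityEngine(random_genome, params, grid=LengthGrid((0, 5)))
        with pytest.raises(ValueError):
            component_matrix(ds, engine)


class TestBootstrap:
    def _setup(self, params, genome, n=6):
        grid = LengthGrid((0, 5, 10))
        engine = PropensityEngine(genome, params, grid=grid, pad=110)
        bps = [
            Breakpoint(int(800 + 10 * i), int(2200 + 10 * i)) for i in range(n)
        ]
        ds = BreakpointDataset("bs", genome, bps)
        P = component_matrix(ds, engine)
        fit = fit_mixture(P)
        return ds, engine, fit

    def test_deterministic_given_seed(self, random_genome, params):
        ds, engine, fit = self._setup(params, random_genome)
        fit1 = bootstrap_sd(fit, ds, engine, B=2, seed=42)
        sd1 = dict(fit1.sd_grouped)
        fit2 = bootstrap_sd(fit, ds, engine, B=2, seed=42)
        assert fit2.sd_grouped == sd1

    def test_resample_preserves_size_and_labels(self, random_genome, params):
        ds, engine, fit = self._setup(params, random_genome)
        rng = np.random.default_rng(0)
        rep = resample_dataset(ds, engine, fit.theta, rng)
        assert len(rep) == len(ds)
        assert set(rep.true_lengths) <= set(engine.grid.lengths)
        # resampled breakpoints stay within one window of the originals
        for old, new in zip(ds, rep):
            assert abs(new.p5 - old.p5) <= engine.W
            assert abs(new.p3 - old.p3) <= engine.W

    def test_strong_signal_gives_small_sd(self, params):
        """Windows with one overwhelming component refit to the same theta
        in every replicate, so the bootstrap SDs collapse."""
        g = sterile_genome_with_repeat(5)
        grid = LengthGrid((0, 5, 10))
        engine = PropensityEngine(g, params, grid=grid, pad=110)
        ds = BreakpointDataset("strong", g, [Breakpoint(800, 2200)] * 5)
        fit = fit_mixture(component_matrix(ds, engine))
        assert fit.grouped["short"] > 0.95
        fit = bootstrap_sd(fit, ds, engine, B=8, seed=7)
        assert fit.sd_grouped["long"] == pytest.approx(0.0, abs=1e-12)
        assert fit.sd_grouped["short"] < 0.2

    def test_b_less_than_2_rejected(self, random_genome, params):
        ds, engine, fit = self._setup(params, random_genome)
        with pytest.raises(ValueError):
            bootstrap_sd(fit, ds, engine, B=1, seed=0)
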