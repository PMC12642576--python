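"""Per-cell Poisson mixture: likelihood, EM, filtering, orchestration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from istclean import (
    CellMixtureParams,
    RunConfig,
    SimConfig,
    ValidationError,
    cell_log_likelihood,
    denoise,
    e_step,
    filter_cell,
    fit_cell_mixture,
    m_step,
    simulate_cell_counts,
    simulate_dataset,
)
from istclean.mixture import DEFAULT_ALPHA_CUTOFF, DEFAULT_N_RESTARTS, LAMBDA_FLOOR

from _oracles import poisson_mixture_loglik


class TestCellLogLikelihood:
    def test_coincident_components_reduce_to_plain_poisson(self, rng):
        x = rng.poisson(5.0, 30).astype(float)
        xplus = rng.uniform(0, 3, 30)
        p = CellMixtureParams(pi=0.5, lam_e=4.0, lam_c=4.0)
        ll = cell_log_likelihood(x, xplus, p, offset_mode="additive")
        expected = poisson.logpmf(x, xplus + 4.0).sum()
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_all_zero_counts_closed_form(self):
        G = 17
        p = CellMixtureParams(pi=0.3, lam_e=10.0, lam_c=0.1)
        ll = cell_log_likelihood(np.zeros(G), np.zeros(G), p, offset_mode="additive")
        expected = G * math.log(0.3 * math.exp(-10.0) + 0.7 * math.exp(-0.1))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_probability_oracle(self, rng):
        """log-sum-exp path equals the naive pmf computation on 100 cases."""
        for _ in range(100):
            G = int(rng.integers(3, 15))
            lam_c = float(rng.uniform(0.05, 2.0))
            lam_e = lam_c + float(rng.uniform(0.5, 15.0))
            p = CellMixtureParams(pi=float(rng.uniform(0.05, 0.95)), lam_e=lam_e, lam_c=lam_c)
            x = rng.poisson(3.0, G).astype(float)
            ll = cell_log_likelihood(x, np.zeros(G), p, offset_mode="additive")
            assert ll == pytest.approx(
                poisson_mixture_loglik(x, p.pi, p.lam_e, p.lam_c), abs=1e-9
            )


class TestEStep:
    PARAMS = CellMixtureParams(pi=0.3, lam_e=10.0, lam_c=0.1)

    def test_scalar_posterior_by_substitution(self):
        alpha, _ = e_step([5.0], [1.0], self.PARAMS, offset_mode="additive")
        num = 0.3 * 11**5 * math.exp(-11)
        den = num + 0.7 * 1.1**5 * math.exp(-1.1)
        assert alpha[0] == pytest.approx(num / den, abs=1e-9)
        assert alpha[0] == pytest.approx(0.6826, abs=5e-4)

    def test_posterior_monotone_in_count(self):
        alphas = [
            e_step([float(x)], [1.0], self.PARAMS, offset_mode="additive")[0][0]
            for x in range(0, 12)
        ]
        assert all(a2 > a1 for a1, a2 in zip(alphas, alphas[1:]))
        assert alphas[8] == pytest.approx(0.9995, abs=5e-4)

    def test_posterior_non_increasing_in_offset(self):
        alphas = [
            e_step([5.0], [xp], self.PARAMS, offset_mode="additive")[0][0]
            for xp in np.linspace(0, 20, 15)
        ]
        assert all(a2 <= a1 + 1e-12 for a1, a2 in zip(alphas, alphas[1:]))

    def test_equal_rates_give_alpha_equal_pi(self, rng):
        p = CellMixtureParams(pi=0.42, lam_e=3.0, lam_c=3.0)
        x = rng.poisson(3.0, 20).astype(float)
        alpha, _ = e_step(x, np.zeros(20), p, offset_mode="additive")
        np.testing.assert_allclose(alpha, 0.42, atol=1e-12)

    def test_posterior_in_unit_interval(self, rng):
        for mode in ("additive", "multiplicative"):
            x = rng.poisson(4.0, 50).astype(float)
            xplus = rng.uniform(0, 10, 50)
            p = CellMixtureParams(pi=0.2, lam_e=8.0, lam_c=0.3)
            alpha, _ = e_step(x, xplus, p, offset_mode=mode)
            assert ((alpha >= 0) & (alpha <= 1)).all()


class TestMStep:
    def test_constant_offset_closed_form_additive(self, rng):
        """With x⁺ ≡ c the additive score has the closed form
        λ = max(Σαx/Σα − c, floor); the root finder must agree."""
        G = 30
        c = 2.5
        x = rng.poisson(8.0, G).astype(float)
        alpha = rng.uniform(0.05, 0.95, G)
        params = m_step(x, np.full(G, c), alpha, offset_mode="additive")
        lam_e_exp = max((alpha * x).sum() / alpha.sum() - c, LAMBDA_FLOOR)
        lam_c_exp = max(((1 - alpha) * x).sum() / (1 - alpha).sum() - c, LAMBDA_FLOOR)
        if lam_c_exp > lam_e_exp:
            lam_e_exp, lam_c_exp = lam_c_exp, lam_e_exp
        assert params.lam_e == pytest.approx(lam_e_exp, abs=1e-6)
        assert params.lam_c == pytest.approx(lam_c_exp, abs=1e-6)

    def test_degenerate_all_responsible_gives_component_mle(self, rng):
        x = rng.poisson(6.0, 25).astype(float)
        params = m_step(x, np.zeros(25), np.ones(25), offset_mode="additive")
        assert 0 < params.pi < 1  # clamped open
        assert params.lam_e == pytest.approx(x.mean(), abs=1e-6)
        assert params.lam_c == LAMBDA_FLOOR

    @pytest.mark.parametrize("mode", ["additive", "multiplicative"])
    def test_maximises_expected_complete_loglik_vs_grid(self, rng, mode):
        """The returned rates beat a dense λ grid on the EM Q-function.

        The M-step may flip component labels to keep λ_e ≥ λ_c, so one of
        the two pairings of (rate, weights) must maximise both scores.
        """
        G = 20
        x = rng.poisson(5.0, G).astype(float)
        xplus = rng.uniform(0.2, 6.0, G)
        alpha = rng.uniform(0.02, 0.98, G)
        params = m_step(x, xplus, alpha, offset_mode=mode)
        lam_grid = np.geomspace(1e-6, x.max() + 1.0, 10000)

        def q(lam, w):
            if mode == "additive":
                mean = xplus[None, :] + lam[:, None]
            else:
                mean = (xplus + 1.0)[None, :] * lam[:, None]
            return (w[None, :] * (x[None, :] * np.log(mean) - mean)).sum(axis=1)

        def pairing_ok(lam_for_alpha, lam_for_rest):
            for lam_hat, w in ((lam_for_alpha, alpha), (lam_for_rest, 1 - alpha)):
                grid_best = q(lam_grid, w).max()
                ours = q(np.array([lam_hat]), w)[0]
                if ours < grid_best - 1e-4 * abs(grid_best):
                    return False
            return True

        assert pairing_ok(params.lam_e, params.lam_c) or pairing_ok(
            params.lam_c, params.lam_e
        )

    def test_reordering_keeps_lam_e_largest(self, rng):
        # weights favouring small counts force a label flip internally
        x = np.array([10.0, 9.0, 0.0, 1.0])
        alpha = np.array([0.01, 0.02, 0.99, 0.98])
        params = m_step(x, np.zeros(4), alpha, offset_mode="additive")
        assert params.lam_e >= params.lam_c


class TestFitCellMixture:
    def test_em_loglik_monotone_within_restart(self, rng):
        """Manual E/M alternation never decreases the log-likelihood."""
        for _ in range(100):
            G = int(rng.integers(10, 40))
            x = rng.poisson(rng.uniform(1, 10), G).astype(float)
            if (x > 0).sum() < 2:
                continue
            xplus = rng.uniform(0, 4, G)
            mode = "additive" if rng.uniform() < 0.5 else "multiplicative"
            p = CellMixtureParams(pi=0.3, lam_e=max(x.mean(), 1.0), lam_c=0.2)
            alpha, ll = e_step(x, xplus, p, offset_mode=mode)
            for _ in range(15):
                p = m_step(x, xplus, alpha, offset_mode=mode)
                alpha, ll_new = e_step(x, xplus, p, offset_mode=mode)
                assert ll_new >= ll - 1e-7 * abs(ll)
                ll = ll_new

    def test_parameter_recovery_no_offsets(self):
        """Simulated additive-model cells: π within ±0.05, λ_e within ±15%."""
        pi_true, lam_e, lam_c, G = 0.2, 20.0, 0.5, 300
        pi_err, lam_err = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x, _ = simulate_cell_counts(G, pi_true, lam_e, lam_c, np.zeros(G), rng)
            fit, _ = fit_cell_mixture(x, np.zeros(G), seed=seed, offset_mode="additive")
            pi_err.append(fit.params.pi - pi_true)
            lam_err.append(fit.params.lam_e / lam_e - 1.0)
        assert np.abs(pi_err).mean() < 0.05
        assert np.abs(lam_err).mean() < 0.15

    def test_exchangeable_genes_give_uniform_decision(self):
        x = np.full(40, 5.0)
        xplus = np.full(40, 2.0)
        fit, alpha = fit_cell_mixture(x, xplus, seed=0, offset_mode="additive")
        # all genes identical -> identical posterior; filter decision uniform
        assert np.ptp(alpha) < 1e-9
        kept = filter_cell(x, alpha)
        assert len(set(kept.tolist())) == 1

    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.poisson(5.0, 60).astype(float)
        xplus = rng.uniform(0, 5, 60)
        f1, a1 = fit_cell_mixture(x, xplus, seed=42)
        f2, a2 = fit_cell_mixture(x, xplus, seed=42)
        assert f1.params == f2.params
        assert f1.log_likelihood == f2.log_likelihood
        np.testing.assert_array_equal(a1, a2)

    def test_reported_fit_has_best_loglik_across_restarts(self, rng):
        x = rng.poisson(4.0, 80).astype(float)
        xplus = rng.uniform(0, 3, 80)
        best, _ = fit_cell_mixture(x, xplus, n_restarts=8, seed=5, offset_mode="additive")
        singles = [
            fit_cell_mixture(x, xplus, n_restarts=1, seed=[5, k], offset_mode="additive")[0]
            for k in range(8)
        ]
        assert best.log_likelihood >= max(s.log_likelihood for s in singles) - 1e-6

    def test_identifiability_ordering(self, rng):
        for seed in range(10):
            x = rng.poisson(3.0, 50).astype(float)
            xplus = rng.uniform(0, 4, 50)
            fit, _ = fit_cell_mixture(x, xplus, seed=seed)
            assert fit.params.lam_e >= fit.params.lam_c >= LAMBDA_FLOOR


class TestFilterCell:
    def test_boundary_is_filtered_inclusively(self):
        out = filter_cell(np.array([5, 5, 5]), np.array([0.2, 0.75, 0.76]), cutoff=0.75)
        np.testing.assert_array_equal(out, [0, 0, 5])

    def test_zero_cutoff_removes_only_alpha_zero(self):
        out = filter_cell(np.array([3, 4]), np.array([0.0, 0.01]), cutoff=0.0)
        np.testing.assert_array_equal(out, [0, 4])

    def test_default_cutoff(self):
        assert DEFAULT_ALPHA_CUTOFF == 0.75
        assert DEFAULT_N_RESTARTS == 10

    def test_integer_dtype_preserved(self):
        x = np.array([2, 9], dtype=np.int64)
        out = filter_cell(x, np.array([0.9, 0.1]))
        assert out.dtype == np.int64
        np.testing.assert_array_equal(out, [2, 0])


class TestDenoise:
    def test_all_zero_matrix_passes_through_skipped(self):
        cells = pd.DataFrame(
            {"cell_id": ["a", "b"], "x": [0.0, 10.0], "y": [0.0, 0.0]}
        )
        res = denoise(np.zeros((2, 4), dtype=int), cells)
        assert res.adjusted.nnz == 0
        assert res.fits["skipped"].all()
        assert np.isnan(res.posterior).all()

    def test_adjusted_entries_kept_whole_or_zeroed(self, small_dataset):
        ds = small_dataset
        res = denoise(
            ds.counts, ds.cells, tx=ds.transcripts,
            config=RunConfig(seed=0), gene_names=ds.gene_names,
        )
        raw = ds.counts.toarray()
        adj = res.adjusted.toarray()
        assert ((adj == 0) | (adj == raw)).all()
        assert (adj <= raw).all()
        post = res.posterior
        fitted = ~res.fits["skipped"].to_numpy()
        assert ((post[fitted] >= 0) & (post[fitted] <= 1)).all()

    def test_same_seed_bit_identical(self, small_dataset):
        ds = small_dataset
        cfg = RunConfig(seed=3, n_restarts=3)
        r1 = denoise(ds.counts, ds.cells, config=cfg, gene_names=ds.gene_names)
        r2 = denoise(ds.counts, ds.cells, config=cfg, gene_names=ds.gene_names)
        assert (r1.adjusted != r2.adjusted).nnz == 0
        pd.testing.assert_frame_equal(r1.fits, r2.fits)

    def test_clean_separated_data_mostly_retained(self):
        """No planted contamination and well-separated (disjoint) programs:
        ≥99% of endogenous entries survive at the default cutoff."""
        cfg = SimConfig(
            n_cells=800, extent=(1580.0, 1580.0), n_shared_genes=0,
            p_spill=0.0, ambient_rate=0.0, seed=2,
        )
        ds = simulate_dataset(cfg)
        res = denoise(
            ds.counts, ds.cells, tx=ds.transcripts,
            config=RunConfig(seed=2), gene_names=ds.gene_names,
        )
        raw = ds.counts.toarray()
        adj = res.adjusted.toarray()
        endo = ds.endogenous.toarray() > 0
        assert (adj[endo] > 0).mean() >= 0.99
        assert (adj <= raw).all()

    def test_mismatched_cells_rejected(self, three_cells):
        with pytest.raises(ValidationError):
            denoise(np.ones((2, 4), dtype=int), three_cells)

    def test_non_integer_counts_rejected(self, three_cells):
        with pytest.raises(ValidationError, match="integer"):
            denoise(np.full((3, 4), 0.5), three_cells)
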