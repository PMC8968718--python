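"""Correlated-instrument IVW estimator: oracles, reductions, panel behavior."""

import numpy as np
import pytest
from scipy import stats as sps

from brainmr.instruments import InstrumentSet, LDMatrix
from brainmr.mr import MRInput, MRResult, ivw_correlated, run_panel, two_tailed_p
from brainmr.simulate import empirical_ld, simulate_exposure_gwas, simulate_outcome_panel

from conftest import make_stats


def gls_oracle(gamma, Gamma, se_y, rho):
    """Independent GLS route: Cholesky whitening, then ordinary least squares."""
    omega = np.outer(se_y, se_y) * rho
    L = np.linalg.cholesky(omega)
    a = np.linalg.solve(L, gamma)
    b = np.linalg.solve(L, Gamma)
    beta = float(a @ b) / float(a @ a)
    se = float(a @ a) ** -0.5
    return beta, se


class TestIvwCorrelated:
    def test_single_instrument_is_wald_ratio(self):
        res = ivw_correlated(MRInput([0.5], [0.05], [0.2], [0.1], [[1.0]]))
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.2)
        assert res.z == pytest.approx(2.0)

    def test_two_instruments_correlated_oracle(self):
        gamma, Gamma = np.array([1.0, 1.0]), np.array([0.3, 0.5])
        se_y = np.array([0.1, 0.1])
        rho = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = ivw_correlated(MRInput(gamma, se_y, Gamma, se_y, rho))
        beta_o, se_o = gls_oracle(gamma, Gamma, se_y, rho)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert res.beta == pytest.approx(beta_o, rel=1e-12)
        assert res.se == pytest.approx(se_o, rel=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.0075), rel=1e-9)  # 2x2 by hand

    def test_identity_rho_reduces_to_textbook_ivw(self):
        rng = np.random.default_rng(11)
        gamma = rng.normal(0.3, 0.1, 4)
        Gamma = rng.normal(0.1, 0.05, 4)
        se_y = rng.uniform(0.05, 0.2, 4)
        res = ivw_correlated(MRInput(gamma, se_y, Gamma, se_y, np.eye(4)))
        w = gamma**2 / se_y**2
        assert res.beta == pytest.approx(np.sum(gamma * Gamma / se_y**2) / w.sum(), rel=1e-14)
        assert res.se == pytest.approx(w.sum() ** -0.5, rel=1e-14)
        # 2-instrument closed form with equal weights
        r2 = ivw_correlated(MRInput([1, 1], [0.05, 0.05], [0.3, 0.5],
                                    [0.1, 0.1], np.eye(2)))
        assert r2.beta == pytest.approx(0.4)
        assert r2.se == pytest.approx(0.1 / np.sqrt(2))

    def test_matches_gls_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            j = int(rng.integers(1, 7))
            x = rng.standard_normal((j + 5, j))
            rho = np.corrcoef(x, rowvar=False) if j > 1 else np.eye(1)
            gamma = rng.normal(0.0, 0.5, j)
            Gamma = rng.normal(0.0, 0.2, j)
            se_y = rng.uniform(0.05, 0.3, j)
            res = ivw_correlated(MRInput(gamma, se_y, Gamma, se_y, np.atleast_2d(rho)))
            beta_o, se_o = gls_oracle(gamma, Gamma, se_y, np.atleast_2d(rho))
            assert res.beta == pytest.approx(beta_o, rel=1e-10)
            assert res.se == pytest.approx(se_o, rel=1e-10)

    def test_equivariance_under_scaling(self):
        inp = MRInput([0.5, 0.3], [0.1, 0.1], [0.2, 0.1], [0.1, 0.2],
                      [[1, 0.3], [0.3, 1]])
        base = ivw_correlated(inp)
        scaled_out = ivw_correlated(MRInput(inp.gamma, inp.se_x, 3 * inp.Gamma,
                                            inp.se_y, inp.rho))
        scaled_exp = ivw_correlated(MRInput(2 * inp.gamma, inp.se_x, inp.Gamma,
                                            inp.se_y, inp.rho))
        assert scaled_out.beta == pytest.approx(3 * base.beta, rel=1e-12)
        assert scaled_exp.beta == pytest.approx(base.beta / 2, rel=1e-12)

    def test_sign_consistency_and_p_domain(self):
        res = ivw_correlated(MRInput([0.5], [0.05], [-0.2], [0.1], [[1.0]]))
        assert np.sign(res.z) == np.sign(res.beta) == -1
        assert 0 < res.p <= 1

    def test_shape_errors_and_conditioning(self):
        with pytest.raises(ValueError):
            ivw_correlated(MRInput([0.5, 0.3], [0.1], [0.2], [0.1], [[1.0]]))
        # perfectly duplicated instruments: the one-shot ridge makes Omega
        # invertible and the estimate collapses to the single-instrument ratio
        res = ivw_correlated(MRInput([0.5, 0.5], [0.1, 0.1], [0.2, 0.2],
                                     [0.1, 0.1], [[1, 1], [1, 1]]))
        assert np.isfinite(res.beta) and np.isfinite(res.se)
        assert res.beta == pytest.approx(0.4, rel=1e-6)


class TestTwoTailedP:
    def test_reported_z_to_p_value(self):
        # a z of -5.11 corresponds to p = 3.22e-7
        assert two_tailed_p(-5.11) == pytest.approx(3.22e-7, rel=5e-3)

    @pytest.mark.parametrize("z,expected", [(0.0, 1.0), (1.959964, 0.05)])
    def test_reference_points(self, z, expected):
        assert two_tailed_p(z) == pytest.approx(expected, rel=1e-4)

    def test_no_underflow_at_large_z(self):
        assert two_tailed_p(8.0) > 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_p(float("nan"))


def _instruments_from(panel, effects, seed):
    stats = simulate_exposure_gwas(panel, effects, seed=seed)
    return InstrumentSet(stats, empirical_ld(panel), r2_max=1.0 + 1e-9)


class TestRunPanel:
    def test_empty_outcome_collection(self, ld_block_panel):
        instr = _instruments_from(ld_block_panel, {"var0000": 0.4}, seed=1)
        assert run_panel(instr, {}).empty

    def test_measure_without_shared_variants_is_skipped(self, ld_block_panel):
        instr = _instruments_from(ld_block_panel, {"var0000": 0.4}, seed=1)
        good = instr.stats
        bad = make_stats("m_bad", [("zzz", "1", 1, "A", "G", 0.1, 0.05, 0.5)])
        panel = run_panel(instr, {"m_good": good, "m_bad": bad})
        assert panel["measure_id"].tolist() == ["m_good"]

    def test_planted_measures_have_top_z(self, demo_run):
        import pandas as pd

        out, summary = demo_run
        panel = pd.read_csv(out / "mr_panel.tsv", sep="\t")
        top6 = set(panel.reindex(panel["z"].abs().sort_values().index)
                   .tail(6)["measure_id"])
        assert top6 == set(summary["planted_measures"])

    def test_null_panel_z_scores_are_standard_normal(self):
        from brainmr.simulate import simulate_reference_panel

        panel_x = simulate_reference_panel(2000, 5, [(5, 0.5)], seed=21)
        panel_y = simulate_reference_panel(2000, 5, [(5, 0.5)], seed=22)
        effects = {f"var{i:04d}": 0.3 for i in range(5)}
        gwas = simulate_exposure_gwas(panel_x, effects, seed=21)
        instr = InstrumentSet(gwas, empirical_ld(panel_x), r2_max=1.0 + 1e-9)
        stats, _, _ = simulate_outcome_panel(panel_y, effects, {}, 500, seed=23)
        panel = run_panel(instr, stats)
        z = panel["z"].to_numpy()
        assert abs(np.abs(z).mean() - np.sqrt(2 / np.pi)) < 0.1  # E|Z| ~ 0.798
        assert sps.kstest(z, "norm").pvalue > 0.01
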