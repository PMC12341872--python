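"""Confidence intervals: closed forms vs the Monte-Carlo oracle, coverage,
approximated-mode reductions, bootstrap behaviour."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import lrvalidate as lv
from lrvalidate import ci, stats
from lrvalidate.errors import InvariantError, LRValidationError

from conftest import make_diagonal_covblocks, make_random_covblocks

SPEC = ci.CiSpec()
Z95 = float(norm.ppf(0.975))


class TestBiasExact:
    def test_no_information_difference(self):
        blocks = lv.CovBlocks(G22=np.eye(3), Cp22=0.2 * np.eye(3), Cw22=0.2 * np.eye(3))
        r = ci.ci_bias_exact(0.1, blocks, SPEC)
        assert r.se == 0.0
        assert r.lower == r.upper == 0.1

    def test_arithmetic_n2(self):
        blocks = lv.CovBlocks(
            G22=np.eye(2), Cp22=0.24 * np.eye(2), Cw22=0.2 * np.eye(2)
        )
        r = ci.ci_bias_exact(0.0, blocks, SPEC)
        assert r.se == pytest.approx(np.sqrt(0.08) / 2)
        assert r.upper == pytest.approx(Z95 * np.sqrt(0.08) / 2)


class TestBiasApprox:
    def _rels(self, rel_w, rel_p):
        n = len(rel_w)
        return lv.ReliabilityTable(table=pd.DataFrame(
            {"level": np.arange(1, n + 1), "rel_whole": rel_w, "rel_partial": rel_p}
        ))

    def test_equal_reliabilities_zero_se(self):
        rels = self._rels([0.5, 0.6], [0.5, 0.6])
        assert ci.ci_bias_approx(0.0, rels, 1.0, SPEC).se == 0.0

    def test_arithmetic(self):
        rels = self._rels([0.59] * 100, [0.5] * 100)
        r = ci.ci_bias_approx(0.0, rels, 1.0, SPEC)
        assert r.se == pytest.approx(0.03)

    def test_swapped_files_hint(self):
        rels = self._rels([0.4] * 10, [0.5] * 10)
        with pytest.raises(InvariantError, match="swapped"):
            ci.ci_bias_approx(0.0, rels, 1.0, SPEC)


class TestDispersionExact:
    def test_identical_runs_degenerate(self):
        """Cw22 = Cp22 makes u_w = u_p almost surely, so the slope is exactly
        one and its exact standard error must vanish."""
        blocks = lv.CovBlocks(G22=np.eye(10), Cp22=0.3 * np.eye(10), Cw22=0.3 * np.eye(10))
        r = ci.ci_dispersion_exact(1.0, blocks, SPEC)
        assert r.se == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_case_closed_form(self, rng):
        """For K = I, D = d*I the variance is d/(m-2), m = n-1 (exact chi-square
        moment) — the quadrature must reproduce it."""
        n, d = 12, 0.25
        blocks = lv.CovBlocks(
            G22=(1.0 + 0.4 + d) * np.eye(n),
            Cp22=(0.4 + d) * np.eye(n),
            Cw22=0.4 * np.eye(n),
        )
        r = ci.ci_dispersion_exact(1.0, blocks, SPEC)
        m = n - 1
        assert r.se == pytest.approx(np.sqrt(d / (m - 2)), rel=1e-6)

    def test_scale_invariance_in_K(self, rng):
        """Scaling both K and D by c leaves the slope se unchanged."""
        blocks = make_random_covblocks(15, rng)
        r1 = ci.ci_dispersion_exact(1.0, blocks, SPEC)
        c = 3.7
        scaled = lv.CovBlocks(G22=c * blocks.G22, Cp22=c * blocks.Cp22,
                              Cw22=c * blocks.Cw22)
        r2 = ci.ci_dispersion_exact(1.0, scaled, SPEC)
        assert r2.se == pytest.approx(r1.se, rel=1e-8)


class TestCorrelationInterval:
    def test_fisher_arithmetic(self):
        r = ci.ci_correlation(0.0, 403, SPEC)
        half = np.tanh(Z95 / 20.0)
        assert half == pytest.approx(0.0976856, abs=1e-6)
        assert r.upper == pytest.approx(half)
        assert r.lower == pytest.approx(-half)

    def test_odd_symmetry(self):
        a = ci.ci_correlation(0.6, 50, SPEC)
        b = ci.ci_correlation(-0.6, 50, SPEC)
        assert a.lower == pytest.approx(-b.upper)
        assert a.upper == pytest.approx(-b.lower)

    def test_degenerate_and_small_n(self):
        with pytest.warns(UserWarning):
            r = ci.ci_correlation(1.0, 50, SPEC)
        assert r.lower == r.upper == 1.0
        with pytest.raises(LRValidationError):
            ci.ci_correlation(0.5, 3, SPEC)

    def test_empirical_coverage_bivariate_normal(self, rng):
        """95% Fisher interval covers the true correlation 0.6 at n=100."""
        n, rho, reps = 100, 0.6, 2000
        cover = 0
        L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ L.T
            r_hat = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            iv = ci.ci_correlation(float(r_hat), n, SPEC)
            cover += iv.contains(rho)
        assert 0.93 <= cover / reps <= 0.97


class TestReliabilityExact:
    def test_perfect_information_zero_se(self):
        n = 6
        blocks = lv.CovBlocks(G22=np.eye(n), Cp22=np.zeros((n, n)),
                              Cw22=np.zeros((n, n)))
        # D = 0 and K = G: se = sqrt(2 tr(SGSG))/((n-1) sgi2) > 0; the true
        # zero-information case is G = Cp = Cw:
        degenerate = lv.CovBlocks(G22=0.5 * np.eye(n), Cp22=0.5 * np.eye(n),
                                  Cw22=0.5 * np.eye(n))
        assert ci.ci_reliability_exact(0.0, degenerate, 0.5, SPEC).se == 0.0
        assert ci.ci_reliability_exact(1.0, blocks, 1.0, SPEC).se > 0.0

    def test_scaling_consistency(self, rng):
        """Scaling all matrices by k^2 scales the se by k^2/sigma_gi2."""
        blocks = make_random_covblocks(12, rng)
        k2 = 4.0
        scaled = lv.CovBlocks(G22=k2 * blocks.G22, Cp22=k2 * blocks.Cp22,
                              Cw22=k2 * blocks.Cw22)
        r1 = ci.ci_reliability_exact(0.5, blocks, 1.0, SPEC)
        r2 = ci.ci_reliability_exact(0.5, scaled, 1.0, SPEC)
        assert r2.se == pytest.approx(k2 * r1.se, rel=1e-9)


class TestReliabilityApprox:
    def test_equal_reliabilities_closed_form(self):
        n, r = 50, 0.36
        rels = lv.ReliabilityTable(table=pd.DataFrame(
            {"level": np.arange(1, n + 1), "rel_whole": [r] * n, "rel_partial": [r] * n}
        ))
        iv = ci.ci_reliability_approx(r, rels, 1.0, 1.0, SPEC)
        assert iv.se == pytest.approx(r * np.sqrt(2.0 / n), rel=1e-9)

    def test_root_n_rate(self):
        def se_at(n):
            rels = lv.ReliabilityTable(table=pd.DataFrame(
                {"level": np.arange(1, n + 1), "rel_whole": [0.5] * n,
                 "rel_partial": [0.4] * n}
            ))
            return ci.ci_reliability_approx(0.4, rels, 1.0, 1.0, SPEC).se
        assert se_at(400) == pytest.approx(se_at(100) / 2.0, rel=1e-9)


class TestPredictivityInterval:
    def test_h_one_reduces_to_correlation(self):
        a = ci.ci_predictivity(0.45, 1.0, 80, SPEC)
        b = ci.ci_correlation(0.45, 80, SPEC)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_zero_correlation_halfwidth(self):
        h = 0.5
        r = ci.ci_predictivity(0.0, h, 103, SPEC)
        assert r.upper == pytest.approx(np.tanh(Z95 / 10.0) / h)
        assert r.lower == pytest.approx(-r.upper)

    def test_empirical_coverage(self, rng):
        """Direct generative check at n=200: u_p carries reliability rel of
        the true breeding value, y* = u + e; the true predictivity is
        sqrt(rel).  Coverage of the 95% interval must sit in [0.92, 0.98]."""
        n, reps = 200, 1000
        sg2, se2, rel = 0.3, 0.7, 0.4
        h = np.sqrt(sg2 / (sg2 + se2))
        truth = np.sqrt(rel)
        cover = 0
        for _ in range(reps):
            u = rng.normal(0, np.sqrt(sg2), n)
            u_p = rel * u + rng.normal(0, np.sqrt(rel * (1 - rel) * sg2), n)
            ystar = u + rng.normal(0, np.sqrt(se2), n)
            raw = np.corrcoef(ystar, u_p)[0, 1]
            iv = ci.ci_predictivity(float(raw / h), float(h), n, SPEC)
            cover += iv.contains(truth)
        assert 0.92 <= cover / reps <= 0.98


class TestOracleAgreement:
    """Closed-form exact SEs vs the empirical SD of oracle draws (release
    blocking at full size in the acceptance suite; spot-checked here)."""

    @pytest.mark.parametrize("n", [10, 25])
    def test_exact_se_matches_oracle(self, n, rng):
        blocks = make_random_covblocks(n, rng)
        sigma_gi2 = float(np.mean(np.diag(blocks.G22)))
        mc = ci.mc_oracle(blocks, 8000, seed=7, sigma_gi2=sigma_gi2)
        se_bias = ci.ci_bias_exact(0.0, blocks, SPEC).se
        se_disp = ci.ci_dispersion_exact(1.0, blocks, SPEC).se
        se_rel = ci.ci_reliability_exact(0.0, blocks, sigma_gi2, SPEC).se
        assert se_bias == pytest.approx(mc.sd("bias"), rel=0.05)
        assert se_disp == pytest.approx(mc.sd("dispersion"), rel=0.05)
        assert se_rel == pytest.approx(mc.sd("reliability"), rel=0.05)

    def test_approx_agrees_with_exact_on_diagonal_pec(self, rng):
        """With PEC off-diagonals below 5% of diagonals and proportional
        reliabilities, every approx se is within 15% of the exact se."""
        n = 120
        blocks, rels = make_diagonal_covblocks(n, rng, c=1.4, off_diag=0.01)
        sg2 = 1.0
        e_bias = ci.ci_bias_exact(0.0, blocks, SPEC).se
        a_bias = ci.ci_bias_approx(0.0, rels, sg2, SPEC).se
        assert a_bias == pytest.approx(e_bias, rel=0.15)
        e_disp = ci.ci_dispersion_exact(1.0, blocks, SPEC).se
        a_disp = ci.ci_dispersion_approx(1.0, rels, SPEC).se
        assert a_disp == pytest.approx(e_disp, rel=0.15)
        e_rel = ci.ci_reliability_exact(0.4, blocks, sg2, SPEC).se
        a_rel = ci.ci_reliability_approx(0.4, rels, sg2, sg2, SPEC).se
        assert a_rel == pytest.approx(e_rel, rel=0.15)


class TestMcOracle:
    def test_identical_blocks_give_unit_dispersion(self, rng):
        blocks = lv.CovBlocks(G22=np.eye(8), Cp22=0.4 * np.eye(8),
                              Cw22=0.4 * np.eye(8))
        mc = ci.mc_oracle(blocks, 200, seed=3)
        assert np.allclose(mc.dispersion, 1.0, atol=1e-7)
        assert np.allclose(mc.ratio_of_accuracies, 1.0, atol=1e-7)

    def test_zero_mean_differences(self, rng):
        blocks = make_random_covblocks(20, rng)
        mc = ci.mc_oracle(blocks, 20000, seed=4)
        assert abs(mc.bias.mean()) < 4 * mc.sd("bias") / np.sqrt(20000) * 10

    def test_diagonal_correlation_theory(self, rng):
        """For diagonal structures corr(u_p, u_w)^2 should concentrate near
        var(u_p)/sqrt(var(u_p) var(u_w)) ratio theory: corr = sqrt(k/a)."""
        n = 400
        k, a = 0.5, 0.8  # var(u_p), var(u_w) diagonals
        blocks = lv.CovBlocks(
            G22=np.eye(n), Cp22=(1 - k) * np.eye(n), Cw22=(1 - a) * np.eye(n)
        )
        mc = ci.mc_oracle(blocks, 400, seed=5)
        assert mc.ratio_of_accuracies.mean() == pytest.approx(np.sqrt(k / a), abs=0.02)

    def test_inconsistent_blocks_fatal(self):
        n = 5
        with pytest.raises(InvariantError, match="PSD|swapped"):
            bad = lv.CovBlocks.__new__(lv.CovBlocks)
            bad.G22 = np.eye(n)
            bad.Cp22 = 0.2 * np.eye(n)
            bad.Cw22 = 0.9 * np.eye(n)  # whole "knows" less than partial
            bad.trait = 1
            ci.mc_oracle(bad, 10, seed=0)


class TestCoverage:
    def test_exact_interval_coverage_under_oracle(self, rng):
        """95% exact intervals for bias, dispersion and reliability cover the
        truth (0, 1, and tr(SK)/((n-1) s_gi2)) in [0.92, 0.98]."""
        n = 40
        blocks = make_random_covblocks(n, rng)
        sigma_gi2 = float(np.mean(np.diag(blocks.G22)))
        K = blocks.G22 - blocks.Cp22
        true_rel = (np.trace(K) - K.sum() / n) / ((n - 1) * sigma_gi2)
        mc = ci.mc_oracle(blocks, 1500, seed=11, sigma_gi2=sigma_gi2)
        se_b = ci.ci_bias_exact(0.0, blocks, SPEC).se
        se_d = ci.ci_dispersion_exact(1.0, blocks, SPEC).se
        se_r = ci.ci_reliability_exact(0.0, blocks, sigma_gi2, SPEC).se
        for draws, se, truth in (
            (mc.bias, se_b, 0.0),
            (mc.dispersion, se_d, 1.0),
            (mc.reliability, se_r, true_rel),
        ):
            cover = np.mean(np.abs(draws - truth) <= Z95 * se)
            assert 0.92 <= cover <= 0.98


class TestBootstrap:
    def test_default_replicates(self):
        assert ci.CiSpec(mode="boot").n_boot == 10_000

    def test_identical_predictions_degenerate_interval(self):
        u = np.array([0.2, -0.4, 0.9, 1.3, -0.6])
        block = stats.FocalBlock(trait=1, ids=np.arange(1, 6), u_w=u, u_p=u)
        r = ci.ci_boot(block, "dispersion", ci.CiSpec(mode="boot", n_boot=200, seed=1))
        assert r.lower == pytest.approx(1.0)
        assert r.upper == pytest.approx(1.0)

    def test_seeded_reproducibility(self, pipeline):
        spec = ci.CiSpec(mode="boot", n_boot=500, seed=42)
        a = ci.ci_boot(pipeline.block, "bias", spec)
        b = ci.ci_boot(pipeline.block, "bias", spec)
        assert (a.estimate, a.se, a.lower, a.upper) == (b.estimate, b.se, b.lower, b.upper)

    def test_boot_bias_se_near_exact_weak_pec(self, rng):
        """On a near-diagonal structure at n=200 the bootstrap se of bias
        agrees with the exact closed form within 10%."""
        n = 200
        blocks, _ = make_diagonal_covblocks(n, rng, c=1.4)
        mc = ci.mc_oracle(blocks, 1, seed=9, keep_draws=True)
        block = stats.FocalBlock(
            trait=1, ids=np.arange(1, n + 1), u_w=mc.u_w[0], u_p=mc.u_p[0]
        )
        boot = ci.ci_boot(block, "bias", ci.CiSpec(mode="boot", n_boot=4000, seed=10))
        exact = ci.ci_bias_exact(0.0, blocks, SPEC)
        assert boot.se == pytest.approx(exact.se, rel=0.10)

    def test_interval_brackets_estimate(self, pipeline):
        spec = ci.CiSpec(mode="boot", n_boot=300, seed=5)
        for name in ("bias", "dispersion", "ratio_of_accuracies", "reliability"):
            r = ci.ci_boot(pipeline.block, name, spec, sigma_gi2=0.3)
            assert r.lower <= r.estimate <= r.upper
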