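"""Monte-Carlo engine, tie-breaking wrapper and closed-form p-values."""

import numpy as np
import pytest

from circuniform import (
    CircularSample,
    NullDistribution,
    chisq_pvalue,
    monte_carlo_pvalue,
    normalize,
    perturb,
    rayleigh_pvalue,
    tb_test,
)
from circuniform.pvalues import simulate_null
from scipy import stats as sps

TWO_PI = 2 * np.pi


class TestDwassRule:
    def test_never_exceeded_gives_floor(self):
        """N_e = 0 with N_R = 10,000 must give exactly 1/10,001."""
        # a wildly clustered sample: its Rao statistic tops any uniform null
        s = CircularSample(np.full(13, 1.0) + np.arange(13) * 1e-9)
        res = monte_carlo_pvalue(s, "rao", n_reps=10_000, seed=0)
        assert res.n_exceed == 0
        assert res.p_value == pytest.approx(1 / 10_001)

    def test_always_exceeded_gives_one(self):
        # equally spaced: Rao statistic is 0, every null draw ties or beats it
        s = CircularSample(np.arange(8) * TWO_PI / 8)
        res = monte_carlo_pvalue(s, "rao", n_reps=500, seed=0)
        assert res.n_exceed == res.n_reps
        assert res.p_value == 1.0

    def test_counts_consistent(self, pigeon):
        res = monte_carlo_pvalue(pigeon, "gini", n_reps=2000, seed=5)
        assert res.p_value == (res.n_exceed + 1) / (res.n_reps + 1)
        assert res.p_value >= 1 / (res.n_reps + 1)

    def test_reproducible_under_seed(self, pigeon):
        a = monte_carlo_pvalue(pigeon, "hr", n_reps=1000, seed=42)
        b = monte_carlo_pvalue(pigeon, "hr", n_reps=1000, seed=42)
        assert (a.p_value, a.n_exceed) == (b.p_value, b.n_exceed)
        c = tb_test(pigeon, "hr", n_reps=1000, seed=42)
        d = tb_test(pigeon, "hr", n_reps=1000, seed=42)
        assert (c.p_value, c.n_exceed, c.statistic.value) == (d.p_value, d.n_exceed, d.statistic.value)

    def test_unknown_statistic(self, pigeon):
        with pytest.raises(ValueError, match="unknown statistic"):
            monte_carlo_pvalue(pigeon, "hodges", n_reps=10)

    def test_mismatched_null_rejected(self, pigeon):
        null = simulate_null("gini", 20, 100, np.random.default_rng(0))
        with pytest.raises(ValueError, match="n=20"):
            monte_carlo_pvalue(pigeon, "gini", null_distribution=null)
        null2 = simulate_null("rao", 13, 100, np.random.default_rng(0))
        with pytest.raises(ValueError, match="rao"):
            monte_carlo_pvalue(pigeon, "gini", null_distribution=null2)

    def test_shrinking_monte_carlo_error(self, pigeon):
        """Spread of repeated p estimates shrinks roughly like 1/sqrt(N_R)."""
        spreads = []
        for n_reps in (200, 3200):
            ps = [monte_carlo_pvalue(pigeon, "rao", n_reps=n_reps, seed=s).p_value for s in range(20)]
            spreads.append(np.std(ps))
        assert spreads[1] < spreads[0] / 2  # 4x reps -> ~4x smaller SE here


class TestPerturb:
    def test_huge_kappa_barely_moves(self, rng):
        s = CircularSample(rng.uniform(0.1, TWO_PI - 0.1, 200))
        out = perturb(s, kappa=1e8, seed=1)
        assert np.max(np.abs(out.angles - s.angles)) < 1e-3

    def test_breaks_ties_but_stays_local(self):
        s = normalize([350, 350, 350], units="degrees")
        out = perturb(s, kappa=1000.0, seed=2)
        assert len(np.unique(out.angles)) == 3
        d = np.abs(np.angle(np.exp(1j * (out.angles - s.angles))))
        assert np.max(d) < 0.15

    def test_wraps_into_range(self):
        s = CircularSample(np.array([TWO_PI - 1e-6]))
        for seed in range(20):
            out = perturb(s, kappa=100.0, seed=seed)
            assert 0 <= out.angles[0] < TWO_PI

    def test_kappa_must_be_positive(self, pigeon):
        with pytest.raises(ValueError, match="kappa"):
            perturb(pigeon, kappa=0.0)


class TestTBTest:
    def test_continuous_data_large_kappa_matches_standard(self, rng):
        """With untied data and kappa -> inf, TB reduces to the plain engine."""
        s = CircularSample(rng.uniform(0, TWO_PI, 30))
        std = monte_carlo_pvalue(s, "rao", n_reps=4000, seed=3)
        tb = tb_test(s, "rao", n_reps=4000, kappa=1e8, seed=3, null_grouping_m=None)
        se = np.sqrt(std.p_value * (1 - std.p_value) / 4000)
        assert abs(tb.p_value - std.p_value) < 4 * se + 1e-9

    def test_result_metadata(self, pigeon):
        res = tb_test(pigeon, "gini", n_reps=500, seed=9)
        assert res.variant == "tb"
        assert res.kappa_tb == 1000.0
        assert res.n_reps == 500

    def test_null_pipeline_mirrors_grouping(self, pigeon):
        """The default TB null for the 5-degree pigeon data is grouped to m=72."""
        null = simulate_null("rao", 13, 50, np.random.default_rng(0), variant="tb", grouping_m=72)
        res = tb_test(pigeon, "rao", seed=1, null_distribution=null)
        assert res.p_value == (res.n_exceed + 1) / 51

    def test_variant_mismatch_rejected(self, pigeon):
        null = simulate_null("rao", 13, 50, np.random.default_rng(0), variant="standard")
        with pytest.raises(ValueError, match="variant"):
            tb_test(pigeon, "rao", null_distribution=null)


class TestSuperUniformValidity:
    def test_null_rejection_rate_bounded(self, rng):
        """P(p <= alpha) <= alpha + MC error when data truly follow the null."""
        n, b, alpha = 10, 2000, 0.05
        null = simulate_null("gini", n, 2000, np.random.default_rng(11))
        from circuniform.stats import gini_batch

        data = rng.uniform(0, TWO_PI, (b, n))
        obs = gini_batch(data)
        sn = np.sort(null.values)
        p = (sn.size - np.searchsorted(sn, obs, side="left") + 1) / (sn.size + 1)
        rate = (p <= alpha).mean()
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / b)


class TestRayleighPValue:
    def test_flat_sample_is_nonsignificant(self):
        grid = np.arange(24) * TWO_PI / 24
        assert rayleigh_pvalue(CircularSample(grid)).p_value == pytest.approx(1.0, abs=1e-6)

    def test_perfect_concentration_is_tiny(self):
        s = CircularSample(np.full(50, 1.0))
        assert rayleigh_pvalue(s).p_value < 1e-15

    def test_agrees_with_monte_carlo(self, rng):
        """The closed-form series is consistent with its own Monte-Carlo fallback."""
        s = CircularSample(rng.vonmises(1.0, 0.8, 25) % TWO_PI)
        closed = rayleigh_pvalue(s).p_value
        mc = monte_carlo_pvalue(s, "rayleigh", n_reps=20_000, seed=4).p_value
        se = np.sqrt(closed * (1 - closed) / 20_000)
        assert abs(closed - mc) < 4 * se + 1e-3


class TestChisqPValue:
    def test_uniform_counts_give_one(self):
        grid = np.arange(36) * TWO_PI / 36
        s = CircularSample(grid, grouping_m=36)
        assert chisq_pvalue(s).p_value == pytest.approx(1.0)

    def test_matches_chi2_survival(self):
        counts = [5, 1, 0, 2, 4, 0]  # n=12, m=6
        angles = np.repeat(np.arange(6) * TWO_PI / 6, counts)
        s = CircularSample(angles, grouping_m=6)
        x2 = sum((c - 2) ** 2 / 2 for c in counts)
        assert chisq_pvalue(s).p_value == pytest.approx(float(sps.chi2.sf(x2, 5)), rel=1e-12)

    def test_requires_grouping_or_m(self, rng):
        s = CircularSample(rng.uniform(0, TWO_PI, 20))
        with pytest.raises(ValueError, match="ungrouped"):
            chisq_pvalue(s)
        assert 0 < chisq_pvalue(s, m=36).p_value <= 1
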