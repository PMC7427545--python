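"""Agreement statistics against independent oracles.

Each estimator is checked against a route that shares no code with it:
ANOVA mean squares computed longhand (and pingouin) for the ICC, a
Monte-Carlo prior-predictive estimate (and pingouin) for the JZS Bayes
factor, exhaustive sign-assignment enumeration for the Wilcoxon test, and
the covariance formula for the Pearson topography correlation.
"""

import numpy as np
import pytest
from scipy import stats as sst

from dualeeg import stats as ST
from dualeeg.types import ERPWaveform


def _wave(values, labels=("Fz",)):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.arange(values.shape[1], dtype=float)
    return ERPWaveform(data=values, time_ms=t, condition="x", n_epochs=1,
                       channel_labels=list(labels))


def brute_force_icc(x, model):
    """Mean-squares ICC computed longhand with explicit loops."""
    n, k = x.shape
    grand = sum(x.ravel()) / (n * k)
    msr = sum((sum(row) / k - grand) ** 2 for row in x) * k / (n - 1)
    msc = sum((sum(x[:, j]) / n - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = sum((x[i, j] - sum(x[i]) / k - sum(x[:, j]) / n + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    if model == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_waveforms_give_one(self):
        rng = np.random.default_rng(0)
        a = _wave(rng.standard_normal(100))
        icc = ST.waveform_icc(a, a, "Fz")
        assert icc.estimate == pytest.approx(1.0)

    def test_null_waveforms_straddle_zero(self):
        covered, small = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = _wave(rng.standard_normal(1000))
            b = _wave(rng.standard_normal(1000))
            icc = ST.waveform_icc(a, b, "Fz")
            small += abs(icc.estimate) < 0.1
            lo, hi = icc.ci95
            covered += lo <= 0.0 <= hi
        assert small >= 90
        assert covered >= 90

    def test_offset_penalized_only_by_absolute_model(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        x = np.column_stack([base, base + 10.0])
        absolute = ST.icc_from_table(x, "absolute")
        consistency = ST.icc_from_table(x, "consistency")
        assert absolute.estimate < consistency.estimate
        assert absolute.estimate == pytest.approx(
            brute_force_icc(x, "absolute"))
        assert consistency.estimate == pytest.approx(
            brute_force_icc(x, "consistency"))

    @pytest.mark.parametrize("model", ["absolute", "consistency"])
    def test_matches_mean_squares_oracle_small_n(self, model):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 31))
            x = rng.standard_normal((n, 2)) + rng.normal(0, 0.5, (1, 2))
            got = ST.icc_from_table(x, model).estimate
            assert got == pytest.approx(brute_force_icc(x, model), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(2)
        a = rng.standard_normal(100)
        b = a + rng.normal(0, 0.5, 100) + 0.3
        x = np.column_stack([a, b])
        df = pd.DataFrame({"targets": np.repeat(np.arange(100), 2),
                           "raters": np.tile([0, 1], 100),
                           "scores": x.ravel()})
        ref = pg.intraclass_corr(df, "targets", "raters", "scores")
        ref_a = ref.iloc[1]  # two-way random, absolute agreement, single
        assert "2" in str(ref_a.Type) or "A,1" in str(ref_a.Type)
        got = ST.icc_from_table(x, "absolute")
        assert got.estimate == pytest.approx(float(ref_a.ICC), abs=1e-9)
        assert got.ci95 == pytest.approx(tuple(ref_a["CI95"]), abs=0.01)


class TestJZSBayesFactor:
    def test_null_t_favors_null(self):
        for n in (5, 20, 100):
            assert ST.jzs_bf_from_t(0.0, n).bf10 < 1.0

    def test_matches_monte_carlo_prior_predictive(self):
        """Quadrature vs 10^6-draw Monte-Carlo estimate of the marginal
        likelihood ratio, within 2%."""
        rng = np.random.default_rng(42)
        r = np.sqrt(2) / 2
        for t, n in [(0.5, 20), (2.5, 20), (4.0, 50)]:
            delta = r * rng.standard_cauchy(10 ** 6)
            mc = (sst.nct.pdf(t, df=n - 1, nc=delta * np.sqrt(n)).mean()
                  / sst.t.pdf(t, df=n - 1))
            got = ST.jzs_bf_from_t(t, n).bf10
            assert got == pytest.approx(mc, rel=0.02)

    def test_matches_pingouin(self):
        import pingouin as pg
        for t, n in [(0.0, 20), (1.3, 12), (2.5, 20), (-3.1, 40)]:
            ref = float(pg.bayesfactor_ttest(t, n, paired=True,
                                             r=np.sqrt(2) / 2))
            assert ST.jzs_bf_from_t(t, n).bf10 == pytest.approx(ref, rel=1e-6)

    def test_monotone_in_effect_size(self):
        bfs = [ST.jzs_bf_from_t(t, 20).bf10 for t in np.arange(0, 5.01, 0.25)]
        assert np.all(np.diff(bfs) > 0)

    def test_quadrature_stable_under_grid_refinement(self):
        """Fixed-grid Simpson evaluation converges to the adaptive result."""
        from scipy.integrate import simpson
        t, n, r = 2.5, 20, np.sqrt(2) / 2
        nu = n - 1

        def integrand(g):
            dens = r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-r ** 2 / (2 * g))
            like = ((1 + n * g) ** -0.5
                    * (1 + t ** 2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2))
            return like * dens

        h0 = (1 + t ** 2 / nu) ** (-(nu + 1) / 2)
        vals = []
        for m in (200_001, 400_001):
            # compactify g in (0, inf) to u in (0, 1) so the heavy tail
            # of the prior is fully covered by the fixed grid
            u = np.linspace(1e-9, 1 - 1e-7, m)
            g = u / (1 - u)
            vals.append(simpson(integrand(g) / (1 - u) ** 2, x=u) / h0)
        assert abs(vals[1] - vals[0]) / vals[1] < 1e-6
        assert ST.jzs_bf_from_t(t, n).bf10 == pytest.approx(vals[1], rel=1e-5)

    def test_paired_differences_interface(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.8, 1.0, 25)
        res = ST.jzs_bf_ttest(d)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t_stat == pytest.approx(t)
        assert res.bf10 == pytest.approx(ST.jzs_bf_from_t(t, 25).bf10)
        with pytest.raises(ValueError, match="variance"):
            ST.jzs_bf_ttest(np.ones(10))


class TestBayes2x2:
    def test_condition_effect_detected_system_null(self):
        hits_cond, hits_sys = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            open_a = rng.lognormal(0.0, 0.3, 20)
            table = np.empty((20, 2, 2))
            for i in (0, 1):  # two systems measure the same alpha
                noise = rng.normal(1.0, 0.05, (20, 2))
                table[:, i, 0] = open_a * noise[:, 0]
                table[:, i, 1] = 5.0 * open_a * noise[:, 1]
            res = ST.bayes_2x2(table)
            hits_cond += res["condition"].bf10 > 3.0
            hits_sys += res["system"].bf10 < 1.0
        assert hits_cond >= 90
        assert hits_sys >= 90

    def test_degenerate_cells_rejected(self):
        table = np.ones((10, 2, 2))
        with pytest.raises(ValueError):
            ST.bayes_2x2(table)

    def test_factor_swap_symmetry(self):
        rng = np.random.default_rng(4)
        table = rng.standard_normal((15, 2, 2))
        res = ST.bayes_2x2(table)
        swapped = ST.bayes_2x2(np.swapaxes(table, 1, 2))
        assert res["system"].bf10 == pytest.approx(swapped["condition"].bf10)
        assert res["condition"].bf10 == pytest.approx(swapped["system"].bf10)


class TestSequentialStop:
    def test_constructed_crossing(self):
        # a stream engineered to cross the upper bound at n = 22
        rng = np.random.default_rng(0)
        base = list(rng.normal(0.4, 1.0, 20))
        stream = base + [5.0] * 8
        trace = ST.sequential_stop(stream)
        assert trace.decision in ("different", "equivalent")
        n, bf = trace.per_n[-1]
        assert trace.n_final == n
        if trace.decision == "different":
            assert bf > 3.0
        else:
            assert bf < 0.33
        for n_i, bf_i in trace.per_n[:-1]:
            assert 0.33 <= bf_i <= 3.0

    def test_no_crossing_is_undecided(self):
        # moderate effects keep the BF inside the bounds for a while;
        # scan seeds and check every undecided trace exhausts its stream
        found = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            trace = ST.sequential_stop(rng.normal(0.45, 1.0, 24))
            if trace.decision == "undecided":
                found += 1
                assert trace.n_final == 24
                assert len(trace.per_n) == 5
                assert all(0.33 <= bf <= 3.0 for _, bf in trace.per_n)
        assert found >= 1

    def test_null_streams_mostly_stop_at_equivalence(self):
        rng = np.random.default_rng(7)
        decided = {"equivalent": 0, "different": 0, "undecided": 0}
        for _ in range(500):
            trace = ST.sequential_stop(rng.standard_normal(100))
            decided[trace.decision] += 1
        n_dec = decided["equivalent"] + decided["different"]
        assert n_dec > 0
        assert decided["equivalent"] / n_dec >= 0.80

    def test_true_effect_stops_different_early(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            trace = ST.sequential_stop(rng.standard_normal(60) + 0.8)
            hits += trace.decision == "different" and trace.n_final < 60
        assert hits / 200 >= 0.90


class TestWilcoxon:
    def test_all_zero_differences_signaled(self):
        with pytest.raises(ST.AllZeroDifferencesError):
            ST.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_exact_enumeration_close_to_normal_approximation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0.5, 1.0, 12)
            y = rng.normal(0.0, 1.0, 12)
            _, p_exact = ST.wilcoxon_signed_rank(x, y, method="exact")
            _, p_norm = ST.wilcoxon_signed_rank(x, y, method="normal")
            assert abs(p_exact - p_norm) <= 0.05

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.8, 1.0, 11)
        y = rng.normal(0.0, 1.0, 11)
        _, p = ST.wilcoxon_signed_rank(x, y, method="exact")
        ref = sst.wilcoxon(x, y, method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-9)

    def test_large_shift_maximizes_z(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        z_shift, _ = ST.wilcoxon_signed_rank(x, 0.5 * x - 100.0)
        m = 30
        z_max = (m * (m + 1) / 2 - m * (m + 1) / 4) / np.sqrt(
            m * (m + 1) * (2 * m + 1) / 24)
        assert z_shift == pytest.approx(z_max)

    def test_tie_correction_applied(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]  # all differences equal -> ties
        z, p = ST.wilcoxon_signed_rank(x, y, method="normal")
        assert z > 0 and 0 < p < 1


class TestTopography:
    def test_scaled_copy_and_sign_flip(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(16)
        assert ST.topography_correlation(a, 2 * a) == pytest.approx(1.0)
        assert ST.topography_correlation(a, -a) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 16))
        num = np.mean((a - a.mean()) * (b - b.mean()))
        ref = num / (a.std() * b.std())
        assert ST.topography_correlation(a, b) == pytest.approx(ref)
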