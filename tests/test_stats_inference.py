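"""Inferential toolkit: oracle equivalences, calibration and properties.

Every non-trivial statistic is checked against an independent route:
ANCOVA against an explicit normal-equations least-squares oracle, the
Watson-Williams F against a from-scratch textbook implementation, and
the Bayes factors against dense trapezoid-rule quadrature (plus the
pingouin implementations as a third-party cross-check).
"""

import numpy as np
import pytest
from scipy import stats as sps

from reachkin import stats_inference as si

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_ancova(y, x, g):
    """Normal-equations ANCOVA: explicit design matrix + SS partitioning."""
    y = np.asarray(y, float)
    levels = list(dict.fromkeys(g))
    k = len(levels)
    n = len(y)
    # sum-to-zero coding: last level = -1 on every dummy
    G = np.zeros((n, k - 1))
    for i, lab in enumerate(g):
        j = levels.index(lab)
        if j < k - 1:
            G[i, j] = 1.0
        else:
            G[i, :] = -1.0
    cols = [np.ones(n)]
    if x is not None:
        cols.append(np.asarray(x, float))
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [G])
    bf, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    br, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    sse_full = float(np.sum((y - X_full @ bf) ** 2))
    sse_red = float(np.sum((y - X_red @ br) ** 2))
    df_err = n - X_full.shape[1]
    ss_g = sse_red - sse_full
    F = (ss_g / (k - 1)) / (sse_full / df_err)
    p = sps.f.sf(F, k - 1, df_err)
    # adjusted means at the grand covariate mean
    adj = {}
    for j, lab in enumerate(levels):
        row = [1.0] + ([float(np.mean(x))] if x is not None else [])
        gr = [0.0] * (k - 1)
        if j < k - 1:
            gr[j] = 1.0
        else:
            gr = [-1.0] * (k - 1)
        adj[lab] = float(np.array(row + gr) @ bf)
    return F, p, ss_g, sse_full, adj


def oracle_jzs_bf(t, n1, n2=None, scale=0.707, m=200_001):
    """Trapezoid-rule JZS Bayes factor on a tan-substituted grid."""
    if n2 is None:
        n_eff, df = n1, n1 - 1
    else:
        n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2
    u = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2 - 1e-9, m)
    delta = scale * np.tan(u)
    # Cauchy(0, scale) density times d delta/d u collapses to 1/pi
    # nct.pdf underflows to nan at extreme noncentrality; those points are 0
    f = np.nan_to_num(sps.nct.pdf(t, df, delta * np.sqrt(n_eff))) / np.pi
    num = np.trapezoid(f, u)
    return num / sps.t.pdf(t, df)


def oracle_corr_bf(r, n, m=100_001):
    """Trapezoid-rule Jeffreys correlation BF, uniform prior on (-1, 1)."""
    from scipy.special import hyp2f1
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, m)

    def kern(rh):
        return ((1 - rh ** 2) ** ((n - 1) / 2) * (1 - rh * r) ** (1.5 - n)
                * hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rh * r + 1) / 2))

    num = np.trapezoid(kern(rho) * 0.5, rho)
    return num / kern(0.0)


def oracle_watson_williams(groups_deg):
    """Textbook Watson-Williams F via complex resultants."""
    zs = [np.exp(1j * np.radians(np.asarray(g, float))) for g in groups_deg]
    Ri = np.array([abs(z.sum()) for z in zs])
    R = abs(np.sum([z.sum() for z in zs]))
    N = sum(len(z) for z in zs)
    k = len(zs)
    rw = Ri.sum() / N
    if rw < 0.53:
        kappa = 2 * rw + rw ** 3 + 5 * rw ** 5 / 6
    elif rw < 0.85:
        kappa = -0.4 + 1.39 * rw + 0.43 / (1 - rw)
    else:
        kappa = 1 / (rw ** 3 - 4 * rw ** 2 + 3 * rw)
    K = 1 + 3 / (8 * kappa)
    return K * ((N - k) * (Ri.sum() - R)) / ((k - 1) * (N - Ri.sum()))


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


class TestAncova:
    def _random_dataset(self, rng):
        k = int(rng.integers(2, 5))
        ns = rng.integers(4, 12, k)
        g = np.repeat([f"g{i}" for i in range(k)], ns)
        n = len(g)
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n) + 0.5 * x \
            + np.repeat(rng.normal(0, 1, k), ns)
        return y, x, g

    def test_null_case(self, rng):
        g = np.repeat(list("abc"), 20)
        y = np.tile(np.arange(20.0), 3)
        x = rng.normal(0, 1, 60)  # orthogonal covariate in expectation
        res = si.ancova(y, x, g)
        assert res.p > 0.5 and res.F < 1.5

    def test_matches_normal_equations_oracle(self, rng):
        """F, p, SS and adjusted means equal the explicit LS oracle."""
        for _ in range(50):
            y, x, g = self._random_dataset(rng)
            res = si.ancova(y, x, g)
            F, p, ss_g, sse, adj = oracle_ancova(y, x, g)
            assert res.F == pytest.approx(F, abs=1e-8, rel=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)
            assert res.ss_effect == pytest.approx(ss_g, rel=1e-8)
            assert res.ss_error == pytest.approx(sse, rel=1e-8)
            for lab in adj:
                assert res.adjusted_means[lab] == pytest.approx(
                    adj[lab], abs=1e-8)

    def test_without_covariate_is_oneway_anova(self, rng):
        y, x, g = self._random_dataset(rng)
        a = si.ancova(y, None, g)
        b = si.oneway_anova(y, g)
        assert a.F == b.F and a.df_error == b.df_error
        F, p, *_ = oracle_ancova(y, None, g)
        assert a.F == pytest.approx(F, rel=1e-8)

    def test_power_matches_noncentral_f(self):
        """Group-test rejection rate tracks the non-central-F power."""
        k, n = 3, 15
        offsets = np.repeat([0.0, 0.0, 1.0], n)
        g = np.repeat(list("abc"), n)
        N = k * n
        df1, df2 = k - 1, N - k - 1
        ncp = n * np.sum((np.array([0, 0, 1.0]) - 1 / 3) ** 2)
        crit = sps.f.isf(0.05, df1, df2)
        power = sps.ncf.sf(crit, df1, df2, ncp)
        rng = np.random.default_rng(77)
        rej = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, N)
            y = offsets + 0.5 * x + rng.normal(0, 1, N)
            if si.ancova(y, x, g).p < 0.05:
                rej += 1
        assert rej / reps == pytest.approx(power, abs=0.03)

    def test_partial_eta_sq_recomputable(self, rng):
        y, x, g = self._random_dataset(rng)
        res = si.ancova(y, x, g)
        assert res.partial_eta_sq == pytest.approx(
            res.ss_effect / (res.ss_effect + res.ss_error))

    def test_tukey_p_not_below_unadjusted(self, rng):
        y, x, g = self._random_dataset(rng)
        res = si.ancova(y, x, g)
        for ph in res.posthoc:
            p_unadj = 2 * sps.t.sf(abs(ph.t), res.df_error)
            assert ph.p_tukey >= p_unadj - 1e-12

    def test_constant_covariate_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            si.ancova([1.0, 2, 3, 4], [5.0, 5, 5, 5], ["a", "a", "b", "b"])

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            si.ancova([1.0, 2, 3], [1.0, 2, 3], ["a", "a", "b"])


# ---------------------------------------------------------------------------
# Watson-Williams
# ---------------------------------------------------------------------------


class TestWatsonWilliams:
    def test_identical_groups_give_zero_f(self):
        angles = [10.0, 25.0, 40.0, 70.0]
        res = si.watson_williams([angles, angles])
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert (res.df1, res.df2) == (1, 6)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            gs = [np.degrees(rng.vonmises(rng.uniform(-np.pi, np.pi), 4,
                                          int(rng.integers(5, 25))))
                  for _ in range(k)]
            res = si.watson_williams(gs)
            assert res.F == pytest.approx(oracle_watson_williams(gs),
                                          abs=1e-10, rel=1e-10)

    def test_null_calibration(self):
        """Type-I error 5% +- 1.5% for concentrated von Mises samples."""
        rng = np.random.default_rng(5)
        rej = 0
        reps = 5000
        for _ in range(reps):
            gs = [np.degrees(rng.vonmises(0.7, 5.0, 17)) for _ in range(3)]
            if si.watson_williams(gs).p < 0.05:
                rej += 1
        assert rej / reps == pytest.approx(0.05, abs=0.015)

    def test_low_concentration_warns(self, rng):
        gs = [np.degrees(rng.uniform(-np.pi, np.pi, 30)) for _ in range(2)]
        with pytest.warns(UserWarning, match="resultant"):
            si.watson_williams(gs)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            si.watson_williams([[10.0], [1.0, 2.0]])


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


class TestBayesFactors:
    def test_null_t_favors_null(self):
        assert si.jzs_bf_ttest(0.0, 16, 16, prior_scale=0.707).bf10 < 1

    def test_monotone_in_t(self):
        bfs = [si.jzs_bf_ttest(t, 20, 20).bf10 for t in (0.0, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("t,n1,n2,scale", [
        (0.0, 16, 16, 0.707), (1.5, 12, 18, 0.707), (2.5, 20, None, 1.0),
        (-3.0, 15, 15, 1.39), (4.2, 25, 25, 0.5),
    ])
    def test_matches_quadrature_oracle(self, t, n1, n2, scale):
        mine = si.jzs_bf_ttest(t, n1, n2, prior_scale=scale).bf10
        assert mine == pytest.approx(oracle_jzs_bf(t, n1, n2, scale),
                                     rel=1e-3)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n1, n2, scale in [(2.0, 16, 16, 0.707), (-1.2, 14, 18, 1.39)]:
            mine = si.jzs_bf_ttest(t, n1, n2, prior_scale=scale).bf10
            ref = float(pg.bayesfactor_ttest(t, n1, n2, r=scale))
            assert mine == pytest.approx(ref, rel=1e-6)

    def test_correlation_bf_null(self):
        assert si.jeffreys_bf_correlation(0.0, 18).bf10 < 1

    def test_correlation_bf_monotone(self):
        bfs = [si.jeffreys_bf_correlation(r, 18).bf10
               for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("r,n", [(0.0, 18), (0.3, 10), (0.76, 18),
                                     (-0.5, 30), (0.9, 8)])
    def test_correlation_bf_matches_oracle(self, r, n):
        mine = si.jeffreys_bf_correlation(r, n).bf10
        assert mine == pytest.approx(oracle_corr_bf(r, n), rel=5e-3)

    def test_bic_inclusion(self, rng):
        import statsmodels.api as sm
        x = rng.normal(0, 1, 50)
        noise = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 1, 50)
        full = sm.OLS(y, np.column_stack([np.ones(50), x])).fit()
        null = sm.OLS(y, np.ones(50)).fit()
        assert si.bf_inclusion_approx(full, full).bf10 == pytest.approx(1.0)
        assert si.bf_inclusion_approx(full, null).bf10 > 3
        noisy = sm.OLS(y, np.column_stack([np.ones(50), x, noise])).fit()
        assert si.bf_inclusion_approx(noisy, full).bf10 < 1

    def test_bic_inclusion_consistency(self, rng):
        """Pure-noise predictors are punished; strong effects rewarded."""
        import statsmodels.api as sm
        punished = rewarded = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 50)
            z = rng.normal(0, 1, 50)
            y_null = rng.normal(0, 1, 50)
            y_eff = x + rng.normal(0, 1, 50)
            base = np.ones(50)
            with_x = np.column_stack([base, x])
            if si.bf_inclusion_approx(
                    sm.OLS(y_null, np.column_stack([base, z])).fit(),
                    sm.OLS(y_null, base).fit()).bf10 < 1:
                punished += 1
            if si.bf_inclusion_approx(
                    sm.OLS(y_eff, with_x).fit(),
                    sm.OLS(y_eff, base).fit()).bf10 > 3:
                rewarded += 1
        assert punished / reps >= 0.95
        assert rewarded / reps >= 0.95


# ---------------------------------------------------------------------------
# Dependent correlations and basic tests
# ---------------------------------------------------------------------------


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        Z, p = si.steiger_z(0.5, 0.5, 0.3, 20)
        assert Z == 0.0 and p == pytest.approx(1.0)

    def test_sign_symmetry(self):
        Z1, _ = si.steiger_z(0.7, 0.3, 0.2, 25)
        Z2, _ = si.steiger_z(0.3, 0.7, 0.2, 25)
        assert Z1 == pytest.approx(-Z2)

    def test_null_calibration(self):
        """Type-I error 5% +- 1.5% under equal population correlations."""
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.3], [0.4, 0.3, 1.0]])
        L = np.linalg.cholesky(cov)
        rej = 0
        reps = 5000
        for _ in range(reps):
            X = rng.standard_normal((14, 3)) @ L.T
            C = np.corrcoef(X.T)
            _, p = si.steiger_z(C[0, 1], C[0, 2], C[1, 2], 14)
            if p < 0.05:
                rej += 1
        assert rej / reps == pytest.approx(0.05, abs=0.015)

    def test_non_psd_triple_warns(self):
        with pytest.warns(UserWarning, match="positive semi-definite"):
            si.steiger_z(0.9, -0.9, 0.9, 20)


class TestBasicTests:
    def test_identical_samples(self):
        x = np.arange(10.0)
        t, df, p = si.pooled_t(x, x)
        assert t == 0.0 and df == 18
        _, p_mw = si.mann_whitney(x + 0.0, x + 0.0)
        assert p_mw > 0.9

    def test_spearman_perfect_monotone(self):
        x = np.arange(10.0)
        rs, _ = si.spearman(x, np.exp(x))
        assert rs == pytest.approx(1.0)

    def test_mann_whitney_statistic_convention(self):
        # W = rank sum of sample 1 minus its minimum n1(n1+1)/2
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]
        W, _ = si.mann_whitney(x, y)
        assert W == 0.0
        W2, _ = si.mann_whitney(y, x)
        assert W2 == 12.0  # n1 * n2

    def test_experience_years_t_from_cohort(self):
        """The cohort table reproduces the printed t(30) = -7.86."""
        from reachkin import load_packaged_cohort
        from reachkin.cohort_usage import apply_inclusion, derive_history
        inc = apply_inclusion(load_packaged_cohort())
        exp_a = [derive_history(r).experience_years for r in inc["acquired"]]
        exp_c = [derive_history(r).experience_years
                 for r in inc["congenital"]]
        t, df, p = si.pooled_t(exp_a, exp_c)
        assert df == 30
        assert t == pytest.approx(-7.86, abs=0.01)
        assert p < 0.001

    def test_results_frame(self):
        frame = si.results_to_frame([
            ("t-test", -7.86, 30, 1e-8, None, None),
            {"test": "ww", "statistic": 1.9, "df": "2,48", "p": 0.15,
             "effect_size": None, "bf": None},
        ])
        assert list(frame["test"]) == ["t-test", "ww"]
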