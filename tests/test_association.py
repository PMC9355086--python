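import numpy as np
import pytest
from scipy import stats

from exoskat.association import (
    SCHEMES,
    beta_weights,
    common_rare_test,
    default_maf_cutoff,
    fit_null,
    gene_test,
    inverse_normal_transform,
    mixture_pvalue,
    permutation_pvalue,
    rare_only_test,
    skat_statistic,
    weighted_kernel_test,
    _inversion_sf,
    _liu_pvalue,
)


# ----------------------------------------------------------------------
# Inverse normal transform
# ----------------------------------------------------------------------
class TestInverseNormalTransform:
    def test_blom_scores_against_quantile_oracle(self):
        z = inverse_normal_transform([10, 20, 30, 40, 50])
        expected_probs = (np.arange(1, 6) - 0.375) / 5.25
        assert z == pytest.approx(stats.norm.ppf(expected_probs), abs=1e-12)
        assert expected_probs == pytest.approx([0.119, 0.310, 0.5, 0.690, 0.881], abs=1e-3)

    def test_mean_zero_and_monotone(self, rng):
        v = rng.exponential(size=501)
        z = inverse_normal_transform(v)
        assert abs(z.mean()) < 1e-8
        order = np.argsort(v)
        assert np.all(np.diff(z[order]) > 0)

    def test_ties_get_average_ranks(self):
        z = inverse_normal_transform([1.0, 1.0, 5.0])
        assert z[0] == z[1] < z[2]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([3.0, 3.0, 3.0])


# ----------------------------------------------------------------------
# Null model
# ----------------------------------------------------------------------
class TestFitNull:
    def test_perfect_fit_gives_zero_residuals_and_p_one(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ np.array([1.0, 2.0])
        null = fit_null(y, X)
        assert np.allclose(null.resid, 0.0)
        assert null.sigma2 == 0.0
        G = rng.binomial(2, 0.3, (30, 2)).astype(float)
        res = weighted_kernel_test(G, np.ones(2), null)
        assert res.p == 1.0

    def test_intercept_only_centres(self, rng):
        y = rng.normal(size=50)
        null = fit_null(y, np.ones((50, 1)))
        assert null.resid == pytest.approx(y - y.mean())
        assert null.sigma2 == pytest.approx(y.var(ddof=1))

    def test_ols_recovers_coefficients(self, rng):
        n = 10_000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        beta = np.array([0.5, -1.0, 0.25, 2.0])
        y = X @ beta + rng.normal(size=n)
        null = fit_null(y, X)
        se = np.sqrt(null.sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(null.coef - beta) < 3 * se)
        assert np.allclose(null.X.T @ null.resid, 0.0, atol=1e-6)

    def test_collinear_column_dropped_with_warning(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x, 2 * x])
        with pytest.warns(UserWarning, match="collinear"):
            null = fit_null(rng.normal(size=40), X)
        assert null.rank == 2
        assert len(null.dropped) == 1


# ----------------------------------------------------------------------
# Weights and cutoffs
# ----------------------------------------------------------------------
class TestWeights:
    def test_flat_weights(self):
        assert beta_weights([0.01, 0.2, 0.5], 1, 1) == pytest.approx([1, 1, 1])

    def test_arcsine_density_closed_form(self):
        # f(x; 0.5, 0.5) = 1 / (pi sqrt(x(1-x))); at x = 1/2 this is 2/pi
        assert beta_weights([0.5], 0.5, 0.5)[0] == pytest.approx(2 / np.pi)

    def test_rare_upweighting_order(self):
        w = beta_weights([0.001, 0.01, 0.1], 0.5, 20)
        assert w[0] > w[1] > w[2]

    def test_zero_maf_rejected_for_divergent_density(self):
        with pytest.raises(ValueError):
            beta_weights([0.0, 0.1], 0.5, 20)

    def test_default_cutoff(self):
        assert default_maf_cutoff(192_633) == pytest.approx(0.0016, abs=5e-5)
        assert default_maf_cutoff(50_000) == pytest.approx(1 / np.sqrt(100_000))
        n = np.array([100, 1000, 10_000, 100_000])
        cut = [default_maf_cutoff(v) for v in n]
        assert np.all(np.diff(cut) < 0)


# ----------------------------------------------------------------------
# Kernel statistic
# ----------------------------------------------------------------------
class TestSkatStatistic:
    def test_single_variant_is_squared_score(self, rng):
        n = 60
        g = rng.binomial(2, 0.3, n).astype(float)
        null = fit_null(rng.normal(size=n), np.ones((n, 1)))
        Q, lam = skat_statistic(g[:, None], [1.0], null)
        assert Q == pytest.approx(float(g @ null.resid) ** 2)
        assert len(lam) == 1

    def test_weight_scale_equivariance(self, rng):
        n, m = 80, 4
        G = rng.binomial(2, 0.25, (n, m)).astype(float)
        null = fit_null(rng.normal(size=n), np.ones((n, 1)))
        w = rng.uniform(0.5, 2.0, m)
        Q1, lam1 = skat_statistic(G, w, null)
        Q2, lam2 = skat_statistic(G, 3.0 * w, null)
        assert Q2 == pytest.approx(9.0 * Q1)
        assert lam2 == pytest.approx(9.0 * lam1)
        assert mixture_pvalue(Q1, lam1)[0] == pytest.approx(mixture_pvalue(Q2, lam2)[0], abs=1e-9)

    def test_all_zero_variance_raises(self, rng):
        G = np.ones((20, 2))
        null = fit_null(rng.normal(size=20), np.ones((20, 1)))
        with pytest.raises(ValueError):
            skat_statistic(G, [1.0, 1.0], null)

    def test_joint_sample_permutation_leaves_result_unchanged(self, rng):
        n, m = 70, 3
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        perm = rng.permutation(n)
        Q1, lam1 = skat_statistic(G, np.ones(m), fit_null(y, X))
        Q2, lam2 = skat_statistic(G[perm], np.ones(m), fit_null(y[perm], X[perm]))
        assert Q1 == pytest.approx(Q2)
        assert lam1 == pytest.approx(lam2)

    def test_orthogonal_covariate_leaves_test_essentially_unchanged(self, rng):
        """A covariate orthogonal to the design, phenotype and genotypes
        leaves Q and the kernel eigen-structure exactly unchanged; the
        p-value moves only through the residual-variance denominator
        (n - rank), an O(1/n) effect."""
        n, m = 200, 3
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        null = fit_null(y, X)
        # a covariate orthogonal to X, the phenotype, and every genotype column
        v = rng.normal(size=n)
        M = np.column_stack([X, y, G])
        v -= M @ np.linalg.lstsq(M, v, rcond=None)[0]
        null2 = fit_null(y, np.column_stack([X, v]))
        Q1, lam1 = skat_statistic(G, np.ones(m), null)
        Q2, lam2 = skat_statistic(G, np.ones(m), null2)
        assert Q1 == pytest.approx(Q2, rel=1e-10)
        dof_ratio = (n - null2.rank) / (n - null.rank)
        assert lam2 * dof_ratio == pytest.approx(lam1, rel=1e-8)
        p1 = mixture_pvalue(Q1, lam1)[0]
        p2 = mixture_pvalue(Q2, lam2)[0]
        assert p1 == pytest.approx(p2, abs=5.0 / n)


# ----------------------------------------------------------------------
# Mixture-of-chi-squares p-values
# ----------------------------------------------------------------------
class TestMixturePvalue:
    def test_single_eigenvalue_matches_chi2_quantile(self):
        p, method = mixture_pvalue(3.841459, [1.0])
        assert p == pytest.approx(0.05, abs=1e-6)
        assert method == "exact_inversion"

    @pytest.mark.parametrize("k,c,q", [(3, 2.0, 10.0), (7, 0.5, 2.0), (1, 4.0, 30.0)])
    def test_equal_eigenvalues_scale_to_chi2(self, k, c, q):
        p, _ = mixture_pvalue(q, [c] * k)
        assert p == pytest.approx(stats.chi2.sf(q / c, k), rel=1e-6)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            mixture_pvalue(-1.0, [1.0])

    def test_no_positive_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            mixture_pvalue(1.0, [0.0, 0.0])

    def test_cross_method_agreement_in_tail(self, rng):
        """Inversion and the 4-moment approximation agree to 1e-3 for tail
        p-values (p <= 1e-2; the moment approximation targets the tail and
        is looser in the bulk)."""
        checked = 0
        for _ in range(300):
            k = int(rng.integers(1, 21))
            lam = np.sort(np.exp(rng.uniform(np.log(1e-2), np.log(10), k)))[::-1]
            q = float(rng.uniform(1.5, 6.0) * lam.sum())
            p_inv = _inversion_sf(q, lam)
            if 1e-4 < p_inv <= 1e-2:
                assert abs(p_inv - _liu_pvalue(q, lam)) < 1e-3
                checked += 1
        assert checked >= 30

    def test_inversion_matches_parametric_monte_carlo(self, rng):
        """Brute-force oracle: simulate Gaussian residuals and recompute Q.

        The Monte-Carlo law of Q under Gaussian errors IS the mixture, so
        this validates the eigenvalue + inversion path end to end.
        """
        n, m = 100, 5
        G = rng.binomial(2, rng.uniform(0.05, 0.45, m), (n, m)).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        null = fit_null(rng.normal(size=n), X)
        w = rng.uniform(5, 35, m)
        Q, lam = skat_statistic(G, w, null)
        p_mix, _ = mixture_pvalue(Q, lam)

        B, count, done = 200_000, 0, 0
        C = G * w
        sd = np.sqrt(null.sigma2)
        while done < B:
            b = min(50_000, B - done)
            eps = rng.normal(0.0, sd, (b, n))
            eps -= (eps @ null.basis) @ null.basis.T
            S = eps @ C
            count += int((np.einsum("ij,ij->i", S, S) >= Q).sum())
            done += b
        p_mc = (1 + count) / (1 + B)
        se = np.sqrt(p_mc * (1 - p_mc) / B)
        assert abs(p_mix - p_mc) <= 3 * se

    def test_permutation_oracle_agreement_to_finite_sample_order(self, rng):
        """Residual permutation is a distinct null law that approaches the
        Gaussian mixture at rate O(1/n); agreement is asserted at that
        scale (2 Monte-Carlo SE plus a 1.5/n finite-sample allowance)."""
        for i in range(3):
            n, m = 100, int(rng.integers(3, 7))
            G = rng.binomial(2, rng.uniform(0.1, 0.45, m), (n, m)).astype(float)
            null = fit_null(rng.normal(size=n), np.ones((n, 1)))
            Q, lam = skat_statistic(G, np.ones(m), null)
            p_mix, _ = mixture_pvalue(Q, lam)
            B = 50_000
            p_perm = permutation_pvalue(G, np.ones(m), null, n_perm=B,
                                        rng=np.random.default_rng(300 + i))
            se = np.sqrt(p_perm * (1 - p_perm) / B)
            assert abs(p_mix - p_perm) <= 2 * se + 1.5 / n


# ----------------------------------------------------------------------
# Scheme-level tests
# ----------------------------------------------------------------------
class TestSchemeTests:
    def _setup(self, rng, maf):
        n = 300
        m = len(maf)
        G = rng.binomial(2, np.asarray(maf), (n, m)).astype(float)
        null = fit_null(rng.normal(size=n), np.ones((n, 1)))
        return G, null

    def test_common_rare_all_rare_equals_single_kernel(self, rng):
        # all empirical MAFs fall below the default cutoff 1/sqrt(2n)=0.041
        maf = [0.005, 0.01, 0.02]
        G, null = self._setup(rng, maf)
        from exoskat.annotation import dosage_maf

        emp_maf, _ = dosage_maf(G)
        scheme = SCHEMES["commonrare_unweighted"]
        res = common_rare_test(G, emp_maf, scheme, null)
        w = beta_weights(emp_maf, *scheme.rare_beta)
        ref = weighted_kernel_test(G, w, null)
        assert res.n_variants_common == 0
        assert res.Q == pytest.approx(ref.Q)
        assert res.p == pytest.approx(ref.p, abs=1e-9)

    def test_common_rare_all_common_equals_single_kernel(self, rng):
        maf = [0.2, 0.3, 0.4]
        G, null = self._setup(rng, maf)
        from exoskat.annotation import dosage_maf

        emp_maf, _ = dosage_maf(G)
        scheme = SCHEMES["commonrare_weighted"]
        res = common_rare_test(G, emp_maf, scheme, null)
        w = beta_weights(emp_maf, *scheme.common_beta)
        ref = weighted_kernel_test(G, w, null)
        assert res.n_variants_rare == 0
        assert res.Q == pytest.approx(ref.Q)
        assert res.p == pytest.approx(ref.p, abs=1e-9)

    def test_unweighted_scheme_equals_flat_beta_weights(self, rng):
        maf = [0.05, 0.2, 0.4]
        G, null = self._setup(rng, maf)
        from exoskat.annotation import dosage_maf

        emp_maf, _ = dosage_maf(G)
        res = gene_test(G, emp_maf, np.zeros(3), "unweighted", null)
        ref = weighted_kernel_test(G, beta_weights(emp_maf, 1, 1), null)
        assert res.Q == pytest.approx(ref.Q)
        assert res.p == pytest.approx(ref.p, abs=1e-10)

    def test_rare_only_empty_restriction_is_no_test(self, rng):
        maf = [0.2, 0.3]
        G, null = self._setup(rng, maf)
        res = rare_only_test(G, np.array(maf), 0.0001, null)
        assert res.status == "no_test"

    def test_rare_only_variant_count_nesting(self, rng):
        maf = np.array([0.0005, 0.004, 0.02, 0.3])
        n = 5000
        G = rng.binomial(2, maf, (n, len(maf))).astype(float)
        null = fit_null(rng.normal(size=n), np.ones((n, 1)))
        counts = []
        for cutoff in (0.001, 0.005, 0.05, 0.4):
            res = rare_only_test(G, maf, cutoff, null)
            counts.append(res.n_variants_rare if res.status == "ok" else 0)
        assert counts == sorted(counts)

    def test_cadd_scheme_uses_scores_as_weights(self, rng):
        maf = [0.1, 0.2]
        G, null = self._setup(rng, maf)
        from exoskat.annotation import dosage_maf

        emp_maf, _ = dosage_maf(G)
        cadd = np.array([12.0, 30.0])
        res = gene_test(G, emp_maf, cadd, "cadd", null)
        ref = weighted_kernel_test(G, cadd, null)
        assert res.Q == pytest.approx(ref.Q)


def test_rare_driven_gene_detected_by_rare_only(standard_discovery):
    """A rare-driven gene's unconditioned RareOnly cascade clears the
    exome-wide Bonferroni threshold at some cutoff, and the best cutoff
    sits just above the causal frequency band (here 0.1%): looser cutoffs
    admit more neutral low-frequency variants and dilute the signal."""
    res, truth = standard_discovery
    cascade = res.cascade
    for gene in truth.genes_with("rare_driven"):
        sub = cascade[(cascade["gene"] == gene) & ~cascade["conditioned"]
                      & (cascade["status"] == "ok")]
        best = sub.loc[sub["p"].idxmin()]
        assert best["p"] < 5.18e-7
        assert best["cutoff"] <= 0.005
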