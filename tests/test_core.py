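"""Global epistasis test: partitioned correlations, the greatest-root
statistic, Johnstone's centering/scaling, and the fitted model chain."""

import numpy as np
import pytest
import scipy.linalg

from epiget import (BinaryPhenotype, CovariateMatrix, GenotypeMatrix,
                    GlobalEpistasisTest, PartitionedCorrelations,
                    centering_and_scaling, global_epistasis_test,
                    greatest_root, partitioned_correlations, tw1_sf)
from epiget.exceptions import (AngleDomainError, DegenerateMarkerError,
                               InvalidInputError, PartitionTooSmallError)


def random_correlation(p, rng):
    a = rng.standard_normal((p + 5, p))
    c = np.corrcoef(a, rowvar=False)
    return c


# ---------------------------------------------------------------------------
# partitioned correlations
# ---------------------------------------------------------------------------

class TestPartitionedCorrelations:
    def test_matches_numpy_corrcoef_per_partition(self, small_dataset):
        g, y = small_dataset
        pc = partitioned_correlations(g, y)
        mask = y.case_mask()
        np.testing.assert_allclose(
            pc.s_case, np.corrcoef(g.values[mask], rowvar=False), atol=1e-12)
        np.testing.assert_allclose(
            pc.s_control, np.corrcoef(g.values[~mask], rowvar=False),
            atol=1e-12)
        assert pc.d == y.d and pc.n == y.n and not pc.partial

    def test_duplicated_marker_gives_unit_off_diagonal(self, rng):
        col = rng.integers(0, 3, size=100)
        g = GenotypeMatrix(values=np.column_stack([col, col,
                                                   rng.integers(0, 3, 100)]))
        y = BinaryPhenotype(values=np.tile([0, 1], 50))
        pc = partitioned_correlations(g, y)
        assert pc.s_case[0, 1] == pytest.approx(1.0)
        assert pc.s_control[0, 1] == pytest.approx(1.0)

    def test_partial_correlation_matches_precision_matrix_oracle(self, rng):
        # oracle: for each marker pair, the partial correlation given the
        # covariates from the inverse covariance of [g_i, g_j, C]
        n, p, k = 400, 4, 2
        g = GenotypeMatrix(values=rng.integers(0, 3, size=(n, p)))
        c = CovariateMatrix(values=rng.standard_normal((n, k)))
        y = BinaryPhenotype(values=np.tile([0, 1], n // 2))
        pc = partitioned_correlations(g, y, c)
        assert pc.partial
        for mask, s in ((y.case_mask(), pc.s_case),
                        (~y.case_mask(), pc.s_control)):
            for i in range(p):
                for j in range(i + 1, p):
                    z = np.column_stack([g.values[mask][:, [i, j]].astype(float),
                                         c.values[mask]])
                    prec = np.linalg.inv(np.cov(z, rowvar=False))
                    oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
                    assert s[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_independent_covariates_barely_change_correlations(self, rng):
        n = 2000
        g = GenotypeMatrix(values=rng.integers(0, 3, size=(n, 5)))
        c = CovariateMatrix(values=rng.standard_normal((n, 2)))
        y = BinaryPhenotype(values=np.tile([0, 1], n // 2))
        plain = partitioned_correlations(g, y)
        adj = partitioned_correlations(g, y, c)
        assert np.max(np.abs(plain.s_case - adj.s_case)) < 5 / np.sqrt(n)

    def test_degenerate_marker_raises_naming_it(self, rng):
        vals = rng.integers(0, 3, size=(60, 3))
        y = BinaryPhenotype(values=np.tile([0, 1], 30))
        vals[y.values == 1, 1] = 2  # constant among cases only
        g = GenotypeMatrix(values=vals, marker_ids=("a", "b", "c"))
        with pytest.raises(DegenerateMarkerError, match="'b'.*cases"):
            partitioned_correlations(g, y)

    def test_drop_degenerate_drops_from_both_matrices(self, rng):
        vals = rng.integers(0, 3, size=(60, 3))
        y = BinaryPhenotype(values=np.tile([0, 1], 30))
        vals[y.values == 1, 1] = 2
        g = GenotypeMatrix(values=vals, marker_ids=("a", "b", "c"))
        with pytest.warns(UserWarning, match="dropping 1"):
            pc = partitioned_correlations(g, y, drop_degenerate=True)
        assert pc.p == 2 and pc.marker_ids == ("a", "c")

    def test_partition_too_small(self, rng):
        g = GenotypeMatrix(values=rng.integers(0, 3, size=(10, 3)))
        y = BinaryPhenotype(values=np.array([1] + [0] * 9))
        with pytest.raises(PartitionTooSmallError):
            partitioned_correlations(g, y)


# ---------------------------------------------------------------------------
# greatest root
# ---------------------------------------------------------------------------

class TestGreatestRoot:
    def test_identity_matrices_balanced(self):
        pc = PartitionedCorrelations(s_case=np.eye(6), s_control=np.eye(6),
                                     d=50, n=100)
        assert greatest_root(pc) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("d,n", [(30, 100), (50, 100), (80, 100)])
    def test_equal_matrices_give_case_fraction(self, d, n, rng):
        # S1 = S0 = S makes the pencil proportional to the identity, so
        # every eigenvalue equals d/n (the case-weighted numerator share)
        s = random_correlation(5, np.random.default_rng(7))
        pc = PartitionedCorrelations(s_case=s, s_control=s, d=d, n=n)
        assert greatest_root(pc) == pytest.approx(d / n, abs=1e-12)

    def test_matches_brute_force_inversion_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            s1 = random_correlation(5, rng)
            s0 = random_correlation(5, rng)
            d, n = int(rng.integers(10, 90)), 100
            pc = PartitionedCorrelations(s_case=s1, s_control=s0, d=d, n=n)
            lam = greatest_root(pc)
            brute = np.linalg.inv(d * s1 + (n - d) * s0) @ (d * s1)
            lam_oracle = np.max(np.linalg.eigvals(brute).real)
            assert lam == pytest.approx(lam_oracle, abs=1e-10)
            assert 0.0 < lam < 1.0


# ---------------------------------------------------------------------------
# centering and scaling
# ---------------------------------------------------------------------------

def _mu_sigma_duplicate(p, n1, n2):
    """Independent transcription of the trigonometric formulas using the
    cos-based half-angle identities instead of arcsin/tan."""
    s = n1 + n2 - 1
    cos_gamma = 1.0 - 2.0 * (min(p, n2) - 0.5) / s
    cos_phi = 1.0 - 2.0 * (max(p, n2) - 0.5) / s
    gamma, phi = np.arccos(cos_gamma), np.arccos(cos_phi)
    tot = gamma + phi
    mu = 2.0 * np.log((1.0 - np.cos(tot)) / np.sin(tot))
    sigma3 = 16.0 / (s ** 2 * np.sin(tot) ** 2 * np.sin(phi) * np.sin(gamma))
    return mu, sigma3 ** (1.0 / 3.0)

class TestCenteringScaling:
    @pytest.mark.parametrize("p,n1,n2", [(10, 100, 100), (50, 500, 500),
                                         (100, 250, 250), (5, 20, 35),
                                         (50, 2000, 2000)])
    def test_matches_duplicate_transcription(self, p, n1, n2):
        mu, sigma = centering_and_scaling(p, n1, n2)
        mu2, sigma2 = _mu_sigma_duplicate(p, n1, n2)
        assert mu == pytest.approx(mu2, abs=1e-12)
        assert sigma == pytest.approx(sigma2, abs=1e-12)
        assert sigma > 0

    def test_asymmetric_in_n1_n2_but_symmetric_when_equal(self):
        assert centering_and_scaling(20, 200, 300) != \
            centering_and_scaling(20, 300, 200)
        assert centering_and_scaling(20, 250, 250) == \
            centering_and_scaling(20, 250, 250)

    def test_angle_domain_error_when_p_too_large(self):
        with pytest.raises(AngleDomainError):
            centering_and_scaling(500, 100, 100)
        with pytest.raises(InvalidInputError):
            centering_and_scaling(1, 100, 100)


# ---------------------------------------------------------------------------
# the fitted test
# ---------------------------------------------------------------------------

class TestGlobalEpistasisTest:
    def test_result_chain_is_consistent(self, small_dataset):
        g, y = small_dataset
        res = GlobalEpistasisTest(g, y).fit()
        logit = np.log(res.lambda1 / (1 - res.lambda1))
        assert res.statistic == pytest.approx((logit - res.mu) / res.sigma)
        assert res.pvalue == pytest.approx(tw1_sf(res.statistic))
        assert 0 < res.lambda1 < 1
        assert res.n_cases + res.n_controls == y.n

    def test_deterministic_and_invariant_to_marker_order(self, small_dataset):
        g, y = small_dataset
        res1 = global_epistasis_test(g, y)
        res2 = global_epistasis_test(g, y)
        assert res1 == res2
        perm = np.random.default_rng(0).permutation(g.n_markers)
        gp = GenotypeMatrix(values=g.values[:, perm])
        res3 = global_epistasis_test(gp, y)
        assert res3.lambda1 == pytest.approx(res1.lambda1, abs=1e-10)
        assert res3.statistic == pytest.approx(res1.statistic, abs=1e-8)

    def test_invariant_to_subject_order(self, small_dataset):
        g, y = small_dataset
        res1 = global_epistasis_test(g, y)
        perm = np.random.default_rng(1).permutation(y.n)
        res2 = global_epistasis_test(
            GenotypeMatrix(values=g.values[perm]),
            BinaryPhenotype(values=y.values[perm]))
        assert res2.lambda1 == pytest.approx(res1.lambda1, abs=1e-12)

    def test_relabeling_cases_and_controls_changes_statistic(self,
                                                             interaction_dataset):
        g, y = interaction_dataset
        res = global_epistasis_test(g, y)
        flipped = global_epistasis_test(
            g, BinaryPhenotype(values=1 - y.values))
        # weights swap between the two correlation matrices: different test
        assert res.statistic != pytest.approx(flipped.statistic, abs=1e-6)

    def test_identical_case_control_rows_force_exact_statistic(self):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 3, size=(120, 6))
        g = GenotypeMatrix(values=np.vstack([block, block]))
        y = BinaryPhenotype(values=np.r_[np.ones(120, int),
                                         np.zeros(120, int)])
        res = global_epistasis_test(g, y)
        # S1 == S0 exactly, so lambda1 = d/n and T is fully determined
        mu, sigma = centering_and_scaling(6, 120, 120)
        expected_t = (np.log(0.5 / 0.5) - mu) / sigma
        assert res.lambda1 == pytest.approx(0.5, abs=1e-12)
        assert res.statistic == pytest.approx(expected_t, abs=1e-8)

    def test_warns_in_low_n_over_p_regime(self, rng):
        g = GenotypeMatrix(values=rng.integers(0, 3, size=(60, 20)))
        y = BinaryPhenotype(values=np.tile([0, 1], 30))
        with pytest.warns(UserWarning, match="n/p"):
            global_epistasis_test(g, y)

    def test_from_dataframe_constructor(self, small_dataset):
        g, y = small_dataset
        df = g.to_dataframe().reset_index(drop=True)
        df["status"] = y.values
        res = GlobalEpistasisTest.from_dataframe(df, phenotype="status").fit()
        assert res == global_epistasis_test(g, y)

    def test_summary_mentions_key_quantities(self, small_dataset):
        g, y = small_dataset
        res = GlobalEpistasisTest(g, y).fit()
        text = res.summary()
        assert "lambda1" in text and "p-value" in text
        frame = res.to_frame()
        assert frame.loc[0, "p_value"] == res.pvalue

    def test_interaction_data_is_detected(self, interaction_dataset):
        # five SNPs, one strong (log 3) interaction, 500/500: the case and
        # control LD structures differ markedly, so the p-value is small
        g, y = interaction_dataset
        res = global_epistasis_test(g, y)
        assert res.pvalue < 0.05
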