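import math

import numpy as np
import pytest

from gcgwas.datatypes import MISSING, GenotypeMatrix
from gcgwas.kinship import RelationshipMatrix, build_a_matrix
from gcgwas.mt_gwas import (
    QCError,
    TraitMatrix,
    VarianceComponents,
    allele_frequencies,
    bh_fdr,
    genetic_parameters,
    hwe_exact_test,
    qc_filter,
    reml_null,
    snp_scan,
    variance_explained,
)
from gcgwas.synthetic_data import SimConfig, simulate_families, simulate_growth_phenotypes


def _geno(codes, chrom=None, bp=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return GenotypeMatrix(
        [f"a{i}" for i in range(n)], [f"s{j}" for j in range(m)], codes,
        np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        np.array(bp if bp is not None else np.arange(1, m + 1) * 1000),
    )


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Brute-force enumeration of the conditional heterozygote distribution."""
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    rare = min(n_a, n_b)
    if rare == 0 or (n_hom1 + n_het + n_hom2) == 0:
        return 1.0
    hets = list(range(rare % 2, rare + 1, 2))
    weights = []
    for h in hets:
        weights.append(
            math.exp(h * math.log(2) - math.lgamma(h + 1)
                     - math.lgamma((n_a - h) / 2 + 1)
                     - math.lgamma((n_b - h) / 2 + 1))
        )
    total = sum(weights)
    p_obs = weights[hets.index(n_het)]
    return sum(w for w in weights if w <= p_obs * (1 + 1e-12)) / total


class TestHwe:
    @pytest.mark.parametrize("counts", [(3, 5, 2), (0, 10, 0), (10, 1, 10),
                                        (50, 20, 5), (7, 0, 7)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-12
        )

    def test_monomorphic_and_empty(self):
        assert hwe_exact_test(5, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 0) == 1.0

    def test_gross_violation_is_tiny(self):
        # only homozygotes at intermediate frequency: extreme het deficit
        assert hwe_exact_test(250, 0, 250) < 1e-7


class TestAlleleFrequencies:
    def test_examples(self):
        g = _geno([[0, 2, 0], [1, 2, 0], [2, 2, MISSING]])
        p = allele_frequencies(g)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(1.0)
        assert p[2] == pytest.approx(0.0)

    def test_with_missing(self):
        g = _geno([[0], [0], [1], [2], [MISSING]])
        assert allele_frequencies(g)[0] == pytest.approx(3 / 8)

    def test_all_missing_is_nan(self):
        g = _geno([[MISSING], [MISSING]])
        assert np.isnan(allele_frequencies(g)[0])


class TestQc:
    def test_low_call_snp_removed(self):
        rng = np.random.default_rng(20)
        codes = rng.integers(0, 3, size=(100, 25)).astype(np.int8)
        codes[:10, 0] = MISSING  # 10% missing on s0, 4% per animal: SNP filter fires
        out, report = qc_filter(_geno(codes), {"hwe_p": 0.0})
        assert report.animals_removed_call == []
        assert "s0" in report.snps_removed_call
        assert "s0" not in out.snp_ids and out.n_snps == 24

    def test_monomorphic_removed_at_maf(self):
        codes = np.column_stack([
            np.zeros(100, dtype=np.int8),
            np.tile([0, 1, 2, 1], 25).astype(np.int8),
        ])
        out, report = qc_filter(_geno(codes), {"hwe_p": 0.0})
        assert "s0" in report.snps_removed_maf and out.snp_ids == ["s1"]

    def test_hwe_violation_removed(self):
        # 250/0/250: MAF fine, HWE exact p << 1e-7
        codes = np.concatenate([np.zeros(250), np.full(250, 2)]).astype(np.int8)
        good = np.tile([0, 1, 2, 1], 125).astype(np.int8)
        out, report = qc_filter(_geno(np.column_stack([codes, good])))
        assert report.snps_removed_hwe == ["s0"] and out.snp_ids == ["s1"]

    def test_low_call_individual_removed(self):
        rng = np.random.default_rng(21)
        codes = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        codes[0, :5] = MISSING  # 25% missing for a0
        out, report = qc_filter(_geno(codes), {"hwe_p": 0.0})
        assert report.animals_removed_call == ["a0"]
        assert out.n_animals == 49

    def test_all_removed_raises_with_report(self):
        codes = np.zeros((50, 2), dtype=np.int8)  # both monomorphic
        with pytest.raises(QCError) as err:
            qc_filter(_geno(codes))
        assert err.value.report.n_snps_out == 0


class TestBhFdr:
    def test_hand_step_up(self):
        q, sig, raw = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert sig.all()

    def test_single_and_degenerate(self):
        q, sig, _ = bh_fdr(np.array([0.2]))
        assert q[0] == pytest.approx(0.2) and not sig[0]
        q, sig, _ = bh_fdr(np.ones(5))
        assert (q == 1).all() and not sig.any()

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(size=200)
        q, sig, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        q2, sig2, _ = bh_fdr(q)
        assert (sig2 >= sig).all() or set(np.flatnonzero(sig)) == set(np.flatnonzero(sig2))

    def test_secondary_raw_flag(self):
        _, _, raw = bh_fdr(np.array([5e-4, 0.002]))
        assert raw.tolist() == [True, False]


class TestVarianceExplained:
    def test_single_nonzero_gets_all(self):
        v = variance_explained(np.array([0.0, 2.0, 0.0]), np.full(3, 0.5))
        np.testing.assert_allclose(v, [0.0, 100.0, 0.0])

    def test_two_equal_snps_split(self):
        v = variance_explained(np.array([1.0, 1.0]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(v, [50.0, 50.0])

    def test_monomorphic_contributes_zero(self):
        v = variance_explained(np.array([5.0, 1.0]), np.array([1.0, 0.5]))
        assert v[0] == 0.0 and v[1] == 100.0

    def test_sums_to_hundred(self):
        rng = np.random.default_rng(23)
        v = variance_explained(rng.normal(size=300), rng.uniform(0.05, 0.95, 300))
        assert v.sum() == pytest.approx(100.0, abs=1e-9)
        assert (v >= 0).all()

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            v = variance_explained(np.zeros(3), np.full(3, 0.5))
        assert (v == 0).all()


def _fullsib_data(nf, no, Su, Se, seed):
    """Balanced full-sib families with known multivariate components."""
    rng = np.random.default_rng(seed)
    k = Su.shape[0]
    Lu = np.linalg.cholesky(Su + 1e-12 * np.eye(k))
    Le = np.linalg.cholesky(Se)
    n = nf * no
    ids = [f"a{i}" for i in range(n)]
    A = np.zeros((n, n))
    Y = np.zeros((n, k))
    for f in range(nf):
        par = rng.standard_normal((2, k)) @ Lu.T
        for o in range(no):
            i = f * no + o
            u = 0.5 * (par[0] + par[1]) + math.sqrt(0.5) * rng.standard_normal(k) @ Lu.T
            Y[i] = u + rng.standard_normal(k) @ Le.T
        A[f * no:(f + 1) * no, f * no:(f + 1) * no] = 0.5 + 0.5 * np.eye(no)
    return TraitMatrix(ids, Y, tuple("T%d" % j for j in range(k)) if k != 3 else ("A", "b", "K")), RelationshipMatrix(ids, A)


class TestReml:
    def test_single_trait_matches_anova_sib_estimator(self):
        # balanced full-sib ANOVA: sigma_u^2 ~ 2*(MSB - MSW)/n_off
        rng = np.random.default_rng(24)
        nf, no, s2u, s2e = 200, 8, 1.0, 2.0
        Y = np.zeros((nf, no))
        for f in range(nf):
            fam = math.sqrt(s2u / 2) * rng.standard_normal()
            Y[f] = fam + rng.standard_normal(no) * math.sqrt(s2u / 2 + s2e)
        msb = no * Y.mean(axis=1).var(ddof=1)
        msw = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum() / (nf * (no - 1))
        anova_u = 2.0 * (msb - msw) / no  # full-sib covariance = sigma_u^2/2
        n = nf * no
        ids = [f"a{i}" for i in range(n)]
        A = np.zeros((n, n))
        for f in range(nf):
            A[f * no:(f + 1) * no, f * no:(f + 1) * no] = 0.5 + 0.5 * np.eye(no)
        y = TraitMatrix(ids, Y.reshape(-1, 1), ("A",))
        vc = reml_null(y, RelationshipMatrix(ids, A))
        assert vc.converged
        se_mc = 0.25  # Monte-Carlo scale for this design
        assert abs(vc.sigma_u[0, 0] - anova_u) < 3 * se_mc

    def test_three_trait_recovery(self):
        Su = np.array([[1.0, 0.3, -0.2], [0.3, 0.8, 0.1], [-0.2, 0.1, 0.5]])
        Se = np.diag([2.0, 1.5, 1.0])
        y, rel = _fullsib_data(100, 8, Su, Se, seed=25)
        vc = reml_null(y, rel)
        assert vc.converged
        # fixed tolerances sized to ~3 Monte-Carlo SEs for this design
        assert np.abs(vc.sigma_u - Su).max() < 0.6
        assert np.abs(vc.sigma_e - Se).max() < 0.5

    def test_null_genetic_variance_small(self):
        Su = np.zeros((3, 3))
        Se = np.diag([2.0, 1.5, 1.0])
        y, rel = _fullsib_data(100, 6, np.eye(3) * 1e-10, Se, seed=26)
        vc = reml_null(y, rel)
        total = np.diag(vc.sigma_u) + np.diag(vc.sigma_e)
        assert (np.diag(vc.sigma_u) / total < 0.08).all()

    def test_loglik_monotone(self):
        Su = np.array([[1.0, 0.5], [0.5, 1.0]])
        Se = np.eye(2) * 2
        y, rel = _fullsib_data(50, 6, Su, Se, seed=27)
        vc = reml_null(y, rel)
        path = np.array(vc.loglik_path)
        assert np.all(np.diff(path) >= -1e-6 * np.maximum(1, np.abs(path[:-1])))

    def test_genetic_parameters_examples(self):
        vc = VarianceComponents(np.eye(3), np.eye(3) * 3, 0.0, True, 1)
        gp = genetic_parameters(vc)
        assert all(v == pytest.approx(0.25) for v in gp.h2.values())
        assert all(v == pytest.approx(0.0) for v in gp.rg.values())
        su = np.eye(3)
        su[0, 1] = su[1, 0] = 0.5
        gp = genetic_parameters(VarianceComponents(su, np.eye(3), 0.0, True, 1))
        assert gp.rg[("A", "b")] == pytest.approx(0.5)


class TestScan:
    def test_equals_ols_when_no_structure(self):
        rng = np.random.default_rng(28)
        n, m = 80, 6
        geno = _geno(rng.integers(0, 3, size=(n, m)))
        Y = rng.standard_normal((n, 3))
        y = TraitMatrix(geno.animal_ids, Y)
        vc = VarianceComponents(np.zeros((3, 3)), np.eye(3), 0.0, True, 1)
        rel = RelationshipMatrix(geno.animal_ids, np.eye(n))
        res = snp_scan(y, geno, vc, rel)
        for j in range(m):
            X = np.column_stack([np.ones(n), geno.codes[:, j]])
            for t_i, t in enumerate(("A", "b", "K")):
                slope = np.linalg.lstsq(X, Y[:, t_i], rcond=None)[0][1]
                assert res[f"s_{t}"][j] == pytest.approx(slope, abs=1e-8)

    def test_equals_dense_gls_on_small_instance(self):
        rng = np.random.default_rng(29)
        n, m = 50, 6
        geno = _geno(rng.integers(0, 3, size=(n, m)))
        L = rng.standard_normal((n, n)) * 0.1
        A = L @ L.T + np.eye(n)
        Dh = np.diag(1 / np.sqrt(np.diag(A)))
        A = 0.5 * ((Dh @ A @ Dh) + (Dh @ A @ Dh).T)
        Su = np.array([[1.0, 0.3, -0.2], [0.3, 0.8, 0.1], [-0.2, 0.1, 0.5]])
        Se = np.diag([2.0, 1.5, 1.0])
        Y = rng.standard_normal((n, 3))
        y = TraitMatrix(geno.animal_ids, Y)
        res = snp_scan(y, geno, VarianceComponents(Su, Se, 0.0, True, 1),
                       RelationshipMatrix(geno.animal_ids, A))
        V = np.kron(Su, A) + np.kron(Se, np.eye(n))
        Vi = np.linalg.inv(V)
        yv = Y.T.ravel()
        for j in range(m):
            X = np.zeros((3 * n, 6))
            for t_i in range(3):
                X[t_i * n:(t_i + 1) * n, t_i] = 1.0
                X[t_i * n:(t_i + 1) * n, 3 + t_i] = geno.codes[:, j]
            C = np.linalg.inv(X.T @ Vi @ X)
            beta = C @ X.T @ Vi @ yv
            for t_i, t in enumerate(("A", "b", "K")):
                assert res[f"s_{t}"][j] == pytest.approx(beta[3 + t_i], abs=1e-6)
                assert res[f"se_{t}"][j] == pytest.approx(
                    math.sqrt(C[3 + t_i, 3 + t_i]), abs=1e-6)

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(30)
        n, m = 60, 5
        geno = _geno(rng.integers(0, 3, size=(n, m)))
        Y = rng.standard_normal((n, 3))
        Su = np.eye(3) * 0.5
        Se = np.eye(3)
        A = np.eye(n)
        A[:30, :30] += 0.25
        np.fill_diagonal(A, 1.0)
        vc = VarianceComponents(Su, Se, 0.0, True, 1)
        rel = RelationshipMatrix(geno.animal_ids, A)
        base = snp_scan(TraitMatrix(geno.animal_ids, Y), geno, vc, rel)
        shifted = snp_scan(TraitMatrix(geno.animal_ids, Y + 7.0), geno, vc, rel)
        np.testing.assert_allclose(base["p_A"], shifted["p_A"], atol=1e-8)
        c = 3.5
        Y2 = Y.copy()
        Y2[:, 0] *= c
        vc2 = VarianceComponents(Su * np.outer([c, 1, 1], [c, 1, 1]),
                                 Se * np.outer([c, 1, 1], [c, 1, 1]), 0.0, True, 1)
        scaled = snp_scan(TraitMatrix(geno.animal_ids, Y2), geno, vc2, rel)
        np.testing.assert_allclose(scaled["s_A"], base["s_A"] * c, atol=1e-8)
        np.testing.assert_allclose(scaled["p_A"], base["p_A"], atol=1e-8)

    def test_constant_snp_flagged_untestable(self):
        rng = np.random.default_rng(31)
        n = 40
        codes = np.column_stack([np.ones(n), rng.integers(0, 3, n)]).astype(np.int8)
        geno = _geno(codes)
        y = TraitMatrix(geno.animal_ids, rng.standard_normal((n, 3)))
        vc = VarianceComponents(np.zeros((3, 3)), np.eye(3), 0.0, True, 1)
        res = snp_scan(y, geno, vc, RelationshipMatrix(geno.animal_ids, np.eye(n)))
        assert bool(res["untestable"][0]) and not bool(res["untestable"][1])
        assert np.isnan(res["p_A"][0])
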