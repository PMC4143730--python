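"""Statistics against hand/brute-force oracles; permutation engine; exact tests."""
import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from conftest import make_matrix, make_phenotype
from supervariant import assoc, collapse
from supervariant.assoc import (
    CalphaInputs,
    FeatureMatrix,
    bonferroni_threshold,
    calpha_from_features,
    calpha_statistic,
    cmc_hotelling,
    fisher_exact_2x2,
    hotelling_t2,
    permutation_pvalue,
    reconstruct_table,
    ssu_statistic,
    supervariant_table,
    two_step_scan,
)
from supervariant.types import (
    ContingencyTable2x2,
    GeneVariantSet,
    PermutationPlan,
    Phenotype,
    SuperVariant,
)
from supervariant.types import TestResult as PermResult
from test_collapse import geneset_for


def features_from(values):
    values = np.asarray(values, dtype=float)
    ac = values.sum(axis=0).astype(int)
    return FeatureMatrix(
        values=values,
        labels=[f"v{j}" for j in range(values.shape[1])],
        allele_counts=ac,
        is_super=np.zeros(values.shape[1], dtype=bool),
    )


class TestBuildFeatureMatrix:
    def test_collapsed_feature_count_matches_arithmetic(self, setx_cohort, setx_geneset):
        """380 variants with 135 singletons collapse to 245 + 1 features."""
        matrix, _, _ = setx_cohort
        fm = assoc.build_feature_matrix(setx_geneset, matrix)
        assert fm.n_features + fm.n_dropped_constant == 246
        assert fm.labels[-1] == "SUPER"
        assert fm.is_super.sum() == 1

    def test_no_singletons_flag_is_noop(self):
        d = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        m = make_matrix(d)
        gs = geneset_for(m)
        on = assoc.build_feature_matrix(gs, m, collapse_singletons=True)
        off = assoc.build_feature_matrix(gs, m, collapse_singletons=False)
        np.testing.assert_array_equal(on.values, off.values)

    def test_all_singletons_reduce_to_supervariant_only(self):
        # 5th sample carries nothing, so the indicator stays non-constant
        m = make_matrix(np.vstack([np.eye(4, dtype=int), np.zeros((1, 4), int)]))
        fm = assoc.build_feature_matrix(geneset_for(m), m)
        assert fm.labels == ["SUPER"]

    def test_constant_columns_dropped(self):
        d = np.array([[1, 1], [0, 1], [1, 1], [0, 1]])
        m = make_matrix(d)
        fm = assoc.build_feature_matrix(geneset_for(m), m, collapse_singletons=False)
        assert fm.n_features == 1
        assert fm.n_dropped_constant == 1


class TestCalpha:
    def test_single_balanced_singleton_is_zero(self):
        t = calpha_statistic(CalphaInputs(n=[1], y=[1], p0=0.5))
        assert t == pytest.approx((1 - 0.5) ** 2 - 0.25) == 0.0

    def test_exact_expectation_attains_minimum(self):
        n = np.array([2.0, 4.0, 10.0])
        p0 = 0.5
        t = calpha_statistic(CalphaInputs(n=n, y=n * p0, p0=p0))
        assert t == pytest.approx(-(n * p0 * (1 - p0)).sum())

    def test_five_variant_toy_term_by_term(self):
        n = np.array([1, 1, 2, 3, 4], dtype=float)
        y = np.array([1, 0, 2, 1, 3], dtype=float)
        p0 = 64 / 103
        expect = sum(
            (yi - ni * p0) ** 2 - ni * p0 * (1 - p0) for ni, yi in zip(n, y)
        )
        assert calpha_statistic(CalphaInputs(n=n, y=y, p0=p0)) == pytest.approx(expect)

    def test_feature_path_matches_sufficient_statistics(self):
        rng = np.random.default_rng(0)
        F = rng.choice([0, 1, 2], size=(20, 5)).astype(float)
        y = np.array([1] * 12 + [0] * 8)
        direct = calpha_statistic(
            CalphaInputs(n=F.sum(axis=0), y=y @ F, p0=y.mean())
        )
        assert calpha_from_features(features_from(F), y) == pytest.approx(direct)


class TestSsu:
    def test_four_sample_hand_computation(self):
        F = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        y = np.array([1, 1, 0, 0])
        # centered y = (.5,.5,-.5,-.5); U = F'(y-ybar) = (1, 0)
        u = F.T @ (y - y.mean())
        assert ssu_statistic(features_from(F), y) == pytest.approx(float(u @ u))
        assert ssu_statistic(features_from(F), y) == pytest.approx(1.0)

    def test_orthogonal_features_give_zero(self):
        y = np.array([1, 1, 0, 0])
        F = np.array([[1.0], [0.0], [1.0], [0.0]])  # balanced across classes
        assert ssu_statistic(features_from(F), y) == pytest.approx(0.0)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            ssu_statistic(features_from(np.eye(3)), np.ones(3))


class TestCmc:
    def test_identical_group_means_zero(self):
        m = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        assert hotelling_t2(m, np.array([1, 0, 1, 0])) == pytest.approx(0.0)

    def test_six_sample_toy_matches_matrix_algebra(self):
        m = np.array([[1], [1], [0], [1], [0], [0]], dtype=float)
        y = np.array([1, 1, 1, 0, 0, 0])
        n1 = n2 = 3
        m1, m2 = m[y == 1].mean(), m[y == 0].mean()
        s = (2 * m[y == 1].var(ddof=1) + 2 * m[y == 0].var(ddof=1)) / 4
        expect = (n1 * n2 / 6) * (m1 - m2) ** 2 / s
        assert hotelling_t2(m, y) == pytest.approx(float(expect))

    def test_duplicated_bin_finite_via_pseudoinverse(self):
        rng = np.random.default_rng(1)
        base = rng.choice([0.0, 1.0], size=(10, 1))
        y = np.array([1] * 5 + [0] * 5)
        single = hotelling_t2(base, y)
        dup = hotelling_t2(np.hstack([base, base]), y)
        assert math.isfinite(dup)
        assert dup == pytest.approx(single, rel=1e-8)

    def test_supervariant_joins_singleton_bin(self):
        # supervariant column (many carriers) must not migrate to the >=2 bin
        values = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=float)
        fm = FeatureMatrix(values=values, labels=["v", "SUPER"],
                           allele_counts=np.array([2, 2]),
                           is_super=np.array([False, True]))
        bins = assoc.cmc_bin_matrix(fm, edges=(1, 2))
        assert bins.shape[1] == 2
        np.testing.assert_array_equal(bins[:, 0], values[:, 1])  # singleton bin = SUPER

    def test_batch_engine_matches_scalar_hotelling(self):
        rng = np.random.default_rng(4)
        m = rng.choice([0.0, 1.0], size=(15, 3))
        y = np.array([1] * 6 + [0] * 9, dtype=float)
        yp = assoc.permuted_label_matrix(y, 50, rng)
        batch = assoc._batch_hotelling(yp, m)
        for i in range(0, 50, 7):
            assert batch[i] == pytest.approx(hotelling_t2(m, yp[i]), rel=1e-8)


class TestPermutation:
    def test_constant_statistic_gives_p_one(self):
        res = permutation_pvalue(lambda F, y: 1.0, features_from(np.eye(4)),
                                 np.array([1, 1, 0, 0]), n_perm=100, seed=0)
        assert res.b == res.B == 100
        assert res.p == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p within 3 binomial SE of the exact permutation p."""
        F = np.array([[2.0], [1.0], [1.0], [0.0], [0.0]])
        y = np.array([1, 1, 0, 0, 0])
        obs = ssu_statistic(features_from(F), y)
        exact_b = sum(
            ssu_statistic(features_from(F), np.array(p)) >= obs - 1e-12
            for p in itertools.permutations(y)
        )
        exact_p = exact_b / math.factorial(5)
        res = permutation_pvalue(ssu_statistic, features_from(F), y,
                                 n_perm=10_000, seed=3)
        se = math.sqrt(exact_p * (1 - exact_p) / 10_000)
        assert abs(res.p - exact_p) < 3 * se

    def test_below_resolution_display_convention(self):
        assert PermResult(statistic=1.0, b=0, B=10**6, method="x").p_display == "<1.0e-06"
        assert PermResult(statistic=1.0, b=1, B=10**6, method="x").p == 1e-6

    def test_calpha_and_ssu_identical_on_shared_stream(self):
        """With flat weights the two statistics differ by a label-invariant
        constant, so their permutation p-values coincide."""
        rng = np.random.default_rng(8)
        F = rng.choice([0.0, 1.0], size=(30, 4), p=[0.8, 0.2])
        y = np.array([1] * 18 + [0] * 12)
        pa = permutation_pvalue(calpha_from_features, features_from(F), y, 2000, seed=5)
        ps = permutation_pvalue(ssu_statistic, features_from(F), y, 2000, seed=5)
        assert pa.b == ps.b

    def test_statistics_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(2)
        F = rng.choice([0.0, 1.0, 2.0], size=(12, 3))
        y = np.array([1] * 5 + [0] * 7)
        perm = rng.permutation(12)
        fm, fm_p = features_from(F), features_from(F[perm])
        assert ssu_statistic(fm, y) == pytest.approx(ssu_statistic(fm_p, y[perm]))
        assert calpha_from_features(fm, y) == pytest.approx(calpha_from_features(fm_p, y[perm]))
        assert cmc_hotelling(fm, y) == pytest.approx(cmc_hotelling(fm_p, y[perm]))

    def test_permutation_p_consistent_with_exact_fisher_on_dichotomy(self):
        """On a balanced cohort the SSU permutation null of a lone binary
        feature reproduces the two-sided Fisher p of the same 2x2."""
        x = np.array([1] * 8 + [0] * 32)
        y = np.array(([1] * 6 + [0] * 14) + ([1] * 14 + [0] * 6))  # 20/20 classes
        sv = SuperVariant(gene="G", x=x, n_singletons_used=8)
        phen = make_phenotype(y)
        fisher_p = fisher_exact_2x2(supervariant_table(sv, phen)).p
        res = permutation_pvalue(ssu_statistic, features_from(x[:, None].astype(float)),
                                 y, n_perm=20_000, seed=9)
        se = math.sqrt(fisher_p * (1 - fisher_p) / 20_000)
        assert abs(res.p - fisher_p) < 3 * se


class TestTwoStepScan:
    def _null_cohort(self, n_genes=40, seed=0):
        from supervariant import preprocess, simulate
        specs = [simulate.GeneSpec(name=f"G{i}", n_variants=20, n_singletons=7)
                 for i in range(n_genes)]
        cfg = simulate.SimConfig(genes=specs, carrier_or=1.0, seed=seed)
        m, phen, models = simulate.simulate_cohort(cfg)
        return preprocess.assign_to_genes(m, models), m, phen

    def test_degenerate_plan_equals_single_stage(self):
        gs, m, phen = self._null_cohort(n_genes=5)
        plan = PermutationPlan(b1=300, alpha_promote=0.5, b2=300, seed=4)
        out = two_step_scan(gs, m, phen, plan)
        assert set(out["stage"]) == {1}
        assert (out["B"] == 300).all()

    def test_null_promotion_rate_in_binomial_band(self):
        gs, m, phen = self._null_cohort(n_genes=120, seed=6)
        plan = PermutationPlan(b1=100, alpha_promote=0.1, b2=100, seed=7)
        out = two_step_scan(gs, m, phen, plan)
        rate = out.groupby("gene")["promoted"].first().mean()
        # per-gene promotion is bounded by 3 correlated ~0.1 chances
        assert 0.02 < rate < 0.45

    def test_signal_gene_promoted_and_flagged(self, setx_cohort, setx_geneset):
        matrix, phen, _ = setx_cohort
        plan = PermutationPlan(b1=1000, alpha_promote=1e-3, b2=5000, seed=1)
        out = two_step_scan([setx_geneset], matrix, phen, plan,
                            threshold_denominator=10)
        assert out["promoted"].all()
        stage2 = out[out["stage"] == 2]
        assert (stage2["B"] == 5000).all()
        assert stage2["significant"].any()

    def test_rows_carry_stage_and_counts(self):
        gs, m, phen = self._null_cohort(n_genes=3)
        plan = PermutationPlan(b1=50, alpha_promote=0.001, b2=100, seed=0)
        out = two_step_scan(gs, m, phen, plan)
        assert {"gene", "method", "stage", "statistic", "b", "B", "p",
                "p_display", "promoted", "significant"} <= set(out.columns)
        assert len(out) >= 3 * 3


class TestBonferroni:
    def test_threshold_values(self):
        assert bonferroni_threshold(0.05, 10_000) == pytest.approx(5.0e-6)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 10_148) == pytest.approx(4.927e-6, rel=1e-3)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSupervariantTable:
    def test_all_zero_indicator(self):
        sv = SuperVariant(gene="G", x=np.zeros(6, dtype=int), n_singletons_used=0)
        t = supervariant_table(sv, make_phenotype([1, 1, 1, 0, 0, 0]))
        assert (t.a, t.c) == (0, 0)
        assert (t.b, t.d) == (3, 3)

    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        sv = SuperVariant(gene="G", x=y.copy(), n_singletons_used=2)
        t = supervariant_table(sv, make_phenotype(y))
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)

    def test_random_fixture_matches_hand_tally(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 2, size=30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 1, 0  # both classes non-empty
        t = supervariant_table(
            SuperVariant(gene="G", x=x, n_singletons_used=int(x.sum())),
            make_phenotype(y),
        )
        assert t.a == int(((x == 1) & (y == 1)).sum())
        assert t.d == int(((x == 0) & (y == 0)).sum())
        assert t.n_cases == int(y.sum())


def enumeration_fisher(table: ContingencyTable2x2):
    """Independent oracle: full scan of the hypergeometric support."""
    n1, n2 = table.n_cases, table.n_controls
    k = table.a + table.c
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n1 + n2, k, n1)
    p_obs = pmf[support == table.a][0]
    # the same relative guard standard implementations use for float ties
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_symmetric_table(self):
        res = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_single_count_toy_matches_enumeration(self):
        t = ContingencyTable2x2(1, 0, 0, 1)
        res = fisher_exact_2x2(t)
        assert res.p == pytest.approx(enumeration_fisher(t))
        assert res.odds_ratio == math.inf

    @pytest.mark.parametrize("margins", [(5, 5), (8, 3), (12, 12), (20, 20)])
    def test_p_matches_hypergeometric_enumeration(self, margins):
        n1, n2 = margins
        for a in range(n1 + 1):
            for c in range(n2 + 1):
                if a + c == 0 or a + c == n1 + n2:
                    continue
                t = ContingencyTable2x2(a, n1 - a, c, n2 - c)
                assert fisher_exact_2x2(t).p == pytest.approx(
                    enumeration_fisher(t), rel=1e-9
                )

    def test_cmle_solves_score_equation_and_ci_inverts_tails(self):
        from scipy.stats import nchypergeom_fisher
        t = ContingencyTable2x2(9, 5, 3, 11)
        res = fisher_exact_2x2(t)
        M, k, nd = 28, 12, 14
        assert nchypergeom_fisher.mean(M, k, nd, res.odds_ratio) == pytest.approx(9, abs=1e-6)
        assert nchypergeom_fisher.sf(8, M, k, nd, res.ci_low) == pytest.approx(0.025, abs=1e-6)
        assert nchypergeom_fisher.cdf(9, M, k, nd, res.ci_high) == pytest.approx(0.025, abs=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 2))


class TestReconstructTable:
    def test_balanced_margins_p_one_includes_balanced_tables(self):
        matches = reconstruct_table(2, 2, 1.0)
        cells = {(t.a, t.c) for t, _ in matches}
        assert (1, 1) in cells

    def test_printed_whole_gene_summary_recovers_or(self):
        matches = reconstruct_table(64, 39, 3.7e-6, ci_target=(3.12, 27.43))
        assert matches
        assert all(round(r.odds_ratio, 1) == 8.8 for _, r in matches)

    def test_printed_intron_summary_recovers_or(self):
        matches = reconstruct_table(64, 39, 8.8e-7, ci_target=(3.43, 28.70))
        assert matches
        assert all(round(r.odds_ratio, 1) == 9.5 for _, r in matches)

    def test_no_match_returns_empty(self):
        assert reconstruct_table(4, 4, 1e-12) == []


class TestPerVariantFisher:
    def test_empty_gene(self):
        m = make_matrix(np.zeros((4, 2)))
        gs = GeneVariantSet(gene=geneset_for(m).gene, variant_indices=np.array([], dtype=int))
        minp, ps = assoc.per_variant_fisher(gs, m, make_phenotype([1, 1, 0, 0]))
        assert ps.size == 0 and math.isinf(minp)

    def test_lone_case_carrier_far_from_significant(self):
        d = np.zeros((103, 1), dtype=int)
        d[0, 0] = 1  # a case carries the singleton
        m = make_matrix(d)
        phen = make_phenotype([1] * 64 + [0] * 39)
        minp, _ = assoc.per_variant_fisher(geneset_for(m), m, phen)
        assert minp == pytest.approx(1.0)

    def test_variant_identical_to_supervariant_same_p(self, setx_cohort, setx_geneset):
        matrix, phen, _ = setx_cohort
        sv = collapse.build_supervariant(setx_geneset, matrix)
        d = sv.x[:, None].astype(int)
        m1 = make_matrix(d)
        gs = geneset_for(m1)
        minp, _ = assoc.per_variant_fisher(gs, m1, phen)
        assert minp == pytest.approx(fisher_exact_2x2(supervariant_table(sv, phen)).p)
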