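"""Co-expression network: correlation, TOM, tree cut, eigengenes, selection."""

import numpy as np
import pandas as pd
import pytest

from cortexreg import coexpr, synthio
from cortexreg.study import ExpressionStudy
from tests.conftest import small_config


def make_study(values, ages=None, **traits):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    t = pd.DataFrame(index=[f"S{i}" for i in range(s)])
    t["age"] = ages if ages is not None else np.linspace(20, 80, s)
    for k, v in traits.items():
        t[k] = v
    return ExpressionStudy(
        genes=[f"g{i}" for i in range(g)],
        samples=[f"S{i}" for i in range(s)],
        values=values,
        traits=t,
    )


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum()))


class TestCorrelationMatrix:
    def test_duplicate_and_negated_genes(self, rng):
        base = rng.standard_normal(10)
        study = make_study([base, base, -base])
        r = coexpr.correlation_matrix(study)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_matches_textbook_pearson(self):
        vals = np.array(
            [[1.0, 2.0, 4.0, 3.0], [2.0, 1.0, 5.0, 7.0], [0.5, 0.5, 1.5, 0.0]]
        )
        study = make_study(vals)
        r = coexpr.correlation_matrix(study)
        for i in range(3):
            for j in range(3):
                assert r[i, j] == pytest.approx(
                    brute_pearson(vals[i], vals[j]), abs=1e-12
                )

    def test_zero_variance_gene_named_in_error(self, rng):
        study = make_study([rng.standard_normal(5), np.ones(5)])
        with pytest.raises(ValueError, match="g1"):
            coexpr.correlation_matrix(study)


class TestSoftPower:
    def test_exact_powerlaw_degree_sequence_reaches_high_fit(self):
        # connectivity k_i proportional to 1/i has density ~ k^-2, which the
        # log-log regression must recognize as near-perfect scale-freeness
        k = 100.0 / np.arange(1, 2001)
        assert coexpr.scale_free_fit(k) >= 0.95

    def test_smallest_power_meeting_target_is_returned(self, small_study):
        sim = coexpr.correlation_matrix(small_study)
        beta, table = coexpr.pick_soft_power(sim, fit_target=0.5)
        meeting = table[table["fit"] >= 0.5]["power"]
        assert len(meeting) and beta == int(meeting.iloc[0])

    def test_fallback_to_argmax_fit_with_warning(self, small_study, caplog):
        sim = coexpr.correlation_matrix(small_study)
        with caplog.at_level("WARNING"):
            beta, table = coexpr.pick_soft_power(sim, fit_target=1.01)
        assert beta == int(table.loc[table["fit"].idxmax(), "power"])
        assert any("argmax" in r.message for r in caplog.records)

    def test_degenerate_connectivity_raises(self):
        sim = np.ones((5, 5))
        with pytest.raises(ValueError):
            coexpr.pick_soft_power(sim, powers=[1, 2])


def brute_force_tom(a):
    n = len(a)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_hand_computed_three_node_case(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = coexpr.adjacency_to_tom(a)
        # l_12 = 0.25; (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_empty_adjacency_gives_zero_overlap(self):
        tom = coexpr.adjacency_to_tom(np.zeros((4, 4)))
        assert np.allclose(tom, np.eye(4))

    def test_identical_profiles_with_unit_edge_give_tom_one(self):
        a = np.array(
            [
                [0.0, 1.0, 1.0, 0.0],
                [1.0, 0.0, 1.0, 0.0],
                [1.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        tom = coexpr.adjacency_to_tom(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_on_random_matrices(self, rng):
        for _ in range(10):
            n = rng.integers(5, 15)
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.max(np.abs(coexpr.adjacency_to_tom(a) - brute_force_tom(a))) < 1e-10

    def test_invalid_entries_raise(self):
        a = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError):
            coexpr.adjacency_to_tom(a)


class TestEigengene:
    def test_single_gene_module_is_standardized_profile(self, rng):
        study = make_study(rng.standard_normal((3, 30)))
        e = coexpr.module_eigengene(study, ["g1"])
        assert abs(np.corrcoef(e, study.values[1])[0, 1]) == pytest.approx(1.0)

    def test_rank_one_block_recovers_factor(self, rng):
        f = rng.standard_normal(50)
        coef = rng.uniform(0.5, 2.0, 20)
        study = make_study(np.outer(coef, f))
        e = coexpr.module_eigengene(study, study.genes)
        assert abs(np.corrcoef(e, f)[0, 1]) >= 0.999
        for row in study.values:
            assert abs(np.corrcoef(e, row)[0, 1]) >= 0.999

    def test_orientation_mean_member_correlation_nonnegative(self, rng):
        study = make_study(rng.standard_normal((10, 40)))
        e = coexpr.module_eigengene(study, study.genes)
        corrs = [np.corrcoef(e, row)[0, 1] for row in study.values]
        assert np.mean(corrs) >= 0

    def test_explains_more_variance_than_any_single_gene(self, rng):
        # brute-force check: projection on the eigengene captures at least
        # as much standardized variance as projection on any member profile
        x = rng.standard_normal((30, 60))
        study = make_study(x)
        e = coexpr.module_eigengene(study, study.genes)
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)

        def var_explained(v):
            v = v / np.linalg.norm(v)
            return float(((xs @ v) ** 2).sum())

        best_gene = max(var_explained(row) for row in xs)
        assert var_explained(e) >= best_gene - 1e-9

    def test_empty_membership_raises(self, rng):
        study = make_study(rng.standard_normal((3, 10)))
        with pytest.raises(ValueError):
            coexpr.module_eigengene(study, [])


def _block_study(rng, n_blocks=2, block_size=20, n_samples=60, factor_corr=0.0):
    factors = [rng.standard_normal(n_samples)]
    for _ in range(n_blocks - 1):
        g = rng.standard_normal(n_samples)
        g -= (g @ factors[0]) / (factors[0] @ factors[0]) * factors[0]
        f = factor_corr * factors[0] / factors[0].std() + np.sqrt(
            max(1 - factor_corr**2, 0)
        ) * g / g.std()
        factors.append(f)
    rows = []
    for f in factors:
        for _ in range(block_size):
            rows.append(f + 0.01 * rng.standard_normal(n_samples))
    return make_study(np.array(rows)), factors


class TestDetectModules:
    @staticmethod
    def _tom_for(study):
        r = coexpr.correlation_matrix(study)
        a = np.abs(r) ** 6
        np.fill_diagonal(a, 0.0)
        return coexpr.adjacency_to_tom(a)

    def test_two_orthogonal_blocks_recovered(self, rng):
        study, _ = _block_study(rng, factor_corr=0.0)
        mods = coexpr.detect_modules(self._tom_for(study), study, min_size=5)
        assert len(mods.module_ids()) == 2
        members = {m: set(mods.members(m)) for m in mods.module_ids()}
        blocks = [set(study.genes[:20]), set(study.genes[20:])]
        assert set(map(frozenset, members.values())) == set(map(frozenset, blocks))

    def test_highly_correlated_blocks_merged(self, rng):
        study, _ = _block_study(rng, factor_corr=0.95)
        mods = coexpr.detect_modules(
            self._tom_for(study), study, min_size=5, merge_height=0.25
        )
        assert len(mods.module_ids()) == 1
        assert len(mods.members(1)) == 40

    def test_permutation_equivariance(self, rng):
        study, _ = _block_study(rng, n_blocks=3, block_size=12)
        mods = coexpr.detect_modules(self._tom_for(study), study, min_size=5)
        perm = rng.permutation(len(study.genes))
        study_p = ExpressionStudy(
            genes=[study.genes[i] for i in perm],
            samples=study.samples,
            values=study.values[perm],
            traits=study.traits,
        )
        mods_p = coexpr.detect_modules(self._tom_for(study_p), study_p, min_size=5)
        assert mods_p.labels == mods.labels

    def test_fewer_genes_than_min_size_warns(self, rng):
        study = make_study(rng.standard_normal((3, 30)))
        with pytest.warns(UserWarning):
            mods = coexpr.detect_modules(
                self._tom_for(study), study, min_size=10
            )
        assert set(mods.labels.values()) == {0}

    def test_planted_module_recovered_from_synthetic_study(self, small_bundle):
        study, truth = small_bundle.study, small_bundle.truth
        mods = coexpr.detect_modules(self._tom_for(study), study, min_size=10)
        best = max(
            mods.module_ids(),
            key=lambda m: len(set(mods.members(m)) & truth.module_genes),
        )
        rec = set(mods.members(best))
        jac = len(rec & truth.module_genes) / len(rec | truth.module_genes)
        assert jac >= 0.7


class TestSelection:
    def test_rule_application(self, small_bundle):
        study = small_bundle.study
        truth = small_bundle.truth
        mods = TestDetectModules._tom_for(study)
        assignment = coexpr.detect_modules(mods, study, min_size=10)
        report = coexpr.select_age_modules(assignment, study, alpha=0.05)
        # planted module must be selected
        best = max(
            assignment.module_ids(),
            key=lambda m: len(set(assignment.members(m)) & truth.module_genes),
        )
        row = report.table[report.table["module_id"] == best].iloc[0]
        assert row["selected"]
        assert row["p_age"] < 0.05
        for c in study.confounder_names():
            assert row["p_age"] < row[f"p_{c}"]

    def test_confounder_domination_suppresses_selection(self):
        cfg = small_config(seed=21, dominant_confounder="RIN")
        bundle_study, truth = synthio.generate_expression(cfg)
        tom = TestDetectModules._tom_for(bundle_study)
        assignment = coexpr.detect_modules(tom, bundle_study, min_size=10)
        report = coexpr.select_age_modules(assignment, bundle_study, alpha=0.05)
        best = max(
            assignment.module_ids(),
            key=lambda m: len(set(assignment.members(m)) & truth.module_genes),
        )
        row = report.table[report.table["module_id"] == best].iloc[0]
        assert not row["selected"]
        assert row["p_RIN"] < row["p_age"]

    def test_constant_trait_skipped_with_warning(self, rng):
        study = make_study(rng.standard_normal((25, 40)), RIN=np.ones(40))
        tom = TestDetectModules._tom_for(study)
        assignment = coexpr.detect_modules(tom, study, min_size=5)
        with pytest.warns(UserWarning, match="RIN"):
            report = coexpr.select_age_modules(assignment, study)
        if len(report.table):
            assert "p_RIN" not in report.table.columns


class TestMatchedCorrelation:
    def test_constant_confounder_single_stratum(self, rng):
        e = rng.standard_normal(40)
        age = np.linspace(20, 80, 40)
        strata = coexpr.matched_correlation(e, age, np.full(40, 7.0), min_group=5)
        assert len(strata) == 1
        level, n, r = strata[0]
        assert n == 40
        assert r == pytest.approx(np.corrcoef(e, age)[0, 1])

    def test_exact_negative_relation_in_every_stratum(self, rng):
        age = np.linspace(20, 80, 60)
        conf = np.repeat([1.0, 2.0, 3.0], 20)
        strata = coexpr.matched_correlation(-age, age, conf, min_group=5)
        assert len(strata) == 3
        for _, _, r in strata:
            assert r == pytest.approx(-1.0)

    def test_no_large_stratum_warns_and_returns_empty(self, rng):
        with pytest.warns(UserWarning):
            out = coexpr.matched_correlation(
                rng.standard_normal(6),
                np.arange(6.0),
                np.arange(6.0),
                min_group=5,
            )
        assert out == []

    def test_planted_confounder_strata_replicate_age_trend(self, small_bundle):
        study, truth = small_bundle.study, small_bundle.truth
        strata = coexpr.matched_correlation(
            truth.planted_eigengene,
            study.age,
            study.traits["RIN"].to_numpy(float),
            min_group=5,
        )
        rs = [r for _, _, r in strata]
        assert len(rs) >= 3
        assert np.mean(np.array(rs) < 0) > 0.5
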