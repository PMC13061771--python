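import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epileptome.association import (
    CovariateSpec,
    ScreenParams,
    build_design,
    exclude_genes,
    overlap_sets,
    partial_spearman,
    reported_view,
    residualize,
    screen_genes,
    spearman,
    spearman_matrix,
)
from epileptome.data_io import ExpressionMatrix, GeneList
from epileptome.preprocess import preprocess
from epileptome.synthetic_data import SpikeSpec, generate_expression


def matrix_of(values, sample_ids, log_scale=True):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(values.shape[0])], columns=sample_ids)
    return ExpressionMatrix(df, log_scale=log_scale)


class TestSpearman:
    def test_perfect_monotone(self):
        r, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0)

    def test_closed_form_with_rank_displacements(self):
        # d = (1,-1,1,-1,0), sum d^2 = 4: r = 1 - 6*4/(5*24) = 0.8
        r, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)

    def test_invariant_under_log_of_x(self):
        x = np.array([1.0, 3.0, 9.0, 27.0, 81.0, 2.0])
        r, _ = spearman(x, np.log2(x + 0.37))
        assert r == pytest.approx(1.0)

    def test_zero_variance_gives_undefined_marker(self):
        r, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and p == 1.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_on_random_data_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        x = rng.integers(0, 8, size=n).astype(float)
        y = rng.integers(0, 8, size=n).astype(float)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestScreen:
    def test_noiseless_spiked_gene_flagged_positive(self, clinical):
        trait = clinical.values_for("duration")
        m = matrix_of([trait * 0.1 + 3], clinical.sample_ids)
        rec = screen_genes(m, trait)
        assert rec.loc[0, "flagged"] and rec.loc[0, "direction"] == "positive"
        assert rec.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_gene_unflagged(self, clinical):
        m = matrix_of([np.zeros(16) + 4], clinical.sample_ids)
        rec = screen_genes(m, clinical.values_for("duration"))
        assert not rec.loc[0, "flagged"] and np.isnan(rec.loc[0, "r"])

    def test_screen_invariant_to_log_transform_of_expression(self, clinical, random_matrix):
        trait = clinical.values_for("duration")
        raw = ExpressionMatrix(random_matrix.data.copy(), log_scale=True)
        logm = ExpressionMatrix(np.log2(random_matrix.data + 0.001), log_scale=True)
        np.testing.assert_allclose(
            screen_genes(raw, trait)["r"], screen_genes(logm, trait)["r"], atol=1e-12
        )

    def test_null_flag_rate_matches_permutation_null_rate(self, clinical):
        # the fraction of pure-noise genes passing |r|>0.5 & p<0.05 equals the
        # rule's null rate, estimated here by correlating permuted traits
        rng = np.random.default_rng(0)
        trait = clinical.values_for("duration")
        noise = rng.normal(size=(4000, 16))
        rec = screen_genes(matrix_of(noise, clinical.sample_ids), trait)
        observed = rec["flagged"].mean()

        perms = np.array([rng.permutation(trait) for _ in range(4000)])
        r, p = spearman_matrix(perms, stats.rankdata(trait))
        null_rate = float(np.mean((np.abs(r) > 0.5) & (p < 0.05)))
        se = np.sqrt(null_rate * (1 - null_rate) * (1 / 4000 + 1 / 4000))
        assert observed == pytest.approx(null_rate, abs=3 * se + 1e-9)


class TestExclusion:
    def test_exclusion_marks_and_reported_view_drops(self):
        rec = pd.DataFrame({"gene_id": [f"G{i}" for i in range(10)], "r": 0.0, "p": 1.0})
        out = exclude_genes(rec, GeneList.from_iterable(["G1", "G5", "G9", "ABSENT"], "age"))
        assert out["age_associated"].sum() == 3
        assert len(reported_view(out)) == 7

    def test_empty_exclusion_is_identity(self):
        rec = pd.DataFrame({"gene_id": ["A", "B"], "r": [0.1, 0.2], "p": [0.5, 0.6]})
        out = exclude_genes(rec, GeneList(frozenset(), "empty"))
        assert not out["age_associated"].any()
        assert len(reported_view(out)) == 2


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        res = residualize(y, np.ones((4, 1)))
        np.testing.assert_allclose(res, y - y.mean())

    def test_exact_linear_dependence_gives_zero_residuals(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        X = np.column_stack([np.ones(4), x])
        np.testing.assert_allclose(residualize(3 * x - 2, X), 0, atol=1e-10)

    def test_simple_regression_closed_form(self):
        # y=(1,2,3,4) on x=(1,2,3,5): slope = Sxy/Sxx, intercept = ybar - b*xbar
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        a = y.mean() - b * x.mean()
        X = np.column_stack([np.ones(4), x])
        np.testing.assert_allclose(residualize(y, X), y - (a + b * x), atol=1e-12)

    def test_residuals_orthogonal_to_design(self, clinical):
        X, _ = build_design(clinical)
        rng = np.random.default_rng(1)
        y = rng.normal(size=16)
        res = residualize(y, X)
        assert np.abs(X.T @ res).max() <= 1e-8 * np.linalg.norm(y)

    def test_rank_deficient_design_handled(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        res = residualize(np.array([1.0, 5.0, 2.0, 8.0, 3.0]), X)
        assert np.abs(X.T @ res).max() < 1e-8


class TestDesign:
    def test_reference_level_is_most_frequent(self, clinical):
        X, names = build_design(clinical)
        assert "intercept" in names and "age" in names
        assert not any("Unk" in n for n in names)  # dominant etiology dropped
        assert not any("gender[M]" in n for n in names)  # 10 M vs 6 F
        assert X.shape == (16, len(names))

    def test_constant_indicator_dropped(self, clinical):
        frame = clinical.data.copy()
        frame["etiology"] = "Unk"
        from epileptome.data_io import ClinicalTable

        X, names = build_design(ClinicalTable(frame))
        assert names == ["intercept", "age", "gender[F]"]


class TestPartialSpearman:
    def test_intercept_only_covariates_reduce_to_plain_spearman(self, clinical, random_matrix):
        logm, _ = preprocess(random_matrix)
        trait = clinical.values_for("duration")
        plain = screen_genes(logm, trait)
        part = partial_spearman(
            logm, trait, clinical, CovariateSpec(numeric=(), categorical=())
        )
        np.testing.assert_allclose(part["r_partial"], plain["r"], atol=1e-12)
        np.testing.assert_allclose(part["p"], plain["p"], atol=1e-12)

    def test_exactly_age_driven_gene_is_deconfounded(self, clinical):
        # plain screen flags it via the age-duration entanglement; the partial
        # screen regresses age out exactly, leaving a zero-variance residual
        age = clinical.values_for("age")
        trait = clinical.values_for("duration")
        m = matrix_of([0.05 * age + 2], clinical.sample_ids)
        plain = screen_genes(m, trait)
        assert plain.loc[0, "flagged"] and abs(plain.loc[0, "r"]) > 0.5
        part = partial_spearman(m, trait, clinical, CovariateSpec(numeric=("age",), categorical=()))
        assert not part.loc[0, "flagged"]
        assert np.isnan(part.loc[0, "r_partial"]) and part.loc[0, "p"] == 1.0

    def test_confounded_class_flag_rate_drops_sharply(self, clinical):
        m, truth = generate_expression(clinical, SpikeSpec(seed=1))
        logm, _ = preprocess(m)
        trait = clinical.values_for("duration", logm.sample_ids)
        conf = [g for g in truth[truth == "age_confounded"].index if g in logm.gene_ids]
        plain = screen_genes(logm, trait).set_index("gene_id")
        part = partial_spearman(logm, trait, clinical).set_index("gene_id")
        plain_rate = plain.loc[conf, "flagged"].mean()
        part_rate = part.loc[conf, "flagged"].mean()
        assert plain_rate >= 0.5
        assert part_rate <= 0.2 * plain_rate + 1e-9

    def test_partial_not_invariant_to_log_transform(self, clinical, random_matrix):
        # residualization precedes ranking, so monotone transforms do matter
        trait = clinical.values_for("duration")
        raw = ExpressionMatrix(random_matrix.data.copy(), log_scale=True)
        logm = ExpressionMatrix(np.log2(random_matrix.data + 0.001), log_scale=True)
        a = partial_spearman(raw, trait, clinical)["r_partial"]
        b = partial_spearman(logm, trait, clinical)["r_partial"]
        assert np.nanmax(np.abs(a - b)) > 1e-6

    def test_adjusted_df_gives_larger_p(self, clinical, random_matrix):
        logm, _ = preprocess(random_matrix)
        trait = clinical.values_for("duration")
        default = partial_spearman(logm, trait, clinical)
        adjusted = partial_spearman(logm, trait, clinical, adjust_df=True)
        assert (adjusted["p"] >= default["p"] - 1e-12).all()

    def test_bounds(self, clinical, random_matrix):
        logm, _ = preprocess(random_matrix)
        trait = clinical.values_for("duration")
        part = partial_spearman(logm, trait, clinical)
        r = part["r_partial"].dropna()
        assert ((r >= -1) & (r <= 1)).all()
        assert ((part["p"] >= 0) & (part["p"] <= 1)).all()


class TestOverlap:
    def test_intersection_sorted(self):
        a = GeneList.from_iterable(["C", "B", "A"], "dur+")
        b = GeneList.from_iterable(["B", "C", "D"], "onset-")
        out = overlap_sets(a, b)
        assert out.sorted == ["B", "C"]
        assert "dur+" in out.label and "onset-" in out.label

    def test_disjoint_and_identity(self):
        a = GeneList.from_iterable(["A", "B"], "a")
        assert len(overlap_sets(a, GeneList.from_iterable(["X"], "x"))) == 0
        assert overlap_sets(a, a).identifiers == a.identifiers
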