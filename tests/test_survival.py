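"""Cohort preprocessing, scoring, stratification, and survival estimation."""

import numpy as np
import pandas as pd
import pytest

from invasig.datatypes import SchemaError
from invasig.genesets import build_signature
from invasig.simulate import CohortSimConfig, simulate_cohort
from invasig.survival import (
    ActivityScores,
    CohortTable,
    PreprocessParams,
    activity_score,
    cox_hr,
    exclude_hpv_positive,
    km_logrank,
    pan_cohort_screen,
    preprocess_cohort,
    quantile_normalize,
    run_survival_chain,
    stratify_equal_halves,
    zscore_genes,
)


def make_cohort(expr, times=None, events=None, hpv=None, detection=None):
    expr = pd.DataFrame(expr)
    expr.index = [f"P{i}" for i in range(len(expr))]
    n = len(expr)
    clinical = pd.DataFrame(
        {
            "os_time_days": times if times is not None else np.arange(1, n + 1) * 100.0,
            "os_event": events if events is not None else np.ones(n, dtype=int),
            "hpv_status": hpv if hpv is not None else ["negative"] * n,
        },
        index=expr.index,
    )
    det = None
    if detection is not None:
        det = pd.DataFrame(detection, index=expr.index, columns=expr.columns)
    return CohortTable(expr=expr, clinical=clinical, detection_p=det)


class TestQuantileNormalization:
    def test_two_patient_closed_form(self):
        qn = quantile_normalize(pd.DataFrame([[1.0, 2, 3], [4.0, 5, 6]]))
        assert np.allclose(qn.to_numpy(), [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_sorted_multisets(self):
        rng = np.random.default_rng(0)
        qn = quantile_normalize(pd.DataFrame(rng.normal(size=(20, 50))))
        sorted_rows = np.sort(qn.to_numpy(), axis=1)
        assert np.allclose(sorted_rows, sorted_rows[0], atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10, 30)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_ties_get_mean_of_candidates(self):
        qn = quantile_normalize(pd.DataFrame([[1.0, 1.0, 5.0], [2.0, 4.0, 6.0]]))
        row = qn.to_numpy()[0]
        # the two tied values share the mean of the two lowest order-statistic means
        assert row[0] == row[1] == pytest.approx((1.5 + 2.5) / 2)


class TestPreprocess:
    def test_clean_cohort_reduces_to_normalization(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(0, 2.0, size=(30, 8))
        cohort = make_cohort(expr)
        pre = preprocess_cohort(cohort, PreprocessParams(seed=0))
        assert np.allclose(
            pre.expr.to_numpy(), quantile_normalize(cohort.expr).to_numpy()
        )

    def test_gene_missing_above_threshold_removed(self):
        expr = pd.DataFrame(
            {"A": [1.0, 2, 3, 4], "B": [np.nan, np.nan, np.nan, 4.0]}
        )
        expr += np.arange(4)[:, None]  # give A some spread
        cohort = make_cohort(expr)
        pre = preprocess_cohort(
            cohort, PreprocessParams(max_missing_frac=0.70, min_gene_sd=0.0, seed=0)
        )
        assert list(pre.expr.columns) == ["A"]

    def test_detection_p_masks_then_seventy_percent_rule(self):
        expr = np.tile(np.arange(1.0, 5.0)[:, None], (1, 2)) * 3
        detection = np.zeros((4, 2))
        detection[:, 1] = [0.5, 0.5, 0.5, 0.01]  # gene 1 fails in 75% of patients
        cohort = make_cohort(expr, detection=detection)
        pre = preprocess_cohort(cohort, PreprocessParams(min_gene_sd=0.0, seed=0))
        assert pre.expr.shape[1] == 1

    def test_imputation_draws_low_values(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.uniform(5, 10, size=(200, 3)))
        expr.iloc[:40, 0] = np.nan
        cohort = make_cohort(expr)
        pre = preprocess_cohort(
            cohort, PreprocessParams(min_gene_sd=0.0, quantile_normalize=False, seed=4)
        )
        observed = cohort.expr.iloc[40:, 0]
        cap = np.percentile(observed, 15)
        imputed = pre.expr.iloc[:40, 0]
        assert imputed.between(observed.min(), cap).all()

    def test_low_sd_genes_removed_after_normalization(self):
        rng = np.random.default_rng(5)
        wide = rng.normal(0, 3.0, size=(50, 4))
        cohort = make_cohort(wide)
        pre = preprocess_cohort(cohort, PreprocessParams(min_gene_sd=0.5, seed=0))
        assert (pre.expr.std(axis=0, ddof=0) >= 0.5).all()

    def test_all_genes_removed_is_error(self):
        cohort = make_cohort(np.ones((5, 2)))
        with pytest.raises(ValueError):
            preprocess_cohort(cohort, PreprocessParams(seed=0))

    def test_seeded_imputation_reproducible(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.uniform(size=(50, 4)))
        expr.iloc[:10, 2] = np.nan
        cohort = make_cohort(expr)
        a = preprocess_cohort(cohort, PreprocessParams(min_gene_sd=0.0, seed=9))
        b = preprocess_cohort(cohort, PreprocessParams(min_gene_sd=0.0, seed=9))
        assert a.expr.equals(b.expr)


class TestScoring:
    def test_zscore_closed_form(self):
        z = zscore_genes(pd.DataFrame({"G": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["G"], [-1.224744871, 0.0, 1.224744871])

    def test_zscore_constant_gene_error(self):
        with pytest.raises(ValueError, match="G"):
            zscore_genes(pd.DataFrame({"G": [1.0, 1.0]}))

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("ABC"))
        z = zscore_genes(df)
        assert np.allclose(z.to_numpy(), zscore_genes(z).to_numpy())

    def test_activity_score_is_mean_of_z(self):
        z = pd.DataFrame({"A": [1.0, -1.0], "B": [1.0, 3.0], "C": [0.0, 0.0]},
                         index=["P0", "P1"])
        sig = build_signature("s", ["A", "B"])
        scores = activity_score(z, sig)
        assert np.allclose(scores.scores, [1.0, 1.0])
        assert scores.genes_used == ["A", "B"]

    def test_single_gene_signature_equals_gene_z(self):
        z = pd.DataFrame({"A": [0.3, -0.7]}, index=["P0", "P1"])
        scores = activity_score(z, build_signature("s", ["A"]))
        assert np.allclose(scores.scores, z["A"])

    def test_no_surviving_gene_error(self):
        z = pd.DataFrame({"A": [0.1, 0.2]}, index=["P0", "P1"])
        with pytest.raises(ValueError):
            activity_score(z, build_signature("s", ["ZZZ"]))

    def test_score_tracks_planted_factor(self):
        cohort, truth = simulate_cohort(
            CohortSimConfig(n_patients=400, seed=5, missing_fraction=0.0,
                            detection_p_fraction=0.0)
        )
        pre = preprocess_cohort(cohort, PreprocessParams(seed=0))
        z = zscore_genes(pre.expr)
        sig = build_signature("s", truth.extras["signature_genes"])
        scores = activity_score(z, sig)
        r = np.corrcoef(scores.scores, truth.extras["factor"])[0, 1]
        assert r > 0.9


class TestStratification:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        strata = stratify_equal_halves(s)
        assert set(strata.group[strata.group == "low"].index) == {"a", "b"}
        assert set(strata.group[strata.group == "high"].index) == {"c", "d"}

    def test_odd_split_extra_to_low(self):
        s = pd.Series(np.arange(5.0), index=list("abcde"))
        strata = stratify_equal_halves(s)
        assert (strata.group == "low").sum() == 3
        assert (strata.group == "high").sum() == 2

    def test_all_tied_deterministic_by_patient_id(self):
        s = pd.Series([1.0] * 4, index=["d", "b", "a", "c"])
        a = stratify_equal_halves(s)
        b = stratify_equal_halves(s.sort_index())
        assert a.group.sort_index().equals(b.group.sort_index())
        assert set(a.group[a.group == "low"].index) == {"a", "b"}


class TestSurvivalEstimates:
    def test_km_matches_empirical_survival_without_censoring(self):
        cohort = make_cohort(
            np.tile(np.arange(8.0)[:, None], (1, 2)),
            times=[1, 2, 3, 4, 10, 20, 30, 40],
            events=[1] * 8,
        )
        group = pd.Series(["low"] * 4 + ["high"] * 4, index=cohort.patients)
        from invasig.survival import StrataAssignment

        res = km_logrank(cohort, StrataAssignment(group=group))
        low = res.km_curves["low"]
        s_at_2 = low.loc[low["time"] == 2, "survival"].iloc[0]
        assert s_at_2 == pytest.approx(0.5)

    def test_identical_groups_logrank_null(self):
        times = [5, 6, 7, 8] * 2
        cohort = make_cohort(np.ones((8, 2)), times=times, events=[1] * 8)
        group = pd.Series(["low"] * 4 + ["high"] * 4, index=cohort.patients)
        from invasig.survival import StrataAssignment

        res = km_logrank(cohort, StrataAssignment(group=group))
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_single_event_flags_nonconvergence(self):
        cohort = make_cohort(
            np.tile(np.arange(6.0)[:, None], (1, 2)),
            times=[1, 2, 3, 4, 5, 6],
            events=[1, 0, 0, 0, 0, 0],
        )
        group = pd.Series(["low"] * 3 + ["high"] * 3, index=cohort.patients)
        from invasig.survival import StrataAssignment

        res = cox_hr(cohort, StrataAssignment(group=group))
        assert not res.converged

    def test_no_events_is_error(self):
        cohort = make_cohort(np.ones((4, 2)), events=[0, 0, 0, 0])
        group = pd.Series(["low", "low", "high", "high"], index=cohort.patients)
        from invasig.survival import StrataAssignment

        with pytest.raises(ValueError):
            cox_hr(cohort, StrataAssignment(group=group))

    def test_hpv_filter_is_row_filter(self):
        cohort = make_cohort(np.ones((4, 2)), hpv=["negative", "positive",
                                                   "negative", "positive"])
        kept = exclude_hpv_positive(cohort)
        assert list(kept.patients) == ["P0", "P2"]

    def test_missing_clinical_column_schema_error(self):
        expr = pd.DataFrame(np.ones((3, 2)), index=["P0", "P1", "P2"])
        clinical = pd.DataFrame({"os_time_days": [1.0, 2, 3]}, index=expr.index)
        with pytest.raises(SchemaError):
            CohortTable(expr=expr, clinical=clinical)


class TestScreen:
    def test_monotone_hrs_across_planted_cohorts(self):
        cohorts = []
        sig = None
        for i, hr in enumerate([1.0, 1.5, 2.0]):
            cohort, truth = simulate_cohort(
                CohortSimConfig(n_patients=600, group_hr=hr, seed=40 + i,
                                name=f"cohort-hr{hr}")
            )
            cohorts.append(cohort)
            sig = build_signature("s", truth.extras["signature_genes"])
        table = pan_cohort_screen(cohorts, sig, PreprocessParams(seed=1))
        assert not table["failed"].any()
        assert list(table["hr"]) == sorted(table["hr"])

    def test_failed_cohort_recorded_not_raised(self):
        good, truth = simulate_cohort(CohortSimConfig(n_patients=100, seed=2))
        bad = make_cohort(np.ones((10, 3)))  # constant genes: all filtered
        sig = build_signature("s", truth.extras["signature_genes"])
        table = pan_cohort_screen([good, bad], sig)
        assert not table["failed"].iloc[0]
        assert table["failed"].iloc[1]

    def test_empty_screen(self):
        sig = build_signature("s", ["A"])
        assert len(pan_cohort_screen([], sig)) == 0
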