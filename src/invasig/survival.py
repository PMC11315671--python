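"""Cohort preprocessing, signature activity scoring, and survival stratification.

The chain mirrors a standard expression-cohort prognosis analysis:

1. optionally drop HPV-positive patients;
2. mask entries with poor probe detection p-values, drop genes with more
   than 70% missing values, impute the rest with seeded low-value draws,
   quantile-normalize across patients, and drop low-variability genes
   (SD < 0.5);
3. z-score each gene, average z-scores over the signature genes present
   to get a per-patient activity score;
4. split the cohort into equal halves at the score median and compare
   overall survival between the halves with a Kaplan-Meier/log-rank test
   and a univariate Cox proportional-hazards model (Efron ties, Wald CI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .datatypes import SchemaError
from .genesets import GeneSignature

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("os_time_days", "os_event")


@dataclass
class CohortTable:
    """Patient x gene expression with aligned clinical annotations.

    ``expr`` is patients x genes (may contain NaN); ``clinical`` shares the
    patient index and carries ``os_time_days``, ``os_event`` (0/1) and
    optional covariates such as ``hpv_status``.  ``detection_p`` (optional)
    has the same shape as ``expr``.
    """

    expr: pd.DataFrame
    clinical: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.clinical.columns]
        if missing:
            raise SchemaError(f"clinical table missing columns: {missing}")
        if not self.expr.index.equals(self.clinical.index):
            raise SchemaError("expression and clinical rows do not align 1:1")
        if self.detection_p is not None and self.detection_p.shape != self.expr.shape:
            raise SchemaError("detection_p shape differs from expression")
        if (self.clinical["os_time_days"] < 0).any():
            raise ValueError("os_time_days must be >= 0")

    @property
    def patients(self) -> pd.Index:
        return self.expr.index

    def subset_patients(self, keep: pd.Index | np.ndarray) -> "CohortTable":
        return CohortTable(
            expr=self.expr.loc[keep].copy(),
            clinical=self.clinical.loc[keep].copy(),
            detection_p=None if self.detection_p is None else self.detection_p.loc[keep].copy(),
            name=self.name,
        )


@dataclass
class PreprocessParams:
    detection_p_max: float = 0.05
    max_missing_frac: float = 0.70
    impute_percentile: float = 15.0
    min_gene_sd: float = 0.5
    seed: int = 0
    # imputation style: uniform draw in [gene min, gene percentile] ("uniform")
    # or the constant percentile value ("constant")
    impute_mode: str = "uniform"
    quantile_normalize: bool = True

    def validate(self) -> None:
        if not 0.0 < self.impute_percentile < 100.0:
            raise ValueError("impute_percentile must lie in (0, 100)")
        if not 0.0 < self.max_missing_frac < 1.0:
            raise ValueError("max_missing_frac must lie in (0, 1)")


def exclude_hpv_positive(cohort: CohortTable, column: str = "hpv_status") -> CohortTable:
    """Row filter removing HPV-positive patients (values 'positive'/1/True)."""
    if column not in cohort.clinical.columns:
        raise SchemaError(f"clinical table has no column {column!r}")
    status = cohort.clinical[column]
    positive = status.map(
        lambda v: str(v).strip().lower() in {"positive", "pos", "1", "true"}
    )
    return cohort.subset_patients(cohort.patients[~positive])


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every patient (row) onto the across-patient mean distribution.

    Each patient's sorted values are replaced by the mean of the order
    statistics across patients; ties within a patient receive the mean of
    their candidate values (average-rank convention).
    """
    x = expr.to_numpy(dtype=float)
    n_genes = x.shape[1]
    mean_sorted = np.sort(x, axis=1).mean(axis=0)
    ranks = scipy.stats.rankdata(x, axis=1, method="average")
    out = np.interp(ranks, np.arange(1, n_genes + 1), mean_sorted)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def preprocess_cohort(cohort: CohortTable, params: PreprocessParams | None = None) -> CohortTable:
    """Detection filter, missingness filter, imputation, quantile
    normalization, and low-variability gene removal, in that fixed order."""
    params = params or PreprocessParams()
    params.validate()
    expr = cohort.expr.astype(float).copy()

    # 1. mask poorly detected entries
    if cohort.detection_p is not None:
        expr = expr.mask(cohort.detection_p.to_numpy() > params.detection_p_max)

    # 2. remove genes with too many missing values
    missing_frac = expr.isna().mean(axis=0)
    expr = expr.loc[:, missing_frac <= params.max_missing_frac]
    if expr.shape[1] == 0:
        raise ValueError("all genes removed by the missingness filter")

    # 3. impute remaining missing entries with seeded low-value draws
    rng = np.random.default_rng(params.seed)
    for gene in expr.columns[expr.isna().any(axis=0).to_numpy()]:
        col = expr[gene]
        observed = col.dropna().to_numpy()
        lo = observed.min()
        hi = np.percentile(observed, params.impute_percentile)
        n_missing = int(col.isna().sum())
        if params.impute_mode == "constant":
            fill = np.full(n_missing, hi)
        else:
            fill = rng.uniform(lo, hi, size=n_missing)
        expr.loc[col.isna(), gene] = fill

    # 4. quantile normalization across patients
    if params.quantile_normalize:
        expr = quantile_normalize(expr)

    # 5. remove low-variability genes
    sd = expr.std(axis=0, ddof=0)
    expr = expr.loc[:, sd >= params.min_gene_sd]
    if expr.shape[1] == 0:
        raise ValueError("all genes removed by the variability filter")

    return CohortTable(expr=expr, clinical=cohort.clinical.copy(), name=cohort.name)


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score with population SD (ddof=0)."""
    sd = expr.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance gene: {zero.index[0]}")
    return (expr - expr.mean(axis=0)) / sd


@dataclass
class ActivityScores:
    scores: pd.Series  # per patient
    genes_used: list[str]


def activity_score(z: pd.DataFrame, signature: GeneSignature) -> ActivityScores:
    """Per-patient mean of z-scores over the signature genes present."""
    upper = {c.upper(): c for c in z.columns}
    used = [upper[g.upper()] for g in signature.genes if g.upper() in upper]
    absent = [g for g in signature.genes if g.upper() not in upper]
    if absent:
        log.warning("signature genes absent after preprocessing: %s", absent)
    if not used:
        raise ValueError("no signature gene survives preprocessing")
    return ActivityScores(scores=z[used].mean(axis=1).rename("activity"), genes_used=used)


@dataclass
class StrataAssignment:
    group: pd.Series  # per patient: "high" / "low"
    rule: dict = field(default_factory=dict)


def stratify_equal_halves(scores: ActivityScores | pd.Series) -> StrataAssignment:
    """Median split into equal halves: sort ascending by score (ties by
    patient id); the first ceil(n/2) patients form the low group."""
    s = scores.scores if isinstance(scores, ActivityScores) else scores
    if len(s) < 2:
        raise ValueError("need at least 2 patients to stratify")
    order = s.to_frame("score").assign(_pid=s.index.astype(str)).sort_values(
        ["score", "_pid"], kind="mergesort"
    )
    n = len(order)
    n_low = int(np.ceil(n / 2))
    group = pd.Series("high", index=order.index, name="group")
    group.iloc[:n_low] = "low"
    group = group.loc[s.index]
    return StrataAssignment(
        group=group,
        rule={"split": "equal_halves", "n_low": n_low, "n_high": n - n_low,
              "tie_break": "patient_id", "odd_patient_to": "low"},
    )


@dataclass
class SurvivalResult:
    km_curves: dict          # group -> DataFrame(time, survival, at_risk)
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    hr_p: float
    n_per_group: dict
    converged: bool = True
    risk_table: pd.DataFrame | None = None


def km_logrank(
    cohort: CohortTable,
    strata: StrataAssignment,
    risk_times: np.ndarray | None = None,
) -> SurvivalResult:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    time = cohort.clinical["os_time_days"]
    event = cohort.clinical["os_event"]
    groups = strata.group.loc[cohort.patients]
    curves, counts = {}, {}
    if risk_times is None:
        risk_times = np.linspace(0, float(time.max()), 6)
    risk_rows = {}
    for name in ("low", "high"):
        mask = (groups == name).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} has zero patients")
        km = KaplanMeierFitter(label=name)
        km.fit(time[mask], event_observed=event[mask])
        sf = km.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[name].to_numpy()}
        )
        counts[name] = int(mask.sum())
        risk_rows[name] = [
            int((time[mask].to_numpy() >= t).sum()) for t in risk_times
        ]
    lr = logrank_test(
        time[(groups == "high").to_numpy()], time[(groups == "low").to_numpy()],
        event_observed_A=event[(groups == "high").to_numpy()],
        event_observed_B=event[(groups == "low").to_numpy()],
    )
    risk_table = pd.DataFrame(risk_rows, index=pd.Index(risk_times, name="time")).T
    return SurvivalResult(
        km_curves=curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=float("nan"),
        hr_ci=(float("nan"), float("nan")),
        hr_p=float("nan"),
        n_per_group=counts,
        risk_table=risk_table,
    )


def cox_hr(cohort: CohortTable, strata: StrataAssignment) -> SurvivalResult:
    """Univariate Cox PH of overall survival on I(high activity).

    Efron tie handling; HR = exp(beta) with the Wald 95% CI
    exp(beta +/- 1.96 SE).  Non-convergence (e.g. a single event) is
    reported through the ``converged`` flag rather than raised.
    """
    groups = strata.group.loc[cohort.patients]
    if int(cohort.clinical["os_event"].sum()) == 0:
        raise ValueError("no events observed")
    df = pd.DataFrame(
        {
            "T": cohort.clinical["os_time_days"].to_numpy(dtype=float),
            "E": cohort.clinical["os_event"].to_numpy(dtype=int),
            "high": (groups == "high").to_numpy(dtype=float),
        }
    )
    result = km_logrank(cohort, strata)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
        beta = float(cph.params_["high"])
        se = float(cph.standard_errors_["high"])
        converged = np.isfinite(beta) and np.isfinite(se) and se < 50
        with np.errstate(over="ignore"):
            result.hazard_ratio = float(np.exp(beta))
            result.hr_ci = (float(np.exp(beta - 1.96 * se)),
                            float(np.exp(beta + 1.96 * se)))
        result.hr_p = float(cph.summary.loc["high", "p"])
        result.converged = bool(converged)
    except Exception as exc:  # degenerate designs: flag, don't crash
        log.warning("Cox fit failed: %s", exc)
        result.converged = False
    return result


def run_survival_chain(
    cohort: CohortTable,
    signature: GeneSignature,
    params: PreprocessParams | None = None,
    drop_hpv_positive: bool = False,
) -> dict:
    """Preprocess -> z-score -> activity score -> stratify -> KM/log-rank/Cox."""
    if drop_hpv_positive and "hpv_status" in cohort.clinical.columns:
        cohort = exclude_hpv_positive(cohort)
    pre = preprocess_cohort(cohort, params)
    z = zscore_genes(pre.expr)
    scores = activity_score(z, signature)
    strata = stratify_equal_halves(scores)
    res = cox_hr(pre, strata)
    return {
        "cohort": cohort.name,
        "n": len(pre.patients),
        "scores": scores,
        "strata": strata,
        "result": res,
    }


def pan_cohort_screen(
    cohorts: list[CohortTable],
    signature: GeneSignature,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Run the full chain on each cohort; one row per cohort, failures
    recorded without aborting the screen."""
    rows = []
    for cohort in cohorts:
        row = {"cohort": cohort.name, "n": len(cohort.patients)}
        try:
            out = run_survival_chain(cohort, signature, params)
            res = out["result"]
            row.update(
                hr=res.hazard_ratio, hr_lo=res.hr_ci[0], hr_hi=res.hr_ci[1],
                logrank_p=res.logrank_p, failed=False, error="",
            )
        except Exception as exc:
            row.update(hr=np.nan, hr_lo=np.nan, hr_hi=np.nan,
                       logrank_p=np.nan, failed=True, error=str(exc))
        rows.append(row)
    columns = ["cohort", "n", "hr", "hr_lo", "hr_hi", "logrank_p", "failed", "error"]
    return pd.DataFrame(rows, columns=columns)
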