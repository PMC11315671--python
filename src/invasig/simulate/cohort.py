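"""Synthetic expression cohort whose survival depends on a planted signature.

A latent per-patient factor drives the signature genes; the planted
activity score (mean z-score of the signature genes on the clean matrix)
defines high/low groups at the median, and overall survival is drawn
from an exponential model whose hazard is multiplied by ``group_hr`` in
the high group.  Censoring is independent uniform, calibrated so the
expected censored fraction matches ``censor_rate``.  Missing entries and
poor detection p-values are injected at the configured rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from ..datatypes import GroundTruth
from ..survival import CohortTable


class InvalidConfigError(ValueError):
    pass


@dataclass
class CohortSimConfig:
    n_patients: int = 500
    n_genes: int = 200
    signature_genes: list[str] = field(
        default_factory=lambda: [f"SIGG{i:02d}" for i in range(7)]
    )
    group_hr: float = 2.0
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    censor_rate: float = 0.2
    missing_fraction: float = 0.05
    detection_p_fraction: float = 0.02
    hpv_positive_fraction: float = 0.0
    # noise SD of a signature gene around the unit-loading latent factor;
    # 1/3 puts the pairwise correlation of signature genes near 0.9, the
    # regime a strongly cross-correlated cluster represents
    signature_noise_sd: float = 1.0 / 3.0
    seed: int = 0
    name: str = "synthetic-cohort"

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_genes < 1:
            raise InvalidConfigError("cohort dimensions too small")
        if not self.signature_genes:
            raise InvalidConfigError("signature_genes must be non-empty")
        if len(self.signature_genes) > self.n_genes:
            raise InvalidConfigError("more signature genes than genes")
        if self.group_hr <= 0 or self.baseline_hazard <= 0:
            raise InvalidConfigError("hazards must be positive")
        for nm in ("missing_fraction", "detection_p_fraction", "hpv_positive_fraction"):
            if not 0.0 <= getattr(self, nm) <= 1.0:
                raise InvalidConfigError(f"{nm} must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise InvalidConfigError("censor_rate must lie in [0, 1)")


def _uniform_censor_bound(rate: float, hazard: float) -> float:
    """Upper bound c of U(0, c) censoring so that P(censor) = rate for an
    exponential(hazard) event time: (1 - exp(-h c)) / (h c) = rate."""
    if rate <= 0:
        return np.inf

    def f(c: float) -> float:
        return (1.0 - np.exp(-hazard * c)) / (hazard * c) - rate

    return scipy.optimize.brentq(f, 1e-9 / hazard, 1e6 / hazard)


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortTable, GroundTruth]:
    """Simulate a patient x gene cohort with planted prognostic signature."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes

    sig = [s.upper() for s in config.signature_genes]
    background = [f"BGG{i:04d}" for i in range(g - len(sig))]
    genes = sig + background
    patients = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")

    factor = rng.normal(size=n)
    expr = np.empty((n, g))
    # signature genes: unit loading on the factor plus noise, scaled and
    # shifted to microarray-like intensities with SD comfortably above the
    # low-variability cutoff
    k = len(sig)
    for j in range(k):
        raw = factor + rng.normal(scale=config.signature_noise_sd, size=n)
        expr[:, j] = 8.0 + 1.2 * raw
    for j in range(k, g):
        mu = rng.uniform(5.0, 11.0)
        sd = rng.uniform(0.8, 1.6)
        expr[:, j] = mu + sd * rng.normal(size=n)

    # planted activity score on the clean matrix (mean of per-gene z-scores)
    clean = expr[:, :k]
    z = (clean - clean.mean(axis=0)) / clean.std(axis=0)
    planted_score = z.mean(axis=1)
    order = np.argsort(planted_score, kind="mergesort")
    n_low = int(np.ceil(n / 2))
    group = np.empty(n, dtype=object)
    group[order[:n_low]] = "low"
    group[order[n_low:]] = "high"

    hazard = config.baseline_hazard * np.where(group == "high", config.group_hr, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    mean_hazard = config.baseline_hazard * (1 + config.group_hr) / 2.0
    c = _uniform_censor_bound(config.censor_rate, mean_hazard)
    censor_time = rng.uniform(0, c, size=n) if np.isfinite(c) else np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    expr_df = pd.DataFrame(expr, index=patients, columns=genes)

    # missingness and detection failure concentrate on low-expression
    # entries, as they do for probes near the detection limit -- the
    # regime that justifies low-value imputation downstream
    def _low_expression_entries(frac: float) -> np.ndarray:
        chosen = np.zeros(expr.shape, dtype=bool)
        n_pick = int(round(frac * n))
        if n_pick == 0:
            return chosen
        for j in range(g):
            col = expr[:, j]
            zcol = (col - col.mean()) / col.std()
            w = np.exp(-2.0 * zcol)
            idx = rng.choice(n, size=n_pick, replace=False, p=w / w.sum())
            chosen[idx, j] = True
        return chosen

    detection_p = None
    if config.detection_p_fraction > 0:
        p = rng.uniform(0.0, 0.04, size=expr.shape)
        bad = _low_expression_entries(config.detection_p_fraction)
        p[bad] = rng.uniform(0.06, 1.0, size=int(bad.sum()))
        detection_p = pd.DataFrame(p, index=patients, columns=genes)

    if config.missing_fraction > 0:
        miss = _low_expression_entries(config.missing_fraction)
        expr_df = expr_df.mask(miss)

    hpv = np.where(
        rng.random(n) < config.hpv_positive_fraction, "positive", "negative"
    )
    clinical = pd.DataFrame(
        {
            "os_time_days": os_time,
            "os_event": os_event,
            "hpv_status": hpv,
        },
        index=patients,
    )
    cohort = CohortTable(expr=expr_df, clinical=clinical,
                         detection_p=detection_p, name=config.name)
    truth = GroundTruth(
        true_group={p: str(gr) for p, gr in zip(patients, group)},
        extras={
            "planted_score": pd.Series(planted_score, index=patients),
            "factor": pd.Series(factor, index=patients),
            "signature_genes": sig,
            "group_hr": config.group_hr,
        },
    )
    return cohort, truth
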