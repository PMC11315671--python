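"""Single-cell quality control: depth/mito gate, gene-UMI envelope, doublet gate.

Three filters are applied per sample, in a fixed order:

1. **Low quality** — drop cells with total UMIs <= ``min_umis`` (default
   1000) or mitochondrial read fraction > ``max_mito`` (default 5%).
2. **Gene-UMI envelope** — regress log10(genes detected + 1) on
   log10(UMIs + 1) and keep cells inside the two-sided prediction
   interval at confidence 1 - alpha, where alpha is 1 divided by the
   number of droplets in the sample.
3. **Doublets** — drop cells with doublet score > ``doublet_cutoff``
   (default 0.5); the score itself is taken as input.

The boundary conventions are deliberate: the UMI bound is exclusive
(a cell at exactly 1000 UMIs is removed), the mito and doublet bounds are
strict (exactly 5% / exactly 0.5 are kept), and the gene-UMI envelope is
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import CELL_META_COLUMNS, CellMatrix, SchemaError

FILTER_ORDER = ("low_quality", "gene_umi", "doublet")


@dataclass
class QCThresholds:
    min_umis: int = 1000       # exclusive lower bound on total UMIs
    max_mito: float = 0.05     # inclusive upper bound on mito fraction
    doublet_cutoff: float = 0.5  # exclusive upper bound on doublet score
    robust: bool = False       # Huber-weighted gene-UMI fit instead of OLS


@dataclass
class GeneUmiBounds:
    """Per-cell prediction-interval bounds for genes detected given UMIs."""

    barcodes: list[str]
    lower: np.ndarray  # on the log10(genes+1) scale
    upper: np.ndarray
    slope: float
    intercept: float
    alpha: float
    degenerate: bool = False


@dataclass
class QCReport:
    """Accounting of cells removed by each filter, per sample."""

    per_sample: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "n_input", "removed_low_quality",
                     "removed_gene_umi", "removed_doublet", "retained"]
        )
    )

    def validate_conservation(self) -> None:
        t = self.per_sample
        removed = t[["removed_low_quality", "removed_gene_umi", "removed_doublet"]].sum(axis=1)
        if not (t["n_input"] == removed + t["retained"]).all():
            raise AssertionError("QC report does not conserve cells")

    def to_dict(self) -> dict:
        return {"per_sample": self.per_sample.to_dict(orient="records"),
                "filter_order": list(FILTER_ORDER)}


def _require_meta(cells: CellMatrix, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in cells.cell_meta.columns]
    if missing:
        raise SchemaError(f"cell metadata missing columns: {missing}")


def filter_low_quality(cells: CellMatrix, t: QCThresholds) -> CellMatrix:
    """Keep cells with n_umis > min_umis and mito_frac <= max_mito."""
    _require_meta(cells, ("n_umis", "mito_frac"))
    meta = cells.cell_meta
    keep = (meta["n_umis"].to_numpy() > t.min_umis) & (
        meta["mito_frac"].to_numpy() <= t.max_mito
    )
    return cells.subset_cells(keep)


def fit_gene_umi_model(cells: CellMatrix, alpha: float, robust: bool = False) -> GeneUmiBounds:
    """Fit genes-detected ~ UMIs in log10 space; return prediction bounds.

    The straight line is fitted by ordinary least squares (optionally with
    Huber weights) and the classical two-sided prediction interval at
    confidence 1 - alpha is evaluated at every cell's own UMI count.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if cells.n_cells < 3:
        raise ValueError("need at least 3 cells to fit the gene-UMI model")
    x = np.log10(cells.cell_meta["n_umis"].to_numpy() + 1.0)
    y = np.log10(cells.cell_meta["n_genes_detected"].to_numpy() + 1.0)
    n = x.size
    if np.ptp(x) == 0.0:
        inf = np.full(n, np.inf)
        return GeneUmiBounds(list(cells.barcodes), -inf, inf,
                             slope=0.0, intercept=float(y.mean()),
                             alpha=alpha, degenerate=True)
    if robust:
        import statsmodels.api as sm

        fit = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
        intercept, slope = fit.params
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    dof = n - 2
    s = np.sqrt((resid**2).sum() / dof)
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    tq = scipy.stats.t.ppf(1.0 - alpha / 2.0, dof)
    half = tq * s * np.sqrt(1.0 + 1.0 / n + (x - xbar) ** 2 / sxx)
    pred = intercept + slope * x
    return GeneUmiBounds(list(cells.barcodes), pred - half, pred + half,
                         slope=float(slope), intercept=float(intercept), alpha=alpha)


def filter_gene_umi_outliers(cells: CellMatrix, bounds: GeneUmiBounds) -> CellMatrix:
    """Keep cells whose observed genes-detected lies within [lower, upper]."""
    if bounds.barcodes != list(cells.barcodes):
        raise ValueError("gene-UMI bounds were computed on a different cell set")
    if cells.n_cells == 0:
        return cells
    y = np.log10(cells.cell_meta["n_genes_detected"].to_numpy() + 1.0)
    keep = (y >= bounds.lower) & (y <= bounds.upper)
    return cells.subset_cells(keep)


def filter_doublets(cells: CellMatrix, cutoff: float = 0.5) -> CellMatrix:
    """Keep cells with doublet score <= cutoff."""
    _require_meta(cells, ("doublet_score",))
    scores = cells.cell_meta["doublet_score"].to_numpy()
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("doublet scores must lie in [0, 1]")
    return cells.subset_cells(scores <= cutoff)


def run_qc(cells: CellMatrix, thresholds: QCThresholds | None = None) -> tuple[CellMatrix, QCReport]:
    """Apply the three filters per sample, in order, and account for every cell.

    alpha for the gene-UMI envelope is computed per sample as 1 divided by
    that sample's droplet (barcode) count.
    """
    thresholds = thresholds or QCThresholds()
    _require_meta(cells, CELL_META_COLUMNS)
    rows = []
    kept_barcodes: set[str] = set()
    for sample in pd.unique(cells.cell_meta["sample"]):
        sub = cells.subset_cells(
            (cells.cell_meta["sample"] == sample).to_numpy()
        )
        n_input = sub.n_cells
        alpha = 1.0 / n_input
        stage1 = filter_low_quality(sub, thresholds)
        if stage1.n_cells >= 3:
            bounds = fit_gene_umi_model(stage1, alpha=alpha, robust=thresholds.robust)
            stage2 = filter_gene_umi_outliers(stage1, bounds)
        else:
            stage2 = stage1
        stage3 = filter_doublets(stage2, thresholds.doublet_cutoff)
        kept_barcodes.update(stage3.barcodes)
        rows.append(
            {
                "sample": sample,
                "n_input": n_input,
                "removed_low_quality": n_input - stage1.n_cells,
                "removed_gene_umi": stage1.n_cells - stage2.n_cells,
                "removed_doublet": stage2.n_cells - stage3.n_cells,
                "retained": stage3.n_cells,
            }
        )
    keep = np.array([b in kept_barcodes for b in cells.barcodes])
    report = QCReport(per_sample=pd.DataFrame(rows))
    report.validate_conservation()
    return cells.subset_cells(keep), report
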