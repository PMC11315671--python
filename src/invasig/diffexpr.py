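"""Normalization and per-gene differential expression between two cell groups.

Counts are depth-normalized to a fixed scale (counts per 10,000 by
default) and log-transformed; per-gene differences between two disjoint
cell groups are tested with a two-sided Wilcoxon rank-sum test and
corrected with Benjamini-Hochberg across all tested genes.  Fold changes
are log2 ratios of the scaled group means with a pseudocount of 1, so a
gene passes the usual gates at logFC >= 0.5 and adjusted p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CellMatrix

DE_COLUMNS = ("gene", "log_fc", "p_value", "adj_p", "mean_a", "mean_b", "direction")


@dataclass
class NormalizedMatrix:
    """Gene x cell matrix of ln(1 + scale_factor * count / cell_total)."""

    values: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame
    scale_factor: float = 10_000.0

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


def normalize_counts(cells: CellMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell and log1p-transform."""
    totals = cells.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell with zero total counts: {cells.barcodes[zero[0]]}")
    values = np.log1p(scale_factor * cells.counts / totals[None, :])
    return NormalizedMatrix(
        values=values,
        gene_names=list(cells.gene_names),
        barcodes=list(cells.barcodes),
        cell_meta=cells.cell_meta.copy(),
        scale_factor=scale_factor,
    )


def _group_indices(norm: NormalizedMatrix, group: object) -> np.ndarray:
    """Resolve a group given as barcodes, boolean mask, or a condition label."""
    if isinstance(group, str):
        idx = np.flatnonzero((norm.cell_meta["condition"] == group).to_numpy())
    else:
        arr = np.asarray(group)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif arr.dtype.kind in "iu":
            idx = arr
        else:
            lookup = {b: i for i, b in enumerate(norm.barcodes)}
            idx = np.array([lookup[b] for b in arr], dtype=int)
    if idx.size == 0:
        raise ValueError("empty cell group")
    return idx


def differential_expression(
    norm: NormalizedMatrix,
    group_a: object,
    group_b: object,
    method: str = "auto",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two disjoint cell groups.

    ``log_fc`` is log2((scaled mean in A + 1) / (scaled mean in B + 1))
    where the scaled mean is the per-group mean of ``scale_factor *
    count / total`` (recovered from the log-normalized values).  p-values
    are BH-adjusted across all genes in the table.

    ``method`` is passed to :func:`scipy.stats.mannwhitneyu`: ``"auto"``
    uses the exact null for small tie-free groups and the tie- and
    continuity-corrected normal approximation otherwise.
    """
    ia = _group_indices(norm, group_a)
    ib = _group_indices(norm, group_b)
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")
    a = norm.values[:, ia]
    b = norm.values[:, ib]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(a, b, axis=1, method=method, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # constant genes carry no evidence
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    adj_p = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": norm.gene_names,
            "log_fc": log_fc,
            "p_value": p,
            "adj_p": adj_p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "direction": np.where(log_fc >= 0, "up_in_A", "up_in_B"),
        }
    )
    table.attrs["provenance"] = {
        "test": "wilcoxon_rank_sum_two_sided",
        "method": method,
        "log_fc": "log2((mean_scaled_A + 1)/(mean_scaled_B + 1))",
        "scale_factor": norm.scale_factor,
        "adjustment": "benjamini_hochberg",
        "n_a": int(ia.size),
        "n_b": int(ib.size),
    }
    return table


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def select_de_genes(
    de: pd.DataFrame, lfc_min: float = 0.5, alpha: float = 0.001
) -> tuple[list[str], list[str]]:
    """Split significant genes into (up in A, up in B).

    Inclusion is ``log_fc >= lfc_min`` (inclusive) with ``adj_p < alpha``
    (strict); the down list is symmetric at ``log_fc <= -lfc_min``.  Each
    list is sorted by |log_fc| descending, ties broken by gene name.
    """
    sig = de[de["adj_p"] < alpha]
    up_a = sig[sig["log_fc"] >= lfc_min]
    up_b = sig[sig["log_fc"] <= -lfc_min]

    def _order(t: pd.DataFrame) -> list[str]:
        t = t.assign(_abs=t["log_fc"].abs()).sort_values(
            ["_abs", "gene"], ascending=[False, True]
        )
        return list(t["gene"])

    return _order(up_a), _order(up_b)


def exclude_gene_set(genes: list[str], excluded) -> list[str]:
    """Order-preserving set difference; matching is case-insensitive."""
    members = {g.upper() for g in getattr(excluded, "members", excluded)}
    return [g for g in genes if g.upper() not in members]


def panel_summary(
    norm: NormalizedMatrix,
    group_a: object,
    group_b: object,
    panel: list[str],
    lfc_flag: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene group means (z-scaled across the two groups) and DE stats
    for a gene panel; returns (table, missing genes)."""
    present = [g for g in panel if g in norm.gene_names]
    missing = [g for g in panel if g not in norm.gene_names]
    if not present:
        return pd.DataFrame(columns=["gene", "scaled_mean_a", "scaled_mean_b",
                                     "log_fc", "adj_p", "flagged"]), missing
    de = differential_expression(norm, group_a, group_b)
    de = de.set_index("gene").loc[present]
    means = de[["mean_a", "mean_b"]].to_numpy()
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    scaled = np.where(sd > 0, (means - mu) / np.where(sd == 0, 1, sd), 0.0)
    table = pd.DataFrame(
        {
            "gene": present,
            "scaled_mean_a": scaled[:, 0],
            "scaled_mean_b": scaled[:, 1],
            "log_fc": de["log_fc"].to_numpy(),
            "adj_p": de["adj_p"].to_numpy(),
            "flagged": de["log_fc"].to_numpy() >= lfc_flag,
        }
    )
    return table, missing
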