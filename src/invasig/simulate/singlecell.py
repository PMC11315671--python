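"""Negative-binomial single-cell count simulator with planted QC flags and DE genes.

The generator emulates a two-condition organoid invasion experiment
(non-invasive vs invasive cells) at the statistical level the downstream
QC and differential-expression stages assume:

* counts are negative-binomial with per-gene relative abundances and a
  log-normal per-cell sequencing depth;
* a chosen subset of genes carries a planted log2 fold change between the
  two conditions;
* a fraction of cells is forced below the quality thresholds (total UMIs
  <= 1000 or mitochondrial fraction > 5%);
* a fraction of cells carries a doublet score above 0.5, all other cells
  score at or below 0.5.

Every flag is recorded in the returned :class:`~invasig.datatypes.GroundTruth`
so parameter-recovery tests can compare pipeline output against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datatypes import CellMatrix, GroundTruth

CONDITIONS = ("non-invasive", "invasive")


class InvalidConfigError(ValueError):
    pass


@dataclass
class ScSimConfig:
    """Parameters of the single-cell count generator."""

    n_genes: int = 2000
    n_cells_per_group: int = 300
    n_de_genes: int = 50
    de_log2fc: float = 1.5
    nb_dispersion: float = 0.1
    mito_gene_fraction: float = 0.02
    depth_mean: int = 5000
    lowq_cell_fraction: float = 0.05
    doublet_fraction: float = 0.05
    seed: int = 0
    # spread of the per-cell depth: log-normal truncated at +/- 2 sd
    depth_sigma: float = 0.35
    # cell-to-cell transcriptome-diversity modulation: per-cell exponent on
    # the gene abundances drawn from U(1 - spread, 1 + spread)
    diversity_spread: float = 0.08

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_group <= 0 or self.depth_mean <= 0:
            raise InvalidConfigError("dimensions and depth must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise InvalidConfigError("n_de_genes must lie in [0, n_genes]")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        for name in ("mito_gene_fraction", "lowq_cell_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2), vectorised."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_sc_counts(config: ScSimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Simulate a two-condition count matrix with planted QC flags and DE genes."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    gene_names = [f"MT-SIM{i:04d}" for i in range(n_mito)] + [
        f"SIMG{i:04d}" for i in range(config.n_genes - n_mito)
    ]
    mito_idx = np.arange(n_mito)
    nonmito_idx = np.arange(n_mito, config.n_genes)

    # relative abundances spanning several decades, as real transcriptomes
    # do; mitochondrial genes together take ~2.5% of reads
    weights = rng.lognormal(mean=0.0, sigma=2.0, size=config.n_genes)
    if n_mito:
        mito_share = 0.025
        weights[mito_idx] *= (
            mito_share / (1 - mito_share) * weights[nonmito_idx].sum() / weights[mito_idx].sum()
        )

    # plant effects on genes expressed at a detectable level (expected
    # >= ~2 counts per 10k reads): an effect on a silent gene is not an
    # observable study condition
    share = weights / weights.sum()
    if config.n_de_genes > len(nonmito_idx):
        raise InvalidConfigError("n_de_genes exceeds the non-mitochondrial gene count")
    eligible = nonmito_idx[share[nonmito_idx] >= 2e-4]
    if len(eligible) < config.n_de_genes:
        eligible = nonmito_idx[np.argsort(share[nonmito_idx])[::-1][: max(
            config.n_de_genes, 1)]]
    de_idx = (
        np.sort(rng.choice(eligible, size=config.n_de_genes, replace=False))
        if config.n_de_genes
        else np.array([], dtype=int)
    )
    fold = np.ones(config.n_genes)
    fold[de_idx] = 2.0 ** config.de_log2fc  # up in the invasive group

    n_cells = 2 * config.n_cells_per_group
    group = np.repeat([0, 1], config.n_cells_per_group)
    condition = np.array(CONDITIONS)[group]
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]

    # truncated log-normal depth: the extreme depth tails are exactly what
    # the low-quality class models, so healthy cells stay within +/- 2 sd
    z = rng.normal(size=n_cells)
    while True:
        extreme = np.abs(z) > 2.0
        if not extreme.any():
            break
        z[extreme] = rng.normal(size=int(extreme.sum()))
    mu_ln = np.log(config.depth_mean) - config.depth_sigma**2 / 2
    depth = np.exp(mu_ln + config.depth_sigma * z)

    # per-cell transcriptome diversity: a bounded exponent on the abundance
    # profile (cells differ in how many genes they express at a given depth)
    tau = rng.uniform(1 - config.diversity_spread, 1 + config.diversity_spread,
                      size=n_cells)
    wt = np.exp(np.log(weights)[:, None] * tau[None, :])  # genes x cells
    wt[:, group == 1] *= fold[:, None]
    probs = wt / wt.sum(axis=0)
    mean_mat = probs * depth[None, :]
    counts = _nb_draw(rng, mean_mat, config.nb_dispersion)

    # --- plant QC flags ------------------------------------------------
    n_lowq = int(round(config.lowq_cell_fraction * n_cells))
    lowq_cells = rng.choice(n_cells, size=n_lowq, replace=False) if n_lowq else np.array([], int)
    flags = np.full(n_cells, "good", dtype=object)
    flags[lowq_cells] = "lowq"

    for j, cell in enumerate(lowq_cells):
        col = counts[:, cell]
        total = col.sum()
        if j % 2 == 0:
            # low-depth barcode: thin counts down to <= 1000 total UMIs
            target = rng.integers(200, 800)
            thinned = rng.binomial(col, min(1.0, target / max(total, 1)))
            while thinned.sum() > 1000:  # pragma: no cover - thinning overshoot is ~impossible
                thinned = rng.binomial(thinned, 0.8)
            counts[:, cell] = thinned
        elif n_mito:
            # mito-damaged barcode: add mitochondrial reads above the 5% gate
            f_target = rng.uniform(0.08, 0.20)
            mito_now = col[mito_idx].sum()
            add = int(np.ceil((f_target * total - mito_now) / (1 - f_target)))
            if add > 0:
                w = weights[mito_idx] / weights[mito_idx].sum()
                counts[mito_idx, cell] += rng.multinomial(add, w)
        else:
            # no mito genes simulated: fall back to depth-based flagging
            thinned = rng.binomial(col, min(1.0, 500 / max(total, 1)))
            counts[:, cell] = thinned

    # guarantee that unflagged cells really satisfy the quality gates
    good_mask = flags == "good"
    totals = counts.sum(axis=0)
    for cell in np.flatnonzero(good_mask & (totals <= 1000)):
        deficit = int(1001 - totals[cell]) + int(rng.integers(50, 200))
        w = weights[nonmito_idx] / weights[nonmito_idx].sum()
        counts[nonmito_idx, cell] += rng.multinomial(deficit, w)
    if n_mito:
        totals = counts.sum(axis=0)
        mito_tot = counts[mito_idx].sum(axis=0)
        for cell in np.flatnonzero(good_mask & (mito_tot / np.maximum(totals, 1) > 0.05)):
            allowed = int(np.floor(0.05 * totals[cell]))
            excess = int(mito_tot[cell] - allowed)
            col_m = counts[mito_idx, cell].astype(float)
            drop = rng.multivariate_hypergeometric(counts[mito_idx, cell], excess)
            counts[mito_idx, cell] -= drop
            w = weights[nonmito_idx] / weights[nonmito_idx].sum()
            counts[nonmito_idx, cell] += rng.multinomial(excess, w)
            del col_m

    # --- doublet scores -------------------------------------------------
    n_dbl = int(round(config.doublet_fraction * n_cells))
    good_pool = np.flatnonzero(flags == "good")
    if n_dbl > len(good_pool):
        raise InvalidConfigError("doublet_fraction too large for the remaining cells")
    dbl_cells = rng.choice(good_pool, size=n_dbl, replace=False) if n_dbl else np.array([], int)
    flags[dbl_cells] = "doublet"

    scores = np.empty(n_cells)
    for i in range(n_cells):
        if flags[i] == "doublet":
            s = rng.beta(8, 2)
            while s <= 0.5:
                s = rng.beta(8, 2)
        else:
            s = rng.beta(2, 8)
            while s > 0.5:
                s = rng.beta(2, 8)
        scores[i] = s

    cells = CellMatrix.from_counts(
        counts=counts,
        gene_names=gene_names,
        barcodes=barcodes,
        sample=list(condition),
        condition=list(condition),
        doublet_score=scores,
    )
    truth = GroundTruth(
        de_gene_names=[gene_names[i] for i in de_idx],
        qc_flags={barcodes[i]: str(flags[i]) for i in range(n_cells)},
        extras={"de_log2fc": config.de_log2fc, "conditions": CONDITIONS},
    )
    return cells, truth
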