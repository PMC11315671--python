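"""Gene sets, over-representation tests, and signature construction.

Signatures are built by intersecting differentially expressed genes with
curated motility/adhesion gene sets (GMT files), testing each set for
over-representation with the hypergeometric tail, and — on a reference
cohort — keeping the subset of candidate genes that forms a strongly
cross-correlated cluster under average-linkage hierarchical clustering
on 1 - Pearson r.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

log = logging.getLogger(__name__)


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]  # upper-cased, deduplicated, order of first appearance

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.members:
            gu = str(g).upper()
            if gu in seen:
                log.warning("duplicate member %s in gene set %s", gu, self.name)
            seen.setdefault(gu, None)
        self.members = list(seen)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection(dict):
    """Ordered mapping name -> GeneSet."""

    def add(self, gs: GeneSet) -> None:
        self[gs.name] = gs


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member genes...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            coll.add(GeneSet(fields[0], fields[1], fields[2:]))
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection.values():
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def intersect_with_sets(query: list[str], sets: GeneSetCollection) -> dict:
    """Exact intersections of a query gene list with each set, plus the
    Venn-style counts for every pairwise region between sets."""
    q = {g.upper() for g in query}
    overlaps = {name: sorted(q & set(gs.members)) for name, gs in sets.items()}
    counts = {name: len(ov) for name, ov in overlaps.items()}
    pairwise = {}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            both = q & set(sets[a].members) & set(sets[b].members)
            pairwise[(a, b)] = sorted(both)
    return {"overlaps": overlaps, "counts": counts, "pairwise": pairwise,
            "query_size": len(q)}


def overrepresentation_test(
    query: list[str], universe: list[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of each set in the query.

    For a universe of N genes containing K set members and a query of n
    genes with k members observed, p = P(X >= k) for X hypergeometric,
    identical to one-sided Fisher's exact on the 2x2 table.  BH-adjusted
    across sets.
    """
    uni = {g.upper() for g in universe}
    q = {g.upper() for g in query}
    if not q <= uni:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, gs in sets.items():
        members = set(gs.members) & uni
        K = len(members)
        k = len(q & members)
        p = scipy.stats.hypergeom.sf(k - 1, N, K, n)
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p_value": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        table["adj_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def cross_correlation_cluster(
    cohort,
    candidates: list[str],
    min_abs_r: float = 0.5,
    linkage: str = "average",
) -> dict:
    """Select the strongly cross-correlated gene cluster on a cohort.

    Computes the gene x gene Pearson correlation over patients,
    hierarchically clusters on distance 1 - r, cuts the dendrogram at
    height 1 - ``min_abs_r`` and returns the largest cluster (ties broken
    by higher mean intra-cluster correlation, then by lexicographically
    first gene).  Candidate genes absent from the cohort are dropped with
    a warning, and a ``no_correlated_cluster`` flag is set when the best
    cluster is a singleton.
    """
    expr = cohort.expr if hasattr(cohort, "expr") else cohort
    upper = {c.upper(): c for c in expr.columns}
    present, dropped = [], []
    for g in candidates:
        col = upper.get(g.upper())
        (present if col is not None else dropped).append(col or g)
    if dropped:
        log.warning("candidate genes absent from cohort: %s", dropped)
    if len(present) < 2:
        raise ValueError("need at least 2 candidate genes present in the cohort")
    sub = expr[present]
    corr = np.corrcoef(sub.to_numpy(), rowvar=False)
    # absolute correlation: distance in [0, 1], so cutting at 1 - min_abs_r
    # with min_abs_r = 0 sits above every possible merge
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(present), k=1)]
    condensed = np.clip(condensed, 0.0, None)
    Z = sch.linkage(condensed, method=linkage)
    labels = sch.fcluster(Z, t=1.0 - min_abs_r, criterion="distance")

    def mean_intra_r(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 1.0
        block = np.abs(corr[np.ix_(idx, idx)])
        return float(block[np.triu_indices(idx.size, k=1)].mean())

    clusters = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        genes = sorted(present[i] for i in idx)
        clusters.append((-idx.size, -mean_intra_r(idx), genes[0], idx, genes))
    clusters.sort(key=lambda c: c[:3])
    _, _, _, idx, genes = clusters[0]
    return {
        "genes": genes,
        "mean_intra_r": mean_intra_r(idx),
        "n_candidates": len(present),
        "dropped": dropped,
        "no_correlated_cluster": len(genes) < 2,
        "params": {"min_abs_r": min_abs_r, "linkage": linkage,
                   "distance": "1 - pearson r"},
    }


@dataclass
class GeneSignature:
    """Named, ordered, deduplicated gene list with provenance."""

    name: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"name": self.name, "genes": self.genes, "provenance": self.provenance},
            indent=2, sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "GeneSignature":
        with open(path) as fh:
            d = json.load(fh)
        return cls(name=d["name"], genes=d["genes"], provenance=d.get("provenance", {}))

    def to_gene_set(self) -> GeneSet:
        return GeneSet(self.name, self.provenance.get("description", ""), self.genes)


def build_signature(name: str, genes: list[str], provenance: dict | None = None) -> GeneSignature:
    """Validate and assemble a signature from a gene list."""
    if not genes:
        raise ValueError("signature gene list is empty")
    seen: dict[str, None] = {}
    for g in genes:
        gu = str(g).upper()
        if gu in seen:
            log.warning("duplicate gene %s in signature %s", gu, name)
        seen.setdefault(gu, None)
    return GeneSignature(name=name, genes=list(seen), provenance=provenance or {})


def null_ora_pvalues(
    n_draws: int = 1000,
    seed: int = 0,
    universe_size: int = 5000,
    set_size: int = 1000,
    query_range: tuple[int, int] = (200, 1000),
) -> np.ndarray:
    """Null-calibration diagnostic: ORA p-values for random queries.

    Draws random gene queries (uniform random size within
    ``query_range``) from a fixed universe and returns the
    over-representation p-value of one set of ``set_size`` genes.  Under
    the null these are super-uniform (the test is discrete and
    conservative); at this granularity they are close enough to uniform
    for a KS check.
    """
    rng = np.random.default_rng(seed)
    universe = [f"G{i}" for i in range(universe_size)]
    member_ids = rng.choice(universe_size, size=set_size, replace=False)
    N, K = universe_size, set_size
    member_set = set(member_ids.tolist())
    out = np.empty(n_draws)
    for i in range(n_draws):
        n = int(rng.integers(*query_range))
        q = rng.choice(universe_size, size=n, replace=False)
        k = len(member_set.intersection(q.tolist()))
        out[i] = scipy.stats.hypergeom.sf(k - 1, N, K, n)
    return out


# Invasion signatures defined on the organoid models, as published:
# 15-gene collective signature, 15-gene single-cell signature, and the
# 7-gene validation subset surviving cohort preprocessing.
COLLECTIVE_SIGNATURE_GENES = [
    "SORL1", "ITGA2", "ADAMTS1", "PDGFB", "SPARC", "ITGB6", "JAG1", "ITGAV",
    "PTPRK", "CSF2", "PDPN", "SERPINE1", "MET", "THBS1", "TNC",
]
SINGLE_CELL_SIGNATURE_GENES = [
    "STC1", "IL33", "CXCL1", "LOXL2", "SH3KBP1", "TIMP1", "IL24", "PTK2B",
    "CD55", "FUT8", "WDR72", "SEMA4B", "WNT7A", "CCDC25", "BEX4",
]
VALIDATION_SUBSET_GENES = [
    "THBS1", "ADAMTS1", "CSF2", "PDPN", "SERPINE1", "SPARC", "TNC",
]
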