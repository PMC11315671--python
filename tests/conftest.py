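import numpy as np
import pytest

from invasig.datatypes import CellMatrix
from invasig.simulate import (
    CohortSimConfig,
    ScSimConfig,
    SceneSimConfig,
    simulate_cohort,
    simulate_invasion_scene,
    simulate_sc_counts,
)


@pytest.fixture(scope="session")
def sc_default():
    """Moderate two-condition count matrix with planted flags."""
    return simulate_sc_counts(ScSimConfig(n_cells_per_group=250, seed=11))


@pytest.fixture(scope="session")
def sc_de():
    """DE-recovery conditions: 300 cells/group, 50 planted genes at log2FC 1.5."""
    cfg = ScSimConfig(
        n_genes=2000, n_cells_per_group=300, n_de_genes=50, de_log2fc=1.5,
        lowq_cell_fraction=0.0, doublet_fraction=0.0, seed=7,
    )
    return simulate_sc_counts(cfg)


@pytest.fixture(scope="session")
def cohort_hr2():
    return simulate_cohort(
        CohortSimConfig(n_patients=500, group_hr=2.0, censor_rate=0.2, seed=7)
    )


@pytest.fixture(scope="session")
def scene_default():
    return simulate_invasion_scene(SceneSimConfig(seed=0))


def toy_cells(umis, mito, doublet=None, n_genes=4):
    """Hand-built CellMatrix with prescribed per-cell totals and mito fractions.

    Gene 0 is mitochondrial; counts are arranged so column sums equal
    ``umis`` and the gene-0 share equals ``mito`` as closely as integer
    counts allow (mito counts are rounded; totals are exact).
    """
    umis = np.asarray(umis)
    n = len(umis)
    counts = np.zeros((n_genes, n), dtype=int)
    for j, (u, m) in enumerate(zip(umis, np.asarray(mito))):
        mt = int(round(u * m))
        counts[0, j] = mt
        rest = int(u) - mt
        base = rest // (n_genes - 1)
        counts[1:, j] = base
        counts[1, j] += rest - base * (n_genes - 1)
    genes = ["MT-A"] + [f"G{i}" for i in range(1, n_genes)]
    return CellMatrix.from_counts(
        counts, genes, [f"B{j}" for j in range(n)],
        sample="s1", condition="c", doublet_score=doublet,
    )
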