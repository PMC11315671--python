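# invasig

Tumor cells leave a carcinoma in two broadly different ways: as cohesive
multicellular strands (**collective invasion**) or as dissociated
individual cells (**single-cell invasion**). In head and neck squamous
cell carcinoma (HNSCC), patient-derived organoids embedded in collagen
recapitulate both modes, and the transcriptional programs that
distinguish invasive from non-invasive cells — and collective from
single-cell invaders — can be distilled into compact gene signatures
whose activity stratifies patient survival.

`invasig` implements that computational path as a tested, reusable
pipeline, exercisable end to end on synthetic data with planted ground
truth:

1. **`invasig.simulate`** — generators for (a) negative-binomial
   single-cell count matrices with planted DE genes, low-quality cells
   and doublets, (b) expression cohorts whose overall-survival hazard
   depends on a planted signature's activity score, and (c) 2-D invasion
   scenes with known nuclear:cytosolic marker ratios and collagen fiber
   textures of controlled orientation and coherency.
2. **`invasig.scqc`** — the three single-cell quality filters, applied
   per sample in a fixed order: cells with ≤ 1000 UMIs or > 5%
   mitochondrial reads are removed; cells outside the 1 − α prediction
   band of the log₁₀ genes-detected ~ log₁₀ UMIs regression (α = 1 /
   droplets in the sample) are removed; cells with doublet score > 0.5
   are removed.
3. **`invasig.diffexpr`** — log-normalization (counts per 10⁴,
   `ln(1+x)`), two-sided Wilcoxon rank-sum DE with Benjamini–Hochberg
   correction, and gene selection at the gates logFC ≥ 0.5 and adjusted
   p < 0.001, with optional cell-cycle gene exclusion from GMT files.
4. **`invasig.genesets`** — GMT parsing, exact gene-set intersections,
   hypergeometric (Fisher) over-representation tests, and selection of a
   strongly cross-correlated gene cluster on a reference cohort
   (average-linkage clustering on 1 − |Pearson r|, dendrogram cut at
   1 − r_min). Ships the published 15-gene collective and single-cell
   invasion signatures and the 7-gene validation subset.
5. **`invasig.survival`** — cohort preprocessing (detection-p masking,
   > 70%-missing gene removal, seeded low-value imputation, quantile
   normalization, SD < 0.5 gene removal), per-gene z-scores, per-patient
   **activity score** (mean z over signature genes), equal-halves
   stratification, Kaplan–Meier/log-rank comparison, univariate Cox
   proportional-hazards HR with Wald 95% CI, and a multi-cohort screen.
6. **`invasig.imaging`** — nuclear/cytosolic marker ratio per cell with
   positional classes (strand / core / single), structure-tensor fiber
   orientation θ ∈ (−90°, 90°] and coherency C ∈ [0, 1], and border
   alignment profiles (mean coherency of near-perpendicular fibers in
   10-µm bins, 0.2 non-random cutoff).

## Worked example

```python
import numpy as np
from invasig.simulate import ScSimConfig, simulate_sc_counts
from invasig.scqc import run_qc
from invasig.diffexpr import normalize_counts, differential_expression, select_de_genes

cells, truth = simulate_sc_counts(ScSimConfig(n_cells_per_group=300, seed=1))
kept, report = run_qc(cells)
print(report.per_sample[["sample", "n_input", "retained"]].to_string(index=False))
norm = normalize_counts(kept)
de = differential_expression(norm, "invasive", "non-invasive")
up_inv, up_non = select_de_genes(de, lfc_min=0.5, alpha=0.001)
planted = set(truth.de_gene_names)
print(f"{len(up_inv)} genes up in invasive; "
      f"sensitivity {len(set(up_inv) & planted) / len(planted):.2f}")
```

prints

```
      sample  n_input  retained
non-invasive      300       268
    invasive      300       272
50 genes up in invasive; sensitivity 1.00
```

Of the 600 simulated cells, 5% are planted low-quality and 5% doublets
(drawn across both samples); QC removes exactly those 60 cells, and all
50 genes planted at log2 fold change 1.5 are recovered at the selection
gates with no false discoveries.

The same kind of round trip runs for the survival arm —

```python
from invasig.simulate import CohortSimConfig, simulate_cohort
from invasig.genesets import build_signature
from invasig.survival import PreprocessParams, run_survival_chain

cohort, truth = simulate_cohort(CohortSimConfig(n_patients=1000, group_hr=2.0, seed=3))
sig = build_signature("planted", truth.extras["signature_genes"])
out = run_survival_chain(cohort, sig, PreprocessParams(seed=3))
res = out["result"]
print(f"HR {res.hazard_ratio:.2f} (95% CI {res.hr_ci[0]:.2f}-{res.hr_ci[1]:.2f}), "
      f"log-rank p = {res.logrank_p:.2e}")
```

```
HR 1.90 (95% CI 1.65-2.20), log-rank p = 1.09e-18
```

— the chain recovers the planted hazard ratio of 2.0 up to the mild
attenuation expected from scoring noise at the median split.

A command-line interface wraps each stage:

```bash
invasig simulate sc --out raw/
invasig scqc --counts raw/ --out qc/
invasig de --counts qc/ --a invasive --b non-invasive --out de/
invasig survival --cohort cohort.csv --signature col_inv.json --seed 17 --out surv/
invasig imaging --scene scene.tif --out img/
```

Real cohort tables (e.g. TCGA or microarray exports) are accepted as
CSV with `patient_id`, `os_time_days`, `os_event`, `hpv_status` and gene
columns; `--exclude-hpv-positive` applies the HPV-negative restriction
before analysis.

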