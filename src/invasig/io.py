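"""Readers and writers for the on-disk formats used by the pipeline.

Counts travel as MatrixMarket MTX plus ``genes.tsv``/``barcodes.tsv``
(or a single dense TSV), per-cell metadata as TSV; cohorts as CSV with
clinical columns followed by gene columns; scenes as multi-page TIFF
(channels: nuclear, marker, collagen) with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile

from .datatypes import CellMatrix, SchemaError
from .imaging import ImageScene
from .survival import CohortTable

META_COLUMNS = ("barcode", "sample", "condition", "n_umis", "mito_frac", "doublet_score")
CLINICAL_PREFIX = ("patient_id", "os_time_days", "os_event", "hpv_status")
SCENE_CHANNELS = ("nuclear", "marker", "collagen")


# --- single-cell counts -------------------------------------------------

def write_counts_mtx(cells: CellMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", scipy.sparse.csr_matrix(cells.counts))
    pd.Series(cells.gene_names).to_csv(outdir / "genes.tsv", sep="\t",
                                       index=False, header=False)
    pd.Series(cells.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t",
                                     index=False, header=False)
    meta = cells.cell_meta.reset_index()[list(META_COLUMNS)]
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_counts_mtx(indir) -> CellMatrix:
    indir = Path(indir)
    counts = np.asarray(scipy.io.mmread(indir / "matrix.mtx").todense()).astype(int)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata.tsv missing columns: {missing}")
    meta = meta.set_index("barcode")
    cm = CellMatrix.from_counts(
        counts, genes, barcodes,
        sample=meta["sample"].tolist(), condition=meta["condition"].tolist(),
        doublet_score=meta["doublet_score"].to_numpy(),
    )
    return cm


def write_counts_tsv(cells: CellMatrix, path) -> None:
    pd.DataFrame(cells.counts, index=cells.gene_names,
                 columns=cells.barcodes).to_csv(path, sep="\t")


def read_counts_tsv(path, meta_path) -> CellMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
    meta = meta.loc[table.columns]
    return CellMatrix.from_counts(
        table.to_numpy().astype(int), table.index.tolist(), table.columns.tolist(),
        sample=meta["sample"].tolist(), condition=meta["condition"].tolist(),
        doublet_score=meta["doublet_score"].to_numpy(),
    )


# --- cohorts ------------------------------------------------------------

def write_cohort_csv(cohort: CohortTable, path, detection_path=None) -> None:
    clin = cohort.clinical.copy()
    if "hpv_status" not in clin.columns:
        clin["hpv_status"] = "unknown"
    out = pd.concat([clin[["os_time_days", "os_event", "hpv_status"]],
                     cohort.expr], axis=1)
    out.index.name = "patient_id"
    out.to_csv(path)
    if detection_path is not None and cohort.detection_p is not None:
        dp = cohort.detection_p.copy()
        dp.index.name = "patient_id"
        dp.to_csv(detection_path)


def read_cohort_csv(path, detection_path=None, name: str | None = None) -> CohortTable:
    table = pd.read_csv(path, index_col="patient_id")
    clin_cols = [c for c in ("os_time_days", "os_event", "hpv_status")
                 if c in table.columns]
    if "os_time_days" not in clin_cols or "os_event" not in clin_cols:
        raise SchemaError("cohort CSV must carry os_time_days and os_event")
    expr = table.drop(columns=clin_cols)
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, index_col="patient_id")
        detection = detection.loc[expr.index, expr.columns]
    return CohortTable(expr=expr, clinical=table[clin_cols],
                       detection_p=detection,
                       name=name or Path(path).stem)


# --- scenes -------------------------------------------------------------

def write_scene_tiff(scene: ImageScene, path, truth: dict | None = None) -> None:
    path = Path(path)
    stack = np.stack([scene.channels[c].astype(np.float32) for c in SCENE_CHANNELS])
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"axes": "CYX"})
    sidecar = {
        "pixel_size_um": scene.pixel_size,
        "channels": list(SCENE_CHANNELS),
    }
    if truth is not None:
        sidecar["ground_truth"] = truth
    if "organoid" in scene.masks:
        sidecar["organoid_mask_rle"] = _rle_encode(scene.masks["organoid"])
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_scene_tiff(path) -> ImageScene:
    path = Path(path)
    stack = tifffile.imread(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    channels = {name: stack[i].astype(float)
                for i, name in enumerate(sidecar["channels"])}
    masks = {}
    if "organoid_mask_rle" in sidecar:
        masks["organoid"] = _rle_decode(sidecar["organoid_mask_rle"],
                                        next(iter(channels.values())).shape)
    return ImageScene(channels=channels, pixel_size=sidecar["pixel_size_um"],
                      masks=masks)


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    # run lengths starting with a run of False
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    out = runs.tolist()
    if flat.size and flat[0]:
        out = [0] + out
    return out


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)
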