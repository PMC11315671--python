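"""End-to-end runs on synthetic data, with deterministic JSON output.

``run_end_to_end`` exercises every stage — simulation, QC, differential
expression, signature construction, survival stratification, and image
quantification — from one integer seed, and returns a JSON-serializable
dictionary of the headline quantities.  Two runs with the same seed
produce byte-identical serializations.
"""

from __future__ import annotations

import json

import numpy as np

from . import diffexpr, genesets, imaging, scqc, survival
from .simulate import (
    CohortSimConfig,
    ScSimConfig,
    SceneSimConfig,
    make_stripes,
    simulate_cohort,
    simulate_invasion_scene,
    simulate_sc_counts,
)


def run_single_cell_arm(seed: int, n_cells_per_group: int = 300) -> dict:
    """Simulate counts, run QC, and call DE at the logFC/adj-p gates."""
    cells, truth = simulate_sc_counts(
        ScSimConfig(n_cells_per_group=n_cells_per_group, seed=seed)
    )
    kept, report = scqc.run_qc(cells)
    good = {b for b, f in truth.qc_flags.items() if f == "good"}
    qc_agreement = len(set(kept.barcodes) & good) / len(good | set(kept.barcodes))
    norm = diffexpr.normalize_counts(kept)
    de = diffexpr.differential_expression(norm, "invasive", "non-invasive")
    up_inv, up_noninv = diffexpr.select_de_genes(de)
    planted = set(truth.de_gene_names)
    hits = set(up_inv)
    sensitivity = len(hits & planted) / len(planted) if planted else float("nan")
    fdr = len(hits - planted) / len(hits) if hits else 0.0
    return {
        "qc_report": report.to_dict(),
        "qc_flag_agreement": qc_agreement,
        "n_cells_retained": kept.n_cells,
        "n_up_invasive": len(up_inv),
        "n_up_noninvasive": len(up_noninv),
        "de_sensitivity": sensitivity,
        "de_fdr": fdr,
        "up_invasive_top10": up_inv[:10],
    }


def run_survival_arm(seed: int, n_patients: int = 1000, group_hr: float = 2.0) -> dict:
    """Simulate a cohort with a planted prognostic signature and recover it."""
    cohort, truth = simulate_cohort(
        CohortSimConfig(n_patients=n_patients, group_hr=group_hr, seed=seed)
    )
    signature = genesets.build_signature(
        "planted-signature", truth.extras["signature_genes"]
    )
    out = survival.run_survival_chain(
        cohort, signature, survival.PreprocessParams(seed=seed)
    )
    res = out["result"]
    g = out["strata"].group
    true_g = np.array([truth.true_group[p] for p in g.index])
    return {
        "n_patients": out["n"],
        "planted_hr": group_hr,
        "cox_hr": res.hazard_ratio,
        "cox_hr_ci": list(res.hr_ci),
        "logrank_p": res.logrank_p,
        "strata_agreement": float((g.to_numpy() == true_g).mean()),
    }


def run_imaging_arm(seed: int) -> dict:
    """Simulate an invasion scene; recover ratios, classes, orientation."""
    cfg = SceneSimConfig(seed=seed)
    scene, truth = simulate_invasion_scene(cfg)
    seg = imaging.segment_cells(scene)
    meas = imaging.nuc_cyt_ratio(seg, scene.channels["marker"])
    meas = imaging.assign_position(seg, meas, scene.masks["organoid"])
    centers = truth.extras["centers"]
    carr = np.array([[c["row"], c["col"]] for c in centers])
    agree, matched = 0, 0
    ratios_by_class: dict[str, list[float]] = {}
    for m in meas:
        d = np.hypot(carr[:, 0] - m.centroid[0], carr[:, 1] - m.centroid[1])
        j = int(d.argmin())
        if d[j] < 5:
            matched += 1
            agree += centers[j]["class"] == m.position_class
            ratios_by_class.setdefault(m.position_class, []).append(m.ratio)
    field = imaging.structure_tensor(scene.channels["collagen"])
    import scipy.ndimage as ndi

    band = scene.masks["aligned_band"]
    inner = band & (ndi.distance_transform_edt(band) > 6)
    profile = imaging.border_alignment(
        field, scene.masks["organoid"], scene.pixel_size,
        depth_um=truth.extras["aligned_depth_um"],
    )
    return {
        "n_cells_segmented": seg.n_cells,
        "n_cells_planted": len(truth.true_class),
        "class_agreement": agree / matched if matched else float("nan"),
        "mean_ratio_by_class": {
            k: float(np.mean(v)) for k, v in sorted(ratios_by_class.items())
        },
        "planted_ratio_by_class": truth.extras["ratios_by_class"],
        "band_median_orientation_deg": float(np.median(field.theta_deg[inner])),
        "planted_fiber_angle_deg": truth.true_fiber_angle,
        "band_median_coherency": float(np.median(field.coherency[inner])),
        "aligned_bins": int(profile.bins["aligned"].sum()),
        "n_bins": int(len(profile.bins)),
    }


def run_orientation_phantoms(seed: int) -> dict:
    """Stripe and white-noise phantoms for the structure-tensor stage."""
    rng = np.random.default_rng(seed)
    stripes = make_stripes((256, 256), 30.0)
    interior = (slice(24, -24),) * 2
    f = imaging.structure_tensor(stripes)
    noise = imaging.structure_tensor(rng.normal(size=(256, 256)), sigma_w=8.0)
    return {
        "stripe_angle_deg": 30.0,
        "stripe_median_orientation_deg": float(np.median(f.theta_deg[interior])),
        "stripe_median_coherency": float(np.median(f.coherency[interior])),
        "noise_median_coherency": float(np.median(noise.coherency[interior])),
    }


def run_end_to_end(seed: int) -> dict:
    """Full pipeline on synthetic data; deterministic given the seed."""
    return {
        "seed": seed,
        "single_cell": run_single_cell_arm(seed),
        "survival": run_survival_arm(seed),
        "imaging": run_imaging_arm(seed),
        "orientation_phantoms": run_orientation_phantoms(seed),
    }


def to_canonical_json(result: dict) -> str:
    """Stable serialization: sorted keys, repr-exact floats."""
    return json.dumps(result, sort_keys=True, indent=2, default=_coerce)


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
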