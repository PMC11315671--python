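"""Invasion-front image quantification.

Two families of measurements on 2-D multi-channel scenes of an invading
organoid:

* **Marker localization** — per-cell nuclear and cytosolic mean
  intensities of a marker channel (nuclear/cytosolic ratio as the
  activity proxy, e.g. for YAP), with each cell assigned a positional
  class: ``core`` (inner cells not in contact with the matrix),
  ``strand`` (cells in collective protrusions at the cell-ECM
  interface) or ``single`` (cells detached from the organoid).

* **Collagen alignment** — per-pixel fiber orientation (degrees in
  (-90, 90], counter-clockwise from the image x-axis) and coherency
  (0 = isotropic, 1 = perfectly aligned) from the structure tensor,
  summarized at the invasive border as the mean coherency of
  near-perpendicular fibers in 10-µm distance bins, with 0.2 as the
  non-random alignment cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import expand_labels, watershed

log = logging.getLogger(__name__)

POSITION_CLASSES = ("strand", "core", "single")


@dataclass
class ImageScene:
    """Named 2-D channels sharing one shape, plus the physical pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm per pixel
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share one shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class Segmentation:
    nuclei: np.ndarray    # label map, 0 = background
    cytosol: np.ndarray   # label map of per-cell annuli, same ids
    n_cells: int


@dataclass
class CellMeasurement:
    cell_id: int
    nuclear_mean: float
    cytosolic_mean: float
    ratio: float
    centroid: tuple[float, float]
    position_class: str = "unassigned"


@dataclass
class OrientationField:
    theta_deg: np.ndarray  # fiber orientation, (-90, 90]
    coherency: np.ndarray  # [0, 1]
    sigma_g: float
    sigma_w: float


@dataclass
class AlignmentProfile:
    bins: pd.DataFrame  # bin_lo_um, bin_hi_um, mean_coherency, n_pixels, aligned
    cutoff: float
    depth_um: float
    perp_tol_deg: float


def _wrap_orientation(theta: np.ndarray) -> np.ndarray:
    """Fold an orientation (mod 180) into (-90, 90]."""
    out = (np.asarray(theta) + 90.0) % 180.0 - 90.0
    return np.where(out == -90.0, 90.0, out)


def segment_cells(
    scene: ImageScene,
    annulus_px: int = 3,
    min_annulus_px: int = 10,
    min_nucleus_px: int = 9,
) -> Segmentation:
    """Segment nuclei (Otsu + connected components + watershed on the
    distance transform) and derive a per-cell cytosolic annulus.

    The annulus is a 3-px dilation ring around each nucleus, clipped
    against neighboring cells; cells whose annulus ends up smaller than
    ``min_annulus_px`` pixels are discarded as mis-segmented.  If the
    scene provides ``masks['nuclei']`` / ``masks['cytosol']`` label maps
    they are passed through unchanged.
    """
    if "nuclei" in scene.masks:
        nuclei = scene.masks["nuclei"]
        cyto = scene.masks.get("cytosol")
        if cyto is None:
            cyto = expand_labels(nuclei, distance=annulus_px) * (nuclei == 0)
        return Segmentation(nuclei, cyto, int(nuclei.max()))
    if "nuclear" not in scene.channels:
        raise ValueError("scene has no nuclear channel and no provided masks")
    img = scene.channels["nuclear"].astype(float)
    if np.ptp(img) == 0:
        log.warning("empty nuclear channel: no cells segmented")
        z = np.zeros(img.shape, dtype=int)
        return Segmentation(z, z.copy(), 0)
    binary = img > threshold_otsu(img)
    binary = ndi.binary_opening(binary, structure=disk(1))
    comps = cc_label(binary)
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=4, labels=comps, num_peaks_per_label=4,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    nuclei = watershed(-distance, markers, mask=binary)
    # prune specks and relabel contiguously
    sizes = np.bincount(nuclei.ravel())
    drop = np.flatnonzero(sizes < min_nucleus_px)
    nuclei[np.isin(nuclei, drop)] = 0
    nuclei = cc_label(nuclei > 0)
    cyto = expand_labels(nuclei, distance=annulus_px) * (nuclei == 0)
    # discard cells with too small an annulus
    ann_sizes = np.bincount(cyto.ravel(), minlength=nuclei.max() + 1)
    bad = np.flatnonzero(ann_sizes[1:] < min_annulus_px) + 1
    if bad.size:
        nuclei[np.isin(nuclei, bad)] = 0
        cyto[np.isin(cyto, bad)] = 0
        relabeled = cc_label(nuclei > 0)
        lut = np.zeros(int(max(nuclei.max(), cyto.max())) + 1, dtype=int)
        for rp in regionprops(relabeled):
            r0, c0 = rp.coords[0]
            lut[nuclei[r0, c0]] = rp.label
        cyto = lut[cyto]
        nuclei = relabeled
    return Segmentation(nuclei, cyto, int(nuclei.max()))


def nuc_cyt_ratio(seg: Segmentation, marker: np.ndarray) -> list[CellMeasurement]:
    """Per-cell mean marker intensity in the nucleus divided by the mean in
    the cytosolic annulus; cells with zero cytosolic mean are excluded."""
    out: list[CellMeasurement] = []
    marker = np.asarray(marker, dtype=float)
    ids = range(1, seg.n_cells + 1)
    nuc_means = ndi.labeled_comprehension(
        marker, seg.nuclei, list(ids), np.mean, float, np.nan
    ) if seg.n_cells else np.array([])
    for cid in range(1, seg.n_cells + 1):
        nuc_mask = seg.nuclei == cid
        cyt_mask = seg.cytosol == cid
        if not cyt_mask.any() or not nuc_mask.any():
            continue
        nm = float(nuc_means[cid - 1])
        cm = float(marker[cyt_mask].mean())
        if cm == 0:
            log.warning("cell %d has zero cytosolic mean; excluded", cid)
            continue
        rr, cc = np.nonzero(nuc_mask)
        out.append(
            CellMeasurement(
                cell_id=cid, nuclear_mean=nm, cytosolic_mean=cm,
                ratio=nm / cm, centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    return out


def assign_position(
    seg: Segmentation,
    measurements: list[CellMeasurement],
    organoid_mask: np.ndarray | None = None,
    core_erosion_layers: int = 3,
) -> list[CellMeasurement]:
    """Classify each measured cell as strand, core, or single.

    ``single``: the cell's pixels are disjoint from the organoid mask;
    ``core``: its centroid lies inside the organoid mask eroded by
    ``core_erosion_layers`` median cell diameters; ``strand``: the rest
    (cells at the cell-ECM interface of protrusions).  When no organoid
    mask is given it is derived as the largest connected cell-occupied
    component; if none can be derived, every cell is classified single.
    """
    occupied = (seg.nuclei > 0) | (seg.cytosol > 0)
    if organoid_mask is None:
        comps = cc_label(ndi.binary_closing(occupied, structure=disk(5)))
        if comps.max() == 0:
            log.warning("no organoid mask derivable; classifying all cells single")
            for m in measurements:
                m.position_class = "single"
            return measurements
        sizes = np.bincount(comps.ravel())
        sizes[0] = 0
        organoid_mask = comps == sizes.argmax()
    organoid_mask = organoid_mask.astype(bool)

    areas = [rp.area for rp in regionprops(seg.nuclei)]
    median_diam = 2.0 * np.sqrt(np.median(areas) / np.pi) if areas else 8.0
    erosion_px = max(1, int(round(core_erosion_layers * median_diam)))
    interior = organoid_mask & (
        ndi.distance_transform_edt(organoid_mask) > erosion_px
    )
    for m in measurements:
        cell_pixels = (seg.nuclei == m.cell_id) | (seg.cytosol == m.cell_id)
        if not (cell_pixels & organoid_mask).any():
            m.position_class = "single"
        elif interior[int(round(m.centroid[0])), int(round(m.centroid[1]))]:
            m.position_class = "core"
        else:
            m.position_class = "strand"
    return measurements


def structure_tensor(
    image: np.ndarray, sigma_g: float = 1.0, sigma_w: float = 4.0
) -> OrientationField:
    """Per-pixel fiber orientation and coherency from the structure tensor.

    Gradients are Gaussian derivatives at scale ``sigma_g``; the tensor
    components <Ix^2>, <IxIy>, <Iy^2> are smoothed at scale ``sigma_w``.
    The fiber orientation is the gradient-dominant direction rotated by
    90 degrees (fibers are bright ridges), reported counter-clockwise
    from the image x-axis in (-90, 90].  Coherency is
    (l1 - l2)/(l1 + l2) of the tensor, set to 0 where the trace vanishes.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("structure_tensor expects a 2-D image")
    ix = ndi.gaussian_filter(image, sigma_g, order=(0, 1))
    iy = ndi.gaussian_filter(image, sigma_g, order=(1, 0))
    jxx = ndi.gaussian_filter(ix * ix, sigma_w)
    jxy = ndi.gaussian_filter(ix * iy, sigma_w)
    jyy = ndi.gaussian_filter(iy * iy, sigma_w)
    trace = jxx + jyy
    # gradient-dominant axis in row-down pixel coordinates
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = _wrap_orientation(90.0 - np.degrees(phi))
    root = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(trace > 1e-12, root / np.where(trace > 0, trace, 1.0), 0.0)
    return OrientationField(theta_deg=theta, coherency=np.clip(coherency, 0.0, 1.0),
                            sigma_g=sigma_g, sigma_w=sigma_w)


def _border_normal_angles(mask: np.ndarray) -> np.ndarray:
    """Orientation of the outward border normal, per pixel, in (-90, 90]."""
    dist = ndi.distance_transform_edt(~mask.astype(bool))
    smooth = ndi.gaussian_filter(dist, 2.0)
    gr = ndi.sobel(smooth, axis=0)  # d/drow (y down)
    gc = ndi.sobel(smooth, axis=1)  # d/dcol (x)
    return _wrap_orientation(np.degrees(np.arctan2(-gr, gc)))


def border_alignment(
    field: OrientationField,
    structure_mask: np.ndarray,
    pixel_size: float,
    depth_um: float = 100.0,
    cutoff: float = 0.2,
    perp_tol_deg: float = 20.0,
    bin_um: float = 10.0,
) -> AlignmentProfile:
    """Mean coherency of near-perpendicular fibers by distance from the border.

    For every pixel within ``depth_um`` of the structure border, the
    angular deviation between the fiber orientation and the border normal
    is folded into [0, 90] degrees; pixels deviating by at most
    ``perp_tol_deg`` count as perpendicular fibers.  Their coherency is
    averaged in ``bin_um``-wide distance bins, and a bin is flagged
    aligned when that mean exceeds ``cutoff``.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if mask.shape != field.theta_deg.shape:
        raise ValueError("mask and orientation field shapes differ")
    if not mask.any():
        raise ValueError("empty structure mask")
    edges = np.arange(0.0, depth_um + 1e-9, bin_um)
    if len(edges) < 2:
        return AlignmentProfile(
            bins=pd.DataFrame(columns=["bin_lo_um", "bin_hi_um", "mean_coherency",
                                       "n_pixels", "aligned"]),
            cutoff=cutoff, depth_um=depth_um, perp_tol_deg=perp_tol_deg,
        )
    dist_um = ndi.distance_transform_edt(~mask) * pixel_size
    normals = _border_normal_angles(mask)
    dtheta = np.abs(field.theta_deg - normals) % 180.0
    dev = np.minimum(dtheta, 180.0 - dtheta)
    perp = (~mask) & (dist_um > 0) & (dev <= perp_tol_deg)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = perp & (dist_um > lo) & (dist_um <= hi)
        n = int(sel.sum())
        mean_c = float(field.coherency[sel].mean()) if n else float("nan")
        rows.append(
            {"bin_lo_um": lo, "bin_hi_um": hi, "mean_coherency": mean_c,
             "n_pixels": n, "aligned": bool(n and mean_c > cutoff)}
        )
    return AlignmentProfile(bins=pd.DataFrame(rows), cutoff=cutoff,
                            depth_um=depth_um, perp_tol_deg=perp_tol_deg)


def region_quantify(
    measurements: list[CellMeasurement],
    zone_mask: np.ndarray,
    pixel_size: float,
    n_regions: int = 5,
    region_size_um2: float = 62_500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean nuclear/cytosolic ratio in randomly placed square regions.

    Squares of area ``region_size_um2`` (250 µm x 250 µm by default) are
    placed uniformly at random, fully inside the zone mask; each region
    reports the mean ratio of the cells whose centroid falls inside it.
    """
    zone = np.asarray(zone_mask, dtype=bool)
    side = max(1, int(round(np.sqrt(region_size_um2) / pixel_size)))
    ok = ndi.minimum_filter(zone, size=side, mode="constant", cval=False)
    # top-left anchors for which the full square fits in the zone
    shift = side // 2
    anchors = np.argwhere(ok)
    anchors = anchors[
        (anchors[:, 0] >= shift) & (anchors[:, 1] >= shift)
        & (anchors[:, 0] - shift + side <= zone.shape[0])
        & (anchors[:, 1] - shift + side <= zone.shape[1])
    ] - shift
    if len(anchors) < n_regions:
        raise ValueError(
            f"zone too small for {n_regions} regions of side {side} px; "
            f"max feasible placements: {len(anchors)}"
        )
    rng = np.random.default_rng(seed)
    chosen = anchors[rng.choice(len(anchors), size=n_regions, replace=False)]
    rows = []
    cents = np.array([m.centroid for m in measurements]) if measurements else np.empty((0, 2))
    ratios = np.array([m.ratio for m in measurements])
    for i, (r0, c0) in enumerate(chosen):
        if len(cents):
            inside = (
                (cents[:, 0] >= r0) & (cents[:, 0] < r0 + side)
                & (cents[:, 1] >= c0) & (cents[:, 1] < c0 + side)
            )
            mean_ratio = float(ratios[inside].mean()) if inside.any() else float("nan")
            n_cells = int(inside.sum())
        else:
            mean_ratio, n_cells = float("nan"), 0
        rows.append({"region": i, "row": int(r0), "col": int(c0),
                     "side_px": side, "n_cells": n_cells, "mean_ratio": mean_ratio})
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray], test: str = "mann_whitney"):
    """Two-sided rank test across groups of measurements.

    ``mann_whitney`` requires exactly 2 groups; ``kruskal_wallis``
    accepts 2 or more.  Returns (statistic, p).
    """
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(values) < 2 or any(v.size == 0 for v in values):
        raise ValueError("need at least 2 non-empty groups")
    if test == "mann_whitney":
        if len(values) != 2:
            raise ValueError("mann_whitney compares exactly 2 groups")
        res = scipy.stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        if all(np.array_equal(values[0], v) for v in values[1:]):
            return 0.0, 1.0  # identical groups carry no evidence
        res = scipy.stats.kruskal(*values)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
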