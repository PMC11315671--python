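"""Synthetic invasion scenes: organoid core, strands, single cells, collagen.

The scene is deliberately schematic — nuclei are disks, strands are
capsule-shaped protrusions touching the core — because the quantities
under test are intensities and angles, not morphology:

* the marker channel encodes a known nuclear:cytosolic intensity ratio
  per positional class (strand / core / single);
* the collagen channel carries a stripe texture at a known angle inside
  a band of ``aligned_depth`` µm around the organoid border, blended
  with isotropic texture according to ``fiber_coherency_target``, and
  isotropic texture elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from ..datatypes import GroundTruth
from ..imaging import ImageScene


class InvalidConfigError(ValueError):
    pass


@dataclass
class SceneSimConfig:
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0  # µm per pixel
    n_strand_cells: int = 12
    n_single_cells: int = 8
    n_core_cells: int = 12
    nuc_cyt_ratio_by_class: dict[str, float] = field(
        default_factory=lambda: {"strand": 2.5, "core": 1.2, "single": 2.0}
    )
    fiber_angle: float = 30.0  # degrees CCW from x-axis, in (-90, 90]
    fiber_coherency_target: float = 1.0
    aligned_depth: float = 60.0  # µm
    seed: int = 0
    core_radius_px: int = 100
    nucleus_radius_px: int = 4
    cyto_radius_px: int = 7
    cyto_intensity: float = 100.0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidConfigError("pixel_size must be > 0")
        if any(r <= 0 for r in self.nuc_cyt_ratio_by_class.values()):
            raise InvalidConfigError("nuclear:cytosolic ratios must be > 0")
        if not -90.0 < self.fiber_angle <= 90.0:
            raise InvalidConfigError("fiber_angle must lie in (-90, 90]")
        if not 0.0 <= self.fiber_coherency_target <= 1.0:
            raise InvalidConfigError("fiber_coherency_target must lie in [0, 1]")
        if min(self.image_shape) < 4 * self.core_radius_px // 2:
            raise InvalidConfigError("image too small for the organoid core")


def make_stripes(shape: tuple[int, int], angle_deg: float, wavelength: float = 8.0,
                 phase: float = 0.0) -> np.ndarray:
    """Sinusoidal stripes whose ridges run at ``angle_deg`` CCW from the
    image x-axis (row index pointing down)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = math.radians(angle_deg)
    proj = -cc * math.sin(th) - rr * math.cos(th)  # along the stripe normal
    return 0.5 + 0.5 * np.cos(2.0 * np.pi * proj / wavelength + phase)


def _isotropic_texture(rng: np.random.Generator, shape: tuple[int, int],
                       sigma: float = 1.5) -> np.ndarray:
    """Smoothed white noise, rescaled to [0, 1]: no preferred orientation."""
    tex = ndi.gaussian_filter(rng.normal(size=shape), sigma)
    tex -= tex.min()
    ptp = tex.max()
    return tex / ptp if ptp > 0 else tex


def _place_points(
    rng: np.random.Generator,
    n: int,
    sampler,
    min_dist: float,
    existing: list[tuple[float, float]],
    max_tries: int = 20_000,
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        cand = sampler()
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist**2
               for p in pts + existing):
            pts.append(cand)
    if len(pts) < n:
        raise InvalidConfigError("could not place the requested number of cells")
    return pts


def simulate_invasion_scene(config: SceneSimConfig) -> tuple[ImageScene, GroundTruth]:
    """Simulate a 3-channel invasion scene with known per-class marker ratios."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    cy, cx = h / 2.0, w / 2.0
    R = config.core_radius_px
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dist_center = np.hypot(rr - cy, cc - cx)

    organoid = dist_center <= R

    # strands: capsules radiating from the core border
    n_strands = max(1, int(np.ceil(config.n_strand_cells / 4))) if config.n_strand_cells else 0
    strand_len = 80.0
    strand_halfwidth = 9.0
    strand_axes = []
    angles = rng.uniform(0, 2 * np.pi, size=n_strands) if n_strands else []
    for a in angles:
        u = np.array([math.sin(a), math.cos(a)])  # (row, col) direction
        p0 = np.array([cy, cx]) + (R - 5.0) * u
        p1 = np.array([cy, cx]) + (R + strand_len) * u
        strand_axes.append((p0, p1, u))
        d = p1 - p0
        t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / (d @ d), 0, 1)
        seg = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
        organoid |= seg <= strand_halfwidth

    min_sep = 2.0 * config.cyto_radius_px + 3.0
    cells: list[tuple[float, float, str]] = []

    # core cells: deep inside the disk, clear of the erosion band used by
    # positional classification
    core_zone = 0.55 * R

    def _sample_core():
        while True:
            p = (cy + rng.uniform(-core_zone, core_zone),
                 cx + rng.uniform(-core_zone, core_zone))
            if np.hypot(p[0] - cy, p[1] - cx) <= core_zone:
                return p

    core_pts = _place_points(
        rng, config.n_core_cells, _sample_core, min_sep, []
    ) if config.n_core_cells else []
    cells += [(p[0], p[1], "core") for p in core_pts]

    # strand cells: along each capsule axis, outside the core disk
    if config.n_strand_cells:
        per = int(np.ceil(config.n_strand_cells / n_strands))
        placed = 0
        for p0, p1, u in strand_axes:
            for j in range(per):
                if placed >= config.n_strand_cells:
                    break
                frac = (j + 0.7) / (per + 0.4)
                pos = np.array([cy, cx]) + (R + 8.0 + frac * (strand_len - 16.0)) * u
                cells.append((float(pos[0]), float(pos[1]), "strand"))
                placed += 1

    # single cells: detached, in an annulus beyond the strands
    r_lo = R + strand_len + 25.0
    r_hi = min(h, w) / 2.0 - 12.0

    def _sample_single():
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(r_lo, r_hi)
        return (cy + rad * math.sin(ang), cx + rad * math.cos(ang))

    existing = [(r, c) for r, c, _ in cells]
    single_pts = _place_points(
        rng, config.n_single_cells, _sample_single, min_sep, existing
    ) if config.n_single_cells else []
    cells += [(p[0], p[1], "single") for p in single_pts]

    # --- paint channels -------------------------------------------------
    nuclear = np.full((h, w), 10.0)
    marker = np.full((h, w), 5.0)
    rn, rcyt = config.nucleus_radius_px, config.cyto_radius_px
    truth_class: dict[int, str] = {}
    centers: list[dict] = []
    for cid, (r0, c0, cls) in enumerate(cells, start=1):
        d = np.hypot(rr - r0, cc - c0)
        nuc = d <= rn
        cyt = (d > rn) & (d <= rcyt)
        nuclear[nuc] = 200.0
        ratio = config.nuc_cyt_ratio_by_class.get(cls, 1.0)
        marker[cyt] = config.cyto_intensity
        marker[nuc] = ratio * config.cyto_intensity
        truth_class[cid] = cls
        centers.append({"id": cid, "row": r0, "col": c0, "class": cls, "ratio": ratio})

    nuclear += rng.normal(scale=1.0, size=(h, w))
    marker += rng.normal(scale=1.0, size=(h, w))

    # --- collagen channel ----------------------------------------------
    depth_px = config.aligned_depth / config.pixel_size
    dist_border = ndi.distance_transform_edt(~organoid)
    band = (~organoid) & (dist_border > 0) & (dist_border <= depth_px)
    stripes = make_stripes((h, w), config.fiber_angle)
    iso = _isotropic_texture(rng, (h, w))
    t = config.fiber_coherency_target
    collagen = np.where(band, t * stripes + (1 - t) * iso, iso)
    collagen = 30.0 + 120.0 * collagen

    scene = ImageScene(
        channels={"nuclear": nuclear, "marker": marker, "collagen": collagen},
        pixel_size=config.pixel_size,
        masks={"organoid": organoid, "aligned_band": band},
    )
    truth = GroundTruth(
        true_class=truth_class,
        true_fiber_angle=config.fiber_angle,
        extras={
            "centers": centers,
            "ratios_by_class": dict(config.nuc_cyt_ratio_by_class),
            "aligned_depth_um": config.aligned_depth,
            "coherency_target": config.fiber_coherency_target,
        },
    )
    return scene, truth
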