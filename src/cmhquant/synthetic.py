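"""Ground-truthed synthetic inputs for the CMH quantification pipelines.

Three generators emulate the study's data:

* :func:`generate_vessel_phantom` — a 3D fluorescence stack of smooth
  tubular vessels (capillary-dominant diameters, 2–11 µm) with the exact
  centerline graph as ground truth.
* :func:`generate_deposit_channel` — the co-registered transmission stack:
  dark Prussian-blue-like deposits clustered into lesions (axial extent up
  to ~200 µm), anchored at recorded offsets from vessel walls.
* :func:`generate_histology_section` — a 2D brightfield RGB section:
  tissue on a white background with blue CMH lesions and optional brown
  DAB immunostaining at an exactly constructed area fraction.
* :func:`generate_cohort` — per-animal tables for two-to-six-group
  hypertension cohorts with Poisson CMH counts and a calibrated
  CMH-density–MAP correlation.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .tracing import VesselGraph

__all__ = [
    "PhantomSpec",
    "SectionSpec",
    "CohortSpec",
    "DepositTruth",
    "SectionTruth",
    "generate_vessel_phantom",
    "generate_deposit_channel",
    "generate_histology_section",
    "generate_cohort",
    "sample_diameters",
]

# H-DAB absorbance unit vectors (rows: hematoxylin, DAB), standard published
# values; used both to render synthetic DAB staining and (in histology) to
# unmix it.
HDAB_VECTORS = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.268, 0.570, 0.776],  # DAB
    ]
)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Optical density per stain → 8-bit RGB via Beer–Lambert."""
    rgb = 255.0 * np.exp(-od @ HDAB_VECTORS)
    return rgb


@dataclass
class PhantomSpec:
    """Parameters of a 3D two-channel vascular phantom.

    Shapes are (z, y, x) voxels; spacing is µm per axis.  The default
    diameter profile is a log-normal truncated to [2, 11] µm with ~98% of
    its mass below 10 µm — capillary-dominant, matching the diameter range
    seen around CMH in cleared tissue.  ``tortuosity`` scales the
    perpendicular jitter of centerline waypoints (0 = straight tubes).
    """

    volume_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_vessels: int = 30
    diameter_distribution: tuple[str, dict] = ("lognormal-capillary", {})
    tortuosity: float = 0.15
    n_lesions: int = 3
    deposits_per_lesion: tuple[int, int] = (1, 10)
    deposit_radius: tuple[float, float] = (3.0, 10.0)
    deposit_offset: tuple[float, float] = (0.0, 4.0)  # µm from vessel wall
    lesion_extent: float = 200.0  # µm axial span of one lesion
    psf_sigma: float = 0.5  # µm
    noise_sigma: float = 8.0  # intensity units
    photon_noise: bool = False
    background_level: float = 20.0
    vessel_intensity: float = 160.0
    deposit_absorbance: float = 2.0
    transmission_background: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.voxel_spacing) <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.deposit_radius[1] * 2 > self.lesion_extent:
            raise ValueError(
                f"deposit diameter up to {2 * self.deposit_radius[1]} µm exceeds "
                f"lesion_extent {self.lesion_extent} µm"
            )

    @classmethod
    def fixed_diameter(
        cls,
        diameter: float,
        seed: int = 0,
        volume_shape: tuple[int, int, int] = (48, 72, 72),
        volume_fraction: float = 0.02,
        **kw,
    ) -> "PhantomSpec":
        """Phantom of curved tubes all at one diameter, with the vessel
        count chosen to hold a ~2% vascular volume fraction (the
        physiological range for cortex).  Keeping the foreground fraction
        up is what makes the global iterative-selection threshold
        well-posed — a single thin tube in a large volume leaves the
        intensity histogram effectively unimodal."""
        vol = float(np.prod(volume_shape))
        est_len = float(np.mean(volume_shape))
        n = max(int(round(volume_fraction * vol / (np.pi * (diameter / 2) ** 2 * est_len))), 1)
        return cls(
            volume_shape=volume_shape,
            n_vessels=n,
            n_lesions=0,
            diameter_distribution=("fixed", {"value": float(diameter)}),
            seed=seed,
            **kw,
        )


@dataclass
class DepositTruth:
    """Ground truth for one rendered deposit."""

    deposit_id: int
    lesion_id: int
    centroid: tuple[float, float, float]  # physical µm, (z, y, x)
    radius: float  # µm
    anchor_segment: int | None  # vessel segment the lesion is anchored to
    anchor_distance: float | None  # centroid→centerline distance, µm


def sample_diameters(
    rng: np.random.Generator, n: int, distribution: tuple[str, dict]
) -> np.ndarray:
    """Draw vessel diameters (µm) from a named profile.

    ``lognormal-capillary``: log-normal (median ≈ 4.5 µm, σ_log = 0.35)
    truncated to [2, 11] µm by rejection — ~98–99% of mass below 10 µm.
    ``uniform``: uniform on [low, high] (defaults [2, 11]).
    ``fixed``: constant ``value``.
    """
    name, kw = distribution
    if name == "lognormal-capillary":
        mu = kw.get("mu", float(np.log(4.5)))
        sigma = kw.get("sigma", 0.35)
        lo, hi = kw.get("low", 2.0), kw.get("high", 11.0)
        out = np.empty(0)
        while out.size < n:
            draw = rng.lognormal(mu, sigma, size=4 * max(n, 8))
            out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
        return out[:n]
    if name == "uniform":
        return rng.uniform(kw.get("low", 2.0), kw.get("high", 11.0), size=n)
    if name == "fixed":
        return np.full(n, float(kw["value"]))
    raise ValueError(f"unknown diameter distribution {name!r}")


def _sample_centerline(
    rng: np.random.Generator,
    shape_um: np.ndarray,
    margin: float,
    tortuosity: float,
    step: float,
) -> np.ndarray:
    """One smooth random curve through the volume: cubic spline through
    jittered waypoints along a random dominant direction.  Returns points
    resampled at ``step`` µm, clipped to the interior margin."""
    lo = np.full(3, margin)
    hi = shape_um - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for requested vessel margin")
    # dominant direction and a chord through the box; resample corner-clipped
    # chords so every tube spans a reasonable fraction of the volume
    min_length = 0.5 * float(np.mean(hi - lo))
    for _ in range(64):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = rng.uniform(lo, hi)
        ts = []
        for sgn in (-1, 1):
            t = np.inf
            for ax in range(3):
                d = direction[ax] * sgn
                if abs(d) > 1e-12:
                    t = min(
                        t,
                        ((hi[ax] - center[ax]) / d if d > 0 else (lo[ax] - center[ax]) / d),
                    )
            ts.append(sgn * t)
        t0, t1 = ts
        length = t1 - t0
        if length >= min_length:
            break
    n_way = max(int(length / 30.0) + 2, 4)
    t_way = np.linspace(t0, t1, n_way)
    waypoints = center + np.outer(t_way, direction)
    # perpendicular jitter, scaled by tortuosity × waypoint spacing
    jitter_sd = tortuosity * (length / (n_way - 1))
    for i in range(1, n_way - 1):
        j = rng.normal(scale=jitter_sd, size=3)
        j -= direction * (j @ direction)
        waypoints[i] += j
    spline = CubicSpline(np.linspace(0, 1, n_way), waypoints, axis=0)
    dense = spline(np.linspace(0, 1, max(int(length / step) + 2, 8)))
    return np.clip(dense, lo, hi)


def _paint_tube(
    volume: np.ndarray,
    points: np.ndarray,
    radius: float,
    spacing: np.ndarray,
    edge: float,
) -> None:
    """Accumulate (max) a soft tube of the given radius around a polyline.

    Intensity profile is 1 inside, falling linearly to 0 across ``edge`` µm
    centered on the radius, so the half-maximum surface sits at the true
    radius.
    """
    reach = radius + edge
    lo_idx = np.maximum(np.floor((points.min(axis=0) - reach) / spacing).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil((points.max(axis=0) + reach) / spacing).astype(int) + 1,
        np.asarray(volume.shape),
    )
    if np.any(hi_idx <= lo_idx):
        return
    tree = cKDTree(points)
    grids = np.meshgrid(
        *[
            (np.arange(lo_idx[ax], hi_idx[ax]) + 0.5) * spacing[ax]
            for ax in range(3)
        ],
        indexing="ij",
    )
    centers = np.stack([g.ravel() for g in grids], axis=1)
    dist, _ = tree.query(centers, distance_upper_bound=reach + spacing.max())
    prof = np.clip((radius - dist) / edge + 0.5, 0.0, 1.0)
    sub = tuple(slice(lo_idx[ax], hi_idx[ax]) for ax in range(3))
    shape = tuple(hi_idx - lo_idx)
    np.maximum(volume[sub], prof.reshape(shape), out=volume[sub])


def _finish_stack(
    rng: np.random.Generator,
    signal: np.ndarray,
    spec: PhantomSpec,
) -> np.ndarray:
    """PSF blur + noise, shared by both channels."""
    spacing = np.asarray(spec.voxel_spacing)
    if spec.psf_sigma > 0:
        signal = ndi.gaussian_filter(signal, sigma=spec.psf_sigma / spacing)
    if spec.photon_noise:
        signal = rng.poisson(np.clip(signal, 0, None)).astype(np.float64)
    if spec.noise_sigma > 0:
        signal = signal + rng.normal(scale=spec.noise_sigma, size=signal.shape)
    return np.clip(signal, 0.0, None)


def generate_vessel_phantom(spec: PhantomSpec) -> tuple[np.ndarray, VesselGraph]:
    """Render the fluorescence vessel channel and its centerline truth.

    Returns
    -------
    fluorescence : 3D float array
        ``background_level`` plus soft tubes at ``vessel_intensity``,
        blurred by the PSF, with additive (and optionally photon) noise.
    truth : VesselGraph
        Exact centerlines (nodes every ~1 µm, physical coordinates) and
        radii in µm; one segment per vessel.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    shape_um = np.asarray(spec.volume_shape) * spacing
    diameters = sample_diameters(rng, spec.n_vessels, spec.diameter_distribution)
    if spec.n_vessels and diameters.min() < 2 * spacing.min():
        raise ValueError("drawn diameter below 2× the finest voxel spacing")

    # feasibility: total tube volume must fit without excessive overlap
    if spec.n_vessels:
        est_len = float(np.mean(shape_um))
        tube_vol = float(np.sum(np.pi * (diameters / 2) ** 2 * est_len))
        if tube_vol > 0.3 * float(np.prod(shape_um)):
            raise ValueError(
                "volume too small to place "
                f"{spec.n_vessels} vessels: estimated tube volume {tube_vol:.0f} µm³ "
                f"exceeds 30% of the {float(np.prod(shape_um)):.0f} µm³ volume"
            )

    tube = np.zeros(spec.volume_shape, dtype=np.float64)
    step = 0.5 * spacing.min()
    edge = float(spacing.min())

    positions_all: list[np.ndarray] = []
    radii_all: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    segments: dict[int, list[int]] = {}
    offset = 0
    for vid in range(spec.n_vessels):
        r = diameters[vid] / 2.0
        pts = _sample_centerline(
            rng, shape_um, margin=r + 2 * spacing.max(), tortuosity=spec.tortuosity, step=step
        )
        _paint_tube(tube, pts, r, spacing, edge)
        # truth nodes at ~1 µm arc spacing
        keep = max(int(round(1.0 / step)), 1)
        nodes = pts[::keep]
        ids = list(range(offset, offset + len(nodes)))
        positions_all.append(nodes)
        radii_all.append(np.full(len(nodes), r))
        edges.extend(zip(ids[:-1], ids[1:]))
        segments[vid] = ids
        offset += len(nodes)

    if positions_all:
        truth = VesselGraph(
            positions=np.concatenate(positions_all),
            radii=np.concatenate(radii_all),
            edges=edges,
            segments=segments,
        )
    else:
        truth = VesselGraph(
            positions=np.zeros((0, 3)), radii=np.zeros(0), edges=[], segments={}
        )

    signal = spec.background_level + spec.vessel_intensity * tube
    return _finish_stack(rng, signal, spec), truth


def generate_deposit_channel(
    spec: PhantomSpec, truth: VesselGraph
) -> tuple[np.ndarray, list[DepositTruth]]:
    """Render the transmission channel: dark deposits clustered into lesions.

    Each lesion is anchored to a randomly chosen vessel centerline node at a
    wall offset drawn from ``spec.deposit_offset``; its remaining deposits
    scatter within a ball of radius ``lesion_extent / 2``.  The returned
    ground truth records each deposit's centroid (µm), radius, lesion id,
    and the anchor vessel segment with its centroid-to-centerline distance.
    """
    # separate stream so vessel truth and deposits are independently reproducible
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    shape_um = np.asarray(spec.volume_shape) * spacing
    if spec.n_lesions > 0 and truth.n_nodes == 0:
        raise ValueError("cannot anchor lesions: vessel truth graph is empty")

    od = np.zeros(spec.volume_shape, dtype=np.float64)
    deposits: list[DepositTruth] = []
    node_segment = np.empty(truth.n_nodes, dtype=int)
    for sid, path in truth.segments.items():
        node_segment[path] = sid

    did = 0
    edge = float(spacing.min())
    for lid in range(spec.n_lesions):
        node = int(rng.integers(truth.n_nodes))
        seg = int(node_segment[node])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wall_offset = rng.uniform(*spec.deposit_offset)
        r0 = rng.uniform(*spec.deposit_radius)
        # anchor deposit centroid: vessel wall + offset + its own radius
        center_dist = truth.radii[node] + wall_offset + r0
        anchor = truth.positions[node] + direction * center_dist
        anchor = np.clip(anchor, r0, shape_um - r0)
        n_dep = int(rng.integers(spec.deposits_per_lesion[0], spec.deposits_per_lesion[1] + 1))
        centers = [anchor]
        radii = [r0]
        max_r = spec.lesion_extent / 2.0
        for _ in range(n_dep - 1):
            rr = rng.uniform(*spec.deposit_radius)
            # uniform in a ball around the anchor, kept inside the volume
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c = anchor + u * rng.uniform(0, max_r - rr)
            centers.append(np.clip(c, rr, shape_um - rr))
            radii.append(rr)
        for c, rr in zip(centers, radii):
            _paint_tube(od, c[None, :], rr, spacing, edge)
            dist = float(np.min(np.linalg.norm(truth.positions - c, axis=1))) if truth.n_nodes else None
            deposits.append(
                DepositTruth(
                    deposit_id=did,
                    lesion_id=lid,
                    centroid=tuple(float(v) for v in c),
                    radius=float(rr),
                    anchor_segment=seg,
                    anchor_distance=dist,
                )
            )
            did += 1

    transmission = spec.transmission_background * np.exp(-spec.deposit_absorbance * od)
    return _finish_stack(rng, transmission, spec), deposits


# ---------------------------------------------------------------------------
# 2D histology sections


@dataclass
class SectionSpec:
    """Parameters of a synthetic 2D brightfield histology section."""

    image_shape: tuple[int, int] = (1400, 1600)
    pixel_size: float = 4.0  # µm
    tissue_area: float = 0.25  # cm²
    cmh_density: float = 1.26  # lesions per cm²
    cmh_area_range: tuple[float, float] = (500.0, 20000.0)  # µm²
    dab_fraction: float = 0.0  # % of tissue area
    stain_colors: dict = field(
        default_factory=lambda: {
            "background": (255, 255, 255),
            "counterstain": (214, 148, 158),  # nuclear fast red
            "prussian_blue": (60, 70, 170),
        }
    )
    stain_model: str = "prussian_blue"  # or "dab" (hematoxylin-toned tissue)
    counterstain_od: float = 0.25  # hematoxylin OD of tissue on DAB sections
    dab_od: float = 1.0  # DAB OD of stained pixels
    noise_sigma: float = 4.0
    poisson_counts: bool = False  # if True, lesion count ~ Poisson(density·area)
    subcortex_fraction: float | None = None  # place this fraction of lesions in
    # the inner (subcortical) half-area of the tissue ellipse; None = uniform
    seed: int = 0

    def __post_init__(self) -> None:
        colors = list(self.stain_colors.values())
        for i in range(len(colors)):
            for j in range(i + 1, len(colors)):
                d = np.linalg.norm(np.asarray(colors[i], float) - np.asarray(colors[j], float))
                if d < 30:
                    raise ValueError("stain colors are not pairwise distinct enough")
        if self.cmh_area_range[0] < self.pixel_size**2:
            raise ValueError(
                "cmh_area_range lower bound is below one pixel at this pixel size"
            )

    @classmethod
    def dab_section(cls, dab_fraction: float, **kw) -> "SectionSpec":
        """A DAB-immunostained section (hematoxylin-toned tissue, no CMH)."""
        base = dict(
            cmh_density=0.0,
            dab_fraction=dab_fraction,
            stain_model="dab",
            tissue_area=kw.pop("tissue_area", 0.1),
            image_shape=kw.pop("image_shape", (900, 1000)),
        )
        base.update(kw)
        return cls(**base)


@dataclass
class SectionTruth:
    """Ground truth accompanying one synthetic section."""

    lesion_labels: np.ndarray  # int label image, 0 = not a lesion
    lesion_count: int
    lesion_areas_um2: np.ndarray
    tissue_mask: np.ndarray
    tissue_area_cm2: float
    dab_mask: np.ndarray
    dab_fraction: float  # % of tissue pixels, exact by construction
    region_labels: np.ndarray | None = None  # 1 = cortex, 2 = subcortex
    subcortex_count: int = 0


def _tissue_ellipse(shape: tuple[int, int], area_px: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ellipse mask of the requested pixel area, centered, aspect from shape."""
    h, w = shape
    aspect = w / h
    b = np.sqrt(area_px / (np.pi * aspect))
    a = aspect * b
    if a > 0.48 * w or b > 0.48 * h:
        raise ValueError("tissue_area does not fit in image_shape at this pixel size")
    yy, xx = np.mgrid[0:h, 0:w]
    e = ((yy - h / 2) / b) ** 2 + ((xx - w / 2) / a) ** 2
    return e <= 1.0, yy, xx


def generate_histology_section(spec: SectionSpec) -> tuple[np.ndarray, SectionTruth]:
    """Render a brightfield RGB section and its ground truth.

    Tissue is an ellipse of exactly ``tissue_area`` (up to pixel
    quantization); CMH lesions are blue elliptical blobs with areas drawn
    from ``cmh_area_range``; DAB staining, when requested, is applied to an
    exact count of tissue pixels (quantile cut of a smoothed random field)
    and rendered through the H-DAB absorbance matrix so color deconvolution
    is exercised downstream.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px_area_um2 = spec.pixel_size**2
    area_px = spec.tissue_area * 1e8 / px_area_um2
    tissue, yy, xx = _tissue_ellipse(spec.image_shape, area_px)
    tissue_area_cm2 = float(tissue.sum() * px_area_um2 * 1e-8)

    # region labels: inner concentric half-area ellipse = "subcortex"
    region = np.zeros(spec.image_shape, dtype=np.int8)
    aspect = w / h
    b = np.sqrt(area_px / (np.pi * aspect))
    a = aspect * b
    ell = ((yy - h / 2) / b) ** 2 + ((xx - w / 2) / a) ** 2
    region[tissue] = 1  # cortex (outer shell)
    region[(ell <= 0.5)] = 2  # subcortex (inner half-area)

    # --- lesions
    mean_count = spec.cmh_density * tissue_area_cm2
    if spec.poisson_counts:
        n_lesions = int(rng.poisson(mean_count))
    else:
        n_lesions = int(round(mean_count))
    labels = np.zeros(spec.image_shape, dtype=np.int32)
    areas = []
    inside = np.argwhere(ell <= 0.8)  # keep lesions away from the tissue rim
    subcortex_target = (
        None
        if spec.subcortex_fraction is None
        else int(round(spec.subcortex_fraction * n_lesions))
    )
    for lid in range(1, n_lesions + 1):
        target_um2 = rng.uniform(*spec.cmh_area_range)
        if subcortex_target is not None:
            want_sub = lid <= subcortex_target
            pool = np.argwhere((ell <= 0.5) if want_sub else ((ell > 0.5) & (ell <= 0.8)))
        else:
            pool = inside
        cy, cx = pool[rng.integers(len(pool))]
        # random-orientation ellipse of the target area
        ecc = rng.uniform(1.0, 2.5)
        r_px = np.sqrt(target_um2 / px_area_um2 / np.pi)
        ra, rb = r_px * np.sqrt(ecc), r_px / np.sqrt(ecc)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        pad = int(np.ceil(max(ra, rb))) + 1
        ys = slice(max(cy - pad, 0), min(cy + pad + 1, h))
        xs = slice(max(cx - pad, 0), min(cx + pad + 1, w))
        ly, lx = np.mgrid[ys, xs]
        u = (lx - cx) * ct + (ly - cy) * st
        v = -(lx - cx) * st + (ly - cy) * ct
        blob = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
        blob &= tissue[ys, xs]
        labels[ys, xs][blob] = lid
        areas.append(float(blob.sum() * px_area_um2))
    lesion_mask = labels > 0
    subcortex_count = 0
    for lid in range(1, n_lesions + 1):
        pts = np.argwhere(labels == lid)
        if len(pts):
            cy, cx = pts.mean(axis=0).round().astype(int)
            if region[cy, cx] == 2:
                subcortex_count += 1

    # --- DAB staining: exact pixel count by quantile cut of a smooth field
    dab_mask = np.zeros(spec.image_shape, dtype=bool)
    stainable = tissue & ~lesion_mask
    if spec.dab_fraction > 0:
        n_target = int(round(spec.dab_fraction / 100.0 * tissue.sum()))
        fld = ndi.gaussian_filter(rng.normal(size=spec.image_shape), sigma=3.0)
        vals = fld[stainable]
        if n_target > len(vals):
            raise ValueError("dab_fraction exceeds available tissue area")
        if n_target > 0:
            cut = np.partition(vals, len(vals) - n_target)[len(vals) - n_target]
            dab_mask = stainable & (fld >= cut)
            # resolve quantile ties to hit the count exactly
            excess = int(dab_mask.sum()) - n_target
            if excess > 0:
                tie = np.argwhere(dab_mask & (fld == cut))
                for k in range(excess):
                    dab_mask[tuple(tie[k])] = False
    dab_fraction_true = 100.0 * float(dab_mask.sum()) / float(tissue.sum())

    # --- render
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.stain_colors["background"], dtype=float)
    if spec.stain_model == "dab":
        # DAB section: hematoxylin-toned tissue rendered through OD space
        od = np.zeros((h, w, 2))
        od[tissue, 0] = spec.counterstain_od
        od[dab_mask, 1] = spec.dab_od
        od[tissue, 0] += 0.05 * rng.random(int(tissue.sum()))  # texture
        rendered = _od_to_rgb(od.reshape(-1, 2)).reshape(h, w, 3)
        img[tissue] = rendered[tissue]
    else:
        img[tissue] = np.asarray(spec.stain_colors["counterstain"], dtype=float)
    img[lesion_mask] = np.asarray(spec.stain_colors["prussian_blue"], dtype=float)
    if spec.noise_sigma > 0:
        img += rng.normal(scale=spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255)

    truth = SectionTruth(
        lesion_labels=labels,
        lesion_count=n_lesions,
        lesion_areas_um2=np.asarray(areas),
        tissue_mask=tissue,
        tissue_area_cm2=tissue_area_cm2,
        dab_mask=dab_mask,
        dab_fraction=dab_fraction_true,
        region_labels=region,
        subcortex_count=subcortex_count,
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class CohortSpec:
    """Parameters of a synthetic multi-group hypertension cohort.

    Group means default to the angiotensin-II infusion experiment: CMH
    densities per cm², final mean arterial pressures (mmHg) elevated only
    in untreated Ang II groups, Iba-1 %-area immunoreactivity doubled under
    hypertension, CD206 area ratio unaffected.  ``cmh_map_correlation`` is
    the pooled Pearson correlation between per-animal CMH density and final
    MAP that the generator achieves in expectation (calibrated analytically,
    accounting for Poisson counting noise and between-group separation).
    """

    n_per_group: int = 26
    group_labels: tuple[str, ...] = ("PBS-CTL", "AngII-CTL", "PBS-Tel", "AngII-Tel")
    cmh_density_means: tuple[float, ...] = (0.59, 1.26, 0.91, 0.86)
    map_baseline_mean: float = 103.0
    map_baseline_sd: float = 8.0
    map_final_means: tuple[float, ...] = (103.0, 139.0, 102.0, 102.0)
    iba1_means: tuple[float, ...] = (0.77, 1.52, 0.84, 1.29)
    cd206_means: tuple[float, ...] = (0.020, 0.020, 0.020, 0.020)
    cmh_map_correlation: float = 0.52
    measurement_noise: dict = field(
        default_factory=lambda: {
            "cmh_density": 0.30,
            "map": 10.0,
            "iba1": 0.40,
            "cd206": 0.005,
        }
    )
    section_area_cm2: float = 12.0  # total analyzed section area per animal
    seed: int = 0

    @classmethod
    def experiment_two_group(cls, **kw) -> "CohortSpec":
        """The two untreated groups only (the pair pooled for the CMH–MAP
        correlation)."""
        base = dict(
            group_labels=("PBS-CTL", "AngII-CTL"),
            cmh_density_means=(0.59, 1.26),
            map_final_means=(103.0, 139.0),
            iba1_means=(0.77, 1.52),
            cd206_means=(0.020, 0.020),
            n_per_group=27,
        )
        base.update(kw)
        return cls(**base)


def _calibrate_latent_rho(spec: CohortSpec) -> float:
    """Latent within-group correlation needed so the pooled Pearson r of
    (cmh_density, map_final) equals ``spec.cmh_map_correlation`` in
    expectation.

    Pooled covariance = within (latent) + between (group-mean separation);
    pooled variances include Poisson counting noise ``mean / area``.
    Raises if no attainable latent correlation produces the target.
    """
    r = spec.cmh_map_correlation
    s = spec.measurement_noise["cmh_density"]
    sig = spec.measurement_noise["map"]
    m = np.asarray(spec.cmh_density_means, float)
    M = np.asarray(spec.map_final_means, float)
    p = np.full(len(m), 1.0 / len(m))
    between_cov = float(p @ ((m - p @ m) * (M - p @ M)))
    var_d = s**2 + float(p @ m) / spec.section_area_cm2 + float(p @ (m - p @ m) ** 2)
    var_M = sig**2 + float(p @ (M - p @ M) ** 2)
    needed = r * np.sqrt(var_d * var_M) - between_cov
    if s == 0 or sig == 0:
        # no latent channel: the between-group structure alone fixes the r
        return 0.0
    rho = needed / (s * sig)
    if abs(rho) >= 1.0:
        raise ValueError(
            f"infeasible correlation: target r={r} requires latent rho={rho:.3f} "
            "given the specified measurement noise"
        )
    return float(rho)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort as a per-animal table.

    Columns: ``animal_id, sex, group, map_baseline, map_final, cmh_count,
    section_area_cm2, cmh_density, iba1_fraction, cd206_ratio``.  CMH counts
    are Poisson with mean ``density × area`` (deterministic rounding when
    the density noise is zero); the CMH-density–MAP correlation is induced
    by a shared latent Gaussian factor calibrated to the requested pooled r.
    """
    rng = np.random.default_rng(spec.seed)
    noise = spec.measurement_noise
    s, sig = noise["cmh_density"], noise["map"]
    zero_noise = all(v == 0 for v in noise.values())
    rho = _calibrate_latent_rho(spec)
    sign = 1.0 if rho >= 0 else -1.0
    A = spec.section_area_cm2
    rows = []
    aid = 0
    for gi, group in enumerate(spec.group_labels):
        for k in range(spec.n_per_group):
            z = rng.normal()
            e_map, e_d = rng.normal(), rng.normal()
            lat = np.sqrt(abs(rho))
            u_map = lat * z + np.sqrt(1 - abs(rho)) * e_map
            u_d = sign * lat * z + np.sqrt(1 - abs(rho)) * e_d
            map_final = spec.map_final_means[gi] + sig * u_map
            map_base = spec.map_baseline_mean + spec.map_baseline_sd * rng.normal()
            d = max(spec.cmh_density_means[gi] + s * u_d, 0.0)
            if s == 0:
                count = int(round(d * A))
            else:
                count = int(rng.poisson(d * A))
            iba1 = max(spec.iba1_means[gi] + noise["iba1"] * rng.normal(), 0.0)
            cd206 = max(spec.cd206_means[gi] + noise["cd206"] * rng.normal(), 0.0)
            if zero_noise:
                map_base = spec.map_baseline_mean
            rows.append(
                {
                    "animal_id": f"A{aid:03d}",
                    "sex": "F" if k % 2 else "M",
                    "group": group,
                    "map_baseline": map_base,
                    "map_final": map_final,
                    "cmh_count": count,
                    "section_area_cm2": A,
                    "cmh_density": count / A,
                    "iba1_fraction": iba1,
                    "cd206_ratio": cd206,
                }
            )
            aid += 1
    return pd.DataFrame(rows)
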