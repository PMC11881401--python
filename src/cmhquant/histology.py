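"""2D histological quantification.

Ratiometric Prussian-blue CMH detection and density per cm², DAB %-area
immunoreactivity by H-DAB color deconvolution, fluorescence area ratio,
and region assignment of lesions against a user-supplied region mask.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segmentation import clean_mask, iterative_selection_threshold
from .synthetic import HDAB_VECTORS

__all__ = [
    "RatioParams",
    "segment_prussian_blue_rgb",
    "enumerate_cmh",
    "tissue_area",
    "cmh_density",
    "dab_immunoreactive_fraction",
    "fluorescence_area_ratio",
    "assign_regions",
]

UM2_PER_CM2 = 1e8


@dataclass
class RatioParams:
    """Ratiometric blue-pixel rule: positive iff B/(R+ε) ≥ blue_ratio and
    B/(G+ε) ≥ blue_ratio and B ≥ min_blue.  The exact thresholds of the
    original rule are not published; these defaults are a reconstruction
    and are configuration-exposed."""

    blue_ratio: float = 1.2
    min_blue: float = 60.0
    eps: float = 1.0
    min_component_size: int = 4  # pixels, speckle suppression


def _require_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("an RGB image (H, W, 3) is required")
    return img


def segment_prussian_blue_rgb(
    image: np.ndarray, params: RatioParams | None = None
) -> np.ndarray:
    """Ratiometric segmentation of Prussian-blue-positive pixels."""
    if params is None:
        params = RatioParams()
    img = _require_rgb(image)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    mask = (
        (b / (r + params.eps) >= params.blue_ratio)
        & (b / (g + params.eps) >= params.blue_ratio)
        & (b >= params.min_blue)
    )
    return clean_mask(mask, min_component_size=params.min_component_size)


def enumerate_cmh(
    mask: np.ndarray, pixel_size: float, min_area: float = 100.0
) -> tuple[int, float, np.ndarray]:
    """Count CMH components and measure their areas.

    8-connected components of the binary mask with area ≥ ``min_area`` µm²
    are counted.  Returns (count, total area µm², per-component areas µm²).
    """
    labels, n = ndi.label(np.asarray(mask, dtype=bool), structure=np.ones((3, 3), int))
    if n == 0:
        return 0, 0.0, np.zeros(0)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    areas = sizes * pixel_size**2
    areas = areas[areas >= min_area]
    return int(len(areas)), float(areas.sum()), areas


def tissue_mask_rgb(image: np.ndarray, white_level: float = 230.0) -> np.ndarray:
    """Tissue = non-background pixels; background is near-white (all
    channels ≥ ``white_level``).  Closed morphologically, then only the
    largest connected component is kept."""
    img = _require_rgb(image)
    mask = ~np.all(img >= white_level, axis=-1)
    if not mask.any():
        return mask
    structure = np.ones((5, 5), bool)
    mask = ndi.binary_erosion(
        ndi.binary_dilation(mask, structure=structure), structure=structure, border_value=1
    )
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def tissue_area(
    image: np.ndarray, pixel_size: float, tissue_mask: np.ndarray | None = None
) -> float:
    """Total tissue area of a section, cm².

    Uses the provided tissue mask or derives one from the RGB image
    (near-white background rule).  Warns when the tissue fraction is below
    1% (likely a blank slide).
    """
    mask = tissue_mask if tissue_mask is not None else tissue_mask_rgb(image)
    frac = mask.mean() if mask.size else 0.0
    if frac < 0.01:
        warnings.warn("tissue fraction < 1%: likely a blank slide")
    return float(mask.sum() * pixel_size**2 / UM2_PER_CM2)


def cmh_density(counts, areas_cm2) -> float:
    """Per-animal CMH density: total count over total analyzed area (cm²),
    pooled across all of the animal's sections."""
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas_cm2, dtype=float)
    if counts.shape != areas.shape:
        raise ValueError("counts and areas must align")
    total_area = float(areas.sum())
    if total_area <= 0:
        raise ValueError("zero total section area")
    return float(counts.sum() / total_area)


def _gated_threshold_mask(values: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Iterative-selection threshold with a two-class separation gate.

    On signal-free input the iterative threshold merely splits the noise,
    so the bright class is only accepted when the two class means separate
    by more than 3× the pooled within-class standard deviation; otherwise
    nothing is positive.  ``floor``, when given, is an absolute positivity
    level: values above it count even when thresholding is degenerate
    (e.g. uniformly stained tissue), and values below it never count.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    above_floor = v > floor if floor is not None else np.ones(v.shape, dtype=bool)
    if v.max() - v.min() < 1e-12:
        return above_floor if floor is not None else np.zeros(v.shape, dtype=bool)
    t = iterative_selection_threshold(v).threshold
    pos = v > t
    if not pos.any() or pos.all():
        return above_floor if floor is not None else np.zeros(v.shape, dtype=bool)
    lo, hi = v[~pos], v[pos]
    pooled_sd = np.sqrt(
        (lo.var(ddof=0) * lo.size + hi.var(ddof=0) * hi.size) / v.size
    )
    if pooled_sd == 0 or (hi.mean() - lo.mean()) > 3.0 * pooled_sd:
        return pos & above_floor
    return above_floor if floor is not None else np.zeros(v.shape, dtype=bool)


def dab_immunoreactive_fraction(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    stain_vectors: np.ndarray | None = None,
) -> float:
    """DAB-positive area as a percentage of the tissue area.

    The RGB brightfield image is unmixed against the H-DAB absorbance
    matrix (standard published stain vectors, replaceable); the DAB
    optical-density channel is thresholded by iterative selection within
    the tissue mask (with a separation gate so unstained fields report 0).
    """
    img = _require_rgb(image)
    mask = np.asarray(tissue_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tissue mask")
    if stain_vectors is None:
        stain_vectors = HDAB_VECTORS
    # complete the stain basis with the residual (cross-product) vector,
    # then unmix Beer–Lambert optical densities: OD = −ln(I/I0) · M⁻¹
    third = np.cross(stain_vectors[0], stain_vectors[1])
    third /= np.linalg.norm(third)
    basis = np.vstack([stain_vectors, third])
    od_rgb = -np.log(np.clip(img, 1, 255) / 255.0)
    od = od_rgb @ np.linalg.inv(basis)
    dab = od[..., 1]
    # 0.3 OD floor: above counterstain bleed-through, well below true DAB
    pos_in_tissue = _gated_threshold_mask(dab[mask], floor=0.3)
    return float(100.0 * pos_in_tissue.sum() / mask.sum())


def fluorescence_area_ratio(image: np.ndarray, cortex_mask: np.ndarray) -> float:
    """Immunofluorescent area over total cortex area (dimensionless).

    Positive pixels are those above the iterative-selection threshold
    computed within the cortex mask (with the same separation gate as the
    DAB quantifier, so dark fields report ~0).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    mask = np.asarray(cortex_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cortex mask")
    pos = _gated_threshold_mask(img[mask])
    return float(pos.sum() / mask.sum())


def assign_regions(
    centroids: list[tuple[float, float]],
    region_mask: np.ndarray,
    labels: dict[int, str] | None = None,
) -> dict[str, int]:
    """Assign each component centroid the region label at its pixel.

    ``region_mask`` is an integer label image; ``labels`` maps label values
    to names (default: 1 = cortex, 2 = subcortex, anything else = other).
    Centroids on unlabeled (0) pixels are counted as "other" and logged.
    """
    if labels is None:
        labels = {1: "cortex", 2: "subcortex"}
    counts: Counter[str] = Counter()
    h, w = region_mask.shape
    for cy, cx in centroids:
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < h and 0 <= ix < w):
            counts["other"] += 1
            continue
        val = int(region_mask[iy, ix])
        name = labels.get(val)
        if name is None:
            warnings.warn(f"centroid ({cy:.0f}, {cx:.0f}) on unlabeled pixel")
            name = "other"
        counts[name] += 1
    return dict(counts)
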