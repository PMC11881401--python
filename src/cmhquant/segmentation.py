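"""Binary segmentation primitives shared by the 3D and 2D pipelines.

Two thresholding families are provided:

* :func:`iterative_selection_threshold` — the global Ridler–Calvard
  ("iterative selection" / ISODATA) threshold used to segment the
  fluorescently labeled vasculature in cleared-tissue stacks.
* :func:`sauvola_threshold` — the local Sauvola threshold used to segment
  dark Prussian-blue deposits in transmission stacks, where illumination
  varies across the field.

plus :func:`clean_mask` for morphological cleanup of either output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_objects

__all__ = [
    "ThresholdResult",
    "SauvolaParams",
    "iterative_selection_threshold",
    "sauvola_threshold",
    "sauvola_threshold_map",
    "clean_mask",
    "rgb_to_gray",
]

#: fixed luminance weights for RGB → grayscale conversion (Rec. 601)
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

MAX_ITERATIONS = 500


@dataclass
class ThresholdResult:
    """Outcome of a global threshold computation.

    Attributes
    ----------
    threshold : float
        The converged threshold, in the image's intensity units.
    iterations : int
        Number of update steps taken.
    converged : bool
        Whether ``|ΔT| < tol`` was reached within the iteration cap.
    """

    threshold: float
    iterations: int
    converged: bool


@dataclass
class SauvolaParams:
    """Parameters of the local Sauvola threshold.

    ``window`` is the side length (pixels, odd) of the local square window,
    ``k`` the dimensionless sensitivity, ``R`` the dynamic range of the
    local standard deviation.  ``polarity`` selects whether objects darker
    or brighter than the local threshold are kept; Prussian-blue deposits
    are dark in transmission, hence the default.
    """

    window: int = 61
    k: float = 0.2
    R: float | None = None  # default: half the image dynamic range
    polarity: Literal["dark-objects", "bright-objects"] = "dark-objects"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.R is not None and self.R <= 0:
            raise ValueError("R must be positive")


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale with fixed luminance weights."""
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image with a trailing channel axis of size 3")
    w = np.asarray(LUMA_WEIGHTS, dtype=float)
    return np.asarray(image, dtype=float) @ w


def iterative_selection_threshold(
    image: np.ndarray,
    tol: float | None = None,
    n_bins: int = 4096,
) -> ThresholdResult:
    """Ridler–Calvard iterative-selection (ISODATA) global threshold.

    Iterates ``T ← (mean(x ≤ T) + mean(x > T)) / 2`` from the global mean
    until the update moves by less than ``tol``.  The iteration runs on an
    intensity histogram, so cost is independent of how often a value
    repeats.

    Parameters
    ----------
    image : ndarray
        Grayscale image or volume with at least two distinct finite values.
    tol : float, optional
        Convergence tolerance on the threshold.  Defaults to 0.5 for
        integer-typed images and ``1e-6 * (max - min)`` for float images.
    n_bins : int
        Histogram resolution for float images; integer images use one bin
        per integer level.

    Returns
    -------
    ThresholdResult
    """
    data = np.asarray(image)
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite intensities")
    lo = float(data.min())
    hi = float(data.max())
    if lo == hi:
        raise ValueError("constant image: threshold undefined")

    if np.issubdtype(data.dtype, np.integer):
        # one bin per integer level
        nbins = int(hi - lo) + 1
        edges = np.arange(lo - 0.5, hi + 1.0, 1.0)
        centers = np.arange(lo, hi + 1.0)
        counts, _ = np.histogram(data, bins=edges)
        if tol is None:
            tol = 0.5
    else:
        nbins = n_bins
        counts, edges = np.histogram(data, bins=nbins, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        if tol is None:
            tol = 1e-6 * (hi - lo)

    weighted = counts * centers
    csum = np.cumsum(counts)
    cwsum = np.cumsum(weighted)
    total_n = csum[-1]
    total_w = cwsum[-1]

    def cut_index(t: float) -> int:
        idx = int(np.searchsorted(centers, t, side="right")) - 1
        return min(max(idx, 0), nbins - 1)

    def update(idx: int, t: float) -> float:
        n_low, w_low = csum[idx], cwsum[idx]
        if n_low == 0 or n_low == total_n:
            # all mass on one side: nudge toward the interior
            return 0.5 * (t + (hi if n_low == 0 else lo))
        mean_low = w_low / n_low
        mean_high = (total_w - w_low) / (total_n - n_low)
        return 0.5 * (mean_low + mean_high)

    # iterate until the induced histogram partition is self-consistent:
    # the update computed from a cut must land back inside the same cut.
    # Initialization at the mid-range: when the foreground occupies only a
    # few percent of the pixels, the global mean sits inside the background
    # mode, whose own (noise-splitting) fixed point would then capture the
    # iteration; the mid-range start descends into the between-class valley.
    t = 0.5 * (lo + hi)
    converged = False
    iterations = 0
    seen: set[int] = set()
    for iterations in range(1, MAX_ITERATIONS + 1):
        idx = cut_index(t)
        t_new = update(idx, t)
        if cut_index(t_new) == idx:
            # at a stable partition the next update is exact: |ΔT| = 0 < tol
            t = t_new
            converged = True
            break
        if idx in seen:  # oscillating between cuts: report the current one
            t = t_new
            break
        seen.add(idx)
        t = t_new
    return ThresholdResult(threshold=float(t), iterations=iterations, converged=converged)


def _local_mean_std(image: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Local windowed mean and standard deviation with reflective padding."""
    img = np.asarray(image, dtype=np.float64)
    m = ndi.uniform_filter(img, size=window, mode="reflect")
    m2 = ndi.uniform_filter(img * img, size=window, mode="reflect")
    var = np.clip(m2 - m * m, 0.0, None)
    return m, np.sqrt(var)


def sauvola_threshold_map(image: np.ndarray, params: SauvolaParams) -> np.ndarray:
    """Per-pixel Sauvola threshold ``t = m · (1 + k·(s/R − 1))``.

    ``m`` and ``s`` are the local window mean and standard deviation
    (reflective border).  ``R`` defaults to half the image dynamic range.
    """
    img = np.asarray(image, dtype=np.float64)
    if params.window > min(img.shape):
        raise ValueError(
            f"window {params.window} does not fit inside image of shape {img.shape}"
        )
    if not 0 < params.k <= 1:
        import warnings

        warnings.warn(f"Sauvola k={params.k} outside (0, 1]; applied anyway")
    R = params.R
    if R is None:
        rng = float(img.max() - img.min())
        R = rng / 2.0 if rng > 0 else 1.0
    m, s = _local_mean_std(img, params.window)
    return m * (1.0 + params.k * (s / R - 1.0))


def sauvola_threshold(image: np.ndarray, params: SauvolaParams | None = None) -> np.ndarray:
    """Sauvola local threshold → binary mask.

    2D input is thresholded directly; 3D input is processed slice by slice
    along the first (z) axis, matching per-focal-plane transmission
    acquisition.

    Returns a boolean mask of the selected objects (dark or bright per
    ``params.polarity``).
    """
    if params is None:
        params = SauvolaParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        t = sauvola_threshold_map(img, params)
        return img < t if params.polarity == "dark-objects" else img > t
    if img.ndim == 3:
        out = np.empty(img.shape, dtype=bool)
        for z in range(img.shape[0]):
            out[z] = sauvola_threshold(img[z], params)
        return out
    raise ValueError("sauvola_threshold expects a 2D image or a 3D stack")


def clean_mask(
    mask: np.ndarray,
    min_component_size: int = 0,
    closing_radius: float = 0.0,
    spacing: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Morphological closing at a physical radius, then small-object removal.

    Parameters
    ----------
    mask : ndarray of bool
        Binary mask, 2D or 3D.
    min_component_size : int
        Components with fewer voxels/pixels are removed
        (26-connectivity in 3D, 8-connectivity in 2D).
    closing_radius : float
        Closing radius in µm (converted to voxels via ``spacing``).
    spacing : tuple of float, optional
        Physical voxel/pixel size per axis in µm; defaults to 1 per axis.
    """
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return m.copy()
    ndim = m.ndim
    if spacing is None:
        spacing = (1.0,) * ndim
    if closing_radius > 0:
        # anisotropic ellipsoid footprint: physical radius per axis
        radii = [max(int(round(closing_radius / s)), 0) for s in spacing]
        if any(r > 0 for r in radii):
            grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
            dist2 = sum(
                (g * s) ** 2 for g, s in zip(grids, spacing)
            )
            footprint = dist2 <= closing_radius**2
            # true closing: dilation sees background outside, erosion sees
            # foreground (scipy's binary_closing erodes away the border)
            m = ndi.binary_erosion(
                ndi.binary_dilation(m, structure=footprint),
                structure=footprint,
                border_value=1,
            )
    if min_component_size > 1:
        structure = np.ones((3,) * ndim, dtype=int)
        labels, n = ndi.label(m, structure=structure)
        if n:
            sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_component_size) + 1
            m = np.isin(labels, keep)
    return m
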