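"""Lipid-droplet quantification from two-channel organoid images.

The measurement follows the standard confocal workflow for Nile Red / DAPI
stained hepatocyte organoids:

1. Z-stacks are maximum-intensity projected to a single plane.
2. The organoid region of interest (ROI) is defined from the nuclei
   (DAPI) channel: the occupancy of nuclear fluorescence delimits the
   organoid surface area.
3. Lipid droplets are segmented from the neutral-lipid (Nile Red)
   channel by an automatic intensity threshold computed inside the ROI.
4. Percent steatosis is the droplet-covered fraction of the ROI, and the
   lipid score is an affine renormalization of that coverage mapping the
   wild-type reference mean to 0 and a steatotic reference mean to 1.

Scores are deliberately NOT clipped to [0, 1]: values above 1 indicate
aggravated steatosis relative to the untreated steatotic reference and
values below 0 indicate lipid levels below the wild-type baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

__all__ = [
    "SegmentationResult",
    "SteatosisMeasurement",
    "LipidScore",
    "project_stack",
    "segment_organoid_roi",
    "segment_droplets",
    "percent_steatosis",
    "lipid_score",
    "measure_image",
]


@dataclass(frozen=True)
class SegmentationResult:
    """Binary masks and summary areas of one segmented image.

    ``droplet_mask`` is always a subset of ``roi_mask``; areas are pixel
    counts of the respective masks.
    """

    roi_mask: np.ndarray
    droplet_mask: np.ndarray
    droplet_count: int
    droplet_area_px: int
    roi_area_px: int
    threshold_value: float


@dataclass(frozen=True)
class SteatosisMeasurement:
    """Percent of the organoid ROI covered by lipid droplets."""

    percent_steatosis: float


@dataclass(frozen=True)
class LipidScore:
    """Coverage normalized to the WT (0) / steatotic-reference (1) scale."""

    score: float
    wt_reference_mean: float
    steatotic_reference_mean: float


def project_stack(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a ``(z, y, x)`` stack.

    A single 2D image passes through unchanged.
    """
    arr = np.asarray(zstack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a non-empty (z, y, x) stack or a 2D image")
    return arr.max(axis=0)


def segment_organoid_roi(
    nuclei_image: np.ndarray,
    sigma: float = 2.0,
    closing_radius: int = 10,
    convex_hull: bool = True,
) -> np.ndarray:
    """Organoid ROI from nuclear-stain signal occupancy.

    Gaussian smoothing, global Otsu threshold, morphological closing to
    bridge the gaps between individual nuclei, hole filling, and
    selection of the largest connected component so exactly one organoid
    region is returned.  Because nuclei sample the organoid surface
    sparsely, the default ROI is the convex hull of that component
    (organoid cross-sections are close to convex); set
    ``convex_hull=False`` for the raw closed mask.

    Raises
    ------
    ValueError
        If no foreground survives thresholding ("no organoid detected").
    """
    img = np.asarray(nuclei_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        raise ValueError("no organoid detected: image has no contrast")
    smoothed = filters.gaussian(img, sigma=sigma, preserve_range=True) if sigma > 0 else img
    thresh = filters.threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        raise ValueError("no organoid detected: nothing above threshold")
    if closing_radius > 0:
        footprint = morphology.disk(closing_radius, decomposition="sequence")
        fg = morphology.closing(fg, footprint)
    fg = ndi.binary_fill_holes(fg)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("no organoid detected")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    roi = labels == largest
    if convex_hull:
        roi = morphology.convex_hull_image(roi)
    return roi


def segment_droplets(
    lipid_image: np.ndarray,
    roi: np.ndarray,
    min_area_px: int = 4,
    threshold: float | None = None,
) -> SegmentationResult:
    """Segment lipid droplets inside the organoid ROI.

    The droplet threshold is computed automatically (Otsu) from the
    lipid-channel intensities inside the ROI unless a fixed ``threshold``
    override is given.  Connected components smaller than ``min_area_px``
    are discarded as speckle.  Zero droplets is a valid result.
    """
    img = np.asarray(lipid_image, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    inside = img[roi]
    if threshold is None:
        if np.ptp(inside) == 0:
            # Degenerate within-ROI contrast: fall back on whole-image
            # statistics so uniformly bright ROIs segment as droplet and
            # uniformly dark images as background.
            threshold = filters.threshold_otsu(img) if np.ptp(img) > 0 else np.inf
        else:
            threshold = filters.threshold_otsu(inside)
    mask = (img > threshold) & roi
    if min_area_px > 1:
        # drop connected components smaller than min_area_px
        mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    labels, count = measure.label(mask, return_num=True)
    return SegmentationResult(
        roi_mask=roi,
        droplet_mask=mask,
        droplet_count=int(count),
        droplet_area_px=int(mask.sum()),
        roi_area_px=int(roi.sum()),
        threshold_value=float(threshold),
    )


def percent_steatosis(seg: SegmentationResult) -> SteatosisMeasurement:
    """Droplet area coverage of the ROI, as a percentage in [0, 100]."""
    if seg.roi_area_px <= 0:
        raise ValueError("ROI area must be positive")
    return SteatosisMeasurement(100.0 * seg.droplet_area_px / seg.roi_area_px)


def lipid_score(coverage: float, wt_mean: float, steatotic_mean: float) -> LipidScore:
    """Affine lipid score: WT reference mean -> 0, steatotic mean -> 1.

    ``coverage`` and the two reference means must be on the same scale
    (either coverage fractions or percent steatosis, consistently).
    """
    if steatotic_mean == wt_mean:
        raise ValueError("degenerate references: steatotic mean equals WT mean")
    return LipidScore(
        score=(coverage - wt_mean) / (steatotic_mean - wt_mean),
        wt_reference_mean=wt_mean,
        steatotic_reference_mean=steatotic_mean,
    )


def measure_image(
    nuclei_image: np.ndarray,
    lipid_image: np.ndarray,
    min_area_px: int = 4,
    roi_sigma: float = 2.0,
    closing_radius: int = 10,
    wt_mean: float | None = None,
    steatotic_mean: float | None = None,
) -> dict:
    """Full single-image pipeline: ROI, droplets, percent steatosis, score.

    Returns a flat record suitable for tabulation.  The lipid score is
    included only when both reference means (percent-steatosis scale) are
    provided.
    """
    nuclei = project_stack(nuclei_image)
    lipid = project_stack(lipid_image)
    roi = segment_organoid_roi(nuclei, sigma=roi_sigma, closing_radius=closing_radius)
    seg = segment_droplets(lipid, roi, min_area_px=min_area_px)
    pct = percent_steatosis(seg).percent_steatosis
    rec = {
        "roi_area_px": seg.roi_area_px,
        "droplet_area_px": seg.droplet_area_px,
        "droplet_count": seg.droplet_count,
        "percent_steatosis": pct,
    }
    if wt_mean is not None and steatotic_mean is not None:
        rec["lipid_score"] = lipid_score(pct, wt_mean, steatotic_mean).score
    return rec
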