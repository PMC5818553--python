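"""Two-channel thresholding and per-bouton mitochondrial occupancy.

The green channel outlines boutons (indicator baseline fluorescence); the
red channel shows strongly stained mitochondria.  Each channel is
thresholded independently, boutons are the connected components of the
green mask, and a bouton counts as occupied when at least ``min_overlap_px``
red pixels fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["ColocResult", "threshold_channel", "occupancy", "best_integer_shift"]


@dataclass
class ColocResult:
    bouton_mask: np.ndarray
    mito_mask: np.ndarray
    labels: np.ndarray                 # labeled bouton components
    occupied: dict[int, bool]
    puncta_count: dict[int, int]
    fraction_occupied: float | None    # None when there are no boutons
    thresholds: dict[str, float]
    min_overlap_px: int


def threshold_channel(
    image: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    percentile: float | None = None,
) -> tuple[np.ndarray, float]:
    """Binary foreground mask from a single-channel 2-D image.

    Methods: ``otsu`` (default; the source states thresholding but not the
    rule), ``absolute`` (fixed ``value``), ``percentile`` (of the intensity
    distribution), ``robust`` (median + ``value`` median-absolute-deviation
    sigmas, default 5; suited to sparse puncta where Otsu's two-class
    assumption fails).  Returns (mask, threshold used).  An empty foreground
    is allowed (warns only through the empty mask itself).
    """

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("a single-channel 2-D image is required")
    if method == "otsu":
        thr = float(threshold_otsu(img))
    elif method == "robust":
        nmads = 5.0 if value is None else float(value)
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        thr = med + nmads * sigma
    elif method == "absolute":
        if value is None:
            raise ValueError("absolute thresholding needs a value")
        thr = float(value)
    elif method == "percentile":
        if percentile is None:
            raise ValueError("percentile thresholding needs a percentile")
        thr = float(np.percentile(img, percentile))
    else:
        raise ValueError(f"unknown method {method!r}")
    return img > thr, thr


def occupancy(
    bouton_mask: np.ndarray,
    mito_mask: np.ndarray,
    min_overlap_px: int = 2,
    labels: np.ndarray | None = None,
    thresholds: dict[str, float] | None = None,
    min_bouton_px: int = 5,
) -> ColocResult:
    """Per-bouton occupancy and the occupied fraction.

    Boutons default to the connected components of ``bouton_mask`` at least
    ``min_bouton_px`` pixels in size (rejects isolated noise specks); a
    label image can be supplied instead (e.g. the simulator's ground-truth
    ROIs).  Puncta are counted as connected red components touching the
    bouton.
    """

    if bouton_mask.shape != mito_mask.shape:
        raise ValueError("channel masks must share a shape")
    if labels is None:
        labels, _ = ndimage.label(bouton_mask)
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_bouton_px)[0]
        labels[np.isin(labels, small[small > 0])] = 0
    ids = [int(i) for i in np.unique(labels) if i != 0]
    mito_labels, _ = ndimage.label(mito_mask)

    occupied: dict[int, bool] = {}
    counts: dict[int, int] = {}
    for i in ids:
        inside = mito_mask & (labels == i)
        occupied[i] = int(inside.sum()) >= min_overlap_px
        counts[i] = len(np.unique(mito_labels[inside & (mito_labels > 0)])) \
            if occupied[i] else 0
    frac = (sum(occupied.values()) / len(ids)) if ids else None
    return ColocResult(
        bouton_mask=np.asarray(bouton_mask, dtype=bool),
        mito_mask=np.asarray(mito_mask, dtype=bool),
        labels=labels,
        occupied=occupied,
        puncta_count=counts,
        fraction_occupied=frac,
        thresholds=thresholds or {},
        min_overlap_px=min_overlap_px,
    )


def best_integer_shift(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    max_shift: int = 0,
) -> tuple[int, int]:
    """Integer (row, col) shift of ``mask_b`` maximizing overlap with ``mask_a``.

    Replaces the manual image merging step; the default ``max_shift=0``
    is the identity (channels assumed registered).
    """

    best = (0, 0)
    best_score = -1
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(mask_b, dr, axis=0), dc, axis=1)
            score = int((mask_a & shifted).sum())
            if score > best_score:
                best, best_score = (dr, dc), score
    return best
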