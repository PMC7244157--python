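"""Identification of intact cell nuclei from the DAPI channel.

Pipeline stage 1: a global two-class Otsu threshold (computed on a 256-bin
histogram over [0, 1] of the smoothed image, multiplied by a correction
factor and clamped to configured bounds) yields the DAPI+ foreground.
Touching nuclei are then separated by "shape"-based declumping: the
Euclidean distance transform of the mask is smoothed, its local maxima
(with mutual separation enforced at the minimum object diameter) become
seeds, and every foreground pixel is assigned to a seed by synchronous
ring propagation. Objects are finally gated on equivalent diameter and
border contact, and burst nuclei are removed by the circularity filter
(FormFactor >= 0.599 by default).

Cytospun nuclei are uniformly rounded and show a definite indentation
where they touch, which is why the distance-transform/shape strategy is
appropriate here; adaptive thresholding and intensity-based declumping
variants are out of scope.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PrimarySegmentationParams

_OTSU_BINS = 256
_LABEL_SENTINEL = np.iinfo(np.int32).max


def otsu_threshold(image: np.ndarray, nbins: int = _OTSU_BINS) -> float:
    """Two-class Otsu threshold over a fixed-range [0, 1] histogram.

    The histogram uses ``nbins`` uniform bins over [0, 1] regardless of the
    observed intensity range. The split maximizing the between-class
    variance is found exhaustively; the threshold is reported at the upper
    edge of the selected bin. Degenerate images (single intensity value, or
    all mass in one bin) return the maximum observed value, so that a
    strict ``>`` comparison yields an empty foreground.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot threshold an empty image")
    vmax = float(image.max())
    if float(image.min()) == vmax:
        return vmax

    bin_idx = np.clip((image.ravel() * nbins).astype(np.int64), 0, nbins - 1)
    hist = np.bincount(bin_idx, minlength=nbins).astype(np.float64)
    centers = (np.arange(nbins) + 0.5) / nbins

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * centers)
    mu_total = s0[-1]
    # split k puts bins 0..k in class 0, k+1.. in class 1
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    if not valid.any():
        return vmax
    m0 = np.where(w0[:-1] > 0, s0[:-1] / np.maximum(w0[:-1], 1), 0.0)
    m1 = np.where(w1[:-1] > 0, (mu_total - s0[:-1]) / np.maximum(w1[:-1], 1), 0.0)
    sigma_b = w0[:-1] * w1[:-1] * (m0 - m1) ** 2
    sigma_b[~valid] = -np.inf
    k = int(np.argmax(sigma_b))  # first maximum wins on exact ties
    return float((k + 1) / nbins)


def effective_threshold(image: np.ndarray, params: PrimarySegmentationParams,
                        smoothed: Optional[np.ndarray] = None) -> float:
    """Corrected, clamped Otsu threshold of the (smoothed) image."""
    if smoothed is None:
        smoothed = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64),
                                           params.sigma, mode="nearest")
    lo, hi = params.threshold_bounds
    return float(np.clip(otsu_threshold(smoothed) * params.threshold_correction, lo, hi))


def threshold_mask(image: np.ndarray, params: PrimarySegmentationParams,
                   return_threshold: bool = False):
    """Smooth, threshold and binarize one channel.

    The image is Gaussian-smoothed with sigma = smoothing_scale/1.3488, the
    Otsu threshold of the smoothed image is multiplied by the correction
    factor and clamped to the configured bounds, and pixels strictly above
    the effective threshold become foreground.
    """
    image = np.asarray(image, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(image, params.sigma, mode="nearest")
    t = effective_threshold(image, params, smoothed=smoothed)
    mask = smoothed > t
    if return_threshold:
        return mask, t
    return mask


def _suppressed_maxima(smoothed_distance: np.ndarray, mask: np.ndarray,
                       min_separation: float) -> List[Tuple[int, int]]:
    """Local maxima of the smoothed distance map, greedily thinned so that
    no two accepted maxima are closer than ``min_separation`` (Euclidean).

    Candidates are scanned in descending value, ties broken by row-major
    order, for determinism.
    """
    neigh_max = ndimage.maximum_filter(smoothed_distance, size=3, mode="constant")
    cand = (smoothed_distance >= neigh_max) & mask & (smoothed_distance > 0)
    rr, cc = np.nonzero(cand)
    if rr.size == 0:
        return []
    values = smoothed_distance[rr, cc]
    order = np.lexsort((cc, rr, -values))  # descending value, then row-major
    rr, cc = rr[order], cc[order]
    accepted_r: List[int] = []
    accepted_c: List[int] = []
    min_sq = float(min_separation) ** 2
    for r, c in zip(rr.tolist(), cc.tolist()):
        ok = True
        for ar, ac in zip(accepted_r, accepted_c):
            if (r - ar) ** 2 + (c - ac) ** 2 < min_sq:
                ok = False
                break
        if ok:
            accepted_r.append(r)
            accepted_c.append(c)
    coords = sorted(zip(accepted_r, accepted_c))
    return coords


def _propagate_rings(seeds: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Synchronous ring-growing of seed labels inside ``mask``.

    One 8-connected pixel layer is added per iteration; when two labels
    reach a pixel in the same iteration the lower label wins.
    """
    lab = np.where(seeds > 0, seeds.astype(np.int64), _LABEL_SENTINEL)
    lab[~mask & (seeds == 0)] = 0  # outside mask stays background
    # encode: 0 = background (ignore), sentinel = unassigned foreground
    unassigned = mask & (seeds == 0)
    lab[unassigned] = _LABEL_SENTINEL
    while True:
        grow = ndimage.minimum_filter(
            np.where(lab == 0, _LABEL_SENTINEL, lab), size=3,
            mode="constant", cval=_LABEL_SENTINEL,
        )
        newly = (lab == _LABEL_SENTINEL) & (grow < _LABEL_SENTINEL) & mask
        if not newly.any():
            break
        lab[newly] = grow[newly]
    lab[lab == _LABEL_SENTINEL] = 0
    return lab.astype(np.int32)


def fill_holes_per_object(labels: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border, per
    object. Only pixels that are currently background are claimed."""
    labels = labels.astype(np.int32, copy=True)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels
    slices = ndimage.find_objects(labels, max_label=int(ids.max()))
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connected background
    for lab in ids:
        sl = slices[int(lab) - 1]
        mask = labels[sl] == lab
        filled = ndimage.binary_fill_holes(mask, structure=structure)
        claim = filled & (labels[sl] == 0)
        labels[sl][claim] = lab
    return labels


def declump_by_shape(mask: np.ndarray, params: PrimarySegmentationParams) -> np.ndarray:
    """Separate touching objects in a binary mask by the distance-transform
    ("shape") strategy and return a label map.

    Seeds are the suppressed maxima of the smoothed Euclidean distance
    transform; foreground pixels are assigned to seeds by synchronous ring
    propagation; holes are filled per object when configured.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    edt = ndimage.distance_transform_edt(mask)
    smoothed = ndimage.gaussian_filter(edt, params.distance_sigma, mode="constant")
    coords = _suppressed_maxima(smoothed, mask, params.min_diameter)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        seeds[r, c] = i
    labels = _propagate_rings(seeds, mask)
    if params.fill_holes:
        labels = fill_holes_per_object(labels)
    return labels


def relabel_sequential_keep(labels: np.ndarray, keep_ids) -> Tuple[np.ndarray, dict]:
    """Keep only ``keep_ids`` (in their original order) and relabel them
    1..K. Returns the new label map and the old->new mapping."""
    labels = np.asarray(labels)
    keep_ids = [int(i) for i in keep_ids]
    mapping = {old: new for new, old in enumerate(keep_ids, start=1)}
    out = np.zeros_like(labels, dtype=np.int32)
    for old, new in mapping.items():
        out[labels == old] = new
    return out, mapping


def gate_primary_objects(labels: np.ndarray, params: PrimarySegmentationParams) -> np.ndarray:
    """Remove objects outside the equivalent-diameter gate and, when
    configured, objects with any pixel on the image border; survivors are
    relabeled 1..K preserving original order."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.astype(np.int32)
    areas = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64),
                               labels=labels, index=ids)
    equiv = 2.0 * np.sqrt(areas / np.pi)
    keep = (equiv >= params.min_diameter) & (equiv <= params.max_diameter)
    if params.exclude_border:
        border = np.zeros(labels.shape, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        border_ids = set(np.unique(labels[border]).tolist()) - {0}
        keep &= np.array([int(i) not in border_ids for i in ids])
    gated, _ = relabel_sequential_keep(labels, ids[keep])
    return gated


def filter_real_nuclei(labels: np.ndarray, table: pd.DataFrame,
                       min_form_factor: float) -> Tuple[np.ndarray, pd.DataFrame]:
    """Keep only objects with FormFactor >= ``min_form_factor`` ("real"
    intact nuclei); relabels survivors 1..K and reindexes the table to
    match."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    missing = [int(i) for i in ids if int(i) not in table.index]
    if missing:
        raise ValueError(f"measurement missing for label(s) {missing}")
    if "form_factor" not in table.columns:
        raise ValueError("table lacks a form_factor column")
    keep = [int(i) for i in table.index if int(i) in set(ids.tolist())
            and table.at[i, "form_factor"] >= min_form_factor]
    new_labels, mapping = relabel_sequential_keep(labels, keep)
    new_table = table.loc[keep].copy()
    new_table.index = pd.Index([mapping[i] for i in keep], name="label")
    return new_labels, new_table
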