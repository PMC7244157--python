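"""Seeded propagation segmentation of VIME+ cell bodies.

Cytospin quality control requires that every counted cell has both an
intact nucleus and an intact cell body. Cell bodies are segmented from the
vimentin (VIME) channel by propagation from the real-nuclei label map:
the VIME foreground (smoothed image > 0.9 x Otsu) is partitioned among
the seeds by a minimal accumulated path cost over 8-connected steps,

    step cost p->q = sqrt( (I(p) - I(q))^2 + lambda * d(p, q)^2 )

with d the Euclidean step length (1 or sqrt(2)) and lambda >= 0 the
regularization factor balancing intensity-gradient-driven against
distance-driven boundaries: small lambda lets borders follow intensity
ridges, large lambda converges to the nearest-seed geodesic partition.
Seed pixels always keep their seed's label even when below threshold, and
bodies touching the image border are kept.

Determinism: ties in accumulated cost are broken by lower seed label,
then row-major pixel order.
"""

from __future__ import annotations

import heapq
import math
import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SecondarySegmentationParams
from .primary import fill_holes_per_object, otsu_threshold

# 8-connected neighborhood: (dr, dc, squared step length)
_NEIGHBORS = (
    (-1, -1, 2.0), (-1, 0, 1.0), (-1, 1, 2.0),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, 2.0), (1, 0, 1.0), (1, 1, 2.0),
)


def secondary_foreground_mask(
    intensity: np.ndarray, params: SecondarySegmentationParams,
    return_threshold: bool = False,
):
    """Smoothed VIME image and its thresholded foreground mask.

    Reuses the global-Otsu convention of the primary stage (smoothing
    scale 1.3488 -> sigma = 1 px) with the secondary correction factor.
    Returns ``(mask, smoothed)`` (plus the threshold when requested).
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(intensity, params.sigma, mode="nearest")
    lo, hi = params.threshold_bounds
    t = float(np.clip(otsu_threshold(smoothed) * params.threshold_correction, lo, hi))
    mask = smoothed > t
    if return_threshold:
        return mask, smoothed, t
    return mask, smoothed


def propagate_labels(seeds: np.ndarray, image: np.ndarray, mask: np.ndarray,
                     regularization_lambda: float) -> np.ndarray:
    """Exact minimal-cost multi-source assignment of masked pixels to seeds.

    Every pixel of ``mask | (seeds > 0)`` that is 8-connected-reachable
    from a seed region receives the label of the seed minimizing the
    accumulated path cost (Dijkstra with lazy deletion). Heap entries are
    ordered by (cost, seed label, row-major pixel index), which realizes
    the documented tie-breaks.
    """
    seeds = np.asarray(seeds)
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if seeds.shape != image.shape or mask.shape != image.shape:
        raise ValueError("seeds, image and mask must share one shape")
    H, W = image.shape
    lam = float(regularization_lambda)

    mask_eff = mask | (seeds > 0)
    flat_img = image.ravel()
    flat_mask = mask_eff.ravel()
    labels = np.zeros(H * W, dtype=np.int32)
    dist = np.full(H * W, np.inf)
    done = np.zeros(H * W, dtype=bool)

    heap = []
    srr, scc = np.nonzero(seeds > 0)
    for r, c in zip(srr.tolist(), scc.tolist()):
        idx = r * W + c
        dist[idx] = 0.0
        heap.append((0.0, int(seeds[r, c]), idx))
    heapq.heapify(heap)

    pop = heapq.heappop
    push = heapq.heappush
    while heap:
        cost, lab, idx = pop(heap)
        if done[idx]:
            continue
        done[idx] = True
        labels[idx] = lab
        r, c = divmod(idx, W)
        base = flat_img[idx]
        for dr, dc, d2 in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if nr < 0 or nr >= H or nc < 0 or nc >= W:
                continue
            nidx = nr * W + nc
            if done[nidx] or not flat_mask[nidx]:
                continue
            di = base - flat_img[nidx]
            ncost = cost + math.sqrt(di * di + lam * d2)
            if ncost <= dist[nidx]:
                dist[nidx] = ncost
                push(heap, (ncost, lab, nidx))

    return labels.reshape(H, W)


def propagate_secondary(seeds: np.ndarray, intensity: np.ndarray,
                        params: Optional[SecondarySegmentationParams] = None) -> np.ndarray:
    """Segment VIME+ cell bodies around real-nuclei seeds.

    Returns a label map in which each body carries the label of its seed
    nucleus. An empty seed map yields an empty result with a warning.
    """
    if params is None:
        params = SecondarySegmentationParams()
    seeds = np.asarray(seeds)
    if seeds.max(initial=0) == 0:
        warnings.warn("no seeds supplied; secondary segmentation is empty")
        return np.zeros(np.asarray(intensity).shape, dtype=np.int32)
    mask, smoothed = secondary_foreground_mask(intensity, params)
    bodies = propagate_labels(seeds, smoothed, mask, params.regularization_lambda)
    if params.fill_holes:
        bodies = fill_holes_per_object(bodies)
    if params.exclude_border:
        border = np.zeros(bodies.shape, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        for lab in set(np.unique(bodies[border]).tolist()) - {0}:
            bodies[bodies == lab] = 0
    return bodies


def filter_intact_cells(
    bodies: np.ndarray, body_table: pd.DataFrame,
    params: SecondarySegmentationParams,
    nuclei_labels: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Apply the intact-cell filters to segmented bodies.

    A body survives iff area >= min_body_area AND form_factor >=
    min_body_form_factor AND VIME mean intensity >=
    min_body_mean_intensity. Body labels equal their seed-nucleus labels,
    so the returned table's ``has_intact_body`` column can be joined onto
    the nuclei table by label.

    Returns the filtered body label map and ``body_table`` with a
    ``has_intact_body`` column.
    """
    bodies = np.asarray(bodies)
    vime_col = "mean_intensity_VIME"
    for col in ("area", "form_factor", vime_col):
        if col not in body_table.columns:
            raise ValueError(f"body table lacks required column {col!r}")
    if nuclei_labels is not None:
        nucleus_ids = set(np.unique(nuclei_labels).tolist()) - {0}
        orphan = set(body_table.index.tolist()) - nucleus_ids
        if orphan:
            raise ValueError(f"body label(s) without a parent nucleus: {sorted(orphan)}")

    table = body_table.copy()
    table["has_intact_body"] = (
        (table["area"] >= params.min_body_area)
        & (table["form_factor"] >= params.min_body_form_factor)
        & (table[vime_col] >= params.min_body_mean_intensity)
    )
    survivors = set(table.index[table["has_intact_body"]].tolist())
    filtered = np.where(np.isin(bodies, list(survivors)), bodies, 0).astype(np.int32)
    return filtered, table
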