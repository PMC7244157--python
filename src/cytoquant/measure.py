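"""Per-object shape and intensity measurements on label maps.

The quality filters of the pipeline consume a small set of features per
segmented object: pixel area, boundary perimeter, circularity (FormFactor
= 4*pi*Area/Perimeter^2, 1 for a perfect circle), equivalent diameter and
per-channel mean intensity. Measurements are returned as a pandas
DataFrame indexed by object label ("ObjectTable").

Perimeter estimation matters: naive pixel-edge counting overestimates the
perimeter of smooth shapes and biases the FormFactor of disks down to
~0.78, which would corrupt the semantics of the 0.599 circularity cut-off.
The default estimator is therefore the boundary-crossing estimator with
isotropic correction weights (straight steps 1, diagonal steps sqrt(2),
corner-corrected) as implemented by ``skimage.measure.perimeter``; the
Crofton-formula estimator is available as an alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter as _perimeter_weighted
from skimage.measure import perimeter_crofton as _perimeter_crofton

SHAPE_COLUMNS = ("area", "perimeter", "form_factor", "equivalent_diameter",
                 "centroid_row", "centroid_col")


def form_factor(area, perimeter):
    """Circularity 4*pi*Area/Perimeter^2 (1 for a perfect circle).

    Accepts scalars or arrays; not clamped to <= 1, small rasterized
    objects may slightly exceed 1.
    """
    area = np.asarray(area, dtype=np.float64)
    perimeter = np.asarray(perimeter, dtype=np.float64)
    out = 4.0 * np.pi * area / perimeter**2
    if out.ndim == 0:
        return float(out)
    return out


def _object_perimeter(mask: np.ndarray, method: str) -> float:
    if method == "weighted":
        p = _perimeter_weighted(mask, neighborhood=4)
    elif method == "crofton":
        p = _perimeter_crofton(mask, directions=4)
    else:
        raise ValueError(f"unknown perimeter method {method!r}")
    # 1-2 px objects can report a zero perimeter; use >= 1 by convention
    return max(float(p), 1.0)


def measure_shape(labels: np.ndarray, perimeter_method: str = "weighted") -> pd.DataFrame:
    """Measure area, perimeter, FormFactor, equivalent diameter and centroid
    for every labelled object.

    Each object's perimeter is computed on its own padded mask so that
    touching objects do not share boundary pixels.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(columns=list(SHAPE_COLUMNS)).rename_axis("label")

    slices = ndimage.find_objects(labels, max_label=int(ids.max()))
    rows = []
    for lab in ids:
        sl = slices[int(lab) - 1]
        mask = labels[sl] == lab
        area = float(mask.sum())
        # pad so boundary estimators see background on all sides
        padded = np.pad(mask, 1)
        perim = _object_perimeter(padded, perimeter_method)
        rr, cc = np.nonzero(mask)
        rows.append(
            {
                "label": int(lab),
                "area": area,
                "perimeter": perim,
                "form_factor": form_factor(area, perim),
                "equivalent_diameter": 2.0 * np.sqrt(area / np.pi),
                "centroid_row": float(rr.mean()) + sl[0].start,
                "centroid_col": float(cc.mean()) + sl[1].start,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def measure_intensity(labels: np.ndarray, channel: np.ndarray,
                      channel_name: str) -> pd.DataFrame:
    """Arithmetic mean of ``channel`` over every object's pixels.

    Returns a DataFrame indexed by label with one column
    ``mean_intensity_<channel_name>``.
    """
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=np.float64)
    if labels.shape != channel.shape:
        raise ValueError(
            f"label map shape {labels.shape} != channel shape {channel.shape}"
        )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    col = f"mean_intensity_{channel_name}"
    if ids.size == 0:
        return pd.DataFrame(columns=[col]).rename_axis("label")
    means = ndimage.mean(channel, labels=labels, index=ids)
    return pd.DataFrame({col: means}, index=pd.Index(ids.astype(int), name="label"))
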