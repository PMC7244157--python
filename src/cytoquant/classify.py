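"""Marker-positivity classification of real nuclei.

Schwann cells are identified by SOX10, a transcription factor confined to
SC nuclei, and proliferating SCs additionally by nuclear EdU
incorporation. Classification is by per-object mean intensity against an
operator-set threshold ("minimum value" semantics, i.e. ``>=``), chosen
per cytospin because staining intensity varies between runs and donors.
EdU positivity is only ever asserted within the SOX10+ subset, matching
the filter cascade of the analysis (proliferating SCs are SOX10+/EdU+).

:func:`suggest_threshold` is a convenience extension beyond the manual
workflow: it proposes the two-class Otsu split of the observed per-object
means. It is only applied automatically when ``auto_suggest`` is set.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import MarkerThresholds
from .primary import otsu_threshold

SOX10_COLUMN = "mean_intensity_SOX10"
EDU_COLUMN = "mean_intensity_EdU"


def filter_by_measurement(table: pd.DataFrame, measurement: str,
                          min_value: float) -> pd.DataFrame:
    """Keep rows whose ``measurement`` value is >= ``min_value``; row order
    is preserved. Generic filter used by all pipeline stages."""
    if measurement not in table.columns:
        raise KeyError(f"unknown measurement column {measurement!r}")
    return table[table[measurement] >= min_value].copy()


def classify_sox10(table: pd.DataFrame, thresholds: MarkerThresholds) -> pd.DataFrame:
    """Set ``is_sox10_pos`` = (mean SOX10 intensity >= threshold)."""
    if SOX10_COLUMN not in table.columns:
        raise ValueError(f"table lacks {SOX10_COLUMN!r}; measure SOX10 first")
    t = thresholds.sox10_min_mean_intensity
    if t is None:
        if thresholds.auto_suggest and len(table) >= 2:
            t = suggest_threshold(table[SOX10_COLUMN].to_numpy())
        else:
            raise ValueError(
                "sox10_min_mean_intensity is unset; set it per cytospin or "
                "enable auto_suggest"
            )
    out = table.copy()
    out["is_sox10_pos"] = out[SOX10_COLUMN] >= t
    return out


def classify_edu(table: pd.DataFrame, thresholds: MarkerThresholds) -> pd.DataFrame:
    """Set ``is_edu_pos`` = is_sox10_pos AND (mean EdU intensity >=
    threshold). Requires :func:`classify_sox10` to have run first."""
    if "is_sox10_pos" not in table.columns:
        raise ValueError("classify_sox10 must be applied before classify_edu")
    if EDU_COLUMN not in table.columns:
        raise ValueError(f"table lacks {EDU_COLUMN!r}; measure EdU first")
    t = thresholds.edu_min_mean_intensity
    if t is None:
        if thresholds.auto_suggest and int(table["is_sox10_pos"].sum()) >= 2:
            t = suggest_threshold(
                table.loc[table["is_sox10_pos"], EDU_COLUMN].to_numpy())
        else:
            raise ValueError(
                "edu_min_mean_intensity is unset; set it per cytospin or "
                "enable auto_suggest"
            )
    out = table.copy()
    out["is_edu_pos"] = out["is_sox10_pos"] & (out[EDU_COLUMN] >= t)
    return out


def suggest_threshold(values: Sequence[float]) -> float:
    """Two-class Otsu split of a list of per-object mean intensities.

    Helper only; in the interactive workflow the operator confirms or
    overrides the suggestion.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values to suggest a threshold")
    if float(values.min()) == float(values.max()):
        raise ValueError("all values identical; no threshold can separate them")
    return otsu_threshold(values)
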