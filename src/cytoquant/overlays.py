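"""Visualization of classification and counting results.

Mirrors the audit-trail images of the interactive workflow: per-nucleus
mean-intensity annotations (to support manual threshold choice), red/green
classification overlays (positive objects outlined red, negative green)
and count-annotated images with consecutive object numbering.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Optional

import imageio.v3 as iio
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from skimage.segmentation import find_boundaries

from .io import MultiChannelImage
from .pipeline import PipelineResult

_RED = (255, 40, 40)
_GREEN = (40, 220, 40)


def _to_rgb(channel: np.ndarray) -> np.ndarray:
    g = np.clip(np.asarray(channel, dtype=np.float64), 0.0, 1.0)
    return np.repeat((g * 255).astype(np.uint8)[..., None], 3, axis=2)


def classification_overlay(channel: np.ndarray, labels: np.ndarray,
                           positive_ids: Iterable[int],
                           restrict_ids: Optional[Iterable[int]] = None) -> np.ndarray:
    """RGB image: positive object outlines red, negative green.

    ``restrict_ids`` limits which objects are drawn at all (e.g. EdU
    classification shown within the SOX10+ subset only).
    """
    rgb = _to_rgb(channel)
    labels = np.asarray(labels)
    if labels.max(initial=0) == 0:
        return rgb
    positive = set(int(i) for i in positive_ids)
    shown = (set(int(i) for i in restrict_ids) if restrict_ids is not None
             else set(np.unique(labels).tolist()) - {0})
    boundaries = find_boundaries(labels, mode="inner")
    rr, cc = np.nonzero(boundaries)
    labs = labels[rr, cc]
    for color, wanted in ((_RED, positive & shown), (_GREEN, shown - positive)):
        if not wanted:
            continue
        sel = np.isin(labs, list(wanted))
        rgb[rr[sel], cc[sel]] = color
    return rgb


def _annotate(channel: np.ndarray, table: pd.DataFrame, texts, path: Path,
              title: str) -> None:
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(channel, cmap="gray", vmin=0, vmax=1)
    for (_, row), text in zip(table.iterrows(), texts):
        ax.text(row["centroid_col"], row["centroid_row"], text,
                color="yellow", fontsize=6, ha="center", va="center")
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_overlays(image: MultiChannelImage, result: PipelineResult,
                    out_dir) -> Dict[str, Path]:
    """Write all overlay/annotation images for one analysed image.

    With zero objects the raw channels are written unannotated.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = result.report.image_id
    table = result.nuclei_table
    labels = result.nuclei_labels
    files: Dict[str, Path] = {}

    has_objects = len(table) > 0
    sox_pos = (table.index[table["is_sox10_pos"]].tolist() if has_objects else [])
    edu_pos = (table.index[table["is_edu_pos"]].tolist() if has_objects else [])
    real = (table.index[table["has_intact_body"]].tolist() if has_objects else [])

    files["sox10_classified"] = out_dir / f"{prefix}_sox10_classified.png"
    iio.imwrite(files["sox10_classified"],
                classification_overlay(image["SOX10"], labels, sox_pos))
    files["edu_classified"] = out_dir / f"{prefix}_edu_classified.png"
    iio.imwrite(files["edu_classified"],
                classification_overlay(image["EdU"], labels, edu_pos,
                                       restrict_ids=sox_pos))

    if has_objects:
        for chan, col, key in (("SOX10", "mean_intensity_SOX10", "sox10_intensity"),
                               ("EdU", "mean_intensity_EdU", "edu_intensity")):
            files[key] = out_dir / f"{prefix}_{key}.png"
            _annotate(image[chan], table, [f"{v:.3f}" for v in table[col]],
                      files[key], f"mean {chan} intensity per real nucleus")
        for key, chan, ids, label in (
            ("real_cells_count", "VIME", real, "real cells"),
            ("sox10_count", "SOX10", [i for i in real if i in set(sox_pos)], "SCs"),
            ("edu_count", "EdU", [i for i in real if i in set(edu_pos)],
             "proliferating SCs"),
        ):
            sub = table.loc[ids]
            files[key] = out_dir / f"{prefix}_{key}.png"
            _annotate(image[chan], sub, [str(i) for i in range(1, len(sub) + 1)],
                      files[key], f"{label}: {len(sub)}")
    else:
        for key, chan in (("sox10_intensity", "SOX10"), ("edu_intensity", "EdU"),
                          ("real_cells_count", "VIME"), ("sox10_count", "SOX10"),
                          ("edu_count", "EdU")):
            files[key] = out_dir / f"{prefix}_{key}.png"
            iio.imwrite(files[key], _to_rgb(image[chan]))
    return files
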