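"""End-to-end cytospin analysis: segmentation -> measurement -> filtering
-> classification -> counting -> export.

Stage order (the fixed module cascade): primary
segmentation on DAPI, shape measurement, real-nuclei circularity filter,
SOX10 intensity + classification, EdU intensity + classification,
secondary propagation on VIME, intact-cell filter, then final counts
restricted to nuclei with an intact body. A stage yielding zero objects
short-circuits later stages with zero counts; it is a valid outcome, not
an error.

Reported rates: culture purity = 100 * SOX10+ real cells / real cells;
proliferation = 100 * SOX10+/EdU+ real cells / denominator, where the
denominator is configurable (real cells by default, or SOX10+ cells,
because "proliferation rate of the SC culture" admits either reading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import classify as _classify
from . import measure as _measure
from . import primary as _primary
from . import secondary as _secondary
from .config import PipelineConfig
from .io import MultiChannelImage, save_label_map

SPREADSHEET_COLUMNS = (
    "image_id", "n_primary_nuclei", "n_real_nuclei", "n_real_cells",
    "n_sox10_cells", "n_sox10_edu_cells", "purity_pct", "proliferation_pct",
)


@dataclass
class CountsReport:
    """Nested counts and derived percentages for one analysed image."""

    image_id: str
    n_primary_nuclei: int
    n_real_nuclei: int
    n_real_cells: int
    n_sox10_cells: int
    n_sox10_edu_cells: int
    purity_pct: float
    proliferation_pct: float
    zero_denominator_warning: bool = False

    def __post_init__(self) -> None:
        chain = (self.n_sox10_edu_cells, self.n_sox10_cells, self.n_real_cells,
                 self.n_real_nuclei, self.n_primary_nuclei)
        for smaller, larger in zip(chain, chain[1:]):
            if smaller > larger:
                raise ValueError(
                    f"count nesting violated for {self.image_id!r}: {chain}"
                )

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in SPREADSHEET_COLUMNS}


@dataclass
class PipelineResult:
    report: CountsReport
    nuclei_table: pd.DataFrame
    nuclei_labels: np.ndarray
    body_labels: np.ndarray
    body_table: pd.DataFrame
    stage_log: List[str] = field(default_factory=list)


def compute_rates(image_id: str, n_primary: int, n_real_nuclei: int,
                  n_real_cells: int, n_sox10: int, n_sox10_edu: int,
                  config: Optional[PipelineConfig] = None) -> CountsReport:
    """Assemble a CountsReport with purity and proliferation percentages.

    Zero denominators yield a rate of 0 with a warning flag.
    """
    denominator_kind = (config.proliferation_denominator
                        if config is not None else "real_cells")
    warning = False
    if n_real_cells > 0:
        purity = 100.0 * n_sox10 / n_real_cells
    else:
        purity, warning = 0.0, True
    denom = n_real_cells if denominator_kind == "real_cells" else n_sox10
    if denom > 0:
        proliferation = 100.0 * n_sox10_edu / denom
    else:
        proliferation, warning = 0.0, True
    return CountsReport(
        image_id=image_id,
        n_primary_nuclei=n_primary,
        n_real_nuclei=n_real_nuclei,
        n_real_cells=n_real_cells,
        n_sox10_cells=n_sox10,
        n_sox10_edu_cells=n_sox10_edu,
        purity_pct=purity,
        proliferation_pct=proliferation,
        zero_denominator_warning=warning,
    )


def _empty_result(image_id: str, shape, config: PipelineConfig,
                  log: List[str], n_primary: int = 0,
                  n_real_nuclei: int = 0) -> PipelineResult:
    report = compute_rates(image_id, n_primary, n_real_nuclei, 0, 0, 0, config)
    empty = pd.DataFrame()
    zeros = np.zeros(shape, dtype=np.int32)
    return PipelineResult(report, empty, zeros, zeros, empty, log)


def run_pipeline(image: MultiChannelImage, config: Optional[PipelineConfig] = None,
                 image_id: str = "image") -> PipelineResult:
    """Run the full analysis on one four-channel image.

    Deterministic for fixed inputs and config; returns counts, the
    per-nucleus measurement/classification table and both label maps.
    """
    if config is None:
        config = PipelineConfig()
    p, s, m = config.primary, config.secondary, config.markers
    log: List[str] = []
    shape = image["DAPI"].shape

    mask, threshold = _primary.threshold_mask(image["DAPI"], p, return_threshold=True)
    log.append(f"DAPI effective threshold {threshold:.4f}; "
               f"foreground {int(mask.sum())} px")
    labels = _primary.declump_by_shape(mask, p)
    n_declumped = int(labels.max())
    labels = _primary.gate_primary_objects(labels, p)
    n_primary = int(labels.max())
    log.append(f"primary objects: {n_declumped} declumped -> {n_primary} "
               "after diameter/border gate")
    if n_primary == 0:
        return _empty_result(image_id, shape, config, log)

    table = _measure.measure_shape(labels)
    labels, table = _primary.filter_real_nuclei(labels, table, p.min_form_factor)
    n_real_nuclei = int(labels.max())
    log.append(f"real nuclei after FormFactor >= {p.min_form_factor}: {n_real_nuclei}")
    if n_real_nuclei == 0:
        return _empty_result(image_id, shape, config, log, n_primary, 0)

    table = table.join(_measure.measure_intensity(labels, image["SOX10"], "SOX10"))
    table = table.join(_measure.measure_intensity(labels, image["EdU"], "EdU"))
    table = _classify.classify_sox10(table, m)
    table = _classify.classify_edu(table, m)
    log.append(f"SOX10+ nuclei: {int(table['is_sox10_pos'].sum())}; "
               f"SOX10+/EdU+ nuclei: {int(table['is_edu_pos'].sum())}")

    bodies = _secondary.propagate_secondary(labels, image["VIME"], s)
    body_table = _measure.measure_shape(bodies)
    body_table = body_table.join(
        _measure.measure_intensity(bodies, image["VIME"], "VIME"))
    bodies, body_table = _secondary.filter_intact_cells(
        bodies, body_table, s, nuclei_labels=labels)
    intact = body_table.index[body_table["has_intact_body"]]
    table["has_intact_body"] = table.index.isin(intact)
    log.append(f"intact cell bodies: {len(intact)} of {len(body_table)}")

    real_cells = table["has_intact_body"]
    sox10_cells = real_cells & table["is_sox10_pos"]
    edu_cells = sox10_cells & table["is_edu_pos"]
    report = compute_rates(
        image_id, n_primary, n_real_nuclei,
        int(real_cells.sum()), int(sox10_cells.sum()), int(edu_cells.sum()),
        config,
    )
    log.append(
        f"counts: real={report.n_real_cells} SC={report.n_sox10_cells} "
        f"proliferating={report.n_sox10_edu_cells} "
        f"purity={report.purity_pct:.1f}% proliferation={report.proliferation_pct:.1f}%"
    )
    return PipelineResult(report, table, labels, bodies, body_table, log)


# ---------------------------------------------------------------------------
# export

def export_spreadsheet(reports: List[CountsReport], path) -> Tuple[Path, Path]:
    """Write one row per image with all counts and rates.

    Produces the tab-delimited ``.txt`` at ``path`` plus a ``.csv`` twin
    with the same stem; re-export is byte-identical.
    """
    if not reports:
        raise ValueError("need at least one report to export")
    path = Path(path)
    df = pd.DataFrame([r.as_row() for r in reports], columns=list(SPREADSHEET_COLUMNS))
    txt = path if path.suffix else path.with_suffix(".txt")
    csv = txt.with_suffix(".csv")
    df.to_csv(txt, sep="\t", index=False, lineterminator="\n")
    df.to_csv(csv, index=False, lineterminator="\n")
    return txt, csv


def save_debug_outputs(result: PipelineResult, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_label_map(out_dir / f"{result.report.image_id}_nuclei_labels.tif",
                   result.nuclei_labels)
    save_label_map(out_dir / f"{result.report.image_id}_body_labels.tif",
                   result.body_labels)
    if len(result.nuclei_table):
        result.nuclei_table.to_csv(
            out_dir / f"{result.report.image_id}_objects.csv", lineterminator="\n")
    (out_dir / f"{result.report.image_id}_log.txt").write_text(
        "\n".join(result.stage_log) + "\n")


# ---------------------------------------------------------------------------
# statistics

@dataclass
class PairedComparison:
    t_statistic: float
    p_value: float
    mean_difference: float
    n: int
    significant: bool


def compare_to_manual(auto, manual, alpha: float = 0.05) -> PairedComparison:
    """Paired t-test of automated vs manual per-donor values.

    t = mean(d) / (sd(d)/sqrt(n)) on the paired differences d, df = n-1,
    two-sided p. Zero-variance differences are handled explicitly: with a
    nonzero mean the difference is systematic (p reported as 0), with zero
    mean t = 0 and p = 1.
    """
    auto = np.asarray(auto, dtype=np.float64)
    manual = np.asarray(manual, dtype=np.float64)
    if auto.shape != manual.shape:
        raise ValueError("paired vectors must have equal length")
    n = auto.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = auto - manual
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_d == 0.0:
            t, pval = 0.0, 1.0
        else:
            t, pval = math.copysign(math.inf, mean_d), 0.0
    else:
        res = _scipy_stats.ttest_rel(auto, manual)
        t, pval = float(res.statistic), float(res.pvalue)
    return PairedComparison(t_statistic=t, p_value=pval, mean_difference=mean_d,
                            n=n, significant=pval < alpha)
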