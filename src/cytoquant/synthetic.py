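"""Synthetic four-channel cytospin images with exact ground truth.

No cytospin image data were deposited with the original study, so every
downstream stage of the pipeline is exercised against synthetic images
that emulate the phenomenology the pipeline assumes:

* uniformly rounded, well-separated nuclei (DAPI), some of them clumped
  in touching pairs with a detectable indentation,
* occasional burst nuclei rendered as star polygons whose circularity
  falls below the 0.599 FormFactor cut-off,
* a larger VIME+ cell body around each nucleus; burst cell bodies are
  rendered as spiky star shapes that fail the 0.35 body-circularity
  filter (the cytocentrifugation step occasionally bursts the body while
  the nucleus stays intact),
* nuclei cut by the image border,
* SOX10 signal confined to SOX10+ nuclei, EdU signal confined to EdU+
  nuclei (EdU+ is drawn within the SOX10+ subset only),
* additive Gaussian noise, clipped to [0, 1].

Identical spec + seed yields bit-identical output: a single pseudo-random
generator is seeded once per :func:`generate` call and all stochastic
choices are drawn from it in a fixed order (cell attributes, marker
assignment, placement retries, then per-channel noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as _draw_polygon

from .io import MultiChannelImage, save_channel_u16, save_label_map

TRUTH_COLUMNS = ("cell_id", "is_burst_nucleus", "is_burst_body",
                 "touches_border", "is_sox10_pos", "is_edu_pos")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cytospin image.

    Defaults describe a typical well-populated field of view: 100 cells on
    a 1024x1024 px image, 70% SOX10+ (Schwann cells), half of those EdU+
    (proliferating), with 10% burst nuclei, 10% burst cell bodies, 10% of
    cells in clumped touching pairs and 5% cut by the image border.
    Nucleus radii of 16-19 px give equivalent diameters of ~32-38 px,
    comfortably inside the pipeline's 16-60 px gate.
    """

    n_cells: int = 100
    frac_sox10_pos: float = 0.7
    frac_edu_pos_given_sox10: float = 0.5
    frac_burst_nuclei: float = 0.0
    frac_burst_bodies: float = 0.0
    frac_clumped_pairs: float = 0.0
    frac_border_touching: float = 0.0
    nucleus_radius_range: Tuple[float, float] = (16.0, 19.0)
    body_radius_range: Tuple[float, float] = (22.0, 27.0)
    noise_sd: float = 0.01
    background_level: float = 0.02
    image_size: Tuple[int, int] = (1024, 1024)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_sox10_pos": self.frac_sox10_pos,
            "frac_edu_pos_given_sox10": self.frac_edu_pos_given_sox10,
            "frac_burst_nuclei": self.frac_burst_nuclei,
            "frac_burst_bodies": self.frac_burst_bodies,
            "frac_clumped_pairs": self.frac_clumped_pairs,
            "frac_border_touching": self.frac_border_touching,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        for name, (lo, hi) in (("nucleus_radius_range", self.nucleus_radius_range),
                               ("body_radius_range", self.body_radius_range)):
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-cell truth accompanying one synthetic image."""

    nucleus_label_map: np.ndarray
    body_label_map: np.ndarray
    cells: pd.DataFrame
    expected_counts: Tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.expected_counts = expected_counts_from_flags(self.cells)
        labelled = set(np.unique(self.nucleus_label_map).tolist()) - {0}
        recorded = set((self.cells["cell_id"] + 1).tolist()) if len(self.cells) else set()
        if labelled - recorded:
            raise ValueError("nucleus label without a per-cell record")


def expected_counts_from_flags(cells: pd.DataFrame) -> Tuple[int, int, int]:
    """(real cells, SOX10+ real cells, SOX10+/EdU+ real cells) from the
    per-cell flags, using the pipeline's nesting rules (EdU+ within SOX10+
    within real)."""
    if len(cells) == 0:
        return (0, 0, 0)
    real = (~cells["is_burst_nucleus"] & ~cells["is_burst_body"]
            & ~cells["touches_border"])
    sox10 = real & cells["is_sox10_pos"]
    edu = sox10 & cells["is_edu_pos"]
    return (int(real.sum()), int(sox10.sum()), int(edu.sum()))


# ---------------------------------------------------------------------------
# shape rasterization

def _rounded_polygon(rng: np.random.Generator, radius: float,
                     n_vertices: int = 48, amplitude: float = 0.06) -> np.ndarray:
    """Vertex radii of a disk with smooth radial perturbation (high
    circularity)."""
    noise = rng.normal(size=n_vertices)
    kernel = np.exp(-0.5 * (np.arange(-6, 7) / 2.5) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np.tile(noise, 3), kernel, mode="same")[n_vertices:2 * n_vertices]
    if np.abs(smooth).max() > 0:
        smooth = smooth / np.abs(smooth).max()
    return radius * (1.0 + amplitude * smooth)


def _star_radii(rng: np.random.Generator, r_out: float, ratio: float,
                n_spikes: int, n_per_spike: int = 8) -> np.ndarray:
    """Vertex radii of a star polygon alternating between r_out and
    ratio*r_out, with slight per-spike jitter (low circularity)."""
    radii = []
    for _ in range(n_spikes):
        tip = r_out * (1.0 + rng.uniform(-0.08, 0.08))
        inner = r_out * ratio * (1.0 + rng.uniform(-0.1, 0.1))
        half = n_per_spike // 2
        up = np.linspace(inner, tip, half, endpoint=False)
        down = np.linspace(tip, inner, half, endpoint=False)
        radii.extend(up)
        radii.extend(down)
    return np.asarray(radii)


def _rasterize(center: Tuple[float, float], radii: np.ndarray,
               phase: float, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    angles = phase + 2.0 * np.pi * np.arange(radii.size) / radii.size
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return _draw_polygon(rows, cols, shape=shape)


# ---------------------------------------------------------------------------
# generation

@dataclass
class _Cell:
    cell_id: int
    role: str  # normal | burst_nucleus | burst_body | clumped | border
    nucleus_radius: float
    body_radius: float
    dapi_level: float
    vime_level: float
    sox10_pos: bool
    edu_pos: bool
    center: Tuple[float, float] = (0.0, 0.0)
    pair_partner: Optional[int] = None


def _assign_roles(rng: np.random.Generator, spec: SyntheticSpec) -> List[str]:
    n = spec.n_cells
    n_border = int(round(spec.frac_border_touching * n))
    n_burst_nuc = int(round(spec.frac_burst_nuclei * n))
    n_burst_body = int(round(spec.frac_burst_bodies * n))
    n_clump = 2 * (int(round(spec.frac_clumped_pairs * n)) // 2)
    if n_border + n_burst_nuc + n_burst_body + n_clump > n:
        raise ValueError("degradation fractions sum to more than the cell count")
    roles = ["normal"] * n
    order = rng.permutation(n)
    pos = 0
    for role, count in (("border", n_border), ("burst_nucleus", n_burst_nuc),
                        ("burst_body", n_burst_body), ("clumped", n_clump)):
        for i in range(count):
            roles[order[pos + i]] = role
        pos += count
    return roles


def _exclusion_radius(cell: _Cell) -> float:
    if cell.role == "burst_body":
        # spiky star body reaches ~2.1x the inner radius (nucleus + 2 px)
        return 2.1 * (cell.nucleus_radius + 2.0)
    return cell.body_radius


def generate(spec: SyntheticSpec) -> Tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic cytospin image and its exact ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.image_size
    n = spec.n_cells

    # -- per-cell attributes (fixed draw order) ----------------------------
    roles = _assign_roles(rng, spec)
    n_sox10 = int(round(spec.frac_sox10_pos * n))
    sox10_ids = set(rng.permutation(n)[:n_sox10].tolist())
    sox10_sorted = sorted(sox10_ids)
    n_edu = int(round(spec.frac_edu_pos_given_sox10 * n_sox10))
    edu_ids = set(np.asarray(sox10_sorted, dtype=int)[
        rng.permutation(n_sox10)[:n_edu]].tolist()) if n_sox10 else set()

    nr_lo, nr_hi = spec.nucleus_radius_range
    br_lo, br_hi = spec.body_radius_range
    cells: List[_Cell] = []
    for cid in range(n):
        cells.append(_Cell(
            cell_id=cid,
            role=roles[cid],
            nucleus_radius=float(rng.uniform(nr_lo, nr_hi)),
            body_radius=float(rng.uniform(br_lo, br_hi)),
            dapi_level=float(rng.uniform(0.68, 0.82)),
            vime_level=float(rng.uniform(0.36, 0.46)),
            sox10_pos=cid in sox10_ids,
            edu_pos=cid in edu_ids,
        ))

    # -- placement ---------------------------------------------------------
    margin = 3.0
    placed: List[Tuple[float, float, float]] = []  # (row, col, exclusion radius)

    def _fits(r: float, c: float, rad: float) -> bool:
        for pr, pc, prad in placed:
            if (r - pr) ** 2 + (c - pc) ** 2 < (rad + prad + 2.0) ** 2:
                return False
        return True

    def _place_interior(rad: float) -> Tuple[float, float]:
        lo_r, hi_r = rad + margin, H - rad - margin
        lo_c, hi_c = rad + margin, W - rad - margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise RuntimeError("image too small for requested cell sizes")
        for _ in range(600):
            r = float(rng.uniform(lo_r, hi_r))
            c = float(rng.uniform(lo_c, hi_c))
            if _fits(r, c, rad):
                return r, c
        raise RuntimeError("could not place cells within overlap constraints")

    def _place_border(cell: _Cell) -> Tuple[float, float]:
        for _ in range(600):
            edge = int(rng.integers(4))
            offset = float(rng.uniform(0.0, max(cell.nucleus_radius - 3.0, 1.0)))
            along = float(rng.uniform(cell.body_radius, (W if edge < 2 else H) - cell.body_radius))
            if edge == 0:
                r, c = offset, along
            elif edge == 1:
                r, c = H - 1 - offset, along
            elif edge == 2:
                r, c = along, offset
            else:
                r, c = along, W - 1 - offset
            if _fits(r, c, _exclusion_radius(cell)):
                return r, c
        raise RuntimeError("could not place border-touching cells")

    clump_ids = [c.cell_id for c in cells if c.role == "clumped"]
    pairs = [(clump_ids[i], clump_ids[i + 1]) for i in range(0, len(clump_ids), 2)]
    paired = set(clump_ids)

    for a, b in pairs:
        ca, cb = cells[a], cells[b]
        ca.pair_partner, cb.pair_partner = b, a
        mean_r = 0.5 * (ca.nucleus_radius + cb.nucleus_radius)
        d = float(rng.uniform(1.2, 1.6)) * mean_r
        theta = float(rng.uniform(0.0, 2.0 * np.pi))
        rad = d / 2.0 + max(ca.body_radius, cb.body_radius)
        r0, c0 = _place_interior(rad)
        dr, dc = 0.5 * d * math.sin(theta), 0.5 * d * math.cos(theta)
        ca.center = (r0 - dr, c0 - dc)
        cb.center = (r0 + dr, c0 + dc)
        placed.append((r0, c0, rad))

    for cell in cells:
        if cell.cell_id in paired:
            continue
        if cell.role == "border":
            r, c = _place_border(cell)
        else:
            r, c = _place_interior(_exclusion_radius(cell))
        cell.center = (r, c)
        placed.append((r, c, _exclusion_radius(cell)))

    # -- rasterization ------------------------------------------------------
    dapi = np.full((H, W), spec.background_level)
    sox10 = np.full((H, W), spec.background_level)
    edu = np.full((H, W), spec.background_level)
    vime = np.full((H, W), spec.background_level)
    nucleus_labels = np.zeros((H, W), dtype=np.int32)
    body_labels = np.zeros((H, W), dtype=np.int32)
    nuc_claim = np.full((H, W), np.inf)
    body_claim = np.full((H, W), np.inf)

    for cell in cells:
        lab = cell.cell_id + 1
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        if cell.role == "burst_nucleus":
            n_spikes = int(rng.integers(4, 8))
            radii = _star_radii(rng, 0.85 * cell.nucleus_radius, 0.33, n_spikes)
        else:
            radii = _rounded_polygon(rng, cell.nucleus_radius)
        rr, cc = _rasterize(cell.center, radii, phase, (H, W))
        dapi[rr, cc] = np.maximum(dapi[rr, cc], cell.dapi_level)
        d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
        closer = d2 < nuc_claim[rr, cc]
        nucleus_labels[rr[closer], cc[closer]] = lab
        nuc_claim[rr[closer], cc[closer]] = d2[closer]

        sox_level = 0.72 + 0.04 * (rng.uniform() - 0.5) if cell.sox10_pos else 0.03
        edu_level = 0.78 + 0.04 * (rng.uniform() - 0.5) if cell.edu_pos else 0.015
        sox10[rr, cc] = np.maximum(sox10[rr, cc], sox_level)
        edu[rr, cc] = np.maximum(edu[rr, cc], edu_level)

        body_phase = float(rng.uniform(0.0, 2.0 * np.pi))
        if cell.role == "burst_body":
            n_spikes = int(rng.integers(7, 10))
            inner = cell.nucleus_radius + 2.0
            radii_b = _star_radii(rng, 2.1 * inner, inner / (2.1 * inner), n_spikes)
        else:
            radii_b = _rounded_polygon(rng, cell.body_radius, amplitude=0.08)
        rrb, ccb = _rasterize(cell.center, radii_b, body_phase, (H, W))
        vime[rrb, ccb] = np.maximum(vime[rrb, ccb], cell.vime_level)
        d2b = (rrb - cell.center[0]) ** 2 + (ccb - cell.center[1]) ** 2
        closer_b = d2b < body_claim[rrb, ccb]
        body_labels[rrb[closer_b], ccb[closer_b]] = lab
        body_claim[rrb[closer_b], ccb[closer_b]] = d2b[closer_b]

    # -- noise (fixed channel order) ----------------------------------------
    channels = {}
    for name, arr in (("DAPI", dapi), ("SOX10", sox10), ("EdU", edu), ("VIME", vime)):
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        channels[name] = np.clip(arr, 0.0, 1.0)

    image = MultiChannelImage(channels=channels,
                              source_paths={k: "synthetic" for k in channels})
    records = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "is_burst_nucleus": [c.role == "burst_nucleus" for c in cells],
            "is_burst_body": [c.role == "burst_body" for c in cells],
            "touches_border": [c.role == "border" for c in cells],
            "is_sox10_pos": [c.sox10_pos for c in cells],
            "is_edu_pos": [c.edu_pos for c in cells],
        },
        columns=list(TRUTH_COLUMNS),
    )
    truth = GroundTruth(nucleus_label_map=nucleus_labels,
                        body_label_map=body_labels, cells=records)
    return image, truth


# ---------------------------------------------------------------------------
# fixtures and truth matching

def write_fixture(image: MultiChannelImage, truth: GroundTruth, out_dir,
                  spec: Optional[SyntheticSpec] = None) -> Dict[str, Path]:
    """Persist a synthetic image + ground truth as a plain-file fixture.

    Layout: ``{dapi,sox10,edu,vime}.tif`` (16-bit), ``nuclei_gt.tif``,
    ``bodies_gt.tif``, ``truth.csv`` (per-cell records),
    ``expected_counts.csv`` and, when given, the generating spec as
    ``spec.yaml``. Re-running on the same inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}
    for name in ("DAPI", "SOX10", "EdU", "VIME"):
        p = out_dir / f"{name.lower()}.tif"
        save_channel_u16(p, image[name])
        files[name] = p
    files["nuclei_gt"] = out_dir / "nuclei_gt.tif"
    save_label_map(files["nuclei_gt"], truth.nucleus_label_map)
    files["bodies_gt"] = out_dir / "bodies_gt.tif"
    save_label_map(files["bodies_gt"], truth.body_label_map)
    files["truth"] = out_dir / "truth.csv"
    truth.cells.to_csv(files["truth"], index=False, lineterminator="\n")
    files["expected_counts"] = out_dir / "expected_counts.csv"
    real, sox, edu = truth.expected_counts
    pd.DataFrame(
        [{"real_cells": real, "sox10_cells": sox, "sox10_edu_cells": edu}]
    ).to_csv(files["expected_counts"], index=False, lineterminator="\n")
    if spec is not None:
        files["spec"] = out_dir / "spec.yaml"
        d = asdict(spec)
        for key in ("nucleus_radius_range", "body_radius_range", "image_size"):
            d[key] = list(d[key])
        files["spec"].write_text(yaml.safe_dump(d, sort_keys=True))
    return files


def match_to_truth(seg_labels: np.ndarray, gt_labels: np.ndarray) -> Dict[int, int]:
    """Map each segmented label to the ground-truth cell label with the
    largest pixel overlap (0 when a segment overlaps no truth object)."""
    seg_labels = np.asarray(seg_labels)
    gt_labels = np.asarray(gt_labels)
    mapping: Dict[int, int] = {}
    for lab in np.unique(seg_labels):
        if lab == 0:
            continue
        overlap = gt_labels[seg_labels == lab]
        overlap = overlap[overlap > 0]
        mapping[int(lab)] = int(np.bincount(overlap).argmax()) if overlap.size else 0
    return mapping
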