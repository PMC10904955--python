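"""Synthetic multi-channel fields with ground truth.

Emulates a 20× field of view from a microfluidic co-culture chip: bright
rounded nuclei on a dark background (nuclear stain), cytoplasm surrounding
each nucleus (pan-cell stain), tag channels lighting only the GFP-/RFP-
expressing subset, dark trapezoidal PDMS post regions along the channel
edges, Poisson shot noise plus Gaussian read noise, and optional deliberate
cell clumps to exercise clump breaking.  Every field is fully determined by
``rng_seed``.

The signal-to-noise ratio is defined as
``snr = (peak nucleus intensity − background mean) / background std``
with background std ``sqrt(background_level + read_noise²)`` (Poisson
variance of the background plus read noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ChannelRole, MultiChannelImage

__all__ = [
    "SceneParams",
    "GroundTruth",
    "MatchMetrics",
    "generate_field",
    "score_against_truth",
    "truth_to_frame",
]


@dataclass(frozen=True)
class SceneParams:
    height: int = 512
    width: int = 512
    n_cells: int = 30
    gfp_fraction: float = 0.4
    rfp_fraction: float = 0.0
    nucleus_radius_range: tuple[float, float] = (15.0, 18.0)
    cytoplasm_scale: float = 1.55     # cell radius / nucleus radius
    clump_probability: float = 0.2    # chance a cell is placed touching a neighbour
    snr: float = 10.0
    background_level: float = 9.0     # mean background counts (low-light imaging)
    read_noise: float = 2.0           # Gaussian read-noise std, counts
    post_base: int = 100              # trapezoid base width, px (≈100 µm at 20×)
    post_spacing: int = 100           # gap between posts, px
    post_height: int = 40             # post depth into the field, px
    max_eccentricity: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gfp_fraction <= 1 and 0 <= self.rfp_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.gfp_fraction + self.rfp_fraction > 1:
            raise ValueError("gfp_fraction + rfp_fraction must be ≤ 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be ≥ 0")

    @property
    def amplitude(self) -> float:
        """Peak nuclear signal above background implied by the snr."""
        bg_std = math.sqrt(self.background_level + self.read_noise**2)
        return self.snr * bg_std


@dataclass
class GroundTruth:
    """Instance-level truth for one generated field."""

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    class_of: dict[int, str]          # cell label → "gfp" | "rfp" | "untagged"
    centroids: np.ndarray             # (n, 2) array of (y, x) nucleus centres
    params: Optional[SceneParams] = None

    @property
    def n_cells(self) -> int:
        return len(self.class_of)

    def count(self, cls: str) -> int:
        return sum(1 for v in self.class_of.values() if v == cls)


def _class_counts(n: int, gfp_fraction: float, rfp_fraction: float) -> tuple[int, int]:
    n_gfp = int(math.floor(n * gfp_fraction + 0.5))
    n_rfp = int(math.floor(n * rfp_fraction + 0.5))
    if n_gfp + n_rfp > n:
        n_rfp = n - n_gfp
    return n_gfp, n_rfp


def _post_mask(p: SceneParams) -> np.ndarray:
    """Trapezoidal posts along the top and bottom field edges."""
    mask = np.zeros((p.height, p.width), dtype=bool)
    if p.post_height <= 0 or p.post_base <= 0:
        return mask
    period = p.post_base + p.post_spacing
    yy = np.arange(p.post_height)
    # linear taper: base width at the edge, 60% of it at the inner side
    half = (p.post_base / 2.0) * (1.0 - 0.4 * yy / max(p.post_height - 1, 1))
    for x0 in range(p.post_base // 2, p.width + period, period):
        for y, h in zip(yy, half):
            lo, hi = int(math.ceil(x0 - h)), int(math.floor(x0 + h))
            if hi < 0 or lo >= p.width:
                continue
            mask[y, max(lo, 0) : min(hi + 1, p.width)] = True
            mask[p.height - 1 - y, max(lo, 0) : min(hi + 1, p.width)] = True
    return mask


def _place_cells(p: SceneParams, rng: np.random.Generator) -> list[dict]:
    """Dart-throwing placement; clumped cells touch a chosen neighbour."""
    cells: list[dict] = []
    rn_max = p.nucleus_radius_range[1]
    rc_max = p.cytoplasm_scale * rn_max
    y_lo = p.post_height + rc_max + 2
    y_hi = p.height - p.post_height - rc_max - 2
    x_lo, x_hi = rc_max + 2, p.width - rc_max - 2
    if p.n_cells > 0 and (y_hi <= y_lo or x_hi <= x_lo):
        raise ValueError("field too small to place any cell clear of the posts")

    for i in range(p.n_cells):
        rn = rng.uniform(*p.nucleus_radius_range)
        rc = p.cytoplasm_scale * rn
        ecc = rng.uniform(0.0, p.max_eccentricity)
        theta = rng.uniform(0.0, math.pi)
        want_clump = bool(cells) and (rng.random() < p.clump_probability)
        for attempt in range(2000):
            # a clump may be impossible near crowded/edge partners; fall back
            # to free placement rather than deadlock
            clump = want_clump and attempt < 500
            if clump:
                partner = cells[int(rng.integers(len(cells)))]
                phi = rng.uniform(0.0, 2.0 * math.pi)
                d = 1.25 * (rn + partner["rn"])
                cy = partner["cy"] + d * math.sin(phi)
                cx = partner["cx"] + d * math.cos(phi)
            else:
                cy = rng.uniform(y_lo, y_hi)
                cx = rng.uniform(x_lo, x_hi)
            if not (y_lo <= cy <= y_hi and x_lo <= cx <= x_hi):
                continue
            ok = True
            for other in cells:
                dist = math.hypot(cy - other["cy"], cx - other["cx"])
                # nuclei must always stay disjoint
                if dist < 1.22 * (rn + other["rn"]):
                    ok = False
                    break
                # non-clumped cells keep their cytoplasm clear of neighbours
                if not clump and dist < 1.05 * (rc + other["rc"]):
                    ok = False
                    break
            if ok:
                cells.append(
                    {"cy": cy, "cx": cx, "rn": rn, "rc": rc, "ecc": ecc, "theta": theta}
                )
                break
        else:
            raise ValueError(
                f"could not place cell {i + 1}/{p.n_cells}: field too crowded"
            )
    return cells


def _ellipse_norm(shape, cy, cx, a, b, theta) -> tuple[tuple[slice, slice], np.ndarray]:
    """Normalised squared ellipse radius on a bounding window (≤1 inside)."""
    r = max(a, b)
    y0, y1 = max(int(cy - r - 2), 0), min(int(cy + r + 3), shape[0])
    x0, x1 = max(int(cx - r - 2), 0), min(int(cx + r + 3), shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (slice(y0, y1), slice(x0, x1)), (u / a) ** 2 + (v / b) ** 2


def generate_field(params: SceneParams) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one field and its instance-level ground truth.

    Channels produced: nuclear and pan_cell always; gfp when any GFP cells
    are possible (gfp_fraction > 0 or always, for protocol compatibility);
    rfp when rfp_fraction > 0.  Bit-identical for identical params.
    """
    p = params
    rng = np.random.default_rng(p.rng_seed)
    shape = (p.height, p.width)

    cells = _place_cells(p, rng)
    n_gfp, n_rfp = _class_counts(len(cells), p.gfp_fraction, p.rfp_fraction)
    tags = ["gfp"] * n_gfp + ["rfp"] * n_rfp + ["untagged"] * (len(cells) - n_gfp - n_rfp)
    order = rng.permutation(len(cells)) if cells else np.array([], dtype=int)
    class_of = {int(i) + 1: tags[int(k)] for i, k in zip(range(len(cells)), order)}

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for i, c in enumerate(cells, start=1):
        an = c["rn"] * (1 + c["ecc"])
        bn = c["rn"] / (1 + c["ecc"])
        win, norm = _ellipse_norm(shape, c["cy"], c["cx"], an, bn, c["theta"])
        nucleus_labels[win][norm <= 1.0] = i
        ac, bc = an * p.cytoplasm_scale, bn * p.cytoplasm_scale
        win, norm = _ellipse_norm(shape, c["cy"], c["cx"], ac, bc, c["theta"])
        inside = norm <= 1.0
        take = inside & (norm < best[win])
        cell_labels[win][take] = i
        best[win][take] = norm[take]
    # overlap resolution must never move a nucleus pixel out of its own cell
    cell_labels[nucleus_labels > 0] = nucleus_labels[nucleus_labels > 0]

    centroids = np.array([[c["cy"], c["cx"]] for c in cells], dtype=float).reshape(-1, 2)
    truth = GroundTruth(nucleus_labels, cell_labels, class_of, centroids, params=p)

    amp = p.amplitude
    nuc_soft = ndimage.gaussian_filter((nucleus_labels > 0).astype(float), sigma=2.0)
    cell_soft = ndimage.gaussian_filter((cell_labels > 0).astype(float), sigma=2.0)
    tag_masks = {}
    for tag in ("gfp", "rfp"):
        ids = [lab for lab, cls in class_of.items() if cls == tag]
        m = np.isin(cell_labels, ids) if ids else np.zeros(shape, dtype=bool)
        tag_masks[tag] = ndimage.gaussian_filter(m.astype(float), sigma=2.0)

    posts = _post_mask(p)
    keep = ~posts

    def render(signal_soft: np.ndarray, scale: float) -> np.ndarray:
        expected = (p.background_level + scale * amp * signal_soft) * keep
        noisy = rng.poisson(expected).astype(np.float64)
        noisy += rng.normal(0.0, p.read_noise, size=shape)
        return np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    planes = {
        ChannelRole.NUCLEAR: render(nuc_soft, 1.0),
        ChannelRole.PAN_CELL: render(cell_soft, 0.8),
        ChannelRole.GFP: render(tag_masks["gfp"], 0.8),
    }
    if p.rfp_fraction > 0:
        planes[ChannelRole.RFP] = render(tag_masks["rfp"], 0.8)
    image = MultiChannelImage(planes=planes, field_id=f"synthetic_{p.rng_seed}")
    return image, truth


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Tabular ground truth: cell_id, class, centroid, nucleus/cell areas."""
    nuc_areas = np.bincount(
        truth.nucleus_labels.ravel(), minlength=truth.n_cells + 1
    )
    cell_areas = np.bincount(truth.cell_labels.ravel(), minlength=truth.n_cells + 1)
    rows = [
        {
            "cell_id": lab,
            "class": cls,
            "centroid_x": float(truth.centroids[lab - 1, 1]),
            "centroid_y": float(truth.centroids[lab - 1, 0]),
            "nucleus_area": int(nuc_areas[lab]),
            "cell_area": int(cell_areas[lab]),
        }
        for lab, cls in sorted(truth.class_of.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "class", "centroid_x", "centroid_y", "nucleus_area", "cell_area"],
    )


@dataclass
class MatchMetrics:
    """Detection quality of one protocol run against ground truth."""

    per_class: dict[str, dict] = field(default_factory=dict)

    def f1(self, cls: str) -> float:
        return self.per_class[cls]["f1"]

    def count_error(self, cls: str) -> int:
        return self.per_class[cls]["count_error"]


_DEFAULT_CLASS_MAP = {
    "gfp_positive": "gfp",
    "gfp_negative": "untagged",
    "gfp": "gfp",
    "rfp": "rfp",
}


def score_against_truth(result, truth: GroundTruth, class_map: dict | None = None) -> MatchMetrics:
    """Match detected whole cells to truth cells and score each population.

    A detected object is a candidate match for the truth cell whose region
    contains its nucleus centroid; candidates are resolved one-to-one,
    greedily by detected-object/truth-cell pixel overlap.  Per class:
    precision, recall, F1, absolute count error and total-area ratio.  With
    zero detections precision is reported as 0 with ``degenerate=True``.
    """
    class_map = class_map or _DEFAULT_CLASS_MAP
    nuclei = result.targets.get("nuclei")
    metrics = MatchMetrics()
    for pop, wcs in result.whole.items():
        truth_cls = class_map.get(pop, pop)
        truth_ids = {lab for lab, cls in truth.class_of.items() if cls == truth_cls}
        labels = np.asarray(wcs.labels)
        n_det = int(labels.max(initial=0))

        candidates = []  # (overlap, det_label, truth_label)
        for det in range(1, n_det + 1):
            det_px = labels == det
            nuc_lab = wcs.nucleus_of.get(det, 0)
            if nuc_lab and nuclei is not None:
                ys, xs = np.nonzero(np.asarray(nuclei) == nuc_lab)
            else:
                ys, xs = np.nonzero(det_px)
            if len(ys) == 0:
                continue
            cy, cx = int(round(ys.mean())), int(round(xs.mean()))
            t_lab = int(truth.cell_labels[cy, cx])
            if t_lab in truth_ids:
                ov = int((det_px & (truth.cell_labels == t_lab)).sum())
                if ov:
                    candidates.append((ov, det, t_lab))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_det, used_truth = set(), set()
        tp = 0
        for ov, det, t_lab in candidates:
            if det in used_det or t_lab in used_truth:
                continue
            used_det.add(det)
            used_truth.add(t_lab)
            tp += 1

        n_truth = len(truth_ids)
        degenerate = n_det == 0 and n_truth > 0
        precision = tp / n_det if n_det else (1.0 if n_truth == 0 else 0.0)
        recall = tp / n_truth if n_truth else 1.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        det_area = int((labels > 0).sum())
        truth_area = int(np.isin(truth.cell_labels, list(truth_ids)).sum())
        metrics.per_class[pop] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "tp": tp,
            "n_detected": n_det,
            "n_truth": n_truth,
            "count_error": abs(n_det - n_truth),
            "area_ratio": det_area / truth_area if truth_area else float("nan"),
            "degenerate": degenerate,
        }
    return metrics
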