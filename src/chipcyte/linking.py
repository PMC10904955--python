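"""Target-set algebra and nuclei–cell linking.

Whole-cell objects are formed by linking candidate cell objects to nuclei:
a cell object is retained only if some nucleus lies at least 80% (by the
nucleus's own pixel count) inside it, which guarantees every reported cell
is nucleated.  Marker-negative cells are derived by mask subtraction
(pan-cell stain minus the marker-positive mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .segment import relabel_raster_order

__all__ = ["LinkSpec", "WholeCellSet", "subtract", "exclude_debris", "link_by_overlap"]


@dataclass(frozen=True)
class LinkSpec:
    """Overlap rule linking a primary target (nuclei) into a secondary (cells).

    ``overlap_fraction`` is the minimum fraction of the *primary* object's
    pixels that must fall inside a secondary object (inclusive ≥).  With
    ``denominator="cell"`` the fraction is measured against the cell's pixel
    count instead (the alternative reading of the 80% rule).
    """

    primary: str = "nuclei"
    secondary: str = "cells"
    overlap_fraction: float = 0.8
    denominator: str = "nucleus"  # "nucleus" | "cell"

    def __post_init__(self) -> None:
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError(f"overlap_fraction must be in (0, 1], got {self.overlap_fraction}")
        if self.denominator not in ("nucleus", "cell"):
            raise ValueError(f"denominator must be nucleus|cell, got {self.denominator!r}")

    def as_fraction(self) -> Fraction:
        # limit_denominator so 0.8 means 4/5 exactly, not the binary float
        return Fraction(self.overlap_fraction).limit_denominator(10**6)


@dataclass
class WholeCellSet:
    """Nucleated cell objects of one population class.

    ``labels`` is a contiguous 1..M label map; ``nucleus_of`` maps each cell
    label to the nucleus that nucleates it (highest overlap fraction, lower
    nucleus id on ties).
    """

    labels: np.ndarray
    population: str
    nucleus_of: dict[int, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return int(self.labels.max(initial=0))


def subtract(minuend: np.ndarray, subtrahend: np.ndarray) -> np.ndarray:
    """Set difference of two masks (minuend \\ subtrahend)."""
    minuend = np.asarray(minuend, dtype=bool)
    subtrahend = np.asarray(subtrahend, dtype=bool)
    if minuend.shape != subtrahend.shape:
        raise ValueError(f"shape mismatch: {minuend.shape} vs {subtrahend.shape}")
    return minuend & ~subtrahend


def exclude_debris(cells: np.ndarray, debris: np.ndarray) -> np.ndarray:
    """Remove all debris-object pixels from the cells mask."""
    debris = np.asarray(debris)
    if debris.shape != np.asarray(cells).shape:
        raise ValueError("debris map shape does not match cells mask")
    return subtract(cells, debris > 0)


def link_by_overlap(
    nuclei: np.ndarray,
    cells: np.ndarray,
    spec: LinkSpec = LinkSpec(),
    population: str = "cells",
) -> WholeCellSet:
    """Keep cell objects overlapped by a nucleus at ≥ the configured fraction.

    The comparison is exact integer arithmetic: with the fraction p/q, nucleus
    n matches cell c iff ``|n ∩ c| · q ≥ p · |n|`` (denominator ``|c|`` under
    the alternative reading).  One match suffices.  Survivors are relabelled
    1..M preserving original label order.
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    if nuclei.shape != cells.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs cells {cells.shape}")

    n_cells = int(cells.max(initial=0))
    n_nuc = int(nuclei.max(initial=0))
    out = np.zeros(cells.shape, dtype=np.int32)
    if n_cells == 0 or n_nuc == 0:
        return WholeCellSet(labels=out, population=population)

    nuc_area = np.bincount(nuclei.ravel(), minlength=n_nuc + 1)
    cell_area = np.bincount(cells.ravel(), minlength=n_cells + 1)
    inside = nuclei > 0
    # joint histogram of (nucleus label, cell label) over nucleus pixels
    pair = nuclei[inside].astype(np.int64) * (n_cells + 1) + cells[inside].astype(np.int64)
    counts = np.bincount(pair, minlength=(n_nuc + 1) * (n_cells + 1))
    overlap = counts.reshape(n_nuc + 1, n_cells + 1)  # overlap[n, c] = |n ∩ c|

    frac = spec.as_fraction()
    p, q = frac.numerator, frac.denominator
    denom = nuc_area[:, None] if spec.denominator == "nucleus" else cell_area[None, :]
    qualifies = overlap * q >= p * denom
    qualifies[0, :] = qualifies[:, 0] = False

    survivors = [c for c in range(1, n_cells + 1) if qualifies[:, c].any()]
    mapping = np.zeros(n_cells + 1, dtype=np.int32)
    nucleus_of: dict[int, int] = {}
    for new, c in enumerate(survivors, start=1):
        mapping[c] = new
        cand = np.flatnonzero(qualifies[:, c])
        # best nucleus = highest overlap fraction of its own area; tie → lower id
        fracs = overlap[cand, c] / np.maximum(nuc_area[cand], 1)
        nucleus_of[new] = int(cand[int(np.argmax(fracs))])
    out = mapping[cells]
    return WholeCellSet(labels=out, population=population, nucleus_of=nucleus_of)
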