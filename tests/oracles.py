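"""Independent brute-force reference implementations.

Deliberately naive (per-pixel loops, flood fill, all-pairs censuses) so they
share no code path with the package; used to verify the vectorised operators
exactly.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def brute_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """A pixel survives iff every footprint neighbour is foreground
    (outside-image pixels count as background)."""
    mask = np.asarray(mask, dtype=bool)
    fh, fw = footprint.shape
    oy, ox = fh // 2, fw // 2
    out = np.zeros_like(mask)
    H, W = mask.shape
    for y in range(H):
        for x in range(W):
            keep = True
            for dy in range(fh):
                for dx in range(fw):
                    if not footprint[dy, dx]:
                        continue
                    yy, xx = y + dy - oy, x + dx - ox
                    if not (0 <= yy < H and 0 <= xx < W) or not mask[yy, xx]:
                        keep = False
                        break
                if not keep:
                    break
            out[y, x] = keep
    return out


def brute_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Foreground plus background regions not 4-connected to the border."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    outside = np.zeros_like(mask)
    stack = [
        (y, x)
        for y in range(H)
        for x in range(W)
        if (y in (0, H - 1) or x in (0, W - 1)) and not mask[y, x]
    ]
    for y, x in stack:
        outside[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < H and 0 <= xx < W and not mask[yy, xx] and not outside[yy, xx]:
                outside[yy, xx] = True
                stack.append((yy, xx))
    return mask | ~outside


def brute_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Flood-fill labelling, labels 1..N in raster order of first pixel."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    if connectivity == 4:
        nbrs = ((1, 0), (-1, 0), (0, 1), (0, -1))
    else:
        nbrs = tuple((dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0))
    out = np.zeros((H, W), dtype=np.int32)
    nxt = 0
    for y in range(H):
        for x in range(W):
            if mask[y, x] and out[y, x] == 0:
                nxt += 1
                stack = [(y, x)]
                out[y, x] = nxt
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in nbrs:
                        yy, xx = cy + dy, cx + dx
                        if 0 <= yy < H and 0 <= xx < W and mask[yy, xx] and out[yy, xx] == 0:
                            out[yy, xx] = nxt
                            stack.append((yy, xx))
    return out


def brute_sieve(labels: np.ndarray, mode: str, threshold: int) -> np.ndarray:
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 0
    for lab in range(1, int(labels.max(initial=0)) + 1):
        area = int((labels == lab).sum())
        if area == 0:
            continue
        keep = area > threshold if mode == "greater_than" else area < threshold
        if keep:
            nxt += 1
            out[labels == lab] = nxt
    return out


def _raster_relabel(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    mapping: dict[int, int] = {}
    H, W = labels.shape
    for y in range(H):
        for x in range(W):
            lab = int(labels[y, x])
            if lab > 0:
                if lab not in mapping:
                    mapping[lab] = len(mapping) + 1
                out[y, x] = mapping[lab]
    return out


def brute_break_clumps(mask: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-seed assignment (squared Euclidean distance to the
    nearest pixel of each seed object; ties to the lower seed label); mask
    components without seed pixels get one fresh label each."""
    mask = np.asarray(mask, dtype=bool)
    seeds = np.asarray(seeds)
    H, W = mask.shape
    seed_px: dict[int, list[tuple[int, int]]] = {}
    for y in range(H):
        for x in range(W):
            if seeds[y, x] > 0:
                seed_px.setdefault(int(seeds[y, x]), []).append((y, x))

    comps = brute_label(mask, connectivity=8)
    comp_has_seed = set()
    for y in range(H):
        for x in range(W):
            if mask[y, x] and seeds[y, x] > 0:
                comp_has_seed.add(int(comps[y, x]))

    out = np.zeros((H, W), dtype=np.int32)
    fresh = max(seed_px) if seed_px else 0
    fresh_of: dict[int, int] = {}
    for y in range(H):
        for x in range(W):
            if not mask[y, x]:
                continue
            comp = int(comps[y, x])
            if comp in comp_has_seed:
                best_lab, best_d = 0, None
                for lab in sorted(seed_px):
                    d = min((y - sy) ** 2 + (x - sx) ** 2 for sy, sx in seed_px[lab])
                    if best_d is None or d < best_d:
                        best_d, best_lab = d, lab
                out[y, x] = best_lab
            else:
                if comp not in fresh_of:
                    fresh += 1
                    fresh_of[comp] = fresh
                out[y, x] = fresh_of[comp]
    return _raster_relabel(out)


def brute_subtract(minuend: np.ndarray, subtrahend: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(minuend, dtype=bool))
    H, W = out.shape
    for y in range(H):
        for x in range(W):
            out[y, x] = bool(minuend[y, x]) and not bool(subtrahend[y, x])
    return out


def brute_link_survivors(
    nuclei: np.ndarray,
    cells: np.ndarray,
    fraction: Fraction,
    denominator: str = "nucleus",
) -> list[int]:
    """All-pairs overlap census → sorted surviving original cell labels."""
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    survivors = set()
    for c in range(1, int(cells.max(initial=0)) + 1):
        c_px = cells == c
        if not c_px.any():
            continue
        for n in range(1, int(nuclei.max(initial=0)) + 1):
            n_px = nuclei == n
            n_area = int(n_px.sum())
            if n_area == 0:
                continue
            ov = int((n_px & c_px).sum())
            denom = n_area if denominator == "nucleus" else int(c_px.sum())
            if ov * fraction.denominator >= fraction.numerator * denom:
                survivors.add(c)
                break
    return sorted(survivors)
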