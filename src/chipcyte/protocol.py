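"""Declarative protocol engine for the two co-culture analysis pipelines.

Protocol 1 classifies a phalloidin-stained co-culture into GFP-positive and
GFP-negative populations:

    Seed      = object-seg(nuclear; kernel 15, sensitivity 50)
                → erosion(disc 16) → sieve(> 20 px)
    Nuclei    = nuclear-seg(nuclear; min area 600 px, sensitivity 15)
                → clump-break(Seed) → fill holes → sieve(<) → sieve(>)
    GFP cells = intensity-seg(gfp) → erosion → clump-break(Nuclei)
                → fill holes → sieve(<) → sieve(>)
    Cells     = intensity-seg(pan_cell) → same chain
    GFP negative cells = (Cells − GFP cells) → sieve(>) → clump-break(Nuclei)
    Whole cells per class = 80% nucleus-overlap linking, then measurement.

Protocol 2 classifies two differently tagged populations (GFP vs RFP); each
tag channel runs the intensity chain and links to the same nuclei.

Parameters printed by the protocol (seed kernel 15 / sensitivity 50, erosion
kernel 16, seed sieve > 20 px, nuclei min area 600 px / sensitivity 15, the
80% overlap) ship as defaults; the sieve thresholds and intensity ranges the
protocol leaves open are documented defaults, all overridable in the config
file (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from . import __version__ as _pkg_version
from .io import ChannelRole, ConfigurationError, MultiChannelImage, write_labelmap
from .linking import LinkSpec, WholeCellSet, exclude_debris, link_by_overlap, subtract
from .measure import measure_objects, summarize
from .morphology import (
    SievePredicate,
    StructuringElement,
    break_clumps,
    erode,
    fill_holes_labels,
    sieve,
)
from .segment import (
    IntensityRange,
    NuclearSegParams,
    ObjectSegParams,
    label_components,
    segment_intensity,
    segment_nuclei,
    segment_objects,
)

__all__ = [
    "SeedConfig",
    "NucleiConfig",
    "IntensityTargetConfig",
    "ProtocolConfig",
    "ProtocolResult",
    "protocol_1_config",
    "protocol_2_config",
    "run_protocol_1",
    "run_protocol_2",
    "run_protocol",
]


@dataclass(frozen=True)
class SeedConfig:
    kernel_size: int = 15
    sensitivity: float = 50.0
    erosion_kernel: int = 16
    sieve_greater_than: int = 20


@dataclass(frozen=True)
class NucleiConfig:
    min_target_area: int = 600
    sensitivity: float = 15.0
    sieve_less_than: int = 15000
    sieve_greater_than: int = 100


@dataclass(frozen=True)
class IntensityTargetConfig:
    """Intensity-segmented cell-scale target and its post-processing chain.

    ``minimum is None`` selects an automatic (Otsu) threshold with the
    maximum left open; a fixed inclusive range is used when both are given.
    """

    minimum: int | None = None
    maximum: int = 65535
    erosion_kernel: int = 3
    sieve_less_than: int = 15000
    sieve_greater_than: int = 100


@dataclass(frozen=True)
class DebrisConfig:
    enabled: bool = False
    minimum: int | None = None
    maximum: int = 65535
    sieve_less_than: int = 100
    channel: str = "pan_cell"


@dataclass(frozen=True)
class ProtocolConfig:
    protocol: int = 1
    channel_map: tuple[str, ...] = ("nuclear", "pan_cell", "gfp")
    connectivity: int = 8
    seed: SeedConfig = field(default_factory=SeedConfig)
    nuclei: NucleiConfig = field(default_factory=NucleiConfig)
    gfp: IntensityTargetConfig = field(default_factory=IntensityTargetConfig)
    pan_cell: IntensityTargetConfig = field(default_factory=IntensityTargetConfig)
    rfp: IntensityTargetConfig = field(default_factory=IntensityTargetConfig)
    negative_sieve_greater_than: int = 100
    overlap_fraction: float = 0.8
    overlap_denominator: str = "nucleus"
    debris: DebrisConfig = field(default_factory=DebrisConfig)

    def __post_init__(self) -> None:
        if self.protocol not in (1, 2):
            raise ConfigurationError(f"protocol must be 1 or 2, got {self.protocol}")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if not (0 < self.overlap_fraction <= 1):
            raise ConfigurationError("overlap_fraction must be in (0, 1]")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_map"] = list(self.channel_map)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        for key, sub in (
            ("seed", SeedConfig),
            ("nuclei", NucleiConfig),
            ("gfp", IntensityTargetConfig),
            ("pan_cell", IntensityTargetConfig),
            ("rfp", IntensityTargetConfig),
            ("debris", DebrisConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "channel_map" in d:
            d["channel_map"] = tuple(d["channel_map"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: protocol config must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def protocol_1_config(**overrides) -> ProtocolConfig:
    """Preset for the GFP-positive vs GFP-negative (phalloidin) pipeline."""
    return replace(ProtocolConfig(protocol=1), **overrides)


def protocol_2_config(**overrides) -> ProtocolConfig:
    """Preset for the GFP vs RFP two-tag pipeline.

    The protocol prints no seed/nuclei numbers of its own; the preset reuses
    the Protocol 1 values.
    """
    base = ProtocolConfig(protocol=2, channel_map=("nuclear", "gfp", "rfp"))
    return replace(base, **overrides)


@dataclass
class ProtocolResult:
    """Everything one protocol run produces.

    ``targets`` holds every intermediate mask/label map by target name;
    ``whole`` the per-class :class:`WholeCellSet`; ``objects`` and
    ``summary`` the measurement tables; ``log`` the parameters and versions
    used (runs are fully deterministic — there is no random state).
    """

    targets: dict[str, np.ndarray]
    whole: dict[str, WholeCellSet]
    objects: pd.DataFrame
    summary: pd.DataFrame
    log: dict

    def counts(self) -> dict[str, int]:
        return {name: wcs.count for name, wcs in self.whole.items()}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.targets.items():
            write_labelmap(np.asarray(arr).astype(np.int64), outdir / f"{name}.tif")
        for name, wcs in self.whole.items():
            write_labelmap(wcs.labels, outdir / f"whole_{name}.tif")
        self.objects.to_csv(outdir / "objects.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------


def _intensity_mask(plane: np.ndarray, cfg: IntensityTargetConfig) -> np.ndarray:
    if cfg.minimum is not None:
        return segment_intensity(plane, IntensityRange(cfg.minimum, cfg.maximum))
    plane = np.asarray(plane)
    if plane.min() == plane.max():
        return np.zeros(plane.shape, dtype=bool)
    thr = threshold_otsu(plane)
    return (plane > thr) & (plane <= cfg.maximum)


def _cell_chain(
    plane: np.ndarray,
    cfg: IntensityTargetConfig,
    nuclei: np.ndarray,
    connectivity: int,
) -> np.ndarray:
    """intensity-seg → erosion → clump-break(nuclei) → fill → sieve< → sieve>"""
    mask = _intensity_mask(plane, cfg)
    if cfg.erosion_kernel and cfg.erosion_kernel > 1:
        mask = erode(mask, StructuringElement("disc", cfg.erosion_kernel))
    labels = break_clumps(mask, nuclei)
    labels = fill_holes_labels(labels)
    labels = sieve(labels, SievePredicate("less_than", cfg.sieve_less_than))
    labels = sieve(labels, SievePredicate("greater_than", cfg.sieve_greater_than))
    return labels


def _seed_and_nuclei(
    image: MultiChannelImage, config: ProtocolConfig
) -> tuple[np.ndarray, np.ndarray]:
    nuc_plane = image.plane(ChannelRole.NUCLEAR)
    s = config.seed
    seed_mask = segment_objects(nuc_plane, ObjectSegParams(s.kernel_size, s.sensitivity))
    seed_mask = erode(seed_mask, StructuringElement("disc", s.erosion_kernel))
    seeds = label_components(seed_mask, config.connectivity)
    seeds = sieve(seeds, SievePredicate("greater_than", s.sieve_greater_than))

    n = config.nuclei
    nuclei = segment_nuclei(
        nuc_plane,
        seeds,
        NuclearSegParams(n.min_target_area, n.sensitivity),
        connectivity=config.connectivity,
    )
    nuclei = break_clumps(nuclei > 0, seeds) if nuclei.max(initial=0) else nuclei
    nuclei = fill_holes_labels(nuclei)
    nuclei = sieve(nuclei, SievePredicate("less_than", n.sieve_less_than))
    nuclei = sieve(nuclei, SievePredicate("greater_than", n.sieve_greater_than))
    return seeds, nuclei


def _check_nucleation(whole: WholeCellSet, nuclei: np.ndarray, spec: LinkSpec) -> None:
    """In-engine invariant: every whole-cell object satisfies the overlap rule."""
    frac = spec.as_fraction()
    for cell_lab, nuc_lab in whole.nucleus_of.items():
        cell_px = whole.labels == cell_lab
        nuc_px = nuclei == nuc_lab
        n_in = int((cell_px & nuc_px).sum())
        denom = int(nuc_px.sum()) if spec.denominator == "nucleus" else int(cell_px.sum())
        if n_in * frac.denominator < frac.numerator * denom:
            raise RuntimeError(
                f"nucleation invariant violated for object {cell_lab} "
                f"({whole.population}): {n_in}/{denom} < {frac}"
            )


def run_protocol_1(image: MultiChannelImage, config: ProtocolConfig | None = None) -> ProtocolResult:
    """GFP-positive vs GFP-negative classification of a phalloidin-stained field."""
    config = config or protocol_1_config()
    image.require(ChannelRole.NUCLEAR, ChannelRole.PAN_CELL, ChannelRole.GFP)

    seeds, nuclei = _seed_and_nuclei(image, config)

    gfp_labels = _cell_chain(
        image.plane(ChannelRole.GFP), config.gfp, nuclei, config.connectivity
    )
    cells_labels = _cell_chain(
        image.plane(ChannelRole.PAN_CELL), config.pan_cell, nuclei, config.connectivity
    )
    cells_mask = cells_labels > 0

    targets: dict[str, np.ndarray] = {
        "seed": seeds,
        "nuclei": nuclei,
        "gfp_cells": gfp_labels,
        "cells": cells_labels,
    }

    if config.debris.enabled:
        d = config.debris
        debris_mask = _intensity_mask(
            image.plane(d.channel),
            IntensityTargetConfig(minimum=d.minimum, maximum=d.maximum, erosion_kernel=0),
        )
        debris = label_components(debris_mask, config.connectivity)
        debris = sieve(debris, SievePredicate("less_than", d.sieve_less_than))
        targets["debris"] = debris
        cells_mask = exclude_debris(cells_mask, debris)

    gfp_mask = gfp_labels > 0
    # marker-positive pixels restricted to the pan-cell mask: keeps the two
    # populations disjoint subsets of the Cells target
    pos_mask = gfp_mask & cells_mask
    neg_mask = subtract(cells_mask, gfp_mask)

    pos_labels = break_clumps(pos_mask, nuclei)
    pos_labels = sieve(pos_labels, SievePredicate("greater_than", config.negative_sieve_greater_than))
    neg_labels = break_clumps(neg_mask, nuclei)
    neg_labels = sieve(neg_labels, SievePredicate("greater_than", config.negative_sieve_greater_than))
    targets["gfp_positive_cells"] = pos_labels
    targets["gfp_negative_cells"] = neg_labels

    spec = LinkSpec(
        overlap_fraction=config.overlap_fraction, denominator=config.overlap_denominator
    )
    whole = {
        "gfp_positive": link_by_overlap(nuclei, pos_labels, spec, "gfp_positive"),
        "gfp_negative": link_by_overlap(nuclei, neg_labels, spec, "gfp_negative"),
    }
    for wcs in whole.values():
        _check_nucleation(wcs, nuclei, spec)
    pos_px = whole["gfp_positive"].labels > 0
    neg_px = whole["gfp_negative"].labels > 0
    if (pos_px & neg_px).any() or not ((pos_px | neg_px) <= cells_mask).all():
        raise RuntimeError("class partition invariant violated")

    objects = _concat_objects(
        measure_objects(whole["gfp_positive"], image.field_id, image.pixel_size),
        measure_objects(whole["gfp_negative"], image.field_id, image.pixel_size),
    )
    return ProtocolResult(
        targets=targets,
        whole=whole,
        objects=objects,
        summary=summarize(objects),
        log=_run_log(image, config),
    )


def _concat_objects(*frames: pd.DataFrame) -> pd.DataFrame:
    nonempty = [f for f in frames if not f.empty]
    if not nonempty:
        return frames[0]
    return pd.concat(nonempty, ignore_index=True)


def run_protocol_2(image: MultiChannelImage, config: ProtocolConfig | None = None) -> ProtocolResult:
    """GFP vs RFP two-population classification."""
    config = config or protocol_2_config()
    image.require(ChannelRole.NUCLEAR, ChannelRole.GFP, ChannelRole.RFP)

    seeds, nuclei = _seed_and_nuclei(image, config)
    gfp_labels = _cell_chain(
        image.plane(ChannelRole.GFP), config.gfp, nuclei, config.connectivity
    )
    rfp_labels = _cell_chain(
        image.plane(ChannelRole.RFP), config.rfp, nuclei, config.connectivity
    )
    targets = {
        "seed": seeds,
        "nuclei": nuclei,
        "gfp_cells": gfp_labels,
        "rfp_cells": rfp_labels,
    }
    spec = LinkSpec(
        overlap_fraction=config.overlap_fraction, denominator=config.overlap_denominator
    )
    whole = {
        "gfp": link_by_overlap(nuclei, gfp_labels, spec, "gfp"),
        "rfp": link_by_overlap(nuclei, rfp_labels, spec, "rfp"),
    }
    for wcs in whole.values():
        _check_nucleation(wcs, nuclei, spec)

    objects = _concat_objects(
        measure_objects(whole["gfp"], image.field_id, image.pixel_size),
        measure_objects(whole["rfp"], image.field_id, image.pixel_size),
    )
    return ProtocolResult(
        targets=targets,
        whole=whole,
        objects=objects,
        summary=summarize(objects),
        log=_run_log(image, config),
    )


def run_protocol(image: MultiChannelImage, config: ProtocolConfig) -> ProtocolResult:
    return run_protocol_1(image, config) if config.protocol == 1 else run_protocol_2(image, config)


def _run_log(image: MultiChannelImage, config: ProtocolConfig) -> dict:
    return {
        "chipcyte_version": _pkg_version,
        "field_id": image.field_id,
        "shape": list(image.shape),
        "channels": [str(r) for r in image.roles],
        "pixel_size": image.pixel_size,
        "config": config.to_dict(),
    }
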