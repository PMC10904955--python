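"""Reading and writing multi-channel fields, label maps and masks.

A *field* is one microscope field of view: a stack of grayscale intensity
planes, one per fluorescence channel, acquired at identical dimensions.
Channels are identified by their biological role (nuclear stain, pan-cell
stain, GFP tag, RFP tag) rather than by acquisition order, which varies by
instrument; the caller supplies the plane-to-role mapping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ChannelRole",
    "MultiChannelImage",
    "ConfigurationError",
    "load_field",
    "write_field",
    "write_labelmap",
    "read_labelmap",
]

MAX_INTENSITY = 65535


class ChannelRole(str, enum.Enum):
    """Biological role of one fluorescence channel."""

    NUCLEAR = "nuclear"     # DNA stain (e.g. DAPI); drives seed + nuclei targets
    PAN_CELL = "pan_cell"   # whole-population stain (e.g. phalloidin / F-actin)
    GFP = "gfp"             # constitutive GFP tag of one population
    RFP = "rfp"             # constitutive RFP tag of the other population

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ConfigurationError(ValueError):
    """Raised when inputs do not match the declared channel configuration."""


def _as_role(role: ChannelRole | str) -> ChannelRole:
    return role if isinstance(role, ChannelRole) else ChannelRole(str(role))


@dataclass
class MultiChannelImage:
    """Aligned per-channel intensity planes of one field of view.

    Parameters
    ----------
    planes
        Mapping from :class:`ChannelRole` to a 2-D ``uint16`` array.  All
        planes must share one shape; values are raw camera counts in
        ``[0, 65535]`` (never rescaled on load).
    pixel_size
        Optional physical pixel size in microns/pixel.  When set, measurement
        tables additionally report areas in µm².
    """

    planes: dict[ChannelRole, np.ndarray]
    pixel_size: float | None = None
    field_id: str = field(default="field_0")

    def __post_init__(self) -> None:
        self.planes = {_as_role(k): np.asarray(v) for k, v in self.planes.items()}
        if not self.planes:
            raise ConfigurationError("a field needs at least one channel plane")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ConfigurationError(f"planes disagree on shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ConfigurationError(f"planes must be 2-D, got shape {shape}")
        for role, plane in self.planes.items():
            if not np.issubdtype(plane.dtype, np.integer):
                raise ConfigurationError(f"{role} plane must be integer counts")
            if plane.min() < 0 or plane.max() > MAX_INTENSITY:
                raise ConfigurationError(
                    f"{role} plane intensities outside [0, {MAX_INTENSITY}]"
                )
            self.planes[role] = plane.astype(np.uint16, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    @property
    def roles(self) -> list[ChannelRole]:
        return list(self.planes)

    def plane(self, role: ChannelRole | str) -> np.ndarray:
        role = _as_role(role)
        if role not in self.planes:
            raise ConfigurationError(
                f"field has no {role.value!r} channel (available: "
                f"{[r.value for r in self.planes]})"
            )
        return self.planes[role]

    def require(self, *roles: ChannelRole | str) -> None:
        missing = [str(_as_role(r)) for r in roles if _as_role(r) not in self.planes]
        if missing:
            raise ConfigurationError(f"field is missing required channels: {missing}")


DEFAULT_CHANNEL_MAP: tuple[ChannelRole, ...] = (
    ChannelRole.NUCLEAR,
    ChannelRole.PAN_CELL,
    ChannelRole.GFP,
)


def load_field(
    path: str | Path,
    channel_map: list[ChannelRole | str] | None = None,
    pixel_size: float | None = None,
    field_id: str | None = None,
) -> MultiChannelImage:
    """Load a single- or multi-plane grayscale TIFF as a field.

    ``channel_map`` assigns roles to planes in storage order (defaults to
    ``nuclear, pan_cell, gfp``).  8-bit inputs are widened to the 16-bit range
    without rescaling values; intensities are never otherwise transformed.

    Raises
    ------
    ConfigurationError
        If the plane count differs from ``len(channel_map)``, or the file is
        an RGB-interleaved image (split channels first), or a role repeats.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise ConfigurationError(
            f"{path.name} looks RGB-interleaved (shape {arr.shape}); "
            "split channels into grayscale planes first"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ConfigurationError(f"{path.name}: expected 2-D or 3-D grayscale data")

    roles = [_as_role(r) for r in (channel_map or DEFAULT_CHANNEL_MAP)]
    if len(set(roles)) != len(roles):
        raise ConfigurationError(f"channel_map repeats a role: {roles}")
    if arr.shape[0] != len(roles):
        raise ConfigurationError(
            f"expected {len(roles)} planes, found {arr.shape[0]} in {path.name}"
        )
    planes = {role: np.ascontiguousarray(arr[i]) for i, role in enumerate(roles)}
    return MultiChannelImage(
        planes=planes,
        pixel_size=pixel_size,
        field_id=field_id or path.stem,
    )


def write_field(image: MultiChannelImage, path: str | Path,
                channel_map: list[ChannelRole | str] | None = None) -> None:
    """Write a field as a plane-stacked uint16 TIFF (inverse of load_field)."""
    roles = [_as_role(r) for r in (channel_map or image.roles)]
    stack = np.stack([image.plane(r) for r in roles])
    tifffile.imwrite(str(path), stack.astype(np.uint16), photometric="minisblack")


def write_labelmap(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label map as a single-plane TIFF.

    uint16 when the largest label fits, uint32 otherwise; re-loading with
    :func:`read_labelmap` reproduces the labels exactly.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer) or labels.min() < 0:
        raise ValueError("label map must contain non-negative integers")
    dtype = np.uint16 if (labels.size == 0 or labels.max() <= MAX_INTENSITY) else np.uint32
    tifffile.imwrite(str(path), labels.astype(dtype), photometric="minisblack")


def read_labelmap(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(str(path))
    return labels.astype(np.int64)
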