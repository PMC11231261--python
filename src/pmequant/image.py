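"""Image container and TIFF/OME-TIFF input/output.

:class:`ImageStack` is the common currency of every pipeline: a
channel-first intensity array — ``(c, y, x)`` for 2D scenes, ``(c, z, y,
x)`` for confocal stacks — plus the physical voxel spacing in µm per
spatial axis and an ordered list of channel roles. Axis order is fixed
as (z, y, x); all physical distances are computed between voxel centers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Multi-channel image with physical spacing.

    Parameters
    ----------
    data:
        Intensity array, shape ``(c, y, x)`` or ``(c, z, y, x)``.
        Channel-first; spatial axes in (z, y, x) order.
    spacing:
        Physical size of one voxel along each *spatial* axis, µm,
        in the same (z, y, x) order. ``None`` when unknown.
    channels:
        Ordered role labels, one per channel (e.g. ``brightfield``,
        ``md``, ``axoneme``, ``puncta``, ``vesicle_primary``).
    metadata:
        Free-form acquisition fields (time point h AEL, egg id,
        genotype, QC flags).
    """

    data: np.ndarray
    spacing: tuple[float, ...] | None = None
    channels: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"data must be (c, y, x) or (c, z, y, x); got shape {self.data.shape}"
            )
        if self.channels:
            self.channels = tuple(self.channels)
            if len(self.channels) != self.data.shape[0]:
                raise ValueError(
                    f"{len(self.channels)} channel roles for {self.data.shape[0]} channels"
                )
        else:
            self.channels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.data.ndim - 1:
                raise ValueError(
                    f"spacing has {len(self.spacing)} entries for "
                    f"{self.data.ndim - 1} spatial axes"
                )
            if any(s <= 0 for s in self.spacing):
                raise ValueError("spacing must be strictly positive")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape_spatial(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the channel array for a role label."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channels}")
        return self.data[idx]

    def voxel_volume_um3(self) -> float:
        """Physical volume (3D) or area (2D) of one voxel."""
        if self.spacing is None:
            raise ValueError("spacing unknown; cannot compute voxel volume")
        return float(np.prod(self.spacing))

    def require_spacing(self, assay: str) -> tuple[float, ...]:
        """Return spacing, raising a clear error for physical-units assays."""
        if self.spacing is None:
            raise ValueError(
                f"the {assay} assay needs physical voxel spacing, but the image "
                "carries none and no override was given"
            )
        return self.spacing


_AXES_FOR_NDIM = {3: "CYX", 4: "CZYX"}


def write_image(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with physical spacing metadata."""
    path = Path(path)
    axes = _AXES_FOR_NDIM[stack.data.ndim]
    metadata: dict = {"axes": axes}
    if stack.spacing is not None:
        # spacing order is (z, y, x) / (y, x); OME names are per-axis
        sp = stack.spacing
        metadata["PhysicalSizeX"] = sp[-1]
        metadata["PhysicalSizeY"] = sp[-2]
        metadata["PhysicalSizeXUnit"] = "µm"
        metadata["PhysicalSizeYUnit"] = "µm"
        if len(sp) == 3:
            metadata["PhysicalSizeZ"] = sp[0]
            metadata["PhysicalSizeZUnit"] = "µm"
    metadata["Channel"] = {"Name": list(stack.channels)}
    tifffile.imwrite(path, stack.data, ome=True, metadata=metadata)


def _parse_physical_sizes(ome_xml: str) -> dict[str, float]:
    sizes: dict[str, float] = {}
    for axis in "XYZ":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        if m:
            sizes[axis] = float(m.group(1))
    return sizes


def read_image(
    path: str | Path,
    channel_roles: Sequence[str] | None = None,
    spacing_override: Sequence[float] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Spacing is taken from OME metadata when present, else from
    ``spacing_override``; assays that need physical units will raise
    later if neither is available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_xml = tif.ome_metadata
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3 and ome_xml:
        # tifffile squeezes singleton axes; restore channel-first layout
        m = re.search(r'SizeZ="(\d+)"', ome_xml)
        if m and int(m.group(1)) == data.shape[0]:
            mc = re.search(r'SizeC="(\d+)"', ome_xml)
            if mc is None or int(mc.group(1)) == 1:
                data = data[None]
    spacing: tuple[float, ...] | None = None
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif ome_xml:
        sizes = _parse_physical_sizes(ome_xml)
        if "X" in sizes and "Y" in sizes:
            if data.ndim == 4:
                if "Z" in sizes:
                    spacing = (sizes["Z"], sizes["Y"], sizes["X"])
            else:
                spacing = (sizes["Y"], sizes["X"])
    if channel_roles is not None:
        if len(channel_roles) != data.shape[0]:
            raise ValueError(
                f"file has {data.shape[0]} channels but {len(channel_roles)} "
                "roles were given"
            )
        roles = tuple(channel_roles)
    elif ome_xml:
        named = re.findall(r'<Channel[^>]*Name="([^"]+)"', ome_xml)
        roles = tuple(named) if len(named) == data.shape[0] else ()
    else:
        roles = ()
    return ImageStack(data=data, spacing=spacing, channels=roles)
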