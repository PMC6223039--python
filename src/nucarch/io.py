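"""TIFF I/O for multi-channel stacks and masks.

Stacks are written channel-axis-first (C, Z, Y, X) as 16-bit TIFF with the
voxel spacing recorded both in the ImageJ-style metadata and in a YAML
sidecar (``<stem>.yml``) holding channel names and spacing — the sidecar is
authoritative when both are present, and a spacing override can be supplied
when reading stacks without either.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import GridSpec, MultiChannelVolume, NuclearMask

__all__ = ["write_stack", "read_stack", "write_mask"]


def write_stack(volume: MultiChannelVolume, path) -> Path:
    path = Path(path)
    data = np.stack([volume.channels[n] for n in volume.channel_names])
    dz, dy, dx = volume.grid.spacing
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    sidecar = path.with_suffix(".yml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "channel_names": list(volume.channel_names),
                "spacing_um": [float(s) for s in volume.grid.spacing],
            }
        )
    )
    return path


def read_stack(
    path,
    channel_names: list[str] | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> MultiChannelVolume:
    """Read a (C, Z, Y, X) TIFF stack; channel names and spacing come from
    the YAML sidecar unless given explicitly."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected a (C, Z, Y, X) stack, got shape {data.shape}")
    sidecar = path.with_suffix(".yml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        channel_names = channel_names or meta.get("channel_names")
        spacing = spacing or tuple(meta.get("spacing_um"))
    if spacing is None:
        raise ValueError(
            f"no voxel spacing for {path.name}: no sidecar and no override"
        )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    if len(channel_names) != data.shape[0]:
        raise ValueError(
            f"{len(channel_names)} channel names for {data.shape[0]} channels"
        )
    grid = GridSpec(shape=data.shape[1:], spacing=spacing)
    return MultiChannelVolume(
        channels={n: data[i] for i, n in enumerate(channel_names)}, grid=grid
    )


def write_mask(mask: NuclearMask, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255)
    return path
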