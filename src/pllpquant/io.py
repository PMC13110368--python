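"""Standard-format I/O: OME-TIFF stacks, 16-bit label volumes, CSV tables,
YAML configs and JSON run logs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
import yaml

from .types import LabelVolume, VoxelStack


def write_stack(stack: VoxelStack, path: Union[str, Path]) -> Path:
    """Write a multi-channel stack as OME-TIFF with voxel spacing metadata."""
    path = Path(path)
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    dz, dy, dx = stack.spacing_um
    tifffile.imwrite(
        path, data, ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx, "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def read_stack(path: Union[str, Path],
               spacing_um: tuple[float, float, float] | None = None
               ) -> VoxelStack:
    """Read an OME-TIFF (or plain TIFF) stack; spacing comes from OME
    metadata unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        names = None
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None and spacing_um is None:
                try:
                    spacing_um = (float(px.get("PhysicalSizeZ")),
                                  float(px.get("PhysicalSizeY")),
                                  float(px.get("PhysicalSizeX")))
                except (TypeError, ValueError):
                    spacing_um = None
            chans = root.findall(".//ome:Channel", ns)
            if chans and all(c.get("Name") for c in chans):
                names = [c.get("Name") for c in chans]
    if spacing_um is None:
        spacing_um = (1.0, 1.0, 1.0)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF of shape {arr.shape} as CZYX")
    if names is None or len(names) != arr.shape[0]:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    channels = {n: arr[i].astype(np.float32) for i, n in enumerate(names)}
    return VoxelStack(channels, spacing_um, meta={"source": str(path)})


def write_labels(labels: LabelVolume, path: Union[str, Path]) -> Path:
    """Write a label volume as 16-bit OME-TIFF."""
    path = Path(path)
    if labels.data.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit 16-bit output")
    dz, dy, dx = labels.spacing_um
    tifffile.imwrite(
        path, labels.data.astype(np.uint16), ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx, "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def read_labels(path: Union[str, Path],
                spacing_um: tuple[float, float, float] | None = None
                ) -> LabelVolume:
    stack = read_stack(path, spacing_um)
    data = next(iter(stack.channels.values()))
    return LabelVolume(data.astype(np.int32), stack.spacing_um)


def write_yaml(obj: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True), encoding="utf-8")
    return path


def read_yaml(path: Union[str, Path]) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))


def write_json_log(obj: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str),
                    encoding="utf-8")
    return path
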