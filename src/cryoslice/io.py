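"""Reading and writing image stacks and their sidecar metadata.

Stacks travel as multi-page grayscale TIFF (16-bit unsigned) or as a
directory of numbered single-slice TIFFs, always accompanied by a YAML
sidecar carrying the physical metadata the pixels cannot: slice thickness
(um), pixel size (um), and the generation parameters/seed when the stack
is synthetic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .volume import ImageStack

__all__ = ["write_stack", "read_stack", "sidecar_path"]

_REQUIRED_METADATA = ("slice_thickness_um", "pixel_size_um")


def sidecar_path(stack_path) -> Path:
    """The conventional metadata path next to a stack file or directory."""
    p = Path(stack_path)
    return p.with_suffix(".yaml") if p.suffix else p / "metadata.yaml"


def write_stack(stack: ImageStack, tiff_path, metadata_path=None) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a YAML sidecar.

    Gray levels are rounded to the nearest integer on write; values beyond
    the 16-bit range are clipped.  Returns the sidecar path.
    """
    tiff_path = Path(tiff_path)
    data = np.clip(np.rint(stack.voxels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, data)
    meta = {
        "slice_thickness_um": float(stack.slice_thickness),
        "pixel_size_um": float(stack.pixel_size),
        "provenance": stack.provenance,
    }
    metadata_path = Path(metadata_path) if metadata_path else sidecar_path(tiff_path)
    metadata_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return metadata_path


def read_stack(stack_path, metadata_path=None) -> ImageStack:
    """Read a stack from a multi-page TIFF or a directory of slice TIFFs.

    Raises
    ------
    KeyError
        Naming the missing field if the sidecar lacks required metadata.
    FileNotFoundError
        If the stack or its sidecar is absent.
    """
    stack_path = Path(stack_path)
    if stack_path.is_dir():
        pages = sorted(p for p in stack_path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not pages:
            raise FileNotFoundError(f"no TIFF slices found in {stack_path}")
        voxels = np.stack([tifffile.imread(p) for p in pages]).astype(float)
    else:
        voxels = np.asarray(tifffile.imread(stack_path), dtype=float)
        if voxels.ndim == 2:
            voxels = voxels[None]
    metadata_path = Path(metadata_path) if metadata_path else sidecar_path(stack_path)
    if not metadata_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {metadata_path}")
    meta = yaml.safe_load(metadata_path.read_text()) or {}
    for key in _REQUIRED_METADATA:
        if key not in meta:
            raise KeyError(f"metadata file {metadata_path} is missing required field '{key}'")
    return ImageStack(
        voxels=voxels,
        slice_thickness=float(meta["slice_thickness_um"]),
        pixel_size=float(meta["pixel_size_um"]),
        provenance=meta.get("provenance", {}) or {},
    )
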