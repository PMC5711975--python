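"""Reading and writing slides, masks and tables.

Slides travel as multi-page TIFF (one page per channel) with a JSON
sidecar recording the channel order and the physical pixel size; masks as
single-page uint8 TIFF (nonzero = inside); tables as CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import MultiChannelImage, RegionMasks

MASK_NAMES = ("tissue", "adipose", "exclusion", "core")


def write_image(image: MultiChannelImage, path: Path) -> None:
    """Write channels as TIFF pages plus a ``<stem>.json`` sidecar."""
    path = Path(path)
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(path, stack.astype(np.float32))
    sidecar = {"channels": names, "pixel_size_um": image.pixel_size,
               "slide_id": image.slide_id}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_image(path: Path) -> MultiChannelImage:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i] for i, name in enumerate(sidecar["channels"])}
    return MultiChannelImage(channels=channels,
                             pixel_size=float(sidecar["pixel_size_um"]),
                             slide_id=sidecar.get("slide_id", path.stem))


def write_masks(masks: RegionMasks, directory: Path, slide_id: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    available = {"tissue": masks.tissue, "adipose": masks.adipose,
                 "exclusion": masks.exclusion, "core": masks.core}
    for name in MASK_NAMES:
        m = available.get(name)
        if m is not None:
            tifffile.imwrite(directory / f"{slide_id}_{name}.tif",
                             m.astype(np.uint8) * 255)


def read_masks(directory: Path, slide_id: str,
               shape: tuple[int, int]) -> RegionMasks:
    """Load the masks of one slide; missing optional masks default sanely.

    ``tumor`` is *not* read here — it is computed by thresholding; a
    missing tissue mask defaults to the full frame.
    """
    directory = Path(directory)

    def load(name):
        p = directory / f"{slide_id}_{name}.tif"
        return tifffile.imread(p) > 0 if p.exists() else None

    tissue = load("tissue")
    if tissue is None:
        tissue = np.ones(shape, dtype=bool)
    adipose = load("adipose")
    if adipose is None:
        adipose = np.zeros(shape, dtype=bool)
    return RegionMasks(tissue=tissue, adipose=adipose,
                       tumor=np.zeros(shape, dtype=bool),
                       exclusion=load("exclusion"), core=load("core"),
                       provenance={"tissue": "supplied", "adipose": "supplied",
                                   "tumor": "computed"})
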