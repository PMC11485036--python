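"""Reading and writing stacks, masks, configs, and tidy tables.

Stacks travel as multi-page TIFF (one page per channel, channel order and
metadata recorded as JSON in the image description); masks as single-page
TIFFs named after the region; configs as YAML; statistics as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .excitation import ExcitationStack
from .scene import MultispectralStack, ROISet, SceneSpec

__all__ = [
    "save_stack",
    "load_stack",
    "save_masks",
    "load_masks",
    "load_scene_config",
    "save_manifest",
]


def save_stack(stack: MultispectralStack | ExcitationStack, path) -> None:
    labels = list(stack.channels)
    meta = {
        "channel_order": labels,
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "dark_rows": stack.dark_rows,
        "steps": list(stack.steps),
        "mode": getattr(stack, "mode", None),
    }
    pages = np.stack([stack.channels[c] for c in labels]).astype(np.float32)
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def load_stack(path, excitation: bool | None = None):
    """Load a stack; returns an ExcitationStack if it was saved as one."""
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray().astype(float)
        meta = json.loads(tif.pages[0].description)
    channels = {c: pages[i] for i, c in enumerate(meta["channel_order"])}
    steps = tuple(meta.get("steps", ("rendered",)))
    is_excitation = "naka_rushton" in steps if excitation is None else excitation
    if is_excitation:
        return ExcitationStack(
            channels=channels,
            mode=meta.get("mode") or "background",
            pixel_pitch_mm=meta["pixel_pitch_mm"],
            dark_rows=meta["dark_rows"],
            steps=steps,
        )
    return MultispectralStack(
        channels=channels,
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        dark_rows=meta["dark_rows"],
        steps=steps,
    )


def save_masks(rois: ROISet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in rois.masks.items():
        tifffile.imwrite(directory / f"{name}.tiff", mask.astype(np.uint8))


def load_masks(directory) -> ROISet:
    masks = {}
    for path in sorted(Path(directory).glob("*.tiff")):
        masks[path.stem] = tifffile.imread(path).astype(bool)
    return ROISet(masks)


def load_scene_config(path) -> SceneSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "shape" in cfg:
        cfg["shape"] = tuple(cfg["shape"])
    return SceneSpec(**cfg)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
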