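"""Co-registered image containers.

One stage position yields five co-registered 8-bit images: a bright-field
color image of the sedimented sample, a blank reference taken without sample
(used for illumination correction), and three epifluorescence channels
targeting the autofluorescence of chlorophyll, phycoerythrin and phycocyanin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

#: channel file-name suffixes, in canonical order
CHANNEL_SUFFIXES = ("_bf", "_blank", "_chl", "_pe", "_pc")


def _as_u8(img: np.ndarray, name: str, ndim: int) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != ndim:
        raise ValueError(f"{name}: expected {ndim}-d array, got shape {img.shape}")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError(f"{name}: values outside [0, 255]")
        img = img.astype(np.uint8)
    return img


@dataclass
class FrameSet:
    """The five co-registered images for one stage position.

    Parameters
    ----------
    brightfield, blank : (H, W, 3) uint8
        Transmitted-light sample image and no-sample reference.
    fluor_chl, fluor_pe, fluor_pc : (H, W) uint8
        Fluorescence channels (chlorophyll, phycoerythrin, phycocyanin).
    frame_id : str
        Identifier carried through segmentation and feature tables.
    um_per_px : float or None
        Optional pixel calibration, recorded but never used; the pipeline
        works in native pixel units.
    """

    brightfield: np.ndarray
    blank: np.ndarray
    fluor_chl: np.ndarray
    fluor_pe: np.ndarray
    fluor_pc: np.ndarray
    frame_id: str = "frame"
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        self.brightfield = _as_u8(self.brightfield, "brightfield", 3)
        self.blank = _as_u8(self.blank, "blank", 3)
        self.fluor_chl = _as_u8(self.fluor_chl, "fluor_chl", 2)
        self.fluor_pe = _as_u8(self.fluor_pe, "fluor_pe", 2)
        self.fluor_pc = _as_u8(self.fluor_pc, "fluor_pc", 2)
        shapes = {img.shape[:2] for img in self.images()}
        if len(shapes) != 1:
            raise ValueError(f"channel dimensions differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape[:2]

    def images(self):
        return (self.brightfield, self.blank, self.fluor_chl, self.fluor_pe,
                self.fluor_pc)

    def fluorescence(self) -> dict[str, np.ndarray]:
        return {"chl": self.fluor_chl, "pe": self.fluor_pe, "pc": self.fluor_pc}

    def save(self, out_dir: str) -> None:
        """Write the five channels as single-channel/RGB TIFFs."""
        os.makedirs(out_dir, exist_ok=True)
        for suffix, img in zip(CHANNEL_SUFFIXES, self.images()):
            tifffile.imwrite(
                os.path.join(out_dir, f"{self.frame_id}{suffix}.tif"), img)

    @classmethod
    def load(cls, in_dir: str, frame_id: str) -> "FrameSet":
        imgs = []
        for suffix in CHANNEL_SUFFIXES:
            path = os.path.join(in_dir, f"{frame_id}{suffix}.tif")
            if not os.path.exists(path):
                raise FileNotFoundError(path)
            imgs.append(tifffile.imread(path))
        return cls(*imgs, frame_id=frame_id)


def list_frame_ids(in_dir: str) -> list[str]:
    """Frame ids present in a directory (every id with a `_bf.tif` file)."""
    ids = []
    for name in sorted(os.listdir(in_dir)):
        if name.endswith("_bf.tif"):
            ids.append(name[: -len("_bf.tif")])
    return ids


def brightness(rgb: np.ndarray) -> np.ndarray:
    """Brightness channel of an RGB image: max(R, G, B), as in the HSB model."""
    return np.asarray(rgb, dtype=np.float64).max(axis=2)
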