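"""Illumination and color-drift correction.

Lamp drift and vignetting are corrected against a blank reference image taken
without sample: each sample pixel is divided by the matching blank pixel and
rescaled by the blank's global mean, so a frame imaged under the same
illumination as the blank comes out flat at the blank's mean level:

    corrected = sample / blank * mean(blank)

The correction runs channel-wise on the bright-field RGB image only; the
fluorescence channels are epifluorescence images for which a transmitted-light
blank carries no information, and pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameSet


@dataclass
class CorrectedFrame:
    """A FrameSet after illumination correction.

    ``mean_lc`` records the per-channel global mean of the blank reference
    that the bright-field channels were rescaled to.
    """

    brightfield: np.ndarray
    fluor_chl: np.ndarray
    fluor_pe: np.ndarray
    fluor_pc: np.ndarray
    mean_lc: tuple[float, float, float]
    frame_id: str = "frame"

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape[:2]

    def fluorescence(self) -> dict[str, np.ndarray]:
        return {"chl": self.fluor_chl, "pe": self.fluor_pe, "pc": self.fluor_pc}


def correct_illumination(sample: np.ndarray, blank: np.ndarray) -> np.ndarray:
    """Divide one channel by the blank reference and rescale to its mean.

    Computed in floating point and rounded once at the end; zero-valued blank
    pixels are floored to 1 before the division, and the result is clipped to
    the 8-bit range.

    Parameters
    ----------
    sample, blank : 2-d arrays of equal shape, values in [0, 255].

    Returns
    -------
    (H, W) uint8 corrected channel.
    """
    sample = np.asarray(sample, dtype=np.float64)
    blank = np.asarray(blank, dtype=np.float64)
    if sample.shape != blank.shape:
        raise ValueError(
            f"sample shape {sample.shape} != blank shape {blank.shape}")
    mean_lc = blank.mean()
    safe_blank = np.maximum(blank, 1.0)
    corrected = sample / safe_blank * mean_lc
    return np.clip(np.rint(corrected), 0, 255).astype(np.uint8)


def correct_frame(frame: FrameSet) -> CorrectedFrame:
    """Correct a frame's bright-field image channel-wise against its blank.

    Each RGB channel is corrected with the blank's matching channel;
    fluorescence channels are returned unchanged.
    """
    bf = np.empty_like(frame.brightfield)
    means = []
    for c in range(3):
        blank_c = frame.blank[:, :, c]
        bf[:, :, c] = correct_illumination(frame.brightfield[:, :, c], blank_c)
        means.append(float(blank_c.mean()))
    return CorrectedFrame(
        brightfield=bf,
        fluor_chl=frame.fluor_chl.copy(),
        fluor_pe=frame.fluor_pe.copy(),
        fluor_pc=frame.fluor_pc.copy(),
        mean_lc=tuple(means),
        frame_id=frame.frame_id,
    )
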