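"""The binary sinus-silhouette container every comparison consumes.

A silhouette is a fixed-size 200x100 (width x height) two-level image with
the sinus cavity in black (pixel value 0) on a white background (pixel
value 1). Pixel coordinates are 0-based with the origin at the top-left,
x rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

CANVAS_WIDTH = 200
CANVAS_HEIGHT = 100


class SilhouetteError(ValueError):
    """Raised when an array does not satisfy the silhouette invariants."""


@dataclass(frozen=True)
class BinarySilhouette:
    """200x100 binary image, 0 = sinus (black), 1 = background (white).

    ``pixels`` has shape (100, 200) — rows are y, columns are x — and dtype
    uint8 with values in {0, 1}.
    """

    pixels: np.ndarray
    case_id: str = ""
    session: str = ""  # "AM" or "PM"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (CANVAS_HEIGHT, CANVAS_WIDTH):
            raise SilhouetteError(
                f"silhouette must be {CANVAS_WIDTH}x{CANVAS_HEIGHT} (w x h), "
                f"got array of shape {px.shape}"
            )
        vals = np.unique(px)
        if not np.all(np.isin(vals, [0, 1])):
            raise SilhouetteError(f"silhouette must be two-level {{0,1}}, found values {vals}")
        if 0 not in vals or 1 not in vals:
            raise SilhouetteError("silhouette needs at least one sinus and one background pixel")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    # -- derived views -------------------------------------------------

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of the sinus cavity (True where black)."""
        return self.pixels == 0

    def to_intensity(self) -> np.ndarray:
        """Float image in [0, 1]: sinus 0.0 (black), background 1.0 (white)."""
        return self.pixels.astype(float)

    def area(self) -> int:
        return int(self.foreground.sum())

    # -- I/O -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as 8-bit grayscale PNG/PGM: sinus 0, background 255."""
        img = Image.fromarray((self.pixels * 255).astype(np.uint8), mode="L")
        img.save(str(path))

    @classmethod
    def load(cls, path: str | Path, case_id: str = "", session: str = "") -> "BinarySilhouette":
        arr = np.asarray(Image.open(str(path)).convert("L"))
        return cls(pixels=(arr >= 128).astype(np.uint8), case_id=case_id, session=session)


def from_mask(fg: np.ndarray, case_id: str = "", session: str = "") -> BinarySilhouette:
    """Build a silhouette from a boolean foreground (sinus) mask."""
    fg = np.asarray(fg, dtype=bool)
    return BinarySilhouette(pixels=(~fg).astype(np.uint8), case_id=case_id, session=session)
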