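"""Keypoint and binary-descriptor containers shared by both extractors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: descriptor bit lengths per method
DESCRIPTOR_BITS = {"orb": 256, "akaze": 486}


class FeatureError(ValueError):
    pass


class InsufficientFeaturesError(RuntimeError):
    """An image yielded no usable keypoints; the cohort layer records the
    pair as missing, never as a zero score."""


@dataclass(frozen=True)
class Keypoint:
    """Detected interest point.

    Coordinates are at base image resolution (sub-pixel allowed for
    pyramid/scale-space levels), ``octave`` is the pyramid / octave index,
    ``scale`` the size in pixels at base resolution, ``angle`` the
    orientation in radians in [0, 2*pi), ``response`` the detector score.
    """

    x: float
    y: float
    octave: int = 0
    scale: float = 1.0
    angle: float = 0.0
    response: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle < 2.0 * np.pi + 1e-12):
            raise FeatureError(f"keypoint angle must lie in [0, 2*pi), got {self.angle}")


def _nbytes(nbits: int) -> int:
    return (nbits + 7) // 8


@dataclass(frozen=True)
class BinaryDescriptor:
    """Fixed-length bit string of one keypoint, stored big-endian packed
    (np.packbits order); pad bits beyond ``nbits`` are zero."""

    bits: np.ndarray  # (nbytes,) uint8
    nbits: int
    method: str

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.ndim != 1 or b.size != _nbytes(self.nbits):
            raise FeatureError(
                f"descriptor must be {_nbytes(self.nbits)} bytes for {self.nbits} bits, "
                f"got shape {b.shape}"
            )
        object.__setattr__(self, "bits", b)
        b.setflags(write=False)

    def unpacked(self) -> np.ndarray:
        """The first ``nbits`` bits as a {0,1} uint8 vector."""
        return np.unpackbits(self.bits)[: self.nbits]


@dataclass(frozen=True)
class DescriptorSet:
    """All descriptors of one image as a (n, nbytes) uint8 matrix, row i
    belonging to keypoint i in the canonical keypoint order."""

    bits: np.ndarray
    nbits: int
    method: str

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.bits, dtype=np.uint8))
        if b.shape[1] != _nbytes(self.nbits):
            raise FeatureError(
                f"descriptor rows must be {_nbytes(self.nbits)} bytes, got {b.shape[1]}"
            )
        object.__setattr__(self, "bits", b)

    def __len__(self) -> int:
        return int(self.bits.shape[0])

    def __getitem__(self, i: int) -> BinaryDescriptor:
        return BinaryDescriptor(bits=self.bits[i].copy(), nbits=self.nbits, method=self.method)


def sort_canonical(keypoints: list[Keypoint]) -> list[Keypoint]:
    """Canonical keypoint order: response descending, then y, then x.
    Makes every downstream result independent of detection storage order."""
    return sorted(keypoints, key=lambda k: (-k.response, k.y, k.x))


def keypoints_to_frame(keypoints: list[Keypoint], descriptors: DescriptorSet):
    """Optional CSV-friendly dump (x, y, octave, angle_rad, response,
    hex-encoded descriptor bits)."""
    import pandas as pd

    return pd.DataFrame({
        "x": [k.x for k in keypoints],
        "y": [k.y for k in keypoints],
        "octave": [k.octave for k in keypoints],
        "scale": [k.scale for k in keypoints],
        "angle_rad": [k.angle for k in keypoints],
        "response": [k.response for k in keypoints],
        "bits_hex": [bytes(row).hex() for row in descriptors.bits],
    })
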