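"""From-scratch ORB-style extractor.

FAST-9 segment-test corners on a Gaussian pyramid, Harris ranking,
intensity-centroid orientation, and a steered 256-bit BRIEF descriptor.
Binary silhouettes are Gaussian-smoothed before detection (sigma 1) and
description (sigma 2): a strict two-level image has degenerate gradients
and segment-test arcs, and the smoothing makes both well posed.

The BRIEF test pattern is generated once from a fixed seed with isotropic
Gaussian sampling (sigma = patch/5); bit-exact parity with any third-party
build is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from ._filters import gaussian, scharr_x, scharr_y
from .features import DescriptorSet, FeatureError, InsufficientFeaturesError, Keypoint
from .silhouette import BinarySilhouette

#: radius-3 Bresenham circle, 16 pixels clockwise from 12 o'clock, as (dx, dy)
CIRCLE_OFFSETS = np.array([
    (0, -3), (1, -3), (2, -2), (3, -1), (3, 0), (3, 1), (2, 2), (1, 3),
    (0, 3), (-1, 3), (-2, 2), (-3, 1), (-3, 0), (-3, -1), (-2, -2), (-1, -3),
], dtype=int)

PATCH_SIZE = 31
_PATCH_R = PATCH_SIZE // 2  # 15
_MARGIN = _PATCH_R  # descriptor/orientation patch support
PATTERN_SEED = 7


@dataclass(frozen=True)
class OrbParams:
    n_features: int = 500
    n_levels: int = 4
    scale_factor: float = 1.2
    fast_threshold: float = 0.08  # on [0,1] intensities
    n_contiguous: int = 9
    harris_k: float = 0.04
    harris_block: int = 7
    detect_sigma: float = 1.0
    describe_sigma: float = 2.0
    pattern_seed: int = PATTERN_SEED


# ---------------------------------------------------------------------------
# FAST segment test


def _arc_score(diffs: np.ndarray, threshold: float, n_contiguous: int) -> float:
    """Score of one circle: max over maximal qualifying bright/dark runs of
    the summed absolute differences; 0.0 if no run of length >= n exists."""
    best = 0.0
    for mask in (diffs > threshold, diffs < -threshold):
        if mask.all():
            best = max(best, float(np.abs(diffs).sum()))
            continue
        # circular runs: rotate so a gap is at the boundary, then split
        gap = int(np.flatnonzero(~mask)[0])
        m = np.roll(mask, -gap)
        d = np.roll(np.abs(diffs), -gap)
        idx = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
        for start, stop in zip(idx[::2], idx[1::2]):
            if stop - start >= n_contiguous:
                best = max(best, float(d[start:stop].sum()))
    return best


def fast_detect(image: np.ndarray, threshold: float = 0.08, n_contiguous: int = 9,
                nms: bool = True) -> list[Keypoint]:
    """FAST corner detection on a grayscale image.

    A pixel p is a corner iff at least ``n_contiguous`` contiguous pixels
    on its radius-3 circle are all brighter than I(p)+t or all darker than
    I(p)-t. The corner score is the summed |difference| over the
    qualifying arc; with ``nms`` a corner survives only if its score is
    strictly greater than every 3x3 neighbour's score.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if h < 7 or w < 7:
        raise FeatureError(f"FAST needs at least a 7x7 image, got {w}x{h}")
    center = img[3:h - 3, 3:w - 3]
    diffs = np.stack([
        img[3 + dy:h - 3 + dy, 3 + dx:w - 3 + dx] - center
        for dx, dy in CIRCLE_OFFSETS
    ])  # (16, h-6, w-6)
    bright = diffs > threshold
    dark = diffs < -threshold
    cand = np.zeros(center.shape, dtype=bool)
    for mask in (bright, dark):
        run = np.ones(center.shape, dtype=bool)
        acc = np.zeros(center.shape, dtype=bool)
        for start in range(16):
            run.fill(True)
            for i in range(n_contiguous):
                run &= mask[(start + i) % 16]
                if not run.any():
                    break
            acc |= run
        cand |= acc

    scores = np.zeros((h, w), dtype=float)
    ys, xs = np.nonzero(cand)
    for y, x in zip(ys, xs):
        scores[y + 3, x + 3] = _arc_score(diffs[:, y, x], threshold, n_contiguous)

    if nms:
        footprint = np.ones((3, 3), dtype=bool)
        footprint[1, 1] = False
        neigh = ndimage.maximum_filter(scores, footprint=footprint, mode="constant", cval=0.0)
        keep = (scores > 0) & (scores > neigh)
    else:
        keep = scores > 0
    out = []
    for y, x in zip(*np.nonzero(keep)):
        out.append(Keypoint(x=float(x), y=float(y), response=float(scores[y, x])))
    return out


# ---------------------------------------------------------------------------
# Harris ranking


def harris_response(image: np.ndarray, x: int, y: int, k: float = 0.04,
                    block: int = 7) -> float | None:
    """Harris measure det(M) - k*trace(M)^2 of the block-summed gradient
    structure tensor at (x, y); None if the block lacks image support."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = block // 2
    if not (r + 1 <= x < w - r - 1 and r + 1 <= y < h - r - 1):
        return None
    win = img[y - r - 1:y + r + 2, x - r - 1:x + r + 2]
    gx = scharr_x(win)[1:-1, 1:-1]
    gy = scharr_y(win)[1:-1, 1:-1]
    sxx = float((gx * gx).sum())
    syy = float((gy * gy).sum())
    sxy = float((gx * gy).sum())
    det = sxx * syy - sxy * sxy
    tr = sxx + syy
    return det - k * tr * tr


# ---------------------------------------------------------------------------
# orientation and descriptor


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    m = dx * dx + dy * dy <= radius * radius
    return dx[m], dy[m]


_ORIENT_DX, _ORIENT_DY = _disk_offsets(_PATCH_R)


def orientation_centroid(image: np.ndarray, x: int, y: int, radius: int = _PATCH_R) -> float:
    """Intensity-centroid orientation: theta = atan2(m01, m10) over the
    circular patch with coordinates centered on the keypoint, mapped to
    [0, 2*pi); 0 by convention when both moments vanish."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if not (radius <= x < w - radius and radius <= y < h - radius):
        raise FeatureError("orientation patch leaves the image")
    if radius == _PATCH_R:
        dx, dy = _ORIENT_DX, _ORIENT_DY
    else:
        dx, dy = _disk_offsets(radius)
    vals = img[y + dy, x + dx]
    m10 = float((dx * vals).sum())
    m01 = float((dy * vals).sum())
    if abs(m10) < 1e-12 and abs(m01) < 1e-12:
        return 0.0
    return float(np.arctan2(m01, m10) % (2.0 * np.pi))


def make_brief_pattern(seed: int = PATTERN_SEED, n_tests: int = 256,
                       patch: int = PATCH_SIZE) -> np.ndarray:
    """(n_tests, 4) integer test pairs (ax, ay, bx, by), drawn once from an
    isotropic Gaussian with sigma = patch/5 and clipped to the patch."""
    rng = np.random.default_rng(seed)
    r = patch // 2
    pts = rng.normal(0.0, patch / 5.0, size=(n_tests, 4))
    return np.clip(np.rint(pts), -r, r).astype(int)


_DEFAULT_PATTERN = make_brief_pattern()


def brief_describe(image: np.ndarray, x: int, y: int,
                   pattern: np.ndarray | None = None, theta: float = 0.0) -> np.ndarray:
    """Steered BRIEF: bit i = 1 iff I(p + R_theta a_i) < I(p + R_theta b_i),
    offsets rounded to the pixel grid and clipped to the 31x31 patch.
    Returns the packed 32-byte descriptor."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if not (_PATCH_R <= x < w - _PATCH_R and _PATCH_R <= y < h - _PATCH_R):
        raise FeatureError("BRIEF patch leaves the image")
    pat = _DEFAULT_PATTERN if pattern is None else pattern
    c, s = np.cos(theta), np.sin(theta)
    ax = np.clip(np.rint(c * pat[:, 0] - s * pat[:, 1]), -_PATCH_R, _PATCH_R).astype(int)
    ay = np.clip(np.rint(s * pat[:, 0] + c * pat[:, 1]), -_PATCH_R, _PATCH_R).astype(int)
    bx = np.clip(np.rint(c * pat[:, 2] - s * pat[:, 3]), -_PATCH_R, _PATCH_R).astype(int)
    by = np.clip(np.rint(s * pat[:, 2] + c * pat[:, 3]), -_PATCH_R, _PATCH_R).astype(int)
    bits = img[y + ay, x + ax] < img[y + by, x + bx]
    return np.packbits(bits.astype(np.uint8))


# ---------------------------------------------------------------------------
# full extractor


def orb_extract(image: BinarySilhouette | np.ndarray,
                params: OrbParams | None = None) -> tuple[list[Keypoint], DescriptorSet]:
    """Run the full ORB-style pipeline on a silhouette or grayscale image.

    Builds the scale pyramid, detects FAST corners per level, ranks them by
    Harris response keeping the top ``n_features`` overall, estimates the
    intensity-centroid orientation, and computes steered BRIEF descriptors.
    Keypoint coordinates are reported at base resolution. Deterministic.
    """
    p = params or OrbParams()
    base = image.to_intensity() if isinstance(image, BinarySilhouette) else np.asarray(image, dtype=float)
    h0, w0 = base.shape
    pattern = make_brief_pattern(p.pattern_seed) if p.pattern_seed != PATTERN_SEED else _DEFAULT_PATTERN

    found: list[tuple[float, int, int, int, float]] = []  # (response, level, x, y, factor)
    level_imgs: list[tuple[np.ndarray, np.ndarray]] = []  # (detect_img, describe_img)
    for level in range(p.n_levels):
        factor = p.scale_factor ** level
        hl, wl = int(round(h0 / factor)), int(round(w0 / factor))
        if hl < 2 * _MARGIN + 2 or wl < 2 * _MARGIN + 2:
            break
        lvl = base if level == 0 else resize(base, (hl, wl), order=1, anti_aliasing=True, mode="edge")
        det_img = gaussian(lvl, p.detect_sigma)
        desc_img = gaussian(lvl, p.describe_sigma)
        level_imgs.append((det_img, desc_img))
        for kp in fast_detect(det_img, p.fast_threshold, p.n_contiguous):
            x, y = int(kp.x), int(kp.y)
            if not (_MARGIN <= x < wl - _MARGIN and _MARGIN <= y < hl - _MARGIN):
                continue
            resp = harris_response(det_img, x, y, p.harris_k, p.harris_block)
            if resp is None:
                continue
            found.append((resp, level, x, y, factor))

    if not found:
        raise InsufficientFeaturesError("no ORB keypoints detected")
    found.sort(key=lambda t: (-t[0], t[4] * t[3], t[4] * t[2]))
    found = found[: p.n_features]

    keypoints: list[Keypoint] = []
    descs: list[np.ndarray] = []
    for resp, level, x, y, factor in found:
        det_img, desc_img = level_imgs[level]
        theta = orientation_centroid(det_img, x, y)
        d = brief_describe(desc_img, x, y, pattern, theta)
        keypoints.append(Keypoint(
            x=x * factor, y=y * factor, octave=level,
            scale=PATCH_SIZE * factor, angle=theta, response=resp,
        ))
        descs.append(d)

    order = sorted(range(len(keypoints)),
                   key=lambda i: (-keypoints[i].response, keypoints[i].y, keypoints[i].x))
    keypoints = [keypoints[i] for i in order]
    bits = np.stack([descs[i] for i in order])
    return keypoints, DescriptorSet(bits=bits, nbits=256, method="orb")
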