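"""Synthetic frontal-sinus silhouette cohorts.

Real antemortem/postmortem CT of the frontal sinus is not publicly
deposited, so this module generates silhouettes with the statistical
structure the identification analysis relies on:

* high between-individual shape variance — each case is a bilobed /
  scalloped outline drawn from a radial lobe model with random lobe sizes,
  scallop frequencies and phases;
* small within-individual perturbation between the AM and the PM image —
  a rigid rotation + translation plus a morphological erosion/dilation
  that emulates slice-selection jitter;
* an optional fraction of near-rectangular "simple" sinuses, the shape
  class known to cause false-positive matches.

Everything is a pure function of the root seed: per-case generator streams
are derived as ``default_rng([seed, stream, case_index, ...])`` so cohorts
are extensible without reshuffling earlier cases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk, erosion

from .silhouette import CANVAS_HEIGHT, CANVAS_WIDTH, BinarySilhouette, from_mask

# sub-stream tags for seed derivation
_STREAM_SHAPE = 0
_STREAM_PERTURB = 1
_STREAM_COVARIATES = 2

_BORDER_MARGIN = 2  # silhouette foreground must stay this far from the canvas edge
_MAX_PERTURB_RETRIES = 10


class SynthParamError(ValueError):
    pass


class PerturbationError(RuntimeError):
    """Perturbation repeatedly pushed the foreground off-canvas."""


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the silhouette generator.

    The perturbation defaults (rotation <= 3 degrees, shift <= 2 px,
    morphological radius <= 1 px) model the small AM/PM differences left
    after an examiner picks the most similar PM slice.
    """

    n_lobes: int = 2
    scallop_amp: float = 0.25
    asymmetry: float = 0.6
    perturb_rot_deg: float = 3.0
    perturb_shift_px: float = 2.0
    perturb_morph_px: int = 1
    simple_shape_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_lobes <= 4):
            raise SynthParamError(f"n_lobes must be in 1..4, got {self.n_lobes}")
        if not (0.0 <= self.scallop_amp <= 0.5):
            raise SynthParamError(f"scallop_amp must be in [0, 0.5], got {self.scallop_amp}")
        if not (0.2 <= self.asymmetry <= 1.0):
            raise SynthParamError(f"asymmetry must be in [0.2, 1], got {self.asymmetry}")
        if not (0.0 <= self.simple_shape_frac <= 1.0):
            raise SynthParamError("simple_shape_frac must be in [0, 1]")
        for name in ("perturb_rot_deg", "perturb_shift_px"):
            if getattr(self, name) < 0:
                raise SynthParamError(f"{name} must be >= 0")
        if self.perturb_morph_px < 0:
            raise SynthParamError("perturb_morph_px must be >= 0")


@dataclass(frozen=True)
class CovariateSpec:
    """Case covariate distribution; defaults mirror a 180-case forensic
    cohort: 135/180 male, 125/180 with an AM-PM interval under 30 days,
    81/180 under 60 years old, ages 19-98, intervals 3-1920 days."""

    male_frac: float = 135 / 180
    short_interval_frac: float = 125 / 180
    under60_frac: float = 81 / 180
    age_range: tuple[int, int] = (19, 98)
    interval_range: tuple[int, int] = (3, 1920)


# ---------------------------------------------------------------------------
# shape synthesis


def _lobe_polygon(rng: np.random.Generator, ax: float, ay: float,
                  scallop_amp: float, n_vertices: int = 240) -> np.ndarray:
    """Radial polygon of one lobe: an ellipse whose radius is modulated by
    a random-frequency sinusoidal scallop. Returns (n, 2) array of (x, y)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    # polar radius of an axis-aligned ellipse
    r = ax * ay / np.sqrt((ay * np.cos(phi)) ** 2 + (ax * np.sin(phi)) ** 2)
    if scallop_amp > 0:
        freq = rng.integers(4, 10)
        phase = rng.uniform(0, 2 * np.pi)
        amp = scallop_amp * rng.uniform(0.6, 1.0)
        r = r * (1.0 + amp * np.sin(freq * phi + phase))
    else:
        rng.integers(4, 10)  # keep the stream layout identical
        rng.uniform(0, 2 * np.pi)
        rng.uniform(0.6, 1.0)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _rasterize(polys: list[np.ndarray], bridges: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Fill lobe polygons and connecting bridges onto the canvas."""
    fg = np.zeros((CANVAS_HEIGHT, CANVAS_WIDTH), dtype=bool)
    for pts in polys:
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=fg.shape)
        fg[rr, cc] = True
    for (seg, half_h) in bridges:
        (x0, y0), (x1, y1) = seg
        quad = np.array([
            [x0, y0 - half_h], [x1, y1 - half_h],
            [x1, y1 + half_h], [x0, y0 + half_h],
        ])
        rr, cc = draw_polygon(quad[:, 1], quad[:, 0], shape=fg.shape)
        fg[rr, cc] = True
    return fg


def _fit_and_center(polys: list[np.ndarray], bridges, jitter: np.ndarray) -> tuple[list, list]:
    """Uniformly scale + translate the analytic geometry so the outline fits
    the canvas with a safety margin, centered near the canvas middle."""
    allpts = np.vstack(polys)
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = hi - lo
    budget = np.array([CANVAS_WIDTH - 2 * (_BORDER_MARGIN + 3),
                       CANVAS_HEIGHT - 2 * (_BORDER_MARGIN + 3)], dtype=float)
    s = min(1.0, float(np.min(budget / np.maximum(span, 1e-9))))
    center = (lo + hi) / 2.0
    target = np.array([CANVAS_WIDTH / 2.0, CANVAS_HEIGHT / 2.0]) + jitter
    polys2 = [(p - center) * s + target for p in polys]
    bridges2 = [(((np.asarray(seg) - center) * s + target), half_h * s) for seg, half_h in bridges]
    return polys2, bridges2


def _simple_rectangle(rng: np.random.Generator) -> np.ndarray:
    """Near-rectangular sinus: the documented false-positive risk shape."""
    w = rng.uniform(110, 165)
    h = rng.uniform(45, 75)
    cx = CANVAS_WIDTH / 2 + rng.uniform(-4, 4)
    cy = CANVAS_HEIGHT / 2 + rng.uniform(-4, 4)
    # slight wobble on the long edges so the outline is not pixel-perfect
    n = 60
    xs = np.linspace(-w / 2, w / 2, n)
    wob_t = rng.uniform(0, 2 * np.pi)
    wob_a = rng.uniform(0.3, 1.0)
    top = np.column_stack([cx + xs, cy - h / 2 + wob_a * np.sin(2 * np.pi * xs / w + wob_t)])
    bot = np.column_stack([cx + xs[::-1], cy + h / 2 + wob_a * np.sin(2 * np.pi * xs[::-1] / w - wob_t)])
    pts = np.vstack([top, bot])
    fg = np.zeros((CANVAS_HEIGHT, CANVAS_WIDTH), dtype=bool)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=fg.shape)
    fg[rr, cc] = True
    return fg


def generate_shape(params: SynthParams, case_index: int) -> BinarySilhouette:
    """Generate the base (antemortem) silhouette of one case.

    Deterministic in ``(params.seed, case_index)``. The foreground is a
    single 4-connected region that touches no canvas border.
    """
    rng = np.random.default_rng([params.seed, _STREAM_SHAPE, case_index])
    simple = rng.random() < params.simple_shape_frac

    if simple:
        fg = _simple_rectangle(rng)
    else:
        n = params.n_lobes
        polys: list[np.ndarray] = []
        centers: list[np.ndarray] = []
        ay_vals: list[float] = []
        # left-to-right lobe scales interpolate asymmetry -> 1
        scales = np.linspace(params.asymmetry, 1.0, n) if n > 1 else np.array([params.asymmetry])
        ax_max = 160.0 / (2 * max(n - 0.3 * (n - 1), 1))  # leave room for overlap
        ay_max = 42.0 / (1.0 + params.scallop_amp)
        x = 0.0
        prev_ax = 0.0
        for i in range(n):
            sc = scales[i]
            ax = sc * ax_max * rng.uniform(0.65, 1.0)
            ay = sc * ay_max * rng.uniform(0.55, 1.0)
            poly = _lobe_polygon(rng, ax, ay, params.scallop_amp)
            if i > 0:
                # spacing keeps adjacent lobes overlapping even at full scallop
                x += 0.8 * (prev_ax + ax) * (1.0 - params.scallop_amp * 0.5)
            cy = rng.uniform(-4.0, 4.0)
            c = np.array([x, cy])
            polys.append(poly + c)
            centers.append(c)
            ay_vals.append(ay)
            prev_ax = ax
        bridges = []
        for i in range(n - 1):
            half_h = 0.3 * min(ay_vals[i], ay_vals[i + 1])
            bridges.append(((centers[i], centers[i + 1]), half_h))
        jitter = rng.uniform(-4.0, 4.0, size=2)
        polys, bridges = _fit_and_center(polys, bridges, jitter)
        fg = _rasterize(polys, bridges)

    # guarantee a single 4-connected component (keep the largest if the
    # rasterization ever splits off slivers)
    lab, nlab = ndimage.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if nlab == 0:
        raise SynthParamError("degenerate parameters produced an empty silhouette")
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return from_mask(fg, case_id=f"case{case_index:04d}", session="AM")


# ---------------------------------------------------------------------------
# AM -> PM perturbation


def _touches_border(fg: np.ndarray) -> bool:
    return bool(fg[0, :].any() or fg[-1, :].any() or fg[:, 0].any() or fg[:, -1].any())


def perturb_shape(img: BinarySilhouette, params: SynthParams, pair_seed: int) -> BinarySilhouette:
    """Render the postmortem counterpart of a silhouette.

    Applies a rigid rotation about the foreground centroid
    (~U(-rot, +rot) degrees), a per-axis translation (~U(-shift, +shift)
    pixels) and a morphological erosion or dilation with radius drawn
    uniformly from {0..perturb_morph_px}, then re-binarizes with
    nearest-neighbour sampling. Deterministic in (params.seed, pair_seed).
    """
    rng = np.random.default_rng([params.seed, _STREAM_PERTURB, pair_seed])
    fg = img.foreground
    cy, cx = ndimage.center_of_mass(fg)

    for _ in range(_MAX_PERTURB_RETRIES):
        rot = np.deg2rad(rng.uniform(-params.perturb_rot_deg, params.perturb_rot_deg))
        shift = rng.uniform(-params.perturb_shift_px, params.perturb_shift_px, size=2)  # (dx, dy)
        radius = int(rng.integers(0, params.perturb_morph_px + 1))
        dilate = bool(rng.integers(0, 2))

        if rot == 0.0 and shift[0] == 0.0 and shift[1] == 0.0:
            out = fg.copy()
        else:
            c, s = np.cos(rot), np.sin(rot)
            rot_mat = np.array([[c, -s], [s, c]])  # acts on (row, col)
            center = np.array([cy, cx])
            offset = center - rot_mat @ (center + shift[::-1])
            out = ndimage.affine_transform(
                fg.astype(np.uint8), rot_mat, offset=offset, order=0,
                mode="constant", cval=0,
            ).astype(bool)
        if radius > 0:
            footprint = disk(radius)
            out = (dilation(out, footprint) if dilate else erosion(out, footprint)).astype(bool)
        if out.any() and not out.all() and not _touches_border(out):
            return from_mask(out, case_id=img.case_id, session="PM")
    raise PerturbationError(
        f"perturbation kept pushing case {img.case_id!r} off-canvas "
        f"after {_MAX_PERTURB_RETRIES} attempts"
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """In-memory cohort: one AM and one PM silhouette per case plus the
    covariate manifest (case_id, sex, age_years, interval_days [, paths])."""

    manifest: pd.DataFrame
    images: dict[tuple[str, str], BinarySilhouette]  # (case_id, "AM"/"PM") -> image

    def case_ids(self) -> list[str]:
        return list(self.manifest["case_id"])

    def image(self, case_id: str, session: str) -> BinarySilhouette:
        return self.images[(case_id, session)]


def _assign_covariates(n_cases: int, spec: CovariateSpec, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng([seed, _STREAM_COVARIATES])
    n_male = int(round(spec.male_frac * n_cases))
    sex = np.array(["M"] * n_male + ["F"] * (n_cases - n_male))
    rng.shuffle(sex)

    n_short = int(round(spec.short_interval_frac * n_cases))
    short = np.array([True] * n_short + [False] * (n_cases - n_short))
    rng.shuffle(short)
    lo, hi = spec.interval_range
    interval = np.where(short,
                        rng.integers(lo, 30, size=n_cases),
                        rng.integers(30, hi + 1, size=n_cases))

    n_young = int(round(spec.under60_frac * n_cases))
    young = np.array([True] * n_young + [False] * (n_cases - n_young))
    rng.shuffle(young)
    alo, ahi = spec.age_range
    age = np.where(young,
                   rng.integers(alo, 60, size=n_cases),
                   rng.integers(60, ahi + 1, size=n_cases))

    return pd.DataFrame({
        "case_id": [f"case{i:04d}" for i in range(n_cases)],
        "sex": sex,
        "age_years": age.astype(int),
        "interval_days": interval.astype(int),
    })


def generate_cohort(
    n_cases: int,
    params: SynthParams,
    covariate_spec: CovariateSpec | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a full synthetic AM/PM cohort.

    For each case the AM silhouette comes from :func:`generate_shape` and
    the PM one from :func:`perturb_shape` (pair_seed = case index). If
    ``out_dir`` is given, images are written as 8-bit PNG and the manifest
    as ``manifest.csv`` with columns case_id, am_path, pm_path, sex,
    age_years, interval_days.
    """
    if n_cases < 2:
        raise SynthParamError("n_cases must be >= 2")
    spec = covariate_spec or CovariateSpec()
    manifest = _assign_covariates(n_cases, spec, params.seed)

    images: dict[tuple[str, str], BinarySilhouette] = {}
    for i, case_id in enumerate(manifest["case_id"]):
        am = generate_shape(params, i)
        pm = perturb_shape(am, params, pair_seed=i)
        images[(case_id, "AM")] = am
        images[(case_id, "PM")] = pm

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        am_paths, pm_paths = [], []
        for case_id in manifest["case_id"]:
            ap = out / f"{case_id}_AM.png"
            pp = out / f"{case_id}_PM.png"
            images[(case_id, "AM")].save(ap)
            images[(case_id, "PM")].save(pp)
            # manifest keeps paths relative to its own directory so cohorts
            # are relocatable and byte-reproducible
            am_paths.append(ap.name)
            pm_paths.append(pp.name)
        manifest = manifest.assign(am_path=am_paths, pm_path=pm_paths)
        manifest = manifest[["case_id", "am_path", "pm_path", "sex", "age_years", "interval_days"]]
        manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump({"n_cases": n_cases, "params": dataclasses.asdict(params)}, fh, indent=2)

    return Cohort(manifest=manifest, images=images)


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort written by :func:`generate_cohort` (or hand-assembled
    with the same manifest schema)."""
    manifest = pd.read_csv(manifest_path)
    required = {"case_id", "am_path", "pm_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = Path(manifest_path).parent
    images = {}
    for _, row in manifest.iterrows():
        for session, col in (("AM", "am_path"), ("PM", "pm_path")):
            p = Path(row[col])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"image listed in manifest not found: {p}")
            images[(row["case_id"], session)] = BinarySilhouette.load(
                p, case_id=row["case_id"], session=session
            )
    return Cohort(manifest=manifest, images=images)
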