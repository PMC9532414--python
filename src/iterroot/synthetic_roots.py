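"""Procedural generation of root-like images with ground-truth masks.

Emulates 2D images of plant root systems grown on dark filter paper:
thin, bright, branching curves of decreasing thickness hanging downward
from near the top of the frame, over a dark lightly-textured background,
with non-root distractors (semi-transparent water droplets, dust specks,
a thick plant stem) that belong to the *background* class.  Every sample
is a pure function of its :class:`RootSceneSpec`, including the seed, so
tests and training sets are reproducible bit for bit.

Root skeletons are grown as depth-limited branching random walks with a
downward drift; masks are rasterized by stamping disks along each
polyline with a radius that shrinks multiplicatively per branch
generation; images are rendered from the mask plus distractors and
sensor noise.  Distractors are drawn after the roots and may occlude
them in the image but never touch the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage


class SceneValidationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RootSceneSpec:
    height_px: int = 512
    width_px: int = 512
    n_primary_roots: int = 3
    step_length_px: float = 4.0
    max_steps: int = 120
    branch_prob_per_step: float = 0.035
    max_branch_depth: int = 3
    curvature_noise_sd: float = 0.15     # radians per step
    initial_thickness_px: float = 4.0
    thickness_decay: float = 0.72        # per branch generation
    root_intensity_mean: float = 0.75
    root_intensity_sd: float = 0.04
    background_mean: float = 0.12
    background_sd: float = 0.03
    sensor_noise_sd: float = 0.015
    droplet_count: int = 3
    dust_count: int = 25
    droplet_radius_range_px: tuple[float, float] = (6.0, 18.0)
    include_stem: bool = True
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("height_px", self.height_px >= 64),
            ("width_px", self.width_px >= 64),
            ("n_primary_roots", self.n_primary_roots >= 1),
            ("step_length_px", self.step_length_px > 0),
            ("max_steps", self.max_steps >= 1),
            ("branch_prob_per_step", 0.0 <= self.branch_prob_per_step <= 1.0),
            ("max_branch_depth", self.max_branch_depth >= 0),
            ("curvature_noise_sd", self.curvature_noise_sd >= 0),
            ("initial_thickness_px", self.initial_thickness_px >= 1.0),
            ("thickness_decay", 0.0 < self.thickness_decay <= 1.0),
            ("root_intensity_mean", 0.0 <= self.root_intensity_mean <= 1.0),
            ("root_intensity_sd", 0.0 <= self.root_intensity_sd <= 1.0),
            ("background_mean", 0.0 <= self.background_mean <= 1.0),
            ("background_sd", 0.0 <= self.background_sd <= 1.0),
            ("sensor_noise_sd", 0.0 <= self.sensor_noise_sd <= 1.0),
            ("droplet_count", self.droplet_count >= 0),
            ("dust_count", self.dust_count >= 0),
            ("droplet_radius_range_px",
             0 < self.droplet_radius_range_px[0] <= self.droplet_radius_range_px[1]),
            ("seed", self.seed >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise SceneValidationError(
                    f"invalid RootSceneSpec field {name!r}: {getattr(self, name)!r}")


@dataclass(frozen=True)
class Polyline:
    """One root segment: (k, 2) float array of (row, col) points."""

    points: np.ndarray
    depth: int = 0       # branch generation, 0 = primary root
    tree: int = 0        # index of the primary root this belongs to


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray            # (H, W, 3) float in [0, 1]
    mask: np.ndarray             # (H, W) uint8 in {0, 1}
    skeleton: list[Polyline]
    spec: RootSceneSpec


# ----------------------------------------------------------------------
# skeleton growth
# ----------------------------------------------------------------------

def _grow(spec: RootSceneSpec, rng: np.random.Generator,
          start: np.ndarray, heading: float, depth: int, steps_left: int,
          tree: int, out: list[Polyline]) -> None:
    """Grow one walk; recursion order fixes the rng draw order.

    Per step the draws are: heading noise, branch decision, and (on a
    branch) the child's branching angle; the child is grown immediately,
    consuming its own draws before the parent resumes.
    """
    pts = [start.copy()]
    pos = start.copy()
    h, w = spec.height_px, spec.width_px
    step = 0
    while step < steps_left:
        heading = 0.95 * heading + rng.normal(0.0, spec.curvature_noise_sd)
        pos = pos + spec.step_length_px * np.array(
            [math.cos(heading), math.sin(heading)])
        if not (0 <= pos[0] <= h - 1 and 0 <= pos[1] <= w - 1):
            break
        pts.append(pos.copy())
        step += 1
        if depth < spec.max_branch_depth and \
                rng.random() < spec.branch_prob_per_step:
            side = 1.0 if rng.random() < 0.5 else -1.0
            angle = rng.uniform(0.35, 1.0)
            _grow(spec, rng, pos, heading + side * angle, depth + 1,
                  steps_left - step, tree, out)
    out.append(Polyline(points=np.array(pts, dtype=np.float64),
                        depth=depth, tree=tree))


def generate_skeleton(spec: RootSceneSpec,
                      rng: np.random.Generator) -> list[Polyline]:
    """Branching random walks with downward drift, one tree per primary root.

    Heading 0 points straight down; per step it relaxes toward vertical
    and is perturbed by Gaussian noise of sd ``curvature_noise_sd``.
    Children spawn with probability ``branch_prob_per_step`` up to
    ``max_branch_depth`` generations; each child inherits the remaining
    step budget of its parent.
    """
    out: list[Polyline] = []
    for tree in range(spec.n_primary_roots):
        col = rng.uniform(0.15 * spec.width_px, 0.85 * spec.width_px)
        row = rng.uniform(2.0, 0.06 * spec.height_px)
        heading = rng.normal(0.0, 0.2)
        _grow(spec, rng, np.array([row, col]), heading, 0,
              spec.max_steps, tree, out)
    return out


# ----------------------------------------------------------------------
# rasterization
# ----------------------------------------------------------------------

def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    h, w = mask.shape
    rad = max(radius, 0.5)
    r0, r1 = int(max(0, math.floor(r - rad))), int(min(h - 1, math.ceil(r + rad)))
    c0, c1 = int(max(0, math.floor(c - rad))), int(min(w - 1, math.ceil(c + rad)))
    if r1 < r0 or c1 < c0:
        return
    yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    mask[r0:r1 + 1, c0:c1 + 1] |= ((yy - r) ** 2 + (xx - c) ** 2) <= rad * rad


def rasterize_mask(skeleton: list[Polyline], spec: RootSceneSpec) -> np.ndarray:
    """Disk-stamped strokes; radius shrinks by ``thickness_decay`` per depth."""
    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    for line in skeleton:
        radius = (spec.initial_thickness_px / 2.0) * \
            spec.thickness_decay ** line.depth
        pts = line.points
        for a, b in zip(pts[:-1], pts[1:]):
            seg = b - a
            length = float(np.hypot(*seg))
            n_sub = max(1, int(math.ceil(length / max(radius * 0.5, 0.5))))
            for t in np.linspace(0.0, 1.0, n_sub + 1):
                p = a + t * seg
                _stamp_disk(mask, p[0], p[1], radius)
        if len(pts) == 1:
            _stamp_disk(mask, pts[0][0], pts[0][1], radius)
    return mask.astype(np.uint8)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _low_freq_texture(shape: tuple[int, int], sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        # keep the rng draw count independent of sd
        rng.normal(size=(9, 9))
        return np.zeros(shape, dtype=np.float64)
    coarse = rng.normal(0.0, sd, size=(9, 9))
    zoom = (shape[0] / 9.0, shape[1] / 9.0)
    tex = ndimage.zoom(coarse, zoom, order=3)
    return tex[:shape[0], :shape[1]]


def render_image(mask: np.ndarray, skeleton: list[Polyline],
                 spec: RootSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Grayscale-in-RGB render of a root scene.

    Background: ``background_mean`` plus a low-frequency texture field.
    Root pixels: ``root_intensity_mean`` with per-pixel jitter.  Then the
    distractors (droplets as semi-transparent bright ellipses, dust as
    1-3 px specks, an optional thick stem bar touching the top edge) are
    composited over the image, followed by additive sensor noise and a
    clip to [0, 1].  The mask is never modified here.
    """
    h, w = mask.shape
    img = np.full((h, w), spec.background_mean, dtype=np.float64)
    img += _low_freq_texture((h, w), spec.background_sd, rng)

    fg = mask.astype(bool)
    root_vals = spec.root_intensity_mean + rng.normal(
        0.0, spec.root_intensity_sd, size=int(fg.sum()))
    img[fg] = root_vals

    # --- distractors (image only, never the mask) ---
    for _ in range(spec.droplet_count):
        cy = rng.uniform(0, h - 1)
        cx = rng.uniform(0, w - 1)
        lo, hi = spec.droplet_radius_range_px
        ry, rx = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, math.pi)
        alpha = rng.uniform(0.35, 0.6)
        yy, xx = np.mgrid[0:h, 0:w]
        ct, st = math.cos(theta), math.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        bright = min(1.0, spec.root_intensity_mean + 0.15)
        img[inside] = (1 - alpha) * img[inside] + alpha * bright

    for _ in range(spec.dust_count):
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        size = int(rng.integers(1, 4))
        val = rng.uniform(spec.root_intensity_mean * 0.8,
                          min(1.0, spec.root_intensity_mean + 0.2))
        img[r:min(h, r + size), c:min(w, c + size)] = val

    if spec.include_stem:
        width = max(4, int(round(3.0 * spec.initial_thickness_px)))
        col = int(rng.uniform(0.25 * w, 0.75 * w))
        length = int(rng.uniform(0.15 * h, 0.35 * h))
        c0 = max(0, col - width // 2)
        c1 = min(w, col + (width - width // 2))
        img[0:length, c0:c1] = min(1.0, spec.root_intensity_mean + 0.1)

    if spec.sensor_noise_sd > 0:
        img += rng.normal(0.0, spec.sensor_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return np.repeat(img[:, :, None], 3, axis=2)


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------

def generate_sample(spec: RootSceneSpec) -> SyntheticSample:
    """Skeleton -> mask -> image, all from one stream seeded by spec.seed."""
    rng = np.random.default_rng(spec.seed)
    skeleton = generate_skeleton(spec, rng)
    mask = rasterize_mask(skeleton, spec)
    frac = float(mask.mean())
    if not (0.0 < frac < 0.5):
        raise GenerationError(
            f"mask foreground fraction {frac:.3f} outside (0, 0.5); "
            "adjust the scene spec")
    image = render_image(mask, skeleton, spec, rng)
    return SyntheticSample(image=image, mask=mask, skeleton=skeleton, spec=spec)


def generate_dataset(spec_template: RootSceneSpec, n: int,
                     split_fractions: tuple[float, float, float],
                     out_dir) -> pd.DataFrame:
    """Write ``n`` image/mask PNG pairs plus a manifest CSV.

    Sample i uses seed ``spec_template.seed + i``.  Split labels
    (train/test/validation) are apportioned by largest remainder and
    assigned by a seeded shuffle; regenerating with the same template
    reproduces files and manifest exactly.
    """
    from pathlib import Path

    from .pipeline import write_image, write_mask

    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    labels = ("train", "test", "validation")
    raw = [f * n for f in split_fractions]
    counts = [int(math.floor(x)) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    for i in sorted(range(3), key=lambda i: (-remainders[i], i))[: n - sum(counts)]:
        counts[i] += 1
    assignment = [lab for lab, k in zip(labels, counts) for _ in range(k)]
    rng = np.random.default_rng(spec_template.seed)
    rng.shuffle(assignment)

    rows = []
    for i in range(n):
        sample = generate_sample(replace(spec_template, seed=spec_template.seed + i))
        img_path = out_dir / f"sample_{i:04d}.png"
        msk_path = out_dir / f"sample_{i:04d}_mask.png"
        write_image(sample.image, img_path)
        write_mask(sample.mask, msk_path)
        rows.append({"image_path": str(img_path), "mask_path": str(msk_path),
                     "split": assignment[i]})
    manifest = pd.DataFrame(rows, columns=["image_path", "mask_path", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
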