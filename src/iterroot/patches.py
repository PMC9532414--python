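"""Overlapping patch grids and majority-vote reassembly.

Full images are segmented patch-wise: the image is reflect-padded, tiled
with ``patch_size`` x ``patch_size`` windows at a fixed ``stride`` (default
256/128, i.e. 50% overlap), each patch is segmented independently, and the
hard per-patch labels are combined per pixel by strict majority vote with
ties resolved to background.

Padding rule: ``patch_size - stride`` pixels on every side, plus the
minimum extra on the bottom/right so the padded extent is a multiple of
the stride.  Under this rule every *original* pixel falls in exactly
``(patch_size / stride)**2`` patches (4 under defaults), which makes the
tie-to-background rule reachable everywhere, including image borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    stride: int
    pad_top: int
    pad_bottom: int
    pad_left: int
    pad_right: int
    origins: tuple[tuple[int, int], ...]
    original_height: int
    original_width: int

    @property
    def padded_height(self) -> int:
        return self.original_height + self.pad_top + self.pad_bottom

    @property
    def padded_width(self) -> int:
        return self.original_width + self.pad_left + self.pad_right

    @property
    def cover(self) -> int:
        """Patches covering each original pixel along one axis, squared."""
        return (self.patch_size // self.stride) ** 2


@dataclass
class VoteAccumulator:
    """Per-pixel foreground votes and coverage, in original coordinates."""

    foreground_votes: np.ndarray
    coverage: np.ndarray

    @classmethod
    def for_grid(cls, grid: PatchGrid) -> "VoteAccumulator":
        shape = (grid.original_height, grid.original_width)
        return cls(np.zeros(shape, dtype=np.int32), np.zeros(shape, dtype=np.int32))

    def add_patch(self, grid: PatchGrid, origin: tuple[int, int],
                  patch_label: np.ndarray) -> None:
        """Accumulate one binary patch prediction (padded coordinates)."""
        r0, c0 = origin
        p = grid.patch_size
        # patch window intersected with the original-image region
        rr0 = max(r0, grid.pad_top) - grid.pad_top
        cc0 = max(c0, grid.pad_left) - grid.pad_left
        rr1 = min(r0 + p, grid.pad_top + grid.original_height) - grid.pad_top
        cc1 = min(c0 + p, grid.pad_left + grid.original_width) - grid.pad_left
        if rr1 <= rr0 or cc1 <= cc0:
            return
        pr0 = rr0 + grid.pad_top - r0
        pc0 = cc0 + grid.pad_left - c0
        sub = patch_label[pr0:pr0 + (rr1 - rr0), pc0:pc0 + (cc1 - cc0)]
        self.foreground_votes[rr0:rr1, cc0:cc1] += (sub > 0)
        self.coverage[rr0:rr1, cc0:cc1] += 1


def make_grid(height: int, width: int, patch_size: int = 256,
              stride: int = 128) -> PatchGrid:
    """Deterministic overlapping-patch layout for an height x width image."""
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be positive")
    if patch_size % stride != 0:
        raise ValueError(
            f"patch_size ({patch_size}) must be a multiple of stride ({stride})")
    margin = patch_size - stride
    pad_top = pad_left = margin
    pad_bottom = margin + (-height) % stride
    pad_right = margin + (-width) % stride
    ph = height + pad_top + pad_bottom
    pw = width + pad_left + pad_right
    rows = range(0, ph - patch_size + 1, stride)
    cols = range(0, pw - patch_size + 1, stride)
    origins = tuple((r, c) for r in rows for c in cols)
    return PatchGrid(patch_size=patch_size, stride=stride,
                     pad_top=pad_top, pad_bottom=pad_bottom,
                     pad_left=pad_left, pad_right=pad_right,
                     origins=origins,
                     original_height=height, original_width=width)


def pad_image(image: np.ndarray, grid: PatchGrid, mode: str = "reflect") -> np.ndarray:
    pads = [(grid.pad_top, grid.pad_bottom), (grid.pad_left, grid.pad_right)]
    pads += [(0, 0)] * (image.ndim - 2)
    if mode == "reflect":
        return np.pad(image, pads, mode="reflect")
    if mode == "zero":
        return np.pad(image, pads, mode="constant")
    raise ValueError(f"unknown padding mode {mode!r}")


def extract_patches(image: np.ndarray, grid: PatchGrid,
                    pad_mode: str = "reflect") -> np.ndarray:
    """Stack of patches in ``grid.origins`` order; shape (n, p, p[, channels])."""
    if image.shape[:2] != (grid.original_height, grid.original_width):
        raise ValueError(
            f"image shape {image.shape[:2]} does not match grid "
            f"({grid.original_height}, {grid.original_width})")
    padded = pad_image(image, grid, mode=pad_mode)
    p = grid.patch_size
    return np.stack([padded[r:r + p, c:c + p] for r, c in grid.origins])


def sample_training_patches(image: np.ndarray, mask: np.ndarray, n: int,
                            rng: np.random.Generator,
                            patch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Random training patches cropped around the root system.

    Both arrays are first cropped to the mask's bounding box, expanded to
    at least ``patch_size`` per side (reflect-padding if the image itself
    is smaller), then ``n`` patch origins are drawn uniformly.
    Returns (image_patches, mask_patches) with matching order.
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask dimensions differ")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError(
            "mask is empty: sample background patches directly instead of "
            "root-centred training patches")
    h, w = mask.shape[:2]

    def expand(lo, hi, size, limit):
        need = max(0, size - (hi - lo))
        lo = max(0, lo - need // 2)
        hi = min(limit, max(hi + (need - need // 2), lo + size))
        lo = max(0, min(lo, hi - size))
        return lo, hi

    r0, r1 = expand(int(rows[0]), int(rows[-1]) + 1, patch_size, h)
    c0, c1 = expand(int(cols[0]), int(cols[-1]) + 1, patch_size, w)
    img_crop = image[r0:r1, c0:c1]
    msk_crop = mask[r0:r1, c0:c1]
    ch, cw = msk_crop.shape[:2]
    if ch < patch_size or cw < patch_size:
        pr, pc = max(0, patch_size - ch), max(0, patch_size - cw)
        pads2 = [(0, pr), (0, pc)]
        img_crop = np.pad(img_crop, pads2 + [(0, 0)] * (img_crop.ndim - 2),
                          mode="reflect")
        msk_crop = np.pad(msk_crop, pads2, mode="reflect")
        ch, cw = msk_crop.shape[:2]
    top = rng.integers(0, ch - patch_size + 1, size=n)
    left = rng.integers(0, cw - patch_size + 1, size=n)
    imgs = np.stack([img_crop[r:r + patch_size, c:c + patch_size]
                     for r, c in zip(top, left)])
    msks = np.stack([msk_crop[r:r + patch_size, c:c + patch_size]
                     for r, c in zip(top, left)])
    return imgs, msks


def reassemble(vote: VoteAccumulator) -> np.ndarray:
    """Strict-majority binary mask: foreground iff votes > coverage / 2.

    With the default 4-cover this requires at least 3 of 4 foreground
    labels; a 2-2 tie resolves to background.
    """
    votes = np.asarray(vote.foreground_votes)
    cover = np.asarray(vote.coverage)
    if votes.shape != cover.shape:
        raise ValueError("vote/coverage shape mismatch")
    if (cover <= 0).any():
        raise ValueError("coverage must be positive everywhere")
    if (votes > cover).any():
        raise ValueError("foreground votes exceed coverage")
    return (2 * votes > cover).astype(np.uint8)
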