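"""Image I/O, the full-image segmentation pipeline, and dataset evaluation.

Full-image segmentation: reflect-pad, tile into overlapping patches,
run the network on every patch, binarize each final probability map,
accumulate per-pixel foreground votes, reassemble by strict majority
(ties -> background) and crop the padding away.  Output dimensions always
equal input dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import nn
from .loss_metrics import score_pair
from .network import IterRoot
from .nn import Tensor
from .patches import VoteAccumulator, extract_patches, make_grid, reassemble

SPLIT_LABELS = ("train", "test", "validation", "holdout")


class ImageIOError(IOError):
    pass


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------

def _load_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix not in (".png", ".tif", ".tiff"):
        raise ImageIOError(f"unsupported image format {suffix!r}: {path}")
    try:
        if suffix in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific
        raise ImageIOError(f"could not read {path}: {exc}") from exc


def _to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise ImageIOError(f"unsupported bit depth {arr.dtype}")


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF image as (H, W, 3) floats in [0, 1]."""
    arr = _load_array(Path(path))
    arr = _to_unit(arr)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ImageIOError(f"unexpected image shape {arr.shape}: {path}")
    return arr


def read_mask(path) -> np.ndarray:
    """Load a mask as (H, W) uint8 in {0, 1} (midpoint binarization)."""
    arr = _load_array(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (_to_unit(arr) > 0.5).astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    """Write an [0, 1] float image as 8-bit RGB PNG/TIFF."""
    path = Path(path)
    data = np.clip(np.asarray(image), 0.0, 1.0)
    out = np.round(data * 255.0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as single-channel {0, 255} PNG/TIFF."""
    path = Path(path)
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def segment_image(model: IterRoot, image: np.ndarray,
                  patch_size: int = 256, stride: int = 128,
                  threshold: float | None = None, batch_size: int = 4,
                  pad_mode: str = "reflect",
                  vote_mode: str = "hard") -> np.ndarray:
    """Patch-wise segmentation of an arbitrary-size image.

    ``vote_mode="hard"`` binarizes each patch at ``threshold`` (defaults
    to the model's configured threshold) and takes a strict per-pixel
    majority; ``"average"`` averages probabilities over covering patches
    and thresholds once (experimental alternative).
    """
    div = model.config.divisibility
    if patch_size % div:
        raise ValueError(f"patch_size must be divisible by {div}")
    if threshold is None:
        threshold = model.config.binarize_threshold
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    h, w = image.shape[:2]
    grid = make_grid(h, w, patch_size, stride)
    stack = extract_patches(image, grid, pad_mode=pad_mode)

    model.eval()
    probs = np.empty((len(stack), patch_size, patch_size), dtype=np.float32)
    with nn.no_grad():
        for i in range(0, len(stack), batch_size):
            xb = Tensor(stack[i:i + batch_size].transpose(0, 3, 1, 2))
            probs[i:i + batch_size] = model(xb)[-1].data[:, 0]

    vote = VoteAccumulator.for_grid(grid)
    if vote_mode == "hard":
        for origin, p in zip(grid.origins, probs):
            vote.add_patch(grid, origin, (p >= threshold).astype(np.uint8))
        return reassemble(vote)
    if vote_mode == "average":
        acc = np.zeros((h, w), dtype=np.float64)
        cnt = np.zeros((h, w), dtype=np.int32)
        for (r0, c0), p in zip(grid.origins, probs):
            rr0 = max(r0, grid.pad_top) - grid.pad_top
            cc0 = max(c0, grid.pad_left) - grid.pad_left
            rr1 = min(r0 + patch_size, grid.pad_top + h) - grid.pad_top
            cc1 = min(c0 + patch_size, grid.pad_left + w) - grid.pad_left
            if rr1 <= rr0 or cc1 <= cc0:
                continue
            pr0, pc0 = rr0 + grid.pad_top - r0, cc0 + grid.pad_left - c0
            acc[rr0:rr1, cc0:cc1] += p[pr0:pr0 + rr1 - rr0, pc0:pc0 + cc1 - cc0]
            cnt[rr0:rr1, cc0:cc1] += 1
        return ((acc / cnt) >= threshold).astype(np.uint8)
    raise ValueError(f"unknown vote_mode {vote_mode!r}")


# ----------------------------------------------------------------------
# manifests and evaluation
# ----------------------------------------------------------------------

@dataclass
class DatasetManifest:
    rows: pd.DataFrame

    @classmethod
    def load(cls, path, require_exists: bool = True) -> "DatasetManifest":
        df = pd.read_csv(path)
        required = {"image_path", "split"}
        if not required <= set(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        bad = set(df["split"]) - set(SPLIT_LABELS)
        if bad:
            raise ValueError(f"unknown split labels {sorted(bad)}; "
                             f"allowed: {SPLIT_LABELS}")
        if require_exists:
            base = Path(path).parent
            for col in ("image_path", "mask_path"):
                if col not in df.columns:
                    continue
                resolved = []
                for p in df[col]:
                    if pd.isna(p):
                        resolved.append(p)
                        continue
                    cand = Path(p)
                    if not cand.is_absolute() and not cand.exists():
                        cand = base / p
                    if not cand.exists():
                        raise FileNotFoundError(f"manifest path not found: {p}")
                    resolved.append(str(cand))
                df[col] = resolved
        return cls(df)

    def select(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.rows
        return self.rows[self.rows["split"] == split].reset_index(drop=True)


@dataclass
class EvaluationReport:
    per_image: pd.DataFrame
    summary: pd.DataFrame
    skipped: list[str]

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)

METRICS = ("dsc", "iou", "sensitivity", "specificity", "accuracy")


def _summarize(df: pd.DataFrame, label: str) -> dict:
    row = {"group": label, "n": len(df)}
    for m in METRICS:
        vals = df[m].to_numpy(dtype=float)
        row[f"{m}_mean"] = float(vals.mean())
        row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return row


def evaluate_dataset(model: IterRoot, manifest: DatasetManifest,
                     split: str | None = None, group_by: str | None = None,
                     patch_size: int = 256, stride: int = 128,
                     threshold: float | None = None,
                     log=None) -> EvaluationReport:
    """Segment and score every manifest row of the requested split.

    Rows without a ground-truth mask are skipped with a warning and
    listed in the report.  The summary holds mean and sample standard
    deviation per metric, overall and per ``group_by`` value.
    """
    rows = manifest.select(split)
    records, skipped = [], []
    for _, row in rows.iterrows():
        mask_path = row.get("mask_path")
        if mask_path is None or (isinstance(mask_path, float) and pd.isna(mask_path)):
            skipped.append(row["image_path"])
            if log is not None:
                log(f"warning: no mask for {row['image_path']}; skipped")
            continue
        image = read_image(row["image_path"])
        truth = read_mask(mask_path)
        pred = segment_image(model, image, patch_size=patch_size,
                             stride=stride, threshold=threshold)
        scores = score_pair(pred, truth)
        rec = {"image_id": Path(row["image_path"]).stem,
               "dsc": scores.dsc, "iou": scores.iou,
               "sensitivity": scores.sensitivity,
               "specificity": scores.specificity,
               "accuracy": scores.accuracy,
               "flags": ";".join(scores.flags)}
        if group_by is not None:
            rec[group_by] = row[group_by]
        records.append(rec)
    per_image = pd.DataFrame(records)
    summaries = []
    if len(per_image):
        summaries.append(_summarize(per_image, "overall"))
        if group_by is not None:
            for value, sub in per_image.groupby(group_by):
                summaries.append(_summarize(sub, str(value)))
    summary = pd.DataFrame(summaries)
    return EvaluationReport(per_image=per_image, summary=summary, skipped=skipped)
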