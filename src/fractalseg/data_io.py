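"""Image/mask I/O, preprocessing, geometric augmentation and splitting.

Conventions: arrays are (row, col), 0-based, origin top-left.  Spacing
is (row_mm, col_mm).  Masks travel as ``metrics.BinaryMask``; images as
``ImageSlice``.  PNG masks are stored as 0/255 uint8; NIfTI masks as
uint8 0/1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .metrics import BinaryMask

__all__ = [
    "ImageSlice",
    "SamplePair",
    "AugmentationPlan",
    "DatasetSplit",
    "FormatError",
    "load_slice",
    "load_mask",
    "save_slice",
    "save_mask",
    "save_pair",
    "load_pair",
    "preprocess",
    "preprocess_pair",
    "augment",
    "split",
    "prepare_dataset",
    "write_manifest",
]

DEFAULT_TRANSFORMS = ("identity", "rotate", "hflip", "vflip", "shift")


class FormatError(IOError):
    """Unreadable or unsupported image file."""


@dataclass(frozen=True)
class ImageSlice:
    """One 2D grayscale slice with physical pixel spacing."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    identifier: str = ""
    source_format: str = "array"

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float32)
        if p.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {p.shape}")
        if not np.isfinite(p).all():
            raise ValueError("slice intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))


@dataclass(frozen=True)
class SamplePair:
    """An image slice with its paired cord (CSA) and lesion masks.

    Lesions are demyelinated foci inside the cord, so the lesion mask is
    nested within the CSA mask; this invariant is enforced.
    """

    image: ImageSlice
    csa_mask: BinaryMask
    lesion_mask: BinaryMask
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {self.image.pixels.shape, self.csa_mask.grid.shape, self.lesion_mask.grid.shape}
        if len(shapes) != 1:
            raise ValueError(f"image/mask shapes differ: {shapes}")
        if np.any(self.lesion_mask.grid > self.csa_mask.grid):
            raise ValueError("lesion mask must be nested inside the CSA mask")

    @property
    def identifier(self) -> str:
        return self.image.identifier


@dataclass(frozen=True)
class AugmentationPlan:
    """Geometric augmentation recipe (pixel structure preserving).

    ``transforms`` always includes the identity ("same") transform; the
    others are in-plane rotation, horizontal/vertical flips about the
    image axes, and integer pixel shifts.
    """

    transforms: tuple[str, ...] = DEFAULT_TRANSFORMS
    rotation_range_deg: float = 15.0
    shift_range_px: int = 10
    target_count: int = 1080
    seed: int = 0

    def __post_init__(self):
        if "identity" not in self.transforms:
            raise ValueError("the identity transform must be included")
        unknown = set(self.transforms) - set(DEFAULT_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {unknown}")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive id partition.

    ``train_ids`` + ``val_ids`` form the training pool (the published
    80% figure counts validation images as part of the training set);
    ``test_ids`` is the held-out remainder.
    """

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    seed: int

    @property
    def n_train_pool(self) -> int:
        return len(self.train_ids) + len(self.val_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    s = "".join(path.suffixes).lower()
    if s.endswith(".png"):
        return "png"
    if s.endswith(".nii") or s.endswith(".nii.gz"):
        return "nifti"
    if s.endswith(".dcm") or s.endswith(".ima"):
        return "dicom"
    raise FormatError(f"cannot infer image format of {path}")


def load_slice(path: str | os.PathLike, fmt: str | None = None) -> ImageSlice:
    """Read a grayscale slice; spacing comes from the header where the
    format has one (DICOM PixelSpacing, NIfTI zooms; PNG defaults to 1 mm)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = fmt or _infer_format(path)
    try:
        if fmt == "png":
            from PIL import Image

            arr = np.asarray(Image.open(path).convert("F"), dtype=np.float32)
            spacing = (1.0, 1.0)
        elif fmt == "nifti":
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asarray(img.dataobj, dtype=np.float32)
            if arr.ndim == 3 and arr.shape[2] == 1:
                arr = arr[:, :, 0]
            zooms = img.header.get_zooms()
            spacing = (float(zooms[0]), float(zooms[1]))
        elif fmt == "dicom":
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(np.float32)
            ps = getattr(ds, "PixelSpacing", [1.0, 1.0])
            spacing = (float(ps[0]), float(ps[1]))
        else:
            raise FormatError(f"unsupported format {fmt!r} for {path}")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - reraise with the file named
        raise FormatError(f"failed to read {path} as {fmt}: {exc}") from exc
    return ImageSlice(pixels=arr, spacing=spacing, identifier=path.stem.split(".")[0],
                      source_format=fmt)


def load_mask(path: str | os.PathLike, fmt: str | None = None) -> BinaryMask:
    """Read a binary mask (PNG 0/255 or NIfTI/DICOM nonzero = foreground)."""
    s = load_slice(path, fmt=fmt)
    grid = (s.pixels > (127 if s.source_format == "png" else 0)).astype(np.uint8)
    return BinaryMask(grid=grid, spacing=s.spacing)


def save_slice(s: ImageSlice, path: str | os.PathLike, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        from PIL import Image

        lo, hi = float(s.pixels.min()), float(s.pixels.max())
        scaled = np.zeros_like(s.pixels) if hi == lo else (s.pixels - lo) / (hi - lo)
        Image.fromarray((scaled * 255).round().astype(np.uint8)).save(path)
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag([s.spacing[0], s.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(s.pixels.astype(np.float32), affine), str(path))
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def save_mask(m: BinaryMask, path: str | os.PathLike, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        from PIL import Image

        Image.fromarray((m.grid * 255).astype(np.uint8)).save(path)
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag([m.spacing[0], m.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(m.grid.astype(np.uint8), affine), str(path))
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def save_pair(pair: SamplePair, out_dir: str | os.PathLike, fmt: str = "png") -> dict:
    """Write image + both masks; returns a manifest row."""
    out = Path(out_dir)
    ext = {"png": ".png", "nifti": ".nii.gz"}[fmt]
    sid = pair.identifier or "slice"
    paths = {
        "image": out / "images" / f"{sid}{ext}",
        "csa": out / "masks_csa" / f"{sid}{ext}",
        "lesion": out / "masks_lesion" / f"{sid}{ext}",
    }
    save_slice(pair.image, paths["image"], fmt=fmt)
    save_mask(pair.csa_mask, paths["csa"], fmt=fmt)
    save_mask(pair.lesion_mask, paths["lesion"], fmt=fmt)
    return {"id": sid, "image": str(paths["image"]), "csa": str(paths["csa"]),
            "lesion": str(paths["lesion"])}


def load_pair(row: dict, fmt: str | None = None) -> SamplePair:
    """Inverse of :func:`save_pair` given one manifest row."""
    image = load_slice(row["image"], fmt=fmt)
    image = replace(image, identifier=str(row["id"]))
    return SamplePair(
        image=image,
        csa_mask=load_mask(row["csa"], fmt=fmt),
        lesion_mask=load_mask(row["lesion"], fmt=fmt),
    )


def write_manifest(rows: list[dict], path: str | os.PathLike) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _pad_to_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    side = max(h, w)
    pr, pc = side - h, side - w
    return np.pad(arr, ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)))


def preprocess(s: ImageSlice, target: tuple[int, int]) -> ImageSlice:
    """Zero-pad to square, resize bilinearly, min–max normalize to [0, 1].

    Constant images come back all-zero (there is no contrast to keep)."""
    arr = _pad_to_square(s.pixels)
    side = arr.shape[0]
    out = resize(arr, target, order=1, preserve_range=True,
                 anti_aliasing=side > max(target)).astype(np.float32)
    lo, hi = float(out.min()), float(out.max())
    out = np.zeros_like(out) if hi == lo else (out - lo) / (hi - lo)
    scale = (side / target[0], side / target[1])
    spacing = (s.spacing[0] * scale[0], s.spacing[1] * scale[1])
    return ImageSlice(pixels=out, spacing=spacing, identifier=s.identifier,
                      source_format=s.source_format)


def preprocess_mask(m: BinaryMask, target: tuple[int, int]) -> BinaryMask:
    """Same geometry as :func:`preprocess` but nearest-neighbour, so the
    mask stays binary."""
    arr = _pad_to_square(m.grid)
    side = arr.shape[0]
    out = resize(arr.astype(float), target, order=0, preserve_range=True,
                 anti_aliasing=False)
    scale = (side / target[0], side / target[1])
    spacing = (m.spacing[0] * scale[0], m.spacing[1] * scale[1])
    return BinaryMask(grid=(out > 0.5).astype(np.uint8), spacing=spacing)


def preprocess_pair(pair: SamplePair, target: tuple[int, int]) -> SamplePair:
    return SamplePair(
        image=preprocess(pair.image, target),
        csa_mask=preprocess_mask(pair.csa_mask, target),
        lesion_mask=preprocess_mask(pair.lesion_mask, target),
        meta=dict(pair.meta),
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _apply_transform(arr: np.ndarray, name: str, params: dict, order: int) -> np.ndarray:
    if name == "identity":
        return arr
    if name == "hflip":
        return arr[:, ::-1]
    if name == "vflip":
        return arr[::-1, :]
    if name == "rotate":
        return ndimage.rotate(arr, params["angle"], reshape=False, order=order,
                              mode="constant", cval=0.0, prefilter=order > 1)
    if name == "shift":
        return ndimage.shift(arr, (params["dr"], params["dc"]), order=0,
                             mode="constant", cval=0.0)
    raise ValueError(f"unknown transform {name!r}")


def augment(samples: list[SamplePair], plan: AugmentationPlan) -> list[SamplePair]:
    """Expand a dataset to exactly ``plan.target_count`` pairs.

    Sources are cycled round-robin; each occurrence gets a transform
    drawn from the seeded stream, applied identically to the image and
    both masks (nearest-neighbour for masks), which preserves the
    lesion-in-cord nesting.
    """
    if not samples:
        raise ValueError("augment needs at least one source pair")
    rng = np.random.default_rng(plan.seed)
    out: list[SamplePair] = []
    n = len(samples)
    for k in range(plan.target_count):
        src = samples[k % n]
        name = plan.transforms[rng.integers(len(plan.transforms))]
        params = {
            "angle": float(rng.uniform(-plan.rotation_range_deg, plan.rotation_range_deg)),
            "dr": int(rng.integers(-plan.shift_range_px, plan.shift_range_px + 1)),
            "dc": int(rng.integers(-plan.shift_range_px, plan.shift_range_px + 1)),
        }
        img = _apply_transform(src.image.pixels, name, params, order=1)
        csa = _apply_transform(src.csa_mask.grid, name, params, order=0)
        les = _apply_transform(src.lesion_mask.grid, name, params, order=0)
        sid = f"{src.identifier}_aug{k:04d}_{name}"
        out.append(
            SamplePair(
                image=ImageSlice(np.ascontiguousarray(img), src.image.spacing, sid,
                                 src.image.source_format),
                csa_mask=BinaryMask(np.ascontiguousarray(csa).astype(np.uint8),
                                    src.csa_mask.spacing),
                lesion_mask=BinaryMask(np.ascontiguousarray(les).astype(np.uint8),
                                       src.lesion_mask.spacing),
                meta={**src.meta, "source_id": src.identifier, "transform": name},
            )
        )
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split(ids: list[str], train_fraction: float, seed: int,
          val_fraction: float = 0.1) -> DatasetSplit:
    """Seeded shuffle + partition.

    ``train_fraction`` fixes the training pool size as round(fraction x
    total); ``val_fraction`` then carves validation ids out of that pool
    (the held-out test set is untouched).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    n_pool = round(train_fraction * len(order))
    pool, test = order[:n_pool], order[n_pool:]
    n_val = round(val_fraction * n_pool)
    val, train = pool[:n_val], pool[n_val:]
    return DatasetSplit(
        train_ids=tuple(train), val_ids=tuple(val), test_ids=tuple(test),
        train_fraction=train_fraction, seed=seed,
    )


def prepare_dataset(
    samples: list[SamplePair],
    plan: AugmentationPlan,
    train_fraction: float = 0.8,
    seed: int = 0,
    split_first: bool = False,
    val_fraction: float = 0.1,
) -> tuple[list[SamplePair], DatasetSplit]:
    """Augment and split.

    Default order is augment-then-split, reproducing the published
    pipeline (augmented copies of one source slice can land on both
    sides of the split).  ``split_first=True`` gives the leakage-free
    alternative: sources are partitioned first and each side is
    augmented separately, so no test image shares a source with a
    training image.
    """
    if not split_first:
        pairs = augment(samples, plan)
        sp = split([p.identifier for p in pairs], train_fraction, seed,
                   val_fraction=val_fraction)
        return pairs, sp
    src_split = split([p.identifier for p in samples], train_fraction, seed,
                      val_fraction=0.0)
    by_id = {p.identifier: p for p in samples}
    n_pool = round(train_fraction * plan.target_count)
    pool_plan = replace(plan, target_count=n_pool)
    test_plan = replace(plan, target_count=plan.target_count - n_pool, seed=plan.seed + 1)
    pool_pairs = augment([by_id[i] for i in src_split.train_ids], pool_plan)
    test_pairs = augment([by_id[i] for i in src_split.test_ids], test_plan)
    n_val = round(val_fraction * n_pool)
    pool_ids = [p.identifier for p in pool_pairs]
    sp = DatasetSplit(
        train_ids=tuple(pool_ids[n_val:]), val_ids=tuple(pool_ids[:n_val]),
        test_ids=tuple(p.identifier for p in test_pairs),
        train_fraction=train_fraction, seed=seed,
    )
    return pool_pairs + test_pairs, sp
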