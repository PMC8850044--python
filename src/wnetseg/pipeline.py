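"""CT slice/mask data pipeline: loading, normalisation, resizing, augmentation,
and patient-level splitting.

The real-data path reads one DICOM series per patient (images plus expert
liver masks, 3Dircadb1 directory layout); the fixture path reads PNG pairs
written by the phantom generator.  Intensities are min-max normalised per
slice to 0-255 — deliberately without Hounsfield-unit windowing or histogram
equalisation — images are resized 512->256 bilinearly (masks nearest-
neighbour), and the augmentation expands each slice by horizontal/vertical
flips combined with 15-degree-step rotations, 40 variants per input by
default.  Splitting is by *patient*, never by slice, so no augmented copy of
a test patient's anatomy can leak into training; the canonical 20-patient
cohort splits 14 train / 4 validation / 2 test with patients 5 and 20 held
out for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "SliceRecord",
    "SplitManifest",
    "AugmentationConfig",
    "ForegroundRatio",
    "load_patient",
    "normalize_to_255",
    "resize_image",
    "augment",
    "split_patients",
    "foreground_ratio",
    "records_to_arrays",
    "write_manifest",
]

FLIP_VARIANTS = ("identity", "flip_h", "flip_v", "flip_hv")


@dataclass
class SliceRecord:
    """One image/mask pair with patient identity and transform provenance."""

    patient_id: object
    slice_index: int
    image: np.ndarray
    mask: np.ndarray
    provenance: str = "original"
    source_path: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} differ"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")


@dataclass(frozen=True)
class SplitManifest:
    """Disjoint patient lists for training, validation, and testing."""

    train_patients: tuple
    val_patients: tuple
    test_patients: tuple

    def __post_init__(self) -> None:
        groups = [set(self.train_patients), set(self.val_patients),
                  set(self.test_patients)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be pairwise disjoint")

    @property
    def counts(self) -> tuple:
        return (len(self.train_patients), len(self.val_patients),
                len(self.test_patients))

    def split_of(self, patient_id) -> str:
        if patient_id in self.train_patients:
            return "train"
        if patient_id in self.val_patients:
            return "val"
        if patient_id in self.test_patients:
            return "test"
        raise KeyError(f"patient {patient_id!r} not in manifest")


@dataclass(frozen=True)
class AugmentationConfig:
    """Flip x rotation grid applied to every slice.

    Default: 4 flip variants x 10 rotation angles (0°..135° in 15° steps)
    = 40 outputs per input, which carries the 2,823-slice cohort to 112,920.
    Border pixels exposed by rotation are filled with ``fill`` and masks are
    re-binarised at 0.5 after interpolation.
    """

    flip_variants: tuple = FLIP_VARIANTS
    rotation_step: float = 15.0
    rotation_count: int = 10
    fill: float = 0.0
    allow_non_square: bool = False

    def __post_init__(self) -> None:
        bad = set(self.flip_variants) - set(FLIP_VARIANTS)
        if bad:
            raise ValueError(f"unknown flip variants {sorted(bad)}")
        if self.rotation_count < 1:
            raise ValueError("rotation_count must be >= 1")

    @property
    def variants_per_input(self) -> int:
        return len(self.flip_variants) * self.rotation_count

    def angles(self) -> tuple:
        return tuple(k * self.rotation_step for k in range(self.rotation_count))


@dataclass(frozen=True)
class ForegroundRatio:
    """Positive:negative pixel balance of a mask collection, as 1:r."""

    positive: int
    negative: int

    @property
    def r(self) -> float:
        return self.negative / self.positive if self.positive else float("inf")

    @property
    def flagged(self) -> bool:
        return self.positive == 0

    def __str__(self) -> str:
        if self.positive == 0:
            return f"0:{self.negative}"
        return f"1:{self.r:.2f}"


# ---------------------------------------------------------------------------
# loading


def _read_dicom_series(directory: Path) -> list:
    import pydicom

    files = sorted(directory.glob("*"))
    files = [f for f in files if f.is_file() and not f.name.startswith(".")]
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        order = getattr(ds, "InstanceNumber", None)
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None and abs(float(spacing[0]) - float(spacing[1])) > 1e-9:
            warnings.warn(
                f"{f.name}: non-square pixels {list(spacing)}", UserWarning
            )
        slices.append((order if order is not None else f.name, str(f), arr))
    slices.sort(key=lambda t: t[0])
    return slices


def _read_png_series(directory: Path) -> list:
    import imageio.v3 as iio

    files = sorted(directory.glob("*.png"))
    return [(f.name, str(f), np.asarray(iio.imread(f), dtype=float))
            for f in files]


def load_patient(directory, mask_structure: str = "liver") -> list:
    """Read one patient directory into a list of :class:`SliceRecord`.

    Supported layouts: 3Dircadb1 (``PATIENT_DICOM/`` + ``MASKS_DICOM/<organ>/``)
    and the fixture layout (``images/`` + ``masks/`` holding DICOM or PNG
    files).  Slices are ordered by DICOM instance number (file name for
    PNGs); any positive mask label is binarised to 1.  Slices without liver
    are kept — the cohort is used unfiltered.
    """
    d = Path(directory)
    if (d / "PATIENT_DICOM").is_dir():
        img_dir = d / "PATIENT_DICOM"
        mask_dir = d / "MASKS_DICOM" / mask_structure
        if not mask_dir.is_dir():
            mask_dir = d / "MASKS_DICOM"
    elif (d / "images").is_dir() and (d / "masks").is_dir():
        img_dir, mask_dir = d / "images", d / "masks"
    else:
        raise FileNotFoundError(
            f"{d}: expected PATIENT_DICOM/MASKS_DICOM or images/masks layout"
        )

    reader = _read_png_series if list(img_dir.glob("*.png")) else _read_dicom_series
    images = reader(img_dir)
    masks = reader(mask_dir)
    if len(images) != len(masks):
        raise ValueError(
            f"{d}: {len(images)} image slices but {len(masks)} mask slices"
        )
    records = []
    for idx, ((_, path, img), (_, _, msk)) in enumerate(zip(images, masks)):
        records.append(
            SliceRecord(
                patient_id=d.name,
                slice_index=idx,
                image=img,
                mask=(msk > 0).astype(np.uint8),
                provenance="original",
                source_path=path,
            )
        )
    return records


# ---------------------------------------------------------------------------
# per-slice transforms


def normalize_to_255(image: np.ndarray) -> np.ndarray:
    """Linear per-slice min-max map onto [0, 255] (no HU windowing).

    A constant slice has no dynamic range and maps to all zeros with a
    warning.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        warnings.warn("constant slice; normalised to all zeros", UserWarning)
        return np.zeros_like(image)
    # divide first so the maximum maps to exactly 255.0
    return (image - lo) / (hi - lo) * 255.0


def resize_image(record: SliceRecord, target: int) -> SliceRecord:
    """Resize to ``target`` x ``target``: bilinear image, nearest mask."""
    if target < 1:
        raise ValueError("target size must be positive")
    img = _sk_resize(
        record.image.astype(float), (target, target), order=1,
        preserve_range=True, anti_aliasing=record.image.shape[0] > target,
    )
    msk = _sk_resize(
        record.mask.astype(float), (target, target), order=0,
        preserve_range=True, anti_aliasing=False,
    )
    return replace(record, image=img, mask=(msk > 0.5).astype(np.uint8))


_FLIP_OPS = {
    "identity": lambda a: a,
    "flip_h": lambda a: a[:, ::-1],
    "flip_v": lambda a: a[::-1, :],
    "flip_hv": lambda a: a[::-1, ::-1],
}


def _rotate(arr: np.ndarray, angle: float, order: int, fill: float) -> np.ndarray:
    if angle % 360.0 == 0.0:
        return arr
    return ndimage.rotate(
        arr, angle, reshape=False, order=order, mode="constant", cval=fill,
        prefilter=False,
    )


def augment(records, config: AugmentationConfig | None = None) -> list:
    """Expand every record by the full flip x rotation grid.

    Image and mask receive identical geometric transforms (bilinear vs
    nearest interpolation); output order is input order x flip order x
    angle order, and provenance tags record the chain, so the expansion is
    fully deterministic.  Output count = inputs x flips x rotations.
    """
    config = config or AugmentationConfig()
    out = []
    for rec in records:
        if rec.image.shape[0] != rec.image.shape[1] and not config.allow_non_square:
            if config.rotation_count > 1:
                raise ValueError(
                    f"refusing to rotate non-square slice {rec.image.shape}; "
                    "set allow_non_square=True to override"
                )
        for flip in config.flip_variants:
            fimg = _FLIP_OPS[flip](rec.image)
            fmsk = _FLIP_OPS[flip](rec.mask)
            for angle in config.angles():
                img = _rotate(fimg.astype(float), angle, 1, config.fill)
                msk = _rotate(fmsk.astype(float), angle, 0, config.fill)
                if flip == "identity" and angle == 0.0:
                    tag = rec.provenance
                else:
                    tag = f"{rec.provenance}|{flip}|rot{angle:g}"
                out.append(
                    replace(
                        rec,
                        image=img,
                        mask=(msk > 0.5).astype(np.uint8),
                        provenance=tag,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# cohort-level operations


def split_patients(patients, test_ids, val_count: int, seed: int = 0
                   ) -> SplitManifest:
    """Patient-level split: fixed test ids, seeded shuffle of the rest.

    With 20 patients, ``test_ids=(5, 20)`` and ``val_count=4`` this yields
    the canonical 14/4/2 partition.
    """
    patients = list(patients)
    test_ids = list(test_ids)
    if len(set(patients)) != len(patients):
        raise ValueError("duplicate patient ids")
    missing = [t for t in test_ids if t not in patients]
    if missing:
        raise ValueError(f"test ids {missing} not among patients")
    rest = [p for p in patients if p not in test_ids]
    if not 0 <= val_count < len(rest) + 1:
        raise ValueError(f"val_count {val_count} impossible with {len(rest)} "
                         "non-test patients")
    if val_count >= len(rest) and len(rest) > 0:
        raise ValueError("val_count leaves no training patients")
    rng = np.random.default_rng(seed)
    shuffled = [rest[i] for i in rng.permutation(len(rest))]
    return SplitManifest(
        train_patients=tuple(shuffled[val_count:]),
        val_patients=tuple(shuffled[:val_count]),
        test_patients=tuple(test_ids),
    )


def foreground_ratio(records) -> ForegroundRatio:
    """Positive:negative pixel ratio over all masks (about 1:15 for liver CT)."""
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    pos = int(sum(int(r.mask.sum()) for r in records))
    total = int(sum(r.mask.size for r in records))
    ratio = ForegroundRatio(positive=pos, negative=total - pos)
    if ratio.flagged:
        warnings.warn("no foreground pixels in any mask", UserWarning)
    return ratio


def records_to_arrays(records, dtype=np.float32) -> tuple:
    """Stack records into network tensors: X (n,1,h,w) in [0,1], y (n,1,h,w)."""
    X = np.stack([np.asarray(r.image, dtype=dtype) for r in records])[:, None]
    y = np.stack([np.asarray(r.mask, dtype=dtype) for r in records])[:, None]
    if X.max() > 1.0:
        X = X / 255.0
    return X, y


def write_manifest(records, manifest: SplitManifest | None, path) -> pd.DataFrame:
    """Write the slice manifest CSV (patient, slice, split, provenance, paths)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "slice_index": r.slice_index,
            "split": manifest.split_of(r.patient_id) if manifest else "",
            "provenance": r.provenance,
            "image_path": r.source_path,
            "mask_path": "",
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
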