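"""Image and manifest I/O for retinal cSLO fundus frames.

A fundus frame is a single-channel grayscale image (the averaged blue-
autofluorescence export of one eye at one timepoint) plus acquisition
metadata: animal, eye, week post immunization and treatment group.
Images arrive as 8- or 16-bit TIFF or PNG; all downstream arithmetic is
floating point, quantization happens only at export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class Eye(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Group(str, Enum):
    EAE = "EAE"
    SHAM = "sham"
    NAIVE = "naive"
    UNKNOWN = "unknown"


_EYE_ALIASES = {
    "left": Eye.LEFT,
    "l": Eye.LEFT,
    "os": Eye.LEFT,
    "right": Eye.RIGHT,
    "r": Eye.RIGHT,
    "od": Eye.RIGHT,
}

_GROUP_ALIASES = {g.value.lower(): g for g in Group}

MANIFEST_COLUMNS = ("animal_id", "eye", "week", "group", "source_path")

# filename pattern fallback: <animal>_<eye>_week<N> (or _w<N>)
_FILENAME_RE = re.compile(
    r"^(?P<animal>[A-Za-z0-9.-]+)_(?P<eye>left|right|l|r)_(?:week|w)(?P<week>\d+)$",
    re.IGNORECASE,
)


def parse_eye(value: str) -> Eye:
    try:
        return _EYE_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"invalid eye {value!r}: expected one of left/right (aliases L, R, OS, OD)"
        ) from None


def parse_group(value: str) -> Group:
    try:
        return _GROUP_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"invalid group {value!r}: expected one of EAE, sham, naive, unknown"
        ) from None


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition metadata for one fundus frame.

    ``week`` is the longitudinal key (weeks post immunization); ``eye`` is a
    within-subject variable, so (animal_id, eye, week) identifies a frame.
    """

    animal_id: str
    eye: Eye = Eye.LEFT
    week: int = 0
    group: Group = Group.UNKNOWN
    source_path: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "eye", Eye(self.eye))
        object.__setattr__(self, "group", Group(self.group))
        if int(self.week) < 0:
            raise ValueError(f"week must be non-negative, got {self.week}")
        object.__setattr__(self, "week", int(self.week))

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.animal_id, self.eye.value, self.week)


def infer_meta_from_filename(path: str | Path) -> ImageMeta | None:
    """Parse ``<animal>_<eye>_week<N>`` from a file stem; None if no match."""
    m = _FILENAME_RE.match(Path(path).stem)
    if m is None:
        return None
    return ImageMeta(
        animal_id=m.group("animal"),
        eye=parse_eye(m.group("eye")),
        week=int(m.group("week")),
        group=Group.UNKNOWN,
        source_path=str(path),
    )


@dataclass
class FundusImage:
    """One grayscale intensity grid plus its metadata.

    ``bit_depth`` is the declared storage depth (8 or 16) for raw frames.
    Preprocessed frames live in an unbounded floating-point domain and carry
    ``bit_depth=None``; the range invariant only applies to raw frames.
    ``provenance`` accumulates one record per processing stage.
    """

    pixels: np.ndarray
    bit_depth: int | None = 8
    meta: ImageMeta = field(default_factory=lambda: ImageMeta("unknown"))
    provenance: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 8:
            raise ValueError(
                f"image too small: {self.pixels.shape}, need at least 8x8"
            )
        if self.bit_depth is not None:
            if self.bit_depth not in (8, 16):
                raise ValueError(f"unsupported bit depth {self.bit_depth}")
            lo = float(np.min(self.pixels))
            hi = float(np.max(self.pixels))
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise ValueError(
                    f"intensities [{lo}, {hi}] outside declared "
                    f"{self.bit_depth}-bit range"
                )

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    def as_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)

    def with_pixels(
        self, pixels: np.ndarray, bit_depth: int | None, record: dict | None = None
    ) -> "FundusImage":
        prov = self.provenance + ((record,) if record is not None else ())
        return FundusImage(pixels=pixels, bit_depth=bit_depth, meta=self.meta,
                           provenance=prov)


_DTYPE_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


def _collapse_channels(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1])
                and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise ValueError(
                f"{path}: color image with divergent channels; expected a "
                "grayscale export (R=G=B)"
            )
        return rgb[..., 0]
    raise ValueError(f"{path}: unsupported image dimensionality {arr.shape}")


def read_image(path: str | Path, meta: ImageMeta | None = None) -> FundusImage:
    """Read a TIFF/PNG fundus frame, preserving its native bit depth.

    RGB inputs with identical channels are collapsed to a single channel;
    divergent channels are rejected (they signal a wrong export). Metadata
    falls back to the ``<animal>_<eye>_week<N>`` filename pattern, then to
    an unknown placeholder.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (expected TIFF/PNG)")
    arr = _collapse_channels(np.asarray(arr), str(path))
    try:
        depth = _DTYPE_DEPTH[arr.dtype]
    except KeyError:
        raise ValueError(
            f"{path}: unsupported sample dtype {arr.dtype}; expected uint8/uint16"
        ) from None
    if meta is None:
        meta = infer_meta_from_filename(path) or ImageMeta("unknown")
    meta = replace(meta, source_path=str(path))
    return FundusImage(pixels=arr, bit_depth=depth, meta=meta)


def write_image(path: str | Path, img: FundusImage) -> None:
    """Write a frame losslessly at its native bit depth (TIFF or PNG)."""
    path = Path(path)
    if img.bit_depth is None:
        arr = np.asarray(img.pixels, dtype=np.float32)
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("floating-point frames can only be written as TIFF")
        tifffile.imwrite(path, arr)
        return
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = np.asarray(img.pixels, dtype=dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported output format {path.suffix!r}")


def read_manifest(path: str | Path) -> list[ImageMeta]:
    """Read a cohort manifest CSV into validated ImageMeta rows.

    Requires header columns animal_id, eye, week, group, source_path.
    Duplicate (animal_id, eye, week) keys are rejected: the triple is the
    unit of observation and a duplicate means a mislabeled export.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    metas: list[ImageMeta] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            week = int(row.week)
        except ValueError:
            raise ValueError(f"{path} line {i}: invalid week {row.week!r}") from None
        try:
            meta = ImageMeta(
                animal_id=str(row.animal_id),
                eye=parse_eye(row.eye),
                week=week,
                group=parse_group(row.group),
                source_path=str(row.source_path),
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from None
        if meta.key in seen:
            raise ValueError(
                f"{path} line {i}: duplicate (animal_id, eye, week) key "
                f"{meta.key} (first seen on line {seen[meta.key]})"
            )
        seen[meta.key] = i
        metas.append(meta)
    return metas


def write_manifest(path: str | Path, metas: Sequence[ImageMeta]) -> None:
    rows = [
        {
            "animal_id": m.animal_id,
            "eye": m.eye.value,
            "week": m.week,
            "group": m.group.value,
            "source_path": m.source_path,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)
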