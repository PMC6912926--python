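"""Image and metadata I/O, fin-ROI cropping, and CIE L*a*b* conversion.

The unit of analysis is a :class:`FishSample`: one lateral-view RGB image of
an adult fish plus its metadata row (treatment group, gonadally determined
sex, body weight, total length) and a rectangular caudal-fin region of
interest.  The fin ROI is supplied in the metadata — mirroring a manual
cropping step — rather than detected automatically.

Color convention: sRGB primaries, D65 white point, 2 degree observer.  This
is the standard interpretation of CIE L*a*b* for consumer-camera images; the
conversion itself is delegated to scikit-image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage import color as skcolor

logger = logging.getLogger(__name__)

#: Required columns of the cohort metadata CSV.  Coordinates are 0-based,
#: half-open pixel indices (x = column, y = row).
METADATA_COLUMNS = (
    "id",
    "image_path",
    "group",
    "true_sex",
    "body_weight_g",
    "total_length_mm",
    "roi_x",
    "roi_y",
    "roi_w",
    "roi_h",
)

GROUPS = ("control", "treatment")
SEXES = ("M", "F")


@dataclass
class FishSample:
    """One fish: lateral RGB image, metadata, and caudal-fin ROI.

    Parameters
    ----------
    id : str
        Unique individual identifier.
    image : ndarray of uint8, shape (H, W, 3)
        Lateral-view RGB image.
    group : {"control", "treatment"}
        Embryonic temperature treatment group.
    true_sex : {"M", "F", "unknown"}
        Sex from gonad inspection; the classification ground truth.
    body_weight : float or None
        Body weight in grams.
    total_length : float or None
        Total length in millimetres.
    fin_roi : tuple (x, y, w, h)
        Caudal-fin rectangle in pixels, 0-based, half-open.
    """

    id: str
    image: np.ndarray
    group: str
    true_sex: str = "unknown"
    body_weight: Optional[float] = None
    total_length: Optional[float] = None
    fin_roi: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"sample {self.id!r}: image must be HxWx3, got {img.shape}")
        self.image = img
        if self.body_weight is not None and not self.body_weight > 0:
            raise ValueError(f"sample {self.id!r}: body_weight must be > 0")
        if self.total_length is not None and not self.total_length > 0:
            raise ValueError(f"sample {self.id!r}: total_length must be > 0")
        x, y, w, h = (int(v) for v in self.fin_roi)
        H, W = img.shape[:2]
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > W or y + h > H:
            raise ValueError(
                f"sample {self.id!r}: fin ROI {(x, y, w, h)} outside image bounds {(H, W)}"
            )
        self.fin_roi = (x, y, w, h)


def crop_fin(sample: FishSample) -> np.ndarray:
    """Return the caudal-fin sub-image (shape (roi_h, roi_w, 3)).

    The rectangle is half-open: pixel columns ``x .. x+w-1`` and rows
    ``y .. y+h-1``.  Bounds are validated at :class:`FishSample`
    construction, so this is a plain slice.
    """
    x, y, w, h = sample.fin_roi
    return sample.image[y : y + h, x : x + w, :]


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIE L*a*b* (D65, 2 degree observer).

    Returns a float array of the same spatial shape with channels
    L* in [0, 100] and a*, b* in roughly [-128, 127].  The conversion is
    invertible to within 8-bit quantization on the sRGB gamut.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return skcolor.rgb2lab(img)


def lab_to_rgb_u8(lab: np.ndarray) -> np.ndarray:
    """Convert a CIE L*a*b* image to 8-bit sRGB (clipping out-of-gamut pixels)."""
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


class CohortSchemaError(ValueError):
    """Metadata CSV is missing required columns."""


def read_image(path: Path) -> np.ndarray:
    """Read a PNG/TIFF image as an HxWx3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_cohort(
    metadata_path: str | Path, image_root: str | Path | None = None
) -> tuple[list[FishSample], int]:
    """Load a cohort from a metadata CSV plus its image files.

    ``image_path`` entries are resolved relative to ``image_root`` (default:
    the CSV's directory).  Rows whose image cannot be read are dropped with a
    warning; the second return value counts them.  Raises
    :class:`CohortSchemaError` on missing columns and :class:`ValueError` if
    no image at all is readable.
    """
    metadata_path = Path(metadata_path)
    root = Path(image_root) if image_root is not None else metadata_path.parent
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise CohortSchemaError(f"metadata is missing required columns: {missing}")

    samples: list[FishSample] = []
    n_dropped = 0
    for row in meta.itertuples(index=False):
        path = root / str(row.image_path)
        try:
            img = read_image(path)
        except (OSError, UnidentifiedImageError) as exc:
            logger.warning("dropping sample %s: unreadable image %s (%s)", row.id, path, exc)
            n_dropped += 1
            continue
        weight = None if pd.isna(row.body_weight_g) else float(row.body_weight_g)
        length = None if pd.isna(row.total_length_mm) else float(row.total_length_mm)
        samples.append(
            FishSample(
                id=str(row.id),
                image=img,
                group=str(row.group),
                true_sex=str(row.true_sex),
                body_weight=weight,
                total_length=length,
                fin_roi=(int(row.roi_x), int(row.roi_y), int(row.roi_w), int(row.roi_h)),
            )
        )
    if not samples:
        raise ValueError(f"no readable images among {len(meta)} metadata rows")
    if n_dropped:
        logger.warning("dropped %d of %d samples with unreadable images", n_dropped, len(meta))
    return samples, n_dropped
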