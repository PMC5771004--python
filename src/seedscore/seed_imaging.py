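"""Segmentation and feature extraction for single-seed image tiles.

Each tile nominally contains one seed photographed against a light
background. The tile is thresholded to a binary mask, connected components
are labelled, the component nearest the tile centre is taken as *the* seed
object, and two feature blocks are measured on it:

* 25 object descriptors (size, bounding box, position, grey statistics,
  shape) in the style of an ImageJ object counter;
* 1536 colour-histogram counts: pixel counts at each of 256 levels for the
  R, G, B channels and for hue, saturation and brightness (HSB), each
  quantised to the 0-255 integer range.

Coordinates are 0-based, row-major, origin at the top-left; ``x`` denotes
the column axis and ``y`` the row axis. Centroids are real-valued means of
pixel indices.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as _skcolor
from skimage import measure as _skmeasure
from skimage.filters import threshold_otsu

#: Nominal tile geometry (rows, cols) of one seed image.
DEFAULT_TILE_SHAPE = (282, 341)

#: The 25 object-descriptor names, in output order.
OBJECT_FEATURE_NAMES = (
    "area",
    "perimeter",
    "bbox_min_x",
    "bbox_min_y",
    "bbox_width",
    "bbox_height",
    "centroid_x",
    "centroid_y",
    "mass_center_x",
    "mass_center_y",
    "dist_centroid_to_tile_center",
    "dist_mass_center_to_tile_center",
    "dist_centroid_to_mass_center",
    "mean_grey",
    "median_grey",
    "sd_grey",
    "min_grey",
    "max_grey",
    "grey_range",
    "integrated_density",
    "extent",
    "aspect_ratio",
    "equivalent_diameter",
    "circularity",
    "elongation",
)

#: Channel order of the concatenated histogram block.
HISTOGRAM_CHANNELS = ("R", "G", "B", "H", "S", "Br")

#: The 1536 histogram feature names: R0..R255, G0.., B0.., H0.., S0.., Br0..Br255.
HISTOGRAM_FEATURE_NAMES = tuple(
    f"{ch}{level}" for ch in HISTOGRAM_CHANNELS for level in range(256)
)

#: All 1561 feature names in table order.
ALL_FEATURE_NAMES = OBJECT_FEATURE_NAMES + HISTOGRAM_FEATURE_NAMES


class NoForegroundError(ValueError):
    """Thresholding produced no foreground (e.g. a uniform tile)."""


class NoObjectError(ValueError):
    """Segmentation yielded no object to measure in this tile."""


@dataclass
class SeedImage:
    """One RGB tile of a single seed position at one time point.

    ``time_index`` 0 is the pre-test photograph taken before imbibition.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    seed_id: str
    dish_id: str = ""
    time_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        h, w = self.pixels.shape[:2]
        if h < 8 or w < 8:
            raise ValueError("tile must be at least 8 x 8 pixels")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.time_index < 0:
            raise ValueError("time_index must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def grey(self) -> np.ndarray:
        """Grey image: rounded mean of the R, G, B channels (uint8)."""
        return np.rint(self.pixels.astype(np.float64).mean(axis=2)).astype(np.uint8)


@dataclass
class ObjectMask:
    """One 8-connected component of a thresholded tile."""

    mask: np.ndarray  # H x W bool
    label_id: int
    pixel_count: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)  # (row, col)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        rows, cols = np.nonzero(self.mask)
        if rows.size == 0:
            raise ValueError("object mask must contain at least one pixel")
        self.pixel_count = int(rows.size)
        self.centroid = (float(rows.mean()), float(cols.mean()))


def threshold_image(
    image: SeedImage,
    method: str = "otsu",
    polarity: str = "dark_object",
    fixed_threshold: int | None = None,
) -> np.ndarray:
    """Binarise a tile on its grey image.

    ``dark_object`` selects pixels at or below the threshold (seeds are
    darker than the light substrate they sit on); ``light_object`` selects
    the complement.
    """
    if polarity not in ("dark_object", "light_object"):
        raise ValueError(f"unknown polarity {polarity!r}")
    grey = image.grey()
    if method == "otsu":
        if grey.min() == grey.max():
            raise NoForegroundError(
                "Otsu threshold undefined on a uniform tile"
            )
        t = threshold_otsu(grey)
    elif method == "fixed":
        if fixed_threshold is None or not (0 <= fixed_threshold <= 255):
            raise ValueError("fixed method requires a threshold in [0, 255]")
        t = fixed_threshold
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if polarity == "dark_object":
        return grey <= t
    return grey > t


def label_objects(mask: np.ndarray) -> list[ObjectMask]:
    """Split a binary mask into its 8-connected components."""
    mask = np.asarray(mask, dtype=bool)
    labelled, n = _skmeasure.label(mask, connectivity=2, return_num=True)
    return [ObjectMask(mask=labelled == lab, label_id=lab) for lab in range(1, n + 1)]


def select_central_object(
    objects: list[ObjectMask], tile_shape: tuple[int, int]
) -> ObjectMask:
    """Pick the component whose centroid is nearest the tile centre.

    Ties (to 1e-9 in distance) are broken by larger pixel count, then lower
    label id, so the choice is permutation-invariant.
    """
    if not objects:
        raise NoObjectError("no objects to select from (segmentation failed)")
    h, w = tile_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0

    def key(obj: ObjectMask) -> tuple[float, int, int]:
        d = math.hypot(obj.centroid[0] - cr, obj.centroid[1] - cc)
        return (round(d, 9), -obj.pixel_count, obj.label_id)

    return min(objects, key=key)


def _axis_lengths(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    # Major/minor axis lengths of the ellipse with the same second central
    # moments as the pixel set (ImageJ/regionprops convention: 4*sqrt(eig)).
    r = rows - rows.mean()
    c = cols - cols.mean()
    n = r.size
    mrr = float((r * r).sum()) / n
    mcc = float((c * c).sum()) / n
    mrc = float((r * c).sum()) / n
    common = math.sqrt(max((mrr - mcc) ** 2 / 4.0 + mrc**2, 0.0))
    lam1 = (mrr + mcc) / 2.0 + common
    lam2 = (mrr + mcc) / 2.0 - common
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    return major, minor


def extract_object_features(obj: ObjectMask, image: SeedImage) -> dict[str, float]:
    """Measure the 25 object descriptors on the masked grey pixels.

    Perimeter counts object pixels having at least one 4-neighbour outside
    the object (tile borders count as outside); circularity is
    4*pi*area/perimeter^2; elongation is the major/minor axis ratio from the
    second central moments, with degenerate axes floored at 1 px.
    """
    mask = obj.mask
    if mask.shape != image.shape:
        raise ValueError("object mask shape does not match image shape")
    rows, cols = np.nonzero(mask)
    area = rows.size
    grey = image.grey()[rows, cols].astype(np.float64)

    h, w = image.shape
    tile_center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    centroid = np.array([rows.mean(), cols.mean()])
    total_grey = grey.sum()
    if total_grey > 0:
        mass_center = np.array(
            [np.average(rows, weights=grey), np.average(cols, weights=grey)]
        )
    else:  # all-black object: fall back to the geometric centroid
        mass_center = centroid.copy()

    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    bbox_h = rmax - rmin + 1
    bbox_w = cmax - cmin + 1

    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    perimeter = int(mask.sum() - interior.sum())

    mean_grey = float(grey.mean())
    major, minor = _axis_lengths(rows.astype(np.float64), cols.astype(np.float64))
    major = max(major, 1.0)
    minor = max(minor, 1.0)

    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "bbox_min_x": float(cmin),
        "bbox_min_y": float(rmin),
        "bbox_width": float(bbox_w),
        "bbox_height": float(bbox_h),
        "centroid_x": float(centroid[1]),
        "centroid_y": float(centroid[0]),
        "mass_center_x": float(mass_center[1]),
        "mass_center_y": float(mass_center[0]),
        "dist_centroid_to_tile_center": float(np.linalg.norm(centroid - tile_center)),
        "dist_mass_center_to_tile_center": float(
            np.linalg.norm(mass_center - tile_center)
        ),
        "dist_centroid_to_mass_center": float(np.linalg.norm(centroid - mass_center)),
        "mean_grey": mean_grey,
        "median_grey": float(np.median(grey)),
        "sd_grey": float(grey.std()),
        "min_grey": float(grey.min()),
        "max_grey": float(grey.max()),
        "grey_range": float(grey.max() - grey.min()),
        "integrated_density": float(area * mean_grey),
        "extent": float(area / (bbox_w * bbox_h)),
        "aspect_ratio": float(bbox_w / bbox_h),
        "equivalent_diameter": float(2.0 * math.sqrt(area / math.pi)),
        "circularity": float(4.0 * math.pi * area / perimeter**2),
        "elongation": float(major / minor),
    }


def rgb_to_hsb255(rgb: np.ndarray) -> np.ndarray:
    """Convert N x 3 uint8 RGB pixels to HSB with each component in 0-255.

    Follows the ImageJ convention of quantising hue, saturation and
    brightness to the same 0-255 integer range as the RGB channels.
    """
    rgb = np.asarray(rgb, dtype=np.uint8).reshape(-1, 1, 3)
    hsv = _skcolor.rgb2hsv(rgb / 255.0)
    return np.clip(np.rint(hsv.reshape(-1, 3) * 255.0), 0, 255).astype(np.int64)


def extract_histograms(
    obj: ObjectMask | None, image: SeedImage, whole_tile: bool = False
) -> np.ndarray:
    """Per-level pixel counts for R, G, B, H, S, Br over the object pixels.

    Returns the 1536-vector R0..R255, G..., B..., H..., S..., Br0..Br255.
    With ``whole_tile=True`` (or no object) the counts cover every tile
    pixel instead of only the masked ones.
    """
    if whole_tile or obj is None:
        pixels = image.pixels.reshape(-1, 3)
    else:
        pixels = image.pixels[obj.mask]
    hsb = rgb_to_hsb255(pixels)
    blocks = [
        np.bincount(pixels[:, c].astype(np.int64), minlength=256) for c in range(3)
    ]
    blocks += [np.bincount(hsb[:, c], minlength=256) for c in range(3)]
    return np.concatenate(blocks).astype(np.float64)


def extract_features(
    image: SeedImage,
    method: str = "otsu",
    polarity: str = "dark_object",
    fixed_threshold: int | None = None,
    whole_tile_histograms: bool = False,
) -> dict[str, float]:
    """Full 1561-feature extraction for one tile: segment, select, measure."""
    mask = threshold_image(image, method, polarity, fixed_threshold)
    objects = label_objects(mask)
    central = select_central_object(objects, image.shape)
    features = extract_object_features(central, image)
    hist = extract_histograms(central, image, whole_tile=whole_tile_histograms)
    features.update(zip(HISTOGRAM_FEATURE_NAMES, hist))
    return features


def tile_plate_image(
    plate_image: np.ndarray, grid_rows: int, grid_cols: int, dish_id: str = ""
) -> list[SeedImage]:
    """Cut a whole-plate photograph into a row-major grid of seed tiles.

    Remainder pixels at the right/bottom edges are dropped. Tiles get
    deterministic seed ids ``r{row}c{col}``.
    """
    plate_image = np.asarray(plate_image)
    h, w = plate_image.shape[:2]
    th, tw = h // grid_rows, w // grid_cols
    if th < 1 or tw < 1:
        raise ValueError("grid is larger than the plate image")
    tiles = []
    for r in range(grid_rows):
        for c in range(grid_cols):
            block = plate_image[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
            tiles.append(SeedImage(pixels=block, seed_id=f"r{r}c{c}", dish_id=dish_id))
    return tiles


# ---------------------------------------------------------------------------
# Disk I/O: PNG/TIFF tiles named {seed_id}_t{time}.png and the feature CSV.
# ---------------------------------------------------------------------------

_TILE_NAME_RE = re.compile(r"^(?P<seed>.+)_t(?P<time>\d+)\.(png|tif|tiff)$", re.I)


def read_tile(path: str | Path, dish_id: str = "") -> SeedImage:
    """Read one PNG/TIFF tile; seed id and time are parsed from the name."""
    path = Path(path)
    m = _TILE_NAME_RE.match(path.name)
    if not m:
        raise ValueError(
            f"tile filename {path.name!r} does not match '{{seed_id}}_t{{time}}.png'"
        )
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return SeedImage(
        pixels=pixels,
        seed_id=m.group("seed"),
        dish_id=dish_id,
        time_index=int(m.group("time")),
    )


def write_tile(image: SeedImage, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{image.seed_id}_t{image.time_index}.png"
    iio.imwrite(path, image.pixels)
    return path


def extract_feature_table(
    images: list[SeedImage],
    method: str = "otsu",
    polarity: str = "dark_object",
    fixed_threshold: int | None = None,
    whole_tile_histograms: bool = False,
) -> pd.DataFrame:
    """Feature table: one row per (seed_id, time_index), 1561 feature columns."""
    records = []
    for img in images:
        row: dict[str, object] = {"seed_id": img.seed_id, "time_index": img.time_index}
        row.update(
            extract_features(
                img,
                method=method,
                polarity=polarity,
                fixed_threshold=fixed_threshold,
                whole_tile_histograms=whole_tile_histograms,
            )
        )
        records.append(row)
    df = pd.DataFrame.from_records(
        records, columns=["seed_id", "time_index", *ALL_FEATURE_NAMES]
    )
    keys = list(zip(df["seed_id"], df["time_index"]))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (seed_id, time_index) in image set")
    return df


def extract_directory(
    images_dir: str | Path,
    **kwargs,
) -> pd.DataFrame:
    """Extract features for every tile image found in a directory."""
    images_dir = Path(images_dir)
    paths = sorted(
        p for p in images_dir.iterdir() if _TILE_NAME_RE.match(p.name)
    )
    if not paths:
        raise FileNotFoundError(f"no tile images found in {images_dir}")
    return extract_feature_table([read_tile(p) for p in paths], **kwargs)
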