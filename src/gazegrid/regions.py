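"""Scene parcellation and per-region feature extraction.

Images are divided into an a-priori regular grid of rectangular patches.
Each patch is represented as a binary pixel mask; a saliency map (or any
scalar feature raster) is summarised per patch by the mean of its values
under the mask.  Pixel coordinates are 0-based and cells are half-open
rectangles ``[x0, x0+cw) x [y0, y0+ch)``, so every interior pixel belongs
to exactly one cell.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from PIL import Image

log = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "RegionSet",
    "ImageSet",
    "build_grid",
    "normalize_map",
    "extract_mean_feature",
    "load_raster",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle ``[x0, x0+w) x [y0, y0+h)`` in pixels."""

    x0: int
    y0: int
    w: int
    h: int

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.w / 2.0, self.y0 + self.h / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x0 + self.w and self.y0 <= y < self.y0 + self.h

    def mask(self, image_width: int, image_height: int) -> np.ndarray:
        m = np.zeros((image_height, image_width), dtype=bool)
        m[self.y0 : self.y0 + self.h, self.x0 : self.x0 + self.w] = True
        return m


@dataclass
class RegionSet:
    """An ordered set of disjoint regions parcellating an image.

    Grid-built region sets are rectangle-backed (masks are generated on
    demand); the mask representation is the general contract so that
    irregular regions (e.g. object outlines) can be supported without an
    API change.

    Attributes
    ----------
    image_width, image_height
        Source image dimensions in pixels.
    rects
        One :class:`Rect` per region, in row-major order for grids.
    grid_shape
        ``(columns, rows)`` for grid parcellations, else ``None``.
    cell_size
        ``(cell_width, cell_height)`` for grid parcellations, else ``None``.
    """

    image_width: int
    image_height: int
    rects: list[Rect]
    grid_shape: tuple[int, int] | None = None
    cell_size: tuple[int, int] | None = None
    image_id: str | None = None

    def __len__(self) -> int:
        return len(self.rects)

    @property
    def centers(self) -> np.ndarray:
        """(n_regions, 2) array of (x, y) region-center pixel coordinates."""
        return np.array([r.center for r in self.rects], dtype=float)

    @property
    def masks(self) -> Iterator[np.ndarray]:
        """Yield one boolean mask per region (row-major order)."""
        for r in self.rects:
            yield r.mask(self.image_width, self.image_height)

    def to_json(self, path: str | Path) -> None:
        """Serialize geometry to a JSON sidecar."""
        payload = {
            "image_width": self.image_width,
            "image_height": self.image_height,
            "grid_shape": self.grid_shape,
            "cell_size": self.cell_size,
            "image_id": self.image_id,
            "rects": [[r.x0, r.y0, r.w, r.h] for r in self.rects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionSet":
        d = json.loads(Path(path).read_text())
        return cls(
            image_width=d["image_width"],
            image_height=d["image_height"],
            rects=[Rect(*r) for r in d["rects"]],
            grid_shape=tuple(d["grid_shape"]) if d["grid_shape"] else None,
            cell_size=tuple(d["cell_size"]) if d["cell_size"] else None,
            image_id=d.get("image_id"),
        )


def build_grid(
    image_width: int,
    image_height: int,
    cell_width: int,
    cell_height: int,
    *,
    allow_truncation: bool = False,
) -> RegionSet:
    """Parcellate an image into a regular grid of rectangular cells.

    Cells are enumerated in row-major order (left-to-right, top-to-bottom).
    By default the image dimensions must be divisible by the cell
    dimensions so that the grid partitions the image exactly; pass
    ``allow_truncation=True`` to drop a right/bottom remainder instead.

    Examples
    --------
    An 800 x 600 image with 100-px cells yields an 8 x 6 grid of 48
    quadratic patches.
    """
    if cell_width <= 0 or cell_height <= 0:
        raise ValueError("cell dimensions must be positive")
    if image_width <= 0 or image_height <= 0:
        raise ValueError("image dimensions must be positive")
    if cell_width > image_width or cell_height > image_height:
        raise ValueError("cell dimensions exceed image dimensions")
    if (image_width % cell_width or image_height % cell_height) and not allow_truncation:
        raise ValueError(
            f"image {image_width}x{image_height} not divisible by cell "
            f"{cell_width}x{cell_height}; pass allow_truncation=True to drop "
            "the right/bottom remainder"
        )
    cols = image_width // cell_width
    rows = image_height // cell_height
    rects = [
        Rect(c * cell_width, r * cell_height, cell_width, cell_height)
        for r in range(rows)
        for c in range(cols)
    ]
    return RegionSet(
        image_width=image_width,
        image_height=image_height,
        rects=rects,
        grid_shape=(cols, rows),
        cell_size=(cell_width, cell_height),
    )


def normalize_map(raster: np.ndarray) -> np.ndarray:
    """Min-max rescale a feature raster to [0, 1] (per map).

    A constant raster has no scale; it is mapped to all zeros with a
    warning.
    """
    raster = np.asarray(raster, dtype=float)
    if not np.all(np.isfinite(raster)):
        raise ValueError("raster contains non-finite values")
    lo = raster.min()
    hi = raster.max()
    if hi == lo:
        warnings.warn("constant raster: no scale defined, returning zeros")
        return np.zeros_like(raster)
    return (raster - lo) / (hi - lo)


def extract_mean_feature(raster: np.ndarray, regions: RegionSet) -> np.ndarray:
    """Mean raster value within each region, in region order."""
    raster = np.asarray(raster, dtype=float)
    if raster.shape != (regions.image_height, regions.image_width):
        raise ValueError(
            f"raster shape {raster.shape} does not match region set "
            f"({regions.image_height}, {regions.image_width})"
        )
    out = np.empty(len(regions))
    for i, r in enumerate(regions.rects):
        out[i] = raster[r.y0 : r.y0 + r.h, r.x0 : r.x0 + r.w].mean()
    return out


def load_raster(path: str | Path) -> np.ndarray:
    """Read a raster image as a float64 2-D array.

    Multi-channel images are collapsed to luminance (ITU-R 601 luma);
    single-channel images are read as-is.
    """
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "F", "I;16"):
            log.info("converting %s (mode %s) to luminance", path, im.mode)
            im = im.convert("L")
        return np.asarray(im, dtype=float)


@dataclass
class ImageSet:
    """A collection of scenes and associated saliency maps keyed by image ID.

    ``entries[image_id]`` maps saliency-model names to 2-D float rasters;
    all rasters for one image ID must share dimensions.  The scene raster
    itself is optional (only the maps enter the analysis).
    """

    width: int
    height: int
    entries: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        return list(self.entries)

    @property
    def map_names(self) -> list[str]:
        names: list[str] = []
        for maps in self.entries.values():
            for n in maps:
                if n not in names:
                    names.append(n)
        return names

    def add(self, image_id: str, maps: Mapping[str, np.ndarray]) -> None:
        if image_id in self.entries:
            raise ValueError(f"duplicate image ID {image_id!r}")
        clean: dict[str, np.ndarray] = {}
        for name, raster in maps.items():
            raster = np.asarray(raster, dtype=float)
            if raster.shape != (self.height, self.width):
                raise ValueError(
                    f"raster {name!r} for image {image_id!r} has shape "
                    f"{raster.shape}, expected ({self.height}, {self.width})"
                )
            clean[name] = raster
        self.entries[image_id] = clean

    @classmethod
    def from_directory(
        cls,
        root: str | Path,
        map_names: list[str],
        *,
        pattern: str = "{image_id}_{map_name}.png",
    ) -> "ImageSet":
        """Load saliency maps from files named by image ID and map name.

        Image IDs are inferred from files matching ``pattern`` for the
        first map name.
        """
        root = Path(root)
        first = map_names[0]
        suffix = pattern.format(image_id="", map_name=first)
        ids = sorted(
            p.name[: -len(suffix)] if suffix else p.stem
            for p in root.glob(pattern.format(image_id="*", map_name=first))
        )
        if not ids:
            raise FileNotFoundError(f"no rasters matching {pattern!r} under {root}")
        probe = load_raster(root / pattern.format(image_id=ids[0], map_name=first))
        out = cls(width=probe.shape[1], height=probe.shape[0])
        for image_id in ids:
            out.add(
                image_id,
                {
                    name: load_raster(root / pattern.format(image_id=image_id, map_name=name))
                    for name in map_names
                },
            )
        return out
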