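"""Distance-to-center predictors of the central fixation bias.

Observers fixate preferentially near the image center regardless of scene
content.  To model this explicitly, each grid cell is assigned a scalar
measuring how peripheral its center is.  Three distance families are
provided:

* ``euclidean`` — sqrt(dx**2 + dy**2 / nu)
* ``gaussian``  — -exp(-dx**2 / (2*sigma2) - dy**2 / (2*sigma2*nu)),
  entered with a negative sign so that larger values are more peripheral
  (in (-1, 0], -1 at the exact center)
* ``taxicab``   — |dx| + |dy| (L1 distance; a natural choice on a grid)

Coordinates are normalized so that half the image width equals 1 and the
image center is the origin; the Gaussian variance default sigma2 = 0.23 is
stated in those units.  The anisotropy parameter ``nu`` scales the
vertical axis only, acknowledging the horizontally elongated spread of
fixations in scene viewing: nu = 1 is isotropic, nu = h/w matches the
image aspect ratio, and nu = 0.45 is the anisotropic default (giving a
vertical Gaussian variance of 0.45 * 0.23 ~= 0.10).  The taxicab measure
has no aspect-ratio or anisotropic variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import RegionSet

__all__ = [
    "DEFAULT_SIGMA2",
    "DEFAULT_NU_ANISO",
    "CentralBiasParams",
    "euclidean_cb",
    "gaussian_cb",
    "taxicab_cb",
    "central_bias_vector",
    "canonical_variants",
]

DEFAULT_SIGMA2 = 0.23  # Gaussian horizontal variance, units of half image width
DEFAULT_NU_ANISO = 0.45  # default vertical anisotropy scaling


@dataclass(frozen=True)
class CentralBiasParams:
    """Selects one distance-to-center measure and its parameters.

    ``nu`` and ``sigma2`` are ignored by the taxicab measure; supplying a
    ``variant`` label other than "isotropic" together with ``taxicab``
    is an error (the taxonomy has no such cells).
    """

    measure: str = "euclidean"
    nu: float = 1.0
    sigma2: float = DEFAULT_SIGMA2
    name: str | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("euclidean", "gaussian", "taxicab"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.measure == "taxicab":
            if self.nu != 1.0:
                raise ValueError(
                    "the taxicab measure has no aspect-ratio/anisotropic variant"
                )
        else:
            if self.nu <= 0:
                raise ValueError("nu must be positive")
            if self.sigma2 <= 0:
                raise ValueError("sigma2 must be positive")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.measure == "taxicab":
            return "cb_taxicab"
        return f"cb_{self.measure}_nu{self.nu:g}"


def _offsets(geom_xy: np.ndarray, image_width: int, image_height: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (dx, dy) of points from the image center (half width = 1)."""
    half_w = image_width / 2.0
    cx, cy = image_width / 2.0, image_height / 2.0
    xy = np.atleast_2d(np.asarray(geom_xy, dtype=float))
    return (xy[:, 0] - cx) / half_w, (xy[:, 1] - cy) / half_w


def euclidean_cb(dx: np.ndarray, dy: np.ndarray, nu: float = 1.0) -> np.ndarray:
    """sqrt(dx^2 + dy^2/nu) on normalized offsets."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    return np.sqrt(dx**2 + dy**2 / nu)


def gaussian_cb(dx: np.ndarray, dy: np.ndarray, sigma2: float = DEFAULT_SIGMA2, nu: float = 1.0) -> np.ndarray:
    """-exp(-dx^2/(2 sigma2) - dy^2/(2 sigma2 nu)); in (-1, 0], -1 at center."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if nu <= 0:
        raise ValueError("nu must be positive")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    return -np.exp(-(dx**2) / (2 * sigma2) - dy**2 / (2 * sigma2 * nu))


def taxicab_cb(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """|dx| + |dy| on normalized offsets."""
    return np.abs(np.asarray(dx, dtype=float)) + np.abs(np.asarray(dy, dtype=float))


def central_bias_vector(regions: RegionSet, params: CentralBiasParams) -> np.ndarray:
    """Distance-to-center value for every region center, in region order."""
    dx, dy = _offsets(regions.centers, regions.image_width, regions.image_height)
    if params.measure == "euclidean":
        return euclidean_cb(dx, dy, params.nu)
    if params.measure == "gaussian":
        return gaussian_cb(dx, dy, params.sigma2, params.nu)
    return taxicab_cb(dx, dy)


def canonical_variants(aspect_ratio: float, sigma2: float = DEFAULT_SIGMA2) -> list[CentralBiasParams]:
    """The seven canonical central-bias predictors for a given image aspect.

    {euclidean, gaussian} x {isotropic nu=1, aspect-ratio nu=h/w,
    anisotropic nu=0.45} plus the taxicab distance.  ``aspect_ratio`` is
    height/width (0.75 for 4:3 images).
    """
    if aspect_ratio <= 0:
        raise ValueError("aspect ratio must be positive")
    out: list[CentralBiasParams] = []
    for measure in ("euclidean", "gaussian"):
        for tag, nu in (("iso", 1.0), ("aspect", aspect_ratio), ("aniso", DEFAULT_NU_ANISO)):
            out.append(
                CentralBiasParams(
                    measure=measure, nu=nu, sigma2=sigma2, name=f"cb_{measure}_{tag}"
                )
            )
    out.append(CentralBiasParams(measure="taxicab", name="cb_taxicab"))
    return out
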