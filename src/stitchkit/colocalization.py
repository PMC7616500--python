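"""Pixel-level co-occurrence statistics for binary RNA-ISH expression masks.

The statistic is the conditional probability that a target gene is present
in a pixel given that the reference gene is present in the same pixel:
dual-positive pixel count divided by the reference-positive pixel count.
It is asymmetric in its two arguments and uses same-pixel identity only —
no spatial tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MaskImage",
    "CoocResult",
    "cooccurrence",
    "probability_from_counts",
    "mask_from_image",
    "read_mask",
]

#: Physical pixel size of the imaging setup the default statistics assume.
DEFAULT_PIXEL_SIZE_UM = 0.14


@dataclass
class MaskImage:
    """Binary expression mask with physical pixel size."""

    grid: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    gene: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.dtype != bool:
            uniq = np.unique(grid)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask must contain binary values only")
            grid = grid.astype(bool)
        if grid.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={grid.ndim}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.grid = grid

    @property
    def n_positive(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class CoocResult:
    dual_positive: int
    reference_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.dual_positive <= self.reference_total):
            raise ValueError("require 0 <= dual_positive <= reference_total")
        if self.reference_total == 0:
            raise ValueError("reference_total must be positive")

    @property
    def probability(self) -> float:
        return self.dual_positive / self.reference_total


def cooccurrence(target: MaskImage, reference: MaskImage) -> CoocResult:
    """Probability that ``target`` is positive where ``reference`` is positive.

    Tallies pixels where both masks are positive and divides by the total
    number of reference-positive pixels, regardless of the target elsewhere.
    """
    if target.grid.shape != reference.grid.shape:
        raise ValueError(
            f"mask shapes differ: {target.grid.shape} vs {reference.grid.shape}"
        )
    if not np.isclose(target.pixel_size_um, reference.pixel_size_um):
        raise ValueError(
            f"pixel sizes differ: {target.pixel_size_um} vs {reference.pixel_size_um}"
        )
    reference_total = reference.n_positive
    if reference_total == 0:
        raise ValueError("reference mask has no positive pixels")
    dual = int(np.logical_and(target.grid, reference.grid).sum())
    return CoocResult(dual_positive=dual, reference_total=reference_total)


def probability_from_counts(dual: float, total: float) -> float:
    """Co-occurrence probability from already-tallied pixel counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    if dual < 0 or dual > total:
        raise ValueError("require 0 <= dual <= total")
    return dual / total


def mask_from_image(
    image: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    gene: str = "",
) -> MaskImage:
    """Convenience Otsu-threshold binarization of an intensity image.

    This is plumbing for quick exploration only; production masks come from
    an upstream pixel classifier.
    """
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)
    return MaskImage(image > threshold_otsu(image), pixel_size_um, gene)


def read_mask(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    gene: str = "",
) -> MaskImage:
    """Read a binary mask from TIFF/PNG (any nonzero pixel is positive)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse channels; masks are single-plane
        arr = arr.max(axis=-1)
    return MaskImage(arr != 0, pixel_size_um, gene or Path(path).stem)
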