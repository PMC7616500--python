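"""Stitch multiple Visium capture areas into one reconstructed frame.

Spot coordinates of each section are mapped into a common frame by
per-section affine transforms, section images are composited under an
explicit priority rule (the centre section wins in overlaps), and the
count matrices are merged by outer join on gene identifiers — keeping
every spot, including those under image overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage import transform as sktransform

from .transforms import AffineTransform2D
from .visium_io import CaptureArea

__all__ = [
    "AffineTransform2D",
    "StitchedSection",
    "apply_affine",
    "estimate_affine_from_landmarks",
    "transform_spots",
    "composite_images",
    "merge_sections",
]

#: Separator used when suffixing barcodes with their section id.
BARCODE_SUFFIX_SEP = "-"


@dataclass
class StitchedSection:
    """A merged multi-section object in one reconstructed frame.

    ``spots`` carries reconstructed-frame ``pxl_row``/``pxl_col`` plus a
    ``section`` provenance column; ``counts`` is genes x (all spots);
    ``frame_offset`` is the ``(x, y)`` translation that was subtracted so the
    composite bounding box starts at (0, 0).
    """

    spots: pd.DataFrame
    counts: sp.csr_matrix
    genes: list[str]
    image: np.ndarray
    frame_offset: tuple[float, float]
    transforms_used: dict[str, AffineTransform2D] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise ValueError("counts shape does not match genes x spots")
        if self.spots["barcode"].duplicated().any():
            raise ValueError("barcodes must be unique after suffixing")

    @property
    def section_ids(self) -> list[str]:
        return list(self.transforms_used)


def apply_affine(t: AffineTransform2D, points) -> np.ndarray:
    """Apply ``t`` to an ``(n, 2)`` array of ``(x, y)`` points."""
    return t(np.asarray(points, dtype=float))


def estimate_affine_from_landmarks(src, dst) -> AffineTransform2D:
    """Least-squares affine from >=3 non-collinear landmark pairs.

    Solves ``dst ~ A @ src + b`` row-wise; on noiseless consistent input the
    generating transform is recovered to machine precision.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must both be (n, 2) point arrays")
    if src.shape[0] < 3:
        raise ValueError("at least 3 landmark pairs are required")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine is underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    # coef columns: [x', y'] as functions of (x, y, 1)
    a, c, e = coef[0, 0], coef[1, 0], coef[2, 0]
    b, d, f = coef[0, 1], coef[1, 1], coef[2, 1]
    return AffineTransform2D(a, b, c, d, e, f)


def transform_spots(area: CaptureArea, t: AffineTransform2D) -> pd.DataFrame:
    """Map a section's spot pixel coordinates into the reconstructed frame.

    Returns a copy of the spot table with transformed ``pxl_row``/``pxl_col``,
    barcodes suffixed with the section id, and a ``section`` column;
    ``array_row``/``array_col`` are preserved unchanged.
    """
    if area.n_spots == 0:
        raise ValueError(f"section {area.section_id!r} has no spots")
    spots = area.spots.copy()
    xy = np.column_stack(
        [spots["pxl_col"].to_numpy(float), spots["pxl_row"].to_numpy(float)]
    )
    out = apply_affine(t, xy)
    spots["pxl_col"] = out[:, 0]
    spots["pxl_row"] = out[:, 1]
    spots["barcode"] = (
        spots["barcode"].astype(str) + BARCODE_SUFFIX_SEP + area.section_id
    )
    spots["section"] = area.section_id
    return spots


def _corners(shape: tuple[int, ...]) -> np.ndarray:
    h, w = shape[0], shape[1]
    return np.array(
        [[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float
    )


def _warp_into_canvas(
    image: np.ndarray,
    t: AffineTransform2D,
    offset: tuple[float, float],
    canvas_shape: tuple[int, int],
    order: int,
    fill: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one section image onto the global canvas.

    Returns ``(warped, covered)`` where ``covered`` marks canvas pixels whose
    inverse-mapped position falls inside the source pixel-centre extent.
    """
    # canvas (x, y) -> global -> source section coordinates
    shift = AffineTransform2D.translation(offset[0], offset[1])
    canvas_to_src = t.inverse().compose(shift)
    ys, xs = np.mgrid[0 : canvas_shape[0], 0 : canvas_shape[1]]
    src = canvas_to_src(np.column_stack([xs.ravel(), ys.ravel()]))
    sx = src[:, 0].reshape(canvas_shape)
    sy = src[:, 1].reshape(canvas_shape)
    eps = 1e-9
    covered = (
        (sx >= -eps)
        & (sx <= image.shape[1] - 1 + eps)
        & (sy >= -eps)
        & (sy <= image.shape[0] - 1 + eps)
    )
    tf = sktransform.AffineTransform(matrix=canvas_to_src.matrix)

    def _warp2d(img2d: np.ndarray) -> np.ndarray:
        return sktransform.warp(
            img2d.astype(float),
            tf,
            output_shape=canvas_shape,
            order=order,
            cval=fill,
            preserve_range=True,
            clip=False,
        )

    if image.ndim == 2:
        warped = _warp2d(image)
    elif image.ndim == 3:
        warped = np.stack([_warp2d(image[..., k]) for k in range(image.shape[2])], axis=-1)
    else:
        raise ValueError(f"images must be 2D or 3-channel, got ndim={image.ndim}")
    return warped, covered


def composite_images(
    images: dict[str, np.ndarray],
    transforms: dict[str, AffineTransform2D],
    priority: list[str],
    *,
    interpolation_order: int = 1,
    fill: float = 0.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Composite transformed section images onto one canvas.

    The canvas is the bounding box of all transformed image corners,
    translated so its minimum corner is (0, 0); the translation is returned
    as ``frame_offset`` in ``(x, y)`` order. Each canvas pixel takes the
    value of the highest-priority section covering it (``priority[0]`` wins).
    """
    if not images:
        raise ValueError("no images to composite")
    if sorted(priority) != sorted(images):
        raise ValueError("priority must list every section exactly once")
    if set(images) - set(transforms):
        raise ValueError("every image needs a transform")

    corners = np.vstack(
        [apply_affine(transforms[sid], _corners(images[sid].shape)) for sid in priority]
    )
    xmin, ymin = np.floor(corners.min(axis=0))
    xmax, ymax = np.ceil(corners.max(axis=0))
    offset = (float(xmin), float(ymin))
    canvas_shape = (int(ymax - ymin) + 1, int(xmax - xmin) + 1)

    n_channels = {images[s].shape[2] for s in priority if images[s].ndim == 3}
    if len(n_channels) > 1 or (n_channels and any(images[s].ndim == 2 for s in priority)):
        raise ValueError("all images must share the same channel structure")
    out_shape = canvas_shape + (n_channels.pop(),) if n_channels else canvas_shape
    canvas = np.full(out_shape, fill, dtype=float)

    # paint lowest priority first so the highest-priority section wins
    for sid in reversed(priority):
        warped, covered = _warp_into_canvas(
            images[sid], transforms[sid], offset, canvas_shape,
            interpolation_order, fill,
        )
        canvas[covered] = warped[covered]
    return canvas, offset


def merge_sections(
    areas: list[CaptureArea],
    transforms: dict[str, AffineTransform2D],
    centre_id: str,
    *,
    priority: list[str] | None = None,
    interpolation_order: int = 1,
    fill: float = 0.0,
    scale_tolerance: float = 0.01,
) -> StitchedSection:
    """Merge capture areas into one :class:`StitchedSection`.

    All spots are kept (none dropped in overlaps); counts are merged by outer
    join on gene identifiers with zero fill; images are composited with
    ``centre_id`` first in priority; the frame offset is applied consistently
    to spots and image.
    """
    if not areas:
        raise ValueError("no capture areas to merge")
    ids = [a.section_id for a in areas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate section ids: {ids}")
    missing = [sid for sid in ids if sid not in transforms]
    if missing:
        raise ValueError(f"missing transforms for sections {missing}")
    if centre_id not in ids:
        raise ValueError(f"centre_id {centre_id!r} not among sections {ids}")

    diameters = [a.scale.spot_diameter_fullres for a in areas]
    if max(diameters) > min(diameters) * (1 + scale_tolerance):
        raise ValueError(
            "section scale factors differ by more than "
            f"{scale_tolerance:.0%}; refusing to stitch across chips"
        )

    if priority is None:
        priority = [centre_id] + [sid for sid in ids if sid != centre_id]
    elif priority[0] != centre_id:
        raise ValueError("centre_id must be first in priority")

    image, offset = composite_images(
        {a.section_id: a.image for a in areas},
        {sid: transforms[sid] for sid in ids},
        priority,
        interpolation_order=interpolation_order,
        fill=fill,
    )

    frames = []
    for area in areas:
        spots = transform_spots(area, transforms[area.section_id])
        spots["pxl_col"] -= offset[0]
        spots["pxl_row"] -= offset[1]
        frames.append(spots)
    all_spots = pd.concat(frames, ignore_index=True)

    # outer join on gene ids, zero fill; gene order: first-seen across sections
    genes: list[str] = []
    seen: set[str] = set()
    for area in areas:
        for g in area.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    gene_index = {g: i for i, g in enumerate(genes)}
    blocks = []
    for area in areas:
        block = sp.lil_matrix((len(genes), area.n_spots), dtype=area.counts.dtype)
        rows = [gene_index[g] for g in area.genes]
        block[rows, :] = area.counts
        blocks.append(block.tocsr())
    counts = sp.hstack(blocks, format="csr")

    return StitchedSection(
        spots=all_spots,
        counts=counts,
        genes=genes,
        image=image,
        frame_offset=offset,
        transforms_used={sid: transforms[sid] for sid in ids},
    )
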