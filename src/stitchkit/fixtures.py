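"""Seeded generators of synthetic inputs for every other module.

Everything here is deterministic plumbing: Visium-like capture areas on a
reduced hexagonal lattice, overlapping section sets with known ground-truth
transforms, doublet-score tables with planted high-score clusters, and
binary mask pairs with exact joint-occupancy counts.  No attempt is made to
simulate realistic biology — fixtures only guarantee the statistical and
geometric structure their consumers need.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage import transform as sktransform

from .colocalization import MaskImage
from .transforms import AffineTransform2D
from .visium_io import CaptureArea, ScaleFactors, SPOT_COLUMNS

__all__ = [
    "FixtureSpec",
    "make_capture_area",
    "make_overlapping_sections",
    "make_doublet_scores",
    "make_mask_pair",
]

# lattice geometry: half-pitch between adjacent array columns, hexagonal row
# spacing, and an image margin so all spots sit inside the section image
COL_HALF_PITCH_PX = 10.0
ROW_PITCH_PX = 10.0 * np.sqrt(3) / 2
LATTICE_MARGIN_PX = 20.0

# negative binomial count model: mean r*(1-p)/p ~ 4.7 per gene per spot
NB_DISPERSION = 2.0
NB_P = 0.3


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic capture area (same spec => identical bytes)."""

    seed: int
    grid_rows: int = 8
    grid_cols: int = 16
    n_genes: int = 50
    image_shape: tuple[int, int] = (180, 200)
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid_rows and grid_cols must both be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _section_rng(spec: FixtureSpec, section_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, zlib.crc32(section_id.encode("utf-8"))]
    )


def lattice_positions(grid_rows: int, grid_cols: int) -> list[tuple[int, int]]:
    """Array positions on the reduced Visium lattice (col parity == row parity)."""
    return [
        (r, c)
        for r in range(grid_rows)
        for c in range(grid_cols)
        if (r % 2) == (c % 2)
    ]


def _section_image(spec: FixtureSpec, rng: np.random.Generator, phase: float) -> np.ndarray:
    h, w = spec.image_shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    base = 60.0 + 80.0 * rows / max(h - 1, 1) + 40.0 * cols / max(w - 1, 1)
    stripes = 30.0 * np.sin(2 * np.pi * (cols / 23.0 + phase))
    noise = rng.normal(0.0, spec.noise_sd, size=(h, w))
    return np.clip(base + stripes + noise, 0.0, 255.0).astype(np.float32)


def make_capture_area(spec: FixtureSpec, section_id: str = "S0") -> CaptureArea:
    """Generate one Visium-like capture area.

    Spots occupy the reduced hexagonal lattice (array_col parity equals
    array_row parity); pixel coordinates follow the stated pitch constants;
    counts are negative binomial; the image carries a per-section stripe
    phase so sections are visually distinguishable.
    """
    rng = _section_rng(spec, section_id)
    positions = lattice_positions(spec.grid_rows, spec.grid_cols)
    spots = pd.DataFrame(
        {
            "barcode": [f"SPOT{i:05d}-1" for i in range(len(positions))],
            "in_tissue": True,
            "array_row": [r for r, _ in positions],
            "array_col": [c for _, c in positions],
            "pxl_row": [LATTICE_MARGIN_PX + r * ROW_PITCH_PX for r, _ in positions],
            "pxl_col": [LATTICE_MARGIN_PX + c * COL_HALF_PITCH_PX for _, c in positions],
        },
        columns=SPOT_COLUMNS,
    )
    counts = rng.negative_binomial(
        NB_DISPERSION, NB_P, size=(spec.n_genes, len(positions))
    ).astype(np.int64)
    phase = (zlib.crc32(section_id.encode("utf-8")) % 97) / 97.0
    image = _section_image(spec, rng, phase)
    return CaptureArea(
        section_id=section_id,
        spots=spots,
        counts=sp.csr_matrix(counts),
        genes=[f"GENE{j:04d}" for j in range(spec.n_genes)],
        image=image,
        scale=ScaleFactors(
            spot_diameter_fullres=13.0,
            tissue_hires_scalef=0.5,
            tissue_lowres_scalef=0.1,
        ),
    )


def _global_scene(spec: FixtureSpec, bounds: tuple[float, float, float, float]) -> tuple[np.ndarray, tuple[float, float]]:
    """A smooth deterministic global image covering ``bounds`` (xmin,ymin,xmax,ymax)."""
    xmin, ymin, xmax, ymax = bounds
    origin = (np.floor(xmin) - 2, np.floor(ymin) - 2)
    h = int(np.ceil(ymax) - origin[1]) + 4
    w = int(np.ceil(xmax) - origin[0]) + 4
    rng = np.random.default_rng([spec.seed, 0xC0FFEE])
    ys = (np.arange(h) + origin[1])[:, None]
    xs = (np.arange(w) + origin[0])[None, :]
    scene = (
        100.0
        + 60.0 * np.sin(2 * np.pi * xs / 61.0)
        + 50.0 * np.cos(2 * np.pi * ys / 47.0)
        + 0.1 * xs
        + rng.normal(0.0, spec.noise_sd, size=(h, w))
    )
    return np.clip(scene, 0.0, 255.0).astype(np.float32), origin


def make_overlapping_sections(
    spec: FixtureSpec,
    n_sections: int,
    true_transforms: list[AffineTransform2D] | None = None,
) -> tuple[list[CaptureArea], list[AffineTransform2D]]:
    """Generate sections consistent with known section-to-global transforms.

    Each section's image is sampled from one shared global scene through its
    transform, so overlap regions genuinely show the same structure; spot
    pixel coordinates live in section frames and map to the global frame via
    the returned ground-truth transforms.  Default transforms are
    translations giving ~50% horizontal overlap between consecutive sections.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    h, w = spec.image_shape
    if true_transforms is None:
        true_transforms = [
            AffineTransform2D.translation(i * 0.5 * w, i * 0.1 * h)
            for i in range(n_sections)
        ]
    if len(true_transforms) != n_sections:
        raise ValueError("need one transform per section")
    for t in true_transforms:
        if abs(t.determinant) < 1e-12:  # pragma: no cover - dataclass guards too
            raise ValueError("singular ground-truth transform")

    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    pts = np.vstack([t(corners) for t in true_transforms])
    scene, origin = _global_scene(
        spec, (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    )

    areas = []
    for i, t in enumerate(true_transforms):
        area = make_capture_area(spec, section_id=f"S{i}")
        # section pixel (x, y) -> global -> scene array coordinates
        shift = AffineTransform2D.translation(-origin[0], -origin[1])
        sec_to_scene = shift.compose(t)
        image = sktransform.warp(
            scene.astype(float),
            sktransform.AffineTransform(matrix=sec_to_scene.matrix),
            output_shape=(h, w),
            order=1,
            preserve_range=True,
            clip=False,
        ).astype(np.float32)
        area.image = image
        areas.append(area)
    return areas, list(true_transforms)


def make_doublet_scores(
    n_clusters: int,
    cells_per_cluster: int,
    planted_doublet_clusters: set[str] | set[int] | None = None,
    base_score: float = 0.05,
    doublet_score: float = 0.6,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell doublet-score table with optional planted doublet clusters.

    Returns columns ``cell_id``, ``lane_id``, ``raw_score``, ``fine_cluster``
    and the ground-truth flag ``is_doublet_truth`` for power evaluation.
    """
    if not (0 <= base_score < doublet_score <= 1):
        raise ValueError("require 0 <= base_score < doublet_score <= 1")
    if n_clusters < 1 or cells_per_cluster < 1:
        raise ValueError("n_clusters and cells_per_cluster must be >= 1")
    clusters = [f"c{i}" for i in range(n_clusters)]
    planted = {p if isinstance(p, str) else f"c{p}" for p in (planted_doublet_clusters or set())}
    unknown = planted - set(clusters)
    if unknown:
        raise ValueError(f"planted labels {sorted(unknown)} not among cluster labels")
    rng = np.random.default_rng(seed)
    rows = []
    for cl in clusters:
        centre = doublet_score if cl in planted else base_score
        scores = np.clip(
            rng.normal(centre, noise_sd, size=cells_per_cluster), 0.0, 1.0
        )
        for j, s in enumerate(scores):
            rows.append((f"{cl}_cell{j:04d}", "lane0", float(s), cl, cl in planted))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "lane_id", "raw_score", "fine_cluster", "is_doublet_truth"],
    )


def make_mask_pair(
    shape: tuple[int, int],
    n_ref: int,
    n_dual: int,
    seed: int = 0,
    n_target_only: int = 0,
    pixel_size_um: float = 0.14,
) -> tuple[MaskImage, MaskImage]:
    """Mask pair with exact occupancy counts: returns ``(reference, target)``.

    The reference mask has exactly ``n_ref`` positive pixels; the target is
    positive on exactly ``n_dual`` of them plus ``n_target_only`` pixels
    outside the reference, so the co-occurrence probability of (target |
    reference) is ``n_dual / n_ref`` by construction.
    """
    total = int(shape[0]) * int(shape[1])
    if not (0 <= n_dual <= n_ref <= total):
        raise ValueError("require 0 <= n_dual <= n_ref <= total pixels")
    if n_ref == 0:
        raise ValueError("reference mask needs at least one positive pixel")
    if n_target_only > total - n_ref:
        raise ValueError("n_target_only exceeds pixels outside the reference")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    ref_idx = perm[:n_ref]
    dual_idx = ref_idx[:n_dual]
    extra_idx = perm[n_ref : n_ref + n_target_only]
    ref = np.zeros(total, dtype=bool)
    ref[ref_idx] = True
    tgt = np.zeros(total, dtype=bool)
    tgt[dual_idx] = True
    tgt[extra_idx] = True
    return (
        MaskImage(ref.reshape(shape), pixel_size_um=pixel_size_um, gene="REF"),
        MaskImage(tgt.reshape(shape), pixel_size_um=pixel_size_um, gene="TARGET"),
    )
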