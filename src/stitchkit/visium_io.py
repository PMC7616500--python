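"""Readers and writers for the on-disk formats the toolkit touches.

Covers the Space Ranger spatial layout (``tissue_positions_list.csv``,
``scalefactors_json.json``, MTX feature-barcode triplet, section image),
affine-matrix exports (a canonical JSON dialect plus a TrakEM2 XML subset),
and the stitched annotated-matrix container (h5ad dialect + TIFF image).

All pixel coordinates are full-resolution image pixels, row/col order,
0-based, following the Space Ranger convention.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from .transforms import AffineTransform2D

if TYPE_CHECKING:  # pragma: no cover
    from .stitcher import StitchedSection

__all__ = [
    "SpotRecord",
    "ScaleFactors",
    "CaptureArea",
    "SPOT_COLUMNS",
    "read_tissue_positions",
    "write_tissue_positions",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_affine_file",
    "write_affine_file",
    "read_capture_area",
    "write_capture_area",
    "read_stitched",
    "write_stitched",
]

#: Canonical column order for spot tables (Space Ranger v1 dialect).
SPOT_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row",
    "pxl_col",
]


@dataclass(frozen=True)
class SpotRecord:
    """One row of a tissue-positions table."""

    barcode: str
    in_tissue: bool
    array_row: int
    array_col: int
    pxl_row: float
    pxl_col: float

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("barcode must be non-empty")
        if self.array_row < 0 or self.array_col < 0:
            raise ValueError("array_row/array_col must be >= 0")


@dataclass(frozen=True)
class ScaleFactors:
    spot_diameter_fullres: float
    tissue_hires_scalef: float
    tissue_lowres_scalef: float

    def __post_init__(self) -> None:
        for name in (
            "spot_diameter_fullres",
            "tissue_hires_scalef",
            "tissue_lowres_scalef",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CaptureArea:
    """One Visium capture area: spot table, counts, image and scale factors.

    ``spots`` is a DataFrame with the columns in :data:`SPOT_COLUMNS`;
    ``counts`` is a genes x spots matrix (sparse CSR) aligned with ``genes``
    on rows and ``spots`` on columns.
    """

    section_id: str
    spots: pd.DataFrame
    counts: sp.csr_matrix
    genes: list[str]
    image: np.ndarray
    scale: ScaleFactors

    def __post_init__(self) -> None:
        if not self.section_id:
            raise ValueError("section_id must be non-empty")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.spots)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if self.image is None or self.image.size == 0:
            raise ValueError("image must be non-empty")
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns {missing}")

    @property
    def n_spots(self) -> int:
        return len(self.spots)


def spots_to_frame(records: list[SpotRecord]) -> pd.DataFrame:
    """Convert a list of :class:`SpotRecord` to the canonical DataFrame."""
    return pd.DataFrame(
        [
            (r.barcode, r.in_tissue, r.array_row, r.array_col, r.pxl_row, r.pxl_col)
            for r in records
        ],
        columns=SPOT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# tissue positions


def read_tissue_positions(path: str | Path) -> list[SpotRecord]:
    """Parse a ``tissue_positions_list.csv`` into spot records.

    Accepts both Space Ranger dialects: headerless (v1) and with a header
    line (v2, ``tissue_positions.csv``). Malformed rows raise
    :class:`ValueError` naming the offending line number.
    """
    path = Path(path)
    records: list[SpotRecord] = []
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    start = 0
    if lines and lines[0].split(",")[0].strip().lower() == "barcode":
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != 6:
            raise ValueError(
                f"{path}:{lineno}: expected 6 comma-separated fields, "
                f"got {len(fields)}"
            )
        try:
            in_tissue = int(fields[1])
            if in_tissue not in (0, 1):
                raise ValueError(f"in_tissue must be 0 or 1, got {fields[1]!r}")
            rec = SpotRecord(
                barcode=fields[0],
                in_tissue=bool(in_tissue),
                array_row=int(fields[2]),
                array_col=int(fields[3]),
                pxl_row=float(fields[4]),
                pxl_col=float(fields[5]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        records.append(rec)
    return records


def write_tissue_positions(spots: pd.DataFrame, path: str | Path) -> None:
    """Write a headerless (v1 dialect) tissue-positions CSV."""
    out = spots[SPOT_COLUMNS].copy()
    out["in_tissue"] = out["in_tissue"].astype(int)
    out.to_csv(path, header=False, index=False)


# ---------------------------------------------------------------------------
# MTX triplet


def _find_one(directory: Path, stem: str) -> Path:
    for cand in (directory / stem, directory / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def _read_tsv_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df[0].tolist()


def read_counts_mtx(directory: str | Path) -> tuple[list[str], list[str], sp.csr_matrix]:
    """Read an MTX triplet (``matrix.mtx``, ``features.tsv``, ``barcodes.tsv``).

    Returns ``(gene_ids, barcodes, matrix)`` with the matrix genes x barcodes.
    Gzipped triplets are accepted. Dimension mismatches raise ValueError.
    """
    directory = Path(directory)
    matrix = sp.csr_matrix(scipy.io.mmread(_find_one(directory, "matrix.mtx")))
    genes = _read_tsv_column(_find_one(directory, "features.tsv"))
    barcodes = _read_tsv_column(_find_one(directory, "barcodes.tsv"))
    if matrix.shape[0] != len(genes):
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but features.tsv lists "
            f"{len(genes)} genes"
        )
    if matrix.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} barcodes"
        )
    return genes, barcodes, matrix


def write_counts_mtx(
    genes: list[str],
    barcodes: list[str],
    matrix: sp.spmatrix,
    directory: str | Path,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix = sp.coo_matrix(matrix)
    if matrix.shape != (len(genes), len(barcodes)):
        raise ValueError("matrix shape does not match gene/barcode lists")
    scipy.io.mmwrite(str(directory / "matrix.mtx"), matrix)
    pd.DataFrame({0: genes}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({0: barcodes}).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# affine files

_MATRIX_RE = re.compile(
    r"matrix\(\s*([^,\s]+)\s*,\s*([^,\s]+)\s*,\s*([^,\s]+)\s*,"
    r"\s*([^,\s]+)\s*,\s*([^,\s]+)\s*,\s*([^,)\s]+)\s*\)"
)


def parse_matrix_string(text: str) -> AffineTransform2D:
    """Parse a TrakEM2/SVG ``matrix(a,b,c,d,e,f)`` string."""
    m = _MATRIX_RE.search(text)
    if m is None:
        raise ValueError(f"not a matrix(a,b,c,d,e,f) string: {text!r}")
    return AffineTransform2D(*(float(g) for g in m.groups()))


def read_affine_file(path: str | Path) -> dict[str, AffineTransform2D]:
    """Read per-section affine transforms.

    Two dialects are supported:

    * canonical JSON: ``{"resolution": "fullres", "transforms":
      {section_id: [a, b, c, d, e, f], ...}}`` — the ``resolution`` header is
      mandatory and must be ``"fullres"`` (the toolkit refuses to guess which
      image scale exported matrices act on);
    * a TrakEM2 XML subset: any elements carrying a ``transform="matrix(...)"``
      attribute, keyed by their ``title`` (or ``oid``) attribute.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("<"):
        return _read_trakem_xml(text)
    payload = json.loads(text)
    if "resolution" not in payload:
        raise ValueError(
            f"{path}: affine file must declare 'resolution' "
            "(which image scale the matrices act on)"
        )
    if payload["resolution"] != "fullres":
        raise ValueError(
            f"{path}: unsupported resolution {payload['resolution']!r}; "
            "only 'fullres' matrices are accepted"
        )
    transforms = payload.get("transforms")
    if not isinstance(transforms, dict):
        raise ValueError(f"{path}: missing 'transforms' mapping")
    out: dict[str, AffineTransform2D] = {}
    for sid, coeffs in transforms.items():
        if len(coeffs) != 6:
            raise ValueError(f"{path}: section {sid!r}: expected 6 coefficients")
        out[sid] = AffineTransform2D(*(float(v) for v in coeffs))
    return out


def _read_trakem_xml(text: str) -> dict[str, AffineTransform2D]:
    # TrakEM2 exports are DTD-prefixed; strip anything before the root element.
    root_start = text.find("<project")
    if root_start == -1:
        root_start = text.find("<trakem2")
    if root_start > 0:
        text = text[root_start:]
    root = ET.fromstring(text)
    out: dict[str, AffineTransform2D] = {}
    for elem in root.iter():
        transform = elem.attrib.get("transform")
        if transform is None or "matrix" not in transform:
            continue
        sid = elem.attrib.get("title") or elem.attrib.get("oid")
        if sid is None:
            raise ValueError("transform element lacks a title/oid attribute")
        out[sid] = parse_matrix_string(transform)
    if not out:
        raise ValueError("no matrix(...) transforms found in XML")
    return out


def write_affine_file(
    transforms: dict[str, AffineTransform2D],
    path: str | Path,
    resolution: str = "fullres",
) -> None:
    payload = {
        "resolution": resolution,
        "transforms": {
            sid: [float(v) for v in t.coefficients] for sid, t in transforms.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# capture-area directory layout


def write_capture_area(area: CaptureArea, directory: str | Path) -> None:
    """Materialize a capture area in Space Ranger layout::

        DIR/spatial/tissue_positions_list.csv
        DIR/spatial/scalefactors_json.json
        DIR/spatial/tissue_image.tif
        DIR/filtered_feature_bc_matrix/{matrix.mtx,features.tsv,barcodes.tsv}
    """
    directory = Path(directory)
    spatial = directory / "spatial"
    spatial.mkdir(parents=True, exist_ok=True)
    write_tissue_positions(area.spots, spatial / "tissue_positions_list.csv")
    (spatial / "scalefactors_json.json").write_text(
        json.dumps(
            {
                "spot_diameter_fullres": area.scale.spot_diameter_fullres,
                "tissue_hires_scalef": area.scale.tissue_hires_scalef,
                "tissue_lowres_scalef": area.scale.tissue_lowres_scalef,
            }
        )
    )
    tifffile.imwrite(spatial / "tissue_image.tif", area.image)
    write_counts_mtx(
        area.genes,
        area.spots["barcode"].tolist(),
        area.counts,
        directory / "filtered_feature_bc_matrix",
    )


def read_capture_area(directory: str | Path, section_id: str | None = None) -> CaptureArea:
    """Read a capture area written by :func:`write_capture_area`."""
    directory = Path(directory)
    if section_id is None:
        section_id = directory.name
    spatial = directory / "spatial"
    records = read_tissue_positions(spatial / "tissue_positions_list.csv")
    spots = spots_to_frame(records)
    sf = json.loads((spatial / "scalefactors_json.json").read_text())
    scale = ScaleFactors(
        spot_diameter_fullres=sf["spot_diameter_fullres"],
        tissue_hires_scalef=sf["tissue_hires_scalef"],
        tissue_lowres_scalef=sf["tissue_lowres_scalef"],
    )
    image = tifffile.imread(spatial / "tissue_image.tif")
    genes, barcodes, matrix = read_counts_mtx(directory / "filtered_feature_bc_matrix")
    if barcodes != spots["barcode"].tolist():
        # align counts columns to the spot table order
        order = pd.Index(barcodes).get_indexer(spots["barcode"])
        if (order < 0).any():
            raise ValueError(f"{directory}: barcodes.tsv does not match spot table")
        matrix = matrix[:, order]
    return CaptureArea(
        section_id=section_id,
        spots=spots,
        counts=sp.csr_matrix(matrix),
        genes=genes,
        image=image,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# stitched container (h5ad dialect + TIFF sidecar)


def _default_image_path(path: Path) -> Path:
    return path.with_suffix(".image.tif")


def write_stitched(
    stitched: "StitchedSection",
    path: str | Path,
    image_path: str | Path | None = None,
) -> None:
    """Serialize a stitched section as h5ad plus a TIFF image sidecar.

    Layout: ``X`` holds spots x genes counts, ``obs`` the spot table with a
    categorical ``section`` provenance column, ``obsm['spatial']`` the
    reconstructed-frame ``(x, y)`` coordinates, and ``uns`` the frame offset
    and the transforms used.
    """
    path = Path(path)
    image_path = Path(image_path) if image_path else _default_image_path(path)
    if len(stitched.genes) == 0:
        raise ValueError("cannot write a stitched section with an empty gene set")
    spots = stitched.spots
    obs = pd.DataFrame(
        {
            "in_tissue": spots["in_tissue"].astype(bool).to_numpy(),
            "array_row": spots["array_row"].to_numpy(),
            "array_col": spots["array_col"].to_numpy(),
            "section": pd.Categorical(spots["section"]),
        },
        index=pd.Index(spots["barcode"].astype(str), name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(stitched.counts.T),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(stitched.genes, name="gene_id")),
    )
    adata.obsm["spatial"] = np.column_stack(
        [spots["pxl_col"].to_numpy(float), spots["pxl_row"].to_numpy(float)]
    )
    adata.uns["frame_offset"] = np.asarray(stitched.frame_offset, dtype=float)
    adata.uns["transforms"] = {
        sid: [float(v) for v in t.coefficients]
        for sid, t in stitched.transforms_used.items()
    }
    adata.uns["coordinate_convention"] = "spatial[:,0]=pxl_col(x), spatial[:,1]=pxl_row(y), fullres 0-based"
    adata.write_h5ad(path)
    tifffile.imwrite(image_path, stitched.image)


def read_stitched(
    path: str | Path, image_path: str | Path | None = None
) -> "StitchedSection":
    from .stitcher import StitchedSection

    path = Path(path)
    image_path = Path(image_path) if image_path else _default_image_path(path)
    adata = ad.read_h5ad(path)
    image = tifffile.imread(image_path)
    spatial = np.asarray(adata.obsm["spatial"], dtype=float)
    spots = pd.DataFrame(
        {
            "barcode": adata.obs_names.to_numpy(),
            "in_tissue": adata.obs["in_tissue"].to_numpy(bool),
            "array_row": adata.obs["array_row"].to_numpy(int),
            "array_col": adata.obs["array_col"].to_numpy(int),
            "pxl_row": spatial[:, 1],
            "pxl_col": spatial[:, 0],
            "section": adata.obs["section"].astype(str).to_numpy(),
        }
    )
    transforms = {
        sid: AffineTransform2D(*(float(v) for v in coeffs))
        for sid, coeffs in adata.uns["transforms"].items()
    }
    counts = sp.csr_matrix(adata.X).T.tocsr()
    offset = tuple(float(v) for v in adata.uns["frame_offset"])
    return StitchedSection(
        spots=spots,
        counts=counts,
        genes=adata.var_names.tolist(),
        image=image,
        frame_offset=offset,
        transforms_used=transforms,
    )
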