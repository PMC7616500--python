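"""QC filters, embryonic-age estimation, expression-bias odds ratios and
NMF-microenvironment membership.

Boundary semantics are strict and deliberate: a cell expressing *fewer
than* ``min_genes_per_cell`` genes is removed (the boundary count is kept);
a gene seen in *less than* ``min_cells_per_gene`` cells is removed; a cell
with *over* ``max_mito_fraction`` mitochondrial UMIs is removed (the exact
boundary fraction is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import NMF

__all__ = [
    "QcThresholds",
    "QcReport",
    "qc_filter",
    "AgeEstimate",
    "estimate_age",
    "OddsRatioResult",
    "fraction_odds_ratio",
    "summarize_groups",
    "select_biased_genes",
    "AXIS_CUTOFFS",
    "EnvironmentLoading",
    "run_nmf",
    "microenvironment_membership",
]


# ---------------------------------------------------------------------------
# QC filtering

@dataclass(frozen=True)
class QcThresholds:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 5
    max_mito_fraction: float = 0.10
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_cells_per_gene <= 0:
            raise ValueError("count thresholds must be positive")
        if not (0 < self.max_mito_fraction < 1):
            raise ValueError("max_mito_fraction must lie in (0, 1)")


@dataclass
class QcReport:
    kept_cells: np.ndarray
    kept_genes: np.ndarray
    filter_order: tuple[str, ...]
    n_cells_removed_low_genes: int
    n_genes_removed_low_cells: int
    n_cells_removed_mito: int
    warnings: list[str] = field(default_factory=list)


def qc_filter(
    counts,
    gene_ids: list[str],
    thresholds: QcThresholds = QcThresholds(),
) -> QcReport:
    """Apply the three QC rules to a genes x cells count matrix.

    Order (recorded in the report): cells with too few expressed genes,
    then lowly covered genes (evaluated on the kept cells), then the
    mitochondrial-fraction rule — the fraction is computed on each kept
    cell's *unfiltered* gene profile. Returns kept cell/gene index arrays.
    """
    counts = sp.csr_matrix(counts)
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if counts.shape[0] != len(gene_ids):
        raise ValueError("gene_ids length must match the matrix row count")
    if (counts.data < 0).any():
        raise ValueError("counts must be nonnegative")

    expressed = counts.copy()
    expressed.data = (expressed.data > 0).astype(np.int64)

    genes_per_cell = np.asarray(expressed.sum(axis=0)).ravel()
    kept_cells = np.flatnonzero(genes_per_cell >= thresholds.min_genes_per_cell)
    n_low = counts.shape[1] - kept_cells.size

    cells_per_gene = np.asarray(expressed[:, kept_cells].sum(axis=1)).ravel()
    kept_genes = np.flatnonzero(cells_per_gene >= thresholds.min_cells_per_gene)
    n_lowgene = counts.shape[0] - kept_genes.size

    warnings: list[str] = []
    mito_mask = np.array(
        [g.startswith(thresholds.mito_gene_prefix) for g in gene_ids], dtype=bool
    )
    n_mito_removed = 0
    if not mito_mask.any():
        warnings.append(
            f"no genes match mito prefix {thresholds.mito_gene_prefix!r}; "
            "mitochondrial filter skipped"
        )
    else:
        total = np.asarray(counts[:, kept_cells].sum(axis=0)).ravel().astype(float)
        mito = np.asarray(
            counts[mito_mask][:, kept_cells].sum(axis=0)
        ).ravel().astype(float)
        frac = np.divide(mito, total, out=np.zeros_like(total), where=total > 0)
        keep = frac <= thresholds.max_mito_fraction  # "over 10%" removed
        n_mito_removed = int((~keep).sum())
        kept_cells = kept_cells[keep]

    return QcReport(
        kept_cells=kept_cells,
        kept_genes=kept_genes,
        filter_order=("min_genes_per_cell", "min_cells_per_gene", "max_mito_fraction"),
        n_cells_removed_low_genes=int(n_low),
        n_genes_removed_low_cells=int(n_lowgene),
        n_cells_removed_mito=n_mito_removed,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# embryonic age

AGE_SLOPE_DAYS_PER_MM = 0.9022
AGE_INTERCEPT_DAYS = 27.372


@dataclass(frozen=True)
class AgeEstimate:
    """Post-conception age from crown-rump length (linear formula)."""

    crl_mm: float
    days: float
    pcw_week: int
    pcw_day: int

    @property
    def pcw(self) -> str:
        """Week.day rendering, e.g. 'PCW5.6' = 5 weeks and 6 days."""
        return f"PCW{self.pcw_week}.{self.pcw_day}"


def estimate_age(crl_mm: float) -> AgeEstimate:
    if crl_mm <= 0:
        raise ValueError("crown-rump length must be positive")
    days = AGE_SLOPE_DAYS_PER_MM * crl_mm + AGE_INTERCEPT_DAYS
    rounded = int(np.floor(days + 0.5))  # round half up, away from banker's
    return AgeEstimate(
        crl_mm=float(crl_mm),
        days=float(days),
        pcw_week=rounded // 7,
        pcw_day=rounded % 7,
    )


# ---------------------------------------------------------------------------
# expression-bias odds ratios

class OddsRatioResult(NamedTuple):
    value: float
    corrected: bool


def fraction_odds_ratio(k_a: int, n_a: int, k_b: int, n_b: int) -> OddsRatioResult:
    """Odds ratio of non-zero-cell fractions between two groups.

    OR = (p_a/(1-p_a)) / (p_b/(1-p_b)) with p = k/n.  When any of the four
    odds counts (k or n-k) is zero, the Haldane–Anscombe +0.5 correction is
    applied to all four and flagged in the result.
    """
    for k, n, side in ((k_a, n_a, "a"), (k_b, n_b, "b")):
        if n <= 0:
            raise ValueError(f"group {side}: n must be positive")
        if not (0 <= k <= n):
            raise ValueError(f"group {side}: require 0 <= k <= n")
    counts = np.array([k_a, n_a - k_a, k_b, n_b - k_b], dtype=float)
    corrected = bool((counts == 0).any())
    if corrected:
        counts = counts + 0.5
    value = (counts[0] / counts[1]) / (counts[2] / counts[3])
    return OddsRatioResult(value=float(value), corrected=corrected)


def summarize_groups(
    counts,
    gene_ids: list[str],
    group_labels,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene non-zero fractions and odds ratios between two cell groups.

    ``counts`` is genes x cells; ``group_labels`` assigns each cell to a
    group. Cells in other groups are ignored.
    """
    counts = sp.csr_matrix(counts)
    labels = np.asarray(group_labels)
    if counts.shape[1] != labels.size:
        raise ValueError("group_labels length must match the cell count")
    rows = []
    idx = {g: np.flatnonzero(labels == g) for g in (group_a, group_b)}
    for g, cells in idx.items():
        if cells.size == 0:
            raise ValueError(f"group {g!r} has no cells")
    nz = counts.copy()
    nz.data = (nz.data > 0).astype(np.int64)
    k_a = np.asarray(nz[:, idx[group_a]].sum(axis=1)).ravel()
    k_b = np.asarray(nz[:, idx[group_b]].sum(axis=1)).ravel()
    n_a, n_b = idx[group_a].size, idx[group_b].size
    for i, gene in enumerate(gene_ids):
        orr = fraction_odds_ratio(int(k_a[i]), n_a, int(k_b[i]), n_b)
        rows.append(
            (
                gene, group_a, group_b, n_a, n_b, int(k_a[i]), int(k_b[i]),
                k_a[i] / n_a, k_b[i] / n_b, orr.value, orr.corrected,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "group_a", "group_b", "n_a", "n_b", "k_a", "k_b",
            "fraction_a", "fraction_b", "odds_ratio", "corrected",
        ],
    )


#: Fold-change cutoffs per biological axis: proximal/distal is stringent
#: (30-fold), forelimb/hindlimb permissive (3-fold).
AXIS_CUTOFFS = {"proximal_distal": 30.0, "fore_hind": 3.0}


def select_biased_genes(
    summaries: pd.DataFrame,
    axis: str,
    cutoff: float | None = None,
) -> dict[str, list[str]]:
    """Select genes whose odds ratio exceeds the axis cutoff in either direction.

    Inclusive comparison: OR >= cutoff selects for group_a, OR <= 1/cutoff
    for group_b (applied symmetrically).
    """
    if cutoff is None:
        if axis not in AXIS_CUTOFFS:
            raise ValueError(
                f"unknown axis {axis!r}; expected one of {sorted(AXIS_CUTOFFS)}"
            )
        cutoff = AXIS_CUTOFFS[axis]
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    orr = summaries["odds_ratio"]
    return {
        "group_a": summaries.loc[orr >= cutoff, "gene"].tolist(),
        "group_b": summaries.loc[orr <= 1.0 / cutoff, "gene"].tolist(),
    }


# ---------------------------------------------------------------------------
# microenvironments

@dataclass
class EnvironmentLoading:
    """Nonnegative NMF loadings, environments x cell types."""

    loadings: np.ndarray
    cell_types: list[str]
    environments: list[str]
    reconstruction_error: float = float("nan")

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if (self.loadings < 0).any():
            raise ValueError("loadings must be nonnegative")
        if self.loadings.shape != (len(self.environments), len(self.cell_types)):
            raise ValueError("loadings shape must be environments x cell types")

    def fractions(self) -> pd.DataFrame:
        """Per-cell-type fractions: each column normalized to sum to 1."""
        totals = self.loadings.sum(axis=0)
        if (totals == 0).any():
            bad = [ct for ct, t in zip(self.cell_types, totals) if t == 0]
            raise ValueError(f"all-zero loading column(s) for cell types {bad}")
        return pd.DataFrame(
            self.loadings / totals, index=self.environments, columns=self.cell_types
        )


def run_nmf(abundance, n_environments: int, seed: int = 0, max_iter: int = 2000) -> EnvironmentLoading:
    """Factorize a spots x cell-types abundance matrix into microenvironments.

    Wraps scikit-learn NMF with a deterministic seeded initialization; the
    returned loadings are the factor-by-cell-type matrix H.
    """
    if isinstance(abundance, pd.DataFrame):
        cell_types = [str(c) for c in abundance.columns]
        matrix = abundance.to_numpy(dtype=float)
    else:
        matrix = np.asarray(abundance, dtype=float)
        cell_types = [f"ct{j}" for j in range(matrix.shape[1])]
    if (matrix < 0).any():
        raise ValueError("abundance matrix must be nonnegative")
    if n_environments >= min(matrix.shape):
        raise ValueError(
            f"n_environments={n_environments} must be < min(dimensions)={min(matrix.shape)}"
        )
    model = NMF(
        n_components=n_environments,
        init="nndsvda",
        random_state=seed,
        max_iter=max_iter,
        tol=1e-8,
    )
    model.fit_transform(matrix)
    return EnvironmentLoading(
        loadings=model.components_,
        cell_types=cell_types,
        environments=[f"env{i}" for i in range(n_environments)],
        reconstruction_error=float(model.reconstruction_err_),
    )


def microenvironment_membership(
    loadings: EnvironmentLoading, threshold: float = 0.2
) -> pd.DataFrame:
    """Boolean environments x cell-types membership table.

    A cell type belongs to an environment iff its fraction there (loadings
    normalized per cell type across environments) is strictly greater than
    the threshold; at 0.2 a cell type can belong to at most four.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    return loadings.fractions() > threshold
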