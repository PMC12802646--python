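"""From raw counts to model input: QC, denoising, normalization, scaling.

The model consumes two aligned views of the data restricted to the senescence
panel: the (optionally denoised) raw counts X, which enter the zero-inflated
negative-binomial likelihood, and X' — the library-size-normalized,
log1p-transformed, panel-subsetted, per-gene standardized matrix fed to the
encoder.  Size factors (library size / median library size) carry the
per-cell depth back into the likelihood mean.

Orientation is cells-in-rows throughout; the readers in :mod:`snscore.io`
transpose gene-major 10x-style input on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genesets import GeneSet

__all__ = [
    "CountMatrix",
    "ProcessedMatrix",
    "qc_filter",
    "gene_prevalence_filter",
    "denoise",
    "size_factors",
    "lognormalize",
    "subset_and_scale",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Raw cells-by-genes integer counts with identifiers.

    ``mito_flags`` marks mitochondrial genes; when absent it is inferred from
    the ``MT-``/``mt-`` symbol prefix.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    mito_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells-by-genes matrix")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise ValueError("counts must be finite and non-negative")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lengths must match matrix dimensions")
        if self.mito_flags is not None:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
            if len(self.mito_flags) != g:
                raise ValueError("mito_flags length must match gene count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def mito_mask(self) -> np.ndarray:
        if self.mito_flags is not None:
            return self.mito_flags
        return np.array(
            [str(g).upper().startswith("MT-") for g in self.gene_ids]
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[mask], self.cell_ids[mask], self.gene_ids,
            self.mito_flags,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, mask], self.cell_ids, self.gene_ids[mask],
            None if self.mito_flags is None else self.mito_flags[mask],
        )


@dataclass
class ProcessedMatrix:
    """Panel-restricted standardized expression X' plus scaling metadata."""

    x_prime: np.ndarray
    size_factors: np.ndarray
    panel_genes: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_panel_genes: list[str] = field(default_factory=list)
    cell_ids: np.ndarray | None = None
    panel_direction: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = np.zeros(len(self.panel_genes), dtype=bool)
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def n_cells(self) -> int:
        return self.x_prime.shape[0]

    @property
    def n_genes(self) -> int:
        return self.x_prime.shape[1]


def qc_filter(
    counts: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 7000,
    max_mito: float = 0.20,
) -> CountMatrix:
    """Drop low-quality cells by detected-gene count and mitochondrial load.

    Cells are retained when they express more than ``min_genes`` and fewer
    than ``max_genes`` genes and carry less than ``max_mito`` fraction of
    mitochondrial counts.  Genes are untouched.
    """
    detected = (counts.counts > 0).sum(axis=1)
    keep = (detected > min_genes) & (detected < max_genes)
    mito = counts.mito_mask()
    if mito.any() and max_mito is not None:
        lib = counts.library_sizes().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, counts.counts[:, mito].sum(axis=1) / lib, 1.0)
        keep &= frac < max_mito
    if not keep.any():
        raise ValueError(
            f"QC removed every cell (thresholds: >{min_genes} and "
            f"<{max_genes} expressed genes, <{max_mito:.0%} mitochondrial)"
        )
    return counts.subset_cells(keep)


def gene_prevalence_filter(
    counts: CountMatrix, min_frac: float = 0.01
) -> CountMatrix:
    """Keep genes with non-zero expression in at least ``min_frac`` of cells."""
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must lie in [0, 1]")
    prevalence = (counts.counts > 0).mean(axis=0)
    return counts.subset_genes(prevalence >= min_frac)


def denoise(
    counts: CountMatrix,
    method: str = "identity",
    seed: int = 0,
    **ae_kwargs,
) -> CountMatrix:
    """Optionally denoise the full count matrix before panel subsetting.

    ``identity`` returns the input unchanged.  ``internal_zinb_ae`` fits a
    ZINB autoencoder over all genes (wider bottleneck, no decorrelation
    penalty) and returns the estimated count-scale means rounded to integers.
    """
    if method == "identity":
        return counts
    if method != "internal_zinb_ae":
        raise ValueError(f"unknown denoise method {method!r}")
    from .model import denoise_counts

    den = denoise_counts(counts.counts, seed=seed, **ae_kwargs)
    return CountMatrix(den, counts.cell_ids, counts.gene_ids, counts.mito_flags)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Per-cell library size divided by the median library size."""
    lib = counts.library_sizes().astype(float)
    if (lib <= 0).any():
        raise ValueError(
            "cells with zero library size present; run qc_filter first"
        )
    return lib / np.median(lib)


def lognormalize(counts: CountMatrix) -> np.ndarray:
    """Scale each cell to the median library size, then natural log1p."""
    lib = counts.library_sizes().astype(float)
    if (lib <= 0).any():
        raise ValueError("cells with zero library size present")
    target = np.median(lib)
    scaled = counts.counts / lib[:, None] * target
    return np.log1p(scaled)


def subset_and_scale(
    lognorm: np.ndarray,
    gene_ids: np.ndarray,
    panel: GeneSet,
    size_factors: np.ndarray,
    cell_ids: np.ndarray | None = None,
) -> ProcessedMatrix:
    """Restrict to panel genes and standardize each gene column.

    Columns get zero mean and unit standard deviation across cells;
    zero-variance columns are set to all zeros and flagged.  Panel genes
    absent from the matrix are recorded in ``missing_panel_genes``.
    """
    gene_index = {str(g).upper(): i for i, g in enumerate(gene_ids)}
    present, missing = [], []
    for g in panel.genes:
        (present if g in gene_index else missing).append(g)
    if len(present) < 2:
        raise ValueError(
            f"only {len(present)} panel gene(s) found in the matrix; "
            "at least 2 are required — consider a larger panel for "
            "targeted-panel (in situ) data"
        )
    cols = [gene_index[g] for g in present]
    x = np.asarray(lognorm, dtype=float)[:, cols]
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    zero_var = sds < 1e-12
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} constant panel gene(s) set to all-zero "
            "columns", stacklevel=2,
        )
    safe_sd = np.where(zero_var, 1.0, sds)
    xp = (x - means) / safe_sd
    xp[:, zero_var] = 0.0
    direction = None
    if panel.direction is not None:
        direction = {g: panel.direction.get(g, "unknown") for g in present}
    return ProcessedMatrix(
        x_prime=xp,
        size_factors=np.asarray(size_factors, dtype=float),
        panel_genes=np.asarray(present, dtype=object),
        gene_means=means,
        gene_sds=sds,
        zero_variance=zero_var,
        missing_panel_genes=missing,
        cell_ids=cell_ids,
        panel_direction=direction,
    )


def preprocess(
    counts: CountMatrix,
    panel: GeneSet,
    denoise_method: str = "identity",
    run_qc: bool = False,
    min_gene_frac: float | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, ProcessedMatrix]:
    """Full pipeline: [QC] -> denoise -> normalize -> subset -> scale.

    Returns the panel-restricted count matrix X (likelihood input) and the
    processed matrix X' (encoder input).  QC is off by default: the method
    expects a properly filtered matrix, and QC here is a convenience.
    """
    if run_qc:
        counts = qc_filter(counts)
    if min_gene_frac is not None:
        counts = gene_prevalence_filter(counts, min_gene_frac)
    counts = denoise(counts, method=denoise_method, seed=seed)
    sf = size_factors(counts)
    ln = lognormalize(counts)
    processed = subset_and_scale(
        ln, counts.gene_ids, panel, sf, cell_ids=counts.cell_ids
    )
    gene_pos = {str(g).upper(): i for i, g in enumerate(counts.gene_ids)}
    panel_cols = [gene_pos[g] for g in processed.panel_genes]
    x_panel = counts.subset_genes(np.array(
        [i in set(panel_cols) for i in range(counts.n_genes)]
    ))
    # subset_genes preserves matrix order; reorder to panel order
    order = {str(g).upper(): i for i, g in enumerate(x_panel.gene_ids)}
    perm = [order[g] for g in processed.panel_genes]
    x_panel = CountMatrix(
        x_panel.counts[:, perm], x_panel.cell_ids,
        x_panel.gene_ids[perm],
        None if x_panel.mito_flags is None else x_panel.mito_flags[perm],
    )
    return x_panel, processed
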