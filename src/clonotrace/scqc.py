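"""Single-cell RNA-seq QC, size-factor normalization and spike-in HVGs.

Cells are kept when enough reads map to gene features, the gene-mapping
fraction is high enough and the mitochondrial read fraction is low.
Sequencing depth is normalized with median-of-ratios size factors computed
on endogenous genes only; highly variable genes (HVGs) are selected
against a technical-noise baseline fitted to ERCC spike-ins: ordinary
least-squares quadratic of log10 CV on log10 mean over spike-ins whose
normalized mean exceeds ``mean_for_fit`` (default 10), flagging endogenous
genes whose observed log10 CV lies above the predicted curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indexsort import batch_correct

__all__ = [
    "CountsMatrix",
    "QCReport",
    "HVGResult",
    "qc_filter",
    "size_factors",
    "select_hvgs",
    "batch_correct_expression",
]


@dataclass
class CountsMatrix:
    """Genes x cells count matrix with gene flags and per-cell metadata.

    counts : DataFrame (genes x cells), non-negative integers
    is_spikein, is_mito : boolean Series indexed like counts rows
        (spike-ins are never mitochondrial)
    cell_meta : DataFrame indexed like counts columns with at least
        ``total_reads`` and ``reads_in_genes``; optional ``batch``.
    """

    counts: pd.DataFrame
    is_spikein: pd.Series
    is_mito: pd.Series
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.is_spikein = self.is_spikein.reindex(self.counts.index).fillna(False).astype(bool)
        self.is_mito = self.is_mito.reindex(self.counts.index).fillna(False).astype(bool)
        if (self.is_spikein & self.is_mito).any():
            raise ValueError("spike-in genes cannot be mitochondrial")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        spikein_prefix: str = "ERCC-",
        mito_prefix: str = "MT-",
        cell_meta: pd.DataFrame | None = None,
    ) -> "CountsMatrix":
        """Flag spike-in / mito rows by gene-id prefix (overridable)."""
        idx = counts.index.astype(str)
        spike_arr = np.asarray(idx.str.startswith(spikein_prefix))
        mito_arr = np.asarray(idx.str.startswith(mito_prefix)) & ~spike_arr
        is_spike = pd.Series(spike_arr, index=counts.index)
        is_mito = pd.Series(mito_arr, index=counts.index)
        if cell_meta is None:
            in_genes = counts.loc[~is_spike].sum(axis=0)
            cell_meta = pd.DataFrame(
                {"total_reads": counts.sum(axis=0), "reads_in_genes": in_genes}
            )
        return cls(counts=counts, is_spikein=is_spike, is_mito=is_mito, cell_meta=cell_meta)

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[~self.is_spikein]


@dataclass
class QCReport:
    kept_cells: list
    dropped_cells: list
    metrics: pd.DataFrame
    thresholds: dict


@dataclass
class HVGResult:
    hvg_genes: list
    coefficients: np.ndarray  # quadratic fit, highest degree first
    table: pd.DataFrame       # per-gene mean, log10 mean/CV, predicted log10 CV
    margin: float


def qc_filter(
    matrix: CountsMatrix,
    min_gene_reads: float = 2e5,
    min_mapping_fraction: float = 0.20,
    max_mito_fraction: float = 0.20,
    mapping_criterion: str = "read_fraction",
) -> QCReport:
    """Per-cell QC thresholding.

    Keep a cell iff reads_in_genes > min_gene_reads, the mapping criterion
    exceeds min_mapping_fraction, and mito/(mito + nuclear) reads
    < max_mito_fraction.  ``mapping_criterion`` selects how the ambiguous
    middle rule is read: ``"read_fraction"`` (reads_in_genes/total_reads,
    the default) or ``"detected_genes"`` (fraction of endogenous genes
    detected).
    """
    meta = matrix.cell_meta
    for col in ("total_reads", "reads_in_genes"):
        if col not in meta:
            raise ValueError(f"cell metadata missing {col!r}")
    mito_reads = matrix.counts.loc[matrix.is_mito].sum(axis=0)
    nuclear_reads = matrix.counts.loc[~matrix.is_mito & ~matrix.is_spikein].sum(axis=0)
    denom = (mito_reads + nuclear_reads).replace(0, np.nan)
    mito_frac = (mito_reads / denom).fillna(0.0)

    if mapping_criterion == "read_fraction":
        mapping = meta["reads_in_genes"] / meta["total_reads"].replace(0, np.nan)
        mapping = mapping.fillna(0.0)
    elif mapping_criterion == "detected_genes":
        endo = matrix.endogenous
        mapping = (endo > 0).sum(axis=0) / endo.shape[0]
    else:
        raise ValueError(f"unknown mapping criterion: {mapping_criterion!r}")

    keep = (
        (meta["reads_in_genes"] > min_gene_reads)
        & (mapping > min_mapping_fraction)
        & (mito_frac < max_mito_fraction)
    )
    metrics = pd.DataFrame(
        {
            "reads_in_genes": meta["reads_in_genes"],
            "mapping_metric": mapping,
            "mito_fraction": mito_frac,
            "kept": keep,
        }
    )
    return QCReport(
        kept_cells=list(meta.index[keep]),
        dropped_cells=list(meta.index[~keep]),
        metrics=metrics,
        thresholds={
            "min_gene_reads": min_gene_reads,
            "min_mapping_fraction": min_mapping_fraction,
            "max_mito_fraction": max_mito_fraction,
            "mapping_criterion": mapping_criterion,
        },
    )


def size_factors(matrix: CountsMatrix) -> pd.Series:
    """Median-of-ratios depth factors on endogenous genes.

    s_j = median_g (x_gj / GM_g) over endogenous genes with positive
    geometric mean, rescaled so the geometric mean of the factors is 1.
    """
    endo = matrix.endogenous.to_numpy(dtype=float)
    if endo.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    positive = (endo > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no endogenous gene is positive in every cell")
    ref = endo[positive]
    log_gm = np.mean(np.log(ref), axis=1)
    ratios = ref / np.exp(log_gm)[:, None]
    s = np.median(ratios, axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=matrix.counts.columns, name="size_factor")


def select_hvgs(
    matrix: CountsMatrix,
    factors: pd.Series | None = None,
    mean_for_fit: float = 10.0,
    margin: float = 0.0,
    min_spikeins: int = 5,
) -> HVGResult:
    """Spike-in-anchored highly-variable-gene selection.

    CV is on the natural scale, logs base 10.  The quadratic baseline is
    fitted by OLS to spike-ins with normalized mean > ``mean_for_fit``; a
    gene is an HVG iff its log10 CV exceeds the prediction by more than
    ``margin`` and its mean is positive.  Increasing the margin can only
    shrink the HVG set.
    """
    if factors is None:
        factors = size_factors(matrix)
    norm = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    ok = (mean > 0) & (cv > 0)
    log_mean = np.where(ok, np.log10(np.where(ok, mean, 1.0)), np.nan)
    log_cv = np.where(ok, np.log10(np.where(ok, cv, 1.0)), np.nan)

    spike = matrix.is_spikein.to_numpy()
    fit_rows = spike & ok & (mean > mean_for_fit)
    if fit_rows.sum() < min_spikeins:
        raise ValueError(
            f"only {int(fit_rows.sum())} spike-ins with normalized mean > "
            f"{mean_for_fit}; need at least {min_spikeins}"
        )
    coeffs = np.polyfit(log_mean[fit_rows], log_cv[fit_rows], deg=2)
    predicted = np.polyval(coeffs, log_mean)

    above = ok & (log_cv > predicted + margin)
    hvg_mask = above & ~spike
    genes = matrix.counts.index
    table = pd.DataFrame(
        {
            "mean": mean,
            "log10_mean": log_mean,
            "log10_cv": log_cv,
            "predicted_log10_cv": predicted,
            "above_curve": above,
            "is_spikein": spike,
            "is_hvg": hvg_mask,
        },
        index=genes,
    )
    return HVGResult(
        hvg_genes=list(genes[hvg_mask]),
        coefficients=coeffs,
        table=table,
        margin=margin,
    )


def batch_correct_expression(
    matrix: pd.DataFrame, batches, min_total: float = 1.0
) -> pd.DataFrame:
    """Empirical-Bayes batch adjustment of an expression table.

    Applies the location/scale adjustment only to genes whose total count
    exceeds ``min_total``; other genes pass through unchanged.  The table
    is genes x cells (the adjustment itself runs cells x features).
    """
    X = matrix.to_numpy(dtype=float)
    active = X.sum(axis=1) > min_total
    out = matrix.copy().astype(float)
    if active.any():
        adj = batch_correct(X[active].T, batches).T
        out.iloc[np.where(active)[0], :] = adj
    return out
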