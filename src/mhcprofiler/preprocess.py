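"""RNA-seq preprocessing: filtering, GC-aware quantile normalization,
log-CPM transform, PCA outlier removal, batch hygiene and empirical-Bayes
batch correction.

The stage order is fixed: low-expression filter -> GC/quantile normalization
-> log2(CPM + 0.25) -> PCA outlier removal -> duplicate & small-batch removal
-> ComBat -> subtype-size filter. ``preprocess_expression`` runs all stages
and records every threshold used.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    return counts * (1e6 / libsize)


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_fraction`` of samples."""
    if min_cpm <= 0:
        raise ValueError("min_cpm must be > 0")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = (cpm(counts) >= min_cpm).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    logger.info("low-expression filter: kept %d/%d genes (CPM>=%g in >=%g of samples)",
                int(keep.sum()), len(keep), min_cpm, min_fraction)
    return counts.loc[keep]


def _quantile_map(values: np.ndarray, target_sorted: np.ndarray) -> np.ndarray:
    """Full-quantile map of ``values`` onto the distribution of ``target_sorted``.

    Each value is placed at its midrank plotting position within ``values``
    and read off the target's empirical quantile function at that position.
    """
    m = values.size
    n = target_sorted.size
    pos = (rankdata(values, method="average") - 0.5) / m
    grid = (np.arange(n) + 0.5) / n
    return np.interp(pos, grid, target_sorted)


def gc_quantile_normalize(
    counts: pd.DataFrame, gc: pd.Series, n_gc_bins: int = 10
) -> pd.DataFrame:
    """Two-stage normalization removing GC bias then between-sample variation.

    Stage 1 (within sample): genes are stratified into ``n_gc_bins`` GC
    quantile bins; each stratum's count distribution is full-quantile mapped
    onto the sample's overall count distribution, flattening the GC trend.
    Stage 2 (between samples): full quantile normalization so every sample
    shares one sorted-value distribution (the mean of the sorted columns).
    """
    if n_gc_bins < 2:
        raise ValueError("n_gc_bins must be >= 2")
    gc = gc.reindex(counts.index)
    if gc.isna().any():
        raise ValueError("GC content missing for some genes")
    bins = pd.qcut(gc.rank(method="first"), q=n_gc_bins, labels=False)
    sizes = np.bincount(bins, minlength=n_gc_bins)
    if (sizes < 2).any():
        raise ValueError(
            f"GC bin with fewer than 2 genes (sizes {sizes.tolist()}); use fewer bins"
        )
    x = counts.to_numpy(dtype=float)
    stage1 = np.empty_like(x)
    bin_rows = [np.flatnonzero(bins == b) for b in range(n_gc_bins)]
    for j in range(x.shape[1]):
        overall = np.sort(x[:, j])
        for rows in bin_rows:
            stage1[rows, j] = _quantile_map(x[rows, j], overall)
    # stage 2: map every column onto the mean sorted distribution
    ref = np.sort(stage1, axis=0).mean(axis=1)
    out = np.empty_like(stage1)
    n = x.shape[0]
    grid = (np.arange(n) + 0.5) / n
    for j in range(out.shape[1]):
        pos = (rankdata(stage1[:, j], method="average") - 0.5) / n
        out[:, j] = np.interp(pos, grid, ref)
    return pd.DataFrame(np.maximum(out, 0.0), index=counts.index, columns=counts.columns)


def log_cpm(counts: pd.DataFrame, offset: float = 0.25) -> pd.DataFrame:
    """log2(counts-per-million + offset); a zero count maps to log2(offset)."""
    logger.info("log-CPM transform with offset %g", offset)
    return np.log2(cpm(counts) + offset)


def pca_outlier_removal(expr: pd.DataFrame, sd_threshold: float = 3.0) -> pd.Index:
    """Retain samples near the centroid in the first two principal components.

    Samples are projected on the top two PCs of the gene-centred matrix and
    removed when their distance from the projection centroid exceeds
    ``sd_threshold`` times the root-mean-square distance. One pass only.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA outlier removal")
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)      # centre each gene
    # samples as observations: SVD of samples x genes
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    proj = u[:, :2] * s[:2]
    d = np.linalg.norm(proj - proj.mean(axis=0), axis=1)
    rms = np.sqrt(np.mean(d**2))
    keep = d <= sd_threshold * rms if rms > 0 else np.ones(d.size, dtype=bool)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples remain after outlier removal")
    if (~keep).any():
        logger.info("PCA outlier removal dropped %d samples (threshold %gx RMS)",
                    int((~keep).sum()), sd_threshold)
    return expr.columns[keep]


def remove_small_batches(metadata: pd.DataFrame, min_batch_size: int = 5) -> pd.Index:
    """Drop duplicate sample ids (keeping first) and samples from small batches.

    Batches with fewer than ``min_batch_size`` samples (i.e. <= min-1) are
    removed entirely.
    """
    if "batch" not in metadata.columns:
        raise ValueError("metadata lacks a 'batch' column")
    dedup = metadata[~metadata.index.duplicated(keep="first")]
    sizes = dedup.groupby("batch").size()
    good = sizes.index[sizes >= min_batch_size]
    keep = dedup.index[dedup["batch"].isin(good)]
    if len(keep) == 0:
        raise ValueError("all samples dropped by small-batch removal")
    return keep


def combat_adjust(
    expr: pd.DataFrame,
    batch: Sequence[str] | pd.Series,
    tol: float = 1e-4,
    max_iter: int = 200,
    var_floor: float = 1e-8,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction (ComBat).

    Genes are standardized by grand mean and pooled variance; per-batch,
    per-gene location and scale estimates are shrunk toward batch-level
    normal / inverse-gamma priors with moment-matched hyperparameters by
    iterative conditional updates, then the data are adjusted and
    back-transformed. Each gene is finally re-centred to its original overall
    mean (batch correction is defined only up to overall location).

    With a single batch the input is returned unchanged with a warning.
    """
    batch = pd.Series(np.asarray(batch), index=expr.columns)
    levels = batch.unique()
    if len(levels) < 2:
        warnings.warn("combat_adjust called with a single batch; returning input unchanged")
        return expr.copy()
    x = expr.to_numpy(dtype=float)
    n_genes, n = x.shape
    groups = [np.flatnonzero((batch == b).to_numpy()) for b in levels]
    n_b = np.array([len(g) for g in groups])
    if (n_b < 2).any():
        raise ValueError("every batch must contain at least 2 samples")

    batch_means = np.stack([x[:, g].mean(axis=1) for g in groups], axis=1)  # genes x B
    grand = batch_means @ (n_b / n)
    mean_mat = np.empty_like(x)
    for i, g in enumerate(groups):
        mean_mat[:, g] = batch_means[:, [i]]
    resid = x - mean_mat
    pooled_var = (resid**2).mean(axis=1)   # variance after removing batch means
    pooled_sd = np.sqrt(np.maximum(pooled_var, var_floor))
    z = (x - grand[:, None]) / pooled_sd[:, None]

    z_adj = np.empty_like(z)
    for i, g in enumerate(groups):
        zb = z[:, g]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        if (delta_hat < var_floor).any():
            warnings.warn(
                f"batch {levels[i]}: {int((delta_hat < var_floor).sum())} genes with "
                "zero within-batch variance; scale estimate floored"
            )
            delta_hat = np.maximum(delta_hat, var_floor)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        if d_var < var_floor:
            d_var = var_floor
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var
        m = len(g)
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (m * tau2 * gamma_hat + delta_star * gamma_bar) / (m * tau2 + delta_star)
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior + 0.5 * ss) / (m / 2 + a_prior - 1)
            change = max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max())
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        z_adj[:, g] = (zb - gamma_star[:, None]) / np.sqrt(np.maximum(delta_star, var_floor))[:, None]

    out = z_adj * pooled_sd[:, None] + grand[:, None]
    out += (x.mean(axis=1) - out.mean(axis=1))[:, None]   # exact mean preservation
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def filter_small_subtypes(metadata: pd.DataFrame, min_subtype_size: int = 10) -> pd.Index:
    """Drop tumor samples of subtypes with fewer than ``min_subtype_size``
    members (within each cancer type); normal samples are always retained."""
    if "subtype" not in metadata.columns:
        raise ValueError("metadata lacks a 'subtype' column")
    tumors = metadata[metadata["is_tumor"] == 1]
    sizes = tumors.groupby(["cancer_type", "subtype"]).size()
    good = sizes[sizes >= min_subtype_size].index
    key = pd.MultiIndex.from_frame(tumors[["cancer_type", "subtype"]])
    keep_tumor = tumors.index[key.isin(good)]
    normals = metadata.index[metadata["is_tumor"] == 0]
    return metadata.index[metadata.index.isin(keep_tumor.union(normals))]


def preprocess_expression(
    counts: pd.DataFrame,
    gc: pd.Series,
    metadata: pd.DataFrame,
    *,
    min_cpm: float = 1.0,
    min_fraction: float = 0.2,
    n_gc_bins: int = 10,
    log_offset: float = 0.25,
    sd_threshold: float = 3.0,
    min_batch_size: int = 5,
    min_subtype_size: int = 10,
    per_cancer_type: bool = True,
    run_log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full preprocessing chain; returns (log expression, metadata).

    With ``per_cancer_type`` (the default) normalization, outlier removal and
    batch correction operate within each cancer type, mirroring per-dataset
    processing; results are concatenated over types.
    """
    def log(msg: str) -> None:
        logger.info(msg)
        if run_log is not None:
            run_log.append(msg)

    log(f"preprocess: min_cpm={min_cpm} min_fraction={min_fraction} "
        f"n_gc_bins={n_gc_bins} log_offset={log_offset} sd_threshold={sd_threshold} "
        f"min_batch_size={min_batch_size} min_subtype_size={min_subtype_size}")

    groups = (
        [(ct, idx) for ct, idx in metadata.groupby("cancer_type").groups.items()]
        if per_cancer_type else [("all", metadata.index)]
    )
    pieces, meta_pieces = [], []
    for ct, samples in groups:
        sub_counts = counts.loc[:, samples]
        sub_meta = metadata.loc[samples]
        filtered = filter_low_expression(sub_counts, min_cpm, min_fraction)
        normalized = gc_quantile_normalize(filtered, gc, n_gc_bins)
        expr = log_cpm(normalized, log_offset)
        keep = pca_outlier_removal(expr, sd_threshold)
        expr, sub_meta = expr.loc[:, keep], sub_meta.loc[keep]
        keep = remove_small_batches(sub_meta, min_batch_size)
        expr, sub_meta = expr.loc[:, keep], sub_meta.loc[keep]
        if sub_meta["batch"].nunique() >= 2:
            expr = combat_adjust(expr, sub_meta["batch"])
        else:
            log(f"{ct}: single batch after filtering; ComBat skipped")
        keep = filter_small_subtypes(sub_meta, min_subtype_size)
        expr, sub_meta = expr.loc[:, keep], sub_meta.loc[keep]
        log(f"{ct}: {expr.shape[0]} genes x {expr.shape[1]} samples after preprocessing")
        pieces.append(expr)
        meta_pieces.append(sub_meta)
    gene_sets = [set(p.index) for p in pieces]
    shared = sorted(set.intersection(*gene_sets), key=list(counts.index).index)
    expr_all = pd.concat([p.loc[shared] for p in pieces], axis=1)
    meta_all = pd.concat(meta_pieces, axis=0)
    log(f"preprocess result: {expr_all.shape[0]} genes x {expr_all.shape[1]} samples")
    return expr_all, meta_all
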