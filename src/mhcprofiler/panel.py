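"""Immunomodulator panel selection and the pan-cancer correlation summary.

The panel (cancer germline antigens, immunoinhibitors, MHC genes, other)
is pruned in two steps so that the retained genes reflect tumor-cell
expression rather than immune infiltration:

1. genes lowly expressed in at least one subtype of any cancer type are
   removed;
2. genes with a strong (rho >= 0.4) and significant (BH-FDR q <= 0.05)
   Spearman correlation with the inferred immune compartment fraction in any
   cancer type are removed.

The surviving panel plus CD4/CD8 T-cell levels feed the signed pan-cancer
correlation summary: within each cancer type every strong & significant
pairwise Spearman correlation contributes +1 or -1, and contributions are
summed over types into one integer matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def spearman_fdr(x: pd.DataFrame, y: pd.Series | np.ndarray) -> pd.DataFrame:
    """Spearman rho of each row of ``x`` against ``y``, with BH-adjusted q.

    Midrank ties; two-sided p from the t approximation; q values are
    Benjamini-Hochberg adjusted across the rows of ``x``. Zero-variance rows
    get rho = 0, q = 1 with a warning.
    """
    y = np.asarray(y, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    vals = x.to_numpy(dtype=float)
    n = vals.shape[1]
    const = vals.std(axis=1) == 0
    if const.any() or np.std(y) == 0:
        warnings.warn("zero-variance variable(s) in correlation; rho set to 0")
    ry = stats.rankdata(y)
    rx = stats.rankdata(vals, axis=1)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ry_c) / denom
    rho = np.where(np.isfinite(rho), rho, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where((vals.std(axis=1) == 0) | (np.std(y) == 0), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"rho": rho, "p": p, "q": q}, index=x.index)


def flag_low_expressed_panel(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    panel: pd.DataFrame,
    min_median_logcpm: float = 0.0,
) -> set[str]:
    """Panel genes whose median log-CPM falls below the threshold in any
    subtype of any cancer type (tumor samples only)."""
    if "subtype" not in metadata.columns:
        raise ValueError("metadata lacks a 'subtype' column")
    genes = panel.index.intersection(expr.index)
    tumors = metadata[metadata["is_tumor"] == 1]
    flagged: set[str] = set()
    for (_, _), idx in tumors.groupby(["cancer_type", "subtype"]).groups.items():
        med = expr.loc[genes, idx].median(axis=1)
        flagged.update(med.index[med < min_median_logcpm])
    return flagged


def immune_correlation_filter(
    expr: pd.DataFrame,
    immune_fraction: pd.Series,
    metadata: pd.DataFrame,
    panel: pd.DataFrame,
    r_threshold: float = 0.4,
    fdr: float = 0.05,
    mode: str = "positive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove panel genes correlated with the immune compartment fraction.

    Within each cancer type (tumor samples only) a gene is flagged when its
    Spearman rho with the immune fraction satisfies the threshold rule
    (``mode='positive'``: rho >= r_threshold; ``mode='absolute'``:
    |rho| >= r_threshold) at BH-FDR q <= ``fdr``. A gene flagged in any type
    is removed from the global panel.

    Returns (retained panel, per-type flag report).
    """
    if mode not in {"positive", "absolute"}:
        raise ValueError("mode must be 'positive' or 'absolute'")
    genes = panel.index.intersection(expr.index)
    tumors = metadata[metadata["is_tumor"] == 1]
    reports = []
    removed: set[str] = set()
    for ct in sorted(tumors["cancer_type"].unique()):
        idx = tumors.index[tumors["cancer_type"] == ct]
        idx = idx.intersection(expr.columns).intersection(immune_fraction.index)
        if len(idx) < 3:
            logger.warning("cancer type %s: fewer than 3 samples; filter skipped", ct)
            continue
        res = spearman_fdr(expr.loc[genes, idx], immune_fraction.loc[idx])
        strong = res["rho"] >= r_threshold if mode == "positive" else res["rho"].abs() >= r_threshold
        flag = strong & (res["q"] <= fdr)
        removed.update(res.index[flag])
        rep = res.assign(cancer_type=ct, flagged=flag)
        reports.append(rep.reset_index(names="gene"))
    report = (
        pd.concat(reports, ignore_index=True)
        if reports else pd.DataFrame(columns=["gene", "rho", "p", "q", "cancer_type", "flagged"])
    )
    retained = panel.loc[[g for g in panel.index if g not in removed]]
    logger.info("immune-correlation filter removed %d/%d panel genes",
                len(removed), len(panel))
    return retained, report


def select_panel(
    expr: pd.DataFrame,
    immune_fraction: pd.Series,
    metadata: pd.DataFrame,
    panel: pd.DataFrame,
    min_median_logcpm: float = 0.0,
    r_threshold: float = 0.4,
    fdr: float = 0.05,
    mode: str = "positive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Low-expression flagging followed by the immune-correlation filter."""
    low = flag_low_expressed_panel(expr, metadata, panel, min_median_logcpm)
    panel2 = panel.loc[[g for g in panel.index if g not in low and g in expr.index]]
    retained, report = immune_correlation_filter(
        expr, immune_fraction, metadata, panel2, r_threshold, fdr, mode
    )
    logger.info("panel selection: %d low-expressed, %d immune-correlated removed; "
                "%d retained", len(low), len(panel2) - len(retained), len(retained))
    return retained, report


def _pairwise_spearman(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Spearman rho and two-sided t-approximation p values.

    ``values`` is variables x samples; constant variables yield rho 0 / p 1.
    """
    n = values.shape[1]
    r = stats.rankdata(values, axis=1)
    rc = r - r.mean(axis=1, keepdims=True)
    norms = np.sqrt((rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ rc.T) / np.outer(norms, norms)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[norms == 0, :] = 1.0
    p[:, norms == 0] = 1.0
    return rho, p


def pan_cancer_correlation_summary(
    per_type_values: dict[str, pd.DataFrame],
    r_threshold: float = 0.4,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Signed sum over cancer types of strong & significant correlations.

    ``per_type_values`` maps cancer type -> variable-by-sample matrix
    (retained panel genes plus TCD4/TCD8 rows). Within each type all pairwise
    Spearman correlations are computed with BH-FDR across the pairs of that
    type; each pair with |rho| >= ``r_threshold`` and q <= ``fdr`` contributes
    sign(rho). Variables absent from a type contribute 0 for that type.
    """
    if len(per_type_values) < 2:
        raise ValueError("need at least 2 cancer types")
    all_vars: list[str] = []
    for df in per_type_values.values():
        for v in df.index:
            if v not in all_vars:
                all_vars.append(v)
    summary = pd.DataFrame(0, index=pd.Index(all_vars, name="variable"),
                           columns=all_vars, dtype=int)
    for ct, df in per_type_values.items():
        k = len(df.index)
        if k < 2:
            logger.warning("cancer type %s: fewer than 2 variables; no pairs", ct)
            continue
        rho, p = _pairwise_spearman(df.to_numpy(dtype=float))
        iu = np.triu_indices(k, 1)
        q_flat = multipletests(p[iu], method="fdr_bh")[1]
        q = np.ones_like(p)
        q[iu] = q_flat
        q.T[iu] = q_flat
        hit = (np.abs(rho) >= r_threshold) & (q <= fdr)
        np.fill_diagonal(hit, False)
        contrib = np.sign(rho) * hit
        sub = pd.DataFrame(contrib.astype(int), index=df.index, columns=df.index)
        summary.loc[sub.index, sub.columns] += sub
    np.fill_diagonal(summary.values, 0)
    return summary
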