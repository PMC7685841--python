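"""Reference-based methylation deconvolution by robust partial correlations.

A bulk beta-value profile is regressed on cell-type reference profiles with
Huber M-estimation (no intercept: betas and references share the [0,1]
scale); negative coefficients are truncated to zero and the remainder is
renormalized onto the simplex. This is the RPC recipe used for inferring
epithelial / fibroblast / immune compartment fractions, and — with an
extended reference — CD4/CD8 T-cell levels.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


def rpc_deconvolve(
    betas: pd.DataFrame,
    reference: pd.DataFrame,
    huber_c: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Infer cell-type fractions for every sample (samples x cell types).

    Parameters
    ----------
    betas
        CpG-by-sample methylation matrix, values in [0, 1].
    reference
        CpG-by-cell-type reference profiles; only CpGs shared with ``betas``
        are used.
    huber_c
        Huber tuning constant; ``np.inf`` reduces the fit to ordinary least
        squares followed by truncation.
    """
    if not np.isfinite(betas.to_numpy(dtype=float)).all():
        raise ValueError("betas contain non-finite values")
    shared = betas.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("no CpGs shared between betas and reference")
    if len(shared) < 50:
        warnings.warn(f"only {len(shared)} CpGs shared between betas and reference")
    X = reference.loc[shared].to_numpy(dtype=float)
    Y = betas.loc[shared].to_numpy(dtype=float)
    ols = not np.isfinite(huber_c)    # infinite tuning constant = plain OLS
    norm = None if ols else sm.robust.norms.HuberT(t=huber_c)
    out = np.empty((betas.shape[1], reference.shape[1]))
    for j in range(Y.shape[1]):
        if ols:
            params = np.linalg.lstsq(X, Y[:, j], rcond=None)[0]
        else:
            params = sm.RLM(Y[:, j], X, M=norm).fit(maxiter=max_iter, tol=tol).params
        coef = np.maximum(params, 0.0)
        total = coef.sum()
        if total <= 0:
            warnings.warn(
                f"sample {betas.columns[j]!r}: all coefficients non-positive; "
                "returning uniform fractions"
            )
            coef = np.full(coef.size, 1.0 / coef.size)
        else:
            coef = coef / total
        out[j] = coef
    return pd.DataFrame(out, index=betas.columns.rename("sample_id"),
                        columns=reference.columns)


def infer_tcell_levels(
    betas: pd.DataFrame,
    tcell_reference: pd.DataFrame,
    huber_c: float = 1.345,
    max_iter: int = 50,
) -> pd.DataFrame:
    """CD4/CD8 T-cell levels via RPC against an extended reference.

    The reference must contain ``CD4T`` and ``CD8T`` cell types; the full
    simplex fit is performed and the two T-cell columns are returned as-is
    (not renormalized after extraction).
    """
    missing = {"CD4T", "CD8T"} - set(tcell_reference.columns)
    if missing:
        raise ValueError(f"tcell reference lacks cell types: {sorted(missing)}")
    ref = tcell_reference.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(ref)
    if rank < ref.shape[1]:
        warnings.warn("tcell reference is rank-deficient (collinear profiles); "
                      "levels of collinear types are split by the pseudoinverse")
    fractions = rpc_deconvolve(betas, tcell_reference, huber_c=huber_c, max_iter=max_iter)
    return fractions[["CD4T", "CD8T"]]
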