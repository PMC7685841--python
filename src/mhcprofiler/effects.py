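"""Nonparametric relative effects and a permutation ANOVA-type test.

The relative effect of group *i* for a variable is the probability that a
randomly drawn observation from the reference distribution is smaller than
(plus half the probability of being tied with) a randomly drawn observation
from group *i*; 0.5 means "no shift". Two estimators are provided:

* ``weighted`` — the reference is the pooled sample:
  ``p_i = (mean pooled midrank of group i - 0.5) / N``. The group-size
  weighted mean of the effects is exactly 0.5 for every variable (midrank
  identity).
* ``unweighted`` — the reference weights every group equally:
  ``p_i = mean_j [ P(X_j < X_i) + 0.5 P(X_j = X_i) ]`` over all groups *j*
  (including *i*, whose own term is exactly 0.5).

Group differences are tested with a quadratic ANOVA-type statistic
``T = sum_v sum_i n_i (p_vi - 0.5)^2`` whose null distribution is obtained by
permuting group labels jointly across variables, making the test exactly
calibrated regardless of the variance normalization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Interpretation band cutpoints on the probability scale.
BAND_CUTS = (0.4, 0.6)


def _group_indices(groups: pd.Series | np.ndarray) -> tuple[list[str], list[np.ndarray]]:
    groups = pd.Series(np.asarray(groups))
    labels = list(dict.fromkeys(groups))
    idx = [np.flatnonzero((groups == g).to_numpy()) for g in labels]
    return labels, idx


def midrank_relative_effects(
    values: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    variant: str = "weighted",
) -> pd.DataFrame:
    """Relative-effect probabilities, groups x variables.

    ``values`` is variable-by-sample; ``groups`` assigns one label per
    sample. A variable constant across all samples yields 0.5 everywhere.
    """
    if variant not in {"weighted", "unweighted"}:
        raise ValueError("variant must be 'weighted' or 'unweighted'")
    labels, idx = _group_indices(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    x = values.to_numpy(dtype=float)
    n = x.shape[1]
    if len(np.asarray(groups)) != n:
        raise ValueError("group labels must match the number of samples")
    if variant == "weighted":
        ranks = rankdata(x, axis=1)
        # single-division form of (mean midrank - 0.5)/N: exact when the
        # rank sum is exactly representable
        out = np.stack(
            [(ranks[:, g].sum(axis=1) - 0.5 * g.size) / (g.size * n) for g in idx],
            axis=0,
        )
    else:
        k = len(labels)
        out = np.zeros((k, x.shape[0]))
        ranks = rankdata(x, axis=1)
        # P(X_j < x) + 0.5 P(X_j = x) via midranks within the pair (i, j)
        for i in range(k):
            acc = np.full(x.shape[0], 0.5)   # own-group term
            for j in range(k):
                if j == i:
                    continue
                pair = np.concatenate([idx[j], idx[i]])
                pr = rankdata(x[:, pair], axis=1)
                nj = idx[j].size
                # mean midrank of group i within the pair, re-expressed as
                # the pairwise probability estimate
                mi = pr[:, nj:].mean(axis=1)
                ni = idx[i].size
                acc += (mi - (ni + 1) / 2) / nj
            out[i] = acc / k
    return pd.DataFrame(out, index=pd.Index(labels, name="group"), columns=values.index)


def group_sizes(groups: pd.Series | np.ndarray) -> pd.Series:
    labels, idx = _group_indices(groups)
    return pd.Series([g.size for g in idx], index=pd.Index(labels, name="group"))


def ats_statistic(effects: np.ndarray, sizes: np.ndarray) -> float:
    """Quadratic ANOVA-type statistic summed over variables and groups."""
    return float((sizes[:, None] * (effects - 0.5) ** 2).sum())


def permutation_ats_test(
    values: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of equal group distributions across all variables.

    Returns ``(statistic, p_value)`` with
    ``p = (1 + #{permuted T >= observed T}) / (n_perm + 1)``; group labels
    are permuted jointly across variables. Deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, idx = _group_indices(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    x = values.to_numpy(dtype=float)
    n = x.shape[1]
    ranks = rankdata(x, axis=1)
    sizes = np.array([g.size for g in idx], dtype=float)
    # membership matrix scaled so ranks @ M gives group mean ranks
    M = np.zeros((n, len(labels)))
    for i, g in enumerate(idx):
        M[g, i] = 1.0 / g.size
    effects = (ranks @ M - 0.5) / n
    observed = ats_statistic(effects.T, sizes)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        eff = (ranks[:, perm] @ M - 0.5) / n
        if ats_statistic(eff.T, sizes) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, p


def relative_effects_vs_reference(
    values: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    ref_group: str = "normal",
) -> pd.DataFrame:
    """Relative effects of each group against one reference group only.

    ``p_i = P(X_ref < X_i) + 0.5 P(X_ref = X_i)`` estimated by pairwise
    midrank counts between group *i* and the reference group; the reference
    group itself gets 0.5. Unlike the pooled variant, these probabilities do
    not depend on which other groups happen to be present, so rows are
    comparable across independently analyzed strata.
    """
    labels, idx = _group_indices(groups)
    if ref_group not in labels:
        raise ValueError(f"reference group {ref_group!r} not present")
    ref = idx[labels.index(ref_group)]
    if ref.size < 2:
        raise ValueError(f"reference group {ref_group!r} needs >= 2 samples")
    x = values.to_numpy(dtype=float)
    out = np.empty((len(labels), x.shape[0]))
    for i, g in enumerate(idx):
        if labels[i] == ref_group:
            out[i] = 0.5
            continue
        pair = np.concatenate([ref, g])
        pr = rankdata(x[:, pair], axis=1)
        mi = pr[:, ref.size:].mean(axis=1)
        out[i] = (mi - (g.size + 1) / 2) / ref.size
    return pd.DataFrame(out, index=pd.Index(labels, name="group"), columns=values.index)


def bands(effects: pd.DataFrame) -> pd.DataFrame:
    """Discretize probabilities at the 0.4 / 0.5 / 0.6 cutpoints."""
    lo, hi = BAND_CUTS
    x = effects.to_numpy(dtype=float)
    lab = np.where(x <= lo, "lower", np.where(x >= hi, "higher", "not_changed"))
    lab = np.where(np.isnan(x), "missing", lab)
    return pd.DataFrame(lab, index=effects.index, columns=effects.columns)


def subtype_effect_matrix(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    extra: pd.DataFrame | None = None,
    variant: str = "weighted",
    reference: str = "normal",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cancer-type relative effects of every variable, one row per subtype.

    Within each cancer type the groups are its tumor subtypes plus the
    literal group ``normal``. With ``reference='normal'`` (default) each
    subtype's probability is computed against the normal-tissue group only,
    anchoring 0.5 at "unchanged versus normal" and making rows comparable
    across cancer types; ``reference='pooled'`` uses the pooled midrank
    estimator of ``variant`` instead. Normal rows are dropped from the
    output (they remain available through the per-type computation).
    ``extra`` holds additional per-sample variables (MUTsum, TCD4, TCD8) as
    columns.

    Returns ``(effects, sizes)`` with row index ``cancer_type::subtype``.
    """
    if reference not in {"normal", "pooled"}:
        raise ValueError("reference must be 'normal' or 'pooled'")
    variables = list(expr.index)
    if extra is not None:
        variables += list(extra.columns)
    rows, sizes, names = [], [], []
    for ct, samples in metadata.groupby("cancer_type").groups.items():
        meta = metadata.loc[samples]
        n_normal = int((meta["is_tumor"] == 0).sum())
        n_subtypes = meta.loc[meta["is_tumor"] == 1, "subtype"].nunique()
        if n_subtypes < 1 or n_normal < 2:
            raise ValueError(
                f"cancer type {ct}: needs >= 1 subtype and >= 2 normal samples"
            )
        groups = np.where(meta["is_tumor"] == 1, meta["subtype"], "normal")
        mat = expr.loc[:, samples].to_numpy(dtype=float)
        if extra is not None:
            mat = np.vstack([mat, extra.loc[samples].to_numpy(dtype=float).T])
        values = pd.DataFrame(mat, index=pd.Index(variables), columns=samples)
        missing = ~np.isfinite(values.to_numpy()).all(axis=1)
        if missing.any():
            logger.warning("cancer type %s: %d variables with missing values; "
                           "effects set to NaN", ct, int(missing.sum()))
        if reference == "pooled":
            eff = midrank_relative_effects(values.loc[~missing], groups, variant=variant)
        else:
            eff = relative_effects_vs_reference(values.loc[~missing], groups, "normal")
        eff = eff.reindex(columns=pd.Index(variables))
        gsz = group_sizes(groups)
        for st in eff.index:
            if st == "normal":
                continue
            rows.append(eff.loc[st])
            sizes.append(gsz.loc[st])
            names.append(f"{ct}::{st}")
    out = pd.DataFrame(rows, index=pd.Index(names, name="group"))
    return out, pd.Series(sizes, index=out.index, name="n")
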