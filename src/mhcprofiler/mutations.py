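"""Nonsilent mutation burden and MHC-gene mutation frequency.

Works on a MAF-like table of (sample_id, gene, variant_class) records;
standard MAF column names (Tumor_Sample_Barcode, Hugo_Symbol,
Variant_Classification) are accepted as an aliased dialect. The burden is
gene-level by default: several records for one gene in one sample count
once.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

#: Conventional MAF nonsynonymous variant classes.
DEFAULT_NONSILENT = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
})

_MAF_ALIASES = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
}


def normalize_mutation_table(mutations: pd.DataFrame) -> pd.DataFrame:
    """Map MAF column names onto the cohort dialect and check the schema."""
    table = mutations.rename(columns=_MAF_ALIASES)
    missing = {"sample_id", "gene", "variant_class"} - set(table.columns)
    if missing:
        raise ValueError(f"mutation table lacks columns: {sorted(missing)}")
    return table[["sample_id", "gene", "variant_class"]]


def per_sample_mutation_burden(
    mutations: pd.DataFrame,
    sample_ids: pd.Index | list[str],
    nonsilent: frozenset[str] | set[str] = DEFAULT_NONSILENT,
    gene_level: bool = True,
) -> pd.Series:
    """Nonsilent mutation count per sample; absent samples get 0.

    ``gene_level`` counts each mutated gene once per sample; otherwise every
    record counts.
    """
    table = normalize_mutation_table(mutations)
    silent = ~table["variant_class"].isin(nonsilent)
    if silent.any():
        logger.info("dropped %d silent mutation records", int(silent.sum()))
    table = table[~silent]
    if gene_level:
        table = table.drop_duplicates(["sample_id", "gene"])
    counts = table.groupby("sample_id").size()
    return counts.reindex(sample_ids, fill_value=0).rename("MUTsum").astype(int)


def mhc_mutation_frequency(
    mutations: pd.DataFrame,
    gene_set: list[str] | set[str],
    metadata: pd.DataFrame,
    nonsilent: frozenset[str] | set[str] = DEFAULT_NONSILENT,
) -> pd.DataFrame:
    """Per-subtype percentage of samples carrying a nonsilent mutation in the
    gene set.

    Returns one row per (cancer_type, subtype) with the carrier count, the
    subtype size, the exact percentage and the integer-rounded percentage
    used for reporting. Empty subtypes are omitted.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    if "subtype" not in metadata.columns:
        raise ValueError("metadata lacks a 'subtype' column")
    table = normalize_mutation_table(mutations)
    table = table[table["variant_class"].isin(nonsilent) & table["gene"].isin(set(gene_set))]
    carriers = set(table["sample_id"])
    tumors = metadata[metadata["is_tumor"] == 1]
    rows = []
    for (ct, st), idx in tumors.groupby(["cancer_type", "subtype"]).groups.items():
        n = len(idx)
        if n == 0:
            continue
        c = sum(s in carriers for s in idx)
        pct = 100.0 * c / n
        rows.append({"cancer_type": ct, "subtype": st, "n_samples": n,
                     "n_carriers": c, "percent": pct, "percent_rounded": round(pct)})
    return pd.DataFrame(rows)
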