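"""Synthetic multi-cancer cohort generator.

Emulates the statistical structure of a pan-cancer expression/methylation
study: negative-binomial RNA-seq counts with library-size and GC bias,
per-gene batch shifts, a latent immune fraction driving a subset of
immunomodulator genes, methylation beta values arising as convex mixtures
of epithelial / fibroblast / immune reference profiles, per-subtype MHC
expression archetypes (low / intermediate / high), CD4/CD8 T-cell levels
tied to the immune fraction, and per-gene nonsilent mutation indicators
with subtype-level rate multipliers.

The ground truth (cell fractions, T-cell levels, archetypes, immune-driven
gene flags) is carried alongside the observable data so every downstream
stage of the pipeline can be validated against planted structure.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PANEL_CLASSES = ("CAG", "immunoinhibitor", "MHC", "other")
ARCHETYPES = ("low", "intermediate", "high")

#: Nonsilent variant classes emitted by the generator (MAF vocabulary).
NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)

# ---------------------------------------------------------------------------
# Study layout: 13 cancer types, 55 molecular subtypes, three MHC archetypes.
# The "low" set follows the published per-type lists; the 8-member "high" set
# is a synthetic stand-in chosen from hypermutated / viral / immunogenic
# subtypes (see docs/methods.md); everything else is "intermediate".
# ---------------------------------------------------------------------------

_STUDY_SUBTYPES: dict[str, list[str]] = {
    "BLCA": ["Ba-Sq", "LumNS", "LumP", "LumU", "Stroma-rich"],
    "BRCA": ["Basal", "Her2", "LumA", "LumB", "Normal-like"],
    "COAD": ["CMS1", "CMS2", "CMS3", "CMS4"],
    "ESCA": ["EAC", "ESCC1", "ESCC2"],
    "HNSC": ["CIMP", "HPV", "non-CIMP", "NSD1", "Stem-like"],
    "LIHC": ["iCluster-1", "iCluster-2", "iCluster-3"],
    "LUAD": ["AD-1", "AD-2", "AD-3", "AD-4", "AD-5a", "AD-5b"],
    "LUSC": ["AD-1", "SQ-1", "SQ-2a", "SQ-2b"],
    "PAAD": ["ADEX", "Immunogenic", "Progenitor", "Squamous"],
    "PRAD": ["S1", "S2", "S3"],
    "STAD": ["CIN", "EBV", "GS", "MSI"],
    "THCA": ["THCA-1", "THCA-2", "THCA-3", "THCA-4", "THCA-5"],
    "UCEC": ["CN-HIGH", "CN-LOW", "MSI", "POLE"],
}

_STUDY_LOW: set[tuple[str, str]] = {
    ("BLCA", "LumNS"), ("BLCA", "LumP"), ("BLCA", "LumU"), ("BLCA", "Stroma-rich"),
    ("BRCA", "LumA"), ("BRCA", "LumB"),
    ("COAD", "CMS2"), ("COAD", "CMS3"), ("COAD", "CMS4"),
    ("ESCA", "ESCC1"),
    ("HNSC", "NSD1"), ("HNSC", "Stem-like"),
    ("LIHC", "iCluster-1"), ("LIHC", "iCluster-2"),
    ("LUAD", "AD-5a"), ("LUAD", "AD-5b"),
    ("LUSC", "AD-1"), ("LUSC", "SQ-2b"),
    ("PAAD", "ADEX"), ("PAAD", "Squamous"),
    ("PRAD", "S3"),
    ("STAD", "CIN"), ("STAD", "GS"),
    ("THCA", "THCA-1"), ("THCA", "THCA-3"), ("THCA", "THCA-5"),
    ("UCEC", "CN-HIGH"),
}

_STUDY_HIGH: set[tuple[str, str]] = {
    ("COAD", "CMS1"), ("STAD", "MSI"), ("STAD", "EBV"), ("UCEC", "POLE"),
    ("UCEC", "MSI"), ("HNSC", "CIMP"), ("LIHC", "iCluster-3"), ("ESCA", "EAC"),
}


def table1_composition() -> dict[str, dict[str, str]]:
    """Per-subtype MHC archetype layout of the 13-type / 55-subtype study.

    Returns a nested mapping ``{cancer_type: {subtype: archetype}}`` usable
    directly as :attr:`CohortConfig.mhc_composition`.
    """
    out: dict[str, dict[str, str]] = {}
    for ct, subtypes in _STUDY_SUBTYPES.items():
        out[ct] = {}
        for st in subtypes:
            if (ct, st) in _STUDY_LOW:
                out[ct][st] = "low"
            elif (ct, st) in _STUDY_HIGH:
                out[ct][st] = "high"
            else:
                out[ct][st] = "intermediate"
    return out


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Sizes are per cancer type; ``mhc_composition`` (cancer type -> subtype ->
    archetype) overrides the homogeneous ``n_cancer_types``/``subtypes_per_type``
    layout when given.
    """

    n_cancer_types: int = 2
    subtypes_per_type: int = 3
    samples_per_subtype: int = 20
    n_normal_per_type: int = 10
    n_genes_background: int = 400
    panel_spec: Mapping[str, int] = field(
        default_factory=lambda: {"CAG": 105, "immunoinhibitor": 25, "MHC": 32, "other": 0}
    )
    frac_immune_driven: float = 0.3
    immune_beta: float = 2.0
    mhc_composition: Mapping[str, Mapping[str, str]] | None = None
    mhc_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"low": -1.5, "intermediate": -0.25, "high": 1.5}
    )
    nb_dispersion: float = 0.1
    libsize_log_mean: float = 14.5
    libsize_log_sd: float = 0.3
    n_batches: int = 2
    batch_sd: float = 0.5
    gc_bias_sd: float = 1.0
    n_cpgs: int = 500
    beta_noise_sd: float = 0.05
    mut_rate_per_gene: float = 0.002
    mut_rate_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"low": 1.0, "intermediate": 2.0, "high": 5.0}
    )
    dirichlet_alpha: tuple[float, float, float] = (2.0, 1.0, 1.0)
    seed: int = 0

    def layout(self) -> dict[str, dict[str, str]]:
        """Resolve the cancer-type -> subtype -> archetype layout."""
        if self.mhc_composition is not None:
            return {ct: dict(sub) for ct, sub in self.mhc_composition.items()}
        cycle = ["low", "intermediate", "high"]
        out = {}
        for i in range(self.n_cancer_types):
            ct = f"T{i + 1:02d}"
            out[ct] = {
                f"S{j + 1}": cycle[j % 3] for j in range(self.subtypes_per_type)
            }
        return out

    def validate(self) -> None:
        for name in ("n_cancer_types", "subtypes_per_type", "samples_per_subtype",
                     "n_normal_per_type", "n_genes_background", "n_batches", "n_cpgs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0.0 <= self.frac_immune_driven <= 1.0:
            raise ConfigurationError("frac_immune_driven must lie in [0, 1]")
        if not 0.0 <= self.mut_rate_per_gene <= 1.0:
            raise ConfigurationError("mut_rate_per_gene must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be strictly positive")
        unknown = set(self.panel_spec) - set(PANEL_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown panel classes: {sorted(unknown)}")
        layout = self.layout()
        for ct, sub in layout.items():
            bad = {a for a in sub.values() if a not in ARCHETYPES}
            if bad:
                raise ConfigurationError(
                    f"{ct}: archetypes {sorted(bad)} not in {ARCHETYPES}"
                )
        missing = set(ARCHETYPES) - set(self.mhc_shifts)
        if missing:
            raise ConfigurationError(f"mhc_shifts missing archetypes: {sorted(missing)}")


@dataclass
class Cohort:
    """A generated cohort plus its ground truth.

    All sample-indexed tables share one sample ordering; ``truth`` holds the
    per-sample simplex cell fractions and CD4/CD8 levels, ``gene_truth`` the
    per-gene immune-driven flags, ``archetypes`` the per-subtype archetype.
    """

    counts: pd.DataFrame          # genes x samples, integer
    gc: pd.Series                 # per-gene GC fraction
    betas: pd.DataFrame           # CpGs x samples, in [0, 1]
    reference: pd.DataFrame       # CpGs x 3 cell types
    metadata: pd.DataFrame        # sample_id index: cancer_type, subtype, is_tumor, batch
    mutations: pd.DataFrame       # sample_id, gene, variant_class
    panel: pd.DataFrame           # gene_id index: class
    truth: pd.DataFrame           # sample_id index: epithelial, fibroblast, immune, cd4, cd8
    gene_truth: pd.DataFrame      # gene_id index: immune_driven (bool)
    archetypes: pd.DataFrame      # (cancer_type, subtype) rows: archetype
    config: CohortConfig | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.metadata.index

    def check(self) -> None:
        ids = self.metadata.index
        for name, other in (("counts", self.counts.columns),
                            ("betas", self.betas.columns),
                            ("truth", self.truth.index)):
            if not ids.equals(pd.Index(other)):
                raise ValueError(f"sample ids of {name} disagree with metadata")
        fr = self.truth[["epithelial", "fibroblast", "immune"]].to_numpy()
        if (fr < -1e-12).any() or np.abs(fr.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("truth cell fractions must be a point on the 3-simplex")


def _gene_table(config: CohortConfig, rng: np.random.Generator):
    """Gene ids, classes, GC content, baseline log2 abundance, immune flags."""
    gene_ids, classes = [], []
    for i in range(config.n_genes_background):
        gene_ids.append(f"BG{i + 1:04d}")
        classes.append("background")
    prefixes = {"CAG": "CAG", "immunoinhibitor": "INH", "MHC": "MHC", "other": "OTH"}
    for cls in PANEL_CLASSES:
        for i in range(int(config.panel_spec.get(cls, 0))):
            gene_ids.append(f"{prefixes[cls]}{i + 1:04d}")
            classes.append(cls)
    classes = np.asarray(classes)
    n = len(gene_ids)

    gc = rng.uniform(0.35, 0.65, size=n)
    baseline = rng.normal(4.0, 2.0, size=n)
    # a slice of weakly expressed background genes so the low-expression
    # filter has something to remove
    low_bg = (classes == "background") & (rng.random(n) < 0.1)
    baseline[low_bg] = rng.normal(-4.0, 1.0, size=low_bg.sum())
    panel_mask = classes != "background"
    baseline[panel_mask] = np.clip(rng.normal(5.0, 1.5, size=panel_mask.sum()), 2.5, None)

    immune_driven = np.zeros(n, dtype=bool)
    panel_idx = np.flatnonzero(panel_mask)
    k = int(round(config.frac_immune_driven * panel_idx.size))
    if k:
        immune_driven[rng.choice(panel_idx, size=k, replace=False)] = True
    return pd.Index(gene_ids, name="gene_id"), classes, gc, baseline, immune_driven


def _reference_profiles(n_cpgs: int, rng: np.random.Generator) -> pd.DataFrame:
    """Cell-type-discriminating CpG reference panel (betas near 0 or 1)."""
    patterns = np.array([p for p in np.ndindex(2, 2, 2) if len(set(p)) > 1], dtype=float)
    chosen = patterns[rng.integers(0, len(patterns), size=n_cpgs)]
    values = 0.1 + 0.8 * chosen
    return pd.DataFrame(
        values,
        index=pd.Index([f"cg{i + 1:06d}" for i in range(n_cpgs)], name="cpg_id"),
        columns=["epithelial", "fibroblast", "immune"],
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort (expression, methylation, mutations, truth).

    Deterministic given ``config.seed``: the same configuration always yields
    a bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = config.layout()

    gene_ids, classes, gc, baseline, immune_driven = _gene_table(config, rng)
    n_genes = len(gene_ids)

    sample_ids: list[str] = []
    meta_rows: list[tuple[str, str, int, str]] = []
    sample_arche: list[str | None] = []
    for ct, subtypes in layout.items():
        for st, arche in subtypes.items():
            for i in range(config.samples_per_subtype):
                sample_ids.append(f"{ct}_{st}_T{i + 1:03d}")
                meta_rows.append((ct, st, 1, ""))
                sample_arche.append(arche)
        for i in range(config.n_normal_per_type):
            sample_ids.append(f"{ct}_N{i + 1:03d}")
            meta_rows.append((ct, "normal", 0, ""))
            sample_arche.append(None)
    n_samples = len(sample_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["cancer_type", "subtype", "is_tumor", "batch"],
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # batches nested within cancer type; per-gene plate shifts
    batch_shift = np.zeros((n_genes, n_samples))
    for ct in layout:
        in_ct = np.flatnonzero((metadata["cancer_type"] == ct).to_numpy())
        assignment = rng.integers(0, config.n_batches, size=in_ct.size)
        shifts = rng.normal(0.0, config.batch_sd, size=(n_genes, config.n_batches))
        for b in range(config.n_batches):
            cols = in_ct[assignment == b]
            batch_shift[:, cols] = shifts[:, [b]]
        metadata.iloc[in_ct, metadata.columns.get_loc("batch")] = [
            f"{ct}_b{b + 1}" for b in assignment
        ]

    fractions = rng.dirichlet(config.dirichlet_alpha, size=n_samples)
    immune_frac = fractions[:, 2]
    gc_coef = rng.normal(0.0, config.gc_bias_sd, size=n_samples)
    libsize = np.exp(rng.normal(config.libsize_log_mean, config.libsize_log_sd, n_samples))

    arche_shift = np.array(
        [0.0 if a is None else config.mhc_shifts[a] for a in sample_arche]
    )
    log2q = (
        baseline[:, None]
        + batch_shift
        + np.outer(gc - gc.mean(), gc_coef)
        + np.outer(immune_driven.astype(float), config.immune_beta * immune_frac)
        + np.outer((classes == "MHC").astype(float), arche_shift)
    )
    q = np.exp2(log2q)
    q /= q.sum(axis=0, keepdims=True)
    mu = q * libsize[None, :]
    # negative binomial via gamma-Poisson; var = mu + dispersion * mu^2
    lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * mu)
    counts = rng.poisson(lam)

    reference = _reference_profiles(config.n_cpgs, rng)
    betas = reference.to_numpy() @ fractions.T
    betas = np.clip(betas + rng.normal(0.0, config.beta_noise_sd, betas.shape), 0.0, 1.0)

    cd4 = np.clip(0.6 * immune_frac + rng.normal(0.0, 0.02, n_samples), 0.0, 1.0)
    cd8 = np.clip(0.4 * immune_frac + rng.normal(0.0, 0.02, n_samples), 0.0, 1.0)

    # nonsilent mutations: tumor samples only, Bernoulli per sample x gene
    mult = np.array(
        [0.0 if a is None else config.mut_rate_multipliers.get(a, 1.0)
         for a in sample_arche]
    )
    p_mut = np.clip(config.mut_rate_per_gene * mult, 0.0, 1.0)
    hit = rng.random((n_genes, n_samples)) < p_mut[None, :]
    g_idx, s_idx = np.nonzero(hit)
    vclass = rng.choice(NONSILENT_CLASSES, size=g_idx.size, p=[0.7, 0.1, 0.08, 0.07, 0.05])
    mutations = pd.DataFrame({
        "sample_id": np.asarray(sample_ids)[s_idx],
        "gene": gene_ids.to_numpy()[g_idx],
        "variant_class": vclass,
    })

    panel = pd.DataFrame(
        {"class": classes[classes != "background"]},
        index=gene_ids[classes != "background"].rename("gene_id"),
    )
    truth = pd.DataFrame(
        {"epithelial": fractions[:, 0], "fibroblast": fractions[:, 1],
         "immune": immune_frac, "cd4": cd4, "cd8": cd8},
        index=metadata.index,
    )
    gene_truth = pd.DataFrame(
        {"class": classes, "immune_driven": immune_driven, "baseline_log2": baseline},
        index=gene_ids,
    )
    arche_rows = [
        (ct, st, a) for ct, subs in layout.items() for st, a in subs.items()
    ]
    archetypes = pd.DataFrame(arche_rows, columns=["cancer_type", "subtype", "archetype"])

    cohort = Cohort(
        counts=pd.DataFrame(counts, index=gene_ids, columns=metadata.index),
        gc=pd.Series(gc, index=gene_ids, name="gc"),
        betas=pd.DataFrame(betas, index=reference.index, columns=metadata.index),
        reference=reference,
        metadata=metadata,
        mutations=mutations,
        panel=panel,
        truth=truth,
        gene_truth=gene_truth,
        archetypes=archetypes,
        config=replace(config),
    )
    cohort.check()
    return cohort


# ---------------------------------------------------------------------------
# TSV round-trip (header row + row-name first column throughout)
# ---------------------------------------------------------------------------

_FILES = {
    "counts": "counts.tsv",
    "gc": "gc.tsv",
    "betas": "betas.tsv",
    "reference": "reference.tsv",
    "metadata": "metadata.tsv",
    "mutations": "mutations.tsv",
    "panel": "panel.tsv",
    "truth": "truth.tsv",
    "gene_truth": "truth_genes.tsv",
    "archetypes": "truth_archetypes.tsv",
}


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> dict[str, str]:
    """Serialize a cohort as a directory of TSV files; returns the path map."""
    if len(cohort.sample_ids) == 0:
        raise ValueError("cannot write an empty cohort (0 samples)")
    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in _FILES.items()}
    cohort.counts.to_csv(paths["counts"], sep="\t")
    cohort.gc.to_frame().to_csv(paths["gc"], sep="\t")
    cohort.betas.to_csv(paths["betas"], sep="\t", float_format="%.10g")
    cohort.reference.to_csv(paths["reference"], sep="\t", float_format="%.10g")
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.panel.to_csv(paths["panel"], sep="\t")
    cohort.truth.to_csv(paths["truth"], sep="\t", float_format="%.10g")
    cohort.gene_truth.to_csv(paths["gene_truth"], sep="\t")
    cohort.archetypes.to_csv(paths["archetypes"], sep="\t", index=False)
    return paths


def read_cohort(directory: str | os.PathLike) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    paths = {k: os.path.join(directory, v) for k, v in _FILES.items()}
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    gc = pd.read_csv(paths["gc"], sep="\t", index_col=0)["gc"]
    betas = pd.read_csv(paths["betas"], sep="\t", index_col=0)
    reference = pd.read_csv(paths["reference"], sep="\t", index_col=0)
    metadata = pd.read_csv(paths["metadata"], sep="\t", index_col=0)
    mutations = pd.read_csv(paths["mutations"], sep="\t")
    if mutations.empty:
        mutations = mutations.astype({"sample_id": str, "gene": str,
                                      "variant_class": str})
    panel = pd.read_csv(paths["panel"], sep="\t", index_col=0)
    truth = pd.read_csv(paths["truth"], sep="\t", index_col=0)
    gene_truth = pd.read_csv(paths["gene_truth"], sep="\t", index_col=0)
    archetypes = pd.read_csv(paths["archetypes"], sep="\t")
    for df in (counts, betas):
        df.columns.name = "sample_id"
    cohort = Cohort(
        counts=counts, gc=gc, betas=betas, reference=reference, metadata=metadata,
        mutations=mutations, panel=panel, truth=truth, gene_truth=gene_truth,
        archetypes=archetypes,
    )
    cohort.check()
    return cohort
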