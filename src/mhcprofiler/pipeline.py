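"""End-to-end pipeline: preprocess -> deconvolve -> panel selection ->
relative effects -> clustering -> mutation summary -> correlation summary.

The pipeline is driven by a flat key-value configuration (YAML mapping of
scalars). A single master seed deterministically spawns per-stage seeds, so
re-running with the same configuration reproduces every output byte for
byte. Outputs are written with a ``.partial`` suffix while the run is in
progress and renamed on success; an aborted run leaves the partials behind.
"""

from __future__ import annotations

import dataclasses
import difflib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusteringResult, cluster_mhc
from .cohort import Cohort, CohortConfig, generate_cohort, read_cohort, table1_composition
from .deconv import rpc_deconvolve
from .effects import bands, subtype_effect_matrix
from .mutations import mhc_mutation_frequency, per_sample_mutation_burden
from .panel import pan_cancer_correlation_summary, select_panel
from .preprocess import preprocess_expression

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; ``seed`` is mandatory."""

    seed: int
    out_dir: str = "mhcprofiler_out"
    # input: either a cohort directory or synthetic generation
    input_dir: str | None = None
    synthetic: bool = True
    layout: str = "table1"            # 'table1' or 'auto'
    n_cancer_types: int = 2
    subtypes_per_type: int = 3
    samples_per_subtype: int = 20
    n_normal_per_type: int = 10
    n_genes_background: int = 400
    frac_immune_driven: float = 0.3
    immune_beta: float = 2.0
    nb_dispersion: float = 0.1
    n_batches: int = 2
    batch_sd: float = 0.5
    n_cpgs: int = 500
    beta_noise_sd: float = 0.05
    mut_rate_per_gene: float = 0.002
    # preprocessing
    min_cpm: float = 1.0
    min_fraction: float = 0.2
    n_gc_bins: int = 10
    log_offset: float = 0.25
    sd_threshold: float = 3.0
    min_batch_size: int = 5
    min_subtype_size: int = 10
    # deconvolution
    skip_deconvolution: bool = False
    fractions_path: str | None = None
    huber_c: float = 1.345
    # panel selection
    min_median_logcpm: float = 0.0
    r_threshold: float = 0.4
    fdr: float = 0.05
    correlation_mode: str = "positive"
    # relative effects / clustering
    effect_variant: str = "weighted"
    effect_reference: str = "normal"
    k_min: int = 2
    k_max: int = 5

    _RANGES = {
        "r_threshold": (0.0, 1.0), "fdr": (0.0, 1.0), "min_fraction": (0.0, 1.0),
        "frac_immune_driven": (0.0, 1.0), "mut_rate_per_gene": (0.0, 1.0),
        "beta_noise_sd": (0.0, 1.0),
    }

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        issues = validate_config(raw)
        fatal = [i for i in issues if i["severity"] == "error"]
        if fatal:
            raise ValueError("invalid config: " + "; ".join(i["message"] for i in fatal))
        known = {k: v for k, v in raw.items() if k in cls.field_names()}
        if "seed" not in known:
            raise ValueError("config must set 'seed'")
        return cls(**known)


def validate_config(raw: dict) -> list[dict]:
    """Report unknown keys, missing paths and out-of-range thresholds.

    Purely diagnostic: returns a list of {key, message, severity} records and
    never mutates state or raises.
    """
    issues: list[dict] = []
    names = PipelineConfig.field_names()
    for key in raw:
        if key not in names:
            hint = difflib.get_close_matches(str(key), names, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            issues.append({"key": key, "severity": "error",
                           "message": f"unknown key {key!r}{suggestion}"})
    for key, (lo, hi) in PipelineConfig._RANGES.items():
        if key in raw and raw[key] is not None and not lo <= float(raw[key]) <= hi:
            issues.append({"key": key, "severity": "error",
                           "message": f"{key}={raw[key]} outside [{lo}, {hi}]"})
    if not raw.get("synthetic", True) and not raw.get("input_dir"):
        issues.append({"key": "input_dir", "severity": "error",
                       "message": "input_dir required when synthetic is false"})
    for key in ("input_dir", "fractions_path"):
        if raw.get(key) and not os.path.exists(str(raw[key])):
            issues.append({"key": key, "severity": "error",
                           "message": f"{key} path does not exist: {raw[key]}"})
    if raw.get("skip_deconvolution") and not raw.get("fractions_path"):
        issues.append({"key": "fractions_path", "severity": "error",
                       "message": "fractions_path required when skip_deconvolution is set"})
    return issues


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _cohort_config(cfg: PipelineConfig, seed: int) -> CohortConfig:
    comp = table1_composition() if cfg.layout == "table1" else None
    return CohortConfig(
        n_cancer_types=cfg.n_cancer_types,
        subtypes_per_type=cfg.subtypes_per_type,
        samples_per_subtype=cfg.samples_per_subtype,
        n_normal_per_type=cfg.n_normal_per_type,
        n_genes_background=cfg.n_genes_background,
        frac_immune_driven=cfg.frac_immune_driven,
        immune_beta=cfg.immune_beta,
        mhc_composition=comp,
        nb_dispersion=cfg.nb_dispersion,
        n_batches=cfg.n_batches,
        batch_sd=cfg.batch_sd,
        n_cpgs=cfg.n_cpgs,
        beta_noise_sd=cfg.beta_noise_sd,
        mut_rate_per_gene=cfg.mut_rate_per_gene,
        seed=seed,
    )


@dataclass
class PipelineResult:
    cohort: Cohort
    expression: pd.DataFrame
    metadata: pd.DataFrame
    fractions: pd.DataFrame
    retained_panel: pd.DataFrame
    effects: pd.DataFrame
    effect_sizes: pd.Series
    clustering: ClusteringResult
    corr_summary: pd.DataFrame
    mutation_freq: pd.DataFrame
    run_log: list[str] = field(default_factory=list)


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage in the fixed order and (optionally) write outputs."""
    log: list[str] = [f"mhcprofiler {__version__}", f"master seed {cfg.seed}"]
    for f in dataclasses.fields(cfg):
        log.append(f"param {f.name} = {getattr(cfg, f.name)}")
    seeds = _stage_seeds(cfg.seed, ["cohort", "clustering"])
    log += [f"stage seed {k} = {v}" for k, v in seeds.items()]

    stage = "load"
    partials: list[tuple[str, str]] = []
    try:
        if cfg.synthetic:
            stage = "simulate"
            cohort = generate_cohort(_cohort_config(cfg, seeds["cohort"]))
        else:
            cohort = read_cohort(cfg.input_dir)
        log.append(f"cohort: {cohort.counts.shape[0]} genes x "
                   f"{cohort.counts.shape[1]} samples, "
                   f"{cohort.metadata['cancer_type'].nunique()} cancer types")

        stage = "preprocess"
        expr, meta = preprocess_expression(
            cohort.counts, cohort.gc, cohort.metadata,
            min_cpm=cfg.min_cpm, min_fraction=cfg.min_fraction,
            n_gc_bins=cfg.n_gc_bins, log_offset=cfg.log_offset,
            sd_threshold=cfg.sd_threshold, min_batch_size=cfg.min_batch_size,
            min_subtype_size=cfg.min_subtype_size, run_log=log,
        )

        stage = "deconvolve"
        if cfg.skip_deconvolution:
            fractions = pd.read_csv(cfg.fractions_path, sep="\t", index_col=0)
            log.append(f"deconvolution skipped; fractions from {cfg.fractions_path}")
        else:
            fractions = rpc_deconvolve(cohort.betas, cohort.reference, huber_c=cfg.huber_c)
        fractions = fractions.loc[meta.index]

        stage = "panel_selection"
        retained, report = select_panel(
            expr, fractions["immune"], meta, cohort.panel,
            min_median_logcpm=cfg.min_median_logcpm, r_threshold=cfg.r_threshold,
            fdr=cfg.fdr, mode=cfg.correlation_mode,
        )
        log.append(f"panel: {len(retained)}/{len(cohort.panel)} genes retained "
                   f"(FDR within cancer type, mode={cfg.correlation_mode})")

        stage = "relative_effects"
        burden = per_sample_mutation_burden(cohort.mutations, meta.index)
        extra = pd.DataFrame({
            "MUTsum": burden,
            "TCD4": cohort.truth.loc[meta.index, "cd4"],
            "TCD8": cohort.truth.loc[meta.index, "cd8"],
        })
        effects, sizes = subtype_effect_matrix(
            expr.loc[retained.index], meta, extra,
            variant=cfg.effect_variant, reference=cfg.effect_reference,
        )
        log.append(f"effects: {effects.shape[0]} subtype rows x "
                   f"{effects.shape[1]} variables")

        stage = "clustering"
        mhc_genes = [g for g in retained.index if retained.loc[g, "class"] == "MHC"]
        if not mhc_genes:
            raise ValueError("no MHC genes survive panel selection")
        mhc_matrix = effects[mhc_genes]
        clustering = cluster_mhc(
            mhc_matrix, range(cfg.k_min, cfg.k_max + 1), seed=seeds["clustering"]
        )
        counts = clustering.classes.value_counts()
        log.append(f"clustering: selected K = {clustering.selected_k}; "
                   f"class sizes {counts.to_dict()}")

        stage = "mutation_summary"
        panel_mhc = [g for g in cohort.panel.index if cohort.panel.loc[g, "class"] == "MHC"]
        mutfreq = mhc_mutation_frequency(cohort.mutations, panel_mhc, meta)

        stage = "correlation_summary"
        per_type: dict[str, pd.DataFrame] = {}
        for ct, samples in meta[meta["is_tumor"] == 1].groupby("cancer_type").groups.items():
            block = expr.loc[retained.index, samples]
            block.loc["TCD4"] = extra.loc[samples, "TCD4"].to_numpy()
            block.loc["TCD8"] = extra.loc[samples, "TCD8"].to_numpy()
            per_type[ct] = block
        if len(per_type) >= 2:
            corr = pan_cancer_correlation_summary(per_type, cfg.r_threshold, cfg.fdr)
        else:
            corr = pd.DataFrame()
            log.append("correlation summary skipped: fewer than 2 cancer types")

        result = PipelineResult(
            cohort=cohort, expression=expr, metadata=meta, fractions=fractions,
            retained_panel=retained, effects=effects, effect_sizes=sizes,
            clustering=clustering, corr_summary=corr, mutation_freq=mutfreq,
            run_log=log,
        )
        if write:
            stage = "write"
            _write_outputs(cfg, result, partials)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_outputs(cfg: PipelineConfig, res: PipelineResult,
                   partials: list[tuple[str, str]]) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)

    def emit(name: str, writer) -> None:
        final = os.path.join(cfg.out_dir, name)
        partial = final + ".partial"
        writer(partial)
        partials.append((partial, final))

    emit("effects.tsv", lambda p: res.effects.to_csv(p, sep="\t", float_format="%.10g"))
    emit("bands.tsv", lambda p: bands(res.effects).to_csv(p, sep="\t"))
    cl = res.clustering
    clusters = pd.DataFrame({
        "cluster": cl.consensus,
        "mhc_class": cl.classes,
    })
    emit("clusters.tsv", lambda p: clusters.to_csv(p, sep="\t"))
    emit("validity.tsv", lambda p: cl.validity.to_csv(p, sep="\t", index=False,
                                                      float_format="%.10g"))
    emit("corr_summary.tsv", lambda p: res.corr_summary.to_csv(p, sep="\t"))
    emit("mutation_freq.tsv", lambda p: res.mutation_freq.to_csv(p, sep="\t", index=False,
                                                                 float_format="%.10g"))
    emit("fractions.tsv", lambda p: res.fractions.to_csv(p, sep="\t", float_format="%.10g"))
    # plot-ready matrix ordered by cluster then mean probability
    mhc_cols = [g for g in res.retained_panel.index
                if res.retained_panel.loc[g, "class"] == "MHC"]
    heat = res.effects.loc[cl.consensus.index, mhc_cols].copy()
    order = sorted(heat.index, key=lambda r: (cl.consensus[r], heat.loc[r].mean()))
    emit("heatmap_matrix.tsv",
         lambda p: heat.loc[order].to_csv(p, sep="\t", float_format="%.10g"))
    emit("run_log.txt", lambda p: open(p, "w").write("\n".join(res.run_log) + "\n"))
    for partial, final in partials:
        os.replace(partial, final)
    partials.clear()
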