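"""End-to-end orchestration: simulate -> preprocess -> variability -> mQTL ->
EWAS -> clustering -> report.

The pipeline runs each stage in dependency order with deterministic
seeding (one global seed expands to fixed per-stage seeds so stages can be
re-run in isolation), logs record counts at every filter, and produces a
consolidated :class:`RunReport` whose category and overlap accountings are
internally consistent by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import ConfigError, write_beta_matrix, write_table
from .genotype_mqtl import (
    MQTL_THRESHOLD,
    apply_qc,
    cis_scan,
    overlap_eight,
    snp_qc,
)
from .prenatal_ewas import (
    EWAS_THRESHOLD,
    effect_concordance,
    ewas_scan,
    factor_correlations,
    pf_overlap,
)
from .preprocess import (
    associate_pcs,
    build_design,
    combat_adjust,
    estimate_cell_proportions,
    estimate_surrogate_variables,
    run_pca,
)
from .reference_clustering import (
    MIN_COVERAGE,
    cluster,
    harmonize,
    median_profile,
    sample_reference_correlation,
)
from .synthetic_cohort import SimulationConfig, simulate_cohort, simulate_reference_set
from .variability import categorize, iqr_exceedance_curve, variability_table

logger = logging.getLogger("dualtissue")

_STAGE_OFFSETS = {"simulate": 1, "reference": 2}


def derive_seed(seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation from the global seed (below 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Thresholds, toggles and the synthetic-cohort settings for one run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | None = None
    variability_range_threshold: float = 0.10
    variability_tail_threshold: float = 0.05
    mqtl_threshold: float = MQTL_THRESHOLD
    ewas_threshold: float = EWAS_THRESHOLD
    use_surrogate_variables: bool = False
    n_sv: int = 5
    response_scale: str = "beta"
    n_reference_sites: int = 4000
    min_coverage: float = MIN_COVERAGE
    n_correlation_samples: int = 10    # per tissue, for sample-vs-reference Spearman
    n_pca_components: int = 10

    def validate(self) -> None:
        for name in ("variability_range_threshold", "variability_tail_threshold"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name}={v} outside [0, 1)")
        for name in ("mqtl_threshold", "ewas_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        self.simulation.validate()

    def config_hash(self) -> str:
        payload = json.dumps(
            {"pipeline": {k: v for k, v in asdict(self).items() if k != "simulation"},
             "simulation": _jsonable(asdict(self.simulation))},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """Consolidated per-stage accounting for one pipeline run."""

    seed: int
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    category_counts: dict = field(default_factory=dict)
    category_proportions: dict = field(default_factory=dict)
    mqtl: dict = field(default_factory=dict)
    ewas: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


@dataclass
class PipelineResult:
    """Report plus the intermediates downstream consumers may reuse."""

    report: RunReport
    cohort: object
    adjusted_betas: dict
    designs: dict
    proportions: dict
    calls: dict
    category: object
    mqtl_records: dict
    mqtl_overlap: object
    ewas_results: dict
    ewas_overlap: object
    concordance: object
    cluster_result: object
    pc_diagnostics: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a simulated paired-tissue cohort."""
    config.validate()
    seed = config.simulation.seed
    report = RunReport(seed=seed, config_hash=config.config_hash(), version=__version__)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: simulate ----------------------------------------------------
    cohort = simulate_cohort(config.simulation)
    tissues = list(cohort.betas)
    report.stages["simulate"] = {
        t: list(cohort.betas[t].shape) for t in tissues
    } | {"n_snps": int(cohort.genotypes.dosages.shape[0])}
    logger.info("simulate: %s", report.stages["simulate"])

    # --- stage: preprocess ----------------------------------------------------
    adjusted, designs, proportions, pc_diag = {}, {}, {}, {}
    for t in tissues:
        beta = cohort.betas[t]
        props = estimate_cell_proportions(beta, cohort.panels[t])
        proportions[t] = props
        design = build_design(cohort.metadata, props, tissue=t)
        m_raw = beta.to_m()
        scores, varexp = run_pca(m_raw, n_components=config.n_pca_components)
        tech_vars = [c for c in ("chip", "chip_set", "chip_position", "bisulfite_batch",
                                 "dna_extraction_batch") if c in cohort.metadata.columns]
        pc_diag[t] = associate_pcs(scores, cohort.metadata, tech_vars, varexp)
        m_adj = combat_adjust(m_raw, cohort.metadata["chip"], design.frame)
        if config.use_surrogate_variables and config.n_sv > 0:
            sv = estimate_surrogate_variables(m_adj, design, config.n_sv)
            design = build_design(cohort.metadata, props, tissue=t, extra=sv)
        designs[t] = design
        adjusted[t] = m_adj.to_beta()
        report.stages.setdefault("preprocess", {})[t] = {
            "design_columns": len(design.frame.columns),
            "design_dropped": len(design.dropped),
            "cell_types": list(props.proportions.columns),
        }

    # --- stage: variability ---------------------------------------------------
    calls = {
        t: variability_table(
            adjusted[t],
            range_threshold=config.variability_range_threshold,
            tail_threshold=config.variability_tail_threshold,
        )
        for t in tissues
    }
    ta, tb = tissues[0], tissues[1]
    category = categorize(calls[ta], calls[tb], label_a=ta, label_b=tb)
    curves = {t: iqr_exceedance_curve(calls[t], np.round(np.arange(0.0, 0.51, 0.05), 2))
              for t in tissues}
    report.category_counts = {k: int(v) for k, v in category.counts.items()}
    report.category_proportions = {
        k: round(float(v), 4) for k, v in category.proportions.items()
    }
    report.stages["variability"] = {
        t: {"n_variable": int(calls[t]["is_variable"].sum())} for t in tissues
    }
    logger.info("variability: %s", report.stages["variability"])

    # --- stage: mQTL ----------------------------------------------------------
    qc = snp_qc(cohort.genotypes)
    genotypes = apply_qc(cohort.genotypes, qc)
    report.stages["genotype_qc"] = {
        "n_snps_pass": int(qc.snp_table["pass"].sum()),
        "n_snps_fail": int((~qc.snp_table["pass"]).sum()),
        "n_samples_pass": int(qc.sample_table["pass"].sum()),
    }
    mqtl_records = {}
    for t in tissues:
        var_cpgs = calls[t].index[calls[t]["is_variable"]]
        mqtl_records[t] = cis_scan(
            adjusted[t], genotypes, designs[t], var_cpgs,
            threshold=config.mqtl_threshold, response_scale=config.response_scale,
        )
        n_sig = int(mqtl_records[t]["is_significant"].sum())
        report.mqtl[t] = {
            "n_scanned": len(mqtl_records[t]),
            "n_significant": n_sig,
            "pct_of_variable": round(100.0 * n_sig / max(len(var_cpgs), 1), 2),
        }
    mqtl_overlap = overlap_eight(mqtl_records[ta], mqtl_records[tb],
                                 calls[ta], calls[tb], label_a=ta, label_b=tb)
    report.mqtl["overlap"] = {
        "universe": mqtl_overlap.universe_size,
        "both_associated": int(mqtl_overlap.counts.loc[("associated", "associated")]),
        "pct_of_" + ta: round(mqtl_overlap.overlap_pct_by_a, 2),
        "pct_of_" + tb: round(mqtl_overlap.overlap_pct_by_b, 2),
        "counts": {" / ".join(k): int(v) for k, v in mqtl_overlap.counts.items()},
    }
    logger.info("mqtl: %s", report.mqtl)

    # --- stage: EWAS ----------------------------------------------------------
    ewas_results = {}
    for t in tissues:
        var_cpgs = calls[t].index[calls[t]["is_variable"]]
        ewas_results[t] = ewas_scan(
            adjusted[t], cohort.factors, designs[t], var_cpgs,
            threshold=config.ewas_threshold, response_scale=config.response_scale,
        )
        n_sig = int(ewas_results[t].summary["is_pf_associated"].sum())
        report.ewas[t] = {
            "n_scanned": len(ewas_results[t].summary),
            "n_pf_associated": n_sig,
            "pct_of_variable": round(100.0 * n_sig / max(len(var_cpgs), 1), 2),
        }
    ewas_overlap = pf_overlap(ewas_results[ta], ewas_results[tb],
                              calls[ta], calls[tb], label_a=ta, label_b=tb)
    pf_a = ewas_results[ta].summary
    select = pf_a.index[pf_a["is_pf_associated"]]
    concordance = effect_concordance(ewas_results[ta], ewas_results[tb], select)
    report.ewas["overlap"] = {
        "universe": ewas_overlap.universe_size,
        "both_associated": int(ewas_overlap.counts.loc[("associated", "associated")]),
    }
    report.ewas["concordance"] = {
        "n_pairs": len(concordance.pairs),
        "sign_agreement": (None if np.isnan(concordance.sign_agreement)
                           else round(concordance.sign_agreement, 3)),
    }
    factor_corr = factor_correlations(cohort.factors)

    # --- stage: clustering ----------------------------------------------------
    n_sites = min(config.n_reference_sites, len(cohort.betas[ta].cpg_ids))
    site_map = cohort.betas[ta].cpg_map.iloc[:n_sites]
    refset = simulate_reference_set(
        site_map=site_map, n_sites=n_sites, seed=derive_seed(seed, "reference")
    )
    profiles = {t: median_profile(adjusted[t]).loc[site_map.index] for t in tissues}
    panel = harmonize(refset.references, profiles, min_coverage=config.min_coverage)
    cluster_result = cluster(panel)
    sub = {
        t: type(adjusted[t])(
            adjusted[t].values.iloc[:, :config.n_correlation_samples]
            .loc[panel.site_ids],
            tissue_label=t,
        )
        for t in tissues
    }
    sample_corr = {t: sample_reference_correlation(sub[t], panel) for t in tissues}
    report.clustering = {
        "n_sites_retained": len(panel.site_ids),
        "n_references": panel.references.shape[1],
        "dropped_reasons": {
            k: int(v) for k, v in panel.dropped.value_counts().items()
        },
    }
    logger.info("clustering: %s", report.clustering)

    # --- consistency identities ------------------------------------------------
    assert sum(report.category_counts.values()) == len(calls[ta])
    assert sum(mqtl_overlap.counts) == mqtl_overlap.universe_size
    for lab in (ta, tb):
        assert int(mqtl_overlap.marginals[lab].sum()) == mqtl_overlap.universe_size

    # --- outputs ----------------------------------------------------------------
    if out_dir:
        for t in tissues:
            write_beta_matrix(adjusted[t], out_dir / f"beta_adjusted_{t}.tsv")
            write_table(calls[t], out_dir / f"variability_calls_{t}.tsv")
            write_table(mqtl_records[t], out_dir / f"mqtl_records_{t}.tsv")
            write_table(ewas_results[t].summary, out_dir / f"ewas_summary_{t}.tsv")
            write_table(curves[t], out_dir / f"iqr_curve_{t}.tsv", index=False)
            write_table(proportions[t].proportions, out_dir / f"cell_proportions_{t}.tsv")
            write_table(pc_diag[t], out_dir / f"pc_diagnostics_{t}.tsv", index=False)
        write_table(category.summary(), out_dir / "variability_categories.tsv")
        write_table(factor_corr, out_dir / "factor_correlations.tsv")
        write_table(cohort.truth.to_frame(), out_dir / "truth.tsv", index=False)
        (out_dir / "dendrogram.nwk").write_text(cluster_result.newick + "\n")
        for t in tissues:
            write_table(sample_corr[t], out_dir / f"sample_reference_correlation_{t}.tsv")
        (out_dir / "report.json").write_text(report.to_json() + "\n")

    return PipelineResult(
        report=report,
        cohort=cohort,
        adjusted_betas=adjusted,
        designs=designs,
        proportions=proportions,
        calls=calls,
        category=category,
        mqtl_records=mqtl_records,
        mqtl_overlap=mqtl_overlap,
        ewas_results=ewas_results,
        ewas_overlap=ewas_overlap,
        concordance=concordance,
        cluster_result=cluster_result,
        pc_diagnostics=pc_diag,
    )


def sensitivity_rerun(config: PipelineConfig, n_sv: int) -> tuple[PipelineResult, PipelineResult, pd.DataFrame]:
    """Run with and without surrogate variables; tabulate the call-rate deltas.

    Returns (base result, SV result, delta table of SNP- and PF-associated
    percentages per tissue). With ``n_sv`` = 0 the SV run equals the base run.
    """
    import copy

    base_cfg = copy.deepcopy(config)
    base_cfg.use_surrogate_variables = False
    base = run_pipeline(base_cfg)

    sv_cfg = copy.deepcopy(config)
    sv_cfg.use_surrogate_variables = n_sv > 0
    sv_cfg.n_sv = n_sv
    with_sv = run_pipeline(sv_cfg)

    rows = []
    for t in base.report.mqtl:
        if t == "overlap":
            continue
        rows.append({
            "tissue": t,
            "snp_associated_pct_base": base.report.mqtl[t]["pct_of_variable"],
            "snp_associated_pct_sv": with_sv.report.mqtl[t]["pct_of_variable"],
            "pf_associated_pct_base": base.report.ewas[t]["pct_of_variable"],
            "pf_associated_pct_sv": with_sv.report.ewas[t]["pct_of_variable"],
        })
    return base, with_sv, pd.DataFrame(rows)
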