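"""Synthetic paired-tissue cohort generator with a ground-truth manifest.

Emulates the statistical structure of a two-tissue neonatal methylation
cohort at desk scale: a bimodal beta landscape (most CpGs near 0 or 1),
designated variable CpGs carrying person-level variance, additive cis-SNP
(mQTL) effects, linear prenatal-factor effects, per-chip location/scale
batch effects, and cell-composition mixing at dedicated signature CpGs.
Effects are implanted on the M-value scale and transformed to beta, which
keeps fractions bounded without truncation artifacts.

A companion generator produces sequencing-style reference methylomes
(per-site fraction plus read coverage) organized into lineages, with
between-lineage divergence exceeding within-lineage divergence by
construction — the input the clustering stage expects.

Every draw flows through a single :class:`numpy.random.Generator` seeded
from the config, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    BetaMatrix,
    ConfigError,
    FactorTable,
    GenotypeData,
    ReferenceMethylome,
    beta_to_m,
    m_to_beta,
)

TISSUE_A = "cord_tissue"
TISSUE_B = "cord_blood"

#: Default cell panels: stromal-type panel for cord tissue, leukocyte panel
#: (plus nucleated red blood cells) for cord blood.
DEFAULT_CELL_PANEL_SPEC: dict[str, tuple[str, ...]] = {
    TISSUE_A: ("fibroblast", "b_cell", "t_cell"),
    TISSUE_B: ("nrbc", "granulocyte", "monocyte", "nk", "b_cell", "cd4t", "cd8t"),
}


@dataclass
class SimulationConfig:
    """Desk-scale study conditions for the paired-tissue cohort.

    Variability fractions default to the observed two-tissue landscape:
    ~37.5% of CpGs variable in cord tissue, ~23.3% in cord blood, with a
    20% shared core (so the four-category split lands near 20/18/3/59).
    Effect sizes are in M-value units (per alternate allele for mQTLs, per
    SD of factor for prenatal factors); person-level SD 0.6 and noise SD
    0.1 put implanted effects of the default size comfortably above the
    genome-wide thresholds at n = 200.
    """

    n_samples: int = 200
    n_cpgs: int = 20_000
    n_snps: int = 5_000
    n_chromosomes: int = 4
    fraction_variable_per_tissue: Mapping[str, float] = field(
        default_factory=lambda: {TISSUE_A: 0.375, TISSUE_B: 0.233}
    )
    fraction_variable_both: float = 0.20
    n_mqtl_cpgs: int = 200
    mqtl_effect_size: float = 0.7
    n_factor_cpgs: int = 100
    factor_effect_size: float = 0.25
    allele_frequency_range: tuple[float, float] = (0.15, 0.5)
    missing_genotype_rate: float = 0.0
    n_chips: int | None = None          # default: ceil(n_samples / 12)
    chip_shift_scale: float = 0.3       # SD of per-chip location shift (M units)
    chip_scale_sd: float = 0.05         # SD of per-chip multiplicative scale around 1
    cell_panel_spec: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_CELL_PANEL_SPEC)
    )
    n_panel_cpgs: int = 300             # signature CpGs per tissue
    cell_concentration: float = 5.0     # symmetric Dirichlet concentration
    person_sd: float = 0.6              # person-level SD at variable CpGs (M units)
    noise_sd: float = 0.1               # measurement noise SD (M units)
    n_continuous_factors: int = 40
    n_categorical_factors: int = 5
    factor_block_size: int = 5
    factor_block_rho: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("n_samples", "n_cpgs", "n_snps", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.allele_frequency_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("allele_frequency_range must satisfy 0 < lo <= hi < 1")
        fracs = dict(self.fraction_variable_per_tissue)
        for t, f in fracs.items():
            if not 0 < f < 1:
                raise ConfigError(f"fraction_variable_per_tissue[{t!r}] must be in (0,1)")
        if self.fraction_variable_both > min(fracs.values()):
            raise ConfigError("fraction_variable_both exceeds a per-tissue fraction")
        n_shared = round(self.fraction_variable_both * self.n_cpgs)
        if self.n_mqtl_cpgs + self.n_factor_cpgs > n_shared:
            raise ConfigError(
                f"{self.n_mqtl_cpgs} mQTL + {self.n_factor_cpgs} factor implants exceed "
                f"the {n_shared} shared variable CpGs"
            )


@dataclass
class SyntheticTruth:
    """Manifest of implanted structure; the acceptance oracle for every stage.

    ``cpg`` is a per-(tissue, CpG) table with columns is_variable,
    variable_source (person/composition), mqtl_snp, mqtl_effect (M units per
    allele), factor, factor_effect (M units per factor SD). ``chips`` holds
    per-chip location shifts and scale factors; ``cell_proportions`` the true
    per-sample mixing weights per tissue.
    """

    cpg: pd.DataFrame
    chips: pd.DataFrame
    cell_proportions: dict[str, pd.DataFrame]

    def variable_cpgs(self, tissue: str) -> pd.Index:
        t = self.cpg[(self.cpg["tissue"] == tissue) & self.cpg["is_variable"]]
        return pd.Index(t["cpg_id"])

    def mqtl_cpgs(self, tissue: str) -> pd.DataFrame:
        t = self.cpg[(self.cpg["tissue"] == tissue) & self.cpg["mqtl_snp"].notna()]
        return t.set_index("cpg_id")[["mqtl_snp", "mqtl_effect"]]

    def factor_cpgs(self, tissue: str) -> pd.DataFrame:
        t = self.cpg[(self.cpg["tissue"] == tissue) & self.cpg["factor"].notna()]
        return t.set_index("cpg_id")[["factor", "factor_effect"]]

    def to_frame(self) -> pd.DataFrame:
        return self.cpg.copy()


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    betas: dict[str, BetaMatrix]
    genotypes: GenotypeData
    metadata: pd.DataFrame
    factors: FactorTable
    panels: dict[str, pd.DataFrame]
    truth: SyntheticTruth
    config: SimulationConfig


def _coordinate_grid(n: int, n_chrom: int, prefix: str, step: int) -> pd.DataFrame:
    """Lay n features on a shared per-chromosome coordinate grid."""
    per = [n // n_chrom + (1 if i < n % n_chrom else 0) for i in range(n_chrom)]
    chroms, pos = [], []
    for i, k in enumerate(per):
        chroms += [str(i + 1)] * k
        pos += list(range(step, step * (k + 1), step))
    ids = [f"{prefix}{i:06d}" for i in range(n)]
    return pd.DataFrame({"chrom": chroms, "pos": pos}, index=pd.Index(ids, name="id"))


def _sample_factors(cfg: SimulationConfig, rng: np.random.Generator,
                    sample_ids: pd.Index) -> FactorTable:
    """40 continuous standard-normal factors with block correlation + 5 categoricals."""
    n, k = cfg.n_samples, cfg.n_continuous_factors
    z = rng.standard_normal((n, k))
    rho, bs = cfg.factor_block_rho, cfg.factor_block_size
    x = np.empty_like(z)
    for start in range(0, k, bs):
        block = slice(start, min(start + bs, k))
        shared = rng.standard_normal(n)
        x[:, block] = math.sqrt(rho) * shared[:, None] + math.sqrt(1 - rho) * z[:, block]
    values = pd.DataFrame(
        x, index=sample_ids, columns=[f"factor_c{i:02d}" for i in range(k)]
    )
    schema = {c: "continuous" for c in values.columns}
    for j in range(cfg.n_categorical_factors):
        name = f"factor_k{j:02d}"
        values[name] = rng.choice(["low", "mid", "high"], size=n)
        schema[name] = "categorical"
    return FactorTable(values, schema)


def _sample_metadata(cfg: SimulationConfig, rng: np.random.Generator,
                     sample_ids: pd.Index) -> pd.DataFrame:
    n = cfg.n_samples
    n_chips = cfg.n_chips or math.ceil(n / 12)
    chip_idx = rng.permutation(np.arange(n) % n_chips)
    md = pd.DataFrame(index=sample_ids)
    md["sex"] = rng.choice(["male", "female"], size=n)
    md["gestational_age"] = np.round(rng.normal(38.5, 1.0, size=n), 2)
    md["ethnicity"] = rng.choice(["chinese", "malay", "indian"], size=n, p=[0.49, 0.30, 0.21])
    md["hospital"] = rng.choice(["KKH", "NUH"], size=n, p=[0.7, 0.3])
    md["bisulfite_batch"] = [f"bs{(i // 96):d}" for i in rng.permutation(n)]
    md["chip"] = [f"chip{c:02d}" for c in chip_idx]
    md["chip_set"] = [f"set{(c // 8):d}" for c in chip_idx]
    md["chip_position"] = [f"pos{p:02d}" for p in rng.integers(0, 12, size=n)]
    md["dna_extraction_batch"] = rng.choice([f"ex{i}" for i in range(4)], size=n)
    return md


def _dirichlet(rng: np.random.Generator, conc: float, k: int, n: int) -> np.ndarray:
    """Symmetric Dirichlet draw via normalized gammas (density prop. to prod w^(c-1))."""
    g = rng.gamma(conc, 1.0, size=(n, k))
    return g / g.sum(axis=1, keepdims=True)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full paired-tissue cohort plus its truth manifest.

    See the module docstring for the generative model. Per tissue, bulk
    M-values are baseline + person-level deviation + implanted mQTL/factor
    effects; signature CpGs are replaced by cell-proportion-weighted
    mixtures of cell-specific profiles; per-chip location/scale shifts and
    measurement noise are applied last, on the M scale.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tissues = list(cfg.fraction_variable_per_tissue)

    sample_ids = pd.Index([f"S{i:04d}" for i in range(cfg.n_samples)], name="sample_id")
    cpg_map = _coordinate_grid(cfg.n_cpgs, cfg.n_chromosomes, "cg", step=1000)
    cpg_map.index.name = "cpg_id"
    snp_map = _coordinate_grid(cfg.n_snps, cfg.n_chromosomes, "rs", step=4000)
    snp_map.index.name = "snp_id"
    snp_map["ref"] = rng.choice(list("ACGT"), size=cfg.n_snps)
    snp_map["alt"] = [
        rng.choice([b for b in "ACGT" if b != r]) for r in snp_map["ref"]
    ]
    cpg_ids = cpg_map.index

    # --- genotypes (shared across tissues) ---------------------------------
    lo, hi = cfg.allele_frequency_range
    freqs = rng.uniform(lo, hi, size=cfg.n_snps)
    dos = rng.binomial(2, freqs[:, None], size=(cfg.n_snps, cfg.n_samples)).astype(float)
    if cfg.missing_genotype_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_genotype_rate
        dos[mask] = np.nan
    genotypes = GenotypeData(
        pd.DataFrame(dos, index=snp_map.index, columns=sample_ids), snp_map
    )

    # --- variable-CpG designation ------------------------------------------
    n_both = round(cfg.fraction_variable_both * cfg.n_cpgs)
    only = {
        t: round(cfg.fraction_variable_per_tissue[t] * cfg.n_cpgs) - n_both
        for t in tissues
    }
    perm = rng.permutation(cfg.n_cpgs)
    shared_idx = perm[:n_both]
    cursor = n_both
    only_idx = {}
    for t in tissues:
        only_idx[t] = perm[cursor:cursor + only[t]]
        cursor += only[t]
    variable_idx = {t: np.sort(np.concatenate([shared_idx, only_idx[t]])) for t in tissues}

    # --- baselines (M scale) -----------------------------------------------
    # Non-variable CpGs sit near the beta boundaries (|M| in [2.5, 4]); the
    # sign is shared between tissues for 70% of CpGs and redrawn for the
    # rest, giving the tissues distinct methylomes. Variable CpGs sit at
    # intermediate methylation (M in [-1, 1], shared across tissues).
    base_sign = rng.choice([-1.0, 1.0], size=cfg.n_cpgs)
    base_mag = rng.uniform(2.5, 4.0, size=cfg.n_cpgs)
    base_shared = base_sign * base_mag
    base_mid = rng.uniform(-1.0, 1.0, size=cfg.n_cpgs)
    tissue_specific = rng.random(cfg.n_cpgs) < 0.30
    baselines = {}
    for t in tissues:
        b = base_shared.copy()
        redraw = tissue_specific
        b[redraw] = rng.choice([-1.0, 1.0], size=redraw.sum()) * rng.uniform(
            2.5, 4.0, size=redraw.sum()
        )
        b[variable_idx[t]] = base_mid[variable_idx[t]]
        baselines[t] = b

    # --- implant designation (shared variable core, per tissue) -------------
    implant_pool = rng.permutation(shared_idx)
    mqtl_idx = np.sort(implant_pool[:cfg.n_mqtl_cpgs])
    factor_idx = np.sort(implant_pool[cfg.n_mqtl_cpgs:cfg.n_mqtl_cpgs + cfg.n_factor_cpgs])

    snps_by_chrom = {c: snp_map.index[snp_map["chrom"] == c] for c in snp_map["chrom"].unique()}
    mqtl_snp = {}
    mqtl_eff = {}
    for i in mqtl_idx:
        chrom = cpg_map["chrom"].iloc[i]
        mqtl_snp[i] = rng.choice(snps_by_chrom[chrom])
        mqtl_eff[i] = float(rng.choice([-1.0, 1.0]) * cfg.mqtl_effect_size)
    cont_names = [f"factor_c{i:02d}" for i in range(cfg.n_continuous_factors)]
    factor_name = {i: str(rng.choice(cont_names)) for i in factor_idx}
    factor_eff = {i: float(rng.choice([-1.0, 1.0]) * cfg.factor_effect_size) for i in factor_idx}

    metadata = _sample_metadata(cfg, rng, sample_ids)
    factors = _sample_factors(cfg, rng, sample_ids)

    # --- chip effects --------------------------------------------------------
    chips = sorted(metadata["chip"].unique())
    chip_loc = rng.normal(0.0, cfg.chip_shift_scale, size=len(chips))
    chip_scale = np.clip(1.0 + rng.normal(0.0, cfg.chip_scale_sd, size=len(chips)), 0.2, None)
    chip_table = pd.DataFrame({"chip": chips, "location": chip_loc, "scale": chip_scale})
    loc_by_sample = metadata["chip"].map(dict(zip(chips, chip_loc))).to_numpy()
    scale_by_sample = metadata["chip"].map(dict(zip(chips, chip_scale))).to_numpy()

    # --- per-tissue assembly -------------------------------------------------
    dos_filled = np.nan_to_num(dos, nan=0.0)
    snp_pos = {s: j for j, s in enumerate(snp_map.index)}
    betas: dict[str, BetaMatrix] = {}
    panels: dict[str, pd.DataFrame] = {}
    cell_props: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for t in tissues:
        M = np.tile(baselines[t][:, None], (1, cfg.n_samples))
        # signature CpGs: variance comes from composition, not person effects
        panel_types = list(cfg.cell_panel_spec[t])
        panel_pool = np.setdiff1d(variable_idx[t], np.concatenate([mqtl_idx, factor_idx]))
        panel_sel = np.sort(rng.choice(panel_pool, size=min(cfg.n_panel_cpgs, len(panel_pool)),
                                       replace=False))
        person_rows = np.setdiff1d(variable_idx[t], panel_sel)
        M[person_rows] += rng.normal(0.0, cfg.person_sd, size=(len(person_rows), cfg.n_samples))
        for i in mqtl_idx:
            M[i] += mqtl_eff[i] * dos_filled[snp_pos[mqtl_snp[i]]]
        for i in factor_idx:
            f = factors.values[factor_name[i]].to_numpy(dtype=float)
            fz = (f - f.mean()) / f.std()
            M[i] += factor_eff[i] * fz
        beta_bulk = m_to_beta(M)
        # cell-specific signature profiles: per panel CpG, a random half of
        # the cell types is highly methylated, the rest lowly methylated
        k = len(panel_types)
        high = rng.random((len(panel_sel), k)) < 0.5
        profiles = np.where(high, rng.uniform(0.8, 0.95, size=(len(panel_sel), k)),
                            rng.uniform(0.05, 0.2, size=(len(panel_sel), k)))
        W = _dirichlet(rng, cfg.cell_concentration, k, cfg.n_samples)
        beta_bulk[panel_sel] = profiles @ W.T
        Mmix = beta_to_m(beta_bulk)
        Mfinal = loc_by_sample[None, :] + scale_by_sample[None, :] * Mmix
        Mfinal = Mfinal + rng.normal(0.0, cfg.noise_sd, size=Mfinal.shape)
        bf = pd.DataFrame(m_to_beta(Mfinal), index=cpg_ids, columns=sample_ids)
        betas[t] = BetaMatrix(bf, cpg_map=cpg_map[["chrom", "pos"]], tissue_label=t)
        panels[t] = pd.DataFrame(profiles, index=cpg_ids[panel_sel], columns=panel_types)
        cell_props[t] = pd.DataFrame(W, index=sample_ids, columns=panel_types)

        is_var = np.zeros(cfg.n_cpgs, dtype=bool)
        is_var[variable_idx[t]] = True
        source = np.where(is_var, "person", "")
        source[panel_sel] = "composition"
        tr = pd.DataFrame({
            "tissue": t,
            "cpg_id": cpg_ids,
            "is_variable": is_var,
            "variable_source": source,
            "mqtl_snp": pd.Series({cpg_ids[i]: mqtl_snp[i] for i in mqtl_idx},
                                  dtype="object").reindex(cpg_ids).to_numpy(),
            "mqtl_effect": pd.Series({cpg_ids[i]: mqtl_eff[i] for i in mqtl_idx},
                                     dtype=float).reindex(cpg_ids).to_numpy(),
            "factor": pd.Series({cpg_ids[i]: factor_name[i] for i in factor_idx},
                                dtype="object").reindex(cpg_ids).to_numpy(),
            "factor_effect": pd.Series({cpg_ids[i]: factor_eff[i] for i in factor_idx},
                                       dtype=float).reindex(cpg_ids).to_numpy(),
        })
        truth_rows.append(tr)

    truth = SyntheticTruth(
        cpg=pd.concat(truth_rows, ignore_index=True),
        chips=chip_table,
        cell_proportions=cell_props,
    )
    return SimulatedCohort(betas, genotypes, metadata, factors, panels, truth, cfg)


# ---------------------------------------------------------------------------
# Reference methylomes
# ---------------------------------------------------------------------------

DEFAULT_LINEAGES: dict[str, int] = {
    "ectoderm": 6, "endoderm": 7, "HSC-mesoderm": 6, "MSC-mesoderm": 6,
}


@dataclass
class ReferenceSet:
    """References plus the generator's own lineage-level truth."""

    references: list[ReferenceMethylome]
    lineage_profiles: pd.DataFrame  # site x lineage, beta scale
    site_map: pd.DataFrame          # site_id -> chrom, pos

    def lineage_of(self, tissue_name: str) -> str:
        for r in self.references:
            if r.tissue_name == tissue_name:
                return r.lineage_label
        raise KeyError(tissue_name)

    def cohort_like_profile(self, lineage: str, deviation_sd: float = 0.3,
                            seed: int = 0) -> pd.Series:
        """A cohort-style median profile generated from one lineage's methylome."""
        rng = np.random.default_rng(seed)
        base_m = beta_to_m(self.lineage_profiles[lineage].to_numpy())
        dev = rng.normal(0.0, deviation_sd, size=base_m.shape)
        return pd.Series(m_to_beta(base_m + dev), index=self.lineage_profiles.index)


def simulate_reference_set(
    lineage_structure: Mapping[str, int | Sequence[str]] | None = None,
    n_sites: int = 5_000,
    coverage_mean: float = 40.0,
    seed: int = 0,
    lineage_sd: float = 1.5,
    tissue_sd: float = 0.3,
    missing_rate: float = 0.05,
    site_map: pd.DataFrame | None = None,
) -> ReferenceSet:
    """Generate lineage-structured reference methylomes with read coverage.

    Tissues within a lineage share a lineage-level M profile plus small
    tissue-level deviations (``lineage_sd`` vs ``tissue_sd``, default ratio
    5:1, so between-lineage divergence exceeds within-lineage divergence by
    construction). Coverage is Poisson(``coverage_mean``) per site, so some
    sites fall below any chosen threshold; a ``missing_rate`` fraction of
    sites is additionally dropped per tissue. Pass ``site_map`` (indexed by
    site id with chrom/pos) to place references on an existing CpG grid.
    """
    structure = dict(lineage_structure or DEFAULT_LINEAGES)
    if len(structure) < 2:
        raise ConfigError("need at least 2 lineages")
    names: dict[str, list[str]] = {}
    for lin, spec in structure.items():
        names[lin] = (
            [f"{lin}_t{i}" for i in range(spec)] if isinstance(spec, int) else list(spec)
        )
        if len(names[lin]) < 2:
            raise ConfigError(f"lineage {lin!r} needs at least 2 tissues")

    rng = np.random.default_rng(seed)
    if site_map is None:
        site_map = _coordinate_grid(n_sites, 4, "site", step=2000)
        site_map.index.name = "site_id"
    else:
        site_map = site_map.iloc[:n_sites].copy()
        n_sites = len(site_map)
    sites = site_map.index

    # mixed baseline: 70% of sites at intermediate methylation (informative
    # for lineage separation after the IQR filter), 30% near the boundaries
    mid = rng.random(n_sites) < 0.7
    base = np.where(mid, rng.uniform(-1.0, 1.0, size=n_sites),
                    rng.choice([-1.0, 1.0], size=n_sites) * rng.uniform(2.5, 4.0, size=n_sites))

    lineage_profiles = {}
    refs: list[ReferenceMethylome] = []
    for lin, tissue_names in names.items():
        lin_m = base + rng.normal(0.0, lineage_sd, size=n_sites)
        lineage_profiles[lin] = m_to_beta(lin_m)
        for tn in tissue_names:
            m = lin_m + rng.normal(0.0, tissue_sd, size=n_sites)
            meth = m_to_beta(m)
            coverage = rng.poisson(coverage_mean, size=n_sites).astype(float)
            drop = rng.random(n_sites) < missing_rate
            meth = meth.copy()
            meth[drop] = np.nan
            coverage[drop] = 0.0
            table = pd.DataFrame({
                "chrom": site_map["chrom"].to_numpy(),
                "pos": site_map["pos"].to_numpy(),
                "meth": meth,
                "coverage": coverage,
            }, index=sites)
            refs.append(ReferenceMethylome(table, tissue_name=tn, lineage_label=lin))

    return ReferenceSet(
        references=refs,
        lineage_profiles=pd.DataFrame(lineage_profiles, index=sites),
        site_map=site_map[["chrom", "pos"]],
    )
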