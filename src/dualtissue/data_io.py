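"""Containers and on-disk formats for the two-tissue neonatal EWAS pipeline.

The unit every stage consumes is a methylation *beta matrix*: CpGs as rows,
samples as columns, each entry the fraction methylated in [0, 1]. Linear
modelling and batch adjustment operate on *M-values*, the logit-like
transform M = log2(beta / (1 - beta)). Genotypes are additive alternate
allele dosages in {0, 1, 2}. All tabular formats are tab-delimited text
with a stable column order so that writes are byte-reproducible.

Conventions
-----------
* Autosomes only; chromosome labels are normalized to "1".."22" (a leading
  "chr" prefix is stripped on read).
* Missing methylation values are rejected on input rather than imputed.
* Methylation files carry the CpG identifier in the first column and one
  column per sample; values are written with 6 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dualtissue")

AUTOSOMES = tuple(str(i) for i in range(1, 23))

DEFAULT_M_EPSILON = 1e-6


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class DualTissueError(Exception):
    """Base class for all package errors."""


class FormatError(DualTissueError):
    """A file does not have the expected layout (header, columns, sidecar)."""


class ParseError(DualTissueError):
    """A cell could not be parsed; the message carries row/column context."""


class IntegrityError(DualTissueError):
    """Parsed data violate a container invariant (range, uniqueness, alignment)."""


class ConfigError(DualTissueError):
    """An infeasible or out-of-range configuration."""


class DegenerateInputError(DualTissueError):
    """Too few values (or no variance) for the requested computation."""


# ---------------------------------------------------------------------------
# Beta / M-value conversion
# ---------------------------------------------------------------------------

def beta_to_m(beta, epsilon: float = DEFAULT_M_EPSILON):
    """Convert methylation fractions to M-values, M = log2(b / (1 - b)).

    Betas are clipped to [epsilon, 1 - epsilon] first so the transform is
    total: boundary values 0 and 1 map to finite M. Strictly increasing on
    the clipped domain.
    """
    if not 0 < epsilon < 0.5:
        raise ConfigError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (on the clipped domain): 2^m / (1 + 2^m)."""
    m = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large |m|
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def _normalize_chroms(chroms: pd.Series) -> pd.Series:
    c = chroms.astype(str).str.replace("^chr", "", regex=True)
    bad = ~c.isin(AUTOSOMES)
    if bad.any():
        offenders = sorted(c[bad].unique())[:5]
        raise IntegrityError(
            f"non-autosomal chromosome labels (sex chromosomes disallowed): {offenders}"
        )
    return c


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """CpG x sample methylation fractions with optional CpG coordinates.

    Parameters
    ----------
    values
        DataFrame indexed by CpG id, one column per sample, entries in [0, 1].
    cpg_map
        Optional DataFrame indexed by CpG id with columns ``chrom`` (autosome
        label "1".."22") and ``pos`` (1-based). Required by the cis scan.
    tissue_label
        Free-text tissue name, e.g. ``"cord_tissue"``.
    """

    values: pd.DataFrame
    cpg_map: pd.DataFrame | None = None
    tissue_label: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise IntegrityError(f"duplicate CpG ids: {dups}")
        if v.columns.has_duplicates:
            raise IntegrityError("duplicate sample ids")
        arr = v.to_numpy()
        if arr.size and np.isnan(arr).any():
            bad = v.index[np.isnan(arr).any(axis=1)][:5].tolist()
            raise IntegrityError(f"missing methylation values disallowed (CpGs: {bad})")
        if arr.size and ((arr < 0) | (arr > 1)).any():
            bad = v.index[((arr < 0) | (arr > 1)).any(axis=1)][:5].tolist()
            raise IntegrityError(f"beta values outside [0, 1] at CpGs: {bad}")
        if self.cpg_map is not None:
            m = self.cpg_map.copy()
            missing = v.index.difference(m.index)
            if len(missing):
                raise IntegrityError(f"CpGs absent from cpg_map: {missing[:5].tolist()}")
            m = m.loc[v.index]
            m["chrom"] = _normalize_chroms(m["chrom"])
            self.cpg_map = m

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_m(self, epsilon: float = DEFAULT_M_EPSILON) -> "MValueMatrix":
        m = pd.DataFrame(
            beta_to_m(self.values.to_numpy(), epsilon),
            index=self.values.index,
            columns=self.values.columns,
        )
        return MValueMatrix(m, cpg_map=self.cpg_map, tissue_label=self.tissue_label)


@dataclass
class MValueMatrix:
    """Same axes as :class:`BetaMatrix`; values on the M (log2-ratio) scale."""

    values: pd.DataFrame
    cpg_map: pd.DataFrame | None = None
    tissue_label: str = ""

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise IntegrityError("M-values must be finite")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_beta(self) -> BetaMatrix:
        b = pd.DataFrame(
            m_to_beta(self.values.to_numpy()),
            index=self.values.index,
            columns=self.values.columns,
        )
        return BetaMatrix(b, cpg_map=self.cpg_map, tissue_label=self.tissue_label)


@dataclass
class GenotypeData:
    """SNP x sample additive dosages with a SNP map.

    ``dosages`` holds floats in {0, 1, 2} with NaN for missing calls;
    ``snp_map`` is indexed by SNP id with columns chrom, pos, ref, alt
    (alleles expressed on the positive strand).
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise IntegrityError("duplicate SNP ids")
        arr = self.dosages.to_numpy()
        obs = arr[~np.isnan(arr)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise IntegrityError("dosages must be in {0, 1, 2} or missing")
        missing = self.dosages.index.difference(self.snp_map.index)
        if len(missing):
            raise IntegrityError(f"SNPs absent from snp_map: {missing[:5].tolist()}")
        m = self.snp_map.loc[self.dosages.index].copy()
        m["chrom"] = _normalize_chroms(m["chrom"])
        self.snp_map = m

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class FactorTable:
    """Prenatal-factor values (sample x factor) with a typed schema.

    ``schema`` maps each factor name to ``"continuous"`` or ``"categorical"``;
    exactly the schema's factors must be present. Missingness is allowed and
    handled per-factor downstream (complete-case fits).
    """

    values: pd.DataFrame
    schema: dict[str, str]

    def __post_init__(self) -> None:
        cols = set(self.values.columns)
        declared = set(self.schema)
        if cols != declared:
            raise IntegrityError(
                f"factor table columns do not match schema; extra={sorted(cols - declared)[:5]}, "
                f"missing={sorted(declared - cols)[:5]}"
            )
        for name, kind in self.schema.items():
            if kind not in ("continuous", "categorical"):
                raise ConfigError(f"factor {name!r}: unknown type {kind!r}")

    @property
    def factor_names(self) -> list[str]:
        return list(self.values.columns)

    def continuous(self) -> list[str]:
        return [f for f in self.values.columns if self.schema[f] == "continuous"]

    def categorical(self) -> list[str]:
        return [f for f in self.values.columns if self.schema[f] == "categorical"]


@dataclass
class ReferenceMethylome:
    """A sequencing-based (RRBS-like) reference methylome for one tissue.

    ``table`` is indexed by site id with columns chrom, pos, meth (fraction in
    [0, 1]) and coverage (reads, nonnegative integer). ``lineage_label`` is
    user-provided metadata (e.g. one of ectoderm, endoderm, HSC-mesoderm,
    MSC-mesoderm).
    """

    table: pd.DataFrame
    tissue_name: str
    lineage_label: str = ""

    def __post_init__(self) -> None:
        t = self.table
        meth = t["meth"].to_numpy(dtype=float)
        obs = meth[~np.isnan(meth)]
        if obs.size and ((obs < 0) | (obs > 1)).any():
            raise IntegrityError(f"{self.tissue_name}: methylation fractions outside [0, 1]")
        cov = t["coverage"].to_numpy(dtype=float)
        if (cov[~np.isnan(cov)] < 0).any():
            raise IntegrityError(f"{self.tissue_name}: negative read coverage")


# ---------------------------------------------------------------------------
# Methylation matrix I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path: str | Path,
    id_column: str | None = None,
    sep: str = "\t",
    cpg_map: pd.DataFrame | None = None,
    tissue_label: str = "",
) -> BetaMatrix:
    """Read a tab-delimited CpG x sample methylation matrix.

    The first column (or ``id_column``, configurable because deposited-file
    headers vary) holds CpG identifiers; the header row holds sample ids.
    Rows with any value outside [0, 1], non-numeric cells and duplicate CpG
    ids are rejected with contextual errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.shape[1] < 1:
        raise FormatError(f"{path}: no columns found")
    id_col = id_column if id_column is not None else raw.columns[0]
    if id_col not in raw.columns:
        raise FormatError(f"{path}: id column {id_col!r} not in header")
    raw = raw.set_index(id_col)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()[:5]
        raise IntegrityError(f"{path}: duplicate CpG ids: {dups}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[r, c]!r} at CpG {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    return BetaMatrix(values.astype(float), cpg_map=cpg_map, tissue_label=tissue_label)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, id_column: str = "cpg_id") -> Path:
    """Write a beta matrix as tab-delimited text, 6-decimal fixed formatting.

    Byte-stable for identical input; a 0-CpG matrix yields a header-only file.
    """
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = id_column
    out.to_csv(path, sep="\t", float_format="%.6f", lineterminator="\n")
    return path


def read_cpg_map(path: str | Path) -> pd.DataFrame:
    """Read a CpG coordinate table (columns: cpg_id, chrom, pos)."""
    m = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("cpg_id", "chrom", "pos"):
        if col not in m.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    m = m.set_index("cpg_id")
    m["chrom"] = _normalize_chroms(m["chrom"])
    m["pos"] = m["pos"].astype(int)
    return m


def write_cpg_map(cpg_map: pd.DataFrame, path: str | Path) -> Path:
    out = cpg_map.copy()
    out.index.name = "cpg_id"
    out.to_csv(Path(path), sep="\t", lineterminator="\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    map_path: str | Path | None = None,
) -> GenotypeData:
    """Read genotypes from a VCF or a dosage matrix + SNP map pair.

    VCF records that are not biallelic SNVs are dropped (the count is
    logged). Matrix entries must be 0/1/2 or the missing markers NA/./empty.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        if map_path is None:
            raise FormatError("matrix genotype format requires a companion SNP map file")
        return _read_genotype_matrix(path, map_path)
    raise ConfigError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_dropped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_dropped += 1
            continue
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        dos = np.full(len(samples), np.nan)
        for j, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                continue
            dos[j] = float(sum(1 for a in alleles if a == 1))
        ids.append(sid)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    if n_dropped:
        logger.info("read_genotypes: dropped %d multi-allelic VCF records", n_dropped)
    dosages = pd.DataFrame(np.array(rows) if rows else np.empty((0, len(samples))),
                           index=pd.Index(ids, name="snp_id"), columns=samples)
    snp_map = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeData(dosages, snp_map)


def _read_genotype_matrix(path: str | Path, map_path: str | Path) -> GenotypeData:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad_cells = values.notna() & ~values.isin((0.0, 1.0, 2.0))
    if bad_cells.to_numpy().any():
        r, c = np.argwhere(bad_cells.to_numpy())[0]
        raise ParseError(
            f"{path}: dosage {raw.iloc[r, c]!r} not in {{0,1,2}} at SNP {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    unparsed = values.isna() & raw.notna() & ~raw.isin(("NA", ".", "nan"))
    if unparsed.to_numpy().any():
        r, c = np.argwhere(unparsed.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric dosage {raw.iloc[r, c]!r} at SNP {values.index[r]!r}"
        )
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos", "ref", "alt"}
    if not required.issubset(snp_map.columns):
        raise FormatError(f"{map_path}: SNP map needs columns {sorted(required)}")
    snp_map = snp_map.set_index("snp_id")
    return GenotypeData(values.astype(float), snp_map)


def write_genotype_matrix(gt: GenotypeData, path: str | Path, map_path: str | Path) -> Path:
    out = gt.dosages.copy()
    out.index.name = "snp_id"
    out.to_csv(Path(path), sep="\t", float_format="%.0f", na_rep="NA", lineterminator="\n")
    m = gt.snp_map.copy()
    m.index.name = "snp_id"
    m.to_csv(Path(map_path), sep="\t", lineterminator="\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Metadata / factor / panel / reference I/O
# ---------------------------------------------------------------------------

METADATA_CATEGORICALS = (
    "sex", "ethnicity", "hospital", "bisulfite_batch", "chip", "chip_set",
    "chip_position", "dna_extraction_batch",
)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata table (index: sample_id).

    Categorical columns are read as strings; ``gestational_age`` (weeks)
    stays numeric.
    """
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if md.index.has_duplicates:
        raise IntegrityError(f"{path}: duplicate sample ids")
    if "gestational_age" in md.columns:
        md["gestational_age"] = pd.to_numeric(md["gestational_age"])
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(Path(path), sep="\t", lineterminator="\n")
    return Path(path)


def read_factor_table(path: str | Path, schema_path: str | Path) -> FactorTable:
    """Read a factor table plus its typed schema sidecar (YAML: name -> type)."""
    import yaml

    with open(schema_path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, Mapping):
        raise FormatError(f"{schema_path}: schema must map factor name -> type")
    values = pd.read_csv(path, sep="\t", index_col=0)
    for name, kind in schema.items():
        if kind == "categorical" and name in values.columns:
            values[name] = values[name].astype("object")
    return FactorTable(values, dict(schema))


def write_factor_table(factors: FactorTable, path: str | Path, schema_path: str | Path) -> Path:
    import yaml

    out = factors.values.copy()
    out.index.name = "sample_id"
    out.to_csv(Path(path), sep="\t", lineterminator="\n")
    with open(schema_path, "w") as fh:
        yaml.safe_dump(factors.schema, fh, sort_keys=True)
    return Path(path)


def read_cell_panel(path: str | Path) -> pd.DataFrame:
    """Read a reference cell panel: CpG rows, one beta-profile column per cell type."""
    panel = pd.read_csv(path, sep="\t", index_col=0)
    arr = panel.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise IntegrityError(f"{path}: panel profiles must lie in [0, 1]")
    return panel


def write_cell_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    out = panel.copy()
    out.index.name = "cpg_id"
    out.to_csv(Path(path), sep="\t", float_format="%.6f", lineterminator="\n")
    return Path(path)


def read_reference_methylome(
    path: str | Path, tissue_name: str | None = None, lineage_label: str = ""
) -> ReferenceMethylome:
    """Read one reference site table (site_id, chrom, pos, meth, coverage)."""
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"site_id", "chrom", "pos", "meth", "coverage"}
    if not required.issubset(t.columns):
        raise FormatError(f"{path}: reference table needs columns {sorted(required)}")
    t = t.set_index("site_id")
    name = tissue_name if tissue_name is not None else Path(path).stem
    return ReferenceMethylome(t, tissue_name=name, lineage_label=lineage_label)


def write_reference_methylome(ref: ReferenceMethylome, path: str | Path) -> Path:
    out = ref.table.copy()
    out.index.name = "site_id"
    out.to_csv(Path(path), sep="\t", float_format="%.6f", lineterminator="\n")
    return Path(path)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a results table as tab-delimited text with stable column order."""
    df.to_csv(Path(path), sep="\t", index=index, lineterminator="\n")
    return Path(path)
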