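"""Genotype QC and the per-CpG cis min-p mQTL scan.

QC follows standard array conventions: SNPs fail on call rate < 95%, minor
allele frequency < 10%, or Hardy-Weinberg disequilibrium (1-df chi-square
goodness of fit, P < 1e-6); samples fail on call rate < 99% (computed on
QC-passed SNPs). "cis" means *same chromosome* — no distance window.

Each variable CpG is regressed on every cis-SNP separately under an
additive genotype model, adjusting for the covariate design; the scan keeps
the most significant association (smallest P) per CpG and calls it at the
genome-wide Bonferroni threshold 5e-8. Single-SNP fits with a shared
complete design are computed by the Frisch-Waugh-Lovell route (residualize
response and predictor on the design, then closed-form slope/SE/t), which
is algebraically identical to the full OLS fit; SNPs with missing calls
fall back to per-SNP complete-case fits.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    BetaMatrix,
    ConfigError,
    DegenerateInputError,
    GenotypeData,
    IntegrityError,
    beta_to_m,
)
from .preprocess import DesignMatrix, truncate_outliers_rows

logger = logging.getLogger("dualtissue")

MQTL_THRESHOLD = 5e-8
P_FLOOR = 1e-300

SNP_CALL_RATE_MIN = 0.95
SAMPLE_CALL_RATE_MIN = 0.99
MAF_MIN = 0.10
HWE_P_MIN = 1e-6


# ---------------------------------------------------------------------------
# Hardy-Weinberg and SNP/sample QC
# ---------------------------------------------------------------------------

def hwe_test(genotype_counts) -> float:
    """1-df chi-square goodness-of-fit P for Hardy-Weinberg equilibrium.

    ``genotype_counts`` are the observed counts of dosages (0, 1, 2).
    Expected counts derive from the estimated allele frequency
    (p^2, 2pq, q^2). Monomorphic input returns P = 1 by convention.
    """
    n0, n1, n2 = (float(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ConfigError("genotype counts must be nonnegative")
    n = n0 + n1 + n2
    if n <= 0:
        raise DegenerateInputError("total genotype count must be positive")
    p = (2 * n2 + n1) / (2 * n)
    if p <= 0 or p >= 1:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    chi2 = float((((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class SnpQcReport:
    """Per-SNP and per-sample QC statistics and pass flags."""

    snp_table: pd.DataFrame      # call_rate, maf, hwe_p, pass
    sample_table: pd.DataFrame   # call_rate, pass
    thresholds: dict

    @property
    def passing_snps(self) -> pd.Index:
        return self.snp_table.index[self.snp_table["pass"]]

    @property
    def passing_samples(self) -> pd.Index:
        return self.sample_table.index[self.sample_table["pass"]]


def snp_qc(
    genotypes: GenotypeData,
    snp_call_rate_min: float = SNP_CALL_RATE_MIN,
    maf_min: float = MAF_MIN,
    hwe_p_min: float = HWE_P_MIN,
    sample_call_rate_min: float = SAMPLE_CALL_RATE_MIN,
) -> SnpQcReport:
    """Compute SNP-level then sample-level QC (one pass of each, in order).

    Sample call rates are evaluated on the SNPs that pass the SNP filters,
    mirroring the usual array-QC sequence.
    """
    dos = genotypes.dosages.to_numpy(dtype=float)
    obs = ~np.isnan(dos)
    n_samples = dos.shape[1]
    call_rate = obs.sum(axis=1) / n_samples
    n_obs = obs.sum(axis=1)
    alt = np.nansum(dos, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_obs > 0, alt / (2 * n_obs), np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)
    hwe_p = np.empty(len(dos))
    for i in range(len(dos)):
        row = dos[i][obs[i]]
        counts = ((row == 0).sum(), (row == 1).sum(), (row == 2).sum())
        hwe_p[i] = hwe_test(counts) if len(row) else 1.0
    snp_pass = (call_rate >= snp_call_rate_min) & (maf >= maf_min) & (hwe_p >= hwe_p_min)
    snp_table = pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p, "pass": snp_pass},
        index=genotypes.snp_ids,
    )
    kept = obs[snp_pass]
    sample_rate = (
        kept.sum(axis=0) / kept.shape[0] if kept.shape[0] else np.ones(n_samples)
    )
    sample_table = pd.DataFrame(
        {"call_rate": sample_rate, "pass": sample_rate >= sample_call_rate_min},
        index=genotypes.sample_ids,
    )
    return SnpQcReport(snp_table, sample_table, {
        "snp_call_rate_min": snp_call_rate_min, "maf_min": maf_min,
        "hwe_p_min": hwe_p_min, "sample_call_rate_min": sample_call_rate_min,
    })


def apply_qc(genotypes: GenotypeData, report: SnpQcReport) -> GenotypeData:
    """Subset genotypes to QC-passing SNPs and samples."""
    return GenotypeData(
        genotypes.dosages.loc[report.passing_snps, report.passing_samples],
        genotypes.snp_map.loc[report.passing_snps],
    )


# ---------------------------------------------------------------------------
# OLS scan machinery
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """Best (min-p) single-predictor association for one response."""

    cpg_id: str
    best_predictor_id: str
    effect_estimate: float
    standard_error: float
    t_statistic: float
    p_value: float
    n_used: int
    is_significant: bool


def _orthonormal_basis(D: np.ndarray) -> np.ndarray:
    U, s, _ = np.linalg.svd(D, full_matrices=False)
    keep = s > s[0] * 1e-12 if len(s) else slice(0)
    return U[:, keep]


def _fwl_stats(RY: np.ndarray, RG: np.ndarray, df: int):
    """Closed-form single-predictor OLS stats from design-residualized data.

    RY is (responses x samples), RG (predictors x samples). Returns slope,
    SE, t, and two-sided P arrays of shape (responses, predictors);
    predictors collinear with the design give NaN columns.
    """
    if df < 2:
        raise DegenerateInputError(f"residual degrees of freedom {df} < 2")
    gg = (RG ** 2).sum(axis=1)
    yy = (RY ** 2).sum(axis=1)
    ok = gg > 1e-12
    N = RY @ RG.T
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ok, N / gg, np.nan)
        sse = np.maximum(yy[:, None] - np.where(ok, N ** 2 / gg, 0.0), 0.0)
        sigma2 = sse / df
        se = np.sqrt(np.where(ok, sigma2 / gg, np.nan))
        t = np.where(se > 0, slope / se, np.where(np.isnan(se), np.nan, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(t), np.nan, np.maximum(p, P_FLOOR))
    return slope, se, t, p


def _pick_best(slope, se, t, p, predictor_ids, response_id, n_used, threshold):
    """Min-p predictor with deterministic tie-breaking (|t| desc, then id)."""
    pv = np.where(np.isnan(p), np.inf, p)
    if np.isinf(pv).all():
        return None
    j = int(np.argmin(pv))
    best_p = pv[j]
    ties = np.flatnonzero(pv == best_p)
    if len(ties) > 1:
        order = sorted(ties, key=lambda k: (-abs(t[k]), str(predictor_ids[k])))
        j = order[0]
    return AssociationRecord(
        cpg_id=response_id,
        best_predictor_id=str(predictor_ids[j]),
        effect_estimate=float(slope[j]),
        standard_error=float(se[j]),
        t_statistic=float(t[j]),
        p_value=float(max(p[j], P_FLOOR)),
        n_used=int(n_used),
        is_significant=bool(p[j] < threshold),
    )


def ols_scan(
    response: pd.Series,
    predictors: pd.DataFrame,
    design: DesignMatrix | pd.DataFrame,
    threshold: float = MQTL_THRESHOLD,
) -> AssociationRecord:
    """Scan one response over many predictors; return the min-p record.

    ``predictors`` holds one row per predictor (columns = samples). Each
    predictor is fitted separately by OLS of response on [design +
    predictor]; missing predictor values are dropped pairwise
    (complete-case per fit). Predictors collinear with the design are
    skipped with a log entry.
    """
    D = design.frame if isinstance(design, DesignMatrix) else design
    samples = response.index
    if response.isna().any():
        raise IntegrityError("response must be complete")
    Dm = D.reindex(samples).to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    G = predictors[samples].to_numpy(dtype=float)
    ids = list(predictors.index)

    complete = ~np.isnan(G).any(axis=1)
    slopes = np.full(len(ids), np.nan)
    ses = np.full(len(ids), np.nan)
    ts = np.full(len(ids), np.nan)
    ps = np.full(len(ids), np.nan)
    ns = np.full(len(ids), len(samples))

    if complete.any():
        Q = _orthonormal_basis(Dm)
        df = len(samples) - Q.shape[1] - 1
        Ry = y - Q @ (Q.T @ y)
        RG = G[complete] - (G[complete] @ Q) @ Q.T
        s, e, t, p = _fwl_stats(Ry[None, :], RG, df)
        slopes[complete], ses[complete] = s[0], e[0]
        ts[complete], ps[complete] = t[0], p[0]
    for j in np.flatnonzero(~complete):
        ok = ~np.isnan(G[j])
        Dj = Dm[ok]
        Qj = _orthonormal_basis(Dj)
        df = ok.sum() - Qj.shape[1] - 1
        if df < 2:
            logger.info("ols_scan: predictor %r skipped (df < 2)", ids[j])
            continue
        ry = y[ok] - Qj @ (Qj.T @ y[ok])
        rg = G[j, ok] - Qj @ (Qj.T @ G[j, ok])
        s, e, t, p = _fwl_stats(ry[None, :], rg[None, :], df)
        slopes[j], ses[j], ts[j], ps[j] = s[0, 0], e[0, 0], t[0, 0], p[0, 0]
        ns[j] = ok.sum()
    if np.isnan(ps).any():
        for j in np.flatnonzero(np.isnan(ps) & complete):
            logger.info("ols_scan: predictor %r collinear with design; skipped", ids[j])
    rec = _pick_best(slopes, ses, ts, ps, ids, str(response.name), len(samples), threshold)
    if rec is None:
        raise DegenerateInputError("no predictor could be fitted")
    j = ids.index(rec.best_predictor_id)
    rec.n_used = int(ns[j])
    return rec


def cis_scan(
    beta: BetaMatrix,
    genotypes: GenotypeData,
    design: DesignMatrix | pd.DataFrame,
    variable_cpgs,
    threshold: float = MQTL_THRESHOLD,
    response_scale: str = "beta",
) -> pd.DataFrame:
    """Per-CpG cis min-p scan over same-chromosome SNPs.

    Methylation outliers are truncated to the in-fence boundary before
    fitting; the response is the adjusted beta value by default
    (``response_scale="m"`` fits M-values instead). Returns one record per
    scanned CpG, ordered by cpg_id, with is_significant = (min-P < threshold).
    CpGs on chromosomes without genotyped SNPs are skipped with a log entry.
    """
    if beta.cpg_map is None:
        raise IntegrityError("cis_scan requires a CpG map (chromosome/position)")
    if response_scale not in ("beta", "m"):
        raise ConfigError(f"unknown response_scale {response_scale!r}")
    variable_cpgs = pd.Index(variable_cpgs)
    if len(variable_cpgs) == 0:
        raise ConfigError("variable_cpgs is empty")
    missing = variable_cpgs.difference(beta.cpg_ids)
    if len(missing):
        raise IntegrityError(f"variable CpGs absent from matrix: {missing[:5].tolist()}")

    D = design.frame if isinstance(design, DesignMatrix) else design
    samples = beta.sample_ids.intersection(genotypes.sample_ids).intersection(D.index)
    if len(samples) < len(beta.sample_ids):
        logger.info("cis_scan: restricting to %d samples shared across inputs", len(samples))
    Dm = D.reindex(samples).to_numpy(dtype=float)
    Q = _orthonormal_basis(Dm)
    df = len(samples) - Q.shape[1] - 1

    records: list[AssociationRecord] = []
    chrom_of = beta.cpg_map["chrom"]
    geno_chroms = set(genotypes.snp_map["chrom"])
    for chrom in sorted(chrom_of.loc[variable_cpgs].unique(), key=str):
        cpgs = variable_cpgs[(chrom_of.loc[variable_cpgs] == chrom).to_numpy()]
        if chrom not in geno_chroms:
            logger.info("cis_scan: no SNPs on chromosome %s; skipped %d CpGs",
                        chrom, len(cpgs))
            continue
        snp_ids = genotypes.snp_map.index[genotypes.snp_map["chrom"] == chrom]
        G = genotypes.dosages.loc[snp_ids, samples].to_numpy(dtype=float)
        Y = beta.values.loc[cpgs, samples].to_numpy(dtype=float)
        Y = truncate_outliers_rows(Y)
        if response_scale == "m":
            Y = beta_to_m(Y)
        RY = Y - (Y @ Q) @ Q.T
        complete = ~np.isnan(G).any(axis=1)
        slope = np.full((len(cpgs), len(snp_ids)), np.nan)
        se = np.full_like(slope, np.nan)
        tstat = np.full_like(slope, np.nan)
        pval = np.full_like(slope, np.nan)
        if complete.any():
            RG = G[complete] - (G[complete] @ Q) @ Q.T
            s, e, t, p = _fwl_stats(RY, RG, df)
            slope[:, complete], se[:, complete] = s, e
            tstat[:, complete], pval[:, complete] = t, p
        for jj in np.flatnonzero(~complete):
            ok = ~np.isnan(G[jj])
            Qj = _orthonormal_basis(Dm[ok])
            dfj = ok.sum() - Qj.shape[1] - 1
            if dfj < 2:
                continue
            Yj = Y[:, ok]
            RYj = Yj - (Yj @ Qj) @ Qj.T
            rg = G[jj, ok] - Qj @ (Qj.T @ G[jj, ok])
            s, e, t, p = _fwl_stats(RYj, rg[None, :], dfj)
            slope[:, jj], se[:, jj] = s[:, 0], e[:, 0]
            tstat[:, jj], pval[:, jj] = t[:, 0], p[:, 0]
        for i, cpg in enumerate(cpgs):
            rec = _pick_best(slope[i], se[i], tstat[i], pval[i], list(snp_ids),
                             str(cpg), len(samples), threshold)
            if rec is not None:
                records.append(rec)
    columns = ["cpg_id", "best_predictor_id", "effect_estimate", "standard_error",
               "t_statistic", "p_value", "n_used", "is_significant"]
    table = pd.DataFrame([vars(r) for r in records], columns=columns).set_index("cpg_id")
    return table.sort_index()


# ---------------------------------------------------------------------------
# Eight-category cross-tissue overlap
# ---------------------------------------------------------------------------

STATUS_LABELS = ("associated", "variable_not_associated", "not_variable")


@dataclass
class OverlapSummary:
    """Cross-tissue tri-state accounting over CpGs variable in >= 1 tissue."""

    status: pd.DataFrame          # per CpG: status_a, status_b
    counts: pd.Series             # 8 joint categories (not_variable/not_variable excluded)
    marginals: pd.DataFrame       # per tissue, per status
    overlap_pct_by_a: float       # both-associated / associated-in-A
    overlap_pct_by_b: float       # both-associated / associated-in-B
    label_a: str = "a"
    label_b: str = "b"

    @property
    def universe_size(self) -> int:
        return len(self.status)


def overlap_eight(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
) -> OverlapSummary:
    """Joint accounting of association and variability status in two tissues.

    The universe is the set of CpGs variable in at least one tissue. Per
    tissue each CpG is associated, variable-but-not-associated, or not
    variable; the 3 x 3 joint states minus the impossible
    (not_variable, not_variable) cell give eight categories. Also reports
    the both-associated overlap as a percentage of each tissue's associated
    count (both denominators).
    """
    if set(calls_a.index) != set(calls_b.index):
        diff = calls_a.index.symmetric_difference(calls_b.index)
        raise IntegrityError(f"CpG universes differ, e.g. {diff[:5].tolist()}")

    def status_for(records: pd.DataFrame, calls: pd.DataFrame, label: str) -> pd.Series:
        var = calls["is_variable"].astype(bool)
        sig = records["is_significant"].reindex(calls.index, fill_value=False).astype(bool)
        bad = sig & ~var
        if bad.any():
            raise IntegrityError(
                f"{label}: CpGs associated but not variable (impossible state): "
                f"{calls.index[bad][:5].tolist()}"
            )
        return pd.Series(
            np.where(sig, "associated",
                     np.where(var, "variable_not_associated", "not_variable")),
            index=calls.index,
        )

    sa = status_for(records_a, calls_a, label_a)
    sb = status_for(records_b, calls_b.reindex(calls_a.index), label_b)
    universe = calls_a.index[(sa != "not_variable") | (sb != "not_variable")]
    status = pd.DataFrame({f"status_{label_a}": sa[universe],
                           f"status_{label_b}": sb[universe]})
    cat_index = pd.MultiIndex.from_tuples(
        [(x, y) for x in STATUS_LABELS for y in STATUS_LABELS
         if not (x == "not_variable" and y == "not_variable")],
        names=[label_a, label_b],
    )
    counts = (
        status.value_counts().reindex(cat_index, fill_value=0).astype(int)
    )
    marginals = pd.DataFrame({
        label_a: sa[universe].value_counts().reindex(STATUS_LABELS, fill_value=0),
        label_b: sb[universe].value_counts().reindex(STATUS_LABELS, fill_value=0),
    })
    n_both = int(counts.loc[("associated", "associated")])
    na = int(marginals.loc["associated", label_a])
    nb = int(marginals.loc["associated", label_b])
    return OverlapSummary(
        status=status,
        counts=counts,
        marginals=marginals,
        overlap_pct_by_a=100.0 * n_both / na if na else float("nan"),
        overlap_pct_by_b=100.0 * n_both / nb if nb else float("nan"),
        label_a=label_a,
        label_b=label_b,
    )
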