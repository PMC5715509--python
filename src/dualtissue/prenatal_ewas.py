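"""Multi-factor prenatal EWAS with min-p aggregation per CpG.

Each variable CpG is regressed on each of the prenatal factors separately
(adjusting for the covariate design). Continuous factors are
outlier-truncated first and tested with the usual t-test on their
coefficient; categorical factors are dummy-coded and tested with the
overall F-test for the dummy block (the recorded "effect" is the
largest-magnitude level coefficient). A CpG is called prenatal-factor
associated when its smallest P over factors is below the Bonferroni-style
threshold 1e-3 (0.05 / ~45 factors, with no CpG-dimension correction).

Missing factor values are handled by complete-case fits per factor; a
factor missing for more than half the samples is skipped (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    BetaMatrix,
    ConfigError,
    FactorTable,
    IntegrityError,
    beta_to_m,
)
from .genotype_mqtl import P_FLOOR, OverlapSummary, _fwl_stats, _orthonormal_basis, overlap_eight
from .preprocess import DesignMatrix, truncate_outliers, truncate_outliers_rows

logger = logging.getLogger("dualtissue")

EWAS_THRESHOLD = 1e-3


# ---------------------------------------------------------------------------
# Factor-factor correlations
# ---------------------------------------------------------------------------

def factor_correlations(factors: FactorTable, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete absolute Spearman correlation between factors.

    Categorical factors are rank-coded by sorted level index. Constant
    factors (or pairs with fewer than ``min_pairs`` complete observations)
    yield missing entries; the diagonal is 1.
    """
    coded = {}
    for name in factors.factor_names:
        col = factors.values[name]
        if factors.schema[name] == "categorical":
            levels = sorted(col.dropna().astype(str).unique())
            coded[name] = col.astype(str).map({lev: i for i, lev in enumerate(levels)})
            coded[name][col.isna()] = np.nan
        else:
            coded[name] = pd.to_numeric(col)
    X = pd.DataFrame(coded, index=factors.values.index)
    names = list(X.columns)
    k = len(names)
    out = np.full((k, k), np.nan)
    for i in range(k):
        xi = X.iloc[:, i].to_numpy(dtype=float)
        for j in range(i, k):
            xj = X.iloc[:, j].to_numpy(dtype=float)
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            if i == j:
                out[i, i] = 1.0
                continue
            if ok.sum() < min_pairs:
                continue
            if np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue  # correlation undefined for a constant factor
            rho = stats.spearmanr(xi[ok], xj[ok]).statistic
            out[i, j] = out[j, i] = abs(float(rho))
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# EWAS scan
# ---------------------------------------------------------------------------

@dataclass
class FactorScanResult:
    """Per-CpG x factor effects/SEs/Ps plus the min-p call summary."""

    effects: pd.DataFrame      # CpG x factor
    ses: pd.DataFrame
    pvalues: pd.DataFrame
    summary: pd.DataFrame      # min_p, winning_factor, is_pf_associated per CpG
    skipped_factors: list[str] = field(default_factory=list)
    threshold: float = EWAS_THRESHOLD


def _categorical_block(values: pd.Series) -> tuple[np.ndarray, list[str]] | None:
    levels = sorted(values.astype(str).unique())
    if len(levels) < 2:
        return None
    cols = [(values.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
    return np.column_stack(cols), levels[1:]


def ewas_scan(
    beta: BetaMatrix,
    factors: FactorTable,
    design: DesignMatrix | pd.DataFrame,
    variable_cpgs,
    threshold: float = EWAS_THRESHOLD,
    max_missing_fraction: float = 0.5,
    response_scale: str = "beta",
) -> FactorScanResult:
    """Scan every variable CpG against every prenatal factor.

    Methylation is outlier-truncated once per CpG; continuous factors are
    outlier-truncated per factor (categoricals are not). Each factor is fit
    on its complete cases. Returns per-(CpG, factor) effect, SE and P plus
    the per-CpG min-p aggregation and call.
    """
    if response_scale not in ("beta", "m"):
        raise ConfigError(f"unknown response_scale {response_scale!r}")
    variable_cpgs = pd.Index(variable_cpgs)
    missing = variable_cpgs.difference(beta.cpg_ids)
    if len(missing):
        raise IntegrityError(f"variable CpGs absent from matrix: {missing[:5].tolist()}")

    D = design.frame if isinstance(design, DesignMatrix) else design
    samples = beta.sample_ids.intersection(D.index)
    Dm = D.reindex(samples).to_numpy(dtype=float)
    Y = beta.values.loc[variable_cpgs, samples].to_numpy(dtype=float)
    Y = truncate_outliers_rows(Y)
    if response_scale == "m":
        Y = beta_to_m(Y)
    n = len(samples)

    names = factors.factor_names
    eff = pd.DataFrame(np.nan, index=variable_cpgs, columns=names)
    ses = pd.DataFrame(np.nan, index=variable_cpgs, columns=names)
    pvs = pd.DataFrame(np.nan, index=variable_cpgs, columns=names)
    skipped: list[str] = []

    for name in names:
        col = factors.values[name].reindex(samples)
        ok = col.notna().to_numpy()
        if ok.mean() < 1.0 - max_missing_fraction:
            logger.info("ewas_scan: factor %r missing for >%.0f%% of samples; skipped",
                        name, 100 * max_missing_fraction)
            skipped.append(name)
            continue
        Ds = Dm[ok]
        Q = _orthonormal_basis(Ds)
        Ys = Y[:, ok]
        RY = Ys - (Ys @ Q) @ Q.T
        if factors.schema[name] == "continuous":
            x = truncate_outliers(col[ok].to_numpy(dtype=float))
            df = ok.sum() - Q.shape[1] - 1
            rg = x - Q @ (Q.T @ x)
            s, e, t, p = _fwl_stats(RY, rg[None, :], df)
            eff[name], ses[name], pvs[name] = s[:, 0], e[:, 0], p[:, 0]
        else:
            block = _categorical_block(col[ok])
            if block is None:
                logger.info("ewas_scan: categorical factor %r has one level; skipped", name)
                skipped.append(name)
                continue
            Xb, level_names = block
            RX = Xb - Q @ (Q.T @ Xb)
            Qx, sx, _ = np.linalg.svd(RX, full_matrices=False)
            keep = sx > (sx[0] * 1e-10 if sx[0] > 0 else np.inf)
            Qx = Qx[:, keep]
            k_eff = Qx.shape[1]
            if k_eff == 0:
                skipped.append(name)
                continue
            df = ok.sum() - Q.shape[1] - k_eff
            if df < 2:
                skipped.append(name)
                continue
            yy = (RY ** 2).sum(axis=1)
            proj = RY @ Qx
            explained = (proj ** 2).sum(axis=1)
            rss = np.maximum(yy - explained, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = (explained / k_eff) / (rss / df)
            p = np.maximum(stats.f.sf(F, k_eff, df), P_FLOOR)
            # level coefficients for the "effect": largest-magnitude level
            coef, *_ = np.linalg.lstsq(RX, RY.T, rcond=None)   # levels x CpGs
            sigma2 = rss / df
            XtX_inv = np.linalg.pinv(RX.T @ RX)
            se_lvl = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # levels x CpGs
            jmax = np.abs(coef).argmax(axis=0)
            rows = np.arange(coef.shape[1])
            eff[name] = coef[jmax, rows]
            ses[name] = se_lvl[jmax, rows]
            pvs[name] = p

    scanned = [c for c in names if c not in skipped]
    if not scanned:
        raise ConfigError("no factor could be scanned")
    pmat = pvs[scanned].to_numpy(dtype=float)
    pmat = np.where(np.isnan(pmat), np.inf, pmat)
    jmin = pmat.argmin(axis=1)
    min_p = pmat[np.arange(len(pmat)), jmin]
    summary = pd.DataFrame({
        "min_p": min_p,
        "winning_factor": np.array(scanned, dtype=object)[jmin],
        "is_pf_associated": min_p < threshold,
    }, index=variable_cpgs)
    return FactorScanResult(eff, ses, pvs, summary, skipped, threshold)


def pf_records(result: FactorScanResult) -> pd.DataFrame:
    """Adapt a scan result to the association-record layout used by overlaps."""
    rec = result.summary.rename(columns={"min_p": "p_value",
                                         "winning_factor": "best_predictor_id"})
    rec["is_significant"] = result.summary["is_pf_associated"]
    return rec


def pf_overlap(
    results_a: FactorScanResult,
    results_b: FactorScanResult,
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
) -> OverlapSummary:
    """Eight-category cross-tissue overlap of prenatal-factor calls."""
    return overlap_eight(pf_records(results_a), pf_records(results_b),
                         calls_a, calls_b, label_a=label_a, label_b=label_b)


# ---------------------------------------------------------------------------
# Cross-tissue effect concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Paired same-factor effects in two tissues for selected CpGs."""

    pairs: pd.DataFrame          # cpg_id, factor, effect_a, effect_b
    sign_agreement: float
    median_effect_ratio: float   # median |effect_b / effect_a|


def effect_concordance(
    results_a: FactorScanResult,
    results_b: FactorScanResult,
    select,
) -> ConcordanceResult:
    """For each selected CpG, pair tissue A's winning-factor effect with the
    effect of the *same* factor in tissue B; summarize sign agreement and
    the effect-size ratio. CpGs whose winning factor was not scanned in B
    are skipped with a log entry.
    """
    select = pd.Index(select)
    missing = select.difference(results_a.summary.index)
    if len(missing):
        raise IntegrityError(f"selected CpGs absent from results A: {missing[:5].tolist()}")
    rows = []
    for cpg in select:
        factor = results_a.summary.loc[cpg, "winning_factor"]
        if cpg not in results_b.effects.index or pd.isna(
            results_b.effects.at[cpg, factor] if factor in results_b.effects.columns else np.nan
        ):
            logger.info("effect_concordance: %s / factor %r unavailable in B; skipped",
                        cpg, factor)
            continue
        ea = float(results_a.effects.at[cpg, factor])
        eb = float(results_b.effects.at[cpg, factor])
        rows.append({"cpg_id": cpg, "factor": factor, "effect_a": ea, "effect_b": eb})
    pairs = pd.DataFrame(rows, columns=["cpg_id", "factor", "effect_a", "effect_b"])
    if len(pairs):
        sign = float((np.sign(pairs["effect_a"]) == np.sign(pairs["effect_b"])).mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = float(np.nanmedian(np.abs(pairs["effect_b"] / pairs["effect_a"])))
    else:
        sign, ratio = float("nan"), float("nan")
    return ConcordanceResult(pairs, sign_agreement=sign, median_effect_ratio=ratio)
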