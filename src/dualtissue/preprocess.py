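"""Preprocessing: outlier truncation, PCA diagnostics, empirical-Bayes batch
adjustment, reference-based cell deconvolution, surrogate variables, and
design-matrix construction.

The batch adjustment is the standard parametric empirical-Bayes
location/scale model (ComBat): per-CpG per-batch effects are standardized,
shrunk toward their across-CpG batch means, and removed, after fitting and
setting aside any supplied covariate signal. It operates on M-values.

Surrogate variables are estimated in simplified residual-PCA form: the top
principal components of the methylation matrix after projecting out the
known design. This preserves the testable contract (recovery of hidden
structure orthogonal to the design) without the iteratively re-weighted
published algorithm.
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
    DegenerateInputError,
    IntegrityError,
    MValueMatrix,
)

logger = logging.getLogger("dualtissue")


# ---------------------------------------------------------------------------
# Outlier truncation (Tukey fences)
# ---------------------------------------------------------------------------

def tukey_fences(values: np.ndarray) -> tuple[float, float]:
    """Tukey's boxplot fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR), NaN-aware."""
    q1, q3 = np.nanpercentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def truncate_outliers(values) -> np.ndarray:
    """Truncate values outside the Tukey fences to the boundary value.

    The boundary is the most extreme *observed* value inside the fences
    (low outliers take the in-fence minimum, high outliers the in-fence
    maximum), so truncation never produces values outside the observed data
    range and is idempotent. Order and missingness are preserved.
    """
    arr = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(arr)
    if obs.sum() < 4:
        raise DegenerateInputError("truncate_outliers needs >= 4 non-missing values")
    lo, hi = tukey_fences(arr)
    inside = obs & (arr >= lo) & (arr <= hi)
    bound_lo = arr[inside].min()
    bound_hi = arr[inside].max()
    arr[obs & (arr < lo)] = bound_lo
    arr[obs & (arr > hi)] = bound_hi
    return arr


def truncate_outliers_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`truncate_outliers` for complete 2-D arrays, vectorized."""
    m = np.asarray(matrix, dtype=float)
    if m.shape[1] < 4:
        raise DegenerateInputError("need >= 4 samples per row")
    q1 = np.percentile(m, 25, axis=1)
    q3 = np.percentile(m, 75, axis=1)
    iqr = q3 - q1
    lo = (q1 - 1.5 * iqr)[:, None]
    hi = (q3 + 1.5 * iqr)[:, None]
    inside = (m >= lo) & (m <= hi)
    masked = np.where(inside, m, np.nan)
    bound_lo = np.nanmin(masked, axis=1)[:, None]
    bound_hi = np.nanmax(masked, axis=1)[:, None]
    out = m.copy()
    np.copyto(out, np.broadcast_to(bound_lo, m.shape), where=m < lo)
    np.copyto(out, np.broadcast_to(bound_hi, m.shape), where=m > hi)
    return out


# ---------------------------------------------------------------------------
# PCA and diagnostics against technical variables
# ---------------------------------------------------------------------------

def run_pca(matrix: MValueMatrix | pd.DataFrame, n_components: int | None = None
            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Exact-SVD PCA of a CpG x sample matrix with samples as observations.

    The matrix is CpG-wise centered. Returns per-sample scores (columns
    PC1..PCk, mutually orthogonal) and the fraction of variance explained
    per component (non-increasing).
    """
    values = matrix.values if isinstance(matrix, MValueMatrix) else matrix
    X = values.to_numpy(dtype=float).T  # samples x CpGs
    n, p = X.shape
    k = min(n, p) if n_components is None else int(n_components)
    if k > min(n, p):
        raise ConfigError(f"n_components={k} exceeds min(n_samples, n_cpgs)={min(n, p)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc ** 2).sum())
    if total_var <= 0:
        raise DegenerateInputError("constant matrix: PCA undefined")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    var_explained = (s[:k] ** 2) / total_var
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=values.columns, columns=cols), var_explained


def associate_pcs(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    variables: list[str] | None = None,
    var_explained: np.ndarray | None = None,
) -> pd.DataFrame:
    """Regress each PC against each technical variable.

    Categorical variables get a one-way linear-model F-test P, continuous
    variables a simple-regression P. Constant PCs return P = 1 by
    convention; single-level variables are skipped (logged). Returns a long
    table (pc, variable, p_value, pc_variance_explained).
    """
    if not scores.index.equals(metadata.index):
        if set(scores.index) != set(metadata.index):
            raise IntegrityError("PC scores and metadata sample sets differ")
        metadata = metadata.loc[scores.index]
    variables = variables if variables is not None else list(metadata.columns)
    rows = []
    for pi, pc in enumerate(scores.columns):
        y = scores[pc].to_numpy(dtype=float)
        const_pc = np.allclose(y, y[0])
        for var in variables:
            x = metadata[var]
            ok = x.notna().to_numpy()
            if pd.api.types.is_numeric_dtype(x):
                if const_pc or np.nanstd(x.to_numpy(dtype=float)) == 0:
                    p = 1.0
                else:
                    res = stats.linregress(x.to_numpy(dtype=float)[ok], y[ok])
                    p = float(res.pvalue)
            else:
                groups = [y[ok][x[ok].to_numpy() == lev] for lev in pd.unique(x[ok])]
                groups = [g for g in groups if len(g)]
                if len(groups) < 2:
                    logger.info("associate_pcs: variable %r has one level; skipped", var)
                    continue
                if const_pc:
                    p = 1.0
                else:
                    p = float(stats.f_oneway(*groups).pvalue)
            rows.append({
                "pc": pc,
                "variable": var,
                "p_value": p,
                "pc_variance_explained": (
                    float(var_explained[pi]) if var_explained is not None else np.nan
                ),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment (parametric ComBat)
# ---------------------------------------------------------------------------

def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ss, n, a, b):
    return (0.5 * ss + b) / (n / 2.0 + a - 1.0)


def _aprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(Z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-10, max_iter=5000):
    """Standard fixed-point solver for the EB batch parameters."""
    n = Z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ss = ((Z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(ss, n, a, b)
        change = max(
            (np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-300)).max(),
            (np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-300)).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    matrix: MValueMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    shrink: bool = True,
    df_corrected_variance: bool = True,
) -> MValueMatrix:
    """Parametric empirical-Bayes location/scale batch harmonization.

    Per-CpG batch effects are standardized, shrunk toward their across-CpG
    batch means (normal prior on locations, inverse-gamma on scales) and
    removed; covariate signal is fitted first and restored afterwards, so
    biological effects orthogonal to batch are preserved. Each batch needs
    at least 2 samples. With a single batch the matrix is returned
    unchanged (up to floating point).

    ``df_corrected_variance`` divides the pooled residual variance by the
    residual degrees of freedom rather than the sample count; with a rich
    covariate design the uncorrected estimator understates sigma and the
    rescale step then shrinks all signal by ~sqrt(n / (n - p)). Set False
    to reproduce the classical convention exactly.
    """
    X = matrix.values.to_numpy(dtype=float)
    samples = matrix.values.columns
    batch = batch.reindex(samples)
    if batch.isna().any():
        raise IntegrityError("batch labels missing for some samples")
    levels = sorted(pd.unique(batch))
    counts = batch.value_counts()
    singles = [b for b in levels if counts[b] < 2]
    if singles:
        raise IntegrityError(f"singleton batch(es): {singles}")
    if len(levels) == 1:
        return MValueMatrix(matrix.values.copy(), cpg_map=matrix.cpg_map,
                            tissue_label=matrix.tissue_label)  # nothing to harmonize

    n = len(samples)
    B = np.column_stack([(batch == b).to_numpy(dtype=float) for b in levels])
    if covariates is not None:
        C = covariates.reindex(samples).to_numpy(dtype=float)
        keep = [j for j in range(C.shape[1])
                if not np.allclose(C[:, j], C[:, j].mean())]  # drop intercept-like cols
        C = C[:, keep]
        design = np.column_stack([B, C]) if C.shape[1] else B
    else:
        C = np.empty((n, 0))
        design = B

    # covariate columns nested in batch (e.g. chip-set dummies when batch is
    # chip) carry no information once batch is modelled: drop them, keep rank
    if C.shape[1]:
        base_rank = np.linalg.matrix_rank(B)
        kept_cols = []
        rank = base_rank
        for j in range(C.shape[1]):
            cand = np.column_stack([B] + [C[:, kk] for kk in kept_cols + [j]])
            r = np.linalg.matrix_rank(cand)
            if r > rank:
                kept_cols.append(j)
                rank = r
            else:
                logger.info("combat_adjust: covariate column %d confounded with batch; dropped", j)
        C = C[:, kept_cols]
        design = np.column_stack([B, C]) if C.shape[1] else B
    rank = np.linalg.matrix_rank(design)
    theta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (nbatch+ncov) x G
    gamma_hat_fit = theta[:len(levels)]                   # batch locations per CpG
    beta_cov = theta[len(levels):]
    prop = counts.loc[levels].to_numpy() / n
    alpha = prop @ gamma_hat_fit                          # grand mean per CpG
    cov_signal = (C @ beta_cov).T if C.shape[1] else 0.0
    stand_mean = alpha[:, None] + cov_signal
    resid = X - (design @ theta).T
    denom = max(n - rank, 1) if df_corrected_variance else n
    var_pooled = (resid ** 2).sum(axis=1) / denom
    sigma = np.sqrt(var_pooled)
    sigma_safe = np.where(sigma > 1e-12, sigma, 1.0)
    Z = (X - stand_mean) / sigma_safe[:, None]

    Xadj = np.empty_like(Z)
    for bi, lev in enumerate(levels):
        idx = (batch == lev).to_numpy()
        Zb = Z[:, idx]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)  # sample variance, the standard EB convention
        if shrink and len(g_hat) > 1 and g_hat.var(ddof=1) > 1e-12 and d_hat.var(ddof=1) > 1e-12:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_sol(Zb, g_hat, d_hat, g_bar, t2, a, b)
        else:
            # degenerate prior (zero across-CpG spread): no shrinkage
            g_star, d_star = g_hat, np.maximum(d_hat, 1e-12)
        Xadj[:, idx] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = Xadj * sigma_safe[:, None] + stand_mean
    return MValueMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=samples),
        cpg_map=matrix.cpg_map,
        tissue_label=matrix.tissue_label,
    )


# ---------------------------------------------------------------------------
# Reference-based cell deconvolution
# ---------------------------------------------------------------------------

@dataclass
class CellProportions:
    """Estimated per-sample cell-type proportions (rows on the simplex)."""

    proportions: pd.DataFrame      # sample x cell type
    residual_norm: pd.Series       # per-sample fit residual (L2)

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy()
        if (arr < -1e-8).any():
            raise IntegrityError("cell proportions must be nonnegative")
        if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
            raise IntegrityError("cell proportions must sum to 1 per sample")


def _simplex_lsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A w - b||^2 subject to w >= 0, sum w = 1 (small dense problem)."""
    from scipy.optimize import minimize

    k = A.shape[1]
    AtA, Atb = A.T @ A, A.T @ b

    def fun(w):
        return 0.5 * w @ AtA @ w - Atb @ w

    def jac(w):
        return AtA @ w - Atb

    w0 = np.full(k, 1.0 / k)
    res = minimize(
        fun, w0, jac=jac, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"maxiter": 300, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def estimate_cell_proportions(matrix: BetaMatrix, panel: pd.DataFrame) -> CellProportions:
    """Constrained projection of each sample's signature-CpG betas onto the panel.

    Solves, per sample, the nonnegative sum-to-one least-squares problem
    against the reference profiles (constrained quadratic minimization) and
    reports the residual norm of the fit.
    """
    shared = panel.index.intersection(matrix.cpg_ids)
    missing = panel.index.difference(matrix.cpg_ids)
    if len(shared) < panel.shape[1]:
        raise IntegrityError(
            f"only {len(shared)} panel CpGs present in matrix "
            f"(need >= {panel.shape[1]}); missing e.g. {missing[:5].tolist()}"
        )
    A = panel.loc[shared].to_numpy(dtype=float)
    Y = matrix.values.loc[shared].to_numpy(dtype=float)
    props = np.empty((Y.shape[1], A.shape[1]))
    resid = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        w = _simplex_lsq(A, Y[:, j])
        props[j] = w
        resid[j] = float(np.linalg.norm(A @ w - Y[:, j]))
    return CellProportions(
        pd.DataFrame(props, index=matrix.sample_ids, columns=panel.columns),
        pd.Series(resid, index=matrix.sample_ids, name="residual_norm"),
    )


# ---------------------------------------------------------------------------
# Surrogate variables (residual PCA)
# ---------------------------------------------------------------------------

def estimate_surrogate_variables(
    matrix: MValueMatrix, design: "DesignMatrix | pd.DataFrame", n_sv: int
) -> pd.DataFrame:
    """Top ``n_sv`` principal components of the design-residual matrix.

    Captures unmodeled per-sample structure (hidden batches, composition).
    Columns are mutually orthogonal; a zero-residual matrix yields all-zero
    scores.
    """
    D = design.frame if isinstance(design, DesignMatrix) else design
    X = matrix.values.to_numpy(dtype=float).T       # samples x CpGs
    Dm = D.reindex(matrix.values.columns).to_numpy(dtype=float)
    r = np.linalg.matrix_rank(Dm)
    if n_sv >= X.shape[0] - r:
        raise ConfigError(f"n_sv={n_sv} must be < n_samples - rank(design) = {X.shape[0] - r}")
    if n_sv == 0:
        return pd.DataFrame(index=matrix.values.columns)
    beta, *_ = np.linalg.lstsq(Dm, X, rcond=None)
    R = X - Dm @ beta
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    scale = np.sqrt((R ** 2).sum())
    sv = U[:, :n_sv] * s[:n_sv]
    sv[:, s[:n_sv] <= 1e-10 * max(scale, 1.0)] = 0.0
    return pd.DataFrame(sv, index=matrix.values.columns,
                        columns=[f"SV{i + 1}" for i in range(n_sv)])


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Full-column-rank covariate design aligned to the sample order.

    Contains an intercept, encoded covariates, cell-proportion principal
    components, and cellPC x ethnicity-dummy interactions. Columns that were
    dropped to restore full rank are recorded in ``dropped``.
    """

    frame: pd.DataFrame
    dropped: list[str] = field(default_factory=list)
    cell_pc_variance: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.frame.to_numpy(dtype=float)))

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Reference-level dummy coding; the most frequent level is the reference."""
    counts = series.value_counts()
    ref = counts.index[0]
    levels = [lev for lev in sorted(counts.index.astype(str)) if lev != str(ref)]
    cols = {}
    for lev in levels:
        cols[f"{prefix}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _cell_pcs(proportions: pd.DataFrame, min_variance: float = 0.90) -> tuple[pd.DataFrame, np.ndarray]:
    """PCs of cell proportions: smallest k with >= 90% variance, capped at k_types - 1."""
    W = proportions.to_numpy(dtype=float)
    Wc = W - W.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Wc, full_matrices=False)
    var = s ** 2
    cap = max(proportions.shape[1] - 1, 1)
    frac = var / var.sum() if var.sum() > 0 else var
    k = 1
    while k < cap and frac[:k].sum() < min_variance:
        k += 1
    scores = U[:, :k] * s[:k]
    return (
        pd.DataFrame(scores, index=proportions.index,
                     columns=[f"cellPC{i + 1}" for i in range(k)]),
        frac[:k],
    )


def build_design(
    metadata: pd.DataFrame,
    proportions: CellProportions | pd.DataFrame | None,
    tissue: str,
    covariates: tuple[str, ...] = (
        "sex", "gestational_age", "ethnicity", "hospital", "bisulfite_batch",
        "chip_position",
    ),
    extra: pd.DataFrame | None = None,
    interactions: bool = True,
) -> DesignMatrix:
    """Assemble the regression design for one tissue.

    The covariate set follows the tissue-specific convention: the DNA
    extraction batch enters for cord tissue, the chip-set for cord blood.
    Cell proportions are summarized by their leading principal components
    and cellPC x ethnicity interaction columns are appended (in addition to
    the main effects). Rank-deficient columns are dropped and logged.
    """
    idx = metadata.index
    parts: list[pd.DataFrame] = [pd.DataFrame({"intercept": np.ones(len(idx))}, index=idx)]
    tissue_cov = "dna_extraction_batch" if tissue == "cord_tissue" else "chip_set"
    cov_list = list(covariates) + ([tissue_cov] if tissue_cov in metadata.columns else [])
    eth_dummies = None
    for cov in cov_list:
        if cov not in metadata.columns:
            logger.info("build_design: covariate %r absent from metadata; skipped", cov)
            continue
        col = metadata[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).to_frame(cov))
        else:
            d = _dummies(col, cov)
            if d.shape[1] == 0:
                logger.info("build_design: covariate %r has a single level; no columns", cov)
            parts.append(d)
            if cov == "ethnicity":
                eth_dummies = d

    cell_pc_var = None
    if proportions is not None:
        props = proportions.proportions if isinstance(proportions, CellProportions) else proportions
        if not props.index.equals(idx):
            if set(props.index) != set(idx):
                raise IntegrityError("cell proportions and metadata sample sets differ")
            props = props.loc[idx]
        pcs, cell_pc_var = _cell_pcs(props)
        parts.append(pcs)
        if interactions and eth_dummies is not None and eth_dummies.shape[1]:
            inter = {}
            for pc in pcs.columns:
                for ed in eth_dummies.columns:
                    inter[f"{pc}:{ed}"] = pcs[pc] * eth_dummies[ed]
            parts.append(pd.DataFrame(inter, index=idx))
    if extra is not None:
        parts.append(extra.reindex(idx))

    frame = pd.concat(parts, axis=1)
    frame, dropped = _drop_rank_deficient(frame)
    for name in dropped:
        logger.info("build_design: dropped rank-deficient column %r", name)
    return DesignMatrix(frame, dropped=dropped, cell_pc_variance=cell_pc_var)


def _drop_rank_deficient(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right sweep keeping a maximal independent column set."""
    X = frame.to_numpy(dtype=float)
    kept: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(j)
            rank = r
        else:
            dropped.append(frame.columns[j])
    return frame.iloc[:, kept], dropped
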