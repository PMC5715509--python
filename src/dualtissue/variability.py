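"""Inter-individual variability calls and cross-tissue category accounting.

A CpG shows inter-individual variation when its methylation range
(maximum - minimum, computed after excluding Tukey-fence outliers) exceeds
10% and its 99th - 1st percentile spread exceeds 5% (both strict
inequalities). The percentile clause is computed on all values — outliers
are excluded only for the range clause — with linear-interpolation
percentiles; both choices are switchable.

Two tissues' calls partition the shared CpG set into four categories
(variable in both, in one tissue only, or in neither), and the per-CpG IQR
distribution is summarized as an exceedance curve: the proportion of CpGs
whose IQR is at least each grid threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import BetaMatrix, ConfigError, DegenerateInputError, IntegrityError

RANGE_THRESHOLD = 0.10
TAIL_THRESHOLD = 0.05

CATEGORY_LABELS = ("both_variable", "a_only", "b_only", "neither")


def variability_stats(betas) -> pd.Series:
    """Variability statistics for one CpG's per-sample beta vector.

    Returns range_excl_outliers (max - min over in-fence values),
    p99_minus_p1 and iqr (both over all values, linear-interpolation
    percentiles). Needs at least 4 samples.
    """
    arr = np.asarray(betas, dtype=float)
    if arr.ndim != 1:
        raise ConfigError("variability_stats expects a 1-D vector")
    if len(arr) < 4 or np.isnan(arr).any():
        raise DegenerateInputError("need >= 4 non-missing samples")
    t = variability_table(pd.DataFrame(arr[None, :], index=["_cpg"]))
    return t.iloc[0].drop("is_variable")


def variability_table(
    matrix: BetaMatrix | pd.DataFrame,
    range_threshold: float = RANGE_THRESHOLD,
    tail_threshold: float = TAIL_THRESHOLD,
    percentiles_exclude_outliers: bool = False,
) -> pd.DataFrame:
    """Per-CpG variability statistics and boolean calls for a whole matrix.

    Vectorized over CpGs. Set ``percentiles_exclude_outliers`` to compute
    the 99th - 1st percentile clause on the outlier-excluded values instead
    of all values (the alternative dialect).
    """
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    m = values.to_numpy(dtype=float)
    if m.shape[1] < 4:
        raise DegenerateInputError("need >= 4 samples")
    q1, q3 = np.percentile(m, [25, 75], axis=1)
    iqr = q3 - q1
    lo = (q1 - 1.5 * iqr)[:, None]
    hi = (q3 + 1.5 * iqr)[:, None]
    masked = np.where((m >= lo) & (m <= hi), m, np.nan)
    rng = np.nanmax(masked, axis=1) - np.nanmin(masked, axis=1)
    if percentiles_exclude_outliers:
        p1 = np.nanpercentile(masked, 1, axis=1)
        p99 = np.nanpercentile(masked, 99, axis=1)
    else:
        p1, p99 = np.percentile(m, [1, 99], axis=1)
    tail = p99 - p1
    calls = call_variable(rng, tail, range_threshold, tail_threshold)
    return pd.DataFrame(
        {
            "range_excl_outliers": rng,
            "p99_minus_p1": tail,
            "iqr": iqr,
            "is_variable": calls,
        },
        index=values.index,
    )


def call_variable(
    range_excl_outliers,
    p99_minus_p1,
    range_threshold: float = RANGE_THRESHOLD,
    tail_threshold: float = TAIL_THRESHOLD,
):
    """Strict two-criterion variability call (> on both clauses)."""
    r = np.asarray(range_excl_outliers, dtype=float)
    t = np.asarray(p99_minus_p1, dtype=float)
    out = (r > range_threshold) & (t > tail_threshold)
    return bool(out) if out.ndim == 0 else out


@dataclass
class CategoryPartition:
    """Four-way cross-tissue partition of the shared CpG set."""

    category: pd.Series          # per CpG, one of CATEGORY_LABELS
    counts: pd.Series            # per category
    proportions: pd.Series       # per category, sums to 1
    label_a: str = "a"
    label_b: str = "b"

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "proportion": self.proportions})


def categorize(
    calls_a: pd.DataFrame | pd.Series,
    calls_b: pd.DataFrame | pd.Series,
    label_a: str = "a",
    label_b: str = "b",
) -> CategoryPartition:
    """Partition CpGs by variability in two tissues (identical CpG sets).

    ``a_only`` means variable in tissue A and not in B, etc.; counts sum to
    the shared total and proportions to 1.
    """
    a = calls_a["is_variable"] if isinstance(calls_a, pd.DataFrame) else calls_a
    b = calls_b["is_variable"] if isinstance(calls_b, pd.DataFrame) else calls_b
    if set(a.index) != set(b.index):
        diff = a.index.symmetric_difference(b.index)
        raise IntegrityError(f"CpG sets differ; symmetric difference e.g. {diff[:5].tolist()}")
    b = b.reindex(a.index)
    av, bv = a.to_numpy(dtype=bool), b.to_numpy(dtype=bool)
    cat = np.where(av & bv, "both_variable",
                   np.where(av, "a_only", np.where(bv, "b_only", "neither")))
    category = pd.Series(cat, index=a.index, name="category")
    counts = category.value_counts().reindex(CATEGORY_LABELS, fill_value=0)
    return CategoryPartition(
        category=category,
        counts=counts,
        proportions=counts / counts.sum(),
        label_a=label_a,
        label_b=label_b,
    )


def iqr_exceedance_curve(calls: pd.DataFrame, grid) -> pd.DataFrame:
    """Proportion of CpGs with IQR >= each grid threshold (non-increasing).

    The value at threshold 0 is 1 by construction.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not (np.diff(grid) > 0).all():
        raise ConfigError("grid must be strictly increasing")
    iqr = calls["iqr"].to_numpy(dtype=float)
    prop = (iqr[None, :] >= grid[:, None]).mean(axis=1)
    return pd.DataFrame({"threshold": grid, "proportion": prop})
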