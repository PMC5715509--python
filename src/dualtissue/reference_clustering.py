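"""Surrogate-vs-reference methylome harmonization and hierarchical clustering.

Cohort tissues are summarized by their per-CpG median profile and joined
with sequencing-based reference methylomes. Sites are retained when they
(i) are present in every cohort profile, (ii) meet the minimum read
coverage wherever observed in a reference (below-threshold observations
become missing), (iii) are non-missing in enough references (default 10 of
25, scaled proportionally for other panel sizes), and (iv) have
interquartile range above 10% across reference tissues. Clustering uses
1 - Spearman correlation (pairwise-complete) with average linkage;
sample-to-reference similarity is reported as pairwise-complete Spearman
correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .data_io import (
    BetaMatrix,
    ConfigError,
    DegenerateInputError,
    IntegrityError,
    ReferenceMethylome,
)

MIN_COVERAGE = 30
MIN_PRESENT_DEFAULT_RATIO = 10 / 25
MIN_IQR = 0.10


def median_profile(matrix: BetaMatrix) -> pd.Series:
    """Per-CpG median methylation across samples (linear-interpolation median)."""
    if matrix.shape[1] < 1:
        raise DegenerateInputError("median_profile needs >= 1 sample")
    med = np.median(matrix.values.to_numpy(dtype=float), axis=1)
    return pd.Series(med, index=matrix.cpg_ids, name=matrix.tissue_label or "median")


@dataclass
class HarmonizedPanel:
    """Sites shared by cohort profiles and references after all filters.

    ``references`` is site x reference-tissue methylation (NaN = missing or
    under-covered); ``cohort`` is site x cohort-tissue median methylation.
    ``dropped`` records one reason per excluded site (not_in_cohort,
    low_coverage, too_missing, low_iqr). ``lineages`` maps reference tissue
    name to its lineage label.
    """

    references: pd.DataFrame
    cohort: pd.DataFrame
    dropped: pd.Series
    lineages: dict[str, str]

    @property
    def site_ids(self) -> pd.Index:
        return self.references.index

    def combined(self) -> pd.DataFrame:
        """All columns (references then cohort tissues) over retained sites."""
        return pd.concat([self.references, self.cohort], axis=1)


def harmonize(
    references: Sequence[ReferenceMethylome],
    cohort_profiles: Mapping[str, pd.Series],
    min_coverage: float = MIN_COVERAGE,
    min_present: int | None = None,
    min_iqr: float = MIN_IQR,
) -> HarmonizedPanel:
    """Join references with cohort median profiles and apply the site filters.

    Coverage masking precedes missingness counting: an observation covered
    below ``min_coverage`` is set missing first, then sites observed in
    fewer than ``min_present`` references are dropped, then sites with
    reference IQR <= ``min_iqr``. ``min_present`` defaults to
    ceil(0.4 * n_references), preserving the 10-of-25 convention.
    """
    if len(references) < 2:
        raise ConfigError("need at least 2 reference methylomes")
    if min_present is None:
        min_present = math.ceil(MIN_PRESENT_DEFAULT_RATIO * len(references))

    meth = pd.DataFrame({r.tissue_name: r.table["meth"] for r in references})
    cov = pd.DataFrame({r.tissue_name: r.table["coverage"] for r in references})
    cohort = pd.DataFrame(dict(cohort_profiles))
    all_sites = meth.index.union(cohort.index)

    dropped: dict[str, str] = {}
    in_cohort = cohort.notna().all(axis=1).reindex(all_sites, fill_value=False)
    for s in all_sites[~in_cohort]:
        dropped[s] = "not_in_cohort"
    sites = all_sites[in_cohort]

    meth = meth.reindex(sites)
    cov = cov.reindex(sites)
    present_before = meth.notna().sum(axis=1)
    meth = meth.where(cov.fillna(0) >= min_coverage)   # mask under-covered observations
    present_after = meth.notna().sum(axis=1)
    enough = present_after >= min_present
    for s in sites[~enough]:
        dropped[s] = (
            "low_coverage" if present_before.loc[s] >= min_present else "too_missing"
        )
    sites = sites[enough]

    q1 = meth.loc[sites].quantile(0.25, axis=1)
    q3 = meth.loc[sites].quantile(0.75, axis=1)
    iqr_ok = (q3 - q1) > min_iqr
    for s in sites[~iqr_ok]:
        dropped[s] = "low_iqr"
    sites = sites[iqr_ok]

    if len(sites) == 0:
        raise IntegrityError("no sites retained after harmonization filters")
    return HarmonizedPanel(
        references=meth.loc[sites],
        cohort=cohort.loc[sites],
        dropped=pd.Series(dropped, dtype="object", name="reason"),
        lineages={r.tissue_name: r.lineage_label for r in references},
    )


# ---------------------------------------------------------------------------
# Spearman distances and clustering
# ---------------------------------------------------------------------------

def _pairwise_spearman(frame: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation between columns."""
    cols = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    k = len(cols)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if ok.sum() < min_shared:
                raise IntegrityError(
                    f"columns {cols[i]!r} and {cols[j]!r} share only {int(ok.sum())} "
                    f"non-missing sites (< {min_shared})"
                )
            rho = stats.spearmanr(X[ok, i], X[ok, j]).statistic
            out[i, j] = out[j, i] = float(rho)
    return pd.DataFrame(out, index=cols, columns=cols)


@dataclass
class ClusterResult:
    """Dendrogram plus correlation structure for tissues and references."""

    linkage: np.ndarray
    labels: list[str]
    cophenetic: pd.DataFrame
    correlations: pd.DataFrame
    newick: str

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster assignment for the given number of clusters."""
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")


def cluster(panel: HarmonizedPanel, linkage_method: str = "average") -> ClusterResult:
    """Hierarchically cluster references and cohort profiles.

    Distance is 1 - Spearman correlation over retained sites
    (pairwise-complete); agglomeration is average linkage by default.
    Columns are ordered lexicographically first so ties break
    deterministically by label order.
    """
    combined = panel.combined()
    if combined.shape[1] < 3:
        raise ConfigError("need >= 3 columns (tissues/references) to cluster")
    combined = combined[sorted(combined.columns)]
    corr = _pairwise_spearman(combined)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage_method)
    coph = hierarchy.cophenet(Z)
    k = combined.shape[1]
    cmat = np.zeros((k, k))
    cmat[np.triu_indices(k, 1)] = coph
    cmat = cmat + cmat.T
    labels = list(combined.columns)
    return ClusterResult(
        linkage=Z,
        labels=labels,
        cophenetic=pd.DataFrame(cmat, index=labels, columns=labels),
        correlations=corr,
        newick=to_newick(Z, labels),
    )


def to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def sample_reference_correlation(
    cohort: BetaMatrix, panel: HarmonizedPanel, min_shared: int = 10
) -> pd.DataFrame:
    """Pairwise-complete Spearman of each cohort sample against each reference."""
    shared = panel.site_ids.intersection(cohort.cpg_ids)
    if len(shared) < min_shared:
        raise IntegrityError(
            f"only {len(shared)} sites shared between cohort and panel (< {min_shared})"
        )
    S = cohort.values.loc[shared].to_numpy(dtype=float)
    R = panel.references.loc[shared].to_numpy(dtype=float)
    out = np.full((S.shape[1], R.shape[1]), np.nan)
    for j in range(R.shape[1]):
        ok = ~np.isnan(R[:, j])
        if ok.sum() < min_shared:
            raise IntegrityError(
                f"reference {panel.references.columns[j]!r} shares "
                f"only {int(ok.sum())} sites with the cohort (< {min_shared})"
            )
        ranks_ref = stats.rankdata(R[ok, j])
        ranks_smp = np.apply_along_axis(stats.rankdata, 0, S[ok, :])
        rc = ranks_ref - ranks_ref.mean()
        sc = ranks_smp - ranks_smp.mean(axis=0)
        denom = np.sqrt((rc ** 2).sum() * (sc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = (sc.T @ rc) / denom
    return pd.DataFrame(out, index=cohort.sample_ids, columns=panel.references.columns)
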