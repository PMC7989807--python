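"""Community comparison statistics between sequencing methods/pipelines.

Per-sample Bray-Curtis dissimilarity and Pearson correlation against a
designated reference method, Hurlbert's analytic rarefied richness, and
heatmap-ready relative-abundance tables. Note on naming: the comparison
layer reports Bray-Curtis DISSIMILARITY (0 = identical communities), the
quantity R's vegdist returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from scipy.special import gammaln
from scipy import stats

from .cluster_assign import UNASSIGNED, AbundanceMatrix


def _normalise(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    return x / total


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity of two relative-abundance vectors.

    Inputs are normalised to sum 1 first, so sequencing depth differences
    do not contribute. Sum|x-y| / Sum(x+y), in [0, 1].
    """
    xn, yn = _normalise(x), _normalise(y)
    return float(ssd.braycurtis(xn, yn))


def pearson(x, y) -> float:
    """Product-moment correlation of two relative-abundance vectors."""
    xn, yn = _normalise(x), _normalise(y)
    if len(xn) < 2:
        raise ValueError("need at least 2 clusters")
    if np.ptp(xn) == 0 or np.ptp(yn) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(xn, yn).statistic)


def rarefied_richness(counts, n: int) -> float:
    """Hurlbert's expected richness in a random subsample of size n.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] with N the total count,
    evaluated with log-gamma for numerical safety.
    """
    c = np.asarray(counts, dtype=np.int64)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    N = int(c.sum())
    if n > N:
        raise ValueError(f"subsample size {n} exceeds total count {N}")
    if n < 0:
        raise ValueError("subsample size must be >= 0")
    # log C(N - Ni, n) - log C(N, n); C(M, n) = 0 when M < n
    with np.errstate(divide="ignore"):
        log_keep = (
            gammaln(N - c + 1) - gammaln(n + 1) - gammaln(N - c - n + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
    absent_prob = np.where(N - c >= n, np.exp(log_keep), 0.0)
    return float(np.sum(1.0 - absent_prob))


@dataclass
class ComparisonReport:
    """Per-sample Pearson/Bray-Curtis of a method against a reference."""

    table: pd.DataFrame  # index sample_id; columns pearson_r, bray_curtis
    reference_method: str
    comparand_method: str
    missing_samples: list[str]


def compare_methods(
    matrix_ref: AbundanceMatrix | pd.DataFrame,
    matrix_alt: AbundanceMatrix | pd.DataFrame,
    reference_method: str = "reference",
    comparand_method: str = "comparand",
    include_unassigned: bool = False,
) -> ComparisonReport:
    """Per-shared-sample Pearson and Bray-Curtis between two methods.

    Cluster label spaces are unioned (absent clusters count 0); rows are
    converted to relative abundances before comparison.
    """
    a = _as_relative(matrix_ref, include_unassigned)
    b = _as_relative(matrix_alt, include_unassigned)
    clusters = sorted(set(a.columns) | set(b.columns))
    a = a.reindex(columns=clusters, fill_value=0.0)
    b = b.reindex(columns=clusters, fill_value=0.0)
    shared = [s for s in a.index if s in set(b.index)]
    if not shared:
        raise ValueError("no shared samples between the two matrices")
    missing = sorted(set(a.index).symmetric_difference(b.index))
    rows = {}
    for s in shared:
        x, y = a.loc[s].to_numpy(), b.loc[s].to_numpy()
        try:
            r = pearson(x, y)
        except ValueError:
            r = np.nan
        try:
            bc = bray_curtis(x, y)
        except ValueError:
            bc = np.nan
        rows[s] = {"pearson_r": r, "bray_curtis": bc}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ComparisonReport(table, reference_method, comparand_method, missing)


def _as_relative(m, include_unassigned: bool) -> pd.DataFrame:
    if isinstance(m, AbundanceMatrix):
        return m.relative(include_unassigned=include_unassigned)
    df = m if include_unassigned else m.drop(columns=[UNASSIGNED],
                                             errors="ignore")
    totals = df.sum(axis=1)
    return df.div(totals.where(totals > 0, other=np.nan), axis=0).fillna(0.0)


def heatmap_table(matrix: AbundanceMatrix | pd.DataFrame,
                  bin_width: float = 0.125) -> pd.DataFrame:
    """Clusters x samples relative abundances binned at fixed intervals
    (12.5% by default, matching the heatmap legend convention)."""
    rel = _as_relative(matrix, include_unassigned=False)
    binned = np.ceil(rel / bin_width) * bin_width
    return binned.T


def sample_linkage(matrix: AbundanceMatrix | pd.DataFrame):
    """UPGMA linkage of samples on Bray-Curtis dissimilarity (for callers
    who want to order heatmap rows); returns a scipy linkage matrix."""
    from scipy.cluster import hierarchy

    rel = _as_relative(matrix, include_unassigned=False).to_numpy()
    dvec = ssd.pdist(rel, metric="braycurtis")
    return hierarchy.linkage(dvec, method="average")
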