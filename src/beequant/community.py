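"""Community-level analytics: richness, rarefaction, ordination.

Per-sample richness is computed from either identification mode
(morphological specimen counts or mapped read counts) and compared by
Pearson correlation.  Sample-based rarefaction interpolates expected
richness over sampling units via the classical hypergeometric formula and
extrapolates beyond the observed effort with the Chao2 estimate of
undetected richness.  Ordination is a PCA of row-normalized (relative
abundance), column-centred community matrices, with per-group minimum
convex polygons on the first two components.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .exceptions import UndefinedStatisticError
from .reads import ReadCountTable
from .simulate import parse_sample_id


def _counts_frame(table) -> pd.DataFrame:
    return table.counts if isinstance(table, ReadCountTable) else table


def sample_richness(table) -> pd.Series:
    """Number of taxa with count > 0 per sample (calibrator excluded).

    Accepts a specimen table or a :class:`ReadCountTable`; the latter's
    count matrix already excludes calibrator reads.
    """
    counts = _counts_frame(table)
    return (counts > 0).sum(axis=1)


def richness_correlation(morph_richness, mol_richness) -> float:
    """Pearson correlation between the two per-sample richness vectors."""
    x = np.asarray(morph_richness, dtype=float)
    y = np.asarray(mol_richness, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedStatisticError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass
class IncidenceMatrix:
    """Presence/absence over sampling units with rarefaction ingredients.

    T is the number of sampling units, ``incidence_freq`` the per-taxon
    count of units occupied (T_i), Q1/Q2 the numbers of taxa found in
    exactly one/two units, and S_obs the observed richness.
    """

    presence: pd.DataFrame

    def __post_init__(self) -> None:
        self.presence = (_counts_frame(self.presence) > 0).astype(int)

    @classmethod
    def from_counts(cls, table) -> "IncidenceMatrix":
        return cls(_counts_frame(table))

    @property
    def T(self) -> int:
        return self.presence.shape[0]

    @property
    def incidence_freq(self) -> pd.Series:
        return self.presence.sum(axis=0)

    @property
    def Q1(self) -> int:
        return int((self.incidence_freq == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.incidence_freq == 2).sum())

    @property
    def S_obs(self) -> int:
        return int((self.incidence_freq > 0).sum())


def _chao2_undetected(T: int, Q1: int, Q2: int) -> float:
    if Q2 > 0:
        return (T - 1) / T * Q1 * Q1 / (2.0 * Q2)
    return (T - 1) / T * Q1 * (Q1 - 1) / 2.0


def rarefaction_curve(inc: IncidenceMatrix, t_values: Sequence[int]) -> pd.DataFrame:
    """Expected richness at each number of sampling units t.

    Interpolation (t <= T) uses the exact hypergeometric expectation

        S(t) = S_obs - sum_i C(T - T_i, t) / C(T, t),

    the mean richness over all subsets of t units.  Extrapolation (t > T)
    uses the Chao2 estimate Q0 of undetected taxa:

        S(T + t*) = S_obs + Q0 * (1 - (1 - Q1 / (T*Q0 + Q1))**t*).

    Returns a DataFrame with columns t, expected_richness, method.
    """
    T, S_obs, Q1, Q2 = inc.T, inc.S_obs, inc.Q1, inc.Q2
    freqs = inc.incidence_freq.to_numpy()
    freqs = freqs[freqs > 0]
    q0 = _chao2_undetected(T, Q1, Q2)
    rows = []
    for t in t_values:
        t = int(t)
        if t <= 0:
            raise ValueError("t must be a positive integer")
        if t <= T:
            denom = comb(T, t)
            missing = sum(comb(T - ti, t) for ti in freqs) / denom
            rows.append((t, S_obs - missing, "interpolated"))
        else:
            t_star = t - T
            if Q1 == 0 or q0 == 0:
                s = float(S_obs)
            else:
                s = S_obs + q0 * (1.0 - (1.0 - Q1 / (T * q0 + Q1)) ** t_star)
            rows.append((t, s, "extrapolated"))
    return pd.DataFrame(rows, columns=["t", "expected_richness", "method"])


@dataclass
class OrdinationResult:
    """PCA scores, explained variances, and per-group convex polygons."""

    scores: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    hulls: dict[str, np.ndarray]


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Minimum convex polygon vertices (counter-clockwise); degenerate
    groups (fewer than 3 distinct points, or collinear) return their
    distinct points."""
    unique = np.unique(points, axis=0)
    if len(unique) < 3:
        return unique
    try:
        hull = ConvexHull(unique)
    except QhullError:
        return unique
    return unique[hull.vertices]


def pca_ordination(
    table, groups: Mapping[str, str] | None = None
) -> OrdinationResult:
    """PCA of relative-abundance community profiles.

    Rows are normalized to relative abundance (all-zero rows stay zero),
    columns centred but not scaled, and the full eigendecomposition taken so
    explained variances sum to the total column variance.  When ``groups``
    maps samples to labels, a minimum convex polygon is computed per group
    on the first two components.
    """
    counts = _counts_frame(table)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 taxa")
    x = counts.to_numpy(dtype=float)
    row_sums = x.sum(axis=1, keepdims=True)
    x = np.divide(x, row_sums, out=np.zeros_like(x), where=row_sums > 0)
    pca = PCA(n_components=min(x.shape))
    scores = pca.fit_transform(x)
    score_df = pd.DataFrame(
        scores,
        index=counts.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    hulls: dict[str, np.ndarray] = {}
    if groups is not None:
        labels = pd.Series({s: groups[s] for s in counts.index})
        for label in sorted(set(labels)):
            pts = score_df.loc[labels == label, ["PC1", "PC2"]].to_numpy()
            hulls[label] = _hull_vertices(pts)
    return OrdinationResult(
        scores=score_df,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        hulls=hulls,
    )


def group_summary(values: pd.Series) -> pd.DataFrame:
    """Mean with a normal-approximation 95% CI per location x management.

    ``values`` is a per-sample statistic (e.g. richness) indexed by
    ``management|location|date`` community-pool labels.
    """
    meta = pd.DataFrame(
        [parse_sample_id(s) for s in values.index],
        index=values.index,
        columns=["management", "location", "date"],
    )
    rows = []
    for (loc, mgmt), group in values.groupby(
        [meta["location"], meta["management"]]
    ):
        mean = group.mean()
        se = group.std(ddof=1) / np.sqrt(len(group)) if len(group) > 1 else np.nan
        rows.append((loc, mgmt, len(group), mean, mean - 1.96 * se, mean + 1.96 * se))
    return pd.DataFrame(
        rows, columns=["location", "management", "n", "mean", "ci_low", "ci_high"]
    )


def plot_ordination(result: OrdinationResult, groups: Mapping[str, str], ax=None):
    """Scatter of PC1/PC2 with shaded per-group convex polygons."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = pd.Series({s: groups[s] for s in result.scores.index})
    for label in sorted(set(labels)):
        pts = result.scores.loc[labels == label, ["PC1", "PC2"]].to_numpy()
        ax.scatter(pts[:, 0], pts[:, 1], label=label, alpha=0.7)
        hull = result.hulls.get(label)
        if hull is not None and len(hull) >= 3:
            ax.fill(hull[:, 0], hull[:, 1], alpha=0.2)
    pct = 100 * result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    ax.legend()
    return ax
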