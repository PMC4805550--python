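"""Cross-cell pattern comparison: correlation, sliding-window medians,
correlation matrix, spectral co-clustering and the soma-centered control.

Cells recorded in different animals are registered to a common mediolateral
frame (zebrin-band coordinates), grouped in 100 µm sliding windows shifted
by 10 µm, and each group's elementwise-median pattern is correlated with
every other group's (Pearson, on a shared 10 µm support).  Spectral
co-clustering of the correlation matrix recovers blocks of contiguous,
correlated groups — the stereotyped input-pattern clusters.  A shuffle null
(random non-self, non-neighbour re-pairings) calibrates the pairwise
correlations, and centering all patterns on their somata provides the
position-blind control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import SpectralCoclustering

from .errors import DegenerateStructureError, UndefinedCorrelationError
from .mapping import MediolateralPattern

CORRELATION_STEP_UM = 10.0
GROUP_WINDOW_UM = 100.0
GROUP_SHIFT_UM = 10.0
NEIGHBOR_RADIUS_UM = 50.0


def _common_support(
    p1: MediolateralPattern,
    p2: MediolateralPattern,
    step_um: float = CORRELATION_STEP_UM,
) -> np.ndarray:
    lo = max(p1.positions_um[0], p2.positions_um[0])
    hi = min(p1.positions_um[-1], p2.positions_um[-1])
    if hi <= lo:
        raise UndefinedCorrelationError("patterns have no overlapping support")
    return np.arange(lo, hi + 1e-9, step_um)


def pattern_correlation(
    p1: MediolateralPattern,
    p2: MediolateralPattern,
    step_um: float = CORRELATION_STEP_UM,
) -> float:
    """Pearson r between two patterns on the intersection of their supports."""
    support = _common_support(p1, p2, step_um)
    a, b = p1.resample(support), p2.resample(support)
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("zero-variance pattern")
    return float(stats.pearsonr(a, b)[0])


def shuffle_null(
    patterns: list[MediolateralPattern],
    n_shuffles: int,
    seed: int,
    *,
    positions_um: np.ndarray | None = None,
    neighbor_radius_um: float = NEIGHBOR_RADIUS_UM,
    exclude_pairs: set | None = None,
    min_overlap_um: float = 100.0,
) -> np.ndarray:
    """Distribution of Pearson r over random non-matched cell pairings.

    Each shuffle round re-pairs the cells without replacement (a random
    derangement-style matching); self-pairs, explicitly excluded pairs and
    pairs of true neighbours (soma distance below ``neighbor_radius_um``
    when positions are given) are dropped, as are pairs whose patterns
    overlap by less than ``min_overlap_um``.
    """
    n = len(patterns)
    if n < 3:
        raise ValueError("need >= 3 cells for a shuffle null")
    if positions_um is None:
        positions_um = np.array(
            [np.nan if p.soma_position_um is None else p.soma_position_um for p in patterns]
        )
    excluded = exclude_pairs or set()
    rng = np.random.default_rng(seed)
    rs: list[float] = []
    rounds = 0
    max_rounds = max(50, 10 * n_shuffles)
    while len(rs) < n_shuffles:
        rounds += 1
        if rounds > max_rounds:
            if not rs:
                raise ValueError("no admissible shuffled pairs found")
            break
        perm = rng.permutation(n)
        for i, j in enumerate(perm):
            if i == j or (i, j) in excluded or (j, i) in excluded:
                continue
            d = abs(positions_um[i] - positions_um[j])
            if np.isfinite(d) and d < neighbor_radius_um:
                continue
            try:
                support = _common_support(patterns[i], patterns[j])
            except UndefinedCorrelationError:
                continue
            if support[-1] - support[0] < min_overlap_um:
                continue
            try:
                rs.append(pattern_correlation(patterns[i], patterns[j]))
            except UndefinedCorrelationError:
                continue
            if len(rs) >= n_shuffles:
                break
    return np.array(rs)


@dataclass
class MedianPatternGroup:
    """Sliding-window group of cells and their elementwise-median pattern."""

    center_um: float
    window_um: float
    member_ids: tuple
    pattern: MediolateralPattern
    mad: np.ndarray  # per-position median absolute deviation

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def median_patterns(
    patterns: list[MediolateralPattern],
    positions_um: np.ndarray | None = None,
    window_um: float = GROUP_WINDOW_UM,
    shift_um: float = GROUP_SHIFT_UM,
    min_members: int = 1,
) -> list[MedianPatternGroup]:
    """Sliding-window elementwise-median patterns along the mediolateral axis.

    One group per window centre (spacing ``shift_um``) whose members are the
    cells with registered soma position within ``window_um / 2`` of the
    centre; empty windows are skipped.  The group pattern is the per-position
    median across member patterns on the intersection of their supports, with
    the per-position median absolute deviation as dispersion.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    if positions_um is None:
        positions_um = np.array([p.soma_position_um for p in patterns], dtype=float)
    positions_um = np.asarray(positions_um, dtype=float)
    centers = np.arange(
        np.floor(positions_um.min()), np.ceil(positions_um.max()) + shift_um / 2, shift_um
    )
    groups: list[MedianPatternGroup] = []
    half = window_um / 2.0
    for c in centers:
        members = np.flatnonzero(np.abs(positions_um - c) <= half)
        if members.size < min_members or members.size == 0:
            continue
        lo = max(patterns[m].positions_um[0] for m in members)
        hi = min(patterns[m].positions_um[-1] for m in members)
        if hi <= lo:
            continue
        support = np.arange(lo, hi + 1.0)
        stack = np.stack([patterns[m].resample(support) for m in members])
        med = np.median(stack, axis=0)
        mad = np.median(np.abs(stack - med), axis=0)
        groups.append(
            MedianPatternGroup(
                center_um=float(c),
                window_um=window_um,
                member_ids=tuple(
                    patterns[m].cell_id if patterns[m].cell_id is not None else int(m)
                    for m in members
                ),
                pattern=MediolateralPattern(support, med, cell_id=f"group@{c:.0f}"),
                mad=mad,
            )
        )
    return groups


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson-r matrix between group median patterns."""

    values: np.ndarray  # (n, n), NaN where undefined
    centers_um: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.centers_um = np.asarray(self.centers_um, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.centers_um.size != n:
            raise ValueError("matrix must be square with one centre per row")

    def to_long_frame(self) -> pd.DataFrame:
        n = self.values.shape[0]
        i, j = np.meshgrid(range(n), range(n), indexing="ij")
        return pd.DataFrame(
            {
                "center_i_um": self.centers_um[i.ravel()],
                "center_j_um": self.centers_um[j.ravel()],
                "r": self.values.ravel(),
            }
        )


def correlation_matrix(
    groups: list[MedianPatternGroup], step_um: float = CORRELATION_STEP_UM
) -> CorrelationMatrix:
    """Pairwise Pearson correlation between all group median patterns.

    Undefined entries (zero variance, no overlap) propagate as NaN, never 0.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    n = len(groups)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pattern_correlation(groups[i].pattern, groups[j].pattern, step_um)
            except UndefinedCorrelationError:
                r = np.nan
            vals[i, j] = vals[j, i] = r
    return CorrelationMatrix(vals, np.array([g.center_um for g in groups]))


@dataclass
class ClusterAssignment:
    """Co-clustering result over position-ordered groups."""

    labels: np.ndarray
    n_clusters: int
    contiguous: dict  # cluster id -> bool
    centers_um: np.ndarray | None = None

    @property
    def all_contiguous(self) -> bool:
        return all(self.contiguous.values())


def _contiguity(labels: np.ndarray) -> dict:
    """Whether each cluster occupies one contiguous run of the index axis."""
    out = {}
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        out[int(k)] = bool(idx.size == idx[-1] - idx[0] + 1)
    return out


class CorrelationBiclustering(BaseEstimator):
    """Spectral co-clustering of a pattern correlation matrix.

    The matrix entries are mapped monotonically to nonnegative values
    (r -> (r + 1) / 2) and fed to bipartite spectral graph partitioning
    (normalised matrix SVD, leading singular vectors, k-means on the
    row/column embeddings).  For a symmetric matrix the row and column
    partitions coincide and the row labels are reported.

    ``n_clusters`` may be an integer or ``"auto"``, which scans
    ``k_range`` and keeps the k maximising (mean within-cluster r -
    mean between-cluster r).

    Attributes
    ----------
    row_labels_, column_labels_ : per-group cluster ids
    n_clusters_ : the number of clusters used
    contiguous_ : dict mapping cluster id to position-contiguity
    score_ : within-minus-between mean r of the final partition
    """

    def __init__(self, n_clusters=4, k_range=range(2, 9), random_state=0):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.random_state = random_state

    def fit(self, X, y=None):
        M, centers = self._as_matrix(X)
        n = M.shape[0]
        if np.isnan(M).any():
            raise ValueError("correlation matrix contains undefined entries")
        if np.allclose(M, M.ravel()[0]):
            raise DegenerateStructureError("constant correlation matrix")
        if self.n_clusters == "auto":
            ks = [k for k in self.k_range if 2 <= k <= n]
            if not ks:
                raise ValueError("no admissible k in k_range")
            scored = [(self._score(M, self._labels_for(M, k)), k) for k in ks]
            _, best_k = max(scored)
            k = best_k
        else:
            k = int(self.n_clusters)
            if k < 2 or k > n:
                raise ValueError(f"n_clusters must be in [2, {n}], got {k}")
        labels = self._labels_for(M, k)
        self.row_labels_ = labels
        self.column_labels_ = labels
        self.n_clusters_ = k
        self.contiguous_ = _contiguity(labels)
        self.score_ = self._score(M, labels)
        self.centers_um_ = centers
        return self

    def assignment(self) -> ClusterAssignment:
        return ClusterAssignment(
            labels=self.row_labels_,
            n_clusters=self.n_clusters_,
            contiguous=self.contiguous_,
            centers_um=self.centers_um_,
        )

    def _labels_for(self, M: np.ndarray, k: int) -> np.ndarray:
        shifted = (M + 1.0) / 2.0
        model = SpectralCoclustering(n_clusters=k, random_state=self.random_state)
        model.fit(shifted)
        return np.asarray(model.row_labels_)

    @staticmethod
    def _score(M: np.ndarray, labels: np.ndarray) -> float:
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        within = M[same & off]
        between = M[~same]
        if within.size == 0 or between.size == 0:
            return -np.inf
        return float(within.mean() - between.mean())

    @staticmethod
    def _as_matrix(X):
        if isinstance(X, CorrelationMatrix):
            return X.values.copy(), X.centers_um
        M = np.asarray(X, dtype=float)
        return M, None


def spectral_cocluster(
    matrix: CorrelationMatrix | np.ndarray, k: int = 4, random_state: int = 0
) -> ClusterAssignment:
    """Co-cluster a correlation matrix into k biclusters (thin wrapper)."""
    est = CorrelationBiclustering(n_clusters=k, random_state=random_state).fit(matrix)
    return est.assignment()


def center_on_soma(
    patterns: list[MediolateralPattern],
    positions_um: np.ndarray | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Soma-centered mean profile: the position-blind control.

    Each pattern is translated so its soma sits at offset 0 and (optionally)
    normalised to unit peak; profiles are averaged per offset over the
    patterns that cover it.  When hotspot positions are tied to absolute
    location rather than to the recorded cell, centering destroys the
    structure and the mean shows a single central peak with no secondary
    peak.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    if positions_um is None:
        positions_um = np.array([p.soma_position_um for p in patterns], dtype=float)
    offsets_min = min(p.positions_um[0] - s for p, s in zip(patterns, positions_um))
    offsets_max = max(p.positions_um[-1] - s for p, s in zip(patterns, positions_um))
    support = np.arange(np.ceil(offsets_min), np.floor(offsets_max) + 1.0)
    acc = np.zeros_like(support)
    cnt = np.zeros_like(support)
    for p, s in zip(patterns, positions_um):
        off = p.positions_um - s
        vals = p.values
        if normalize:
            peak = np.abs(vals).max()
            if peak > 0:
                vals = vals / peak
        inside = (support >= off[0]) & (support <= off[-1])
        acc[inside] += np.interp(support[inside], off, vals)
        cnt[inside] += 1
    mean = np.full_like(support, np.nan)
    covered = cnt > 0
    mean[covered] = acc[covered] / cnt[covered]
    return support, mean
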