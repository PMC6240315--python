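"""Information-weighted sparse-sample (IWSS) distance between scar profiles.

Binary scar profiles of dissected body structures are extremely sparse: most
scars are absent from most structures, and absences carry far less information
than the presence of a rare clone marker.  The IWSS dissimilarity weights each
scar by its information content across the cohort — a match on a rare scar
(high surprise, weight −log2 p) pulls two structures together far more than a
match on a common one; mismatches are penalized by the same presence weight;
matches on absence contribute the (small) absence information −log2(1−p).

For profiles x, y over scars s with presence weight w_s and absence weight
v_s::

    D(x, y) = Σ_{x≠y} w_s  /  ( Σ_{x=y=1} w_s + Σ_{x=y=0} v_s + Σ_{x≠y} w_s )

so D ∈ [0, 1], D(x, x) = 0, and D = 1 when the profiles share no state.  The
weighting uses a Jeffreys pseudocount (α = 0.5 by default) to keep all weights
finite.  IWSS is a dissimilarity, not a metric: triangle-inequality violations
are possible and merely logged.  The exact published weighting of the distance
this emulates is unavailable, so results should be read as IWSS-like; the
definition is isolated in :func:`iwss` so an alternative can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .scar_filtering import BinaryScarMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScarWeights:
    """Per-scar information weights derived from presence frequencies.

    ``p`` is the pseudocounted presence frequency of each scar across samples,
    strictly inside (0, 1); ``w = −log2 p`` weights presences and mismatches,
    ``v = −log2(1−p)`` weights shared absences.
    """

    scar_ids: list
    p: np.ndarray
    w: np.ndarray
    v: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if not ((self.p > 0) & (self.p < 1)).all():
            raise ValueError("presence frequencies must lie strictly in (0,1)")
        if not (self.w > 0).all() or not (self.v > 0).all():
            raise ValueError("weights must be positive")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise IWSS dissimilarity, zero diagonal, entries in [0,1]."""

    labels: list
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.abs(D - D.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(D)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if (D < -1e-12).any() or (D > 1 + 1e-12).any():
            raise ValueError("distances outside [0, 1]")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def scar_weights(B: BinaryScarMatrix, alpha: float = 0.5) -> ScarWeights:
    """Information weights from a binary scar matrix.

    p_s = (presence count + α) / (n_rows + 2α); w_s = −log2 p_s;
    v_s = −log2(1 − p_s).  Requires at least two samples.
    """
    if B.n_samples < 2:
        raise ValueError("need at least 2 samples to weight scars")
    presence = B.presence.to_numpy()
    n = presence.shape[0]
    p = (presence.sum(axis=0) + alpha) / (n + 2 * alpha)
    return ScarWeights(
        scar_ids=list(B.presence.columns),
        p=p,
        w=-np.log2(p),
        v=-np.log2(1.0 - p),
        alpha=alpha,
    )


def iwss(x: np.ndarray, y: np.ndarray, W: ScarWeights) -> float:
    """IWSS dissimilarity between two binary scar profiles.

    See the module docstring for the formula.  Returns 0 for identical
    profiles (including two all-zero profiles, where the shared absences fill
    the denominator).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape or x.shape[0] != W.w.shape[0]:
        raise ValueError(
            f"length mismatch: x {x.shape}, y {y.shape}, weights {W.w.shape}"
        )
    mismatch = x != y
    match11 = x & y
    match00 = ~x & ~y
    num = W.w[mismatch].sum()
    den = W.w[match11].sum() + W.v[match00].sum() + num
    if den == 0:  # zero-length profiles
        return 0.0
    return float(num / den)


def distance_matrix(B: BinaryScarMatrix, alpha: float = 0.5) -> DistanceMatrix:
    """All-pairs IWSS over the rows of a binary scar matrix."""
    if B.n_samples < 2:
        raise ValueError("need at least 2 samples")
    W = scar_weights(B, alpha=alpha)
    X = B.presence.to_numpy().astype(bool)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = iwss(X[i], X[j], W)
    dm = DistanceMatrix(list(B.presence.index), D)
    _log_triangle_violations(dm)
    return dm


def _log_triangle_violations(dm: DistanceMatrix, tol: float = 1e-9) -> None:
    D, n = dm.D, len(dm.labels)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if D[i, j] > D[i, k] + D[k, j] + tol:
                    logger.info(
                        "triangle inequality violated for (%s, %s, %s); "
                        "IWSS is a dissimilarity, not a metric",
                        dm.labels[i], dm.labels[j], dm.labels[k],
                    )
                    return


def cluster_log_distance(
    dm: DistanceMatrix, epsilon: float = 1e-6
) -> tuple[np.ndarray, list]:
    """Average-linkage clustering of log10-transformed distance rows.

    Rows of the distance matrix are mapped to log10(D + ε) and agglomerated
    with average linkage on euclidean distances between transformed rows —
    the ordering behind the clustered log-distance heatmaps.  Returns the
    scipy linkage matrix and the leaf order as labels.  The linkage is
    deterministic; among equal merge heights scipy takes the earlier
    candidate pair, i.e. ties break toward smaller input indices.
    """
    logD = np.log10(dm.D + epsilon)
    Z = sch.linkage(logD, method="average", metric="euclidean")
    order = sch.leaves_list(Z)
    return Z, [dm.labels[i] for i in order]


def write_linkage(Z: np.ndarray, path) -> None:
    """Write a linkage matrix as a flat merge table (step, left, right, height)."""
    df = pd.DataFrame(Z[:, :3], columns=["left", "right", "height"])
    df.insert(0, "step", np.arange(len(df)))
    df[["left", "right"]] = df[["left", "right"]].astype(int)
    df.to_csv(path, sep="\t", index=False)


def plot_heatmap(dm: DistanceMatrix, path, epsilon: float = 1e-6) -> None:
    """Clustered log10-distance heatmap (average linkage, euclidean metric)."""
    import seaborn as sns  # local import: plotting only

    logD = pd.DataFrame(
        np.log10(dm.D + epsilon), index=dm.labels, columns=dm.labels
    )
    g = sns.clustermap(logD, method="average", metric="euclidean")
    g.savefig(path)
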