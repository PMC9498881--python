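"""SNP-SNP similarity networks from the row-normalized association map.

Five scoring functions compare each pair of SNP rows (their association
patterns over all ROIs): Pearson correlation, Spearman correlation,
Manhattan (L1) distance, Euclidean (L2) distance, and cosine similarity.
Correlations and cosine are normalized by absolute value; distances are
mapped to similarities through a Gaussian radial basis function centered at
distance 0 with standard deviation (dmax - dmin) / 3, where the minimum and
maximum are taken over all entries of the distance matrix including its zero
diagonal (hence dmin = 0).  All resulting networks are symmetric, lie in
[0, 1], and have unit diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import pearsonr, rankdata, spearmanr

from .association import AssociationMap

__all__ = [
    "MEASURES",
    "SimilarityNetwork",
    "raw_score",
    "distance_to_similarity",
    "build_network",
    "build_all_networks",
]

logger = logging.getLogger(__name__)

#: The five scoring measures, in canonical order.
MEASURES = ("pearson", "spearman", "manhattan", "euclidean", "cosine")

#: Sentinel for a raw score that is undefined (zero-variance vector under a
#: correlation, or a zero vector under cosine).
UNDEFINED = float("nan")


@dataclass
class SimilarityNetwork:
    """Symmetric SNP x SNP similarity matrix in [0, 1] with unit diagonal."""

    snp_ids: list[str]
    measure: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        s = len(self.snp_ids)
        if self.weights.shape != (s, s):
            raise ValueError("network weights must be square and match snp_ids")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("network weights must be symmetric")
        if self.weights.min() < -1e-12 or self.weights.max() > 1 + 1e-12:
            raise ValueError("network entries must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.snp_ids, columns=self.snp_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, measure: str) -> "SimilarityNetwork":
        return cls([str(i) for i in frame.index], measure, frame.to_numpy(dtype=float))


def raw_score(x: np.ndarray, y: np.ndarray, measure: str) -> float:
    """Raw pairwise score of two ROI vectors under one measure.

    Correlations and cosine return values in [-1, 1]; Manhattan and
    Euclidean return nonnegative distances.  Undefined cases (constant
    vector under a correlation, zero vector under cosine) return NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("raw_score expects two equal-length vectors of length >= 2")
    if measure == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return UNDEFINED
        return float(pearsonr(x, y).statistic)
    if measure == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return UNDEFINED
        return float(spearmanr(x, y).statistic)
    if measure == "manhattan":
        return float(np.abs(x - y).sum())
    if measure == "euclidean":
        return float(np.linalg.norm(x - y))
    if measure == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return UNDEFINED
        return float(np.dot(x, y) / (nx * ny))
    raise ValueError(f"unknown measure {measure!r}")


def distance_to_similarity(d_matrix: np.ndarray) -> np.ndarray:
    """Gaussian RBF transform of a distance matrix onto (0, 1].

    ``s(i,j) = exp(-0.5 * ((d(i,j) - dmin) / sigma)^2)`` with
    ``sigma = (dmax - dmin) / 3``; dmin/dmax range over all entries
    including the zero diagonal, so dmin = 0 and the kernel is centered at
    distance 0.  If every distance is equal, all similarities are 1.
    """
    d = np.asarray(d_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        return np.ones_like(d)
    sigma = (dmax - dmin) / 3.0
    return np.exp(-0.5 * ((d - dmin) / sigma) ** 2)


def _correlation_weights(values: np.ndarray, measure: str) -> np.ndarray:
    """|Pearson| / |Spearman| / |cosine| pairwise weights, NaN where undefined."""
    if measure == "spearman":
        values = rankdata(values, axis=1)
    if measure in ("pearson", "spearman"):
        sd = values.std(axis=1)
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
    else:  # cosine
        sd = None
        centered = values
        norms = np.linalg.norm(values, axis=1)
    undefined = norms == 0 if sd is None else sd == 0
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, np.newaxis]
    weights = unit @ unit.T
    weights[undefined, :] = np.nan
    weights[:, undefined] = np.nan
    return np.abs(np.clip(weights, -1.0, 1.0))


def build_network(assoc: AssociationMap, measure: str) -> SimilarityNetwork:
    """Build one normalized SNP network from a row-normalized map.

    Undefined raw scores become weight 0 (logged); the diagonal is forced to
    exactly 1 after any transform.
    """
    if not assoc.normalized:
        raise ValueError("build_network expects a row-normalized association map")
    values = assoc.values
    if measure in ("pearson", "spearman", "cosine"):
        weights = _correlation_weights(values, measure)
        n_undef = int(np.isnan(weights).sum())
        if n_undef:
            logger.warning(
                "%s network: %d undefined pairwise scores set to 0", measure, n_undef
            )
        weights = np.nan_to_num(weights, nan=0.0)
    elif measure in ("manhattan", "euclidean"):
        metric = "cityblock" if measure == "manhattan" else "euclidean"
        d = squareform(pdist(values, metric=metric))
        weights = distance_to_similarity(d)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    weights = (weights + weights.T) / 2.0
    np.fill_diagonal(weights, 1.0)
    return SimilarityNetwork(list(assoc.snp_ids), measure, weights)


def build_all_networks(assoc: AssociationMap) -> list[SimilarityNetwork]:
    """One network per measure, all sharing the map's SNP order."""
    return [build_network(assoc, m) for m in MEASURES]
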