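"""Sample-similarity metrics for contact maps and derived feature tables.

Two metrics:

* the stratum-adjusted correlation coefficient (SCC, HiCRep-style): both
  maps are mean-smoothed, Pearson correlations are computed within each
  genomic-distance stratum (diagonal), and averaged with weights
  proportional to stratum size times the geometric mean of the rank
  variances;

* the weighted Euclidean distance (WED) between samples embedded by PCA,

      WED_ij = sqrt( sum_n (PC_ni - PC_nj)^2 * w_n ),  n = 1..N,

  with w_n the fraction of variance explained by component n (N = 10 by
  default).  WED is a weighted Euclidean metric on the retained components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .matrix import ContactMatrix

__all__ = ["PCAEmbedding", "scc", "pca_embed", "weighted_distance"]


@dataclass
class PCAEmbedding:
    """Samples embedded on principal components with variance weights."""

    samples: tuple
    coords: np.ndarray        # (n_samples, N)
    weights: np.ndarray       # variance-explained fraction per component
    components: np.ndarray | None = None   # (N, n_vars) loadings
    mean: np.ndarray | None = None         # per-variable centring offset

    def reconstruct(self) -> np.ndarray:
        """Rebuild the (centred-and-shifted) input from the retained components."""
        if self.components is None or self.mean is None:
            raise ValueError("embedding carries no loadings")
        return self.coords @ self.components + self.mean

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or self.weights.sum() > 1 + 1e-9:
            raise ValueError("weights must be non-negative with sum <= 1")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be non-increasing")

    def index_of(self, sample) -> int:
        try:
            return self.samples.index(sample)
        except ValueError as exc:
            raise KeyError(f"unknown sample {sample!r}") from exc


def scc(
    a: ContactMatrix,
    b: ContactMatrix,
    max_dist: int = 5_000_000,
    smooth_span: int = 3,
) -> float:
    """Stratum-adjusted correlation coefficient between two cis maps.

    Both matrices are smoothed with a 2-D mean filter of ``smooth_span``
    bins; per-diagonal Pearson correlations over jointly valid bin pairs
    are then combined with weights ``N_d * sqrt(var(rank x_d) var(rank
    y_d))``.  Strata with zero variance in either map are skipped.  The
    self-comparison returns exactly 1; the metric is invariant to positive
    scaling of either map.
    """
    if a.chrom != b.chrom or a.n_bins != b.n_bins or a.binsize != b.binsize:
        raise ValueError("matrices must share chromosome and grid")
    if max_dist % a.binsize:
        raise ValueError("max_dist must be a multiple of the bin size")
    valid = a.valid & b.valid
    n = a.n_bins
    D = min(n - 1, max_dist // a.binsize)
    av = _smooth(np.where(valid[:, None] & valid[None, :], a.values, 0.0), smooth_span)
    bv = _smooth(np.where(valid[:, None] & valid[None, :], b.values, 0.0), smooth_span)
    num = 0.0
    den = 0.0
    used = 0
    for d in range(1, D + 1):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        if ok.sum() < 3:
            continue
        x = av[i[ok], j[ok]]
        y = bv[i[ok], j[ok]]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        w = len(x) * np.sqrt(
            np.var(stats.rankdata(x)) * np.var(stats.rankdata(y))
        )
        num += w * r
        den += w
        used += 1
    if used == 0 or den == 0:
        raise ValueError("no usable strata for SCC")
    return float(num / den)


def _smooth(values: np.ndarray, span: int) -> np.ndarray:
    """Box-mean smoothing with windows truncated at matrix borders.

    Normalising by the actual window coverage avoids the shared
    edge-shrinkage pattern zero-padding would imprint on both maps.
    """
    if span <= 1:
        return values
    total = ndimage.uniform_filter(values, size=span, mode="constant", cval=0.0)
    coverage = ndimage.uniform_filter(
        np.ones_like(values), size=span, mode="constant", cval=0.0
    )
    return total / coverage


def pca_embed(features: pd.DataFrame, N: int = 10) -> PCAEmbedding:
    """Centered PCA of a samples × variables table.

    Variables with any missing values are dropped.  Up to ``N`` components
    are retained; ``w_n`` is the eigenvalue fraction of total variance.
    Component signs follow a deterministic convention: the largest-magnitude
    loading of each component is made positive.
    """
    if len(features) < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = features.dropna(axis=1).to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("no complete variables left after dropping missing values")
    Xc = X - X.mean(axis=0)
    total_var = (Xc ** 2).sum()
    if total_var == 0:
        raise ValueError("zero-variance input")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: flip so the largest-|loading| entry is positive
    for k in range(len(S)):
        lead = np.argmax(np.abs(Vt[k]))
        if Vt[k, lead] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    keep = min(N, len(S))
    coords = (U * S)[:, :keep]
    weights = (S ** 2 / total_var)[:keep]
    return PCAEmbedding(
        samples=tuple(features.index),
        coords=coords,
        weights=weights,
        components=Vt[:keep],
        mean=X.mean(axis=0),
    )


def weighted_distance(e: PCAEmbedding, i, j) -> float:
    """Variance-weighted Euclidean distance between two embedded samples.

    Symmetric, zero iff the two samples coincide on all retained components,
    and homogeneous of degree 1 under coordinate scaling.
    """
    a = e.coords[e.index_of(i)]
    b = e.coords[e.index_of(j)]
    return float(np.sqrt(np.sum((a - b) ** 2 * e.weights)))
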