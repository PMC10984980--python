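"""Cis contact-matrix containers and the cleaning/normalisation pipeline.

The processing chain mirrors standard Hi-C compartment pipelines:

    raw counts -> filter_bins -> ice_normalize -> distance_correct
               -> correlation_matrix

``filter_bins`` removes bins dominated by long-range (artefactual) signal,
ICE balances bin marginals, distance correction turns counts into an
observed/expected ratio per genomic-distance stratum, and the final step
produces the median-filtered Pearson correlation matrix that compartment
eigenvector calling consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import GenomeGrid

__all__ = [
    "ContactMatrix",
    "CorrelationMatrix",
    "filter_bins",
    "ice_normalize",
    "distance_correct",
    "correlation_matrix",
]


@dataclass
class ContactMatrix:
    """A symmetric cis contact grid for one chromosome.

    Attributes
    ----------
    grid : GenomeGrid
        The binning the matrix lives on.
    chrom : str
        Chromosome name.
    values : (n, n) ndarray
        Symmetric, non-negative. Rows/columns of masked bins are all zero.
    valid : (n,) bool ndarray
        Per-bin validity mask; False bins are excluded from every statistic.
    stage : str
        One of ``raw``, ``iced``, ``oe`` (observed/expected).
    converged : bool
        Whether the last normalisation converged (meaningful after ICE).
    """

    grid: GenomeGrid
    chrom: str
    values: np.ndarray
    valid: np.ndarray | None = None
    stage: str = "raw"
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.grid.n_bins(self.chrom)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} != grid bins ({n}) for {self.chrom}"
            )
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(self.values) < 0:
            raise ValueError("contact matrix must be non-negative")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (n,):
                raise ValueError("valid mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def binsize(self) -> int:
        return self.grid.binsize

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.grid, self.chrom, self.values.copy(), self.valid.copy(),
            self.stage, self.converged,
        )


@dataclass
class CorrelationMatrix:
    """Pearson correlation of distance-corrected contact profiles.

    Masked bins carry NaN rows/columns; the diagonal is 1 on valid bins.
    """

    grid: GenomeGrid
    chrom: str
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


def _zero_masked(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = values.copy()
    out[~valid, :] = 0.0
    out[:, ~valid] = 0.0
    return out


def filter_bins(
    m: ContactMatrix,
    max_dist: int = 5_000_000,
    min_ratio: float = 1.0,
    include_diagonal: bool = False,
) -> ContactMatrix:
    """Mask bins dominated by long-range signal.

    A bin is kept when its ratio of mid-range cis contacts (pair distance
    below ``max_dist``) over its total contacts is at least ``min_ratio``;
    bins below the ratio, or with no contacts at all, are masked and their
    rows/columns zeroed.  Self-interactions (the main diagonal) are excluded
    from both numerator and denominator by default.

    Idempotent: re-filtering a filtered matrix changes nothing.
    """
    if max_dist % m.binsize != 0:
        raise ValueError("max_dist must be a multiple of the bin size")
    n = m.n_bins
    w = max_dist // m.binsize
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    vals = _zero_masked(m.values, m.valid)
    pair_ok = np.ones((n, n), dtype=bool) if include_diagonal else dist > 0
    total = np.where(pair_ok, vals, 0.0).sum(axis=1)
    mid = np.where(pair_ok & (dist < w), vals, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, mid / np.where(total > 0, total, 1.0), 0.0)
    keep = m.valid & (total > 0) & (ratio >= min_ratio)
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    return ContactMatrix(m.grid, m.chrom, _zero_masked(vals, keep), keep, m.stage)


def ice_normalize(
    m: ContactMatrix, max_iter: int = 100, tol: float = 1e-5
) -> ContactMatrix:
    """Iterative correction (ICE): balance valid-bin marginals.

    Each entry is repeatedly divided by the product of its row and column
    marginal (relative to their mean over valid bins) until the coefficient
    of variation of valid-bin sums drops below ``tol``.  Total matrix mass is
    rescaled to the input total, so ICE conserves signal.  Masked bins keep
    bias 1 and stay zero.

    On non-convergence the last iterate is returned with ``converged=False``
    and a warning.
    """
    if m.valid.sum() < 2:
        raise ValueError("ICE needs at least 2 valid bins")
    vals = _zero_masked(m.values, m.valid).astype(float)
    total0 = vals.sum()
    valid = m.valid
    converged = False
    for _ in range(max_iter):
        s = vals.sum(axis=1)
        sv = s[valid]
        mean = sv.mean()
        if mean == 0:
            raise ValueError("valid bins carry no signal")
        cv = sv.std() / mean
        if cv < tol:
            converged = True
            break
        b = np.ones_like(s)
        b[valid] = sv / mean
        b[b == 0] = 1.0
        vals = vals / np.outer(b, b)
    else:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (CV={cv:.2e})",
            stacklevel=2,
        )
    if vals.sum() > 0:
        vals *= total0 / vals.sum()
    return ContactMatrix(m.grid, m.chrom, vals, valid.copy(), "iced", converged)


def distance_correct(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected transform: divide each entry by its diagonal mean.

    The expected value at genomic distance ``d`` is the mean of the ``d``-th
    diagonal over pairs of valid bins.  Strata with zero mean map to zero
    (no division error).  The output has per-diagonal valid-bin mean 1
    wherever the stratum carries signal.
    """
    n = m.n_bins
    valid = m.valid
    vals = _zero_masked(m.values, valid)
    out = np.zeros_like(vals)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        pair_valid = valid[i] & valid[j]
        if not pair_valid.any():
            continue
        mu = vals[i[pair_valid], j[pair_valid]].mean()
        if mu <= 0:
            continue
        out[i, j] = vals[i, j] / mu
        out[j, i] = out[i, j]
    return ContactMatrix(m.grid, m.chrom, out, valid.copy(), "oe", m.converged)


def _nanmedian_filter(grid: np.ndarray, size: int) -> np.ndarray:
    """2-D median filter ignoring NaNs; windows truncate at borders."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return ndimage.generic_filter(
            grid, np.nanmedian, size=size, mode="constant", cval=np.nan
        )


def correlation_matrix(
    m: ContactMatrix, median_filter_bins: int = 3
) -> CorrelationMatrix:
    """Pearson correlation of observed/expected bin profiles, median filtered.

    Correlations are computed between valid-bin rows of the O/E matrix.
    Genomic-distance strata that carry no signal at all (entirely zero
    diagonals, e.g. beyond the contact support of the map) are treated as
    unsupported rather than as observed zeros: each pair of rows is
    correlated over the columns that lie in supported strata of *both*
    rows (pairwise-complete).  When every stratum is supported — the usual
    case for a fully populated chromosome — this reduces exactly to the
    plain row-wise Pearson correlation.

    A square median filter of ``median_filter_bins`` bins then damps
    isolated noise (mask-aware: masked bins are NaN and excluded from
    windows; windows truncate at matrix borders).  The diagonal is restored
    to 1.
    """
    valid = m.valid.copy()
    # zero-variance rows cannot be correlated; fold them into the mask
    sub = m.values[np.ix_(valid, valid)]
    row_var = sub.var(axis=1)
    valid_idx = np.flatnonzero(valid)
    valid[valid_idx[row_var == 0]] = False
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid bins for a correlation matrix")
    n = m.n_bins
    vidx = np.flatnonzero(valid)
    sub = m.values[np.ix_(valid, valid)]
    k = len(vidx)

    # supported strata: diagonals (in full-matrix coordinates) with signal
    idx = np.arange(n)
    dist_full = np.abs(idx[:, None] - idx[None, :])
    support = np.zeros(n, dtype=bool)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        if ok.any() and np.any(m.values[i[ok], j[ok]] != 0):
            support[d] = True
    dist_sub = dist_full[np.ix_(valid, valid)]
    supported_sub = support[dist_sub]

    if supported_sub.all():
        corr_sub = np.corrcoef(sub)
    else:
        X = np.where(supported_sub, sub, np.nan)
        corr_sub = np.full((k, k), np.nan)
        finite = np.isfinite(X)
        for a in range(k):
            for b in range(a, k):
                ok = finite[a] & finite[b]
                if ok.sum() < 3:
                    continue
                x, y = X[a, ok], X[b, ok]
                if x.std() == 0 or y.std() == 0:
                    continue
                corr_sub[a, b] = corr_sub[b, a] = np.corrcoef(x, y)[0, 1]
        corr_sub[~np.isfinite(corr_sub)] = 0.0  # undefined pairs carry no signal

    corr = np.full((n, n), np.nan)
    corr[np.ix_(valid, valid)] = corr_sub
    if median_filter_bins and median_filter_bins > 1:
        corr = _nanmedian_filter(corr, median_filter_bins)
        corr[~valid, :] = np.nan
        corr[:, ~valid] = np.nan
        corr = (corr + corr.T) / 2  # median windows are asymmetric at mask edges
    corr[np.diag_indices(n)] = np.where(valid, 1.0, np.nan)
    return CorrelationMatrix(m.grid, m.chrom, corr, valid)
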