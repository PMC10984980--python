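"""A/B compartment calling and time-course compartment dynamics.

Compartments are called independently per chromosome and time point at
100 kb resolution.  The leading eigenvectors of the median-filtered
correlation matrix are computed on valid bins; one eigenvector is selected
(by default the one most correlated with a transcriptional-activity track)
and oriented so that positive values mark the active A compartment.  A
bounded sigmoid transform of the oriented eigenvector — ``tanh(e / 2σ)``
with σ the per-chromosome standard deviation — damps outliers and yields
the per-bin *compartment score* in (−1, 1); its sign gives the A/B label.

Across a time course, bins whose label changes between any two time points
are *dynamic*; their score trajectories are grouped by Ward hierarchical
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.cluster import hierarchy

from .matrix import ContactMatrix, CorrelationMatrix

__all__ = [
    "CompartmentProfile",
    "CompartmentDynamics",
    "leading_eigenvectors",
    "select_and_orient",
    "sigmoid_score",
    "call_compartments",
    "classify_and_cluster_dynamics",
]


@dataclass
class CompartmentProfile:
    """Per-bin compartment scores for one chromosome at one time point."""

    chrom: str
    binsize: int
    eigenvector: np.ndarray          # oriented, NaN on masked bins
    eigenvector_index: int           # 1-based index of the chosen eigenvector
    orientation_sign: int            # +1 or -1 applied to the raw eigenvector
    score: np.ndarray                # sigmoid-transformed, NaN on masked bins
    diagnostics: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        """Per-bin label: 'A' (score > 0), 'B' (score < 0), '.' otherwise."""
        lab = np.full(self.score.shape, ".", dtype=object)
        lab[self.score > 0] = "A"
        lab[self.score < 0] = "B"
        return lab

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.score)


@dataclass
class CompartmentDynamics:
    """Per-bin compartment behaviour across an ordered time course."""

    bins: np.ndarray                 # indices of bins valid at every time point
    category: np.ndarray             # 'stable A' | 'stable B' | 'dynamic' per bin
    trajectories: np.ndarray         # (n_bins, T) score matrix
    switch_counts: dict              # (t_i, t_j) -> {'A->B': int, 'B->A': int}
    cluster_ids: np.ndarray          # cluster id per bin (0 for non-dynamic)
    time_points: tuple

    @property
    def dynamic_fraction(self) -> float:
        return float(np.mean(self.category == "dynamic"))


def leading_eigenvectors(c: CorrelationMatrix, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` eigenpairs of the valid-bin submatrix, by descending eigenvalue.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvectors as columns of an
    ``(n_bins, k)`` array re-embedded to full bin coordinates (NaN on masked
    bins) and normalised to unit norm.
    """
    valid = c.valid
    n_valid = int(valid.sum())
    if k > n_valid:
        raise ValueError(f"k={k} exceeds the {n_valid} valid bins")
    sub = c.values[np.ix_(valid, valid)]
    if not np.all(np.isfinite(sub)):
        raise ValueError("correlation matrix has non-finite entries on valid bins")
    w, v = linalg.eigh(sub)
    order = np.argsort(w)[::-1][:k]
    evals = w[order]
    evecs = np.full((c.values.shape[0], k), np.nan)
    for out_col, col in enumerate(order):
        vec = v[:, col]
        evecs[valid, out_col] = vec / np.linalg.norm(vec)
    return evals, evecs


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def select_and_orient(
    eigenvalues: np.ndarray,
    eigenvectors: np.ndarray,
    activity: np.ndarray,
    gc: np.ndarray | None = None,
    override: int | None = None,
) -> tuple[int, int, dict]:
    """Choose the compartment eigenvector and its orientation.

    Default selection takes the eigenvector with maximum absolute Pearson
    correlation with the activity track (H3K27ac / expression), falling back
    to GC content when the activity track is degenerate.  The sign is set so
    the correlation with the selection track is positive, i.e. positive
    values mark the A compartment.  ``override`` forces a 1-based eigenvector
    index (the per-chromosome manual choice; e.g. the second eigenvector on
    some chromosomes) but the orientation rule still applies.

    Returns ``(index_1based, sign, diagnostics)`` where diagnostics carry all
    candidate correlations with both tracks and the eigenvalues.
    """
    k = eigenvectors.shape[1]
    act_corr = np.array([_pearson(eigenvectors[:, i], activity) for i in range(k)])
    gc_corr = (
        np.array([_pearson(eigenvectors[:, i], gc) for i in range(k)])
        if gc is not None
        else np.full(k, np.nan)
    )
    diagnostics = {
        "eigenvalues": np.asarray(eigenvalues),
        "activity_correlation": act_corr,
        "gc_correlation": gc_corr,
    }
    ref = act_corr
    if np.all(~np.isfinite(act_corr)):
        if gc is None or np.all(~np.isfinite(gc_corr)):
            raise ValueError("both activity and GC tracks are degenerate")
        ref = gc_corr
    if override is not None:
        if not 1 <= override <= k:
            raise ValueError(f"override index {override} outside 1..{k}")
        idx = override - 1
    else:
        idx = int(np.nanargmax(np.abs(ref)))
    r = ref[idx]
    sign = 1 if (not np.isfinite(r) or r >= 0) else -1
    return idx + 1, sign, diagnostics


def sigmoid_score(eigvec: np.ndarray) -> np.ndarray:
    """Bounded compartment score: ``tanh(e / 2σ)`` per chromosome.

    σ is the standard deviation of the oriented eigenvector over valid
    (finite) bins, so the score is invariant to positive rescaling of the
    eigenvector, strictly monotone, sign-preserving and bounded in (−1, 1).
    A zero-variance eigenvector maps to all-zero scores with a warning.
    """
    e = np.asarray(eigvec, dtype=float)
    ok = np.isfinite(e)
    sigma = e[ok].std() if ok.any() else 0.0
    if sigma == 0:
        warnings.warn("zero-variance eigenvector: all compartment scores set to 0", stacklevel=2)
        out = np.where(ok, 0.0, np.nan)
        return out
    return np.tanh(e / (2.0 * sigma))


def call_compartments(
    corr: CorrelationMatrix,
    activity: np.ndarray,
    gc: np.ndarray | None = None,
    k: int = 3,
    override: int | None = None,
) -> CompartmentProfile:
    """Full per-chromosome compartment call from a correlation matrix."""
    evals, evecs = leading_eigenvectors(corr, k=k)
    idx, sign, diag = select_and_orient(evals, evecs, activity, gc, override=override)
    oriented = sign * evecs[:, idx - 1]
    return CompartmentProfile(
        chrom=corr.chrom,
        binsize=corr.grid.binsize,
        eigenvector=oriented,
        eigenvector_index=idx,
        orientation_sign=sign,
        score=sigmoid_score(oriented),
        diagnostics=diag,
    )


def classify_and_cluster_dynamics(
    profiles: Sequence[CompartmentProfile],
    n_clusters: int = 7,
    time_points: Sequence[str] | None = None,
) -> CompartmentDynamics:
    """Classify bins as stable A / stable B / dynamic and cluster the dynamic ones.

    Bins masked at any time point are excluded.  A bin is *dynamic* when its
    A/B label changes between any two time points; otherwise it is stable A
    or stable B.  Pairwise A→B / B→A switch counts are tallied for every
    ordered pair of time points.  Dynamic-bin score trajectories are grouped
    by Ward hierarchical clustering cut at ``n_clusters``; cluster ids are
    renumbered by first occurrence so they are stable for a fixed input.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 time points")
    T = len(profiles)
    tps = tuple(time_points) if time_points is not None else tuple(range(T))
    if len(tps) != T:
        raise ValueError("time_points length mismatch")
    scores = np.vstack([p.score for p in profiles])     # (T, n)
    ok = np.all(np.isfinite(scores), axis=0)
    bins = np.flatnonzero(ok)
    traj = scores[:, ok].T                              # (n_ok, T)
    signs = np.sign(traj)
    all_a = np.all(signs > 0, axis=1)
    all_b = np.all(signs < 0, axis=1)
    category = np.full(len(bins), "dynamic", dtype=object)
    category[all_a] = "stable A"
    category[all_b] = "stable B"

    switch_counts: dict = {}
    for i in range(T):
        for j in range(i + 1, T):
            a2b = int(np.sum((signs[:, i] > 0) & (signs[:, j] < 0)))
            b2a = int(np.sum((signs[:, i] < 0) & (signs[:, j] > 0)))
            switch_counts[(tps[i], tps[j])] = {"A->B": a2b, "B->A": b2a}

    cluster_ids = np.zeros(len(bins), dtype=int)
    dyn = category == "dynamic"
    n_dyn = int(dyn.sum())
    if n_dyn:
        kk = min(n_clusters, n_dyn)
        if n_dyn == 1:
            raw = np.array([1])
        else:
            link = hierarchy.linkage(traj[dyn], method="ward")
            raw = hierarchy.fcluster(link, t=kk, criterion="maxclust")
        relabel: dict[int, int] = {}
        stable_ids = np.empty_like(raw)
        for pos, r in enumerate(raw):
            if r not in relabel:
                relabel[r] = len(relabel) + 1
            stable_ids[pos] = relabel[r]
        cluster_ids[dyn] = stable_ids

    return CompartmentDynamics(
        bins=bins,
        category=category,
        trajectories=traj,
        switch_counts=switch_counts,
        cluster_ids=cluster_ids,
        time_points=tps,
    )
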