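"""Regulome integration: from peaks and promoter-anchored loops to targets.

This module links transcription-factor binding to the genes it regulates,
following the logic of a Nutlin-3a p53-activation time course (0 h, 1 h,
10 h):

* promoters are 1000 bp upstream to 200 bp downstream of the TSS,
  strand-aware;
* enhancers are intersections of H3K4me1 and H3K27ac consensus peaks,
  merged across time points and excluded from promoter windows, with a
  per-time-point state (primed = H3K4me1 only, active = both marks);
* a p53 binding site is *functional* when it overlaps an H3K27ac peak by at
  least 1 bp at an activation time point (1 h or 10 h);
* functional sites are classified promoter-bound > enhancer-bound >
  other-distal;
* proximal targets are genes with a functional site in their promoter;
  distal targets are baits of high-confidence interactions (score >= 5)
  whose other end overlaps an enhancer-bound site, prioritised by the
  largest gain in promoter H3K27ac (mean log2 fold change, exact ties all
  kept);
* a distal target is *primed* when its supporting loop already exists at
  0 h, and a *neo-loop* target otherwise.

Differential H3K27ac uses background-based median-of-ratios size factors
(10-kb bins outside enriched regions) and a pseudocount log2 fold change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy

from .grid import AnnotatedGene, Interval, overlap_length, overlaps
from .io import InteractionRecord

__all__ = [
    "Promoter",
    "EnhancerElement",
    "FunctionalP53Site",
    "TargetAssignment",
    "define_promoters",
    "call_enhancers",
    "functional_sites",
    "classify_sites",
    "size_factors_background",
    "log2fc",
    "assign_targets",
    "classify_priming",
    "interaction_dynamics",
    "PATTERN_CLUSTER_IDS",
]

ACTIVATION_TIME_POINTS = ("1h", "10h")


@dataclass(frozen=True)
class Promoter:
    """Strand-aware promoter window of one gene (−1000/+200 bp of the TSS)."""

    gene_id: str
    window: Interval
    tss: int
    strand: str


@dataclass(frozen=True)
class EnhancerElement:
    """A consensus enhancer element with a chromatin state per time point.

    States: ``absent`` (no H3K4me1), ``primed`` (H3K4me1 only), ``active``
    (H3K4me1 and H3K27ac).
    """

    interval: Interval
    states: tuple[tuple[str, str], ...]   # ((time_point, state), ...)

    def state(self, time_point: str) -> str:
        for tp, s in self.states:
            if tp == time_point:
                return s
        raise KeyError(time_point)

    def active_at_any(self, time_points: Iterable[str]) -> bool:
        return any(self.state(tp) == "active" for tp in time_points)


@dataclass(frozen=True)
class FunctionalP53Site:
    """A p53 peak supported by H3K27ac at an activation time point."""

    peak: Interval
    support: tuple[str, ...]              # activation time points with K27ac overlap
    site_class: str = "unclassified"      # promoter-bound | enhancer-bound | other-distal


@dataclass(frozen=True)
class TargetAssignment:
    """A p53 site → gene link with its supporting evidence."""

    site: FunctionalP53Site
    gene_id: str
    mode: str                             # proximal | distal
    time_point: str
    distance: float                       # |site midpoint - TSS|, bp
    log2fc: float | None = None           # prioritizing promoter H3K27ac gain
    primed: bool | None = None            # distal only; set by classify_priming
    nearest_gene: bool | None = None


# ---------------------------------------------------------------------------
# interval machinery


def _build_tree(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _hits(trees: Mapping[str, IntervalTree], query: Interval) -> list[Interval]:
    tree = trees.get(query.chrom)
    if tree is None:
        return []
    return [h.data for h in tree.overlap(query.start, query.end)]


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals per chromosome."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out


def _intersect_sets(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Pairwise intersection regions of two peak sets (merged afterwards)."""
    trees = _build_tree(b)
    pieces = []
    for iv in a:
        for hit in _hits(trees, iv):
            start = max(iv.start, hit.start)
            end = min(iv.end, hit.end)
            if start < end:
                pieces.append(Interval(iv.chrom, start, end))
    return _merge(pieces) if pieces else []


# ---------------------------------------------------------------------------
# elements


def define_promoters(
    genes: Sequence[AnnotatedGene],
    upstream: int = 1000,
    downstream: int = 200,
    chromsizes: Mapping[str, int] | None = None,
) -> list[Promoter]:
    """Promoter windows spanning ``upstream`` bp 5' to ``downstream`` bp 3' of the TSS.

    One promoter per gene id — the first annotated TSS wins when a gene id
    recurs.  Windows are clipped at chromosome edges when sizes are given.
    """
    seen: set[str] = set()
    out: list[Promoter] = []
    for g in genes:
        if g.gene_id in seen:
            continue
        seen.add(g.gene_id)
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        start = max(0, start)
        if chromsizes is not None:
            end = min(end, chromsizes[g.chrom])
        out.append(Promoter(g.gene_id, Interval(g.chrom, start, end), g.tss, g.strand))
    return out


def call_enhancers(
    k4me1: Mapping[str, Sequence[Interval]],
    k27ac: Mapping[str, Sequence[Interval]],
    promoters: Sequence[Promoter],
    time_points: Sequence[str] | None = None,
) -> list[EnhancerElement]:
    """Consensus enhancers with a per-time-point activity state.

    Per time point an enhancer is the intersection region of an H3K4me1 and
    an H3K27ac peak; the consensus set is the merged union across time
    points, with any element overlapping a promoter window (>= 1 bp)
    removed.  Element states per time point come from mark presence on the
    consensus interval: both marks → active, H3K4me1 only → primed,
    otherwise (including H3K27ac only) → absent.
    """
    tps = list(time_points) if time_points is not None else list(k4me1)
    per_tp = []
    for tp in tps:
        per_tp.extend(_intersect_sets(list(k4me1.get(tp, [])), list(k27ac.get(tp, []))))
    if not per_tp:
        return []
    consensus = _merge(per_tp)
    prom_tree = _build_tree([p.window for p in promoters])
    k4_trees = {tp: _build_tree(k4me1.get(tp, [])) for tp in tps}
    k27_trees = {tp: _build_tree(k27ac.get(tp, [])) for tp in tps}
    out = []
    for iv in consensus:
        if any(overlaps(iv, h) for h in _hits(prom_tree, iv)):
            continue
        states = []
        for tp in tps:
            has_k4 = any(overlaps(iv, h) for h in _hits(k4_trees[tp], iv))
            has_k27 = any(overlaps(iv, h) for h in _hits(k27_trees[tp], iv))
            if has_k4 and has_k27:
                states.append((tp, "active"))
            elif has_k4:
                states.append((tp, "primed"))
            else:
                states.append((tp, "absent"))
        out.append(EnhancerElement(iv, tuple(states)))
    return out


def functional_sites(
    p53_peaks: Sequence[Interval],
    k27ac_by_tp: Mapping[str, Sequence[Interval]],
    activation_time_points: Sequence[str] = ACTIVATION_TIME_POINTS,
) -> list[FunctionalP53Site]:
    """p53 peaks overlapping (>= 1 bp) H3K27ac at an activation time point."""
    trees = {tp: _build_tree(k27ac_by_tp.get(tp, [])) for tp in activation_time_points}
    out = []
    for peak in p53_peaks:
        support = tuple(
            tp
            for tp in activation_time_points
            if any(overlaps(peak, h) for h in _hits(trees[tp], peak))
        )
        if support:
            out.append(FunctionalP53Site(peak, support))
    return out


def classify_sites(
    sites: Sequence[FunctionalP53Site],
    promoters: Sequence[Promoter],
    enhancers: Sequence[EnhancerElement],
    activation_time_points: Sequence[str] = ACTIVATION_TIME_POINTS,
) -> list[FunctionalP53Site]:
    """Classify functional sites: promoter-bound > enhancer-bound > other-distal.

    Promoter overlap takes precedence; enhancer-bound requires overlap with
    an element active at an activation time point.
    """
    prom_tree = _build_tree([p.window for p in promoters])
    enh_tree = _build_tree(
        [e.interval for e in enhancers if e.active_at_any(activation_time_points)]
    )
    out = []
    for s in sites:
        if any(overlaps(s.peak, h) for h in _hits(prom_tree, s.peak)):
            cls = "promoter-bound"
        elif any(overlaps(s.peak, h) for h in _hits(enh_tree, s.peak)):
            cls = "enhancer-bound"
        else:
            cls = "other-distal"
        out.append(replace(s, site_class=cls))
    return out


# ---------------------------------------------------------------------------
# differential signal


def size_factors_background(
    counts: pd.DataFrame,
    bins: Sequence[Interval],
    enriched: Sequence[Interval],
) -> pd.Series:
    """Median-of-ratios size factors from background genomic bins.

    ``counts`` is a bins × samples table aligned with ``bins`` (typically
    10-kb genomic bins); bins overlapping any enriched region are excluded,
    so factors reflect background depth only.  Each factor is the median
    over usable background bins of (bin count / geometric mean of the bin
    across samples); bins whose geometric mean is zero are skipped, and the
    factors are normalised to geometric mean 1.
    """
    if len(counts) != len(bins):
        raise ValueError("counts rows must align with bins")
    enr_tree = _build_tree(enriched)
    background = np.array(
        [not any(overlaps(b, h) for h in _hits(enr_tree, b)) for b in bins]
    )
    X = counts.to_numpy(dtype=float)[background]
    if X.size == 0:
        raise ValueError("no usable background bins")
    if np.any(X.sum(axis=0) == 0):
        raise ValueError("a sample has zero background signal")
    with np.errstate(divide="ignore"):
        log_geo = np.log(X).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no background bin with non-zero counts in every sample")
    ratios = X[usable] / np.exp(log_geo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor")
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2fc(
    counts: pd.DataFrame,
    factors: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Mean log2 fold change (B over A) of size-factor-normalised counts.

    ``log2((mean_B + pseudocount) / (mean_A + pseudocount))`` per region;
    the pseudocount keeps the statistic finite at zero counts.
    """
    norm = counts / factors
    mean_a = norm[list(group_a)].mean(axis=1)
    mean_b = norm[list(group_b)].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount)).rename("log2fc")


# ---------------------------------------------------------------------------
# target assignment


def assign_targets(
    sites: Sequence[FunctionalP53Site],
    promoters: Sequence[Promoter],
    enhancers: Sequence[EnhancerElement],
    interactions: Sequence[InteractionRecord],
    promoter_log2fc: Mapping[str, float],
    time_point: str,
    genes: Sequence[AnnotatedGene] | None = None,
    threshold: float = 5.0,
    activation_time_points: Sequence[str] = ACTIVATION_TIME_POINTS,
) -> list[TargetAssignment]:
    """Assign proximal and distal target genes to classified p53 sites.

    Promoter-bound sites proximally target every gene whose promoter they
    overlap.  Each enhancer-bound site distally targets the bait gene(s) of
    interactions significant at ``time_point`` (score >= ``threshold``)
    whose other end overlaps the site by >= 1 bp; among candidates the
    gene(s) with the maximal promoter H3K27ac log2 fold change are kept —
    exact ties are all retained.  Other-distal sites yield nothing.

    When the full gene annotation is supplied, each assignment is flagged
    with whether the assigned gene is the nearest gene to the site (minimal
    TSS distance to the site midpoint, strand-ignorant).
    """
    prom_by_gene = {p.gene_id: p for p in promoters}
    prom_tree = _build_tree([p.window for p in promoters])
    window_to_gene = {(p.window.chrom, p.window.start, p.window.end): p.gene_id for p in promoters}
    out: list[TargetAssignment] = []

    def nearest_flag(site: FunctionalP53Site, gene_id: str) -> bool | None:
        if genes is None:
            return None
        mid = site.peak.midpoint
        dists = {
            g.gene_id: abs(g.tss - mid) for g in genes if g.chrom == site.peak.chrom
        }
        if gene_id not in dists:
            return None
        return dists[gene_id] == min(dists.values())

    for site in sites:
        if site.site_class == "promoter-bound":
            for hit in _hits(prom_tree, site.peak):
                if not overlaps(site.peak, hit):
                    continue
                gid = window_to_gene[(hit.chrom, hit.start, hit.end)]
                prom = prom_by_gene[gid]
                out.append(
                    TargetAssignment(
                        site=site,
                        gene_id=gid,
                        mode="proximal",
                        time_point=time_point,
                        distance=abs(site.peak.midpoint - prom.tss),
                        log2fc=promoter_log2fc.get(gid),
                        nearest_gene=nearest_flag(site, gid),
                    )
                )
        elif site.site_class == "enhancer-bound":
            candidates: dict[str, InteractionRecord] = {}
            for rec in interactions:
                if rec.scores.get(time_point, -np.inf) < threshold:
                    continue
                if not overlaps(site.peak, rec.other_end):
                    continue
                for gid in rec.bait_genes:
                    if gid in prom_by_gene:
                        candidates.setdefault(gid, rec)
            if not candidates:
                continue
            scored = {
                gid: promoter_log2fc.get(gid) for gid in candidates
            }
            if all(v is None for v in scored.values()):
                continue
            best = max(v for v in scored.values() if v is not None)
            for gid, fc in sorted(scored.items()):
                if fc is None or fc != best:
                    continue
                prom = prom_by_gene[gid]
                out.append(
                    TargetAssignment(
                        site=site,
                        gene_id=gid,
                        mode="distal",
                        time_point=time_point,
                        distance=abs(site.peak.midpoint - prom.tss),
                        log2fc=fc,
                        nearest_gene=nearest_flag(site, gid),
                    )
                )
    return out


def classify_priming(
    assignments: Sequence[TargetAssignment],
    interactions: Sequence[InteractionRecord],
    baseline: str = "0h",
    threshold: float = 5.0,
) -> list[TargetAssignment]:
    """Flag distal targets as primed (loop already present at baseline) or neo.

    A distal assignment is *primed* when some interaction linking the
    site's fragment to the gene's bait is significant at the baseline time
    point as well; otherwise the loop formed upon activation (neo-loop).
    Proximal assignments pass through unchanged.
    """
    out = []
    for a in assignments:
        if a.mode != "distal":
            out.append(a)
            continue
        primed = any(
            rec.scores.get(baseline, -np.inf) >= threshold
            and a.gene_id in rec.bait_genes
            and overlaps(a.site.peak, rec.other_end)
            for rec in interactions
        )
        out.append(replace(a, primed=primed))
    return out


def assignments_to_frame(assignments: Sequence[TargetAssignment]) -> pd.DataFrame:
    """Deterministic tabular form of a target-assignment list.

    Rows are sorted by (chromosome, site start, gene id); tri-state flags
    render as ``True`` / ``False`` / ``.`` so the table is stable enough to
    diff byte-for-byte.
    """
    def flag(v) -> str:
        return "." if v is None else str(bool(v))

    rows = [
        {
            "site_chrom": a.site.peak.chrom,
            "site_start": a.site.peak.start,
            "site_end": a.site.peak.end,
            "site_class": a.site.site_class,
            "gene": a.gene_id,
            "mode": a.mode,
            "time_point": a.time_point,
            "distance": format(a.distance, "g"),
            "log2fc": "." if a.log2fc is None else format(a.log2fc, "g"),
            "primed": flag(a.primed),
            "nearest_gene": flag(a.nearest_gene),
        }
        for a in sorted(
            assignments, key=lambda a: (a.site.peak.chrom, a.site.peak.start, a.gene_id)
        )
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_chrom", "site_start", "site_end", "site_class", "gene", "mode",
            "time_point", "distance", "log2fc", "primed", "nearest_gene",
        ],
    )


def write_assignments(path, assignments: Sequence[TargetAssignment]) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


# lexicographic enumeration of non-empty significance patterns over
# (0 h, 1 h, 10 h); the mapping to narrative cluster names lives in docs
PATTERN_CLUSTER_IDS: dict[tuple[int, ...], str] = {
    p: f"C{i}"
    for i, p in enumerate(
        sorted(p for p in itertools.product((0, 1), repeat=3) if any(p)), start=1
    )
}


def interaction_dynamics(
    interactions: Sequence[InteractionRecord],
    time_points: Sequence[str],
    threshold: float = 5.0,
) -> pd.DataFrame:
    """Classify per-pair loop dynamics and group records by significance pattern.

    For every ordered pair of time points a record is *gained*
    (non-significant → significant), *lost*, *maintained* (significant at
    both) or absent.  Records significant at at least one time point get a
    cluster id C1–C7 — their significance pattern over the time course —
    and, within each pattern, an ordering from complete-linkage
    hierarchical clustering of asinh-transformed scores.
    """
    if len(time_points) < 2:
        raise ValueError("need at least 2 time points")
    tps = list(time_points)
    rows = []
    for idx, rec in enumerate(interactions):
        pattern = rec.significance_pattern(tps, threshold)
        row: dict = {
            "record": idx,
            "pattern": pattern,
            "cluster": PATTERN_CLUSTER_IDS.get(pattern) if len(tps) == 3 else None,
        }
        for i, j in itertools.combinations(range(len(tps)), 2):
            key = f"{tps[i]}->{tps[j]}"
            if pattern[i] == 0 and pattern[j] == 1:
                row[key] = "gained"
            elif pattern[i] == 1 and pattern[j] == 0:
                row[key] = "lost"
            elif pattern[i] == 1 and pattern[j] == 1:
                row[key] = "maintained"
            else:
                row[key] = "absent"
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["within_order"] = -1
    scores = np.asinh(
        np.array([[rec.scores[t] for t in tps] for rec in interactions], dtype=float)
    )
    for pattern, sub in df[df["cluster"].notna()].groupby("pattern"):
        idx = sub.index.to_numpy()
        if len(idx) == 1:
            df.loc[idx, "within_order"] = 0
            continue
        link = hierarchy.linkage(scores[sub["record"].to_numpy()], method="complete")
        order = hierarchy.leaves_list(link)
        for rank, leaf in enumerate(order):
            df.loc[idx[leaf], "within_order"] = rank
    return df
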