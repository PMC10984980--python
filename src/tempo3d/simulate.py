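"""Seeded synthetic-data generators with machine-readable ground truth.

Every input class the pipeline consumes can be generated at desk scale with
known truth, so each stage is testable without downloads:

* contact maps — Poisson counts around an expected surface combining
  power-law distance decay, a planted A/B checkerboard and planted TAD
  blocks:  ``lambda_ij = depth * (1+|i-j|)^(-alpha) * c^(s_i*s_j) *
  t^[same TAD]`` with planted labels ``s`` in {-1,+1}, compartment strength
  ``c >= 1`` and TAD fold ``t >= 1``;
* time courses — selected bins flip compartment label and selected TAD
  junctions appear/disappear at chosen time points, with independent
  Poisson noise per time point;
* peak sets and count tables — p53/H3K4me1/H3K27ac peaks with controlled
  overlap structure, negative-binomial region counts with planted log2
  fold changes and per-sample scale factors;
* interaction tables — CHiCAGO-style scores drawn above the significance
  threshold for planted loops at their active time points (shifted gamma)
  and below it for decoys, with primed loops significant at 0 h.

All draws go through ``numpy.random.default_rng`` (PCG64, integer state),
so a fixed seed reproduces every output bit-exactly across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import AnnotatedGene, GenomeGrid, Interval
from .io import InteractionRecord
from .matrix import ContactMatrix
from .regulome import Promoter, define_promoters

__all__ = [
    "RegulomeData",
    "default_checkerboard",
    "make_contact_map",
    "make_timecourse",
    "make_peaks_and_counts",
    "make_interactions",
    "make_regulome",
    "write_preset",
]

TIME_POINTS = ("0h", "1h", "10h")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def default_checkerboard(n_bins: int, block: int = 10) -> np.ndarray:
    """Alternating blocks of +1/-1 labels (1 Mb blocks at 100 kb bins)."""
    return np.array([1 if (b // block) % 2 == 0 else -1 for b in range(n_bins)])


def _tad_ids(n_bins: int, junctions: Sequence[int]) -> np.ndarray:
    """TAD membership per bin; a junction at j starts a new domain at bin j."""
    ids = np.zeros(n_bins, dtype=int)
    for j in sorted(junctions):
        ids[j:] += 1
    return ids


def make_contact_map(
    seed,
    n_bins: int = 100,
    binsize: int = 100_000,
    depth: float = 500.0,
    alpha: float = 1.0,
    comp_strength: float = 2.0,
    tad_fold: float = 1.0,
    labels: np.ndarray | None = None,
    junctions: Sequence[int] = (),
    chrom: str = "chrS",
    max_range: int | None = 5_000_000,
) -> tuple[ContactMatrix, dict]:
    """One synthetic cis contact map plus its planted truth.

    Expected counts follow distance decay modulated by compartment and TAD
    structure; observed counts are Poisson.  Defaults emulate a 10 Mb
    chromosome at 100 kb with paper-like mid-range coverage; expected
    contacts are truncated beyond ``max_range`` (5 Mb), mirroring the
    mid-range support the downstream bin filter assumes — bins with
    long-range signal are exactly the artefacts that filter masks.
    """
    if n_bins < 40:
        raise ValueError("need at least 40 bins")
    if depth <= 0 or alpha <= 0:
        raise ValueError("depth and alpha must be positive")
    if comp_strength < 1 or tad_fold < 1:
        raise ValueError("comp_strength and tad_fold must be >= 1")
    rng = _rng(seed)
    if labels is None:
        labels = default_checkerboard(n_bins)
    labels = np.asarray(labels)
    if labels.shape != (n_bins,) or not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be +/-1 per bin")
    tids = _tad_ids(n_bins, junctions)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = depth * (1.0 + dist) ** (-alpha)
    lam *= comp_strength ** (labels[:, None] * labels[None, :]).astype(float)
    lam *= np.where(tids[:, None] == tids[None, :], tad_fold, 1.0)
    if max_range is not None:
        lam[dist * binsize >= max_range] = 0.0
    upper = np.triu(rng.poisson(lam), k=0)
    counts = upper + np.triu(upper, k=1).T
    truth = {
        "chrom": chrom,
        "n_bins": n_bins,
        "binsize": binsize,
        "depth": depth,
        "alpha": alpha,
        "comp_strength": comp_strength,
        "tad_fold": tad_fold,
        "labels": labels.tolist(),
        "junctions": sorted(int(j) for j in junctions),
    }
    grid = GenomeGrid({chrom: n_bins * binsize}, binsize)
    return ContactMatrix(grid, chrom, counts.astype(float)), truth


def make_timecourse(
    seed,
    T: int = 6,
    n_bins: int = 100,
    binsize: int = 100_000,
    switch_fraction: float = 0.125,
    switch_run: int = 3,
    junction_events: Sequence[tuple[int, int, str]] = (),
    junctions: Sequence[int] = (),
    **map_params,
) -> tuple[list[ContactMatrix], dict]:
    """A contact-map time course with planted compartment and border dynamics.

    A fraction of bins (12.5 % by default, the scale of the compartment
    switching the analysis is built to detect) flips its A/B label at a
    random time point and stays flipped.  Switching bins come in contiguous
    runs of ``switch_run`` bins (300 kb at 100 kb resolution) — compartment
    switches span regions, not isolated bins, and the correlation-matrix
    median filter deliberately suppresses single-bin flips as noise.
    ``junction_events`` is a list of ``(junction_bin, time_index,
    'gain'|'loss')``: the junction (dis)appears from that time point
    onwards.  Each time point gets independent Poisson noise; everything
    else is held fixed.
    """
    if not 0 <= switch_fraction <= 1:
        raise ValueError("switch_fraction must be in [0, 1]")
    if T < 2:
        raise ValueError("need at least 2 time points")
    rng = _rng(seed)
    base_labels = default_checkerboard(n_bins)
    n_switch = int(round(switch_fraction * n_bins))
    n_runs = max(1, round(n_switch / switch_run)) if n_switch else 0
    starts: list[int] = []
    if n_runs:
        for s in rng.permutation(n_bins - switch_run + 1):
            if all(abs(s - t) >= switch_run + 1 for t in starts):
                starts.append(int(s))
            if len(starts) == n_runs:
                break
    switch_bins = np.sort(
        np.concatenate([np.arange(s, s + switch_run) for s in starts])
        if starts
        else np.array([], dtype=int)
    )
    run_times = rng.integers(1, T, size=len(starts))
    time_of = {}
    for s, t in zip(starts, run_times):
        for b in range(s, s + switch_run):
            time_of[b] = int(t)
    switch_times = np.array([time_of[b] for b in switch_bins], dtype=int)
    matrices = []
    labels_per_tp = []
    junctions_per_tp = []
    for t in range(T):
        labels = base_labels.copy()
        for b, st in zip(switch_bins, switch_times):
            if t >= st:
                labels[b] = -labels[b]
        juncs = set(int(j) for j in junctions)
        for j, et, kind in junction_events:
            if kind == "gain" and t >= et:
                juncs.add(int(j))
            elif kind == "loss" and t >= et:
                juncs.discard(int(j))
        m, _ = make_contact_map(
            rng, n_bins=n_bins, binsize=binsize,
            labels=labels, junctions=sorted(juncs), **map_params,
        )
        matrices.append(m)
        labels_per_tp.append(labels.tolist())
        junctions_per_tp.append(sorted(juncs))
    truth = {
        "T": T,
        "n_bins": n_bins,
        "binsize": binsize,
        "switch_fraction": switch_fraction,
        "switch_bins": switch_bins.tolist(),
        "switch_times": switch_times.tolist(),
        "labels_per_tp": labels_per_tp,
        "junctions_per_tp": junctions_per_tp,
    }
    return matrices, truth


# ---------------------------------------------------------------------------
# regulome generator


@dataclass
class RegulomeData:
    """All synthetic regulome inputs plus the planted truth."""

    chrom: str
    chromsizes: dict
    genes: list[AnnotatedGene]
    promoters: list[Promoter]
    p53_peaks: list[Interval]
    k4me1: dict                         # time point -> list[Interval]
    k27ac: dict                         # time point -> list[Interval]
    interactions: list[InteractionRecord]
    promoter_counts: pd.DataFrame       # promoters x samples
    background_counts: pd.DataFrame     # 10-kb bins x samples
    background_bins: list[Interval]
    enriched_regions: list[Interval]
    samples_a: list[str]
    samples_b: list[str]
    truth: dict


def _negbin(rng: np.random.Generator, mean, dispersion: float):
    """NB draws parameterised by mean and dispersion (var = mu + disp*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def make_peaks_and_counts(
    seed,
    genes: Sequence[AnnotatedGene],
    promoters: Sequence[Promoter],
    layout: dict,
    chromsizes: Mapping[str, int],
    dispersion_regions: float = 0.05,
    dispersion_background: float = 0.02,
    background_mean: float = 50.0,
    n_replicates: int = 3,
) -> dict:
    """Peak sets (p53, H3K4me1, H3K27ac per time point) and count tables.

    ``layout`` is the planted regulatory skeleton produced by
    :func:`make_regulome` (enhancer sites, proximal sites, decoy sites,
    planted log2FC per gene, per-sample scale factors).  Counts are drawn
    negative-binomial around size-factor-scaled means.
    """
    rng = _rng(seed)
    chrom = layout["chrom"]
    p53_peaks: list[Interval] = []
    k4me1: dict[str, list[Interval]] = {tp: [] for tp in TIME_POINTS}
    k27ac: dict[str, list[Interval]] = {tp: [] for tp in TIME_POINTS}

    for site in layout["enhancer_sites"]:
        c = site["center"]
        p53_peaks.append(Interval(chrom, c - 250, c + 250))
        enh = Interval(chrom, c - 1000, c + 1000)
        for tp in TIME_POINTS:
            k4me1[tp].append(enh)
        active_tps = ("1h", "10h") if site["primed_state_at_0h"] else TIME_POINTS
        for tp in active_tps:
            k27ac[tp].append(Interval(chrom, c - 1200, c + 1200))
    for site in layout["proximal_sites"]:
        prom = next(p for p in promoters if p.gene_id == site["gene"])
        mid = (prom.window.start + prom.window.end) // 2
        p53_peaks.append(Interval(chrom, mid - 250, mid + 250))
        for tp in ("1h", "10h"):
            k27ac[tp].append(Interval(chrom, prom.window.start - 200, prom.window.end + 200))
    for site in layout["nonfunctional_sites"]:
        c = site["center"]
        p53_peaks.append(Interval(chrom, c - 250, c + 250))

    # promoter H3K27ac counts: 0 h vs 1 h, n_replicates each
    samples_a = [f"0h_r{i+1}" for i in range(n_replicates)]
    samples_b = [f"1h_r{i+1}" for i in range(n_replicates)]
    samples = samples_a + samples_b
    sf = np.asarray(layout["scale_factors"], dtype=float)
    if len(sf) != len(samples):
        raise ValueError("scale_factors length must match 2 * n_replicates")
    gene_ids = [p.gene_id for p in promoters]
    base = rng.lognormal(mean=5.0, sigma=0.4, size=len(gene_ids))  # ~150 fragments/promoter
    lfc = np.array([layout["log2fc"][g] for g in gene_ids])
    rows = []
    for gi in range(len(gene_ids)):
        mu_a = base[gi]
        mu_b = base[gi] * 2.0 ** lfc[gi]
        mus = np.array([mu_a] * n_replicates + [mu_b] * n_replicates) * sf
        rows.append(_negbin(rng, mus, dispersion_regions))
    promoter_counts = pd.DataFrame(rows, index=gene_ids, columns=samples)

    # background 10-kb bins for size-factor estimation
    L = chromsizes[chrom]
    bins = [Interval(chrom, s, min(s + 10_000, L)) for s in range(0, L, 10_000)]
    bg_mu = rng.lognormal(mean=np.log(background_mean), sigma=0.3, size=len(bins))
    bg = _negbin(rng, np.outer(bg_mu, sf), dispersion_background)
    background_counts = pd.DataFrame(
        bg, index=[f"{b.chrom}:{b.start}" for b in bins], columns=samples
    )
    enriched = (
        p53_peaks
        + [iv for tp in TIME_POINTS for iv in k4me1[tp] + k27ac[tp]]
        + [p.window for p in promoters]
    )
    return {
        "p53_peaks": p53_peaks,
        "k4me1": k4me1,
        "k27ac": k27ac,
        "promoter_counts": promoter_counts,
        "background_counts": background_counts,
        "background_bins": bins,
        "enriched_regions": enriched,
        "samples_a": samples_a,
        "samples_b": samples_b,
    }


def make_interactions(
    seed,
    promoters: Sequence[Promoter],
    layout: dict,
    n_decoys: int = 40,
    fragment_half: int = 2000,
) -> list[InteractionRecord]:
    """CHiCAGO-style interaction table for the planted regulome.

    Each planted loop links the bait fragment around a candidate gene's TSS
    to the fragment around the p53-bound enhancer.  Scores at active time
    points are 5 + Gamma(2, 2) (well above the significance threshold);
    primed target loops are significant at 0 h too, all other 0 h scores
    and all decoy scores are uniform in (0.5, 4.5).
    """
    rng = _rng(seed)
    chrom = layout["chrom"]
    prom_by_gene = {p.gene_id: p for p in promoters}
    records = []
    for site in layout["enhancer_sites"]:
        c = site["center"]
        other = Interval(chrom, c - fragment_half, c + fragment_half)
        for gid in site["candidates"]:
            prom = prom_by_gene[gid]
            bait = Interval(chrom, max(0, prom.tss - fragment_half), prom.tss + fragment_half)
            scores = {}
            for tp in TIME_POINTS:
                if tp == "0h":
                    sig = site["primed"] and gid == site["target"]
                else:
                    sig = True
                scores[tp] = float(5.0 + rng.gamma(2.0, 2.0)) if sig else float(
                    rng.uniform(0.5, 4.5)
                )
            records.append(InteractionRecord(bait, other, (gid,), scores))
    gene_ids = list(prom_by_gene)
    L = layout["length"]
    for _ in range(n_decoys):
        gid = gene_ids[rng.integers(len(gene_ids))]
        prom = prom_by_gene[gid]
        bait = Interval(chrom, max(0, prom.tss - fragment_half), prom.tss + fragment_half)
        pos = int(rng.integers(fragment_half, L - fragment_half))
        other = Interval(chrom, pos - fragment_half, pos + fragment_half)
        if other.start == bait.start and other.end == bait.end:
            continue
        scores = {tp: float(rng.uniform(0.5, 4.5)) for tp in TIME_POINTS}
        records.append(InteractionRecord(bait, other, (gid,), scores))
    return records


def make_regulome(
    seed,
    n_genes: int = 64,
    n_enhancer_sites: int = 20,
    n_proximal_sites: int = 3,
    n_nonfunctional_sites: int = 5,
    primed_fraction: float = 0.5,
    target_log2fc: float = 2.0,
    chrom: str = "chrS",
    length: int = 10_000_000,
) -> RegulomeData:
    """A complete synthetic regulome on one 10 Mb chromosome.

    Plants: genes with strand-aware promoters; enhancer-bound functional
    p53 sites with three candidate genes each, the true target carrying a
    promoter H3K27ac gain of ``target_log2fc`` (others near zero); a set of
    promoter-bound (proximal) sites; non-functional decoy sites; primed vs
    neo loops at the stated fraction; and per-sample library scale factors
    (one sample planted at 2x for size-factor recovery checks).
    """
    if n_genes < 3 * n_enhancer_sites + n_proximal_sites:
        raise ValueError(
            "need at least 3 genes per enhancer site (disjoint candidate triples) "
            "plus the proximally targeted genes"
        )
    rng = _rng(seed)
    chromsizes = {chrom: length}
    spacing = (length - 1_400_000) // n_genes
    genes = []
    for i in range(n_genes):
        tss = 400_000 + i * spacing + int(rng.integers(-20_000, 20_000))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(AnnotatedGene(f"G{i:03d}", chrom, tss, strand))
    promoters = define_promoters(genes, chromsizes=chromsizes)

    n_primed = int(round(primed_fraction * n_enhancer_sites))
    primed_flags = np.array([True] * n_primed + [False] * (n_enhancer_sites - n_primed))
    rng.shuffle(primed_flags)
    log2fc: dict[str, float] = {
        g.gene_id: float(np.clip(rng.normal(0.0, 0.3), -0.8, 0.8)) for g in genes
    }
    enhancer_sites = []
    for k in range(n_enhancer_sites):
        gi = 1 + 3 * k   # disjoint candidate triples: no gene serves two sites
        center = genes[gi].tss + 60_000 + int(rng.integers(-5_000, 5_000))
        candidates = [genes[gi - 1].gene_id, genes[gi].gene_id, genes[gi + 1].gene_id]
        target = candidates[int(rng.integers(3))]
        log2fc[target] = target_log2fc
        enhancer_sites.append(
            {
                "center": center,
                "candidates": candidates,
                "target": target,
                "primed": bool(primed_flags[k]),
                "primed_state_at_0h": bool(k % 2),   # half the elements lack 0 h K27ac
            }
        )
    proximal_sites = [{"gene": genes[-(i + 1)].gene_id} for i in range(n_proximal_sites)]
    nonfunctional = [
        {"center": 100_000 + 40_000 * i} for i in range(n_nonfunctional_sites)
    ]
    scale_factors = [1.0, 0.8, 1.25, 2.0, 1.0, 0.9]
    layout = {
        "chrom": chrom,
        "length": length,
        "enhancer_sites": enhancer_sites,
        "proximal_sites": proximal_sites,
        "nonfunctional_sites": nonfunctional,
        "log2fc": log2fc,
        "scale_factors": scale_factors,
    }
    peaks = make_peaks_and_counts(rng, genes, promoters, layout, chromsizes)
    interactions = make_interactions(rng, promoters, layout)
    truth = {
        "seed": seed if not isinstance(seed, np.random.Generator) else None,
        "planted_targets": [
            {
                "site_start": s["center"] - 250,
                "site_end": s["center"] + 250,
                "gene": s["target"],
                "primed": s["primed"],
            }
            for s in enhancer_sites
        ],
        "primed_fraction": float(np.mean([s["primed"] for s in enhancer_sites])),
        "proximal_genes": [s["gene"] for s in proximal_sites],
        "n_functional_sites": n_enhancer_sites + n_proximal_sites,
        "n_p53_peaks": n_enhancer_sites + n_proximal_sites + n_nonfunctional_sites,
        "log2fc": log2fc,
        "scale_factors": scale_factors,
        "layout": layout,
    }
    return RegulomeData(
        chrom=chrom,
        chromsizes=chromsizes,
        genes=genes,
        promoters=promoters,
        p53_peaks=peaks["p53_peaks"],
        k4me1=peaks["k4me1"],
        k27ac=peaks["k27ac"],
        interactions=interactions,
        promoter_counts=peaks["promoter_counts"],
        background_counts=peaks["background_counts"],
        background_bins=peaks["background_bins"],
        enriched_regions=peaks["enriched_regions"],
        samples_a=peaks["samples_a"],
        samples_b=peaks["samples_b"],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# presets / file emission


def write_preset(preset: str, seed: int, outdir: str | Path) -> dict:
    """Emit a named synthetic dataset as standard-format files plus truth.json.

    Presets: ``compartments`` (100-bin 100 kb checkerboard time course),
    ``tads`` (200-bin 50 kb map with 4 planted junctions), ``regulome``
    (peaks, counts, interactions, genes), ``full`` (all three).
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"preset": preset, "seed": seed}
    if preset in ("compartments", "full"):
        mats, t = make_timecourse(seed)
        for i, m in enumerate(mats):
            tio.write_contacts(outdir / f"contacts_100kb_t{i}.tsv", m)
        truth["compartments"] = t
    if preset in ("tads", "full"):
        m, t = make_contact_map(
            seed, n_bins=200, binsize=50_000, comp_strength=1.0,
            tad_fold=3.0, junctions=(40, 80, 120, 160),
        )
        tio.write_contacts(outdir / "contacts_50kb.tsv", m)
        truth["tads"] = t
    if preset in ("regulome", "full"):
        data = make_regulome(seed)
        tio.write_bed(outdir / "p53_peaks.bed", data.p53_peaks)
        for tp in TIME_POINTS:
            tio.write_bed(outdir / f"k4me1_{tp}.bed", data.k4me1[tp])
            tio.write_bed(outdir / f"k27ac_{tp}.bed", data.k27ac[tp])
        gene_ivs = [
            Interval(g.chrom, g.tss, g.tss + 1, strand=g.strand, name=g.gene_id)
            for g in data.genes
        ]
        tio.write_bed(outdir / "genes.bed", gene_ivs)
        tio.write_interactions(outdir / "interactions.tsv", data.interactions)
        data.promoter_counts.to_csv(outdir / "promoter_counts.tsv", sep="\t")
        data.background_counts.to_csv(outdir / "background_counts.tsv", sep="\t")
        truth["regulome"] = {
            k: v for k, v in data.truth.items() if k != "layout"
        }
    if preset not in ("compartments", "tads", "regulome", "full"):
        raise ValueError(f"unknown preset {preset!r}")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
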