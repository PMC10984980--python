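"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3–BED6 (peaks, borders, elements), bedGraph (score tracks),
sparse tab-separated contact lists (``chrom  bin_i  bin_j  count``), dense
matrix text, CHiCAGO-style interaction tables (bait and other-end
coordinates plus one score column per sample), and gene annotations as BED6
or a minimal GTF subset.

Everything is parsed into the 0-based half-open convention of
:mod:`tempo3d.grid`; GTF (1-based, closed) is converted at this boundary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import AnnotatedGene, GenomeGrid, Interval
from .matrix import ContactMatrix

__all__ = [
    "InteractionRecord",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_contacts",
    "write_contacts",
    "read_dense_matrix",
    "read_genes_bed",
    "read_genes_gtf",
    "read_interactions",
    "write_interactions",
]

_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class InteractionRecord:
    """One promoter-anchored (bait ↔ other-end) interaction.

    ``scores`` maps sample labels (e.g. ``"0h"``) to per-sample confidence
    scores on the CHiCAGO scale, where values at or above 5 are treated as
    high-confidence throughout the package.
    """

    bait: Interval
    other_end: Interval
    bait_genes: tuple[str, ...]
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if (
            self.bait.chrom == self.other_end.chrom
            and self.bait.start == self.other_end.start
            and self.bait.end == self.other_end.end
        ):
            raise ValueError(
                f"self-interaction: bait equals other end at "
                f"{self.bait.chrom}:{self.bait.start}-{self.bait.end}"
            )

    @property
    def is_trans(self) -> bool:
        return self.bait.chrom != self.other_end.chrom

    @property
    def distance(self) -> float | None:
        """Cis distance between fragment midpoints; None for trans pairs."""
        if self.is_trans:
            return None
        return abs(self.bait.midpoint - self.other_end.midpoint)

    def significance_pattern(
        self, samples: Sequence[str], threshold: float = 5.0
    ) -> tuple[int, ...]:
        return tuple(int(self.scores[s] >= threshold) for s in samples)


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path: str | Path) -> list[Interval]:
    """Parse a 3–6 column BED file into intervals (file order preserved).

    Comment, ``track`` and ``browser`` lines are tolerated.  Malformed lines
    and empty/inverted intervals raise with the offending line number.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            signal = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    signal = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Interval(chrom, start, end, strand=strand, name=name, signal=signal))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str | Path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.signal is None else format(iv.signal, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def write_bedgraph(
    path: str | Path, grid: GenomeGrid, chrom: str, track: np.ndarray
) -> None:
    """Write a per-bin track as bedGraph; NaN bins are skipped."""
    with open(path, "w") as fh:
        for b, v in enumerate(np.asarray(track, dtype=float)):
            if np.isnan(v):
                continue
            iv = grid.bin_interval(chrom, b)
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Contact matrices


def read_contacts(path: str | Path, grid: GenomeGrid, chrom: str | None = None) -> ContactMatrix:
    """Read a sparse ``chrom  bin_i  bin_j  count`` list into a dense matrix.

    The upper triangle is sufficient; entries are mirrored, duplicate pairs
    are summed, and missing pairs are zero.  Bin indices outside the grid and
    negative counts raise.
    """
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields (chrom bin_i bin_j count)")
            c = fields[0]
            try:
                i, j, cnt = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if cnt < 0:
                raise ValueError(f"{path}:{lineno}: negative count {cnt}")
            rows.append((c, i, j, cnt))
    if chrom is None:
        chroms = {r[0] for r in rows}
        if len(chroms) != 1:
            raise ValueError(f"{path}: expected a single chromosome, found {sorted(chroms)}")
        chrom = chroms.pop()
    n = grid.n_bins(chrom)
    vals = np.zeros((n, n))
    for c, i, j, cnt in rows:
        if c != chrom:
            raise ValueError(f"unexpected chromosome {c!r} (reading {chrom!r})")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bin pair ({i},{j}) out of range for {chrom} ({n} bins)")
        vals[i, j] += cnt
        if i != j:
            vals[j, i] += cnt
    return ContactMatrix(grid, chrom, vals)


def write_contacts(path: str | Path, m: ContactMatrix) -> None:
    """Write the upper triangle (including diagonal) of non-zero entries."""
    with open(path, "w") as fh:
        n = m.n_bins
        for i in range(n):
            for j in range(i, n):
                v = m.values[i, j]
                if v != 0:
                    fh.write(f"{m.chrom}\t{i}\t{j}\t{v:.17g}\n")


def read_dense_matrix(path: str | Path, grid: GenomeGrid, chrom: str) -> ContactMatrix:
    """Read a whitespace-separated dense square grid of counts."""
    vals = np.loadtxt(path, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {vals.shape}")
    return ContactMatrix(grid, chrom, vals)


# ---------------------------------------------------------------------------
# Gene annotations


def read_genes_bed(path: str | Path) -> list[AnnotatedGene]:
    """BED6 gene annotation: name = gene id; TSS = strand-aware 5' end."""
    genes = []
    for iv in read_bed(path):
        if iv.strand not in ("+", "-"):
            raise ValueError(f"gene {iv.name}: BED6 strand required for TSS definition")
        tss = iv.start if iv.strand == "+" else iv.end - 1
        genes.append(AnnotatedGene(iv.name, iv.chrom, tss, iv.strand))
    return genes


def read_genes_gtf(path: str | Path, feature: str = "gene") -> list[AnnotatedGene]:
    """Minimal GTF subset reader (gene_id attribute; 1-based closed coords).

    Converts to 0-based: TSS = start-1 on '+', end-1 on '-'.
    """
    genes: list[AnnotatedGene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields")
            if fields[2] != feature:
                continue
            chrom, start, end, strand, attrs = (
                fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8],
            )
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            tss = start - 1 if strand == "+" else end - 1
            genes.append(AnnotatedGene(gene_id, chrom, tss, strand))
    return genes


# ---------------------------------------------------------------------------
# Interaction tables

_COORD_COLS = [
    "bait_chrom", "bait_start", "bait_end", "bait_genes",
    "oe_chrom", "oe_start", "oe_end",
]


def read_interactions(
    path: str | Path, samples: Sequence[str] | None = None
) -> list[InteractionRecord]:
    """Read a CHiCAGO-style interaction table.

    The header is required.  Seven fixed columns give bait and other-end
    coordinates plus a comma-separated bait gene list; every remaining
    column is a per-sample score column (an optional ``score_`` prefix is
    stripped to obtain the sample label).  When ``samples`` is given, those
    labels must all be present — score columns are matched by header name,
    never by position.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    score_cols = {
        (c[len("score_"):] if c.startswith("score_") else c): c
        for c in df.columns
        if c not in _COORD_COLS
    }
    if not score_cols:
        raise ValueError(f"{path}: no score columns found")
    if samples is not None:
        absent = [s for s in samples if s not in score_cols]
        if absent:
            raise ValueError(f"{path}: missing score column(s) for sample(s) {absent}")
        score_cols = {s: score_cols[s] for s in samples}
    records = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        genes = () if pd.isna(r["bait_genes"]) or r["bait_genes"] in (".", "") else tuple(
            str(r["bait_genes"]).split(",")
        )
        records.append(
            InteractionRecord(
                bait=Interval(str(r["bait_chrom"]), int(r["bait_start"]), int(r["bait_end"])),
                other_end=Interval(str(r["oe_chrom"]), int(r["oe_start"]), int(r["oe_end"])),
                bait_genes=genes,
                scores={label: float(r[col]) for label, col in score_cols.items()},
            )
        )
    return records


def write_interactions(
    path: str | Path, records: Sequence[InteractionRecord], samples: Sequence[str] | None = None
) -> None:
    if samples is None:
        samples = list(records[0].scores) if records else []
    with open(path, "w") as fh:
        header = _COORD_COLS + [f"score_{s}" for s in samples]
        fh.write("\t".join(header) + "\n")
        for r in records:
            fields = [
                r.bait.chrom, str(r.bait.start), str(r.bait.end),
                ",".join(r.bait_genes) if r.bait_genes else ".",
                r.other_end.chrom, str(r.other_end.start), str(r.other_end.end),
            ] + [format(r.scores[s], ".17g") for s in samples]
            fh.write("\t".join(fields) + "\n")
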