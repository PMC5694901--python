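"""Genomic interval primitives, plain-text format I/O and interval algebra.

Coordinates are 0-based, half-open ``[start, end)`` everywhere inside the
package (the BED convention); any 1-based format is converted at the
boundary.  Strand is carried but ignored by all overlap operations —
sheared genomic-DNA inserts and peak regions are unstranded objects.

The module also houses the Tn5 cut-site correction used for ATAC-seq
reads: the transposase inserts with a 9-bp stagger, so a read start on
the plus strand sits 4 bp left of the binding-event center and a read
end on the minus strand sits 5 bp right of it.
"""
from __future__ import annotations

import io
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ScoreTrack",
    "IntervalIndex",
    "read_intervals",
    "write_bed6",
    "read_bedgraph",
    "write_bedgraph",
    "overlaps_any",
    "nearest_gene",
    "nearest_gene_many",
    "adjust_tn5_offsets",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand-aware TSS and total exonic length (for RPKM)."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    exonic_length: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body of {self.gene_id} "
                f"({self.interval.start}-{self.interval.end})"
            )
        if self.exonic_length < 1:
            raise ValueError(f"exonic_length must be >= 1 for {self.gene_id}")


class ScoreTrack:
    """Sparse per-base score track (e.g. a conservation score bedGraph).

    Stores, per chromosome, sorted non-overlapping scored intervals.
    Bases not covered by any interval are *missing*, not zero.
    """

    def __init__(self, entries: Iterable[tuple[GenomicInterval, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in entries:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping score intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)

    def mean_over(self, region: GenomicInterval) -> float:
        """Mean score over the *covered* bases of ``region``.

        Returns NaN when no base of the region is covered.
        """
        if region.chrom not in self._data:
            return float("nan")
        starts, ends, values = self._data[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        total = 0.0
        nbases = 0
        for i in range(lo, hi):
            ov = min(ends[i], region.end) - max(starts[i], region.start)
            if ov > 0:
                total += values[i] * ov
                nbases += ov
        return total / nbases if nbases else float("nan")

    def items(self) -> Iterable[tuple[GenomicInterval, float]]:
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)


class IntervalIndex:
    """Per-chromosome sorted index of (optionally weighted) intervals.

    Supports O(log n) weighted counting of intervals overlapping a query
    window by >= 1 bp, via the identity

        count = W(start < query_end) - W(end <= query_start)

    which holds because every interval with ``end <= query_start`` also
    has ``start < query_end``.
    """

    def __init__(
        self,
        intervals: Sequence[GenomicInterval] | None = None,
        weights: Sequence[float] | None = None,
        *,
        arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    ):
        per_chrom: dict[str, dict[str, np.ndarray]] = {}
        if arrays is not None:
            raw = {c: (s, e, w) for c, (s, e, w) in arrays.items()}
        else:
            assert intervals is not None
            groups: dict[str, list[tuple[int, int, float]]] = {}
            if weights is None:
                weights = np.ones(len(intervals))
            for iv, w in zip(intervals, weights):
                groups.setdefault(iv.chrom, []).append((iv.start, iv.end, float(w)))
            raw = {}
            for chrom, rows in groups.items():
                arr = np.array(rows, dtype=float)
                raw[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        self.total_weight = 0.0
        for chrom, (starts, ends, w) in raw.items():
            order = np.lexsort((ends, starts))
            s_sorted = starts[order]
            e_by_start = ends[order]
            w_by_start = w[order]
            cum_w_start = np.concatenate([[0.0], np.cumsum(w_by_start)])
            # running max of ends in start order: rightmost base reached by
            # any interval starting before a position
            prefix_max_end = np.maximum.accumulate(e_by_start) if len(e_by_start) else e_by_start
            order_e = np.argsort(ends, kind="stable")
            e_sorted = ends[order_e]
            w_by_end = w[order_e]
            s_by_end = starts[order_e]
            cum_w_end = np.concatenate([[0.0], np.cumsum(w_by_end)])
            # suffix min of starts in end order: leftmost start among
            # intervals ending after a position
            if len(s_by_end):
                suffix_min_start = np.minimum.accumulate(s_by_end[::-1])[::-1]
            else:
                suffix_min_start = s_by_end
            per_chrom[chrom] = {
                "s_sorted": s_sorted,
                "cum_w_start": cum_w_start,
                "prefix_max_end": prefix_max_end,
                "e_sorted": e_sorted,
                "cum_w_end": cum_w_end,
                "suffix_min_start": suffix_min_start,
            }
            self.total_weight += float(np.sum(w))
        self._chrom = per_chrom

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def count_in_windows(
        self, chrom: str, wstarts: np.ndarray, wends: np.ndarray
    ) -> np.ndarray:
        """Weighted count of intervals overlapping each window by >= 1 bp."""
        wstarts = np.asarray(wstarts, dtype=np.int64)
        wends = np.asarray(wends, dtype=np.int64)
        if chrom not in self._chrom:
            return np.zeros(len(wstarts))
        d = self._chrom[chrom]
        i1 = np.searchsorted(d["s_sorted"], wends, side="left")
        i2 = np.searchsorted(d["e_sorted"], wstarts, side="right")
        return d["cum_w_start"][i1] - d["cum_w_end"][i2]

    def count(self, chrom: str, start: int, end: int) -> float:
        return float(self.count_in_windows(chrom, np.array([start]), np.array([end]))[0])

    def covered_extent(self, chrom: str, start: int, end: int) -> tuple[int, int] | None:
        """Outermost bases within ``[start, end)`` covered by >= 1 interval.

        Returns None when no interval overlaps the span.
        """
        if chrom not in self._chrom:
            return None
        d = self._chrom[chrom]
        i1 = int(np.searchsorted(d["s_sorted"], end, side="left"))
        if i1 == 0 or d["prefix_max_end"][i1 - 1] <= start:
            return None
        i2 = int(np.searchsorted(d["e_sorted"], start, side="right"))
        if i2 >= len(d["suffix_min_start"]):
            return None
        lo = max(start, int(d["suffix_min_start"][i2]))
        hi = min(end, int(d["prefix_max_end"][i1 - 1]))
        if lo >= hi:
            return None
        return lo, hi


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, n_min: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise ValueError(
            f"line {lineno}: expected >= {n_min} tab-separated fields, got {len(fields)}"
        )
    return fields


def _interval_from_fields(fields: list[str], lineno: int, stranded: bool) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinate: {exc}") from None
    if start >= end:
        raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
    strand = "."
    if stranded and len(fields) >= 6 and fields[5] in ("+", "-"):
        strand = fields[5]
    try:
        return GenomicInterval(fields[0], start, end, strand)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_intervals(path: str | Path, fmt: str = "BED6"):
    """Read a BED file in the named dialect.

    BED3/BED6 return a list of :class:`GenomicInterval` (BED6 keeps
    strand when present).  BED12 returns a list of
    :class:`GeneModel` with ``exonic_length`` = sum of block sizes and a
    strand-aware TSS.  Malformed lines raise ``ValueError`` naming the
    line number.
    """
    fmt = fmt.upper()
    if fmt not in ("BED3", "BED6", "BED12"):
        raise ValueError(f"unknown BED dialect {fmt!r}")
    out: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            if fmt == "BED3":
                fields = _parse_bed_line(line, lineno, 3)
                out.append(_interval_from_fields(fields, lineno, stranded=False))
            elif fmt == "BED6":
                fields = _parse_bed_line(line, lineno, 3)
                out.append(_interval_from_fields(fields, lineno, stranded=True))
            else:
                fields = _parse_bed_line(line, lineno, 12)
                iv = _interval_from_fields(fields, lineno, stranded=True)
                try:
                    sizes = [int(s) for s in fields[10].rstrip(",").split(",") if s]
                except ValueError:
                    raise ValueError(f"line {lineno}: malformed blockSizes {fields[10]!r}") from None
                if not sizes:
                    raise ValueError(f"line {lineno}: empty blockSizes")
                tss = iv.start if iv.strand != "-" else iv.end - 1
                out.append(GeneModel(fields[3], iv, tss, sum(sizes)))
    return out


def write_bed6(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read the simplified gene-model TSV
    (gene_id, chrom, start, end, strand, tss, exonic_length)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line) or line.startswith("gene_id\t"):
                continue
            f = _parse_bed_line(line, lineno, 7)
            try:
                iv = GenomicInterval(f[1], int(f[2]), int(f[3]), f[4])
                genes.append(GeneModel(f[0], iv, int(f[5]), int(f[6])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttss\texonic_length\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{g.tss}\t{g.exonic_length}\n"
            )


def read_bedgraph(path: str | Path) -> ScoreTrack:
    """Read a 4-column bedGraph into a :class:`ScoreTrack`.

    Track/browser/comment lines are tolerated and skipped.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            fields = _parse_bed_line(line, lineno, 4)
            iv = _interval_from_fields(fields, lineno, stranded=False)
            try:
                value = float(fields[3])
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric score {fields[3]!r}") from None
            entries.append((iv, value))
    return ScoreTrack(entries)


def write_bedgraph(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, value in track.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per query: does it overlap >= 1 subject by >= 1 bp?

    Strand is ignored.  Empty subject list yields all-False.
    """
    idx = IntervalIndex(subjects) if subjects else None
    out = np.zeros(len(queries), dtype=bool)
    if idx is None:
        return out
    for i, q in enumerate(queries):
        out[i] = idx.count(q.chrom, q.start, q.end) > 0
    return out


def nearest_gene(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str, int]:
    """Nearest gene by |region center - TSS| on the region's chromosome.

    Returns ``(gene_id, signed_distance)`` with distance measured
    ``center - tss``.  Ties break toward the smaller TSS coordinate, then
    lexicographic gene id.
    """
    if not genes:
        raise ValueError("gene list is empty")
    same = [g for g in genes if g.interval.chrom == region.chrom]
    if not same:
        raise ValueError(f"no gene on chromosome {region.chrom}")
    center = region.center
    best = min(same, key=lambda g: (abs(center - g.tss), g.tss, g.gene_id))
    return best.gene_id, center - best.tss


def nearest_gene_many(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[tuple[str, int]]:
    """Vectorized-ish nearest-gene assignment (same rule as nearest_gene)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    # sort by the tie-break key so argmin on |d| alone is deterministic
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.tss, g.gene_id))
    out = []
    for r in regions:
        cands = by_chrom.get(r.chrom)
        if not cands:
            raise ValueError(f"no gene on chromosome {r.chrom}")
        center = r.center
        best = min(cands, key=lambda g: (abs(center - g.tss), g.tss, g.gene_id))
        out.append((best.gene_id, center - best.tss))
    return out


def adjust_tn5_offsets(reads: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Convert aligned ATAC-seq reads to corrected Tn5 cut sites.

    Plus-strand reads are offset by +4 bp and minus-strand reads by
    -5 bp; each read is then represented by its corrected cut site as a
    1-bp interval (the center of the transposition event), since all
    downstream accessibility counting is cut-site based.  Not
    idempotent: apply exactly once per read set.
    """
    out = []
    for r in reads:
        if r.strand == "+":
            cut = r.start + 4
        elif r.strand == "-":
            cut = r.end - 5
        else:
            raise ValueError(f"unstranded read {r.chrom}:{r.start}-{r.end} cannot be offset")
        out.append(GenomicInterval(r.chrom, cut, cut + 1, r.strand))
    return out
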