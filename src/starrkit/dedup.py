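"""Fragment deduplication with index-sublibrary multiplexing.

STARR-seq output libraries are amplified in several separately indexed
PCR reactions (16 in the default protocol).  Identical fragment
coordinates *within* one index sublibrary are PCR/sequencing duplicates
and are collapsed to a single distinct fragment; identical coordinates
seen in *different* index sublibraries arose from independent molecules
and are kept as biological duplicates.  The pooled library therefore
stores each distinct interval with a multiplicity equal to the number of
index sets that contain it, and the library size is the total pooled
distinct-fragment count.

Fragment identity is ``(chrom, start, end)``; strand is ignored.
Biological replicates are pooled after per-replicate, per-index
collapsing, and fragments duplicated across replicates are counted as
independent observations.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalIndex, _is_skippable, _parse_bed_line

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "fragments_from_pairs",
    "collapse_within_index",
    "pool_indexes",
    "dedup_and_pool",
    "read_bedpe",
    "read_fragments_bed",
    "write_pooled_bed",
    "read_pooled_bed",
]

FragKey = tuple[str, int, int]


@dataclass(frozen=True)
class Fragment:
    """One aligned insert with its index-sublibrary label."""

    interval: GenomicInterval
    index_label: str
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        if not self.index_label:
            raise ValueError("index_label must be non-empty")

    @property
    def key(self) -> FragKey:
        return (self.interval.chrom, self.interval.start, self.interval.end)


class FragmentLibrary:
    """A pooled multiset of distinct fragments with fast window counting.

    ``fragments`` maps ``(chrom, start, end)`` to its pooled
    multiplicity; ``library_size`` is the sum of multiplicities (the
    total pooled distinct-fragment count used for scaling).
    """

    def __init__(self, role: str, fragments: Mapping[FragKey, int]):
        if role not in ("input", "output"):
            raise ValueError(f"role must be 'input' or 'output', got {role!r}")
        self.role = role
        self.fragments: dict[FragKey, int] = dict(fragments)
        for key, mult in self.fragments.items():
            if mult < 1:
                raise ValueError(f"non-positive multiplicity for {key}")
        self._index: IntervalIndex | None = None

    @property
    def library_size(self) -> int:
        return sum(self.fragments.values())

    @property
    def n_distinct(self) -> int:
        return len(self.fragments)

    @property
    def index(self) -> IntervalIndex:
        """Lazily built weighted interval index over pooled fragments."""
        if self._index is None:
            per_chrom: dict[str, list[tuple[int, int, float]]] = {}
            for (chrom, start, end), mult in self.fragments.items():
                per_chrom.setdefault(chrom, []).append((start, end, float(mult)))
            arrays = {}
            for chrom, rows in per_chrom.items():
                arr = np.array(rows, dtype=float)
                arrays[chrom] = (
                    arr[:, 0].astype(np.int64),
                    arr[:, 1].astype(np.int64),
                    arr[:, 2],
                )
            self._index = IntervalIndex(arrays=arrays)
        return self._index

    def count_overlapping(self, chrom: str, start: int, end: int) -> float:
        """Pooled (multiplicity-weighted) fragments overlapping by >= 1 bp."""
        return self.index.count(chrom, start, end)

    def mean_fragment_length(self) -> float:
        if not self.fragments:
            return 0.0
        total = sum((e - s) * m for (c, s, e), m in self.fragments.items())
        return total / self.library_size

    def items(self) -> Iterable[tuple[FragKey, int]]:
        return self.fragments.items()


def fragments_from_pairs(
    paired_records: Sequence[tuple[GenomicInterval, GenomicInterval, str]],
    replicate: str = "rep1",
) -> tuple[list[Fragment], int]:
    """Infer insert fragments from read pairs.

    Each record is ``(read1, read2, index_label)``; the fragment spans
    from the leftmost mate start to the rightmost mate end.
    Inter-chromosomal pairs are skipped; the skip tally is returned.
    """
    fragments: list[Fragment] = []
    skipped = 0
    for r1, r2, index_label in paired_records:
        if r1.chrom != r2.chrom:
            skipped += 1
            continue
        iv = GenomicInterval(r1.chrom, min(r1.start, r2.start), max(r1.end, r2.end))
        fragments.append(Fragment(iv, index_label, replicate))
    return fragments, skipped


def collapse_within_index(
    fragments: Iterable[Fragment],
) -> dict[tuple[str, str], set[FragKey]]:
    """Collapse identical coordinates within each (replicate, index) set.

    Returns, per ``(replicate, index_label)``, the set of distinct
    ``(chrom, start, end)`` keys.  Idempotent by construction.
    """
    sets: dict[tuple[str, str], set[FragKey]] = {}
    for frag in fragments:
        sets.setdefault((frag.replicate, frag.index_label), set()).add(frag.key)
    return sets


def pool_indexes(
    per_index_sets: Mapping[tuple[str, str], set[FragKey]] | Mapping[str, set[FragKey]],
    role: str = "output",
) -> FragmentLibrary:
    """Pool distinct fragments across index sublibraries (and replicates).

    The multiplicity of an interval is the number of index sets that
    contain it; the library size is the total multiplicity.
    """
    counts: Counter[FragKey] = Counter()
    for keys in per_index_sets.values():
        counts.update(keys)
    return FragmentLibrary(role, counts)


def dedup_and_pool(fragments: Iterable[Fragment], role: str = "output") -> FragmentLibrary:
    """Per-index collapse followed by cross-index pooling, in one call."""
    return pool_indexes(collapse_within_index(fragments), role=role)


def pool_from_arrays(
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    replicate_ids: np.ndarray,
    index_ids: np.ndarray,
    role: str,
) -> FragmentLibrary:
    """Vectorized collapse-and-pool over flat arrays of a single chromosome.

    Same algorithm as :func:`collapse_within_index` + :func:`pool_indexes`
    (unique coordinates within each (replicate, index) set, multiplicity =
    number of sets containing the coordinate), vectorized for large
    libraries.
    """
    rec = np.stack(
        [
            np.asarray(replicate_ids, dtype=np.int64),
            np.asarray(index_ids, dtype=np.int64),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
        ],
        axis=1,
    )
    distinct = np.unique(rec, axis=0)
    keys, mult = np.unique(distinct[:, 2:4], axis=0, return_counts=True)
    counts = {
        (chrom, int(s), int(e)): int(m) for (s, e), m in zip(keys, mult)
    }
    return FragmentLibrary(role, counts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bedpe(
    path: str | Path, replicate: str = "rep1"
) -> tuple[list[Fragment], int]:
    """Read a BEDPE file (one record per read pair, index label in the
    name column) into fragments; returns (fragments, n_skipped)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            fields = _parse_bed_line(line, lineno, 7)
            try:
                r1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                r2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            records.append((r1, r2, fields[6]))
    return fragments_from_pairs(records, replicate=replicate)


def read_fragments_bed(path: str | Path, replicate: str = "rep1") -> list[Fragment]:
    """Read fragments from BED6 with the index label in the name column."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            fields = _parse_bed_line(line, lineno, 4)
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            out.append(Fragment(iv, fields[3], replicate))
    return out


def write_pooled_bed(library: FragmentLibrary, path: str | Path) -> None:
    """Write pooled fragments as BED with multiplicity in the score column."""
    with open(path, "w") as fh:
        for i, ((chrom, start, end), mult) in enumerate(sorted(library.items())):
            fh.write(f"{chrom}\t{start}\t{end}\tfrag_{i}\t{mult}\t.\n")


def read_pooled_bed(path: str | Path, role: str) -> FragmentLibrary:
    counts: dict[FragKey, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            fields = _parse_bed_line(line, lineno, 5)
            try:
                key = (fields[0], int(fields[1]), int(fields[2]))
                mult = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if key[1] >= key[2]:
                raise ValueError(f"line {lineno}: start >= end")
            counts[key] = counts.get(key, 0) + mult
    return FragmentLibrary(role, counts)
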