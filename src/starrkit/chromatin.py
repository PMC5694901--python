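"""Chromatin-context integration for called enhancers.

Classifies enhancer peaks as open (overlapping an accessibility peak by
>= 1 bp) or closed, and computes signal-over-input fold-enrichment
summaries around region centers: the +/-10-kb meta-profile in 100-bp
bins, and the per-region +/-200-bp center enrichment used for box-plot
comparisons.  Read counts from the two sets are placed on a common
footing by scaling each to the same nominal sequencing depth (50 M reads
by default); fold enrichment per bin is the ratio of the pooled, scaled
counts (ratio of means across regions), with the input count floored at
one read pre-scaling to avoid division by zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .calling import EnhancerPeak
from .intervals import GenomicInterval, IntervalIndex, ScoreTrack, overlaps_any

__all__ = [
    "MetaProfile",
    "RegionEnrichment",
    "classify_by_accessibility",
    "meta_profile",
    "center_enrichment",
    "mean_region_score",
    "profile_matrix",
    "write_profile_tsv",
]


@dataclass
class MetaProfile:
    """Mean fold enrichment of a signal over input in bins around centers."""

    bin_centers: np.ndarray  # offsets from region center, bp
    fold_enrichment: np.ndarray
    n_regions: int
    n_dropped: int
    flagged_bins: np.ndarray  # bins where the input count was floored


@dataclass
class RegionEnrichment:
    """Per-region fold enrichment within +/-flank bp of the region center."""

    regions: list[GenomicInterval]
    fold_enrichment: np.ndarray
    flagged: np.ndarray  # regions where the input count was floored

    def median(self) -> float:
        return float(np.median(self.fold_enrichment))


def classify_by_accessibility(
    peaks: Sequence[EnhancerPeak],
    accessibility_peaks: Sequence[GenomicInterval],
) -> list[EnhancerPeak]:
    """Set each peak's accessibility class.

    A peak overlapping >= 1 accessibility peak by >= 1 bp is *open*;
    otherwise *closed*.  Open and closed strictly partition the peak
    set.  Peaks are modified in place and returned.
    """
    is_open = overlaps_any([p.interval for p in peaks], list(accessibility_peaks))
    for peak, flag in zip(peaks, is_open):
        peak.accessibility_class = "open" if flag else "closed"
    return list(peaks)


def _usable_regions(
    regions: Sequence[GenomicInterval],
    genome: Sequence[tuple[str, int]] | None,
    half_width: int,
) -> tuple[list[GenomicInterval], int]:
    sizes = dict(genome) if genome else None
    kept, dropped = [], 0
    for r in regions:
        c = r.center
        limit = sizes.get(r.chrom) if sizes else None
        if c - half_width < 0 or (limit is not None and c + half_width > limit):
            dropped += 1
            continue
        kept.append(r)
    return kept, dropped


def _binned_counts(
    idx: IntervalIndex, regions: Sequence[GenomicInterval], edges: np.ndarray
) -> np.ndarray:
    """Pooled read counts per offset bin across all region centers."""
    total = np.zeros(len(edges) - 1)
    for r in regions:
        c = r.center
        total += idx.count_in_windows(r.chrom, c + edges[:-1], c + edges[1:])
    return total


def meta_profile(
    regions: Sequence[GenomicInterval],
    signal_reads: Sequence[GenomicInterval],
    input_reads: Sequence[GenomicInterval],
    half_width: int = 10_000,
    bin_size: int = 100,
    norm_depth: float = 50e6,
    genome: Sequence[tuple[str, int]] | None = None,
) -> MetaProfile:
    """Signal-over-input fold enrichment in bins around region centers.

    Both read sets are scaled to ``norm_depth``; per bin the fold
    enrichment is the ratio of the pooled scaled counts across all
    regions.  Regions whose center is closer than ``half_width`` to a
    chromosome edge are dropped with their count reported.
    """
    if not signal_reads or not input_reads:
        raise ValueError("signal and input read sets must be non-empty")
    if (2 * half_width) % bin_size != 0:
        raise ValueError("2*half_width must be a multiple of bin_size")
    kept, dropped = _usable_regions(regions, genome, half_width)
    n_bins = (2 * half_width) // bin_size
    edges = np.arange(-half_width, half_width + bin_size, bin_size, dtype=np.int64)
    sig_idx = IntervalIndex(signal_reads)
    in_idx = IntervalIndex(input_reads)
    sig = _binned_counts(sig_idx, kept, edges)
    inp = _binned_counts(in_idx, kept, edges)
    flagged = inp < 1
    inp_floored = np.maximum(inp, 1.0)
    sig_scale = norm_depth / len(signal_reads)
    in_scale = norm_depth / len(input_reads)
    fe = (sig * sig_scale) / (inp_floored * in_scale)
    centers = (edges[:-1] + edges[1:]) // 2
    assert len(centers) == n_bins
    return MetaProfile(centers, fe, len(kept), dropped, flagged)


def center_enrichment(
    regions: Sequence[GenomicInterval],
    signal_reads: Sequence[GenomicInterval],
    input_reads: Sequence[GenomicInterval],
    flank: int = 200,
    norm_depth: float = 50e6,
    genome: Sequence[tuple[str, int]] | None = None,
) -> RegionEnrichment:
    """Per-region fold enrichment over ``[center - flank, center + flank)``.

    One value per region, suitable for box-plot summaries; regions with
    zero input reads in the window use the one-read pseudocount floor
    and are flagged.
    """
    if not signal_reads or not input_reads:
        raise ValueError("signal and input read sets must be non-empty")
    kept, _ = _usable_regions(regions, genome, flank)
    sig_idx = IntervalIndex(signal_reads)
    in_idx = IntervalIndex(input_reads)
    sig_scale = norm_depth / len(signal_reads)
    in_scale = norm_depth / len(input_reads)
    fe = np.zeros(len(kept))
    flagged = np.zeros(len(kept), dtype=bool)
    for i, r in enumerate(kept):
        c = r.center
        s = sig_idx.count(r.chrom, c - flank, c + flank)
        n = in_idx.count(r.chrom, c - flank, c + flank)
        if n < 1:
            n = 1.0
            flagged[i] = True
        fe[i] = (s * sig_scale) / (n * in_scale)
    return RegionEnrichment(kept, fe, flagged)


def mean_region_score(
    regions: Sequence[GenomicInterval], track: ScoreTrack
) -> np.ndarray:
    """Covered-base mean of a score track per region (NaN when uncovered)."""
    return np.array([track.mean_over(r) for r in regions])


def profile_matrix(
    regions: Sequence[GenomicInterval],
    signal_reads: Sequence[GenomicInterval],
    half_width: int = 10_000,
    bin_size: int = 100,
    sample: int | None = None,
    seed: int | None = None,
    genome: Sequence[tuple[str, int]] | None = None,
) -> tuple[np.ndarray, list[GenomicInterval]]:
    """Raw per-region read-count matrix (regions x bins) for heat maps.

    ``sample`` randomly subsamples regions (seeded) the way large peak
    sets are thinned before rendering; summary statistics elsewhere in
    the module always use all regions.
    """
    kept, _ = _usable_regions(regions, genome, half_width)
    if sample is not None and sample < len(kept):
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(kept), size=sample, replace=False)
        kept = [kept[i] for i in sorted(pick)]
    edges = np.arange(-half_width, half_width + bin_size, bin_size, dtype=np.int64)
    idx = IntervalIndex(signal_reads)
    mat = np.zeros((len(kept), len(edges) - 1))
    for i, r in enumerate(kept):
        c = r.center
        mat[i] = idx.count_in_windows(r.chrom, c + edges[:-1], c + edges[1:])
    return mat, kept


def write_profile_tsv(profile: MetaProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_fold_enrichment\n")
        for c, v in zip(profile.bin_centers, profile.fold_enrichment):
            fh.write(f"{c}\t{v:.6g}\n")
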