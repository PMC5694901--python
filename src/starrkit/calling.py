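"""Poisson-enrichment enhancer peak calling and activity scoring.

A region is called an enhancer when the output (reporter-RNA) library
carries significantly more distinct fragments there than the input
(plasmid) library's representation of the same region predicts.  The
test statistic is the Poisson upper tail of the output window count with
expectation

    lam = max(input_window_count, lambda_floor) * (output_size / input_size)

where ``lambda_floor`` is the genome-wide input density scaled to the
window length, guarding windows with zero or near-zero input coverage.
Window p-values are corrected by Benjamini-Hochberg; significant windows
within ``merge_gap`` of one another are merged, trimmed to the outermost
output-covered base, re-tested on exact fragment counts and re-corrected.

Enhancer activity is the scaled fragment-count ratio

    activity = (out_count / out_library_size) / (in_count / in_library_size)

i.e. the fold by which the region is over-represented in the reporter
RNA relative to the transfected plasmid pool.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dedup import FragmentLibrary
from .intervals import GenomicInterval

__all__ = [
    "CallerConfig",
    "CoverageTrack",
    "EnhancerPeak",
    "fragment_coverage",
    "poisson_upper_tail",
    "bh_qvalues",
    "call_enhancers",
    "enhancer_activity",
    "write_peaks_bed",
    "read_peaks_bed",
]

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    """Sliding-window caller parameters.

    Defaults re-implement a transparent equivalent of a default
    treatment-vs-input Poisson caller: 500-bp windows stepped by 100 bp,
    significant windows within 200 bp merged, peaks shorter than 200 bp
    dropped, q < 0.05.
    """

    window_size: int = 500
    step: int = 100
    merge_gap: int = 200
    min_peak_length: int = 200
    q_threshold: float = 0.05
    pseudocount: float = 1.0  # input-count floor in the activity ratio
    lambda_floor: float | None = None  # None -> genome-wide input density

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.step < 1:
            raise ValueError("window_size and step must be >= 1")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")


@dataclass
class CoverageTrack:
    """Per-window pooled fragment counts over a tiled genome."""

    role: str
    window_size: int
    step: int
    library_size: int
    windows: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (starts, counts)


@dataclass
class EnhancerPeak:
    interval: GenomicInterval
    output_count: int
    input_count: int
    activity: float
    p_value: float
    q_value: float
    accessibility_class: str = "unset"

    def __post_init__(self) -> None:
        if self.activity <= 0:
            raise ValueError("activity must be > 0")
        if not (0 <= self.p_value <= 1 and 0 <= self.q_value <= 1):
            raise ValueError("p and q values must lie in [0, 1]")


def _tile(length: int, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, max(length - window, 0) + step, step, dtype=np.int64)
    starts = starts[starts < length]
    ends = np.minimum(starts + window, length)
    return starts, ends


def fragment_coverage(
    library: FragmentLibrary,
    window_size: int,
    genome: Sequence[tuple[str, int]],
    step: int | None = None,
) -> CoverageTrack:
    """Count pooled fragments (with multiplicity) overlapping each window.

    Windows are tiled per chromosome with ``step`` (default:
    non-overlapping tiles of ``window_size``).  Fragments extending past
    the chromosome end are effectively clipped by the final short
    window; a warning is logged when this occurs.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    step = step or window_size
    sizes = dict(genome)
    for (chrom, s, e), _ in library.items():
        if chrom in sizes and e > sizes[chrom]:
            logger.warning("fragment %s:%d-%d extends past chromosome end; clipped", chrom, s, e)
    windows = {}
    for chrom, length in genome:
        wstarts, wends = _tile(length, window_size, step)
        counts = library.index.count_in_windows(chrom, wstarts, wends)
        windows[chrom] = (wstarts, counts)
    return CoverageTrack(library.role, window_size, step, library.library_size, windows)


def poisson_upper_tail(k: int | np.ndarray, lam: float | np.ndarray) -> float | np.ndarray:
    """P(X >= k) for X ~ Poisson(lam), stable in log space for large k."""
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be > 0")
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer) and np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be a non-negative integer")
    out = stats.poisson.sf(k_arr - 1, lam_arr)
    return float(out) if np.isscalar(k) and np.isscalar(lam) else out


def bh_qvalues(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enhancer_activity(
    peak_region: GenomicInterval,
    output_lib: FragmentLibrary,
    input_lib: FragmentLibrary,
    pseudocount: float | None = 1.0,
) -> float:
    """Scaled distinct-fragment ratio of output over input in a region.

    ``activity = (out_count / out_size) / (in_count / in_size)`` with the
    input count floored at ``pseudocount`` (pass None to disable, in
    which case a zero input count raises).
    """
    out_c = output_lib.count_overlapping(peak_region.chrom, peak_region.start, peak_region.end)
    in_c = input_lib.count_overlapping(peak_region.chrom, peak_region.start, peak_region.end)
    if in_c == 0:
        if not pseudocount:
            raise ValueError(
                f"zero input fragments in {peak_region.chrom}:{peak_region.start}-"
                f"{peak_region.end} and pseudocount disabled"
            )
        in_c = pseudocount
    elif pseudocount:
        in_c = max(in_c, pseudocount)
    return (out_c / output_lib.library_size) / (in_c / input_lib.library_size)


def _merge_spans(
    starts: np.ndarray, ends: np.ndarray, merge_gap: int
) -> list[tuple[int, int]]:
    """Merge sorted spans whose gap is <= merge_gap (overlaps always merge)."""
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def call_enhancers(
    output_lib: FragmentLibrary,
    input_lib: FragmentLibrary,
    genome: Sequence[tuple[str, int]],
    config: CallerConfig | None = None,
) -> list[EnhancerPeak]:
    """Call enhancer peaks by Poisson enrichment of output over input.

    Two-stage procedure: (1) sliding windows are tested and BH-corrected
    genome-wide; (2) significant windows are merged, trimmed to the
    outermost output-covered base, re-tested on exact fragment counts and
    BH-corrected again across candidate regions.  Peaks shorter than
    ``min_peak_length`` are dropped.
    """
    config = config or CallerConfig()
    if input_lib.library_size == 0:
        raise ValueError("input library is empty")
    if output_lib.library_size == 0:
        raise ValueError("output library is empty")
    ratio = output_lib.library_size / input_lib.library_size
    w, step = config.window_size, config.step

    # stage 1: window scan
    per_chrom: dict[str, dict[str, np.ndarray]] = {}
    all_p: list[np.ndarray] = []
    in_count_sum = 0.0
    n_windows = 0
    for chrom, length in genome:
        wstarts, wends = _tile(length, w, step)
        out_counts = output_lib.index.count_in_windows(chrom, wstarts, wends)
        in_counts = input_lib.index.count_in_windows(chrom, wstarts, wends)
        per_chrom[chrom] = {
            "wstarts": wstarts,
            "wends": wends,
            "out": out_counts,
            "in": in_counts,
        }
        in_count_sum += in_counts.sum()
        n_windows += len(wstarts)
    if n_windows == 0:
        return []
    floor = config.lambda_floor if config.lambda_floor is not None else max(
        in_count_sum / n_windows, 1e-9
    )
    for chrom, d in per_chrom.items():
        lam = np.maximum(d["in"], floor) * ratio
        p = stats.poisson.sf(np.round(d["out"]).astype(np.int64) - 1, lam)
        d["p"] = p
        all_p.append(p)
    q = bh_qvalues(np.concatenate(all_p))
    offset = 0
    candidates: list[tuple[str, int, int]] = []
    for chrom, length in genome:
        d = per_chrom[chrom]
        n = len(d["wstarts"])
        qc = q[offset : offset + n]
        offset += n
        sig = (qc < config.q_threshold) & (d["out"] > np.maximum(d["in"], floor) * ratio)
        if not sig.any():
            continue
        for span_start, span_end in _merge_spans(
            d["wstarts"][sig], d["wends"][sig], config.merge_gap
        ):
            extent = output_lib.index.covered_extent(chrom, span_start, span_end)
            if extent is None:
                continue
            candidates.append((chrom, extent[0], extent[1]))

    if not candidates:
        return []

    # stage 2: re-test merged, trimmed candidate regions on exact counts
    rows = []
    for chrom, start, end in candidates:
        out_c = output_lib.count_overlapping(chrom, start, end)
        in_c = input_lib.count_overlapping(chrom, start, end)
        lam = max(in_c, floor * (end - start) / w) * ratio
        p = float(stats.poisson.sf(int(round(out_c)) - 1, lam))
        rows.append((chrom, start, end, out_c, in_c, p))
    qs = bh_qvalues([r[5] for r in rows])
    peaks = []
    for (chrom, start, end, out_c, in_c, p), qv in zip(rows, qs):
        if qv >= config.q_threshold:
            continue
        if end - start < config.min_peak_length:
            continue
        region = GenomicInterval(chrom, start, end)
        activity = enhancer_activity(region, output_lib, input_lib, config.pseudocount)
        peaks.append(
            EnhancerPeak(
                interval=region,
                output_count=int(round(out_c)),
                input_count=int(round(in_c)),
                activity=activity,
                p_value=p,
                q_value=float(qv),
            )
        )
    peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start))
    return peaks


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_peaks_bed(peaks: Sequence[EnhancerPeak], path: str | Path) -> None:
    """BED6+ peak export: score = round(10 x activity); extra columns are
    output_count, input_count, p, q, activity, accessibility_class."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{round(10 * pk.activity)}\t.\t"
                f"{pk.output_count}\t{pk.input_count}\t{pk.p_value:.6g}\t{pk.q_value:.6g}\t"
                f"{pk.activity:.6g}\t{pk.accessibility_class}\n"
            )


def read_peaks_bed(path: str | Path) -> list[EnhancerPeak]:
    from .intervals import _is_skippable, _parse_bed_line

    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            f = _parse_bed_line(line, lineno, 12)
            peaks.append(
                EnhancerPeak(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    output_count=int(f[6]),
                    input_count=int(f[7]),
                    activity=float(f[10]),
                    p_value=float(f[8]),
                    q_value=float(f[9]),
                    accessibility_class=f[11],
                )
            )
    return peaks
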