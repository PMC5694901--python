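"""Synthetic STARR-seq study generator with known ground truth.

Produces every pipeline input at desk scale: a single-chromosome genome
(10 Mb by default) with planted non-overlapping enhancers, index-
multiplexed input/output fragment libraries with PCR duplicates,
chromatin-mark and accessibility read sets, an accessibility peak set, a
two-condition (vehicle / TSA-treated) expression table, and per-region
accessibility counts.  The truth object records everything a recovery
test needs: planted coordinates and activities, open/closed labels,
TSA-opened subsets, duplicate provenance and true expression means.

Activity convention.  Enhancer activity is, by definition, the
enrichment of a region's distinct-fragment share in the output library
relative to its share of the input library.  The generator therefore
plants sampling weights on that same scale: with background weight 1
per base-pair-equivalent and requested activities ``A_e`` over lengths
``L_e`` on a genome of ``G`` bp, the raw total weight would be
``B = G - sum(L_e) + sum(w_e L_e)``; weights are set to
``w_e = A_e * B / G`` (a one-line fixed point, solved in closed form)
so that a fragment fully inside an enhancer of activity ``A`` is
``A``-fold enriched *relative to the pooled library* — the quantity the
scaled-ratio estimator measures.  Without this normalization every
planted activity would be deflated by the total planted enrichment
mass, which at desk scale (enhancers covering ~10% of the toy genome)
is far from negligible.

Every operation is deterministic under the config seed; independent
operations draw from independent seeded streams so the outputs do not
depend on call order.
"""
from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dedup import FragmentLibrary, Fragment, pool_from_arrays
from .intervals import GeneModel, GenomicInterval, nearest_gene_many
from .tsa import ConditionCounts

__all__ = [
    "SimulationConfig",
    "TruthEnhancer",
    "TruthRegion",
    "SyntheticTruth",
    "FragmentSet",
    "simulate_genome",
    "simulate_fragment_libraries",
    "simulate_signal_reads",
    "simulate_expression_and_tsa",
]

# rng stream ids, one per generator operation
_STREAM_GENOME = 1
_STREAM_INPUT = 2
_STREAM_OUTPUT = 3
_STREAM_SIGNAL = {"active_mark": 4, "repressed_mark": 5, "accessibility": 6}
_STREAM_EXPRESSION = 7


@dataclass
class SimulationConfig:
    """All generator parameters, with desk-scale defaults.

    The fragment-length distribution (truncated normal, mean 500 bp,
    bounds 350-650 bp) and the 16 index sublibraries mirror the assay's
    size selection and indexing-PCR design; the open fraction default
    mirrors the observed 12.7% of active enhancers in accessible
    chromatin.
    """

    seed: int = 0
    chrom: str = "chr1"
    genome_length: int = 10_000_000
    # enhancers
    n_enhancers: int = 200
    enhancer_length_range: tuple[int, int] = (4000, 6000)
    activity_range: tuple[float, float] = (1.5, 20.0)  # log-uniform
    activity_fixed: float | None = None  # overrides activity_range when set
    fraction_open: float = 0.127
    min_region_separation: int = 2000
    edge_margin: int = 12_000
    # fragment libraries
    fragment_length_mean: float = 500.0
    fragment_length_sd: float = 60.0
    fragment_length_bounds: tuple[int, int] = (350, 650)
    n_input_fragments: int = 500_000
    n_output_fragments: int = 500_000
    n_indexes: int = 16
    n_replicates: int = 2
    pcr_duplication_rate: float = 0.15
    # genes and expression
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (5000, 20_000)
    exonic_length_range: tuple[int, int] = (1000, 5000)
    baseline_expression: float = 2.0
    expression_coupling: float = 1.0
    coupling_window: int = 50_000
    expression_count_scale: float = 10.0
    n_expression_replicates: int = 3
    nb_dispersion: float = 0.1
    # accessibility / TSA
    n_background_open_peaks: int = 300
    accessibility_peak_length_range: tuple[int, int] = (500, 1500)
    n_closed_inactive_regions: int = 400
    closed_inactive_length_range: tuple[int, int] = (800, 1500)
    tsa_opened_fraction: float = 0.2  # closed *active* enhancers opened by TSA
    tsa_opened_fraction_inactive: float = 0.05  # closed inactive regions opened
    accessibility_fold_gain: float = 5.0
    atac_baseline_mean: float = 100.0
    n_atac_replicates: int = 3
    # chromatin-mark reads
    n_signal_reads: int = 200_000
    n_chromatin_input_reads: int = 200_000
    read_length: int = 50
    active_mark_fold: float = 3.0
    repressed_mark_fold: float = 1.5
    signal_halfwidth: int = 1000

    def __post_init__(self) -> None:
        for name in ("n_enhancers", "n_genes", "n_input_fragments", "n_output_fragments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for frac in (self.fraction_open, self.tsa_opened_fraction, self.pcr_duplication_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.fragment_length_bounds
        if not (0 < lo <= hi):
            raise ValueError("fragment_length_bounds must be ordered and positive")
        if self.n_indexes < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 index and >= 1 replicate")

    @property
    def genome(self) -> list[tuple[str, int]]:
        return [(self.chrom, self.genome_length)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthEnhancer:
    region: GenomicInterval
    activity: float
    open_chromatin: bool
    tsa_opened: bool = False


@dataclass
class TruthRegion:
    """A closed, STARR-inactive background region (TSA candidate)."""

    region: GenomicInterval
    tsa_opened: bool = False


@dataclass
class SyntheticTruth:
    genome: list[tuple[str, int]]
    enhancers: list[TruthEnhancer]
    genes: list[GeneModel]
    accessibility_peaks: list[GenomicInterval]
    closed_inactive_regions: list[TruthRegion]
    # filled by simulate_fragment_libraries
    input_provenance: dict = field(default_factory=dict)
    output_provenance: dict = field(default_factory=dict)
    # filled by simulate_expression_and_tsa
    expression_means: pd.DataFrame | None = None
    enhancer_gene: list[str] = field(default_factory=list)

    @property
    def open_enhancers(self) -> list[TruthEnhancer]:
        return [e for e in self.enhancers if e.open_chromatin]

    @property
    def closed_enhancers(self) -> list[TruthEnhancer]:
        return [e for e in self.enhancers if not e.open_chromatin]

    def to_json(self, path: str | Path) -> None:
        def iv(i: GenomicInterval) -> list:
            return [i.chrom, i.start, i.end]

        payload = {
            "genome": [[c, l] for c, l in self.genome],
            "enhancers": [
                {
                    "region": iv(e.region),
                    "activity": e.activity,
                    "open": e.open_chromatin,
                    "tsa_opened": e.tsa_opened,
                }
                for e in self.enhancers
            ],
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "region": iv(g.interval),
                    "strand": g.interval.strand,
                    "tss": g.tss,
                    "exonic_length": g.exonic_length,
                }
                for g in self.genes
            ],
            "accessibility_peaks": [iv(p) for p in self.accessibility_peaks],
            "closed_inactive_regions": [
                {"region": iv(r.region), "tsa_opened": r.tsa_opened}
                for r in self.closed_inactive_regions
            ],
            "input_provenance": _jsonable(self.input_provenance),
            "output_provenance": _jsonable(self.output_provenance),
        }
        with open(path, "w") as fh:
            json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class FragmentSet:
    """Raw (pre-dedup) fragment records of one library, as flat arrays."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    replicate_ids: np.ndarray  # index into replicate_labels
    index_ids: np.ndarray  # index into index_labels
    replicate_labels: list[str]
    index_labels: list[str]

    def __len__(self) -> int:
        return len(self.starts)

    def to_fragments(self) -> list[Fragment]:
        return [
            Fragment(
                GenomicInterval(self.chrom, int(s), int(e)),
                self.index_labels[i],
                self.replicate_labels[r],
            )
            for s, e, r, i in zip(self.starts, self.ends, self.replicate_ids, self.index_ids)
        ]

    def dedup_pool(self, role: str) -> FragmentLibrary:
        """Collapse within (replicate, index) and pool — vectorized path."""
        return pool_from_arrays(
            self.chrom, self.starts, self.ends, self.replicate_ids, self.index_ids, role
        )

    def write_bed(self, path: str | Path) -> None:
        """BED6 with 'replicate:index' in the name column."""
        with open(path, "w") as fh:
            for s, e, r, i in zip(self.starts, self.ends, self.replicate_ids, self.index_ids):
                name = f"{self.replicate_labels[r]}:{self.index_labels[i]}"
                fh.write(f"{self.chrom}\t{s}\t{e}\t{name}\t0\t.\n")


# ---------------------------------------------------------------------------
# genome / truth skeleton
# ---------------------------------------------------------------------------

def _place_regions(
    rng: np.random.Generator,
    lengths: Sequence[int],
    genome_length: int,
    margin: int,
    separation: int,
    max_tries: int = 200_000,
) -> list[tuple[int, int]]:
    """Place regions uniformly without overlap and with a minimum gap."""
    placed_starts: list[int] = []
    placed_ends: list[int] = []
    out = []
    for L in lengths:
        lo, hi = margin, genome_length - margin - L
        if hi <= lo:
            raise ValueError("genome too small for the requested regions")
        for _ in range(max_tries):
            s = int(rng.integers(lo, hi))
            e = s + L
            j = bisect_left(placed_starts, s)
            ok = True
            if j < len(placed_starts) and placed_starts[j] < e + separation:
                ok = False
            if j > 0 and placed_ends[j - 1] + separation > s:
                ok = False
            if ok:
                placed_starts.insert(j, s)
                placed_ends.insert(j, e)
                out.append((s, e))
                break
        else:
            raise ValueError(
                f"could not place {len(lengths)} non-overlapping regions "
                f"on a {genome_length}-bp genome"
            )
    return out


def simulate_genome(config: SimulationConfig) -> SyntheticTruth:
    """Build the truth skeleton: enhancers, genes, accessibility peaks
    and closed inactive background regions, all non-overlapping."""
    rng = config.rng(_STREAM_GENOME)
    chrom, G = config.chrom, config.genome_length

    lo, hi = config.enhancer_length_range
    enh_lengths = rng.integers(lo, hi + 1, size=config.n_enhancers)
    lo, hi = config.closed_inactive_length_range
    ci_lengths = rng.integers(lo, hi + 1, size=config.n_closed_inactive_regions)
    lo, hi = config.accessibility_peak_length_range
    bg_lengths = rng.integers(lo, hi + 1, size=config.n_background_open_peaks)

    all_lengths = np.concatenate([enh_lengths, ci_lengths, bg_lengths]).astype(int)
    spans = _place_regions(
        rng, all_lengths, G, config.edge_margin, config.min_region_separation
    )
    n_e = config.n_enhancers
    n_ci = config.n_closed_inactive_regions
    enh_spans = spans[:n_e]
    ci_spans = spans[n_e : n_e + n_ci]
    bg_spans = spans[n_e + n_ci :]

    if config.activity_fixed is not None:
        activities = np.full(n_e, float(config.activity_fixed))
    else:
        a_lo, a_hi = config.activity_range
        activities = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=n_e))

    n_open = int(round(config.fraction_open * n_e))
    open_idx = set(rng.choice(n_e, size=n_open, replace=False).tolist()) if n_open else set()

    enhancers = [
        TruthEnhancer(
            GenomicInterval(chrom, s, e), float(a), open_chromatin=(i in open_idx)
        )
        for i, ((s, e), a) in enumerate(zip(enh_spans, activities))
    ]

    # TSA opens a fraction of the *closed* enhancers and of the closed
    # inactive background regions
    closed_ids = [i for i, e in enumerate(enhancers) if not e.open_chromatin]
    n_opened = int(round(config.tsa_opened_fraction * len(closed_ids)))
    if n_opened:
        for i in rng.choice(closed_ids, size=n_opened, replace=False):
            enhancers[i].tsa_opened = True

    ci_regions = [TruthRegion(GenomicInterval(chrom, s, e)) for s, e in ci_spans]
    n_ci_open = int(round(config.tsa_opened_fraction_inactive * n_ci))
    if n_ci_open:
        for i in rng.choice(n_ci, size=n_ci_open, replace=False):
            ci_regions[i].tsa_opened = True

    # accessibility peaks: one centered on each open enhancer, plus
    # background open regions elsewhere
    acc_peaks = []
    plo, phi = config.accessibility_peak_length_range
    for e in enhancers:
        if not e.open_chromatin:
            continue
        plen = int(rng.integers(plo, phi + 1))
        c = e.region.center
        acc_peaks.append(GenomicInterval(chrom, max(c - plen // 2, 0), c + (plen + 1) // 2))
    acc_peaks.extend(GenomicInterval(chrom, s, e) for s, e in bg_spans)

    # genes: TSS uniform, random strand
    genes = []
    glo, ghi = config.gene_length_range
    xlo, xhi = config.exonic_length_range
    for i in range(config.n_genes):
        glen = int(rng.integers(glo, ghi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(config.edge_margin, G - config.edge_margin))
        if strand == "+":
            start, end = tss, min(tss + glen, G)
        else:
            start, end = max(tss - glen + 1, 0), tss + 1
        exonic = int(min(rng.integers(xlo, xhi + 1), end - start))
        genes.append(
            GeneModel(f"gene_{i:04d}", GenomicInterval(chrom, start, end, strand), tss, max(exonic, 1))
        )

    return SyntheticTruth(
        genome=config.genome,
        enhancers=enhancers,
        genes=genes,
        accessibility_peaks=acc_peaks,
        closed_inactive_regions=ci_regions,
    )


# ---------------------------------------------------------------------------
# fragment libraries
# ---------------------------------------------------------------------------

def _sample_fragment_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    lo, hi = config.fragment_length_bounds
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = np.round(keep[:take]).astype(np.int64)
        filled += take
    return out


def _total_weight(truth: SyntheticTruth, G: int) -> tuple[float, np.ndarray]:
    """Closed-form fixed point for the library-relative weight scale.

    Returns ``(B, w)`` with ``B`` the total genome weight and ``w`` the
    per-enhancer sampling weights such that ``w_e * G / B = A_e``.
    """
    L = np.array([e.region.length for e in truth.enhancers], dtype=float)
    A = np.array([e.activity for e in truth.enhancers], dtype=float)
    SA = float((A * L).sum())
    S1 = float(L.sum())
    if SA >= G:
        raise ValueError("planted enrichment mass exceeds genome size; reduce activities")
    B = G * (G - S1) / (G - SA)
    return B, A * B / G


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    config: SimulationConfig,
    truth: SyntheticTruth | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment coordinates; uniform, or enhancer-weighted when truth given."""
    G = config.genome_length
    if truth is None or not truth.enhancers:
        lengths = _sample_fragment_lengths(rng, n, config)
        starts = rng.integers(0, G - lengths)
        return starts, starts + lengths
    _, weights = _total_weight(truth, G)
    e_starts = np.array([e.region.start for e in truth.enhancers])
    e_ends = np.array([e.region.end for e in truth.enhancers])
    order = np.argsort(e_starts)
    e_starts, e_ends = e_starts[order], e_ends[order]
    w = weights[order]
    w_max = max(float(w.max()), 1.0)
    out_s = np.empty(n, dtype=np.int64)
    out_e = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * w_max * 1.1), 1024)
        m = min(m, 4_000_000)
        lens = _sample_fragment_lengths(rng, m, config)
        starts = rng.integers(0, G - lens)
        ends = starts + lens
        # at most one enhancer can overlap a fragment (separation exceeds
        # the maximum fragment length)
        j = np.searchsorted(e_ends, starts, side="right")
        j_c = np.minimum(j, len(e_starts) - 1)
        ov = np.minimum(ends, e_ends[j_c]) - np.maximum(starts, e_starts[j_c])
        ov = np.where(j < len(e_starts), np.maximum(ov, 0), 0)
        wt = 1.0 + (w[j_c] - 1.0) * ov / lens
        accept = rng.random(m) * w_max < wt
        ks, ke = starts[accept], ends[accept]
        take = min(len(ks), n - filled)
        out_s[filled : filled + take] = ks[:take]
        out_e[filled : filled + take] = ke[:take]
        filled += take
    return out_s, out_e


def _attach_reads(
    rng: np.random.Generator,
    starts: np.ndarray,
    ends: np.ndarray,
    config: SimulationConfig,
) -> FragmentSet:
    """Assign replicate and index labels and add PCR duplicate reads."""
    n = len(starts)
    rep = rng.integers(0, config.n_replicates, size=n)
    idx = rng.integers(0, config.n_indexes, size=n)
    d = config.pcr_duplication_rate
    extra = rng.poisson(d / (1.0 - d), size=n) if d > 0 else np.zeros(n, dtype=np.int64)
    reps = 1 + extra
    return FragmentSet(
        chrom=config.chrom,
        starts=np.repeat(starts, reps),
        ends=np.repeat(ends, reps),
        replicate_ids=np.repeat(rep, reps),
        index_ids=np.repeat(idx, reps),
        replicate_labels=[f"rep{r + 1}" for r in range(config.n_replicates)],
        index_labels=[f"i{i + 1:02d}" for i in range(config.n_indexes)],
    )


def _provenance(fs: FragmentSet) -> dict:
    """Ground-truth dedup bookkeeping for a fragment set."""
    rec = np.stack([fs.replicate_ids, fs.index_ids, fs.starts, fs.ends], axis=1)
    distinct = np.unique(rec, axis=0)
    keys, mult = np.unique(distinct[:, 2:4], axis=0, return_counts=True)
    per_index: dict[str, int] = {}
    pairs, pair_counts = np.unique(distinct[:, :2], axis=0, return_counts=True)
    for (r, i), cnt in zip(pairs, pair_counts):
        per_index[f"{fs.replicate_labels[r]}:{fs.index_labels[i]}"] = int(cnt)
    return {
        "n_reads": int(len(fs)),
        "n_molecules": int(len(distinct)),
        "pooled_library_size": int(mult.sum()),
        "n_distinct_intervals": int(len(keys)),
        "per_index_distinct": per_index,
        "pooled_multiplicity": {
            f"{fs.chrom}:{int(s)}-{int(e)}": int(m) for (s, e), m in zip(keys, mult)
        },
    }


def simulate_fragment_libraries(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[FragmentSet, FragmentSet]:
    """Input (uniform) and output (enhancer-weighted) raw read sets.

    Output fragments are sampled with probability proportional to
    ``1 + (w_e - 1) * overlap_fraction`` where ``w_e`` is the
    library-normalized weight of the overlapped enhancer (module
    docstring); PCR duplicates are added within each index sublibrary at
    the configured rate.  Duplicate provenance is recorded on the truth
    object.
    """
    rng_in = config.rng(_STREAM_INPUT)
    s, e = _sample_positions(rng_in, config.n_input_fragments, config, truth=None)
    input_set = _attach_reads(rng_in, s, e, config)

    rng_out = config.rng(_STREAM_OUTPUT)
    s, e = _sample_positions(rng_out, config.n_output_fragments, config, truth=truth)
    output_set = _attach_reads(rng_out, s, e, config)

    truth.input_provenance = _provenance(input_set)
    truth.output_provenance = _provenance(output_set)
    return input_set, output_set


# ---------------------------------------------------------------------------
# chromatin-mark reads
# ---------------------------------------------------------------------------

def simulate_signal_reads(
    config: SimulationConfig, truth: SyntheticTruth, mark: str
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Signal and matched-input read sets for one chromatin feature.

    ``active_mark`` piles reads (at ``active_mark_fold``) within
    +/- ``signal_halfwidth`` of *open* enhancer centers; the
    ``repressed_mark`` is weakly enriched at *closed* enhancer centers;
    ``accessibility`` piles at accessibility peaks.  Input reads are
    uniform.
    """
    if mark not in _STREAM_SIGNAL:
        raise ValueError(f"unknown mark {mark!r}")
    rng = config.rng(_STREAM_SIGNAL[mark])
    G, chrom, rl = config.genome_length, config.chrom, config.read_length

    if mark == "active_mark":
        centers = [e.region.center for e in truth.open_enhancers]
        fold = config.active_mark_fold
        half = config.signal_halfwidth
    elif mark == "repressed_mark":
        centers = [e.region.center for e in truth.closed_enhancers]
        fold = config.repressed_mark_fold
        half = config.signal_halfwidth
    else:
        centers = [p.center for p in truth.accessibility_peaks]
        fold = config.accessibility_fold_gain
        half = config.signal_halfwidth

    def uniform_reads(n: int) -> list[GenomicInterval]:
        starts = rng.integers(0, G - rl, size=n)
        return [GenomicInterval(chrom, int(s), int(s) + rl) for s in starts]

    n_bg = config.n_signal_reads
    signal = uniform_reads(n_bg)
    density = n_bg / G
    for c in centers:
        lam = (fold - 1.0) * density * 2 * half
        n_extra = int(rng.poisson(lam))
        if n_extra:
            starts = rng.integers(max(c - half, 0), min(c + half, G) - rl, size=n_extra)
            signal.extend(GenomicInterval(chrom, int(s), int(s) + rl) for s in starts)
    input_reads = uniform_reads(config.n_chromatin_input_reads)
    return signal, input_reads


# ---------------------------------------------------------------------------
# expression and TSA condition
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression_and_tsa(
    config: SimulationConfig, truth: SyntheticTruth
):
    """Two-condition expression counts and per-region accessibility counts.

    A gene's vehicle *expression level* is ``baseline + coupling * sum of
    activities of open enhancers within the coupling window of its TSS``
    (the same 50-kb edge-to-TSS proximity rule used for gene
    classification); TSA treatment additionally couples the activities
    of TSA-opened closed enhancers in the window.  Expected read counts
    are ``level * count_scale * exonic_length / 1 kb`` — proportional to
    transcript length as in real RNA-seq, so RPKM recovers the level —
    drawn NB with the configured dispersion per replicate.
    Accessibility counts are NB around a flat baseline, with the
    configured fold gain at TSA-opened regions in treated samples.
    Returns ``(ExpressionTable, ConditionCounts)`` and records true
    levels on the truth object.
    """
    from .expression import ExpressionTable  # local import to avoid cycle

    rng = config.rng(_STREAM_EXPRESSION)
    gene_ids = [g.gene_id for g in truth.genes]

    vehicle = np.full(len(gene_ids), config.baseline_expression)
    treated = np.full(len(gene_ids), config.baseline_expression)
    if truth.enhancers and truth.genes:
        truth.enhancer_gene = [
            g for g, _ in nearest_gene_many([e.region for e in truth.enhancers], truth.genes)
        ]
        w = config.coupling_window
        for enh in truth.enhancers:
            r = enh.region
            for i, g in enumerate(truth.genes):
                if g.interval.chrom != r.chrom:
                    continue
                # region edge to TSS distance
                d = max(r.start - g.tss, g.tss - (r.end - 1), 0)
                if d > w:
                    continue
                if enh.open_chromatin:
                    vehicle[i] += config.expression_coupling * enh.activity
                    treated[i] += config.expression_coupling * enh.activity
                elif enh.tsa_opened:
                    treated[i] += config.expression_coupling * enh.activity

    scale = config.expression_count_scale
    len_kb = np.array([g.exonic_length for g in truth.genes], dtype=float) / 1e3
    counts = {}
    for r in range(config.n_expression_replicates):
        counts[f"vehicle_{r + 1}"] = _nb_draw(rng, vehicle * scale * len_kb, config.nb_dispersion)
    for r in range(config.n_expression_replicates):
        counts[f"treated_{r + 1}"] = _nb_draw(rng, treated * scale * len_kb, config.nb_dispersion)
    df = pd.DataFrame(counts, index=gene_ids)
    exonic = {g.gene_id: g.exonic_length for g in truth.genes}
    table = ExpressionTable(df, exonic)
    truth.expression_means = pd.DataFrame(
        {"vehicle": vehicle, "treated": treated}, index=gene_ids
    )

    # accessibility counts over the TSA candidate universe
    regions = (
        [e.region for e in truth.enhancers]
        + [r.region for r in truth.closed_inactive_regions]
    )
    gained = np.array(
        [e.tsa_opened for e in truth.enhancers]
        + [r.tsa_opened for r in truth.closed_inactive_regions]
    )
    n_regions = len(regions)
    nrep = config.n_atac_replicates
    base = np.full(n_regions, config.atac_baseline_mean)
    cond_counts = np.zeros((n_regions, 2 * nrep))
    conditions = []
    for r in range(nrep):
        cond_counts[:, r] = _nb_draw(rng, base, config.nb_dispersion)
        conditions.append("vehicle")
    for r in range(nrep):
        mean = np.where(gained, base * config.accessibility_fold_gain, base)
        cond_counts[:, nrep + r] = _nb_draw(rng, mean, config.nb_dispersion)
        conditions.append("treated")
    lib_sizes = np.full(2 * nrep, max(cond_counts.sum(axis=0).mean(), 1.0))
    atac = ConditionCounts(regions, cond_counts, conditions, lib_sizes)
    return table, atac
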