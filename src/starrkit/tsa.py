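"""TSA-response analyses: differential accessibility, overlap with
closed active enhancers, enrichment testing and gene classification.

Trichostatin A (TSA) is a histone deacetylase inhibitor that relaxes
chromatin; regions gaining accessibility after treatment are
"TSA-induced sites".  Differential accessibility between vehicle and
treated ATAC-seq samples is assessed with a negative-binomial exact test
using a single common dispersion estimated by method of moments across
regions (a deliberately simple, fully specified test — it makes no claim
of equivalence to per-region GLM tagwise-dispersion modeling).

Downstream, closed STARR-active enhancers that gain accessibility are
tabulated against closed inactive regions in a 2x2 table, tested for
enrichment (one-sided Fisher or a log-space exact binomial tail against
a configurable background rate), and genes are labeled Class I (a
closed *active* enhancer opened by TSA within 50 kb of the TSS, no
nearby accessibility loss) or Class II (same rule with closed
*inactive* opened regions).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .calling import bh_qvalues
from .intervals import GeneModel, GenomicInterval, IntervalIndex, overlaps_any

__all__ = [
    "ConditionCounts",
    "TsaSite",
    "TwoByTwo",
    "differential_accessibility",
    "tsa_overlap_classify",
    "enrichment_test",
    "classify_gene_classes",
]

POISSON_DISPERSION_EPS = 1e-12  # below this the NB exact test runs as Poisson


@dataclass
class ConditionCounts:
    """Per-region read counts across samples of a two-condition design."""

    regions: list[GenomicInterval]
    counts: np.ndarray  # regions x samples
    conditions: list[str]  # per sample: "vehicle" | "treated"
    library_sizes: np.ndarray  # per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.regions), len(self.conditions)):
            raise ValueError("counts must be regions x samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        for cond in ("vehicle", "treated"):
            if cond not in self.conditions:
                raise ValueError(f"need >= 1 {cond} sample")
        if np.any(self.library_sizes < 1):
            raise ValueError("library sizes must be >= 1")


@dataclass
class TsaSite:
    region: GenomicInterval
    direction: str  # "gain" | "loss"
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if not (0 <= self.q_value <= 1):
            raise ValueError("q_value must lie in [0, 1]")


@dataclass
class TwoByTwo:
    """Counts: rows = STARR-active vs inactive closed regions, columns =
    TSA-induced vs not."""

    a: int  # active, induced
    b: int  # active, not induced
    c: int  # inactive, induced
    d: int  # inactive, not induced

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def odds_ratio(self) -> float:
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:  # Haldane-Anscombe correction
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# differential accessibility
# ---------------------------------------------------------------------------

def _moment_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray]) -> float:
    """Common NB dispersion by method of moments across regions.

    For NB, ``var = mu + alpha * mu^2``; per-region moment estimates at
    2-3 replicates are extremely noisy (and their median is biased low),
    so the common alpha is the pooled regression through the origin of
    the excess variance on the squared mean:
    ``alpha = sum(v_g - m_g) / sum(m_g^2)`` over both condition groups.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm_counts[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    if alpha <= POISSON_DISPERSION_EPS:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def _exact_two_group_p(y_a: int, y_b: int, n_a: int, n_b: int, alpha: float) -> float:
    """Two-sided exact test for a split of ``t = y_a + y_b`` pooled counts.

    Conditional on the total, sums the probabilities of all splits no
    more likely than the observed one, under per-condition sums
    distributed NB(mean n_c * mu, dispersion alpha / n_c) with the
    common mean mu estimated from the pooled normalized counts.
    """
    t = y_a + y_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    ks = np.arange(t + 1)
    # sum of n iid NB(mu, alpha) is NB(n*mu, alpha/n)
    la = _nb_logpmf(ks, n_a * mu, alpha / n_a)
    lb = _nb_logpmf(ks[::-1], n_b * mu, alpha / n_b)
    joint = la + lb
    denom = logsumexp(joint)
    obs = joint[y_a]
    keep = joint <= obs + 1e-10  # include ties with the observed probability
    return float(min(math.exp(logsumexp(joint[keep]) - denom), 1.0))


def differential_accessibility(
    counts: ConditionCounts,
    q_threshold: float = 0.05,
    dispersion: float | None = None,
) -> tuple[list[TsaSite], list[GenomicInterval]]:
    """Call regions with differential accessibility between conditions.

    Counts are library-size normalized to the mean depth, summed within
    condition, and tested with the common-dispersion NB exact test; BH
    correction across regions; direction from the normalized mean
    difference.  With fewer than two samples in either condition the
    dispersion cannot be estimated and the test falls back to Poisson
    (dispersion 0).  Returns ``(sites called at q < q_threshold,
    excluded all-zero regions)``.
    """
    cond = np.asarray(counts.conditions)
    idx_v = np.where(cond == "vehicle")[0]
    idx_t = np.where(cond == "treated")[0]
    norm = counts.counts * (counts.library_sizes.mean() / counts.library_sizes)

    nonzero = counts.counts.sum(axis=1) > 0
    excluded = [r for r, keep in zip(counts.regions, nonzero) if not keep]

    if dispersion is None:
        if len(idx_v) >= 2 and len(idx_t) >= 2:
            dispersion = _moment_dispersion(norm[nonzero], [idx_v, idx_t])
        else:
            dispersion = 0.0

    sites: list[TsaSite] = []
    pvals, dirs, regions = [], [], []
    for i in np.where(nonzero)[0]:
        y_v = int(round(norm[i, idx_v].sum()))
        y_t = int(round(norm[i, idx_t].sum()))
        p = _exact_two_group_p(y_t, y_v, len(idx_t), len(idx_v), dispersion)
        pvals.append(p)
        dirs.append("gain" if norm[i, idx_t].mean() >= norm[i, idx_v].mean() else "loss")
        regions.append(counts.regions[i])
    if not pvals:
        return [], excluded
    qvals = bh_qvalues(pvals)
    for region, direction, p, q in zip(regions, dirs, pvals, qvals):
        if q < q_threshold:
            sites.append(TsaSite(region, direction, float(p), float(q)))
    return sites, excluded


# ---------------------------------------------------------------------------
# overlap tabulation and enrichment
# ---------------------------------------------------------------------------

def tsa_overlap_classify(
    closed_active_peaks: Sequence[GenomicInterval],
    closed_inactive_regions: Sequence[GenomicInterval],
    tsa_gain_sites: Sequence[GenomicInterval],
) -> tuple[TwoByTwo, list[GenomicInterval]]:
    """2x2 tabulation of closed regions against TSA-induced sites.

    ``a`` = closed-active peaks overlapping >= 1 gain site, ``b`` = the
    rest; ``c``/``d`` analogously for closed-inactive regions.  The set
    of overlapping closed-active peaks is returned for downstream gene
    assignment.  The two input classes must be disjoint region sets.
    """
    if closed_active_peaks and closed_inactive_regions:
        if overlaps_any(list(closed_active_peaks), list(closed_inactive_regions)).any():
            raise ValueError("active and inactive closed region classes overlap")
    hit_active = overlaps_any(list(closed_active_peaks), list(tsa_gain_sites))
    hit_inactive = overlaps_any(list(closed_inactive_regions), list(tsa_gain_sites))
    a = int(hit_active.sum())
    c = int(hit_inactive.sum())
    table = TwoByTwo(a, len(closed_active_peaks) - a, c, len(closed_inactive_regions) - c)
    overlap_set = [r for r, h in zip(closed_active_peaks, hit_active) if h]
    return table, overlap_set


def _log_binom_sf(k: int, n: int, p0: float) -> float:
    """log10 of P(X >= k) for X ~ Binomial(n, p0), exact in log space."""
    ks = np.arange(k, n + 1)
    logs = stats.binom.logpmf(ks, n, p0)
    return float(logsumexp(logs) / math.log(10))


def enrichment_test(
    table: TwoByTwo, method: str = "fisher", p0: float | None = None
) -> tuple[float, float]:
    """Enrichment p-value and odds ratio for a 2x2 table.

    ``fisher``: one-sided hypergeometric tail in the enrichment
    direction.  ``binomial``: P(X >= a) with n = a + c and background
    success rate ``p0`` (required), summed exactly in log space so
    astronomically small tails do not underflow to zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b) == 0 or (c + d) == 0 or (a + c) + (b + d) == 0:
        raise ValueError("degenerate table margins")
    if method == "fisher":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        return float(p), table.odds_ratio
    if method == "binomial":
        if p0 is None:
            raise ValueError("binomial method requires a background rate p0")
        n = a + c
        if n == 0:
            raise ValueError("no induced regions to test")
        log10p = _log_binom_sf(a, n, p0)
        return float(10 ** log10p) if log10p > -300 else float(10.0 ** log10p), table.odds_ratio
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# gene classes
# ---------------------------------------------------------------------------

def _within_window(
    tss: int, chrom: str, idx: IntervalIndex | None, window: int
) -> bool:
    if idx is None:
        return False
    return idx.count(chrom, max(tss - window, 0), tss + window + 1) > 0


def classify_gene_classes(
    genes: Sequence[GeneModel],
    closed_active_opened: Sequence[GenomicInterval],
    closed_inactive_opened: Sequence[GenomicInterval],
    tsa_loss_sites: Sequence[GenomicInterval],
    window: int = 50_000,
) -> dict[str, str]:
    """Label genes Class I / Class II / neither by the 50-kb TSS rule.

    Class I: >= 1 closed-active enhancer opened by TSA within ``window``
    of the TSS and no accessibility-loss site within the window.
    Class II: same, but with closed-*inactive* opened regions and no
    closed-active opened region nearby.  Distance is measured from the
    region's closest edge to the TSS; the classes are disjoint by
    construction.
    """
    cao = IntervalIndex(closed_active_opened) if closed_active_opened else None
    cio = IntervalIndex(closed_inactive_opened) if closed_inactive_opened else None
    loss = IntervalIndex(tsa_loss_sites) if tsa_loss_sites else None
    out: dict[str, str] = {}
    for g in genes:
        chrom, tss = g.interval.chrom, g.tss
        if _within_window(tss, chrom, loss, window):
            out[g.gene_id] = "neither"
            continue
        has_cao = _within_window(tss, chrom, cao, window)
        has_cio = _within_window(tss, chrom, cio, window)
        if has_cao:
            out[g.gene_id] = "ClassI"
        elif has_cio:
            out[g.gene_id] = "ClassII"
        else:
            out[g.gene_id] = "neither"
    return out
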