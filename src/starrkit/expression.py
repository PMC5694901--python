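"""Linking enhancer activity to nearest-gene expression.

Expression is quantified as RPKM (reads per kilobase of exon model per
million mapped reads).  Enhancer-centric binned analyses rank peaks by
activity (and optionally by an accessibility signal), split the ranks
into near-equal contiguous bins, and summarize the nearest-gene RPKM per
bin (1-D) or per grid cell (2-D, six-by-six at defaults).  Group
comparisons use the two-sided Wilcoxon rank-sum test, exact by full
enumeration for small tie-free samples and a tie- and
continuity-corrected normal approximation otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import EnhancerPeak
from .intervals import GeneModel, nearest_gene_many

__all__ = [
    "ExpressionTable",
    "rpkm",
    "rank_bins",
    "expression_by_bins",
    "rank_sum_test",
]

EXACT_MAX_N = 12  # largest |x|+|y| for the exact rank-sum branch


class ExpressionTable:
    """Per-gene raw counts and RPKM across samples.

    ``counts`` is a genes x samples DataFrame of raw read counts;
    ``library_sizes`` maps sample -> total mapped reads (defaults to the
    column sums); ``exonic_lengths`` maps gene_id -> total exon bp.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        exonic_lengths: dict[str, int],
        library_sizes: dict[str, int] | None = None,
    ):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.exonic_lengths = dict(exonic_lengths)
        missing = set(counts.index) - set(self.exonic_lengths)
        if missing:
            raise ValueError(f"missing exonic lengths for {sorted(missing)[:3]}...")
        if library_sizes is None:
            library_sizes = {c: int(counts[c].sum()) for c in counts.columns}
        self.library_sizes = library_sizes
        for sample, size in self.library_sizes.items():
            if size < 1:
                raise ValueError(f"library size for {sample} must be >= 1")

    def rpkm(self) -> pd.DataFrame:
        lengths = np.array([self.exonic_lengths[g] for g in self.counts.index], dtype=float)
        out = {}
        for sample in self.counts.columns:
            out[sample] = rpkm(
                self.counts[sample].to_numpy(dtype=float),
                lengths,
                self.library_sizes[sample],
            )
        return pd.DataFrame(out, index=self.counts.index)

    def mean_rpkm(self, samples: Sequence[str] | None = None) -> pd.Series:
        r = self.rpkm()
        return r[list(samples)].mean(axis=1) if samples is not None else r.mean(axis=1)

    @classmethod
    def from_tsv(
        cls, path: str | Path, exonic_lengths: dict[str, int],
        library_sizes: dict[str, int] | None = None,
    ) -> "ExpressionTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, exonic_lengths, library_sizes)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


def rpkm(
    count: float | np.ndarray, exonic_length: float | np.ndarray, library_size: float
) -> float | np.ndarray:
    """``count / ((exonic_length / 1e3) * (library_size / 1e6))``."""
    exonic_length = np.asarray(exonic_length, dtype=float)
    if np.any(exonic_length < 1):
        raise ValueError("exonic_length must be >= 1")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    out = np.asarray(count, dtype=float) / ((exonic_length / 1e3) * (library_size / 1e6))
    return float(out) if np.isscalar(count) else out


def rank_bins(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Contiguous near-equal rank bins, label 0 = lowest ranks.

    Values are ranked ascending with ties broken by stable input order;
    ranks are split into ``n_bins`` contiguous blocks whose sizes differ
    by at most one, any remainder going to the lowest bins.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    if n_bins < 1 or n_bins > len(values):
        raise ValueError("need 1 <= n_bins <= len(values)")
    order = np.argsort(values, kind="stable")
    n = len(values)
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    for b, size in enumerate(sizes):
        labels[order[pos : pos + size]] = b
        pos += size
    return labels


def expression_by_bins(
    peaks: Sequence[EnhancerPeak],
    genes: Sequence[GeneModel],
    expression: ExpressionTable,
    n_bins: int = 5,
    signal: Sequence[float] | None = None,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Nearest-gene expression summarized over activity rank bins.

    Each peak contributes one observation: the mean RPKM (over
    ``samples``) of its nearest gene.  With ``signal`` given, peaks are
    independently rank-binned on activity and on the accessibility
    signal and an ``n_bins x n_bins`` grid is summarized (the 6x6
    activity-by-accessibility analysis at ``n_bins=6``); otherwise a
    1-D binning on activity.
    Returns a tidy DataFrame with bin labels, n, mean and median RPKM
    (empty cells are absent, not zero).
    """
    if not peaks:
        raise ValueError("no peaks given")
    assignments = nearest_gene_many([p.interval for p in peaks], genes)
    rpkm_per_gene = expression.mean_rpkm(samples)
    expr = np.array([rpkm_per_gene[g] for g, _ in assignments])
    act_bin = rank_bins([p.activity for p in peaks], n_bins)
    df = pd.DataFrame({"activity_bin": act_bin, "rpkm": expr})
    if signal is not None:
        if len(signal) != len(peaks):
            raise ValueError("signal must align with peaks")
        df["signal_bin"] = rank_bins(signal, n_bins)
        keys = ["activity_bin", "signal_bin"]
    else:
        keys = ["activity_bin"]
    grouped = df.groupby(keys)["rpkm"].agg(n="size", mean="mean", median="median")
    return grouped.reset_index()


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration of rank assignments when the pooled sample
    has at most 12 observations and no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: no ordering information
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))
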