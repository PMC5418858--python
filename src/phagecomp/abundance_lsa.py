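"""Genome-size-normalized abundance series and local similarity analysis.

Relative abundance of a target in a sample is the mapped-read fraction
scaled by the inverse of the target genome length in kilobases, expressed
as a percentage: RA% = 100 * (m / T) / (L / 1000).

Local similarity analysis (LSA) scores delayed local co-variation between
two equal-length series. Each series is normal-score transformed (ranks
mapped to standard normal quantiles); a dynamic program over alignments
with bounded lag accumulates the maximal positive and maximal negative
partial sums of pointwise products, and the score is the best partial sum
divided by the series length. Because a cell only depends on its diagonal
predecessor, the DP reduces to an independent maximum-subarray scan per
lag diagonal, which is what the implementation (and its vectorized
permutation test) does. Significance is a permutation p-value with the
add-one estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Relative abundance


def relative_abundance(mapped: float, total_reads: float, genome_length: float) -> float:
    """RA% = 100 * (mapped / total_reads) / (genome_length / 1000)."""
    if total_reads <= 0:
        raise ValidationError("total_reads must be positive")
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    if mapped < 0 or mapped > total_reads:
        raise ValidationError(
            f"mapped reads ({mapped}) must lie in [0, total_reads={total_reads}]"
        )
    return 100.0 * (mapped / total_reads) / (genome_length / 1000.0)


@dataclass(frozen=True)
class AbundanceSeries:
    """Time-ordered relative abundances (percent) of one target."""

    target_id: str
    genome_length: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValidationError(f"{self.target_id}: negative abundance value")


def read_counts_table(path) -> pd.DataFrame:
    """Read a long-format counts TSV.

    Columns: sample_id, time_index, total_reads, target_id, mapped_reads.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_index", "total_reads", "target_id", "mapped_reads"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"counts table missing columns {sorted(missing)}")
    return frame


def abundance_table(
    counts: pd.DataFrame, genome_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Wide table of RA% values: rows = time_index (sorted), columns = target_id."""
    frame = counts.copy()
    for target in frame["target_id"].unique():
        if target not in genome_lengths:
            raise ValidationError(f"no genome length for target {target!r}")
    frame["ra_percent"] = [
        relative_abundance(m, t, genome_lengths[g])
        for m, t, g in zip(frame["mapped_reads"], frame["total_reads"], frame["target_id"])
    ]
    wide = frame.pivot_table(
        index="time_index", columns="target_id", values="ra_percent", aggfunc="sum"
    ).sort_index()
    return wide


# ---------------------------------------------------------------------------
# Local similarity analysis


@dataclass(frozen=True)
class LSAResult:
    ls_score: float
    sign: str  # "+" or "-"
    delay: int
    p_value: float
    n_permutations: int
    seed: int | None


def normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based transform to standard normal quantiles, rank/(n+1)."""
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise ValidationError("constant series: ranks undefined")
    ranks = rankdata(x, method="average")
    return norm.ppf(ranks / (len(x) + 1))


def _interpolate_missing(x: np.ndarray, label: str) -> np.ndarray:
    """Linear interpolation of NaNs; rejects series with >25% missing."""
    x = np.asarray(x, dtype=float)
    miss = np.isnan(x)
    if not miss.any():
        return x
    if miss.mean() > 0.25:
        raise ValidationError(f"{label}: more than 25% of values missing")
    if miss.all() or (~miss).sum() < 2:
        raise ValidationError(f"{label}: not enough observed values to interpolate")
    logger.warning("%s: %d missing values linearly interpolated", label, int(miss.sum()))
    idx = np.arange(len(x))
    x = x.copy()
    x[miss] = np.interp(idx[miss], idx[~miss], x[~miss])
    return x


def _max_runs(products: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal positive and maximal negative partial sums per row.

    *products* has shape (batch, m); returns two (batch,) arrays with the
    best zero-floored running sums of +products and -products (Kadane).
    """
    batch = products.shape[0]
    s_pos = np.zeros(batch)
    s_neg = np.zeros(batch)
    best_pos = np.zeros(batch)
    best_neg = np.zeros(batch)
    for k in range(products.shape[1]):
        col = products[:, k]
        s_pos = np.maximum(0.0, s_pos + col)
        s_neg = np.maximum(0.0, s_neg - col)
        best_pos = np.maximum(best_pos, s_pos)
        best_neg = np.maximum(best_neg, s_neg)
    return best_pos, best_neg


def _diagonal_products(x: np.ndarray, Y: np.ndarray, d: int) -> np.ndarray:
    """Pointwise products x[i] * Y[:, i + d] along lag diagonal d."""
    n = x.shape[0]
    if d >= 0:
        return x[np.newaxis, : n - d] * Y[:, d:]
    return x[np.newaxis, -d:] * Y[:, : n + d]


def _ls_statistic_batch(x: np.ndarray, Y: np.ndarray, max_delay: int) -> np.ndarray:
    """Best |partial sum| / n over all lags and both signs, per row of Y."""
    n = x.shape[0]
    best = np.zeros(Y.shape[0])
    for d in range(-max_delay, max_delay + 1):
        bp, bn = _max_runs(_diagonal_products(x, Y, d))
        best = np.maximum(best, np.maximum(bp, bn))
    return best / n


def local_similarity(
    x: Sequence[float],
    y: Sequence[float],
    max_delay: int = 3,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> LSAResult:
    """Local similarity between two equal-length series.

    Delay is reported as the lag of *y* relative to *x* (positive: y
    follows x). Ties across lags resolve to the smallest ``|delay|``.
    The p-value is ``(1 + #{permuted LS >= observed}) / (1 + n_permutations)``,
    permuting *y*; with ``n_permutations=0`` the p-value is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("series too short (need n >= 4)")
    if max_delay < 0 or max_delay >= n:
        raise ValidationError("max_delay must be in [0, n)")
    x = _interpolate_missing(x, "x")
    y = _interpolate_missing(y, "y")
    zx = normal_scores(x)
    zy = normal_scores(y)

    best_score = -1.0
    best_sign = "+"
    best_delay = 0
    for d in sorted(range(-max_delay, max_delay + 1), key=lambda v: (abs(v), -v)):
        bp, bn = _max_runs(_diagonal_products(zx, zy[np.newaxis, :], d))
        for sign, val in (("+", bp[0]), ("-", bn[0])):
            if val > best_score + 1e-12:
                best_score, best_sign, best_delay = val, sign, d
    ls = best_score / n

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(zy, (n_permutations, 1)), axis=1)
        null = _ls_statistic_batch(zx, perms, max_delay)
        exceed = int(np.sum(null >= ls - 1e-12))
        p_value = (1 + exceed) / (1 + n_permutations)
    else:
        p_value = 1.0

    return LSAResult(
        ls_score=ls,
        sign=best_sign,
        delay=best_delay,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


def local_similarity_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Brute-force LS for max_delay = 0: exhaustive search over all
    contiguous intervals of the pointwise-product series, both signs.

    Independent of the DP implementation; intended for small n.
    """
    zx = normal_scores(np.asarray(x, dtype=float))
    zy = normal_scores(np.asarray(y, dtype=float))
    prod = zx * zy
    n = len(prod)
    best = 0.0
    for i in range(n):
        for j in range(i + 1, n + 1):
            s = float(np.sum(prod[i:j]))
            best = max(best, s, -s)
    return best / n


# ---------------------------------------------------------------------------
# Reports


def phage_host_report(
    abundance: pd.DataFrame,
    phage_ids: Iterable[str],
    host_id: str,
    max_delay: int = 3,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """LSA of each phage series against the host series.

    *abundance* is the wide table from :func:`abundance_table` (rows =
    time points, columns = targets, shared time grid).
    """
    if host_id not in abundance.columns:
        raise ValidationError(f"host {host_id!r} not in abundance table")
    rows = []
    host = abundance[host_id].to_numpy()
    for pid in phage_ids:
        if pid not in abundance.columns:
            raise ValidationError(f"phage {pid!r} not in abundance table")
        res = local_similarity(
            host, abundance[pid].to_numpy(),
            max_delay=max_delay, n_permutations=n_permutations, seed=seed,
        )
        rows.append(
            {
                "host_id": host_id,
                "phage_id": pid,
                "ls_score": res.ls_score,
                "sign": res.sign,
                "delay": res.delay,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)


def functional_profile(
    gene_counts: pd.DataFrame,
    categories: Mapping[str, str],
    unknown_label: str = "unknown",
) -> pd.DataFrame:
    """Per-sample transcript percentages by functional category.

    *gene_counts* has genes as rows (index = gene_id) and samples as
    columns. Genes whose category is *unknown_label* (or unmapped) are
    excluded from the denominator; a sample with no known-function reads
    yields missing values with a warning.
    """
    cat = pd.Series({g: categories.get(g, unknown_label) for g in gene_counts.index})
    known = cat[cat != unknown_label]
    by_cat = gene_counts.loc[known.index].groupby(known).sum()
    totals = by_cat.sum(axis=0)
    out = by_cat.divide(totals, axis=1) * 100.0
    for sample in out.columns[totals == 0]:
        logger.warning("sample %s: no known-function reads; percentages missing", sample)
    return out
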