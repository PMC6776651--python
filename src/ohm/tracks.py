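"""Correlating per-bin tracks: binned signals, Spearman and partial Spearman,
chunk-randomized controls, quartile stratification, Mood's median test and
bivariate-Gaussian summaries.

Signals (peak sets or quantitative tracks) are summarized onto genomic bins
(10 kb by default in the analyses this supports): peak sets as the fraction
of the bin covered after resizing each peak to 1 kb around its center,
quantitative tracks as the coverage-weighted mean.  Correlations are rank
based; genomic autocorrelation is controlled by permuting 200-kb blocks of
bins rather than single bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binmatrix import BinTable
from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)
from .structure import GenomicTrack

BinnedSignal = GenomicTrack  # a per-bin scalar summary of an external signal


def _values(x) -> np.ndarray:
    if isinstance(x, GenomicTrack):
        return x.values
    return np.asarray(x, dtype=float)


def resize_peaks(intervals: pd.DataFrame, width: int = 1000) -> pd.DataFrame:
    """Resize each interval to ``width`` bp around its center."""
    center = (intervals["start"] + intervals["end"]) // 2
    out = intervals.copy()
    out["start"] = np.maximum(center - width // 2, 0)
    out["end"] = center - width // 2 + width
    return out


def bin_signal(
    intervals: pd.DataFrame,
    bins: BinTable,
    mode: str = "fraction",
    resize_to: int | None = None,
) -> BinnedSignal:
    """Summarize intervals (0-based half-open) onto genomic bins.

    ``mode="fraction"``: fraction of each bin covered by the (merged)
    intervals -- the summary used for peak sets, optionally after resizing
    each peak to ``resize_to`` bp around its center.  ``mode="mean"``:
    coverage-weighted mean of the ``value`` column (bedGraph-style tracks);
    NaN where nothing overlaps.  Intervals beyond the chromosome end are
    clipped with a warning.
    """
    if mode not in ("fraction", "mean"):
        raise InvalidParameterError(f"unknown mode: {mode}")
    df = intervals
    if resize_to is not None:
        df = resize_peaks(df, resize_to)
    res = bins.resolution
    cover = np.zeros(bins.n_bins)
    wsum = np.zeros(bins.n_bins)
    clipped = 0
    for chrom, L in bins.chrom_sizes.items():
        sub = df.loc[df["chrom"] == chrom]
        if len(sub) == 0:
            continue
        starts = sub["start"].to_numpy().astype(np.int64)
        ends = sub["end"].to_numpy().astype(np.int64)
        vals = sub["value"].to_numpy(dtype=float) if "value" in sub else np.ones(len(sub))
        if (ends > L).any() or (starts < 0).any():
            clipped += int(((ends > L) | (starts < 0)).sum())
            starts = np.clip(starts, 0, L)
            ends = np.clip(ends, 0, L)
        if mode == "fraction":
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            merged = []
            cur_s, cur_e = None, None
            for s, e in zip(starts, ends):
                if e <= s:
                    continue
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                merged.append((cur_s, cur_e))
            spans = merged
            vals_iter = [1.0] * len(merged)
        else:
            spans = list(zip(starts, ends))
            vals_iter = vals
        off = bins.chrom_slice(chrom).start
        for (s, e), v in zip(spans, vals_iter):
            if e <= s:
                continue
            b0, b1 = s // res, (e - 1) // res
            if b0 == b1:
                cover[off + b0] += e - s
                wsum[off + b0] += v * (e - s)
            else:
                first = (b0 + 1) * res - s
                cover[off + b0] += first
                wsum[off + b0] += v * first
                last = e - b1 * res
                cover[off + b1] += last
                wsum[off + b1] += v * last
                if b1 - b0 > 1:
                    cover[off + b0 + 1:off + b1] += res
                    wsum[off + b0 + 1:off + b1] += v * res
    if clipped:
        warnings.warn(f"{clipped} interval(s) extended beyond the chromosome; clipped")
    if mode == "fraction":
        # terminal bins may be shorter than the resolution
        bin_len = np.empty(bins.n_bins)
        for chrom, L in bins.chrom_sizes.items():
            sl = bins.chrom_slice(chrom)
            starts = np.arange(0, L, res)
            bin_len[sl] = np.minimum(starts + res, L) - starts
        values = cover / bin_len
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(cover > 0, wsum / cover, np.nan)
    return BinnedSignal(bins=bins, values=values, metadata={"mode": mode})


def spearman_pairwise(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties), dropping incomplete pairs."""
    xv, yv = _values(x), _values(y)
    ok = np.isfinite(xv) & np.isfinite(yv)
    if ok.sum() < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    rho, p = stats.spearmanr(xv[ok], yv[ok])
    return float(rho), float(p)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y controlling for z.

    Ranks all three variables (mid-rank ties) over complete triples, then
    applies the partial-Pearson formula
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` with a
    t-approximation on ``n - 3`` degrees of freedom for the p-value.
    """
    xv, yv, zv = _values(x), _values(y), _values(z)
    ok = np.isfinite(xv) & np.isfinite(yv) & np.isfinite(zv)
    n = int(ok.sum())
    if n < 4:
        raise InsufficientDataError("need at least 4 complete triples")
    rx = stats.rankdata(xv[ok])
    ry = stats.rankdata(yv[ok])
    rz = stats.rankdata(zv[ok])
    rxy = np.corrcoef(rx, ry)[0, 1]
    rxz = np.corrcoef(rx, rz)[0, 1]
    ryz = np.corrcoef(ry, rz)[0, 1]
    if abs(rxz) >= 1.0 - 1e-12 or abs(ryz) >= 1.0 - 1e-12:
        raise DegenerateFitError("control variable perfectly correlated with input")
    r = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def chunk_randomize(signal: BinnedSignal, chunk_bp: int = 200_000, seed: int = 0) -> BinnedSignal:
    """Permute consecutive blocks of bins within each chromosome.

    Blocks span ``chunk_bp`` (must be a multiple of the bin size); values
    within a block keep their order, so the value multiset is conserved
    exactly while long-range positional structure is destroyed.
    """
    bins = signal.bins
    if chunk_bp % bins.resolution != 0:
        raise InvalidParameterError("chunk_bp must be a multiple of the bin size")
    k = chunk_bp // bins.resolution
    rng = np.random.default_rng(seed)
    values = signal.values.copy()
    for chrom in bins.chrom_sizes:
        sl = bins.chrom_slice(chrom)
        v = values[sl]
        blocks = [v[i:i + k] for i in range(0, len(v), k)]
        order = rng.permutation(len(blocks))
        values[sl] = np.concatenate([blocks[i] for i in order])
    return BinnedSignal(bins=bins, values=values, metadata={**signal.metadata,
                                                           "chunk_randomized": chunk_bp})


def quartile_stratify(y, by) -> list[np.ndarray]:
    """Partition complete bins into quartiles of ``by`` (low to high).

    Ties are resolved by mid-rank then stable index order; the four groups
    differ in size by at most one bin.  Returns index arrays into the track.
    """
    yv, bv = _values(y), _values(by)
    ok = np.flatnonzero(np.isfinite(yv) & np.isfinite(bv))
    r = stats.rankdata(bv[ok])
    order = ok[np.argsort(r, kind="stable")]
    return [np.asarray(g) for g in np.array_split(order, 4)]


def mood_median_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Mood's median test across groups.

    Chi-square test on counts above/below the pooled grand median, with
    values tied at the median counted below; no continuity correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidParameterError("need >= 2 nonempty groups")
    grand = np.median(np.concatenate(groups))
    if any(np.all(g == grand) for g in groups):
        warnings.warn("a group lies entirely at the grand median; test is degenerate")
    stat, p, _, _ = stats.median_test(
        *groups, ties="below", correction=False, lambda_="pearson"
    )
    return float(stat), float(p)


@dataclass
class GaussianFit:
    """Sample bivariate Gaussian with its Mahalanobis-2 ellipse."""

    mean: np.ndarray
    cov: np.ndarray
    ellipse_center: np.ndarray
    ellipse_axes: np.ndarray  # semi-axis lengths at Mahalanobis distance 2
    ellipse_angle: float  # radians, major axis vs x


def fit_bivariate_gaussian(x, y, mahalanobis: float = 2.0) -> GaussianFit:
    """Fit a bivariate Gaussian and its ±2-SD (Mahalanobis 2) ellipse."""
    xv, yv = _values(x), _values(y)
    ok = np.isfinite(xv) & np.isfinite(yv)
    if ok.sum() < 3:
        raise InsufficientDataError("need at least 3 complete points")
    pts = np.column_stack([xv[ok], yv[ok]])
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    scale = np.trace(cov)
    if scale <= 0 or np.linalg.det(cov) <= 1e-12 * scale ** 2:
        raise DegenerateFitError("singular covariance; points are collinear")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    axes = mahalanobis * np.sqrt(evals)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return GaussianFit(
        mean=mean,
        cov=cov,
        ellipse_center=mean,
        ellipse_axes=axes,
        ellipse_angle=angle,
    )
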