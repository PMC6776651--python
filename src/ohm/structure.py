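"""Pairing score, insulation score, boundary calling and overlap statistics.

The pairing score of bin *i* is the log2 of the mean balanced trans-homolog
contact frequency over all bin pairs within a window of +/-W bins around the
homologous diagonal; it quantifies contacts between homologous loci and their
immediate neighbours.  The insulation score of bin *i* sums balanced contacts
crossing it within a fixed window, normalized by the genome-wide median and
log2-transformed; local minima of sufficient prominence are insulating
boundaries.  Boundary sets are compared by tolerant overlap percentages with
a randomized-subset null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .binmatrix import BinnedMap, BinTable
from .errors import InvalidParameterError


@dataclass
class GenomicTrack:
    """A per-bin scalar track (NaN = undefined)."""

    bins: BinTable
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.bins.n_bins:
            raise InvalidParameterError("track length must match the bin table")

    def to_bedgraph(self, path) -> None:
        df = self.bins.to_frame()
        df["value"] = self.values
        df = df.dropna(subset=["value"])
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class BoundarySet:
    """Called insulating boundaries: global bin indices with prominences."""

    bins: BinTable
    table: pd.DataFrame  # columns: bin, prominence

    def __len__(self):
        return len(self.table)

    @property
    def bin_ids(self) -> np.ndarray:
        return self.table["bin"].to_numpy()

    def to_bed(self, path) -> None:
        frame = self.bins.to_frame().loc[self.bin_ids].reset_index()
        frame["name"] = "boundary"
        frame["score"] = self.table["prominence"].to_numpy()
        frame[["chrom", "start", "end", "name", "score"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def _chrom_diagonals(m: sp.csr_matrix, sl: slice, max_offset: int) -> dict[int, np.ndarray]:
    """Diagonals 0..max_offset of one chromosome's square block."""
    block = m[sl, sl]
    return {d: block.diagonal(d) for d in range(max_offset + 1)}


def pairing_score(
    cmap: BinnedMap,
    W: int = 3,
    component: str = "trans_homolog",
    max_masked_fraction: float = 0.5,
    truncate_ends: bool = True,
) -> GenomicTrack:
    """Pairing score: log2 mean balanced CF over the (2W+1)^2 window pairs.

    Window pairs involving masked bins are excluded from the mean; the score
    is NaN where more than ``max_masked_fraction`` of the window pairs are
    masked.  At chromosome ends the window is truncated (or NaN with
    ``truncate_ends=False``).  ``W=0`` reduces to log2 of the diagonal.
    """
    if W < 0:
        raise InvalidParameterError("W must be >= 0")
    bal = cmap.balanced(component)
    good = (~cmap.mask).astype(float)
    out = np.full(cmap.bins.n_bins, np.nan)
    for chrom in cmap.bins.chrom_sizes:
        sl = cmap.bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n == 0:
            continue
        diags = _chrom_diagonals(bal, sl, min(2 * W, n - 1))
        g = good[sl]
        total = np.zeros(n)
        # windowed sum of good-bin indicators; valid pair count is its square
        gsum = np.zeros(n)
        for a in range(-W, W + 1):
            lo, hi = max(0, -a), n - max(0, a)
            gsum[lo:hi] += g[lo + a:hi + a]
        for a in range(-W, W + 1):
            for b in range(-W, W + 1):
                d = abs(b - a)
                if d >= n:
                    continue
                D = diags[d]
                j0 = min(a, b)  # row index offset of the diagonal entry
                # contribution to total[i] is A[i+a, i+b] = D[i + j0]
                lo = max(0, -j0)
                hi = min(n, len(D) - j0)
                if hi <= lo:
                    continue
                total[lo:hi] += D[lo + j0:hi + j0]
        full = np.zeros(n)
        for a in range(-W, W + 1):
            lo, hi = max(0, -a), n - max(0, a)
            full[lo:hi] += 1.0
        valid = gsum ** 2
        window_pairs = full ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            ps = np.log2(total / valid)
        ps[valid < (1.0 - max_masked_fraction) * window_pairs] = np.nan
        ps[g == 0] = np.nan
        if not truncate_ends:
            ps[full < 2 * W + 1] = np.nan
        out[sl] = ps
    return GenomicTrack(
        bins=cmap.bins,
        values=out,
        metadata={"kind": "pairing_score", "W": W, "component": component},
    )


def insulation_score(
    cmap: BinnedMap,
    window_bp: int = 40_000,
    component: str = "trans_homolog",
    max_masked_fraction: float = 0.5,
) -> GenomicTrack:
    """Insulation score: log2 of the median-normalized crossing-contact sum.

    For each bin *i*, sums balanced contacts between ``a in [i-w, i-1]`` and
    ``b in [i+1, i+w]`` (``w = window_bp / resolution`` bins on each side).
    Windows with masked pairs are rescaled to the full pair count; the score
    is NaN where the window is incomplete (chromosome ends), where bin *i*
    itself is masked, or where more than ``max_masked_fraction`` of window
    pairs are masked.  The raw sums are divided by their genome-wide median
    before the log2, so the un-logged track has median 1 by construction.
    """
    if window_bp % cmap.resolution != 0:
        raise InvalidParameterError("window_bp must be a multiple of the resolution")
    w = window_bp // cmap.resolution
    if w < 1:
        raise InvalidParameterError("window must span at least one bin per side")
    bal = cmap.balanced(component)
    good = (~cmap.mask).astype(float)
    raw = np.full(cmap.bins.n_bins, np.nan)
    for chrom in cmap.bins.chrom_sizes:
        sl = cmap.bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n == 0:
            continue
        diags = _chrom_diagonals(bal, sl, min(2 * w, n - 1))
        g = good[sl]
        total = np.zeros(n)
        for a in range(1, w + 1):
            for b in range(1, w + 1):
                d = a + b
                if d >= n:
                    continue
                D = diags[d]
                # contribution to total[i]: A[i-a, i+b] = D[i - a]
                lo, hi = a, min(n, len(D) + a)
                total[lo:hi] += D[lo - a:hi - a]
        left = np.zeros(n)
        right = np.zeros(n)
        for a in range(1, w + 1):
            left[a:] += g[:-a]
            right[:-a] += g[a:]
        valid = left * right
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = total * (w * w) / valid
        scaled[valid < (1.0 - max_masked_fraction) * w * w] = np.nan
        scaled[g == 0] = np.nan
        idx = np.arange(n)
        scaled[(idx < w) | (idx >= n - w)] = np.nan
        raw[sl] = scaled
    med = np.nanmedian(raw)
    if not np.isfinite(med) or med <= 0:
        values = np.full_like(raw, np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.log2(raw / med)
        values[~np.isfinite(values)] = np.nan
    return GenomicTrack(
        bins=cmap.bins,
        values=values,
        metadata={
            "kind": "insulation",
            "window_bp": window_bp,
            "component": component,
            "median": float(med) if np.isfinite(med) else np.nan,
        },
    )


def _peakdet(values: np.ndarray, delta: float):
    """Alternating extremum detection (Billauer's peakdet).

    A maximum is emitted once the series drops ``delta`` below the running
    maximum, a minimum once it rises ``delta`` above the running minimum.
    Returns (maxima, minima) as lists of (index, value).
    """
    maxima, minima = [], []
    mn, mx = np.inf, -np.inf
    mnpos = mxpos = -1
    look_for_max = True
    for i, v in enumerate(values):
        if v > mx:
            mx, mxpos = v, i
        if v < mn:
            mn, mnpos = v, i
        if look_for_max:
            if v < mx - delta:
                maxima.append((mxpos, mx))
                mn, mnpos = v, i
                look_for_max = False
        else:
            if v > mn + delta:
                minima.append((mnpos, mn))
                mx, mxpos = v, i
                look_for_max = True
    return maxima, minima


def call_boundaries(
    track: GenomicTrack,
    prominence_cutoff: float = 0.3,
    mask: np.ndarray | None = None,
) -> BoundarySet:
    """Call insulating boundaries as prominent local minima of the track.

    Minima are detected with the peakdet delta algorithm (delta equal to the
    cutoff); the prominence of a minimum is the smaller of the rises to its
    adjacent detected maxima (or to the extreme of the remaining segment at
    the track ends).  Minima with prominence below the cutoff, and minima
    adjacent (within one bin) to a masked or NaN bin, are discarded.
    Invariant under adding a constant to the track.
    """
    if prominence_cutoff <= 0:
        raise InvalidParameterError("prominence_cutoff must be > 0")
    values = track.values
    bad = ~np.isfinite(values)
    if mask is not None:
        bad = bad | np.asarray(mask, dtype=bool)
    rows = []
    for chrom in track.bins.chrom_sizes:
        sl = track.bins.chrom_slice(chrom)
        v = values[sl]
        b = bad[sl]
        n = len(v)
        # contiguous finite segments
        finite = np.isfinite(v)
        starts = np.flatnonzero(finite & ~np.roll(finite, 1))
        if finite.any() and finite[0]:
            starts = np.union1d(starts, [0])
        for s0 in starts:
            e0 = s0
            while e0 < n and finite[e0]:
                e0 += 1
            seg = v[s0:e0]
            if len(seg) < 3:
                continue
            maxima, minima = _peakdet(seg, prominence_cutoff)
            for pos, val in minima:
                left = [m for m in maxima if m[0] < pos]
                right = [m for m in maxima if m[0] > pos]
                left_rise = (left[-1][1] - val) if left else (np.max(seg[: pos + 1]) - val)
                right_rise = (right[0][1] - val) if right else (np.max(seg[pos:]) - val)
                prom = min(left_rise, right_rise)
                if prom < prominence_cutoff:
                    continue
                gpos = sl.start + s0 + pos
                lo, hi = s0 + pos - 1, s0 + pos + 1
                if (lo >= 0 and b[lo]) or (hi < n and b[hi]) or b[s0 + pos]:
                    continue
                rows.append((gpos, prom))
    table = pd.DataFrame(rows, columns=["bin", "prominence"]).astype(
        {"bin": np.int64, "prominence": float}
    )
    return BoundarySet(bins=track.bins, table=table)


def _overlap_fraction(a_ids, b_ids, chrom_of, tolerance: int) -> float:
    """Fraction of A boundaries with a B boundary within tolerance (same chrom)."""
    if len(a_ids) == 0:
        return np.nan
    hits = 0
    b_by_chrom = {}
    for bid in b_ids:
        b_by_chrom.setdefault(chrom_of(bid), []).append(bid)
    b_by_chrom = {c: np.sort(np.array(v)) for c, v in b_by_chrom.items()}
    for aid in a_ids:
        arr = b_by_chrom.get(chrom_of(aid))
        if arr is None or len(arr) == 0:
            continue
        i = np.searchsorted(arr, aid)
        near = min(
            abs(int(arr[min(i, len(arr) - 1)]) - int(aid)),
            abs(int(arr[max(i - 1, 0)]) - int(aid)),
        )
        if near <= tolerance:
            hits += 1
    return hits / len(a_ids)


def boundary_overlap(
    a: BoundarySet, b: BoundarySet, tolerance_bins: int = 4
) -> dict[str, float]:
    """Tolerant overlap percentages between two boundary sets.

    A boundary overlaps if the other set has a boundary within
    ``tolerance_bins`` on the same chromosome.  Returns the percentage of A
    overlapping B, of B overlapping A, and their mean.
    """
    if not a.bins.compatible(b.bins):
        raise InvalidParameterError("boundary sets are on different bin tables")
    bins = a.bins
    chrom_starts = {c: bins.chrom_slice(c) for c in bins.chrom_sizes}

    def chrom_of(bid: int) -> str:
        for c, sl in chrom_starts.items():
            if sl.start <= bid < sl.stop:
                return c
        raise InvalidParameterError(f"bin id out of range: {bid}")

    pct_a = 100.0 * _overlap_fraction(a.bin_ids, b.bin_ids, chrom_of, tolerance_bins)
    pct_b = 100.0 * _overlap_fraction(b.bin_ids, a.bin_ids, chrom_of, tolerance_bins)
    return {
        "pct_a_in_b": pct_a,
        "pct_b_in_a": pct_b,
        "mean_pct": (pct_a + pct_b) / 2.0,
    }


def random_overlap_null(
    a_size: int,
    b_size: int,
    visible_bins: np.ndarray,
    bins: BinTable,
    tolerance_bins: int = 4,
    n_reps: int = 10,
    seed: int = 0,
    observed: float | None = None,
) -> dict:
    """Overlap expected between random boundary sets of the given sizes.

    Draws ``n_reps`` pairs of uniform random subsets of ``visible_bins``,
    computes the mean overlap percentage for each, and (when ``observed`` is
    given) a two-sided one-sample t-test of the replicate distribution
    against the observed overlap.
    """
    if n_reps < 2:
        raise InvalidParameterError("n_reps must be >= 2")
    visible_bins = np.asarray(visible_bins)
    if len(visible_bins) < max(a_size, b_size):
        raise InvalidParameterError("not enough visible bins for the set sizes")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        a_ids = rng.choice(visible_bins, a_size, replace=False)
        b_ids = rng.choice(visible_bins, b_size, replace=False)
        a_set = BoundarySet(
            bins=bins, table=pd.DataFrame({"bin": np.sort(a_ids), "prominence": 0.0})
        )
        b_set = BoundarySet(
            bins=bins, table=pd.DataFrame({"bin": np.sort(b_ids), "prominence": 0.0})
        )
        reps.append(boundary_overlap(a_set, b_set, tolerance_bins)["mean_pct"])
    reps = np.array(reps)
    result = {"expected_pct": float(reps.mean()), "sd_pct": float(reps.std(ddof=1)),
              "replicates": reps}
    if observed is not None:
        t, p = stats.ttest_1samp(reps, observed)
        result["t"] = float(t)
        result["p_value"] = float(p)
    return result


def insulation_delta(condition: GenomicTrack, control: GenomicTrack) -> GenomicTrack:
    """Per-bin insulation change, condition minus control (NaN-propagating)."""
    if not condition.bins.compatible(control.bins):
        raise InvalidParameterError("tracks are on different bin tables")
    wa = condition.metadata.get("window_bp")
    wb = control.metadata.get("window_bp")
    if wa is not None and wb is not None and wa != wb:
        raise InvalidParameterError("tracks were computed with different windows")
    return GenomicTrack(
        bins=condition.bins,
        values=condition.values - control.values,
        metadata={"kind": "insulation_delta", "window_bp": wa},
    )
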