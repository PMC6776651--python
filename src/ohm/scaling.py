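"""Contact frequency versus genomic separation, P(s), and byproduct estimation.

P(s) is computed on exponentially spaced separation bins (8 per decade by
default, spanning 10 bp - 10 Mb): the number of observed contacts in a
separation range divided by the total number of base-pair locus pairs
separated by such distances.  Curves can be stratified by pair class (cis /
trans-homolog) and by mutual read orientation (inward / outward / tandem),
which is what exposes the Hi-C byproduct signatures: dangling ends enrich
inward pairs below ~1 kb, self-circles enrich outward pairs up to ~10 kb, and
hairpin loops enrich same-strand pairs below ~500 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import pairs as _pairs
from .errors import InvalidParameterError

ORIENTATIONS = ("inward", "outward", "tandem")


@dataclass
class ScalingCurve:
    """Contact frequency on an exponential separation grid.

    ``frequency = observed / possible`` per bin ``(edges[k], edges[k+1]]``;
    NaN where no locus pair exists at those separations.
    """

    edges: np.ndarray
    observed: np.ndarray
    possible: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        self.possible = np.asarray(self.possible, dtype=float)
        if (np.diff(self.edges) <= 0).any():
            raise InvalidParameterError("bin edges must be strictly increasing")

    @property
    def frequency(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.observed / self.possible
        return np.where(self.possible > 0, f, np.nan)

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of(self, s: float) -> int:
        """Index of the bin ``(a, b]`` containing separation ``s``."""
        idx = int(np.searchsorted(self.edges, s, side="left")) - 1
        if idx < 0 or idx >= self.n_bins:
            raise InvalidParameterError(f"separation {s} outside the grid")
        return idx

    def frequency_at(self, s: float) -> float:
        return float(self.frequency[self.bin_of(s)])

    def same_grid(self, other: "ScalingCurve") -> bool:
        return len(self.edges) == len(other.edges) and np.allclose(
            self.edges, other.edges
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_lo": self.edges[:-1],
                "s_hi": self.edges[1:],
                "observed": self.observed,
                "possible": self.possible,
                "frequency": self.frequency,
            }
        )


@dataclass
class ByproductReport:
    """Upper estimates of byproduct fractions of the library."""

    f_dangling: float
    f_self_circle: float
    f_hairpin: float
    baseline: np.ndarray  # per-orientation-combination baseline frequency per bin
    n_total: int


def make_log_bins(s_min: float, s_max: float, bins_per_decade: int = 8) -> np.ndarray:
    """Geometric bin edges ``s_min * 10^(k / bins_per_decade)`` covering ``s_max``."""
    if bins_per_decade <= 0:
        raise InvalidParameterError("bins_per_decade must be > 0")
    if not 0 < s_min < s_max:
        raise InvalidParameterError("need 0 < s_min < s_max")
    n = int(np.ceil(np.log10(s_max / s_min) * bins_per_decade - 1e-9))
    k = np.arange(n + 1)
    return s_min * 10 ** (k / bins_per_decade)


def possible_pairs(edges: np.ndarray, chrom_sizes: Mapping[str, int]) -> np.ndarray:
    """Base-pair locus pairs per separation bin.

    For bin ``(a, b]``, counts integer separations ``s`` from ``floor(a)+1`` to
    ``floor(b)`` and sums ``L - s`` over chromosomes (closed-form arithmetic
    series; zero where the bin lies beyond the chromosome).
    """
    edges = np.asarray(edges, dtype=float)
    out = np.zeros(len(edges) - 1)
    lo_all = np.floor(edges[:-1]).astype(np.int64) + 1
    hi_all = np.floor(edges[1:]).astype(np.int64)
    for L in chrom_sizes.values():
        s1 = np.maximum(lo_all, 1)
        s2 = np.minimum(hi_all, L - 1)
        m = s2 - s1 + 1
        valid = m > 0
        contrib = np.zeros_like(out)
        contrib[valid] = m[valid] * L - (s1[valid] + s2[valid]) * m[valid] / 2.0
        out += contrib
    return out


def _bin_counts(s: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per ``(a, b]`` bin."""
    idx = np.searchsorted(edges, s, side="left") - 1
    ok = (idx >= 0) & (idx < len(edges) - 1) & (s > edges[0])
    return np.bincount(idx[ok], minlength=len(edges) - 1).astype(float)


def compute_ps(
    records: pd.DataFrame,
    edges: np.ndarray,
    chrom_sizes: Mapping[str, int],
    pair_class: str | None = None,
    orientation: str | Iterable[str] | None = None,
) -> ScalingCurve:
    """P(s) for same-chromosome contacts of one class and orientation subset.

    ``pair_class`` is ``"cis"`` or ``"trans_homolog"`` (classified from the
    haplotype tags), or ``None`` to pool all same-chromosome records including
    haplotype-unassigned ones (used for byproduct estimation, which does not
    need phasing).  For trans-homolog pairs the separation is the distance
    between homologous coordinates, and the same locus-pair denominator is
    used; the convention cancels in every downstream ratio.
    """
    if pair_class not in (None, "cis", "trans_homolog"):
        raise InvalidParameterError(f"unsupported class filter: {pair_class}")
    df = records
    df = df.loc[_pairs._eq_cols(df["chrom1"], df["chrom2"])]
    if pair_class is not None and len(df):
        df = df.loc[(_pairs.classify(df) == pair_class).to_numpy()]
    if orientation is not None and len(df):
        if isinstance(orientation, str):
            orientation = (orientation,)
        _, orient = _pairs.separation_and_orientation(df)
        df = df.loc[orient.isin(orientation).to_numpy()]
    s = (df["pos2"].to_numpy() - df["pos1"].to_numpy()) if len(df) else np.empty(0)
    observed = _bin_counts(s, np.asarray(edges, dtype=float))
    return ScalingCurve(
        edges=np.asarray(edges, dtype=float),
        observed=observed,
        possible=possible_pairs(edges, chrom_sizes),
        labels={"pair_class": pair_class, "orientation": orientation},
    )


def trans_heterolog_frequency(
    records: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    cross_parent: bool = False,
) -> float:
    """Average trans-heterolog contact frequency.

    Plain mode divides the trans-heterolog pair count by the number of
    heterologous base-pair locus pairs ``sum_{c<c'} L_c * L_c'``.  With
    ``cross_parent=True`` only pairs joining different parents are counted and
    the denominator doubles (two cross-parent haplotype combinations per locus
    pair), which puts the scalar on the same per-haplotype-pair scale as the
    trans-homolog P(s) and is the convention of the no-pairing null.
    """
    cls = _pairs.classify(records)
    het = records.loc[(cls == "trans_heterolog").to_numpy()]
    if cross_parent:
        het = het.loc[~_pairs._eq_cols(het["hap1"], het["hap2"])]
    sizes = list(chrom_sizes.values())
    denom = 0.0
    for i, La in enumerate(sizes):
        for Lb in sizes[i + 1:]:
            denom += float(La) * float(Lb)
    if cross_parent:
        denom *= 2.0
    if denom == 0:
        raise InvalidParameterError("need at least two chromosomes")
    return len(het) / denom


def _arm_coordinates(pos, chrom, chrom_sizes, centromeres):
    """Distance to centromere and arm length for each locus (vectorized)."""
    x = np.empty(len(pos), dtype=float)
    arm_len = np.empty(len(pos), dtype=float)
    for c, L in chrom_sizes.items():
        cen = centromeres.get(c, 0)
        m = chrom == c
        p = pos[m]
        right = p >= cen
        x[m] = np.where(right, p - cen, cen - p)
        arm_len[m] = np.where(right, L - cen, cen)
    return x, arm_len


def rabl_ps(
    records: pd.DataFrame,
    edges: np.ndarray,
    chrom_sizes: Mapping[str, int],
    centromeres: Mapping[str, int] | None = None,
) -> ScalingCurve:
    """Coalignment curve of heterologous arms (Rabl configuration).

    For each trans-heterolog pair, each side's distance to its centromere
    ``x`` and arm length ``L`` define the position mismatch
    ``s = |x1 - x2 / L2 * L1|``; mismatches are binned like separations.  The
    denominator counts rescaled locus pairs per mismatch bin, evaluated by
    discretized integration over arm pairs.  Records on an arm of zero length
    are skipped (their count is reported in ``labels["skipped"]``).
    """
    centromeres = dict(centromeres or {})
    cls = _pairs.classify(records)
    het = records.loc[(cls == "trans_heterolog").to_numpy()]
    chrom1 = het["chrom1"].to_numpy(dtype=object)
    chrom2 = het["chrom2"].to_numpy(dtype=object)
    x1, L1 = _arm_coordinates(het["pos1"].to_numpy() - 1, chrom1, chrom_sizes, centromeres)
    x2, L2 = _arm_coordinates(het["pos2"].to_numpy() - 1, chrom2, chrom_sizes, centromeres)
    ok = (L1 > 0) & (L2 > 0)
    s = np.abs(x1[ok] - x2[ok] / L2[ok] * L1[ok])
    observed = _bin_counts(s, np.asarray(edges, dtype=float))

    # denominator: rescaled locus pairs per mismatch bin, over all arm pairs
    edges = np.asarray(edges, dtype=float)
    possible = np.zeros(len(edges) - 1)
    arms = []
    for c, L in chrom_sizes.items():
        cen = centromeres.get(c, 0)
        for arm_len in (cen, L - cen):
            if arm_len > 0:
                arms.append((c, float(arm_len)))
    n_grid = 512
    for i, (ca, La) in enumerate(arms):
        for cb, Lb in arms:
            if ca == cb:
                continue
            # x2 on arm b rescaled into arm a's coordinates; count x1 within bin
            u = (np.arange(n_grid) + 0.5) / n_grid * La  # rescaled positions
            du = Lb / n_grid  # each grid cell represents this many x2 bp
            for k in range(len(edges) - 1):
                a, b = edges[k], edges[k + 1]
                span = np.clip(np.minimum(u + b, La) - np.maximum(u + a, 0.0), 0, None)
                span += np.clip(
                    np.minimum(u - a, La) - np.maximum(u - b, 0.0), 0, None
                )
                possible[k] += float(span.sum() * du) / 2.0  # unordered arm pairs
    return ScalingCurve(
        edges=edges,
        observed=observed,
        possible=possible,
        labels={"pair_class": "rabl", "skipped": int((~ok).sum())},
    )


def estimate_byproducts(
    inward: ScalingCurve,
    outward: ScalingCurve,
    tandem: ScalingCurve,
    n_total: int,
    baseline_flat_below: float = 1000.0,
    dangling_max_s: float = 1000.0,
    self_circle_max_s: float = 10_000.0,
    hairpin_max_s: float = 500.0,
) -> ByproductReport:
    """Upper estimates of dangling-end, self-circle and hairpin-loop fractions.

    The true contact curve is assumed to follow the same-strand (tandem) pairs
    above 1 kb and to be flat below; the baseline is expressed per single
    orientation combination (the pooled tandem curve counts two of the four
    combinations, inward and outward one each).  Each byproduct fraction is
    the clamped excess of its orientation curve over the baseline, summed over
    its separation window and divided by the library size.
    """
    for other in (outward, tandem):
        if not inward.same_grid(other):
            raise InvalidParameterError("orientation curves must share a grid")
    if n_total <= 0:
        raise InvalidParameterError("n_total must be > 0")
    tandem_freq = tandem.frequency
    per_combo = tandem_freq / 2.0  # tandem pools (+,+) and (-,-)
    ref = tandem.bin_of(baseline_flat_below)
    baseline = per_combo.copy()
    flat_region = tandem.edges[1:] <= baseline_flat_below
    baseline[flat_region] = per_combo[ref]

    def excess(curve: ScalingCurve, n_combos: float, max_s: float) -> float:
        window = curve.edges[:-1] < max_s
        diff = np.nan_to_num(curve.frequency - n_combos * baseline, nan=0.0)
        counts = np.clip(diff, 0, None) * curve.possible
        return float(counts[window].sum()) / n_total

    return ByproductReport(
        f_dangling=excess(inward, 1.0, dangling_max_s),
        f_self_circle=excess(outward, 1.0, self_circle_max_s),
        f_hairpin=excess(tandem, 2.0, hairpin_max_s),
        baseline=baseline,
        n_total=n_total,
    )


def normalize_by_reference(
    curve: ScalingCurve, reference: ScalingCurve, s_ref: float = 1000.0
) -> ScalingCurve:
    """Rescale a curve by the reference's frequency at ``s_ref``.

    Used to plot curve families relative to the cis contact frequency at 1 kb
    (the geometric bin containing ``s_ref``); ratios between curves are
    unchanged.
    """
    if not curve.same_grid(reference):
        raise InvalidParameterError("curves must share a grid")
    ref = reference.frequency_at(s_ref)
    if not np.isfinite(ref) or ref <= 0:
        raise InvalidParameterError(f"reference frequency at {s_ref} is not positive")
    return ScalingCurve(
        edges=curve.edges,
        observed=curve.observed / ref,
        possible=curve.possible,
        labels={**curve.labels, "normalized_at": s_ref},
    )


def fit_powerlaw_slope(
    curve: ScalingCurve, s_min: float | None = None, s_max: float | None = None
) -> float:
    """Log-log least-squares slope of a P(s) curve over a separation range."""
    f = curve.frequency
    c = curve.centers
    ok = np.isfinite(f) & (f > 0)
    if s_min is not None:
        ok &= c >= s_min
    if s_max is not None:
        ok &= c <= s_max
    if ok.sum() < 2:
        raise InvalidParameterError("need at least two positive bins for a slope")
    slope = np.polyfit(np.log10(c[ok]), np.log10(f[ok]), 1)[0]
    return float(slope)
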