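"""Haplotype-aware binned contact matrices: binning, filtering, balancing, O/E.

Classified contacts are aggregated into four components over a shared bin
table: cis-maternal, cis-paternal, trans-homolog (maternal-by-paternal bins of
the same chromosome, pooled with its mirror by default) and trans-heterolog.
Low-coverage bins are masked with the MADmax filter, the cis and trans-homolog
components are balanced by iterative correction so that every unmasked
marginal equals 1.0 (see :data:`BALANCED_COMPONENTS`),
and observed/expected maps divide each intra-chromosomal diagonal by its
chromosome-wide mean over unmasked bin pairs.

Matrices are scipy sparse, stored symmetric (both triangles, diagonal once).
Cis- and trans-homolog contacts below a minimum separation (default 3 kb) are
excluded at binning time, as those separations are dominated by unligated and
self-ligated fragments rather than chromatin contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import pairs as _pairs
from .errors import InvalidParameterError, PairsFormatError

COMPONENTS = ["cis_maternal", "cis_paternal", "trans_homolog", "trans_heterolog"]


@dataclass
class BinTable:
    """Uniform genomic bins tiling each chromosome (0-based half-open)."""

    chrom_sizes: dict[str, int]
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise InvalidParameterError("resolution must be > 0")
        self.chrom_sizes = dict(self.chrom_sizes)
        self._n_per_chrom = {
            c: -(-L // self.resolution) for c, L in self.chrom_sizes.items()
        }
        offs = np.cumsum([0] + list(self._n_per_chrom.values()))
        self._offsets = dict(zip(self.chrom_sizes, offs[:-1]))
        self.n_bins = int(offs[-1])

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offsets[chrom]
        return slice(o, o + self._n_per_chrom[chrom])

    def bin_ids(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Global bin index of 0-based positions; -1 for out-of-range."""
        out = np.full(len(pos0), -1, dtype=np.int64)
        for c in self.chrom_sizes:
            m = chrom == c
            if not m.any():
                continue
            p = pos0[m]
            bad = (p < 0) | (p >= self.chrom_sizes[c])
            ids = self._offsets[c] + p // self.resolution
            ids[bad] = -1
            out[m] = ids
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, L in self.chrom_sizes.items():
            starts = np.arange(0, L, self.resolution)
            ends = np.minimum(starts + self.resolution, L)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        df = pd.concat(rows, ignore_index=True)
        df.index.name = "bin_id"
        return df

    def compatible(self, other: "BinTable") -> bool:
        return (
            self.resolution == other.resolution
            and self.chrom_sizes == other.chrom_sizes
        )


@dataclass
class BinnedMap:
    """Sparse symmetric contact matrices per haplotype component."""

    bins: BinTable
    components: dict[str, sp.csr_matrix]
    mask: np.ndarray | None = None  # True = bad bin
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def resolution(self) -> int:
        return self.bins.resolution

    def combined(self) -> sp.csr_matrix:
        out = None
        for m in self.components.values():
            out = m if out is None else out + m
        return out

    def balanced(self, component: str) -> sp.csr_matrix:
        """Balanced matrix of a component (masked rows/columns empty)."""
        if component not in self.weights:
            raise InvalidParameterError(f"component not balanced yet: {component}")
        w = np.nan_to_num(self.weights[component], nan=0.0)
        D = sp.diags(w)
        return (D @ self.components[component] @ D).tocsr()


def bin_contacts(
    records: pd.DataFrame,
    bins: BinTable,
    min_separation: int = 3000,
    pool_homolog: bool = True,
) -> BinnedMap:
    """Aggregate classified contacts into per-component matrices.

    Cis and trans-homolog pairs with separation below ``min_separation`` are
    excluded (a pair at exactly ``min_separation`` is kept); trans-heterolog
    pairs are unaffected.  Haplotype-unassigned pairs are dropped.  With
    ``pool_homolog`` the trans-homolog matrix pools (maternal_i, paternal_j)
    with (paternal_i, maternal_j) counts into one symmetric map.
    """
    cls = _pairs.classify(records).to_numpy()
    chrom1 = records["chrom1"].to_numpy(dtype=object)
    chrom2 = records["chrom2"].to_numpy(dtype=object)
    pos1 = records["pos1"].to_numpy() - 1
    pos2 = records["pos2"].to_numpy() - 1
    hap1 = records["hap1"].to_numpy(dtype=object)
    b1 = bins.bin_ids(chrom1, pos1)
    b2 = bins.bin_ids(chrom2, pos2)
    if (b1 < 0).any() or (b2 < 0).any():
        raise PairsFormatError("record position outside the bin table")

    same = chrom1 == chrom2
    s = np.where(same, np.abs(pos2 - pos1), -1)
    short = same & (s < min_separation)

    comps = {}
    exclusions = {}
    n = bins.n_bins
    selections = {
        "cis_maternal": (cls == "cis") & (hap1 == _pairs.MATERNAL),
        "cis_paternal": (cls == "cis") & (hap1 == _pairs.PATERNAL),
        "trans_homolog": cls == "trans_homolog",
        "trans_heterolog": cls == "trans_heterolog",
    }
    for name, sel in selections.items():
        if name != "trans_heterolog":
            excluded = sel & short
            sel = sel & ~short
            exclusions[name] = int(excluded.sum())
        i, j = b1[sel], b2[sel]
        m = sp.coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(n, n)
        ) if len(i) else sp.coo_matrix((n, n))
        sym = m + m.T
        sym.setdiag(sym.diagonal() / 2.0)  # diagonal counted once
        comps[name] = sym.tocsr()
    if not pool_homolog:
        # keep the maternal-side-by-paternal-side orientation as an
        # asymmetric matrix alongside the pooled one
        sel = selections["trans_homolog"] & ~short
        i = np.where(hap1[sel] == _pairs.MATERNAL, b1[sel], b2[sel])
        j = np.where(hap1[sel] == _pairs.MATERNAL, b2[sel], b1[sel])
        comps["trans_homolog_mp"] = sp.coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(n, n)
        ).tocsr()
    exclusions["unassigned"] = int((cls == "unassigned").sum())
    return BinnedMap(bins=bins, components=comps, exclusions=exclusions)


def madmax_filter(cmap: BinnedMap, n_mads: float = 7.0) -> np.ndarray:
    """Mask bins whose log coverage falls ``n_mads`` MADs below the median.

    Coverage is the marginal of the combined map (all components).  Zero
    coverage bins are always masked.  Scale-invariant: rescaling all counts
    shifts every log coverage equally.  Sets and returns ``cmap.mask``.
    """
    cov = np.asarray(cmap.combined().sum(axis=1)).ravel()
    mask = cov <= 0
    logc = np.log(cov[~mask])
    if len(logc):
        med = np.median(logc)
        mad = np.median(np.abs(logc - med))
        mask[~mask] = logc < med - n_mads * mad
    cmap.mask = mask
    return mask


#: Components balanced by default.  The trans-heterolog component is excluded:
#: it only connects different chromosomes, so a symmetric scaling with unit
#: marginals on every bin is infeasible whenever chromosomes hold different
#: numbers of unmasked bins (the per-chromosome marginal sums are forced equal).
BALANCED_COMPONENTS = ["cis_maternal", "cis_paternal", "trans_homolog"]


def iterative_correction(
    cmap: BinnedMap,
    tol: float = 1e-6,
    max_iter: int = 2000,
    components: list[str] | None = None,
    joint: bool = False,
) -> BinnedMap:
    """Balance each component so every unmasked marginal equals 1.0.

    Multiplicative per-bin weights, found by iterative correction; converged
    when the variance of the unmasked marginals (after the final rescale to
    1.0) drops below ``tol``.  Masked bins get NaN weights.  Non-convergence
    warns and keeps the best iterate.

    By default each of :data:`BALANCED_COMPONENTS` is balanced separately.
    With ``joint=True`` a single weight vector is computed from the combined
    (all-component) map and shared by every component.
    """
    if cmap.mask is None:
        raise InvalidParameterError("apply madmax_filter (or set mask) before balancing")
    good = ~cmap.mask
    if joint:
        targets = {"__joint__": cmap.combined()}
    else:
        names = components or [c for c in BALANCED_COMPONENTS if c in cmap.components]
        targets = {name: cmap.components[name] for name in names}
    for name, matrix in targets.items():
        M = matrix.copy().astype(float)
        # zero out masked rows/columns
        d = sp.diags(good.astype(float))
        M = (d @ M @ d).tocsr()
        row_has = np.asarray(M.sum(axis=1)).ravel() > 0
        active = good & row_has
        w = np.where(active, 1.0, 0.0)
        converged = not active.any()
        for _ in range(max_iter):
            marg = w * (M @ w)
            mean = marg[active].mean()
            if mean <= 0:
                break
            rel = marg / mean
            if np.var(rel[active] - 1.0) < tol:
                w = w / np.sqrt(mean)  # unit marginals, variance unchanged
                converged = True
                break
            w = np.where(active, w / np.sqrt(np.where(rel > 0, rel, 1.0)), 0.0)
        if not converged and active.any():
            marg = w * (M @ w)
            mean = marg[active].mean()
            if mean > 0:
                w = w / np.sqrt(mean)
            warnings.warn(
                f"iterative correction did not converge for {name}: "
                f"marginal variance {np.var((w * (M @ w))[active] - 1.0):.3g}",
                RuntimeWarning,
            )
        weights = np.where(active, w, np.nan)
        if name == "__joint__":
            for comp in cmap.components:
                cmap.weights[comp] = weights
        else:
            cmap.weights[name] = weights
    return cmap


def _diag_counts(good: np.ndarray) -> np.ndarray:
    """Number of unmasked bin pairs on each diagonal offset (0..n-1)."""
    g = good.astype(float)
    # correlate g with itself: counts[d] = sum_i g[i] * g[i+d]
    n = len(g)
    counts = np.correlate(g, g, mode="full")[n - 1:]
    return np.rint(counts).astype(np.int64)


def observed_expected(cmap: BinnedMap, component: str) -> sp.csr_matrix:
    """Observed/expected map: each intra-chromosomal diagonal of the balanced
    matrix divided by its chromosome-wide mean over unmasked bin pairs.

    Applies to the cis and trans-homolog components (diagonal ``|i - j|`` is
    the separation between homologous coordinates).  Returns a sparse matrix
    holding O/E values at the positions of observed contacts; entries on
    empty diagonals are NaN.
    """
    bal = cmap.balanced(component).tocoo()
    good = ~cmap.mask
    vals = bal.data.copy()
    for chrom in cmap.bins.chrom_sizes:
        sl = cmap.bins.chrom_slice(chrom)
        in_chrom = (bal.row >= sl.start) & (bal.row < sl.stop) & \
                   (bal.col >= sl.start) & (bal.col < sl.stop)
        if not in_chrom.any():
            continue
        d = np.abs(bal.col[in_chrom] - bal.row[in_chrom])
        g = good[sl]
        counts = _diag_counts(g).astype(float)
        # the symmetric store holds each off-diagonal pair twice, so both the
        # per-diagonal sums and the pair counts are doubled for d > 0
        sums = np.bincount(d, weights=bal.data[in_chrom], minlength=len(counts))
        entry_counts = counts.copy()
        entry_counts[1:] *= 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            diag_mean = np.where(entry_counts > 0, sums / entry_counts, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals[in_chrom] = bal.data[in_chrom] / diag_mean[d]
    return sp.coo_matrix((vals, (bal.row, bal.col)), shape=bal.shape).tocsr()


def write_cooler(cmap: BinnedMap, component: str, path) -> None:
    """Write one component as an HDF5 container following the cooler layout.

    Groups ``chroms``, ``bins``, ``pixels`` (upper triangle) and ``indexes``;
    balancing weights land in ``bins/weight`` (NaN where masked or not yet
    balanced).  Readable by the cooler library and htsviewers that speak the
    format.
    """
    import h5py

    bins = cmap.bins
    m = sp.triu(cmap.components[component].tocoo())
    order = np.lexsort((m.col, m.row))
    row, col, data = m.row[order], m.col[order], m.data[order]
    bin_frame = bins.to_frame()
    chrom_names = list(bins.chrom_sizes)
    chrom_codes = pd.Categorical(bin_frame["chrom"], categories=chrom_names).codes
    w = cmap.weights.get(component)
    if w is None:
        w = np.full(bins.n_bins, np.nan)
    n_per_chrom = [bins.chrom_slice(c).stop - bins.chrom_slice(c).start
                   for c in chrom_names]
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["format-version"] = 3
        h5.attrs["bin-size"] = bins.resolution
        h5.attrs["bin-type"] = "fixed"
        h5.attrs["nbins"] = bins.n_bins
        h5.attrs["nchroms"] = len(chrom_names)
        h5.attrs["nnz"] = len(data)
        h5.attrs["sum"] = float(data.sum())
        g = h5.create_group("chroms")
        g.create_dataset("name", data=np.array(chrom_names, dtype="S"))
        g.create_dataset(
            "length", data=np.array([bins.chrom_sizes[c] for c in chrom_names],
                                    dtype=np.int64)
        )
        g = h5.create_group("bins")
        g.create_dataset("chrom", data=chrom_codes.astype(np.int32))
        g.create_dataset("start", data=bin_frame["start"].to_numpy(np.int64))
        g.create_dataset("end", data=bin_frame["end"].to_numpy(np.int64))
        g.create_dataset("weight", data=w.astype(float))
        g = h5.create_group("pixels")
        g.create_dataset("bin1_id", data=row.astype(np.int64))
        g.create_dataset("bin2_id", data=col.astype(np.int64))
        g.create_dataset("count", data=data.astype(np.int32))
        g = h5.create_group("indexes")
        bin1_offset = np.searchsorted(row, np.arange(bins.n_bins + 1))
        chrom_offset = np.concatenate([[0], np.cumsum(n_per_chrom)])
        g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))
        g.create_dataset("chrom_offset", data=chrom_offset.astype(np.int64))


def write_coo_tsv(cmap: BinnedMap, component: str, path) -> None:
    """Plain-text sparse exchange format: bin1, bin2, count, balanced."""
    m = sp.triu(cmap.components[component].tocoo())
    w = cmap.weights.get(component)
    bal = (
        w[m.row] * w[m.col] * m.data if w is not None else np.full(len(m.data), np.nan)
    )
    pd.DataFrame(
        {"bin1": m.row, "bin2": m.col, "count": m.data.astype(np.int64), "balanced": bal}
    ).to_csv(path, sep="\t", index=False)
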