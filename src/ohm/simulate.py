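"""Synthetic diploid Hi-C contact libraries with known ground truth.

The generator emits haplotype-tagged contact pairs from a mixture of six
populations:

* informative cis contacts with power-law distance decay (flattened to a
  plateau below ~1 kb, the restriction-fragment scale);
* true trans-homolog contacts: a near-diagonal exponential pairing kernel on
  top of a flat background equal to the trans-heterolog level;
* trans-heterolog contacts: flat background, optionally with a Rabl
  coalignment component concentrating contacts at matching relative arm
  positions;
* three Hi-C byproducts, each a single un- or self-ligated fragment and hence
  truly cis: dangling ends (inward read pairs, 100-1000 bp), self-circles
  (outward, 1-10 kb) and hairpin loops (same-strand, <500 bp).

Haplotypes are read out through SNVs: each read side overlaps the SNVs within
one read length of its 5' position; a side with no SNV is unassigned.  Homolog
misassignment is injected either directly (``p_hm`` per pair, ``p_hm/2`` per
assigned side) or mechanistically through per-SNV sequencing errors
(``snv_error_rate``), under which requiring more SNVs per side suppresses
misassignment.

Class mixture weights derive from the model's relative intensities so that
measured contact frequencies (counts per possible locus pair) reproduce the
configured amplitude ratios; the library size ``n_pairs`` sets the overall
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .pairs import HAP_CATEGORIES, PAIRS_COLUMNS, STRAND_CATEGORIES

TRUTH_COLUMNS = ["true_class", "true_hap1", "true_hap2", "mis1", "mis2"]
TRUE_CLASSES = [
    "cis",
    "trans_homolog",
    "trans_heterolog",
    "dangling",
    "self_circle",
    "hairpin",
]


@dataclass
class SimGenome:
    """A diploid genome skeleton: chromosome sizes, SNV positions, centromeres.

    SNV positions are 0-based, sorted, unique, shared by both homologs (an SNV
    is a site at which the homologs differ).  Centromeres default to position 0
    (telocentric), giving a single arm per chromosome.
    """

    chrom_sizes: dict[str, int]
    snv_density: float
    snvs: dict[str, np.ndarray]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise InvalidParameterError(f"zero/negative chromosome length: {chrom}")
        if self.snv_density < 0:
            raise InvalidParameterError("snv_density must be >= 0")
        for chrom, pos in self.snvs.items():
            pos = np.asarray(pos)
            if len(pos) and (
                (np.diff(pos) <= 0).any()
                or pos[0] < 0
                or pos[-1] >= self.chrom_sizes[chrom]
            ):
                raise InvalidParameterError(
                    f"SNV positions must be strictly increasing within [0, L): {chrom}"
                )
        for chrom in self.chrom_sizes:
            self.centromeres.setdefault(chrom, 0)


@dataclass
class SimModel:
    """Generative parameters of a synthetic library.

    Amplitudes (``cis_amplitude``, ``pairing_amplitude``, ``het_level``,
    ``rabl_amplitude``) are relative contact intensities per possible locus
    pair; only their ratios matter.  Byproduct fractions are absolute fractions
    of the emitted library.  ``p_hm`` is the probability of homolog
    misassignment per paired read (applied as ``p_hm/2`` per haplotype-assigned
    side); if ``snv_error_rate`` is set it takes precedence and misassignment
    emerges from per-SNV read errors instead.
    """

    # informative cis: frequency ~ cis_amplitude * s^-cis_exponent, flat below plateau
    cis_exponent: float = 0.8
    cis_amplitude: float = 6.3e6
    cis_plateau: float = 1000.0
    min_cis_separation: float = 10.0
    # trans-homolog pairing kernel: pairing_amplitude * exp(-s / pairing_scale)
    pairing_amplitude: float = 300.0
    pairing_scale: float = 50_000.0
    # flat trans-heterolog background (also the trans-homolog far-from-diagonal level)
    het_level: float = 1.0
    # Rabl coalignment of heterologous arms
    rabl_amplitude: float = 0.0
    rabl_scale: float = 2e6
    # byproducts
    f_dangling: float = 0.395
    f_self_circle: float = 0.003
    f_hairpin: float = 0.029
    dangling_range: tuple[float, float] = (100.0, 1000.0)
    self_circle_range: tuple[float, float] = (1000.0, 10_000.0)
    hairpin_range: tuple[float, float] = (100.0, 500.0)
    # haplotype readout / errors
    p_hm: float = 0.0017
    snv_error_rate: float | None = None
    mismatch_rate: float = 0.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self):
        fracs = (self.f_dangling, self.f_self_circle, self.f_hairpin)
        if any(f < 0 or f > 1 for f in fracs):
            raise InvalidParameterError("byproduct fractions must be in [0, 1]")
        if sum(fracs) > 1:
            raise InvalidParameterError("byproduct fractions must sum to <= 1")
        if not 0 <= self.p_hm <= 1:
            raise InvalidParameterError("p_hm must be in [0, 1]")
        if self.snv_error_rate is not None and not 0 <= self.snv_error_rate < 1:
            raise InvalidParameterError("snv_error_rate must be in [0, 1)")


def simulate_genome(
    chrom_sizes: Mapping[str, int], snv_density: float, seed: int
) -> SimGenome:
    """Draw SNV positions uniformly without replacement at ``snv_density``/kb.

    Deterministic given ``seed``; the SNV count per chromosome is exactly
    ``round(density * L / 1000)``.
    """
    chrom_sizes = dict(chrom_sizes)
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise InvalidParameterError(f"zero/negative chromosome length: {chrom}")
    if snv_density < 0:
        raise InvalidParameterError("snv_density must be >= 0")
    rng = np.random.default_rng(seed)
    snvs = {}
    for chrom, size in chrom_sizes.items():
        n = int(round(snv_density * size / 1000.0))
        n = min(n, size)
        if n == 0:
            snvs[chrom] = np.empty(0, dtype=np.int64)
            continue
        # uniform without replacement: oversample, deduplicate, random subset
        uniq = np.empty(0, dtype=np.int64)
        factor = 1.2
        while len(uniq) < n:
            draw = rng.integers(0, size, size=int(n * factor) + 16)
            uniq = np.unique(np.concatenate([uniq, draw]))
            factor *= 1.5
        pick = rng.permutation(len(uniq))[:n]
        snvs[chrom] = np.sort(uniq[pick]).astype(np.int64)
    return SimGenome(chrom_sizes=chrom_sizes, snv_density=snv_density, snvs=snvs)


def default_genome(seed: int = 0, snv_density: float = 5.0) -> SimGenome:
    """Two-autosome genome emulating the large fly autosomes (22 + 26 Mb)."""
    return simulate_genome({"chr2": 22_000_000, "chr3": 26_000_000}, snv_density, seed)


# ---------------------------------------------------------------------------
# mixture weights


def _log_grid(lo: float, hi: float, n: int = 4096) -> np.ndarray:
    return np.geomspace(max(lo, 1.0), hi, n)


def _cis_weight(s: np.ndarray, model: SimModel) -> np.ndarray:
    s_eff = np.maximum(s, model.cis_plateau)
    return s_eff ** (-model.cis_exponent)


def _mass_on_grid(grid: np.ndarray, intensity: np.ndarray, L: float) -> float:
    return float(np.trapezoid(intensity * np.maximum(L - grid, 0.0), grid))


def class_mixture(genome: SimGenome, model: SimModel) -> dict[str, float]:
    """Expected fraction of the library in each generated population.

    Keys: ``dangling, self_circle, hairpin, cis, hom_flat, hom_kernel,
    het_flat, het_rabl``.  Byproduct fractions are as configured; informative
    populations share the remainder proportionally to their intensity masses.
    """
    sizes = list(genome.chrom_sizes.values())
    m_cis = 0.0
    m_hom_kernel = 0.0
    m_hom_flat = 0.0
    for L in sizes:
        grid = _log_grid(model.min_cis_separation, L)
        m_cis += model.cis_amplitude * _mass_on_grid(grid, _cis_weight(grid, model), L)
        kgrid = _log_grid(1.0, L)
        m_hom_kernel += model.pairing_amplitude * _mass_on_grid(
            kgrid, np.exp(-kgrid / model.pairing_scale), L
        )
        m_hom_flat += model.het_level * L * L / 2.0
    cross = 0.0
    m_rabl = 0.0
    for i, La in enumerate(sizes):
        for Lb in sizes[i + 1:]:
            cross += La * Lb
            m_rabl += model.rabl_amplitude * 2.0 * model.rabl_scale * Lb
    m_het = model.het_level * 4.0 * cross
    masses = {
        "cis": m_cis,
        "hom_flat": m_hom_flat,
        "hom_kernel": m_hom_kernel,
        "het_flat": m_het,
        "het_rabl": m_rabl,
    }
    total = sum(masses.values())
    f_inf = 1.0 - model.f_dangling - model.f_self_circle - model.f_hairpin
    mix = {k: f_inf * v / total for k, v in masses.items()}
    mix["dangling"] = model.f_dangling
    mix["self_circle"] = model.f_self_circle
    mix["hairpin"] = model.f_hairpin
    return mix


# ---------------------------------------------------------------------------
# sampling helpers


def _sample_inverse_cdf(rng, grid: np.ndarray, weight: np.ndarray, n: int) -> np.ndarray:
    """Sample separations from a density tabulated on ``grid``."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # cumulative trapezoid of weight over grid
    seg = 0.5 * (weight[1:] + weight[:-1]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    u = rng.random(n)
    s = np.interp(u, cdf, grid)
    return np.rint(s).astype(np.int64)


def _split_by_chrom(rng, weights: np.ndarray, n: int) -> np.ndarray:
    p = weights / weights.sum()
    return rng.multinomial(n, p)


def _log_uniform(rng, lo: float, hi: float, n: int) -> np.ndarray:
    return np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), n))).astype(np.int64)


# ---------------------------------------------------------------------------
# library generation


# Internal integer encodings (only for generation speed; the emitted frame
# uses the categorical string encodings of the pairs dialect).
_HAP_M, _HAP_P, _HAP_UN = 0, 1, 2  # indices into HAP_CATEGORIES
_FWD, _REV = 0, 1  # indices into STRAND_CATEGORIES


class _Columns:
    """Growable column store for the generated records (integer-coded)."""

    def __init__(self):
        self.chrom1 = []
        self.pos1 = []
        self.chrom2 = []
        self.pos2 = []
        self.strand1 = []
        self.strand2 = []
        self.hap1 = []
        self.hap2 = []
        self.true_class = []

    def add(self, chrom1, pos1, chrom2, pos2, strand1, strand2, hap1, hap2, true_class):
        n = len(pos1)
        if n == 0:
            return
        self.chrom1.append(np.full(n, chrom1, dtype=np.int16) if np.isscalar(chrom1) else chrom1)
        self.chrom2.append(np.full(n, chrom2, dtype=np.int16) if np.isscalar(chrom2) else chrom2)
        self.pos1.append(pos1)
        self.pos2.append(pos2)
        self.strand1.append(strand1)
        self.strand2.append(strand2)
        self.hap1.append(hap1)
        self.hap2.append(hap2)
        self.true_class.append(np.full(n, true_class, dtype=np.int8))


def _random_strands(rng, n):
    return (
        rng.integers(0, 2, n, dtype=np.int8),
        rng.integers(0, 2, n, dtype=np.int8),
    )


def _random_same_hap(rng, n):
    h = rng.integers(0, 2, n, dtype=np.int8)
    return h, h.copy()


def _count_snvs(snvs: np.ndarray, pos: np.ndarray, strand: np.ndarray, read_length: int):
    """Number of SNVs overlapped by a read of ``read_length`` from its 5' position."""
    lo = np.where(strand == _FWD, pos, pos - read_length + 1)
    hi = lo + read_length
    return (np.searchsorted(snvs, hi) - np.searchsorted(snvs, np.maximum(lo, 0))).astype(
        np.int64, copy=False
    )


def simulate_library(
    genome: SimGenome, model: SimModel, n_pairs: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``n_pairs`` contact records plus a ground-truth sidecar.

    Returns ``(pairs, truth)``, two row-aligned DataFrames.  ``pairs`` has the
    columns of the pairs dialect (1-based positions, canonical side order,
    ``readID`` is the integer emission index, chromosomes / strands /
    haplotypes are categorical);
    ``truth`` records the true class, the true haplotypes and per-side
    misassignment flags (True only where an *assigned* emitted haplotype
    differs from the truth; unassigned sides are never flagged).

    Deterministic given ``(genome, model, n_pairs)``; the stream is fixed by
    ``model.seed``.
    """
    if n_pairs <= 0:
        raise InvalidParameterError("n_pairs must be > 0")
    rng = np.random.default_rng(model.seed)
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    mix = class_mixture(genome, model)
    order = ["dangling", "self_circle", "hairpin", "cis", "hom_flat", "hom_kernel",
             "het_flat", "het_rabl"]
    counts = rng.multinomial(n_pairs, [mix[k] for k in order])
    n_by = dict(zip(order, counts))
    cols = _Columns()
    class_code = {name: TRUE_CLASSES.index(name) for name in TRUE_CLASSES}

    # --- informative cis ---------------------------------------------------
    cis_masses = []
    for c in chroms:
        L = genome.chrom_sizes[c]
        grid = _log_grid(model.min_cis_separation, L)
        cis_masses.append(_mass_on_grid(grid, _cis_weight(grid, model), L))
    per_chrom = _split_by_chrom(rng, np.array(cis_masses), n_by["cis"])
    for ci, n_c in enumerate(per_chrom):
        L = genome.chrom_sizes[chroms[ci]]
        grid = _log_grid(model.min_cis_separation, L)
        s = _sample_inverse_cdf(
            rng, grid, _cis_weight(grid, model) * np.maximum(L - grid, 0.0), n_c
        )
        s = np.clip(s, int(model.min_cis_separation), L - 1)
        p1 = rng.integers(0, L - s)
        st1, st2 = _random_strands(rng, n_c)
        h1, h2 = _random_same_hap(rng, n_c)
        cols.add(ci, p1, ci, p1 + s, st1, st2, h1, h2, class_code["cis"])

    # --- trans-homolog: flat background + pairing kernel -------------------
    per_chrom = _split_by_chrom(rng, sizes ** 2, n_by["hom_flat"])
    for ci, n_c in enumerate(per_chrom):
        L = genome.chrom_sizes[chroms[ci]]
        x1 = rng.integers(0, L, n_c)
        x2 = rng.integers(0, L, n_c)
        st1, st2 = _random_strands(rng, n_c)
        h1 = rng.integers(0, 2, n_c, dtype=np.int8)
        h2 = (1 - h1).astype(np.int8)
        cols.add(ci, x1, ci, x2, st1, st2, h1, h2, class_code["trans_homolog"])
    kernel_masses = []
    for c in chroms:
        L = genome.chrom_sizes[c]
        kgrid = _log_grid(1.0, L)
        kernel_masses.append(
            _mass_on_grid(kgrid, np.exp(-kgrid / model.pairing_scale), L)
        )
    per_chrom = _split_by_chrom(rng, np.array(kernel_masses), n_by["hom_kernel"])
    for ci, n_c in enumerate(per_chrom):
        L = genome.chrom_sizes[chroms[ci]]
        kgrid = _log_grid(1.0, L)
        s = _sample_inverse_cdf(
            rng, kgrid, np.exp(-kgrid / model.pairing_scale) * np.maximum(L - kgrid, 0), n_c
        )
        p1 = rng.integers(0, L - s)
        st1, st2 = _random_strands(rng, n_c)
        h1 = rng.integers(0, 2, n_c, dtype=np.int8)
        h2 = (1 - h1).astype(np.int8)
        cols.add(ci, p1, ci, p1 + s, st1, st2, h1, h2, class_code["trans_homolog"])

    # --- trans-heterolog ----------------------------------------------------
    pair_idx = [(i, j) for i in range(len(chroms)) for j in range(i + 1, len(chroms))]
    if pair_idx:
        w = np.array([sizes[i] * sizes[j] for i, j in pair_idx])
        per_pair = _split_by_chrom(rng, w, n_by["het_flat"])
        for (i, j), n_p in zip(pair_idx, per_pair):
            Li, Lj = int(sizes[i]), int(sizes[j])
            x1 = rng.integers(0, Li, n_p)
            x2 = rng.integers(0, Lj, n_p)
            st1, st2 = _random_strands(rng, n_p)
            h1 = rng.integers(0, 2, n_p, dtype=np.int8)
            h2 = rng.integers(0, 2, n_p, dtype=np.int8)
            cols.add(i, x1, j, x2, st1, st2, h1, h2, class_code["trans_heterolog"])
        if n_by["het_rabl"]:
            w = np.array([2.0 * model.rabl_scale * sizes[j] for i, j in pair_idx])
            per_pair = _split_by_chrom(rng, w, n_by["het_rabl"])
            for (i, j), n_p in zip(pair_idx, per_pair):
                Li, Lj = int(sizes[i]), int(sizes[j])
                x2 = rng.integers(0, Lj, n_p)
                # exponential mismatch in the rescaled coordinate, random sign
                mis = rng.exponential(model.rabl_scale, n_p) * np.where(
                    rng.integers(0, 2, n_p) == 0, 1, -1
                )
                x1 = np.clip(
                    np.rint(x2 * (Li / Lj) + mis).astype(np.int64), 0, Li - 1
                )
                st1, st2 = _random_strands(rng, n_p)
                h1 = rng.integers(0, 2, n_p, dtype=np.int8)
                h2 = rng.integers(0, 2, n_p, dtype=np.int8)
                cols.add(i, x1, j, x2, st1, st2, h1, h2,
                         class_code["trans_heterolog"])
    elif n_by["het_flat"] or n_by["het_rabl"]:
        raise InvalidParameterError(
            "heterolog contacts require at least two chromosomes"
        )

    # --- byproducts ---------------------------------------------------------
    byproduct_spec = {
        "dangling": (model.dangling_range, "inward"),
        "self_circle": (model.self_circle_range, "outward"),
        "hairpin": (model.hairpin_range, "tandem"),
    }
    for name, ((lo, hi), orientation) in byproduct_spec.items():
        n_k = n_by[name]
        per_chrom = _split_by_chrom(rng, sizes, n_k)
        for ci, n_c in enumerate(per_chrom):
            L = genome.chrom_sizes[chroms[ci]]
            s = np.clip(_log_uniform(rng, lo, hi, n_c), 1, L - 1)
            p1 = rng.integers(0, L - s)
            if orientation == "inward":
                st1 = np.full(n_c, _FWD, dtype=np.int8)
                st2 = np.full(n_c, _REV, dtype=np.int8)
            elif orientation == "outward":
                st1 = np.full(n_c, _REV, dtype=np.int8)
                st2 = np.full(n_c, _FWD, dtype=np.int8)
            else:
                st1 = rng.integers(0, 2, n_c, dtype=np.int8)
                st2 = st1.copy()
            h1, h2 = _random_same_hap(rng, n_c)
            cols.add(ci, p1, ci, p1 + s, st1, st2, h1, h2, class_code[name])

    # --- assemble, canonicalize sides, shuffle ------------------------------
    chrom1 = np.concatenate(cols.chrom1)
    pos1 = np.concatenate(cols.pos1).astype(np.int64, copy=False)
    chrom2 = np.concatenate(cols.chrom2)
    pos2 = np.concatenate(cols.pos2).astype(np.int64, copy=False)
    strand1 = np.concatenate(cols.strand1)
    strand2 = np.concatenate(cols.strand2)
    hap1 = np.concatenate(cols.hap1)
    hap2 = np.concatenate(cols.hap2)
    true_class = np.concatenate(cols.true_class)

    swap = (chrom1 == chrom2) & (pos1 > pos2)
    for a, b in (
        (pos1, pos2),
        (strand1, strand2),
        (hap1, hap2),
    ):
        tmp = a[swap].copy()
        a[swap] = b[swap]
        b[swap] = tmp

    perm = rng.permutation(len(pos1))
    chrom1, pos1, chrom2, pos2 = chrom1[perm], pos1[perm], chrom2[perm], pos2[perm]
    strand1, strand2, hap1, hap2 = strand1[perm], strand2[perm], hap1[perm], hap2[perm]
    true_class = true_class[perm]

    # --- SNV readout and misassignment --------------------------------------
    snv1 = np.zeros(len(pos1), dtype=np.int64)
    snv2 = np.zeros(len(pos1), dtype=np.int64)
    for ci, c in enumerate(chroms):
        snvs = genome.snvs[c]
        m1 = chrom1 == ci
        m2 = chrom2 == ci
        snv1[m1] = _count_snvs(snvs, pos1[m1], strand1[m1], model.read_length)
        snv2[m2] = _count_snvs(snvs, pos2[m2], strand2[m2], model.read_length)

    true_hap1, true_hap2 = hap1.copy(), hap2.copy()
    emitted1, mis1, mm1 = _emit_side(rng, hap1, snv1, model)
    emitted2, mis2, mm2 = _emit_side(rng, hap2, snv2, model)

    def _chrom(codes):
        return pd.Categorical.from_codes(codes, categories=chroms)

    def _strand(codes):
        return pd.Categorical.from_codes(codes, categories=STRAND_CATEGORIES)

    def _hap(codes):
        return pd.Categorical.from_codes(codes, categories=HAP_CATEGORIES)

    pairs = pd.DataFrame(
        {
            "readID": np.arange(len(pos1), dtype=np.int64),
            "chrom1": _chrom(chrom1),
            "pos1": pos1 + 1,
            "chrom2": _chrom(chrom2),
            "pos2": pos2 + 1,
            "strand1": _strand(strand1),
            "strand2": _strand(strand2),
            "hap1": _hap(emitted1),
            "hap2": _hap(emitted2),
            "snv1": snv1,
            "snv2": snv2,
            "mm1": mm1,
            "mm2": mm2,
        },
        columns=PAIRS_COLUMNS,
        copy=False,
    )
    truth = pd.DataFrame(
        {
            "true_class": pd.Categorical.from_codes(true_class, categories=TRUE_CLASSES),
            "true_hap1": _hap(true_hap1),
            "true_hap2": _hap(true_hap2),
            "mis1": mis1,
            "mis2": mis2,
        },
        copy=False,
    )
    return pairs, truth


def _emit_side(rng, true_hap: np.ndarray, snv: np.ndarray, model: SimModel):
    """Apply the haplotype readout model to one side of every pair."""
    n = len(true_hap)
    emitted = true_hap.copy()
    mis = np.zeros(n, dtype=bool)
    assigned = snv >= 1
    emitted[~assigned] = _HAP_UN

    if model.snv_error_rate is None:
        # direct injection: flip each assigned side with probability p_hm / 2
        flip = assigned & (rng.random(n) < model.p_hm / 2.0)
        emitted[flip] = (1 - true_hap[flip]).astype(np.int8)
        mis[flip] = True
        if model.mismatch_rate > 0:
            mm = rng.binomial(model.read_length, model.mismatch_rate, n)
        else:
            mm = np.zeros(n, dtype=np.int64)
        return emitted, mis, mm

    # mechanistic mode: each SNV on the read is misread with probability eps;
    # a misread lands on the opposite allele 1/3 of the time (an apparent vote
    # for the other homolog) and on a non-allele base 2/3 of the time (a
    # mismatch to both homologs, no vote).  The side is assigned to the
    # homolog with more supporting votes; ties are unassigned.
    eps = model.snv_error_rate
    k = snv
    n_flip = rng.binomial(k, eps / 3.0)
    rest = k - n_flip
    q_bad = (2.0 * eps / 3.0) / max(1.0 - eps / 3.0, 1e-12)
    n_bad = rng.binomial(rest, min(q_bad, 1.0))
    votes_true = k - n_flip - n_bad
    wrong = assigned & (n_flip > votes_true)
    tie = assigned & (n_flip == votes_true) & (k > 0) & (n_flip > 0)
    emitted[wrong] = (1 - true_hap[wrong]).astype(np.int8)
    emitted[tie] = _HAP_UN
    mis[wrong] = True
    # mm counts non-SNV mismatches: background errors over the rest of the read
    mm = rng.binomial(np.maximum(model.read_length - k, 0), eps)
    return emitted, mis, mm


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth sidecar as TSV keyed by record index."""
    truth.to_csv(path, sep="\t", index_label="index")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col="index")
    truth["true_class"] = pd.Categorical(truth["true_class"], categories=TRUE_CLASSES)
    return truth


def with_seed(model: SimModel, seed: int) -> SimModel:
    """A copy of ``model`` with a different stream seed."""
    return replace(model, seed=seed)
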