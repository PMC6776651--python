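"""Haplotype-tagged Hi-C contact pairs: IO, canonicalization, classification, filtering.

Contacts are held in a :class:`pandas.DataFrame` with one row per pair and the
columns listed in :data:`PAIRS_COLUMNS`.  Coordinates are 1-based 5' mapped
positions, as in the 4DN pairs convention; records are stored upper-triangular
under the chromosome order declared in the accompanying chromosome-size table
(``(chrom1, pos1) <= (chrom2, pos2)``).

Haplotypes are encoded ``"M"`` (maternal), ``"P"`` (paternal) and ``"."``
(unassigned).  A side that overlaps no SNV can never be assigned a haplotype,
so ``snv == 0`` implies ``hap == "."``.
"""

from __future__ import annotations

import gzip
import io
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    OrderingError,
    PairsFormatError,
    UndefinedSeparationError,
)

#: Column order of the pairs dialect.
PAIRS_COLUMNS = [
    "readID",
    "chrom1",
    "pos1",
    "chrom2",
    "pos2",
    "strand1",
    "strand2",
    "hap1",
    "hap2",
    "snv1",
    "snv2",
    "mm1",
    "mm2",
]

MATERNAL = "M"
PATERNAL = "P"
UNASSIGNED = "."

HAP_CATEGORIES = [MATERNAL, PATERNAL, UNASSIGNED]
STRAND_CATEGORIES = ["+", "-"]

#: Pair classes (see :func:`classify`).
CLASS_CATEGORIES = ["cis", "trans_homolog", "trans_heterolog", "unassigned"]

#: Stringency presets: (min_snv, max_mismatch) per side.
STRINGENCY_PRESETS: Mapping[str, tuple[int, int]] = {
    "snv1": (1, np.iinfo(np.int64).max),
    "snv2-strict": (2, 0),
    "snv3-strict": (3, 0),
}

_SIDE1 = ["chrom1", "pos1", "strand1", "hap1", "snv1", "mm1"]
_SIDE2 = ["chrom2", "pos2", "strand2", "hap2", "snv2", "mm2"]


def _eq_cols(a: pd.Series, b: pd.Series) -> np.ndarray:
    """Elementwise equality of two columns; compares categorical codes when
    both sides share a dtype (no object materialization)."""
    if isinstance(a.dtype, pd.CategoricalDtype) and a.dtype == b.dtype:
        return a.cat.codes.to_numpy() == b.cat.codes.to_numpy()
    return np.asarray(a.to_numpy(dtype=object) == b.to_numpy(dtype=object))


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def empty_pairs() -> pd.DataFrame:
    """An empty pairs frame with the correct dtypes."""
    df = pd.DataFrame(
        {
            "readID": pd.Series(dtype=str),
            "chrom1": pd.Series(dtype=str),
            "pos1": pd.Series(dtype=np.int64),
            "chrom2": pd.Series(dtype=str),
            "pos2": pd.Series(dtype=np.int64),
            "strand1": pd.Series(dtype=str),
            "strand2": pd.Series(dtype=str),
            "hap1": pd.Series(dtype=str),
            "hap2": pd.Series(dtype=str),
            "snv1": pd.Series(dtype=np.int64),
            "snv2": pd.Series(dtype=np.int64),
            "mm1": pd.Series(dtype=np.int64),
            "mm2": pd.Series(dtype=np.int64),
        }
    )
    return df


def _chrom_codes(chroms: pd.Series, chrom_order: list[str], what: str) -> np.ndarray:
    codes = pd.Categorical(chroms, categories=chrom_order).codes
    if (codes < 0).any():
        bad = sorted(set(np.asarray(chroms)[codes < 0]))
        raise PairsFormatError(f"unknown chromosome(s) in {what}: {bad}")
    return codes.astype(np.int64)


def canonicalize(df: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Enforce the upper-triangular invariant, swapping all per-side fields.

    The chromosome order is the declaration order of ``chrom_sizes``.
    """
    order = list(chrom_sizes)
    c1 = _chrom_codes(df["chrom1"], order, "chrom1")
    c2 = _chrom_codes(df["chrom2"], order, "chrom2")
    swap = (c1 > c2) | ((c1 == c2) & (df["pos1"].to_numpy() > df["pos2"].to_numpy()))
    if not swap.any():
        return df
    out = df.copy()
    swap = np.asarray(swap)
    for a, b in zip(_SIDE1, _SIDE2):
        va = out.loc[swap, a].to_numpy()
        out.loc[swap, a] = out.loc[swap, b].to_numpy()
        out.loc[swap, b] = va
    return out


def read_pairs(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a haplotype-tagged pairs file.

    Returns ``(pairs, chrom_sizes)``.  The header must contain ``#chromsize:``
    lines (declaring the chromosome order) and a ``#columns:`` line naming at
    least the columns of :data:`PAIRS_COLUMNS`.  Records violating the
    upper-triangular invariant are emitted with their sides swapped.
    Transparently reads gzip files.
    """
    chrom_sizes: dict[str, int] = {}
    columns = None
    body = io.StringIO()
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("#chromsize:"):
                    fields = line[len("#chromsize:"):].split()
                    if len(fields) != 2:
                        raise PairsFormatError(f"malformed chromsize line: {line!r}")
                    chrom_sizes[fields[0]] = int(fields[1])
                elif line.startswith("#columns:"):
                    columns = line[len("#columns:"):].split()
                continue
            body.write(line)
    if columns is None:
        raise PairsFormatError("missing #columns: header line")
    missing = [c for c in PAIRS_COLUMNS if c not in columns]
    if missing:
        raise PairsFormatError(f"missing required column(s): {missing}")
    if not chrom_sizes:
        raise PairsFormatError("missing #chromsize: header lines")
    body.seek(0)
    df = pd.read_csv(
        body,
        sep="\t",
        names=columns,
        dtype={
            "readID": str,
            "chrom1": str,
            "chrom2": str,
            "strand1": str,
            "strand2": str,
            "hap1": str,
            "hap2": str,
            "pos1": np.int64,
            "pos2": np.int64,
            "snv1": np.int64,
            "snv2": np.int64,
            "mm1": np.int64,
            "mm2": np.int64,
        },
    )
    if len(df) == 0:
        df = empty_pairs()
    df = df[PAIRS_COLUMNS]
    df = canonicalize(df, chrom_sizes)
    return df, chrom_sizes


def write_pairs(df: pd.DataFrame, chrom_sizes: Mapping[str, int], path) -> None:
    """Write pairs in the dialect read by :func:`read_pairs`."""
    with _open_text(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        df[PAIRS_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def dedup(df: pd.DataFrame, max_offset: int = 0) -> pd.DataFrame:
    """Remove PCR duplicates.

    Input must be sorted by ``(chrom1, pos1, chrom2, pos2)``.  Among groups of
    records whose chromosomes and strands match on both sides and whose
    positions differ by at most ``max_offset`` on both sides, the first record
    in sort order is kept.  ``max_offset=0`` is exact duplicate removal.
    """
    if max_offset < 0:
        raise InvalidParameterError("max_offset must be >= 0")
    key = df[["chrom1", "pos1", "chrom2", "pos2"]]
    sorted_ok = (
        key.sort_values(["chrom1", "pos1", "chrom2", "pos2"], kind="stable")
        .index.equals(key.index)
    )
    if not sorted_ok:
        raise OrderingError("dedup requires input sorted by (chrom1, pos1, chrom2, pos2)")
    if len(df) == 0:
        return df
    if max_offset == 0:
        keep = ~df.duplicated(
            subset=["chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
        )
        return df.loc[keep]

    # Offset-tolerant pass: scan in sort order keeping a window of previously
    # kept records with pos1 within max_offset.
    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    kept_idx: list[int] = []
    window: list[int] = []
    keep = np.ones(len(df), dtype=bool)
    for i in range(len(df)):
        window = [
            j for j in window if c1[j] == c1[i] and p1[i] - p1[j] <= max_offset
        ]
        dup = any(
            c2[j] == c2[i]
            and s1[j] == s1[i]
            and s2[j] == s2[i]
            and abs(p2[i] - p2[j]) <= max_offset
            for j in window
        )
        if dup:
            keep[i] = False
        else:
            window.append(i)
            kept_idx.append(i)
    return df.loc[keep]


def classify(pairs) -> pd.Series | str:
    """Classify pairs as cis / trans_homolog / trans_heterolog / unassigned.

    ``cis``: same chromosome, same haplotype on both sides.
    ``trans_homolog``: same chromosome, different haplotypes.
    ``trans_heterolog``: different chromosomes (haplotypes both assigned).
    Any unassigned side makes the pair ``unassigned``.  Pure function;
    invariant under the canonicalization swap.

    Accepts a DataFrame (vectorized, returns a categorical Series) or a single
    record (a Series/namedtuple with the pairs fields, returns a string).
    """
    single = not isinstance(pairs, pd.DataFrame)
    if single:
        df = pd.DataFrame([pairs._asdict() if hasattr(pairs, "_asdict") else dict(pairs)])
    else:
        df = pairs
    same_chrom = _eq_cols(df["chrom1"], df["chrom2"])
    same_hap = _eq_cols(df["hap1"], df["hap2"])
    assigned = (df["hap1"] != UNASSIGNED).to_numpy() & (df["hap2"] != UNASSIGNED).to_numpy()
    codes = np.full(len(df), CLASS_CATEGORIES.index("unassigned"), dtype=np.int8)
    codes[assigned & ~same_chrom] = CLASS_CATEGORIES.index("trans_heterolog")
    codes[assigned & same_chrom & same_hap] = CLASS_CATEGORIES.index("cis")
    codes[assigned & same_chrom & ~same_hap] = CLASS_CATEGORIES.index("trans_homolog")
    result = pd.Series(
        pd.Categorical.from_codes(codes, categories=CLASS_CATEGORIES),
        index=df.index,
        name="pair_class",
    )
    if single:
        return str(result.iloc[0])
    return result


def stringency_filter(
    df: pd.DataFrame, min_snv: int, max_mismatch: int | float = np.inf
) -> pd.DataFrame:
    """Keep pairs with ``snv >= min_snv`` and ``mm <= max_mismatch`` on both sides."""
    if min_snv < 1:
        raise InvalidParameterError("min_snv must be >= 1")
    keep = (
        (df["snv1"] >= min_snv)
        & (df["snv2"] >= min_snv)
        & (df["mm1"] <= max_mismatch)
        & (df["mm2"] <= max_mismatch)
    )
    return df.loc[keep.to_numpy()]


def separation_and_orientation(pairs) -> tuple:
    """Genomic separation and mutual read orientation of same-chromosome pairs.

    Separation is the distance between 5' mapped positions, ``pos2 - pos1``
    (non-negative under canonical ordering).  Orientation: ``(+,-)`` inward,
    ``(-,+)`` outward, same-strand tandem.

    Accepts a DataFrame (returns ``(Series s, categorical Series orientation)``)
    or a single record (returns ``(int, str)``).  Raises
    :class:`UndefinedSeparationError` for cross-chromosome records.
    """
    single = not isinstance(pairs, pd.DataFrame)
    if single:
        df = pd.DataFrame([pairs._asdict() if hasattr(pairs, "_asdict") else dict(pairs)])
    else:
        df = pairs
    if not _eq_cols(df["chrom1"], df["chrom2"]).all():
        raise UndefinedSeparationError(
            "separation undefined for cross-chromosome records"
        )
    s = df["pos2"].to_numpy() - df["pos1"].to_numpy()
    fwd1 = (df["strand1"] == "+").to_numpy()
    fwd2 = (df["strand2"] == "+").to_numpy()
    categories = ["inward", "outward", "tandem"]
    codes = np.full(len(df), categories.index("tandem"), dtype=np.int8)
    codes[fwd1 & ~fwd2] = categories.index("inward")
    codes[~fwd1 & fwd2] = categories.index("outward")
    orient = pd.Categorical.from_codes(codes, categories=categories)
    if single:
        return int(s[0]), str(orient[0])
    return (
        pd.Series(s, index=df.index, name="separation"),
        pd.Series(orient, index=df.index, name="orientation"),
    )
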