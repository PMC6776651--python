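"""Binning, MADmax filtering, iterative correction, O/E, container output."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ohm import binmatrix as bm
from ohm import pairs
from ohm.errors import InvalidParameterError, PairsFormatError

SIZES = {"chrA": 100_000, "chrB": 60_000}


def rec(chrom1="chrA", pos1=1, chrom2="chrA", pos2=50_001, hap1="M", hap2="M",
        readID=0):
    return [readID, chrom1, pos1, chrom2, pos2, "+", "-", hap1, hap2,
            int(hap1 != "."), int(hap2 != "."), 0, 0]


def make_df(rows):
    return pd.DataFrame(rows, columns=pairs.PAIRS_COLUMNS)


def sinkhorn_dense(A, max_iter=100_000, tol=1e-14):
    """Independent alternating row/column scaling oracle on a dense matrix."""
    A = np.asarray(A, dtype=float)
    r = np.ones(A.shape[0])
    c = np.ones(A.shape[1])
    for _ in range(max_iter):
        r_new = 1.0 / (A @ c)
        c_new = 1.0 / (A.T @ r_new)
        if np.allclose(r_new, r, rtol=tol) and np.allclose(c_new, c, rtol=tol):
            r, c = r_new, c_new
            break
        r, c = r_new, c_new
    # symmetrize the scaling (A symmetric => r == c at the fixed point up to
    # a global gauge factor)
    w = np.sqrt(r * c)
    return w[:, None] * A * w[None, :]


class TestBinTable:
    def test_tiling(self):
        bins = bm.BinTable(SIZES, 10_000)
        frame = bins.to_frame()
        assert bins.n_bins == 16
        assert (frame.groupby("chrom", sort=False)["end"].max()
                == pd.Series(SIZES)).all()
        # gapless
        for c, grp in frame.groupby("chrom", sort=False):
            assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()

    def test_bin_ids(self):
        bins = bm.BinTable(SIZES, 10_000)
        ids = bins.bin_ids(np.array(["chrA", "chrB"], dtype=object),
                           np.array([15_000, 5]))
        np.testing.assert_array_equal(ids, [1, 10])

    def test_invalid_resolution(self):
        with pytest.raises(InvalidParameterError):
            bm.BinTable(SIZES, 0)


class TestBinContacts:
    def test_ten_records_entry_ten(self):
        bins = bm.BinTable(SIZES, 10_000)
        df = make_df([rec(readID=i) for i in range(10)])
        cmap = bm.bin_contacts(df, bins)
        assert cmap.components["cis_maternal"][0, 5] == 10

    def test_separation_boundary(self):
        bins = bm.BinTable(SIZES, 10_000)
        kept = make_df([rec(pos2=3001)])       # s = 3000: kept
        dropped = make_df([rec(pos2=3000)])    # s = 2999: excluded
        assert bm.bin_contacts(kept, bins).components["cis_maternal"].sum() == 1
        out = bm.bin_contacts(dropped, bins)
        assert out.components["cis_maternal"].sum() == 0
        assert out.exclusions["cis_maternal"] == 1

    def test_heterolog_unaffected_by_separation(self):
        bins = bm.BinTable(SIZES, 10_000)
        df = make_df([rec(chrom2="chrB", pos2=2, hap2="P")])
        cmap = bm.bin_contacts(df, bins)
        # symmetric store: one record appears once in the upper triangle
        assert sp.triu(cmap.components["trans_heterolog"]).sum() == 1

    def test_out_of_range_raises(self):
        bins = bm.BinTable(SIZES, 10_000)
        df = make_df([rec(pos2=200_000)])
        with pytest.raises(PairsFormatError):
            bm.bin_contacts(df, bins)

    def test_totals_match_truth_counts(self, small_library, small_genome):
        lib, truth = small_library
        bins = bm.BinTable(small_genome.chrom_sizes, 50_000)
        cmap = bm.bin_contacts(lib, bins)
        cls = pairs.classify(lib)
        for comp, sel in [
            ("trans_homolog", cls == "trans_homolog"),
            ("trans_heterolog", cls == "trans_heterolog"),
        ]:
            total = sp.triu(cmap.components[comp]).sum()
            expect = int(sel.sum()) - cmap.exclusions.get(comp, 0)
            assert total == expect
        cis_total = (sp.triu(cmap.components["cis_maternal"]).sum()
                     + sp.triu(cmap.components["cis_paternal"]).sum())
        n_cis = int((cls == "cis").sum())
        assert cis_total == n_cis - cmap.exclusions["cis_maternal"] \
            - cmap.exclusions["cis_paternal"]
        assert cmap.exclusions["unassigned"] == int((cls == "unassigned").sum())

    def test_homolog_pooling_symmetric(self, small_library, small_genome):
        lib, _ = small_library
        bins = bm.BinTable(small_genome.chrom_sizes, 50_000)
        cmap = bm.bin_contacts(lib, bins)
        hom = cmap.components["trans_homolog"]
        assert (hom != hom.T).nnz == 0
        unpooled = bm.bin_contacts(lib, bins, pool_homolog=False)
        mp = unpooled.components["trans_homolog_mp"]
        assert mp.sum() == sp.triu(hom).sum()


class TestMadmax:
    def random_map(self, n=1000, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        A = rng.random((n, n)) * scale
        A = A + A.T + n * np.eye(n)
        bins = bm.BinTable({"c": n * 1000}, 1000)
        return bm.BinnedMap(bins=bins,
                            components={"cis_maternal": sp.csr_matrix(A)})

    def test_uniform_nothing_masked(self):
        cmap = self.random_map(100)
        cmap.components["cis_maternal"] = sp.csr_matrix(np.ones((100, 100)))
        mask = bm.madmax_filter(cmap)
        assert not mask.any()

    def test_constructed_outlier(self):
        n = 1000
        A = np.ones((n, n))
        A[7, :] *= 1e-6
        A[:, 7] *= 1e-6
        bins = bm.BinTable({"c": n * 1000}, 1000)
        cmap = bm.BinnedMap(bins=bins,
                            components={"cis_maternal": sp.csr_matrix(A)})
        mask = bm.madmax_filter(cmap)
        assert mask[7] and mask.sum() == 1

    def test_scale_invariance(self):
        a = self.random_map(200, seed=3, scale=1.0)
        b = self.random_map(200, seed=3, scale=1.0)
        b.components["cis_maternal"] = b.components["cis_maternal"] * 1234.5
        np.testing.assert_array_equal(bm.madmax_filter(a), bm.madmax_filter(b))

    def test_zero_coverage_always_masked(self):
        n = 50
        A = np.ones((n, n))
        A[4, :] = 0
        A[:, 4] = 0
        bins = bm.BinTable({"c": n * 1000}, 1000)
        cmap = bm.BinnedMap(bins=bins,
                            components={"cis_maternal": sp.csr_matrix(A)})
        assert bm.madmax_filter(cmap)[4]


class TestIterativeCorrection:
    def diag_dominant(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.random((n, n))
        A = A + A.T + n * np.eye(n)
        return A

    def make_cmap(self, A, component="cis_maternal"):
        n = A.shape[0]
        bins = bm.BinTable({"c": n * 1000}, 1000)
        cmap = bm.BinnedMap(bins=bins, components={component: sp.csr_matrix(A)})
        cmap.mask = np.zeros(n, dtype=bool)
        return cmap

    def test_mask_required(self):
        cmap = self.make_cmap(self.diag_dominant())
        cmap.mask = None
        with pytest.raises(InvalidParameterError):
            bm.iterative_correction(cmap)

    def test_doubly_stochastic_unit_weights(self):
        n = 40
        A = np.full((n, n), 1.0 / n)
        cmap = self.make_cmap(A)
        bm.iterative_correction(cmap, tol=1e-16)
        np.testing.assert_allclose(cmap.weights["cis_maternal"], 1.0, atol=1e-6)

    def test_marginals_and_sinkhorn_oracle(self):
        A = self.diag_dominant(50, seed=1)
        cmap = self.make_cmap(A)
        bm.iterative_correction(cmap, tol=1e-16)
        bal = cmap.balanced("cis_maternal").toarray()
        np.testing.assert_allclose(bal.sum(axis=1), 1.0, atol=1e-6)
        oracle = sinkhorn_dense(A)
        np.testing.assert_allclose(bal, oracle, atol=1e-8)

    def test_gauge_property(self):
        A = self.diag_dominant(30, seed=2)
        a = self.make_cmap(A)
        b = self.make_cmap(7.0 * A)
        bm.iterative_correction(a, tol=1e-16)
        bm.iterative_correction(b, tol=1e-16)
        np.testing.assert_allclose(
            b.weights["cis_maternal"], a.weights["cis_maternal"] / np.sqrt(7.0),
            rtol=1e-6,
        )
        np.testing.assert_allclose(
            b.balanced("cis_maternal").toarray(),
            a.balanced("cis_maternal").toarray(),
            atol=1e-10,
        )

    def test_masked_bins_nan_weights(self):
        A = self.diag_dominant(20, seed=4)
        cmap = self.make_cmap(A)
        cmap.mask[3] = True
        bm.iterative_correction(cmap, tol=1e-16)
        w = cmap.weights["cis_maternal"]
        assert np.isnan(w[3])
        bal = cmap.balanced("cis_maternal").toarray()
        good = ~cmap.mask
        np.testing.assert_allclose(bal[good][:, good].sum(axis=1), 1.0,
                                   atol=1e-6)
        assert bal[3].sum() == 0

    def test_default_skips_heterolog(self, small_library, small_genome):
        lib, _ = small_library
        bins = bm.BinTable(small_genome.chrom_sizes, 100_000)
        cmap = bm.bin_contacts(lib, bins)
        bm.madmax_filter(cmap)
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            bm.iterative_correction(cmap)
        assert set(cmap.weights) == set(bm.BALANCED_COMPONENTS)

    def test_joint_mode_shares_weights(self, small_library, small_genome):
        lib, _ = small_library
        bins = bm.BinTable(small_genome.chrom_sizes, 100_000)
        cmap = bm.bin_contacts(lib, bins)
        bm.madmax_filter(cmap)
        bm.iterative_correction(cmap, joint=True)
        ws = list(cmap.weights.values())
        assert set(cmap.weights) == set(cmap.components)
        for w in ws[1:]:
            np.testing.assert_array_equal(w, ws[0])


class TestObservedExpected:
    def test_constant_diagonals_give_one(self):
        n = 30
        d = np.arange(n)
        A = 1.0 / (1.0 + np.abs(d[:, None] - d[None, :]))
        bins = bm.BinTable({"c": n * 1000}, 1000)
        cmap = bm.BinnedMap(bins=bins,
                            components={"cis_maternal": sp.csr_matrix(A)})
        cmap.mask = np.zeros(n, dtype=bool)
        cmap.weights["cis_maternal"] = np.ones(n)
        oe = bm.observed_expected(cmap, "cis_maternal").toarray()
        np.testing.assert_allclose(oe, 1.0, atol=1e-12)

    def test_diagonal_means_one(self):
        rng = np.random.default_rng(8)
        n = 40
        A = rng.random((n, n)) + 0.1
        A = A + A.T
        bins = bm.BinTable({"c": n * 1000}, 1000)
        cmap = bm.BinnedMap(bins=bins,
                            components={"cis_maternal": sp.csr_matrix(A)})
        cmap.mask = np.zeros(n, dtype=bool)
        cmap.mask[5] = True
        cmap.weights["cis_maternal"] = np.where(cmap.mask, np.nan, 1.0)
        oe = sp.coo_matrix(bm.observed_expected(cmap, "cis_maternal"))
        good = ~cmap.mask
        for offset in range(n):
            sel = (np.abs(oe.col - oe.row) == offset) & good[oe.row] & good[oe.col]
            if not sel.any():
                continue
            assert np.mean(oe.data[sel]) == pytest.approx(1.0, abs=1e-10)

    def test_localized_enrichment_stands_out(self):
        # O/E normalizes each diagonal to chromosome-wide mean 1, so a
        # *localized* diagonal enrichment yields O/E > 1 there and < 1 elsewhere
        n = 60
        A = np.ones((n, n))
        enriched = slice(20, 30)
        idx = np.arange(20, 30)
        A[idx, idx] += 5.0
        bins = bm.BinTable({"c": n * 1000}, 1000)
        cmap = bm.BinnedMap(bins=bins,
                            components={"trans_homolog": sp.csr_matrix(A)})
        cmap.mask = np.zeros(n, dtype=bool)
        cmap.weights["trans_homolog"] = np.ones(n)
        oe = bm.observed_expected(cmap, "trans_homolog").toarray()
        assert (np.diag(oe)[enriched] > 1).all()
        assert (np.diag(oe)[:20] < 1).all()


class TestContainers:
    def make(self, small_library, small_genome):
        lib, _ = small_library
        bins = bm.BinTable(small_genome.chrom_sizes, 100_000)
        cmap = bm.bin_contacts(lib, bins)
        bm.madmax_filter(cmap)
        bm.iterative_correction(cmap)
        return cmap

    def test_coo_tsv_round_trip(self, tmp_path, small_library, small_genome):
        cmap = self.make(small_library, small_genome)
        path = tmp_path / "m.tsv"
        bm.write_coo_tsv(cmap, "cis_maternal", path)
        back = pd.read_csv(path, sep="\t")
        m = sp.triu(cmap.components["cis_maternal"].tocoo())
        assert back["count"].sum() == m.data.sum()
        w = cmap.weights["cis_maternal"]
        i = 0
        row = back.iloc[i]
        expect = w[int(row.bin1)] * w[int(row.bin2)] * row["count"]
        if np.isfinite(expect):
            assert row["balanced"] == pytest.approx(expect)

    def test_cooler_layout_round_trip(self, tmp_path, small_library,
                                      small_genome):
        import h5py

        cmap = self.make(small_library, small_genome)
        path = tmp_path / "m.cool"
        bm.write_cooler(cmap, "trans_homolog", path)
        with h5py.File(path) as h5:
            assert h5.attrs["format"] == "HDF5::Cooler"
            assert h5.attrs["bin-size"] == cmap.resolution
            names = [n.decode() for n in h5["chroms/name"][:]]
            assert names == list(small_genome.chrom_sizes)
            bin1 = h5["pixels/bin1_id"][:]
            bin2 = h5["pixels/bin2_id"][:]
            count = h5["pixels/count"][:]
            assert (bin1 <= bin2).all()
            m = sp.coo_matrix(
                (count, (bin1, bin2)),
                shape=(cmap.bins.n_bins, cmap.bins.n_bins),
            )
            full = m + sp.triu(m, k=1).T
            assert (full != cmap.components["trans_homolog"]).nnz == 0
            offsets = h5["indexes/bin1_offset"][:]
            assert offsets[0] == 0 and offsets[-1] == len(count)
            assert (np.diff(offsets) >= 0).all()
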