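"""Window statistics against brute-force pairwise-difference oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divflow.landscape import (
    PlacementTable,
    Window,
    dxy_window,
    fst_window,
    hudson_fst_window,
    lift_windows,
    peak_census,
    pi_window,
    spearman_correlation,
    tajima_d_window,
    window_partition,
    window_scan,
    z_vs_autosome_test,
)

from conftest import make_matrix


def whole(gm):
    return Window(str(gm.chrom[0]), 0, int(gm.pos.max()))


# ----------------------------------------------------------------------
# brute-force oracles: enumerate allele pairs explicitly


def site_alleles(dosages_row, cols):
    """Expand a dosage row into the explicit multiset of alleles."""
    out = []
    for c in cols:
        d = dosages_row[c]
        if d < 0:
            continue
        out.extend([1] * d + [0] * (2 - d))
    return out


def pi_oracle(gm, population, denom):
    cols = gm.pop_indices(population)
    total = 0.0
    for row in gm.dosages:
        alleles = site_alleles(row, cols)
        pairs = list(itertools.combinations(alleles, 2))
        if pairs:
            total += sum(a != b for a, b in pairs) / len(pairs)
    return total / denom


def dxy_oracle(gm, denom):
    p1, p2 = gm.populations
    cols1, cols2 = gm.pop_indices(p1), gm.pop_indices(p2)
    total = 0.0
    for row in gm.dosages:
        a1 = site_alleles(row, cols1)
        a2 = site_alleles(row, cols2)
        pairs = [(x, y) for x in a1 for y in a2]
        if pairs:
            total += sum(x != y for x, y in pairs) / len(pairs)
    return total / denom


def wc_fst_oracle(gm):
    """Independent transcription of the Weir-Cockerham (1984) components."""
    p1, p2 = gm.populations
    cols = [gm.pop_indices(p1), gm.pop_indices(p2)]
    num = den = 0.0
    for row in gm.dosages:
        n_i, p_i, h_i = [], [], []
        for cc in cols:
            called = [row[c] for c in cc if row[c] >= 0]
            if not called:
                break
            n_i.append(len(called))
            p_i.append(sum(called) / (2 * len(called)))
            h_i.append(sum(1 for d in called if d == 1) / len(called))
        else:
            r = 2
            n_bar = sum(n_i) / r
            if n_bar <= 1:
                continue
            nc = (sum(n_i) - sum(x * x for x in n_i) / sum(n_i)) / (r - 1)
            if nc <= 0:
                continue
            p_bar = sum(n * p for n, p in zip(n_i, p_i)) / sum(n_i)
            if p_bar in (0.0, 1.0):
                continue
            s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
            h_bar = sum(n * h for n, h in zip(n_i, h_i)) / sum(n_i)
            a = (n_bar / nc) * (
                s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - s2 * (r - 1) / r
                - h_bar * (2 * n_bar - 1) / (4 * n_bar)
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num / den if den else float("nan")


class TestWindowPartition:
    def test_tiling_with_trailing_partial(self):
        ws = window_partition({"c": 500_000}, size=200_000)
        assert [(w.start, w.end, w.partial) for w in ws] == [
            (0, 200_000, False),
            (200_000, 400_000, False),
            (400_000, 500_000, True),
        ]

    def test_exact_fit_single_window(self):
        ws = window_partition({"c": 200_000}, 200_000)
        assert len(ws) == 1 and not ws[0].partial

    def test_zero_length_sequence(self):
        assert window_partition({"c": 0}, 200_000) == []


class TestPi:
    def test_singleton_among_ten_sites(self):
        # one site, alt count 1 of 4 alleles; 10 accessible sites
        gm = make_matrix([[1, 0, 0, 0]], ["p1", "p1", "p2", "p2"])
        w = Window("chr1", 0, 100)
        assert pi_window(gm, w, "p1", n_accessible=10) == pytest.approx(0.5 / 10)

    def test_monomorphic_window_is_zero(self):
        gm = make_matrix([[0, 0, 2, 2]], ["p1", "p1", "p2", "p2"])
        w = Window("chr1", 0, 100)
        assert pi_window(gm, w, "p1", n_accessible=5) == 0.0

    def test_matches_pairwise_oracle(self, toy_matrix):
        w = whole(toy_matrix)
        for pop in toy_matrix.populations:
            got = pi_window(toy_matrix, w, pop, n_accessible=5)
            assert got == pytest.approx(pi_oracle(toy_matrix, pop, 5), rel=1e-12)


class TestDxy:
    def test_fixed_difference(self):
        gm = make_matrix([[2, 2, 0, 0]], ["p1", "p1", "p2", "p2"])
        assert dxy_window(gm, Window("chr1", 0, 10), n_accessible=10) == pytest.approx(0.1)

    def test_intermediate_frequencies(self):
        # p1 = p2 = 0.5 -> per-site dxy 0.5, over 10 sites
        gm = make_matrix([[2, 0, 1, 1]], ["p1", "p1", "p2", "p2"])
        assert dxy_window(gm, Window("chr1", 0, 10), n_accessible=10) == pytest.approx(0.05)

    def test_matches_pairwise_oracle(self, toy_matrix):
        got = dxy_window(toy_matrix, whole(toy_matrix), n_accessible=5)
        assert got == pytest.approx(dxy_oracle(toy_matrix, 5), rel=1e-12)


class TestFst:
    def test_fixed_difference_is_one(self):
        gm = make_matrix([[2] * 9 + [0] * 9], ["p1"] * 9 + ["p2"] * 9)
        assert fst_window(gm, Window("chr1", 0, 10)) == pytest.approx(1.0)

    def test_identical_populations_not_positive(self):
        gm = make_matrix(
            [[0, 1, 2, 0, 1, 2], [1, 1, 0, 1, 1, 0]], ["p1"] * 3 + ["p2"] * 3
        )
        assert fst_window(gm, Window("chr1", 0, 10)) <= 0.0

    def test_single_site_matches_component_oracle(self):
        # pop1: 5 ref/ref + 4 ref/alt; pop2: 2 ref/ref + 7 alt/alt
        row = [0] * 5 + [1] * 4 + [0] * 2 + [2] * 7
        gm = make_matrix([row], ["p1"] * 9 + ["p2"] * 9)
        got = fst_window(gm, Window("chr1", 0, 10))
        assert got == pytest.approx(wc_fst_oracle(gm), rel=1e-12)

    def test_multisite_matches_component_oracle(self, rng):
        dos = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.1] = -1
        gm = make_matrix(dos, ["p1"] * 3 + ["p2"] * 3)
        got = fst_window(gm, Window("chr1", 0, 30))
        want = wc_fst_oracle(gm)
        assert got == pytest.approx(want, rel=1e-12)


class TestTajimaD:
    def test_no_segregating_sites_undefined(self):
        gm = make_matrix([[0, 0, 0, 0]], ["p1", "p1", "p2", "p2"])
        assert np.isnan(tajima_d_window(gm, Window("chr1", 0, 10), "p1"))

    def test_n2_haplotypes_undefined(self):
        # query the 1-diploid population of a two-population matrix
        gm = make_matrix([[1, 0], [1, 2]], ["p1", "p2"], pos=[1, 2])
        assert np.isnan(tajima_d_window(gm, Window("chr1", 0, 10), "p1"))

    def test_four_singletons_n4(self):
        """n = 4 haplotypes with 4 singleton sites gives D ~ -0.78."""
        dos = [[1, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0]]
        gm = make_matrix(dos, ["p1", "p1", "p2"], pos=[1, 2, 3, 4])
        got = tajima_d_window(gm, Window("chr1", 0, 10), "p1")
        assert got == pytest.approx(-0.780, abs=5e-3)


class TestSummaries:
    def test_spearman_monotone_limits(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_spearman_hand_ranked_case(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*(25-1)) = 0.8
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_peak_census_strict_threshold(self):
        df = pd.DataFrame(
            {"chrom": "c", "start": 0, "end": 1, "fst": [0.1, 0.3, 0.26, 0.25]}
        )
        count, peaks = peak_census(df, 0.25)
        assert count == 2
        assert list(peaks["fst"]) == [0.3, 0.26]  # sorted descending

    def test_peak_census_handles_negatives(self):
        df = pd.DataFrame({"chrom": "c", "start": 0, "end": 1, "fst": [-0.01, 0.0, 0.3]})
        assert peak_census(df, 0.0)[0] == 1

    def test_z_vs_autosome_identical_groups(self):
        df = pd.DataFrame(
            {
                "chrom": ["1", "1", "1", "Z", "Z", "Z"],
                "start": 0,
                "end": 1,
                "fst": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
            }
        )
        t, p = z_vs_autosome_test(df)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_z_vs_autosome_pooled_t(self):
        df = pd.DataFrame(
            {
                "chrom": ["1"] * 3 + ["Z"] * 3,
                "start": 0,
                "end": 1,
                "fst": [2.1, 2.5, 2.3] + [1.0, 1.2, 1.1],
            }
        )
        t, _ = z_vs_autosome_test(df)
        # textbook pooled-variance two-sample t
        a, z = np.array([2.1, 2.5, 2.3]), np.array([1.0, 1.2, 1.1])
        sp2 = (a.var(ddof=1) * 2 + z.var(ddof=1) * 2) / 4
        want = (a.mean() - z.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(want, rel=1e-12)


class TestLiftWindows:
    def make_stats(self, chrom="s1"):
        return pd.DataFrame(
            {"chrom": [chrom], "start": [0], "end": [200_000], "fst": [0.1]}
        )

    def placement(self):
        return PlacementTable(
            pd.DataFrame(
                {
                    "scaffold": ["s1", "s2"],
                    "chrom": ["chr1", "chr1"],
                    "offset": [1_000_000, 5_000_000],
                    "strand": ["+", "-"],
                    "length": [400_000, 300_000],
                }
            )
        )

    def test_plus_strand_shift(self):
        out = lift_windows(self.make_stats("s1"), self.placement())
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (1_000_000, 1_200_000)
        assert out.loc[0, "chrom"] == "chr1"
        assert bool(out.loc[0, "placed"])

    def test_minus_strand_reflection(self):
        out = lift_windows(self.make_stats("s2"), self.placement())
        # length 300k: [0, 200k) reflects to [offset+100k, offset+300k)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (5_100_000, 5_300_000)

    def test_unplaced_scaffold_flagged(self):
        out = lift_windows(self.make_stats("s9"), self.placement())
        assert out.loc[0, "chrom"] == "s9"
        assert not bool(out.loc[0, "placed"])

    def test_overlapping_placements_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PlacementTable(
                pd.DataFrame(
                    {
                        "scaffold": ["a", "b"],
                        "chrom": ["c", "c"],
                        "offset": [0, 100],
                        "strand": ["+", "+"],
                        "length": [200, 200],
                    }
                )
            )


class TestWindowSizeInvariance:
    def test_genomewide_averages_independent_of_window_size(self, rng):
        """Summed per-site quantities agree across window tilings to 1e-12."""
        n_sites = 300
        dos = rng.integers(0, 3, size=(n_sites, 8)).astype(np.int8)
        pos = np.sort(rng.choice(100_000, size=n_sites, replace=False)) + 1
        gm = make_matrix(dos, ["p1"] * 4 + ["p2"] * 4, pos=pos)
        totals = {}
        for size in (10_000, 20_000, 50_000, 100_000):
            ws = window_partition({"chr1": 100_000}, size)
            stats = window_scan(gm, ws, min_sites=0)
            # aggregate per-site sums: weight each window by its site count
            ok = stats["n_sites"] > 0
            dxy_sum = (stats.loc[ok, "dxy"] * stats.loc[ok, "n_sites"]).sum()
            pi1_sum = (stats.loc[ok, "pi1"] * stats.loc[ok, "n_sites"]).sum()
            totals[size] = (dxy_sum, pi1_sum)
        ref = totals[10_000]
        for size, vals in totals.items():
            assert vals == pytest.approx(ref, rel=1e-12)
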