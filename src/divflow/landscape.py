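"""Windowed genomic-landscape statistics for a two-population genome scan.

Per non-overlapping window (default 200 kb): Weir-Cockerham weighted FST,
absolute divergence dXY, per-population nucleotide diversity pi, and
per-population Tajima's D; plus genome-scan summaries (rank correlations
between statistics, the census of high-FST windows, the autosome-vs-Z
comparison) and lifting of scaffold windows onto pseudo-chromosome
coordinates via a placement table.

Undefined statistics are carried as NaN, never as zeros.  pi and dXY are
per-site quantities: the per-window sums of per-site estimators are divided
by the number of accessible (genotyped) sites, which defaults to the SNP
count in the matrix but can be supplied explicitly when invariant-site
counts are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix

__all__ = [
    "Window",
    "PlacementTable",
    "window_partition",
    "pi_window",
    "dxy_window",
    "fst_window",
    "hudson_fst_window",
    "tajima_d_window",
    "window_scan",
    "spearman_correlation",
    "peak_census",
    "z_vs_autosome_test",
    "lift_windows",
]


@dataclass(frozen=True)
class Window:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def size(self) -> int:
        return self.end - self.start


def window_partition(
    sequence_lengths: dict[str, int], size: int = 200_000
) -> list[Window]:
    """Tile each sequence with non-overlapping windows of ``size`` bases.

    A trailing partial window is retained and flagged.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    out: list[Window] = []
    for chrom, length in sequence_lengths.items():
        start = 0
        while start < length:
            end = min(start + size, length)
            out.append(Window(str(chrom), start, end, partial=(end - start) < size))
            start = end
    return out


def _window_site_index(gm: GenotypeMatrix, window: Window) -> np.ndarray:
    # VCF positions are 1-based; windows are 0-based half-open
    return np.flatnonzero(
        (gm.chrom.astype(str) == window.chrom)
        & (gm.pos - 1 >= window.start)
        & (gm.pos - 1 < window.end)
    )


def _per_site_pi(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*c_ref*c_alt / (n*(n-1))."""
    n = called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (n - alt) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def pi_window(
    gm: GenotypeMatrix,
    window: Window,
    population: str,
    n_accessible: int | None = None,
) -> float:
    """Per-site nucleotide diversity of one population in a window.

    Sums the unbiased per-site estimator over genotyped SNPs and divides by
    ``n_accessible`` (the count of genotyped sites, invariant + variant).
    By default ``n_accessible`` is the number of matrix sites in the window,
    which is exact when the matrix includes monomorphic rows and an
    underestimate of the true denominator when it holds SNPs only.
    """
    idx = _window_site_index(gm, window)
    alt, called = gm.allele_counts(population)
    alt, called = alt[idx], called[idx]
    ok = called >= 2
    denom = len(idx) if n_accessible is None else n_accessible
    if denom == 0 or not ok.any():
        return float("nan")
    return float(np.nansum(_per_site_pi(alt[ok], called[ok])) / denom)


def dxy_window(
    gm: GenotypeMatrix, window: Window, n_accessible: int | None = None
) -> float:
    """Per-site absolute divergence between the two populations."""
    idx = _window_site_index(gm, window)
    p1_lab, p2_lab = gm.populations
    a1, c1 = gm.allele_counts(p1_lab)
    a2, c2 = gm.allele_counts(p2_lab)
    a1, c1, a2, c2 = a1[idx], c1[idx], a2[idx], c2[idx]
    ok = (c1 >= 1) & (c2 >= 1)
    denom = len(idx) if n_accessible is None else n_accessible
    if denom == 0 or not ok.any():
        return float("nan")
    p1 = a1[ok] / c1[ok]
    p2 = a2[ok] / c2[ok]
    dxy = p1 * (1 - p2) + p2 * (1 - p1)
    return float(dxy.sum() / denom)


def _wc_components(gm: GenotypeMatrix, idx: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components a, b, c (r=2)."""
    p1_lab, p2_lab = gm.populations
    cols1 = gm.pop_indices(p1_lab)
    cols2 = gm.pop_indices(p2_lab)
    d1 = gm.dosages[np.ix_(idx, cols1)]
    d2 = gm.dosages[np.ix_(idx, cols2)]
    r = 2.0
    n_i = np.stack([(d1 >= 0).sum(axis=1), (d2 >= 0).sum(axis=1)]).astype(float).T
    alt_i = np.stack(
        [np.where(d1 >= 0, d1, 0).sum(axis=1), np.where(d2 >= 0, d2, 0).sum(axis=1)]
    ).T
    het_i = np.stack([(d1 == 1).sum(axis=1), (d2 == 1).sum(axis=1)]).astype(float).T
    ok = (n_i >= 1).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i
        n_bar = n_i.sum(axis=1) / r
        n_sum = n_i.sum(axis=1)
        nc = (n_sum - (n_i**2).sum(axis=1) / n_sum) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=1) / n_sum
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / n_sum
        a = (n_bar / nc) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    # restrict to sites polymorphic across the pooled sample with data in both pops
    poly = ok & (p_bar > 0) & (p_bar < 1) & (n_bar > 1) & (nc > 0)
    return a[poly], b[poly], c[poly]


def fst_window(gm: GenotypeMatrix, window: Window) -> float:
    """Weir-Cockerham weighted FST (ratio of sums) over a window.

    May be slightly negative; undefined (NaN) when no polymorphic site with
    data in both populations falls in the window.
    """
    idx = _window_site_index(gm, window)
    a, b, c = _wc_components(gm, idx)
    denom = (a + b + c).sum()
    if len(a) == 0 or denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def genomewide_fst(gm: GenotypeMatrix) -> float:
    """Weir-Cockerham weighted FST over every polymorphic site in the matrix."""
    idx = np.arange(gm.n_sites)
    a, b, c = _wc_components(gm, idx)
    denom = (a + b + c).sum()
    if len(a) == 0 or denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def hudson_fst_window(gm: GenotypeMatrix, window: Window) -> float:
    """Hudson's FST (1 - Hw/Hb, ratio-of-sums form), offered as a cross-check."""
    idx = _window_site_index(gm, window)
    p1_lab, p2_lab = gm.populations
    a1, c1 = gm.allele_counts(p1_lab)
    a2, c2 = gm.allele_counts(p2_lab)
    a1, c1, a2, c2 = a1[idx], c1[idx], a2[idx], c2[idx]
    ok = (c1 >= 2) & (c2 >= 2)
    if not ok.any():
        return float("nan")
    p1 = a1[ok] / c1[ok]
    p2 = a2[ok] / c2[ok]
    hw = _per_site_pi(a1[ok], c1[ok]) / 2.0 + _per_site_pi(a2[ok], c2[ok]) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb.sum() == 0:
        return float("nan")
    return float(1.0 - hw.sum() / hb.sum())


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajima_d_window(gm: GenotypeMatrix, window: Window, population: str) -> float:
    """Tajima's D for one population over a window.

    Computed from the segregating-site count S and the summed per-site
    diversity, with the 1989 normalising constants evaluated at the nominal
    haploid sample size of the population.  Undefined (NaN) when S = 0 or
    n < 4 (the variance degenerates at n <= 2 and is numerically unstable
    below 4 only through the constants, which remain valid from n = 3).
    """
    idx = _window_site_index(gm, window)
    alt, called = gm.allele_counts(population)
    alt, called = alt[idx], called[idx]
    n = 2 * len(gm.pop_indices(population))
    if n < 3:
        return float("nan")
    seg = (alt > 0) & (alt < called)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_total = float(np.nansum(_per_site_pi(alt[seg], called[seg])))
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))


def window_scan(
    gm: GenotypeMatrix,
    windows: list[Window],
    min_sites: int = 10,
    accessible_sites: dict[Window, int] | None = None,
) -> pd.DataFrame:
    """Compute all window statistics; one row per window.

    Windows with fewer than ``min_sites`` usable SNPs report NaN statistics
    to avoid ratio instability.  ``accessible_sites`` optionally supplies the
    per-window genotyped-site denominator for pi and dXY (e.g. the window
    span when all other positions are known monomorphic).
    """
    p1_lab, p2_lab = gm.populations
    rows = []
    for w in windows:
        idx = _window_site_index(gm, w)
        n_acc = None if accessible_sites is None else accessible_sites.get(w)
        n_used = len(idx)
        if n_used < min_sites:
            rows.append(
                (w.chrom, w.start, w.end, n_used, *([float("nan")] * 6))
            )
            continue
        rows.append(
            (
                w.chrom,
                w.start,
                w.end,
                n_used,
                fst_window(gm, w),
                dxy_window(gm, w, n_accessible=n_acc),
                pi_window(gm, w, p1_lab, n_accessible=n_acc),
                pi_window(gm, w, p2_lab, n_accessible=n_acc),
                tajima_d_window(gm, w, p1_lab),
                tajima_d_window(gm, w, p2_lab),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "fst", "dxy", "pi1", "pi2", "tajd1", "tajd2"],
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    NaN pairs are dropped; at least three complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired defined values")
    res = sps.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def peak_census(
    window_stats: pd.DataFrame, fst_threshold: float = 0.25
) -> tuple[int, pd.DataFrame]:
    """Windows with FST strictly above ``fst_threshold``, sorted descending."""
    defined = window_stats.dropna(subset=["fst"])
    peaks = defined[defined["fst"] > fst_threshold].sort_values("fst", ascending=False)
    return len(peaks), peaks.reset_index(drop=True)


def z_vs_autosome_test(
    window_stats: pd.DataFrame, z_chromosomes: set[str] = frozenset({"Z", "chrZ"})
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test of window FST, Z vs autosomes."""
    defined = window_stats.dropna(subset=["fst"])
    is_z = defined["chrom"].astype(str).isin(z_chromosomes)
    fst_z = defined.loc[is_z, "fst"].to_numpy()
    fst_a = defined.loc[~is_z, "fst"].to_numpy()
    if len(fst_z) < 2 or len(fst_a) < 2:
        raise ValueError("need >= 2 windows in each class")
    res = sps.ttest_ind(fst_a, fst_z, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PlacementTable:
    """Scaffold placements on pseudo-chromosomes.

    One row per scaffold: target chromosome, offset of the scaffold start on
    the pseudo-chromosome, strand, and scaffold length (needed to reflect
    minus-strand coordinates).
    """

    rows: pd.DataFrame  # scaffold, chrom, offset, strand, length

    def __post_init__(self) -> None:
        req = {"scaffold", "chrom", "offset", "strand", "length"}
        if not req.issubset(self.rows.columns):
            raise ValueError(f"placement table needs columns {sorted(req)}")
        if self.rows["scaffold"].duplicated().any():
            raise ValueError("a scaffold maps twice in the placement table")
        if (self.rows["offset"] < 0).any():
            raise ValueError("placement offsets must be non-negative")
        spans = self.rows.assign(end=self.rows["offset"] + self.rows["length"])
        for chrom, grp in spans.groupby("chrom"):
            g = grp.sort_values("offset")
            if (g["offset"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError(f"overlapping placements on {chrom}")

    @classmethod
    def from_tsv(cls, path) -> "PlacementTable":
        df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "chrom": str})
        return cls(df)


def lift_windows(window_stats: pd.DataFrame, placement: PlacementTable) -> pd.DataFrame:
    """Lift scaffold windows onto pseudo-chromosome coordinates.

    Plus-strand windows shift by the scaffold offset; minus-strand windows
    reflect within the scaffold span.  Scaffolds absent from the table are
    retained under their own ids with ``placed = False``.
    """
    table = placement.rows.set_index("scaffold")
    out = window_stats.copy()
    out["placed"] = False
    chroms = out["chrom"].astype(str)
    for scaf in chroms.unique():
        sel = chroms == scaf
        if scaf not in table.index:
            continue
        row = table.loc[scaf]
        offset, length = int(row["offset"]), int(row["length"])
        if row["strand"] == "+":
            out.loc[sel, "start"] = window_stats.loc[sel, "start"] + offset
            out.loc[sel, "end"] = window_stats.loc[sel, "end"] + offset
        else:
            s = window_stats.loc[sel, "start"].to_numpy()
            e = window_stats.loc[sel, "end"].to_numpy()
            out.loc[sel, "start"] = offset + length - e
            out.loc[sel, "end"] = offset + length - s
        out.loc[sel, "chrom"] = str(row["chrom"])
        out.loc[sel, "placed"] = True
    return out
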