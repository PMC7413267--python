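"""SNP filtering: VCF ingest, heterozygote-excess HWE test, MAF, LD pruning.

The filter chain mirrors a standard population-genomic pre-processing
pipeline for diploid biallelic SNPs: (1) remove sites with a significant
*excess* of heterozygotes relative to Hardy-Weinberg proportions (a guard
against collapsed paralogs), (2) remove sites with minor allele frequency
below a threshold, (3) prune one site of every pair in strong linkage
disequilibrium within a sliding marker window.  The order HWE -> MAF -> LD
is fixed and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterReport",
    "read_vcf",
    "read_population_map",
    "hwe_excess_het_test",
    "filter_hwe",
    "filter_maf",
    "r_squared",
    "ld_prune",
    "apply_filters",
]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Site counts removed by each filter, in application order."""

    n_input: int = 0
    removed_hwe: int = 0
    removed_maf: int = 0
    removed_ld: int = 0
    n_output: int = 0

    def check(self) -> None:
        expect = self.n_input - self.removed_hwe - self.removed_maf - self.removed_ld
        if expect != self.n_output:
            raise AssertionError("filter report does not reconcile with matrix sizes")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("input", self.n_input),
            ("removed_hwe_excess_het", self.removed_hwe),
            ("removed_maf", self.removed_maf),
            ("removed_ld_prune", self.removed_ld),
            ("output", self.n_output),
        ]
        Path(path).write_text("stage\tsites\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, population) into a dict."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 2:
            raise ValueError(f"malformed population map line: {ln!r}")
        out[parts[0]] = parts[1]
    return out


def read_vcf(path: str | Path, population_map: dict[str, str]) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a genotype matrix.

    Multiallelic and non-SNP records are skipped (the count is logged).
    Missing genotypes are preserved as the missing sentinel.  Every sample
    named in ``population_map`` must be present in the VCF header; samples
    not in the map are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    missing_samples = [s for s in population_map if s not in header_samples]
    if missing_samples:
        raise ValueError(
            f"samples in population map but absent from VCF header: {missing_samples}"
        )
    keep_cols = np.array([i for i, s in enumerate(header_samples) if s in population_map])
    samples = [header_samples[i] for i in keep_cols]
    pop_labels = np.array([population_map[s] for s in samples], dtype=object)

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        d = v.gt_types[keep_cols].astype(np.int8)
        d[d == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(d)
    if n_skipped:
        log.info("skipped %d multiallelic/non-SNP records", n_skipped)
    dosages = (
        np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosages=dosages,
        samples=samples,
        pop_labels=pop_labels,
    )
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


# ----------------------------------------------------------------------
# Hardy-Weinberg heterozygote-excess exact test


def hwe_excess_het_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact p-value for heterozygote *excess* under HWE.

    Uses the exact conditional (Levene-Haldane) distribution of the
    heterozygote count given the allele counts in a diploid sample:
    ``P(h) = N! / (n_AA! n_Aa! n_aa!) * 2**h * n_a! n_b! / (2N)!``.
    Returns ``P(het >= observed)``; monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    N = n_hom_ref + n_het + n_hom_alt
    if N == 0:
        raise ValueError("at least one genotyped individual required")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * N - n_alt)
    if n_minor == 0:
        return 1.0
    # possible het counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = (
        gammaln(N + 1)
        - gammaln((n_minor - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(N - (n_minor + hets) / 2 + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * N - n_minor + 1)
        - gammaln(2 * N + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(p[hets >= n_het].sum())


def _genotype_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = gm.dosages
    return (
        (d == 0).sum(axis=1),
        (d == 1).sum(axis=1),
        (d == 2).sum(axis=1),
    )


def filter_hwe(gm: GenotypeMatrix, alpha: float = 0.01) -> GenotypeMatrix:
    """Remove sites with exact heterozygote-excess p-value below ``alpha``.

    Populations are pooled: the filter targets artefactual heterozygosity
    from collapsed paralogous alignments, which inflates heterozygotes in
    every population.
    """
    hr, het, ha = _genotype_counts(gm)
    pvals = np.array(
        [hwe_excess_het_test(int(a), int(b), int(c)) for a, b, c in zip(hr, het, ha)]
    )
    return gm.take_sites(np.flatnonzero(pvals >= alpha))


def filter_maf(gm: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep sites with pooled minor allele frequency >= ``threshold``."""
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    alt, called = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(maf >= threshold)
    return gm.take_sites(keep)


def r_squared(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete individuals.  Returns ``nan`` (no
    pruning signal) when fewer than two complete pairs remain or either
    site is monomorphic among them.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_size: int = 50,
    step: int = 5,
    r2_threshold: float = 0.5,
) -> GenotypeMatrix:
    """Prune linked sites within sliding marker windows.

    Within each ``window_size``-marker window (advancing by ``step`` markers,
    never spanning scaffolds), pairs are visited in position order and the
    later-positioned member of any pair with ``r^2 > r2_threshold`` is
    removed.  Deterministic.
    """
    removed = np.zeros(gm.n_sites, dtype=bool)
    d = gm.dosages.astype(float)
    chrom_str = gm.chrom.astype(str)
    for c in np.unique(chrom_str):
        idx = np.flatnonzero(chrom_str == c)
        m = len(idx)
        start = 0
        while start < m:
            window = idx[start : start + window_size]
            for ai in range(len(window)):
                i = window[ai]
                if removed[i]:
                    continue
                for bi in range(ai + 1, len(window)):
                    j = window[bi]
                    if removed[j]:
                        continue
                    r2 = r_squared(d[i], d[j])
                    if r2 == r2 and r2 > r2_threshold:
                        removed[j] = True
            if start + window_size >= m:
                break
            start += step
    return gm.take_sites(np.flatnonzero(~removed))


def apply_filters(
    gm: GenotypeMatrix,
    hwe_p: float = 0.01,
    maf: float = 0.05,
    ld_window: int = 50,
    ld_step: int = 5,
    ld_r2: float = 0.5,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the fixed HWE -> MAF -> LD filter chain and report removals."""
    report = FilterReport(n_input=gm.n_sites)
    g1 = filter_hwe(gm, alpha=hwe_p)
    report.removed_hwe = gm.n_sites - g1.n_sites
    g2 = filter_maf(g1, threshold=maf)
    report.removed_maf = g1.n_sites - g2.n_sites
    g3 = ld_prune(g2, window_size=ld_window, step=ld_step, r2_threshold=ld_r2)
    report.removed_ld = g2.n_sites - g3.n_sites
    report.n_output = g3.n_sites
    report.check()
    return g3, report
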