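"""Genotype matrix container shared by the filtering and landscape stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for an uncalled genotype


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for diploid individuals from two populations.

    Attributes
    ----------
    chrom, pos, ref, alt
        Per-site arrays; ``pos`` is 1-based and strictly increasing within a
        chromosome/scaffold.
    dosages
        ``(n_sites, n_samples)`` int8 array of alternate-allele counts in
        {0, 1, 2}, with :data:`MISSING` (-1) for uncalled genotypes.
    samples
        Sample names, column order of ``dosages``.
    pop_labels
        Population label per sample (exactly two distinct labels).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list[str]
    pop_labels: np.ndarray
    populations: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (sites x samples)")
        if self.dosages.shape[0] != len(self.pos):
            raise ValueError("site annotation / dosage row mismatch")
        if self.dosages.shape[1] != len(self.samples):
            raise ValueError("sample list / dosage column mismatch")
        pops = list(dict.fromkeys(self.pop_labels))
        if len(pops) != 2:
            raise ValueError(f"exactly two population labels required, got {pops}")
        self.populations = (pops[0], pops[1])
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def pop_indices(self, population: str) -> np.ndarray:
        """Column indices of the samples belonging to ``population``."""
        idx = np.flatnonzero(self.pop_labels == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def allele_counts(self, population: str | None = None):
        """Per-site ``(alt_count, called_allele_count)`` over non-missing genotypes."""
        d = self.dosages if population is None else self.dosages[:, self.pop_indices(population)]
        called = d >= 0
        alt = np.where(called, d, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosages=self.dosages[index],
            samples=list(self.samples),
            pop_labels=self.pop_labels,
        )

    def sites_frame(self) -> pd.DataFrame:
        """Site annotation as a DataFrame (chrom, pos, ref, alt)."""
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )
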