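"""Two-population joint site frequency spectra: build, fold, project, I/O.

The joint SFS is an ``(n1+1, n2+1)`` array whose entry ``(i, j)`` counts
SNPs with alternate-allele count ``i`` in population 1 and ``j`` in
population 2.  Lacking an outgroup, analyses use the *folded* spectrum:
entries whose total allele count exceeds ``(n1+n2)/2`` are added onto their
complement ``(n1-i, n2-j)`` and masked; entries exactly on the fold axis are
combined once with their complement, keeping the lexicographically smaller
member.  Spectra are serialised in the plain-text ``.fs`` format used by
diffusion-based SFS inference tools (dimension/fold header line, flattened
entries, mask line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = ["JointSFS", "joint_sfs"]


class JointSFS:
    """A (possibly folded) two-population joint site frequency spectrum.

    Parameters
    ----------
    data
        ``(n1+1, n2+1)`` non-negative array of counts or expectations.
    folded
        Whether allele polarity has been collapsed.
    mask
        Boolean array, ``True`` for entries carrying no likelihood weight.
        The fixed corners ``(0, 0)`` and ``(n1, n2)`` are always masked.
    """

    def __init__(
        self,
        data: np.ndarray,
        folded: bool = False,
        mask: np.ndarray | None = None,
    ) -> None:
        self.data = np.array(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("joint SFS must be 2-D")
        if np.any(self.data < 0):
            raise ValueError("SFS entries must be >= 0")
        self.folded = bool(folded)
        self.n1 = self.data.shape[0] - 1
        self.n2 = self.data.shape[1] - 1
        if mask is None:
            mask = np.zeros(self.data.shape, dtype=bool)
            if folded:
                tot = np.add.outer(np.arange(self.n1 + 1), np.arange(self.n2 + 1))
                mask |= 2 * tot > self.n1 + self.n2
                mask |= self._fold_axis_redundant()
        else:
            mask = np.array(mask, dtype=bool)
            if mask.shape != self.data.shape:
                raise ValueError("mask shape mismatch")
        mask[0, 0] = True
        mask[self.n1, self.n2] = True
        self.mask = mask

    def _fold_axis_redundant(self) -> np.ndarray:
        """Mask for the redundant member of each fold-axis complement pair."""
        n1, n2 = self.n1, self.n2
        red = np.zeros((n1 + 1, n2 + 1), dtype=bool)
        if (n1 + n2) % 2:
            return red
        half = (n1 + n2) // 2
        for i in range(n1 + 1):
            j = half - i
            if 0 <= j <= n2:
                ci, cj = n1 - i, n2 - j
                if (ci, cj) > (i, j):  # keep the lexicographically smaller
                    red[ci, cj] = True
        return red

    # ------------------------------------------------------------------

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), self.folded, self.mask.copy())

    def total(self) -> float:
        """Sum over unmasked entries."""
        return float(self.data[~self.mask].sum())

    def unmasked_values(self) -> np.ndarray:
        return self.data[~self.mask]

    def fold(self) -> "JointSFS":
        """Collapse allele polarity; idempotent."""
        if self.folded:
            return self.copy()
        n1, n2 = self.n1, self.n2
        data = self.data
        rev = data[::-1, ::-1]
        tot = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
        minor = 2 * tot < n1 + n2
        major = 2 * tot > n1 + n2
        axis = 2 * tot == n1 + n2
        red = self._fold_axis_redundant()
        vals = np.zeros_like(data)
        vals[minor] = data[minor] + rev[minor]
        kept = axis & ~red
        for i, j in zip(*np.nonzero(kept)):
            ci, cj = n1 - i, n2 - j
            if (ci, cj) != (i, j):
                vals[i, j] = data[i, j] + data[ci, cj]
            else:  # self-complementary centre cell
                vals[i, j] = data[i, j]
        mask = major | red
        mask[0, 0] = True
        mask[n1, n2] = True
        return JointSFS(vals, folded=True, mask=mask)

    def project(self, m1: int, m2: int) -> "JointSFS":
        """Hypergeometric projection down to sample sizes ``(m1, m2)``.

        Each entry's mass is redistributed by the product of the
        per-population probabilities of observing ``k`` of ``i`` alternate
        alleles in a draw of ``m`` from ``n`` genomes.  Total mass is
        conserved before corner masking.  A folded spectrum is projected on
        its kept entries and refolded, which coincides with projecting any
        unfolded preimage and folding (the projection kernel maps complements
        to complements).
        """
        if not (1 <= m1 <= self.n1 and 1 <= m2 <= self.n2):
            raise ValueError("projection sizes must satisfy 1 <= m <= n")
        if m1 == self.n1 and m2 == self.n2:
            return self.copy()
        P1 = _projection_matrix(self.n1, m1)
        P2 = _projection_matrix(self.n2, m2)
        if not self.folded:
            new = P1.T @ self.data @ P2
            return JointSFS(new, folded=False)
        work = np.where(self.mask, 0.0, self.data)
        new = P1.T @ work @ P2
        return JointSFS(new, folded=False).fold()

    # ------------------------------------------------------------------

    def to_file(self, path: str | Path, comment: str | None = None) -> None:
        """Write in the plain-text ``.fs`` spectrum format."""
        lines = []
        if comment:
            lines.append(f"# {comment}")
        fold = "folded" if self.folded else "unfolded"
        lines.append(f"{self.n1 + 1} {self.n2 + 1} {fold}")
        lines.append(" ".join(repr(float(v)) for v in self.data.ravel()))
        lines.append(" ".join("1" if m else "0" for m in self.mask.ravel()))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "JointSFS":
        lines = [
            ln
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        header = lines[0].split()
        d1, d2 = int(header[0]), int(header[1])
        folded = len(header) > 2 and header[2] == "folded"
        data = np.array(lines[1].split(), dtype=float).reshape(d1, d2)
        mask = None
        if len(lines) > 2:
            mask = np.array(lines[2].split(), dtype=int).astype(bool).reshape(d1, d2)
        return cls(data, folded=folded, mask=mask)

    def __repr__(self) -> str:  # pragma: no cover
        state = "folded" if self.folded else "unfolded"
        return f"<JointSFS {self.n1+1}x{self.n2+1} {state} total={self.total():.6g}>"


def fold_stack(stack: np.ndarray) -> np.ndarray:
    """Fold a stack of unfolded spectra (batch axis first) in one pass.

    Applies the same convention as :meth:`JointSFS.fold` to every layer;
    returns the folded stack with masked cells zeroed.
    """
    stack = np.asarray(stack, dtype=float)
    n1 = stack.shape[1] - 1
    n2 = stack.shape[2] - 1
    rev = stack[:, ::-1, ::-1]
    tot = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    minor = 2 * tot < n1 + n2
    vals = np.where(minor[None, :, :], stack + rev, 0.0)
    if (n1 + n2) % 2 == 0:
        half = (n1 + n2) // 2
        for i in range(n1 + 1):
            j = half - i
            if 0 <= j <= n2:
                ci, cj = n1 - i, n2 - j
                if (ci, cj) > (i, j):
                    vals[:, i, j] = stack[:, i, j] + stack[:, ci, cj]
                elif (ci, cj) == (i, j):
                    vals[:, i, j] = stack[:, i, j]
    vals[:, 0, 0] = 0.0
    vals[:, n1, n2] = 0.0
    return vals


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """``(n+1, m+1)`` matrix of hypergeometric probabilities P(k of m | i of n)."""
    i = np.arange(n + 1)[:, None]
    k = np.arange(m + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            _log_comb(i, k)
            + _log_comb(n - i, m - k)
            - _log_comb(np.full_like(i, n), np.full_like(k, m))
        )
    P = np.where(np.isfinite(logp), np.exp(logp), 0.0)
    # zero out impossible draws (k > i or m - k > n - i)
    P[(k > i) | ((m - k) > (n - i))] = 0.0
    return P


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def joint_sfs(
    gm: GenotypeMatrix,
    site_mask: np.ndarray | None = None,
    project_to: tuple[int, int] | None = None,
) -> JointSFS:
    """Build the unfolded (alt-allele polarised) joint SFS from genotypes.

    Sites with complete genotypes are counted directly.  When ``project_to``
    is given, every site is projected hypergeometrically from its available
    (non-missing) allele counts down to ``(m1, m2)``; sites with fewer called
    alleles than the target are dropped.  Without ``project_to``, sites with
    any missing genotype are dropped.  ``site_mask`` restricts the input to a
    boolean selection of sites (e.g. a non-coding mask).
    """
    p1, p2 = gm.populations
    alt1, n1c = gm.allele_counts(p1)
    alt2, n2c = gm.allele_counts(p2)
    n1 = 2 * len(gm.pop_indices(p1))
    n2 = 2 * len(gm.pop_indices(p2))
    keep = np.ones(gm.n_sites, dtype=bool)
    if site_mask is not None:
        keep &= np.asarray(site_mask, dtype=bool)

    if project_to is None:
        m1, m2 = n1, n2
        usable = keep & (n1c == n1) & (n2c == n2)
        data = np.zeros((m1 + 1, m2 + 1))
        np.add.at(data, (alt1[usable], alt2[usable]), 1.0)
        return JointSFS(data, folded=False)

    m1, m2 = project_to
    if not (1 <= m1 <= n1 and 1 <= m2 <= n2):
        raise ValueError("project_to sizes must satisfy 1 <= m <= n")
    usable = keep & (n1c >= m1) & (n2c >= m2)
    data = np.zeros((m1 + 1, m2 + 1))
    # group sites by available allele counts so each group is one matrix op
    for a1 in np.unique(n1c[usable]):
        for a2 in np.unique(n2c[usable & (n1c == a1)]):
            sel = usable & (n1c == a1) & (n2c == a2)
            sub = np.zeros((a1 + 1, a2 + 1))
            np.add.at(sub, (alt1[sel], alt2[sel]), 1.0)
            P1 = _projection_matrix(int(a1), m1)
            P2 = _projection_matrix(int(a2), m2)
            data += P1.T @ sub @ P2
    return JointSFS(data, folded=False)
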