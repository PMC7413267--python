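"""Structured-coalescent simulator for a two-population contact history.

Generates genealogies under the secondary-contact model ladder
(:class:`~divflow.models.DemographicModel`), drops infinite-sites mutations
on them, and emits synthetic diploid VCF datasets with a truth record.  The
same backward-in-time process, run as a fast branch-length accumulator,
provides Monte Carlo expected joint site frequency spectra for demographic
fitting (:func:`expected_sfs_mc`).

Conventions: time in units of ``2 * N_ref`` generations; a pair of lineages
in a deme of relative size ``nu`` coalesces at rate ``1/nu``; a lineage in
deme *i* migrates backward to deme *j* at rate ``M_ij``; mutations arrive on
a branch of length ``L`` as Poisson with mean ``(theta / 2) * L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import _panmictic_branch_sfs, branch_length_sfs
from .genotypes import MISSING, GenotypeMatrix
from .models import DemographicModel, SampleConfig
from .sfs import JointSFS

__all__ = [
    "Genealogy",
    "TruthRecord",
    "simulate_genealogy",
    "sprinkle_mutations",
    "simulate_dataset",
    "expected_sfs_mc",
]


@dataclass
class Genealogy:
    """A coalescent tree over ``n1 + n2`` sampled haploid genomes.

    Leaves are nodes ``0 .. n1+n2-1``: the first ``n1`` were sampled from
    population 1, the rest from population 2.  ``parent[root] == -1``;
    ``time`` is the node age in units of 2*N_ref generations.
    """

    parent: np.ndarray
    time: np.ndarray
    n1: int
    n2: int

    @property
    def n_leaves(self) -> int:
        return self.n1 + self.n2

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node counts of descendant leaves in each population.

        Nodes are created in increasing time order, so a single forward pass
        over ``parent`` accumulates counts bottom-up.
        """
        c1 = np.zeros(self.n_nodes, dtype=np.int64)
        c2 = np.zeros(self.n_nodes, dtype=np.int64)
        c1[: self.n1] = 1
        c2[self.n1 : self.n_leaves] = 1
        for node in range(self.n_nodes - 1):
            p = self.parent[node]
            if p >= 0:
                c1[p] += c1[node]
                c2[p] += c2[node]
        return c1, c2

    def descendant_leaves(self, node: int) -> np.ndarray:
        """Indices of leaves below ``node`` (a leaf is below itself)."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(v)
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            stack.extend(children[v])
        return np.array(sorted(out), dtype=np.int64)


def _epochs(model: DemographicModel | None):
    """(t_sc, t_div, contact sizes+rates, isolation sizes) for the simulator."""
    if model is None:  # single panmictic deme of size 1
        return 0.0, 0.0, (1.0, 1.0, 0.0, 0.0), (1.0, 1.0)
    s1_c, s2_c = model.contact_sizes
    return (
        float(model.t_sc),
        float(model.t_div),
        (s1_c, s2_c, float(model.m12), float(model.m21)),
        (float(model.nu1), float(model.nu2)),
    )


def simulate_genealogy(
    model: DemographicModel | None,
    samples: SampleConfig,
    rng: np.random.Generator,
) -> Genealogy:
    """Draw one genealogy from the structured coalescent.

    Backward in time: during the contact epoch each pair of lineages in
    deme *k* coalesces at rate ``1/nu_k`` and each lineage in deme *i* hops
    to deme *j* at rate ``M_ij``; during the isolation epoch migration stops;
    past the divergence time all lineages join a single ancestral deme of
    relative size 1.  ``model=None`` simulates a single panmictic deme of
    size 1 (used for analytic checks).
    """
    t_sc, t_div, (s1_c, s2_c, m12, m21), (s1_i, s2_i) = _epochs(model)
    n1, n2 = samples.n1, samples.n2
    n = n1 + n2

    max_nodes = 2 * n - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    time = np.zeros(max_nodes)
    next_node = n

    act = list(range(n))
    pop = [0] * n1 + [1] * n2
    if model is None:
        pop = [0] * n
    t = 0.0
    phase = 0 if t_sc > 0 else (1 if t_div > 0 else 2)
    if model is None:
        phase = 2

    while len(act) > 1:
        if phase == 0:
            s1, s2, mm12, mm21, boundary = s1_c, s2_c, m12, m21, t_sc
        elif phase == 1:
            s1, s2, mm12, mm21, boundary = s1_i, s2_i, 0.0, 0.0, t_div
        else:
            s1, s2, mm12, mm21, boundary = 1.0, 1.0, 0.0, 0.0, math.inf

        k1 = sum(1 for a in act if pop[a] == 0)
        k2 = len(act) - k1
        cr1 = 0.5 * k1 * (k1 - 1) / s1
        cr2 = 0.5 * k2 * (k2 - 1) / s2
        mr1 = k1 * mm12
        mr2 = k2 * mm21
        R = cr1 + cr2 + mr1 + mr2
        if not math.isfinite(R) or R < 0:
            raise ValueError("non-finite or negative total event rate")

        w = rng.exponential(1.0 / R) if R > 0 else math.inf
        if t + w >= boundary:
            t = boundary
            phase += 1
            if phase == 2:
                for a in act:
                    pop[a] = 0
            continue
        t += w

        u = rng.random() * R
        if u < cr1 + cr2:
            deme = 0 if u < cr1 else 1
            members = [a for a in act if pop[a] == deme]
            ia, ib = rng.choice(len(members), size=2, replace=False)
            a, b = members[ia], members[ib]
            node = next_node
            next_node += 1
            parent[a] = node
            parent[b] = node
            time[node] = t
            pop_new = deme
            act.remove(a)
            act.remove(b)
            act.append(node)
            pop_arr_extend = pop + [0] * (node + 1 - len(pop))
            pop = pop_arr_extend
            pop[node] = pop_new
        else:
            src = 0 if u < cr1 + cr2 + mr1 else 1
            members = [a for a in act if pop[a] == src]
            a = members[int(rng.integers(len(members)))]
            pop[a] = 1 - src

    return Genealogy(parent=parent[:next_node], time=time[:next_node], n1=n1, n2=n2)


def sprinkle_mutations(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Drop infinite-sites mutations on a genealogy.

    Each branch receives a Poisson(``theta/2 *`` length) number of mutations;
    every mutation defines one biallelic site whose derived allele is carried
    by exactly the branch's descendant leaves.  Returns one leaf-index array
    per site.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0:
        return []
    bl = tree.branch_lengths()
    n_muts = rng.poisson(0.5 * theta * bl)
    sites: list[np.ndarray] = []
    for node in np.flatnonzero(n_muts):
        leaves = tree.descendant_leaves(int(node))
        sites.extend([leaves] * int(n_muts[node]))
    return sites


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to regenerate a simulated dataset bit-identically."""

    model: DemographicModel
    samples: SampleConfig
    theta_per_locus: float
    n_loci: int
    locus_length: int
    seed: int

    def to_file(self, path: str | Path) -> None:
        m = self.model
        lines = [
            f"scenario={m.scenario.value}",
            f"nu1={m.nu1!r}",
            f"nu2={m.nu2!r}",
            f"t_iso={m.t_iso!r}",
            f"t_sc={m.t_sc!r}",
            f"m12={m.m12!r}",
            f"m21={m.m21!r}",
            f"nu1_0={m.nu1_0!r}",
            f"nu2_0={m.nu2_0!r}",
            f"n1={self.samples.n1}",
            f"n2={self.samples.n2}",
            f"theta_per_locus={self.theta_per_locus!r}",
            f"n_loci={self.n_loci}",
            f"locus_length={self.locus_length}",
            f"seed={self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "TruthRecord":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                k, _, v = line.partition("=")
                kv[k] = v
        opt = lambda v: None if v == "None" else float(v)
        model = DemographicModel(
            scenario=kv["scenario"],
            nu1=float(kv["nu1"]),
            nu2=float(kv["nu2"]),
            t_iso=float(kv["t_iso"]),
            t_sc=float(kv["t_sc"]),
            m12=float(kv["m12"]),
            m21=float(kv["m21"]),
            nu1_0=opt(kv["nu1_0"]),
            nu2_0=opt(kv["nu2_0"]),
        )
        return cls(
            model=model,
            samples=SampleConfig(int(kv["n1"]), int(kv["n2"])),
            theta_per_locus=float(kv["theta_per_locus"]),
            n_loci=int(kv["n_loci"]),
            locus_length=int(kv["locus_length"]),
            seed=int(kv["seed"]),
        )


def _locus_rng(seed: int, locus: int) -> np.random.Generator:
    # per-locus stream keyed on (seed, locus): earlier loci are unchanged
    # when n_loci grows
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, locus))))


def simulate_dataset(
    model: DemographicModel | None,
    samples: SampleConfig,
    n_loci: int,
    theta_per_locus: float,
    seed: int,
    locus_length: int = 10_000,
    out_vcf: str | Path | None = None,
    population_names: tuple[str, str] = ("pop1", "pop2"),
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate independent loci and package them as a diploid SNP dataset.

    Haploid leaves ``2k`` and ``2k+1`` of a population form diploid
    individual ``k``, so both haploid sample sizes must be even.  Loci are
    emitted as separate contigs ``locus_0000, ...`` with 1-based positions
    drawn uniformly (without replacement) within the locus.  When ``out_vcf``
    is given, a VCF v4.2 file plus a ``<out_vcf>.truth.txt`` record are
    written; the same (matrix, truth) pair is always returned.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if samples.n1 % 2 or samples.n2 % 2:
        raise ValueError("haploid sample sizes must be even for diploid pairing")
    n_dip1, n_dip2 = samples.n1 // 2, samples.n2 // 2
    sample_names = [f"{population_names[0]}_{k}" for k in range(n_dip1)] + [
        f"{population_names[1]}_{k}" for k in range(n_dip2)
    ]
    pop_labels = [population_names[0]] * n_dip1 + [population_names[1]] * n_dip2

    chroms, positions, dos_rows = [], [], []
    contig_names = []
    width = max(4, len(str(n_loci - 1)))
    for locus in range(n_loci):
        rng = _locus_rng(seed, locus)
        tree = simulate_genealogy(model, samples, rng)
        sites = sprinkle_mutations(tree, theta_per_locus, rng)
        name = f"locus_{locus:0{width}d}"
        contig_names.append(name)
        if not sites:
            continue
        if len(sites) > locus_length:
            raise ValueError(
                f"{len(sites)} mutations exceed locus length {locus_length}; "
                "increase locus_length or decrease theta"
            )
        pos = np.sort(rng.choice(locus_length, size=len(sites), replace=False)) + 1
        # sites arrive in branch order; tie positions to sorted order so the
        # VCF is position-sorted per contig
        for p, leaves in zip(pos, sites):
            hap = np.zeros(samples.n_total, dtype=np.int8)
            hap[leaves] = 1
            dos = hap[0::2] + hap[1::2]
            chroms.append(name)
            positions.append(int(p))
            dos_rows.append(dos)

    n_sites = len(positions)
    dosages = (
        np.array(dos_rows, dtype=np.int8)
        if n_sites
        else np.zeros((0, n_dip1 + n_dip2), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosages=dosages,
        samples=sample_names,
        pop_labels=np.array(pop_labels, dtype=object),
    )
    truth = TruthRecord(
        model=model,
        samples=samples,
        theta_per_locus=theta_per_locus,
        n_loci=n_loci,
        locus_length=locus_length,
        seed=seed,
    )
    if out_vcf is not None:
        write_vcf(gm, out_vcf, contigs={c: locus_length for c in contig_names})
        truth.to_file(str(out_vcf) + ".truth.txt")
    return gm, truth


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF v4.2 (GT only) for a genotype matrix."""
    if contigs is None:
        contigs = {}
        for c, p in zip(gm.chrom, gm.pos):
            contigs[str(c)] = max(contigs.get(str(c), 0), int(p))
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(gt_strings[int(d)] for d in gm.dosages[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def expected_sfs_mc(
    model: DemographicModel | None,
    samples: SampleConfig,
    n_reps: int,
    seed: int,
) -> JointSFS:
    """Monte Carlo expected unfolded joint SFS per unit theta.

    Entry ``(i, j)`` is half the mean total branch length subtending exactly
    ``i`` population-1 and ``j`` population-2 samples over ``n_reps``
    structured-coalescent replicates, so multiplying by theta gives expected
    SNP counts.  The fixed corners ``(0,0)`` and ``(n1,n2)`` are masked.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if model is None:
        # panmictic single deme: divergence at time 0 merges everything
        F = _panmictic_branch_sfs(samples.n1, samples.n2, n_reps, seed)
    else:
        F = branch_length_sfs(samples.n1, samples.n2, model, n_reps, seed)
    return JointSFS(F, folded=False)
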