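# Methods

`divflow` analyses divergence with gene flow between two closely related
taxa from biallelic SNP data: it filters variants, scans the genome in
windows, builds the folded joint site frequency spectrum (SFS), and fits a
ladder of two-population demographic models by composite likelihood. This
note records the models, estimators, numerical choices, and the design
decisions made where the design was genuinely open.

## The demographic model ladder

All models describe two populations that split from a common ancestor and
are parameterised in standard coalescent (diffusion) units: time in
`2·N_ref` generations, sizes as ratios `nu = N / N_ref`, migration as
`M_ij = 2·N_ref·m_ij`, where `m_ij` is the per-generation fraction of
population *i* replaced by migrants from population *j* (forward in time).
`N_ref` is fixed to the ancestral population size, i.e. `nu_anc = 1`; this
anchors the overall scale, which the sample SFS alone constrains only
weakly (see *Identifiability*, below).

| scenario | free parameters | history |
|---|---|---|
| `SI` | `nu1, nu2, t_iso` | split, then strict isolation |
| `IM_SYM` | `nu1, nu2, t_sc, m` | split with continuous symmetric migration |
| `SC_SYM` | `nu1, nu2, t_iso, t_sc, m` | isolation, then symmetric secondary contact |
| `SC_ASYM` | `nu1, nu2, t_iso, t_sc, m12, m21` | isolation, then asymmetric contact |
| `SC_ASYM_GROWTH1/2` | + `nu1_0` or `nu2_0` | + a size step in one population at contact |

Growth is modelled as a two-size step change at the onset of contact (the
contact-epoch size differs from the isolation-epoch size), not as
exponential growth; the choice is a convention, adequate for ranking the
scenarios.

## Expected SFS: a Rao-Blackwellised coalescent engine

Expected joint spectra come from simulating the structured coalescent
backward in time and accumulating, for every branch, the length it
contributes to the class `(i, j)` = (descendants sampled from population 1,
from population 2). Entry `(i, j)` of the expected unfolded SFS per unit
`theta` is half the mean accumulated length, so multiplying by `theta`
gives expected SNP counts under the infinite-sites model.

A naive event-by-event simulation is too noisy and too slow to sit inside
an optimiser, so each epoch is treated with the cheapest exact scheme
available:

- **Contact epoch.** Migration events never change a branch's descendant
  class, so individual hops are not simulated. Lineage locations form
  independent two-state Markov chains; coalescence candidate times are
  proposed by thinning with the global bound `C(k,2)·max(1/s1, 1/s2)`, and
  lineage locations are advanced exactly (by the two-state transition
  probabilities) only at proposal times. This removes the cost blow-up at
  high migration rates.
- **Isolation epoch.** Each deme is a pure-death coalescent over a fixed
  horizon. The *merge pattern* is sampled (uniform pairs), but the *times*
  are integrated exactly: the expected time spent with `l` ancestors and
  the distribution of the number of survivors at the horizon are
  matrix-exponential functionals of the death chain, computed once per
  likelihood evaluation. A block alive from level `l_b` down to `l_d`
  credits its class with `sum E[T_l]` over that range.
- **Ancestral phase.** For `k` exchangeable lineages in a panmictic deme,
  the expected total length of branches subtending a given subset of size
  `i` is `2 / (i·C(k,i))`; a subset-sum dynamic program maps this onto
  descendant classes exactly. Above `k = 10` entering lineages the phase is
  first reduced by direct Gillespie steps, because the DP cost grows
  with `k`.

For a single panmictic deme the engine is exact (the closed form applies
immediately), which the analytic tests exploit: the one-deme spectrum
equals `theta/i` to machine precision. For structured histories the engine
is unbiased Monte Carlo with strongly reduced variance; it is validated
against an independent simulator (msprime branch-mode allele frequency
spectra) on an asymmetric secondary-contact history.

The dataset simulator (`simgen.simulate_dataset`) uses a separate plain
Python realisation of the same process that retains full tree topology,
drops Poisson(`theta/2 ·` branch length) infinite-sites mutations on it,
pairs consecutive haploid genomes into diploids, and writes VCF v4.2 plus a
truth record sufficient to regenerate the dataset bit-identically.
Per-locus RNG streams are keyed on `(seed, locus index)`, so enlarging a
dataset never changes earlier loci. The two engines are cross-checked
against each other (expected vs. empirical SFS) and against closed forms.

## Composite likelihood and optimisation

The fit maximises the Poisson composite log-likelihood over unmasked SFS
entries with the analytically optimal scaling
`theta_hat = sum(data)/sum(model)`; multiplying the model spectrum by any
constant leaves the objective unchanged. Model cells are floored at 1e-8 so
a model-zero/data-positive cell yields a large finite penalty rather than
`-inf`.

Within one fit every expected-SFS evaluation reuses a single simulation
seed per stage (common random numbers), making the objective deterministic
and the whole fit reproducible from its seed.

**Monte Carlo bias correction.** Because the expected spectrum is itself an
estimate, plugging it into the Poisson likelihood biases comparisons: to
leading order `E[d·ln m̂] = d·ln m − d·Var(m̂)/(2m²)`, a penalty that is
*larger for long histories* (deeper trees are estimated with more
variance), so a naive Monte Carlo likelihood systematically favours
spurious short-tree, high-migration models. The engine therefore returns
per-cell variances of the estimate (from 16 replicate batches, formed
after folding so that the covariance of folded-together cells is handled
exactly), and the likelihood adds back `Σ d·Var(m̂)/(2m̂²)` (capped at
relative variance 1). This removes the leading-order tilt and makes
model comparisons at moderate replication agree with near-exact ones.

**Search strategy.** The likelihood surface has an approximate scaling
invariance `(nu, T) -> (c·nu, c·T), M -> M/c` — broken only by the fixed
ancestral size — producing a long curved valley whose tilt is a few tens
of log-likelihood units over large displacements; plain multistart
Nelder-Mead cannot traverse it. The fit therefore runs:

1. *Iterated conditional grid refinement* (global): parameters are grouped
   into natural pairs — sizes `(nu1, nu2)`, epochs `(t_iso, t_sc)`,
   migration `(m12, m21)` — and each pass scans a 9×9 log-grid over each
   pair with the others held fixed, jumps to the best cell, then
   line-searches along the scaling direction. Spans halve each pass
   (4 passes, 4,000 replicates per evaluation).
2. *Polish*: Nelder-Mead in log space with reflecting bounds from the grid
   optimum (15,000 replicates).
3. *Valley refinement*: two rounds, with shrinking spans and an early
   stop once a round gains fewer than 12 log-likelihood units, of (a) a
   2-D scan over scaling `c` × a residual on the dominant time parameter —
   the plane in which the valley floor curves, (b) a local re-scan of the
   epoch pair, and (c) a short Nelder-Mead confined to a ±0.6 log-unit box
   (so high-replication evaluations never wander into expensive parameter
   corners), all at 51,000 replicates with the bias-corrected objective;
   the refined point is kept only if it is no worse at 120,000 replicates.

A practical consequence of the scaling valley is worth noting: all
*converted* quantities (`N_i = nu_i·theta_hat/(4 mu L_eff)`, times in
years, per-generation migration fractions) are invariant along the exact
valley direction, because `theta_hat` scales inversely with `c`. Residual
uncertainty in the overall coalescent-unit scale therefore propagates only
weakly into the absolute estimates, which is what the recovery experiments
measure.

Default optimisation bounds encode the secondary-contact scenario itself:
relative sizes in `[0.05, 20]`, an isolation epoch in `[0.2, 20]` (the
scenario presumes divergence dominates contact), a contact epoch in
`[0.002, 1.5]`, and `M` in `[0.2, 40]`.

**Model comparison** ranks fits by composite log-likelihood, breaking ties
toward fewer parameters. The absolute likelihood values are composite (SNPs
treated as independent), so differences overstate evidence on linked data;
only the ordering is interpreted.

**Unit conversion** uses `N_ref = theta_hat/(4·mu·L_eff)`,
`T_years = T·2·N_ref·g`, `m_ij = M_ij/(2·N_ref)`. `mu`, the generation
time `g`, and the effective (callable) sequence length `L_eff` behind the
SFS are required user inputs; for synthetic data `L_eff` is known exactly.

**Bootstrap.** Confidence intervals resample `n_snps` SNPs i.i.d. with
replacement (a multinomial resample of the spectrum), refit from the MLE
as single start, and report percentile intervals. SNP-level resampling
understates LD-driven variance on real genomes; the iteration count (10 by
default) matches the analysis workflow this package replicates rather than
bootstrap best practice.

## Variant filters

The filter chain is fixed as HWE -> MAF -> LD and reported per stage.

- **Heterozygote-excess test**: one-sided exact conditional test using the
  Levene–Haldane distribution of the heterozygote count given allele
  counts; plain tail sum (no mid-p), which is conservative. Populations are
  pooled, since the filter targets collapsed paralogous alignments that
  inflate heterozygosity in every population. Default `p < 0.01` removes
  the site.
- **Minor allele frequency**: pooled across populations, computed over
  non-missing alleles; default threshold 0.05.
- **LD pruning**: within sliding windows of 50 markers (step 5, never
  spanning scaffolds), pairs are visited in position order and the
  later-positioned member of any pair with `r² > 0.5` (squared Pearson
  correlation of dosages over pairwise-complete individuals) is removed.
  A single pass over sliding windows is not a strict fixed point — markers
  that become window-neighbours only after intervening removals are not
  re-checked — matching common single-pass practice; with one window
  covering all markers the result is idempotent.

## Window statistics

Statistics are computed in non-overlapping windows (default 200 kb) on the
full SNP set (the filters above serve ordination-style analyses, not the
landscape):

- `pi` (per population): sum over genotyped SNPs of the unbiased per-site
  heterozygosity `2·c_ref·c_alt/(n(n−1))`, divided by the number of
  accessible sites. With SNP-only input the accessible-site count defaults
  to the number of matrix sites in the window; when invariant-site counts
  are known they can be supplied per window. Ratio statistics (FST) are
  unaffected by this denominator.
- `dxy`: mean of `p1(1−p2) + p2(1−p1)` over usable sites, same denominator
  convention.
- `FST`: Weir & Cockerham (1984) variance components, "weighted"
  ratio-of-sums form `sum(a)/sum(a+b+c)` over polymorphic sites; slightly
  negative values are legitimate estimator noise. A Hudson-form estimator
  is provided as a cross-check.
- **Tajima's D** (per population): `(pi_total − S/a1)/sqrt(e1·S +
  e2·S(S−1))` with the 1989 constants evaluated at the population's nominal
  haploid size; undefined when `S = 0` or `n < 3`. Missingness slightly
  perturbs the constants' nominal `n`; at the high call rates this package
  targets the effect is negligible.

Windows with fewer than 10 usable SNPs report all statistics as missing
(NaN, never zero) to avoid ratio instability. Summaries include Spearman
rank correlations between per-window statistics, the census of windows with
FST strictly above a threshold (default 0.25), and a pooled-variance
two-sample t-test of window FST between the Z chromosome and autosomes.
Scaffold windows can be lifted onto pseudo-chromosomes via a placement
table (offset shift; minus-strand scaffolds reflect within their span).

## Joint SFS

The unfolded spectrum counts alternate alleles per population. Without an
outgroup the analyses use the folded spectrum: entries with total count
above `(n1+n2)/2` fold onto their complement `(n1−i, n2−j)`; entries
exactly on the fold axis are combined once with their complement, keeping
the lexicographically smaller member and masking the other. Projection to
smaller sample sizes is the standard hypergeometric redistribution; it
commutes with folding (the projection kernel maps complements to
complements), and sites with missing genotypes are absorbed by projecting
each site from its available allele counts (sites below the target are
dropped). Spectra serialise to the plain-text `.fs` format (dimension/fold
header, flattened entries, mask line).

## The synthetic benchmark (`divflow.benchmark`)

Real re-sequencing data for the two goose taxa is not shipped; the
package instead fixes the published point estimates as a generative
"reference history" and validates its machinery by simulation and
recovery:

- divergence 2.66 Myr, secondary contact 58,285 yr, post-split sizes
  102,508 (Taiga) and 62,855 (Tundra), `mu = 1e-9`, `g = 2 yr`,
  9 + 9 diploids;
- `N_ref` (ancestral size; not published) set to 80,000, between the two
  daughter sizes;
- migration rates (not published): `M12 = 12.75` into Taiga, `M21 = 4.25`
  into Tundra — the reported direction of predominant gene flow at a 3:1
  asymmetry, calibrated once so the model-implied genome-wide FST matches
  the published 0.033;
- `L_eff = 1.15e8` nucleotides, giving ≈ 5·10⁵ SNPs in the folded 19×19
  spectrum (`theta_total = 4·N_ref·mu·L_eff = 36,800`).

SFS data are drawn by Poisson-sampling the scaled expected spectrum (the
sampling model under which independent SNPs accrue; the expectation is
estimated with 250,000 coalescent replicates so generator-side noise is
small next to the Poisson sampling); genotype datasets are simulated as
independent 5-kb loci. The recovery experiment fits the `SC_ASYM` model
to five independent spectra projected to 8 + 8 haploids and reports median
converted estimates; a fit whose deficit from the saturated likelihood
exceeds 1,200 units (an order of magnitude above typical) is treated as a
failed search and retried once from a fresh optimiser seed (at most one
retry per experiment, to bound the cost); the ordering experiment fits `SI`, `IM_SYM` and
`SC_ASYM` to one spectrum (with lighter fit settings — the ranking gaps
span orders of magnitude); the FST experiment computes genome-wide
Weir–Cockerham FST on 2,500 simulated loci. Problem sizes (projection,
five replicates, the per-stage Monte Carlo replication above, 2,500 loci)
are the package's validation scale; they keep a full run in the tens of
minutes on one core.

What the generator does *not* emulate: within-locus recombination and
linkage (loci are independent, SNPs within a locus share one genealogy),
sequencing and genotyping error, missing data patterns, selection (so no
FST peaks or islands of differentiation), and chromosome-scale structure.
Passing recovery tests therefore demonstrates correctness of the
estimators and the inference machinery under the model's own assumptions,
not robustness to the violations real data exhibit.

## Numerical details and edge cases

- Monomorphic sites land in the masked `(0,0)`/`(n1,n2)` corners and carry
  no likelihood weight; folding conserves unmasked totals.
- Undefined statistics are NaN throughout, never 0.
- The death-chain tables are computed by one augmented matrix exponential
  per deme per likelihood evaluation (exact and stable for the sample
  sizes involved, unlike the alternating-series ancestral-process
  formulas).
- Optimisation parameters are log-transformed; bounds are enforced by
  reflection (periodic folding of the log coordinates), which keeps
  Nelder-Mead steps meaningful at the boundary.
- Convergence: Nelder-Mead stops at `xatol 1e-3` / `fatol 0.05` in
  log-likelihood units or 250 evaluations; grid passes are fixed count.
- All user-facing randomness flows from a single integer seed through
  `numpy` `SeedSequence`-derived streams; every operation is bit
  reproducible given (parameters, seed).

## Known limitations

- Composite likelihood ignores linkage; likelihood differences are not
  chi-square calibrated, and bootstrap CIs inherit the SNP-independence
  assumption.
- The Monte Carlo expected SFS makes each fit stochastic-but-seeded; two
  fits with different seeds can differ within the Monte Carlo noise floor.
- The expected-SFS engine handles exactly two extant populations and step
  size changes; exponential growth and >2 populations are out of scope.
- The LD pruner is quadratic in window size; it targets the tens of
  thousands of markers per scaffold typical of pruned panels, not
  whole-genome marker sets at step 1.
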