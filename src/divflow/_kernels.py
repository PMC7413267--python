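"""Numba kernels for structured-coalescent branch-length accumulation.

The kernel estimates, for a two-population secondary-contact history, the
expected length of branches subtending exactly ``(i, j)`` sampled genomes
from populations 1 and 2.  Dividing the accumulated array by ``2 * n_reps``
yields the expected unfolded joint SFS per unit theta.

Monte Carlo variance is suppressed by integrating out every source of
randomness with a tractable conditional expectation (Rao-Blackwellisation);
only the parts that genuinely require simulation are simulated:

1. *Contact epoch* ``[0, t_sc)``: two demes exchanging migrants.  Because
   migration never changes a lineage's descendant counts, individual hops
   are never simulated: lineage demes form independent two-state Markov
   chains, sampled exactly at candidate coalescence times proposed by
   thinning with the bound ``C(k,2) * max(1/s1, 1/s2)``.
2. *Isolation epoch* ``[t_sc, t_div)``: two isolated demes.  The merge
   pattern (jump chain) of each deme's pure-death coalescent is sampled,
   but the times are not: the expected time spent with ``l`` ancestors
   within the epoch, ``E[T_l]``, and the distribution of the number of
   survivors at the epoch's end are exact matrix-exponential functionals of
   the death chain, precomputed once per evaluation and passed in as
   tables.  A block alive from level ``l_birth`` down to ``l_death``
   contributes ``sum_l E[T_l]`` over that range to its descendant-count
   class.
3. *Ancestral phase* ``[t_div, inf)``: one panmictic deme of size 1.  For
   ``k`` exchangeable lineages the expected length of branches subtending a
   given subset of size ``i`` is ``2 / (i * C(k, i))``; a subset-sum DP
   maps this onto descendant-count classes.  Above ``_RAO_BLACKWELL_KMAX``
   lineages the phase is first reduced by direct Gillespie steps (the DP
   cost grows with ``k``).

Time is in units of ``2 * N_ref`` generations, so a pair of lineages in a
deme of relative size ``nu`` coalesces at rate ``1 / nu``.
"""

import numpy as np
from numba import njit

# above this many lineages the ancestral phase keeps simulating events
# instead of switching to the closed form (the subset DP grows with k)
_RAO_BLACKWELL_KMAX = 10


def _death_chain_tables(n_max: int, nu: float, horizon: float):
    """Exact time-in-level and survivor tables for a pure-death coalescent.

    For a single deme of relative size ``nu`` observed for ``horizon`` time
    units, returns ``(A, S)`` with ``A[j, l] = E[time spent with l
    ancestors | j at entry]`` and ``S[j, l] = P(l ancestors at the horizon
    | j at entry)``, for ``1 <= l <= j <= n_max``.  Both come from one
    augmented matrix exponential of the chain's generator.
    """
    from scipy.linalg import expm

    m = n_max + 1
    Q = np.zeros((m, m))
    for l in range(2, m):
        lam = l * (l - 1) / (2.0 * nu)
        Q[l, l] = -lam
        Q[l, l - 1] = lam
    if horizon <= 0.0:
        return np.zeros((m, m)), np.eye(m)
    aug = np.zeros((2 * m, 2 * m))
    aug[:m, :m] = Q * horizon
    aug[:m, m:] = np.eye(m) * horizon
    E = expm(aug)
    S = E[:m, :m]
    A = E[:m, m:]
    return A, S


@njit(cache=False)
def _ancestral_closed_form(F, c1, c2, k, n1, n2, weight):
    """Exact expected branch classes for k lineages in a panmictic deme."""
    G = np.zeros((k + 1, n1 + 1, n2 + 1))
    G[0, 0, 0] = 1.0
    for l in range(k):
        a_l = c1[l]
        b_l = c2[l]
        for i in range(min(l + 1, k), 0, -1):
            for a in range(n1, a_l - 1, -1):
                for b in range(n2, b_l - 1, -1):
                    if G[i - 1, a - a_l, b - b_l] > 0.0:
                        G[i, a, b] += G[i - 1, a - a_l, b - b_l]
    comb = 1.0
    for i in range(1, k):
        comb = comb * (k - i + 1) / i
        w = weight * 2.0 / (i * comb)
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                if G[i, a, b] > 0.0:
                    F[a, b] += w * G[i, a, b]


@njit(cache=False)
def _isolation_phase_rb(F, c1, c2, deme, k, d, cumA, Scdf, sc1, sc2, sk, weight):
    """Rao-Blackwellised isolation epoch for one deme.

    ``c1/c2/deme`` describe all ``k`` live lineages; only those in deme
    ``d`` are processed.  Writes expected time-in-level contributions into
    ``F`` and the surviving blocks into ``sc1/sc2`` starting at index
    ``sk``; returns the new survivor count.  ``cumA[j, l]`` is the partial
    sum of expected level times ``sum_{l' >= l} E[T_l']`` for entry count
    ``j``; ``Scdf[j, :]`` the survivor-count CDF.
    """
    # gather this deme's blocks
    j = 0
    bc1 = np.empty(k, dtype=np.int32)
    bc2 = np.empty(k, dtype=np.int32)
    for i in range(k):
        if deme[i] == d:
            bc1[j] = c1[i]
            bc2[j] = c2[i]
            j += 1
    if j == 0:
        return sk
    # sample the survivor count from its exact distribution
    u = np.random.random()
    L = j
    for l in range(1, j + 1):
        if u <= Scdf[j, l]:
            L = l
            break
    if j == 1:
        F[bc1[0], bc2[0]] += weight * cumA[1, 1]
        sc1[sk] = bc1[0]
        sc2[sk] = bc2[0]
        return sk + 1
    # walk the uniform merge path from level j down to 1, crediting each
    # block with the expected time over the levels it is alive
    birth_level = np.empty(2 * j, dtype=np.int32)
    alive = np.empty(2 * j, dtype=np.int32)
    wc1 = np.empty(2 * j, dtype=np.int32)
    wc2 = np.empty(2 * j, dtype=np.int32)
    for b in range(j):
        wc1[b] = bc1[b]
        wc2[b] = bc2[b]
        birth_level[b] = j
        alive[b] = b
    n_blocks = j
    n_alive = j
    for l in range(j, 1, -1):
        if n_alive == L:
            for s in range(n_alive):
                sc1[sk + s] = wc1[alive[s]]
                sc2[sk + s] = wc2[alive[s]]
        a = int(np.random.random() * n_alive)
        b = int(np.random.random() * (n_alive - 1))
        if b >= a:
            b += 1
        ia = alive[a]
        ib = alive[b]
        # merged blocks die leaving level l
        F[wc1[ia], wc2[ia]] += weight * (cumA[j, l] - cumA[j, birth_level[ia] + 1])
        F[wc1[ib], wc2[ib]] += weight * (cumA[j, l] - cumA[j, birth_level[ib] + 1])
        wc1[n_blocks] = wc1[ia] + wc1[ib]
        wc2[n_blocks] = wc2[ia] + wc2[ib]
        birth_level[n_blocks] = l - 1
        # replace slot a with the new block, remove slot b
        alive[a] = n_blocks
        alive[b] = alive[n_alive - 1]
        n_blocks += 1
        n_alive -= 1
    # blocks alive at level 1 (i.e. the final block) accrue down to level 1
    for s in range(n_alive):
        ib = alive[s]
        F[wc1[ib], wc2[ib]] += weight * (cumA[j, 1] - cumA[j, birth_level[ib] + 1])
    if L == 1:
        sc1[sk] = wc1[alive[0]]
        sc2[sk] = wc2[alive[0]]
    return sk + L


@njit(cache=False)
def _accumulate_branch_lengths(
    n1, n2, t_sc, t_div, s1_c, s2_c, m12, m21,
    cumA1, Scdf1, cumA2, Scdf2, n_reps, n_paths, seed,
):  # pragma: no cover - exercised via expected_sfs_mc
    np.random.seed(seed)
    n = n1 + n2
    n_batches = 16 if n_reps >= 16 else 1
    Fb = np.zeros((n_batches, n1 + 1, n2 + 1))
    F = Fb[0]
    deme = np.empty(n, dtype=np.int8)
    c1 = np.empty(n, dtype=np.int32)
    c2 = np.empty(n, dtype=np.int32)
    birth = np.empty(n)
    sc1 = np.empty(n, dtype=np.int32)
    sc2 = np.empty(n, dtype=np.int32)
    pc1 = np.empty(n, dtype=np.int32)
    pc2 = np.empty(n, dtype=np.int32)
    pdeme = np.empty(n, dtype=np.int8)

    m_tot = m12 + m21
    pi1 = m21 / m_tot if m_tot > 0.0 else 1.0  # stationary P(deme 1)
    inv_max_c = max(1.0 / s1_c, 1.0 / s2_c)

    for _rep in range(n_reps):
        F = Fb[_rep * n_batches // n_reps]
        for i in range(n1):
            deme[i] = 0
            c1[i] = 1
            c2[i] = 0
            birth[i] = 0.0
        for i in range(n1, n):
            deme[i] = 1
            c1[i] = 0
            c2[i] = 1
            birth[i] = 0.0
        k = n
        t = 0.0

        # ---- contact epoch: thinned coalescence proposals ----
        if t_sc > 0.0:
            while k > 1:
                lam_bar = 0.5 * k * (k - 1) * inv_max_c
                w = -np.log(np.random.random()) / lam_bar
                crossed = t + w >= t_sc
                dt = (t_sc - t) if crossed else w
                if m_tot > 0.0:
                    decay = np.exp(-m_tot * dt)
                    for i in range(k):
                        if deme[i] == 0:
                            p_stay = pi1 + (1.0 - pi1) * decay
                        else:
                            p_stay = 1.0 - (pi1 - pi1 * decay)
                        if np.random.random() >= p_stay:
                            deme[i] = 1 - deme[i]
                if crossed:
                    t = t_sc
                    break
                t += w
                k1 = 0
                for i in range(k):
                    if deme[i] == 0:
                        k1 += 1
                k2 = k - k1
                lam1 = 0.5 * k1 * (k1 - 1) / s1_c
                lam2 = 0.5 * k2 * (k2 - 1) / s2_c
                if np.random.random() * lam_bar < lam1 + lam2:
                    d = 0 if np.random.random() * (lam1 + lam2) < lam1 else 1
                    kd = k1 if d == 0 else k2
                    a = int(np.random.random() * kd)
                    b = int(np.random.random() * (kd - 1))
                    if b >= a:
                        b += 1
                    ia = -1
                    ib = -1
                    seen = 0
                    for i in range(k):
                        if deme[i] == d:
                            if seen == a:
                                ia = i
                            if seen == b:
                                ib = i
                            seen += 1
                    F[c1[ia], c2[ia]] += t - birth[ia]
                    F[c1[ib], c2[ib]] += t - birth[ib]
                    c1[ia] += c1[ib]
                    c2[ia] += c2[ib]
                    birth[ia] = t
                    k -= 1
                    deme[ib] = deme[k]
                    c1[ib] = c1[k]
                    c2[ib] = c2[k]
                    birth[ib] = birth[k]
            # flush contact-phase branch time at the epoch boundary
            for i in range(k):
                F[c1[i], c2[i]] += t - birth[i]
                birth[i] = 0.0
        t = 0.0

        if k > 1:
            # average the deep history over several sampled merge patterns
            # of the same contact-epoch outcome
            invP = 1.0 / n_paths
            for _path in range(n_paths):
                kp = k
                for i in range(kp):
                    pc1[i] = c1[i]
                    pc2[i] = c2[i]
                    pdeme[i] = deme[i]
                    birth[i] = 0.0
                t = 0.0
                # ---- isolation epoch: exact times, sampled merges ----
                if t_div > t_sc:
                    sk = _isolation_phase_rb(
                        F, pc1, pc2, pdeme, kp, 0, cumA1, Scdf1, sc1, sc2, 0, invP
                    )
                    sk = _isolation_phase_rb(
                        F, pc1, pc2, pdeme, kp, 1, cumA2, Scdf2, sc1, sc2, sk, invP
                    )
                    kp = sk
                    for i in range(kp):
                        pc1[i] = sc1[i]
                        pc2[i] = sc2[i]
                        birth[i] = 0.0

                # ---- ancestral panmictic deme of size 1 ----
                while kp > _RAO_BLACKWELL_KMAX:
                    lam = 0.5 * kp * (kp - 1)
                    w = -np.log(np.random.random()) / lam
                    t += w
                    a = int(np.random.random() * kp)
                    b = int(np.random.random() * (kp - 1))
                    if b >= a:
                        b += 1
                    F[pc1[a], pc2[a]] += invP * (t - birth[a])
                    F[pc1[b], pc2[b]] += invP * (t - birth[b])
                    pc1[a] += pc1[b]
                    pc2[a] += pc2[b]
                    birth[a] = t
                    kp -= 1
                    pc1[b] = pc1[kp]
                    pc2[b] = pc2[kp]
                    birth[b] = birth[kp]
                if kp > 1:
                    for i in range(kp):
                        F[pc1[i], pc2[i]] += invP * (t - birth[i])
                    _ancestral_closed_form(F, pc1, pc2, kp, n1, n2, invP)
    return Fb


def branch_length_sfs(n1, n2, model, n_reps, seed, n_paths=1,
                      return_batches=False):
    """Mean branch lengths by subtended sample counts, as an array.

    Returns the ``(n1+1, n2+1)`` array whose entry ``(i, j)`` is
    ``(1/2) * mean`` total branch length subtending exactly ``i`` population-1
    and ``j`` population-2 samples, i.e. the expected unfolded joint SFS per
    unit theta.  Entries ``(0, 0)`` and ``(n1, n2)`` are structurally zero.
    With ``return_batches`` the per-batch means (16 batches of replicates)
    are returned as well, from which per-cell Monte Carlo variances of the
    estimate can be formed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    s1_c, s2_c = model.contact_sizes
    for v in (model.t_sc, model.t_div, s1_c, s2_c, model.m12, model.m21,
              model.nu1, model.nu2):
        if not np.isfinite(v) or v < 0:
            raise ValueError("model rates/times must be finite and non-negative")
    n = int(n1) + int(n2)
    t_iso = float(model.t_div) - float(model.t_sc)
    cumA1, Scdf1 = _prepared_tables(n, float(model.nu1), t_iso)
    cumA2, Scdf2 = _prepared_tables(n, float(model.nu2), t_iso)
    Fb = _accumulate_branch_lengths(
        int(n1),
        int(n2),
        float(model.t_sc),
        float(model.t_div),
        float(s1_c),
        float(s2_c),
        float(model.m12),
        float(model.m21),
        cumA1,
        Scdf1,
        cumA2,
        Scdf2,
        int(n_reps),
        int(n_paths),
        int(seed) & 0x7FFFFFFF,
    )
    F = Fb.sum(axis=0) / (2.0 * n_reps)
    if not return_batches:
        return F
    # normalise each batch to a per-unit-theta spectrum
    B = Fb.shape[0]
    sizes = np.array([
        ((b + 1) * n_reps) // B - (b * n_reps) // B for b in range(B)
    ], dtype=float)
    batches = Fb / (2.0 * sizes[:, None, None])
    return F, batches


def _panmictic_branch_sfs(n1, n2, n_reps, seed):
    """One-deme (size 1) expected SFS per unit theta, for analytic checks."""
    n = int(n1) + int(n2)
    cumA, Scdf = _prepared_tables(n, 1.0, 0.0)
    Fb = _accumulate_branch_lengths(
        int(n1), int(n2), 0.0, 0.0, 1.0, 1.0, 0.0, 0.0,
        cumA, Scdf, cumA, Scdf, int(n_reps), 1, int(seed) & 0x7FFFFFFF,
    )
    return Fb.sum(axis=0) / (2.0 * n_reps)


def _prepared_tables(n: int, nu: float, horizon: float):
    """cumA (reverse-cumulative expected level times) and survivor CDF."""
    A, S = _death_chain_tables(n, nu, horizon)
    m = n + 1
    cumA = np.zeros((m, m + 1))
    cumA[:, :m] = A
    # reverse cumulative over levels: cumA[j, l] = sum_{l' >= l} A[j, l']
    cumA = np.flip(np.cumsum(np.flip(cumA, axis=1), axis=1), axis=1)
    Scdf = np.cumsum(S, axis=1)
    for j in range(m):  # guard against rounding in the sampling loop
        Scdf[j, j:] = 1.0
    return np.ascontiguousarray(cumA), np.ascontiguousarray(Scdf)
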