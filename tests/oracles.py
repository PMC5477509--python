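"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: statistics are
computed per site with explicit loops, directly from first principles or
from the published formulas.
"""

import math

import numpy as np


def brute_site_pi(genotypes):
    """Average pairwise difference among called alleles at one site.

    ``genotypes``: iterable of diploid codes (-1 missing, else alt dosage).
    Enumerates all allele pairs explicitly.
    """
    alleles = []
    for g in genotypes:
        if g >= 0:
            alleles.extend([1] * g + [0] * (2 - g))
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if alleles[i] != alleles[j]:
                diff += 1
    return diff / pairs


def brute_observed_het(genotypes):
    called = [g for g in genotypes if g >= 0]
    if not called:
        return float("nan")
    return sum(1 for g in called if g == 1) / len(called)


def brute_tajimas_d(genotype_columns):
    """Tajima's D over a set of sites, transcribed from Tajima (1989).

    Uses the median called-allele count across segregating sites as n.
    Returns NaN with no segregating sites.
    """
    pis, ns = [], []
    for col in genotype_columns:
        alleles = []
        for g in col:
            if g >= 0:
                alleles.extend([1] * g + [0] * (2 - g))
        n = len(alleles)
        j = sum(alleles)
        if n >= 4 and 0 < j < n:
            pis.append(brute_site_pi(col))
            ns.append(n)
    S = len(pis)
    if S == 0:
        return float("nan")
    n = int(np.median(ns))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (sum(pis) - S / a1) / math.sqrt(var)


def brute_wc_fst(cols_pop1, cols_pop2):
    """Weir & Cockerham (1984) weighted FST over sites, scalar transcription.

    ``cols_pop*``: list of per-site genotype sequences. Returns NaN if no
    site contributes.
    """
    sum_a = 0.0
    sum_abc = 0.0
    used = 0
    for c1, c2 in zip(cols_pop1, cols_pop2):
        called1 = [g for g in c1 if g >= 0]
        called2 = [g for g in c2 if g >= 0]
        n1, n2 = len(called1), len(called2)
        if n1 < 2 or n2 < 2:
            continue
        p1 = sum(called1) / (2 * n1)
        p2 = sum(called2) / (2 * n2)
        h1 = sum(1 for g in called1 if g == 1) / n1
        h2 = sum(1 for g in called2 if g == 1) / n2
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0
            / (nbar - 1)
            * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        if a + b + c == 0:
            continue
        sum_a += a
        sum_abc += a + b + c
        used += 1
    if used == 0 or sum_abc == 0:
        return float("nan")
    return sum_a / sum_abc


def brute_window_pi(genotype_columns, span):
    return sum(brute_site_pi(c) for c in genotype_columns) / span


def brute_hypergeom_projection(j, n, m):
    """Exact hypergeometric projection weights via combinatorial enumeration."""
    weights = []
    for k in range(m + 1):
        if k > j or m - k > n - j:
            weights.append(0.0)
        else:
            weights.append(
                math.comb(j, k) * math.comb(n - j, m - k) / math.comb(n, m)
            )
    return weights


def watterson_joint_folded(n1, n2, theta_scaled, mask_singletons=True, grid=40001):
    """Numeric oracle for the tau=0 two-sample joint folded SFS.

    With no divergence both samples draw from one equilibrium population
    whose allele-frequency density is Beta(a, a), a = 4*N*mu (recurrent
    symmetric biallelic mutation). Cell (j1, j2) mass is the integral of the
    product of binomial sampling kernels over that density, conditioned on
    segregating in the pooled sample; folded on total minor count, corners
    and singletons masked, normalized over unmasked cells.
    """
    from scipy.stats import beta, binom

    a = theta_scaled
    eps = 1e-9
    p = np.linspace(eps, 1 - eps, grid)
    w = beta.pdf(p, a, a)
    w /= np.trapezoid(w, p)
    b1 = np.array([binom.pmf(j, n1, p) for j in range(n1 + 1)])
    b2 = np.array([binom.pmf(j, n2, p) for j in range(n2 + 1)])
    joint = np.zeros((n1 + 1, n2 + 1))
    for j1 in range(n1 + 1):
        for j2 in range(n2 + 1):
            joint[j1, j2] = np.trapezoid(b1[j1] * b2[j2] * w, p)
    # fold on total minor count (ties fold when j1 > n1 - j1)
    folded = np.zeros_like(joint)
    n_tot = n1 + n2
    for j1 in range(n1 + 1):
        for j2 in range(n2 + 1):
            tot = j1 + j2
            if tot > n_tot - tot or (2 * tot == n_tot and j1 > n1 - j1):
                folded[n1 - j1, n2 - j2] += joint[j1, j2]
            else:
                folded[j1, j2] += joint[j1, j2]
    mask = np.zeros_like(folded, dtype=bool)
    mask[0, 0] = mask[-1, -1] = True
    if mask_singletons:
        for j1 in range(n1 + 1):
            for j2 in range(n2 + 1):
                tot = j1 + j2
                if min(tot, n_tot - tot) == 1:
                    mask[j1, j2] = True
    folded[mask] = 0.0
    return folded / folded.sum(), mask


def wf_discrete_joint_folded(n1, n2, n_ref, theta, burn_factor=8,
                             mask_singletons=True):
    """Exact finite-N oracle for the tau=0 two-sample joint folded SFS.

    Propagates the full allele-count distribution of a 2N-state
    Wright-Fisher chain with symmetric recurrent mutation from a monomorphic
    start through ``burn_factor * N`` generations (matrix-vector products:
    the exact law of the simulator's burn-in), applies the weedy founder
    resampling, integrates the binomial sampling kernels of both samples,
    then folds, masks and normalizes exactly as the estimator does.
    """
    from scipy.stats import binom

    N2 = 2 * n_ref
    mu = theta / (4 * n_ref)
    p_states = np.arange(N2 + 1) / N2
    p_mut = p_states * (1 - mu) + (1 - p_states) * mu
    # transition: rows = current count, cols = next count
    T = binom.pmf(np.arange(N2 + 1)[None, :], N2, p_mut[:, None])
    dist = np.zeros(N2 + 1)
    dist[0] = 1.0
    for _ in range(burn_factor * n_ref):
        dist = dist @ T
    # cultivated sample drawn from p directly; weedy passes through an extra
    # founder resampling of 2*N_w gametes (N_w = n_ref here)
    founder = binom.pmf(np.arange(N2 + 1)[None, :], N2, p_states[:, None])
    k1 = binom.pmf(np.arange(n1 + 1)[None, :], n1, p_states[:, None])
    k2_given_founder = binom.pmf(np.arange(n2 + 1)[None, :], n2, p_states[:, None])
    k2 = founder @ k2_given_founder
    joint = np.einsum("i,ij,ik->jk", dist, k1, k2)
    n_tot = n1 + n2
    folded = np.zeros_like(joint)
    for j1 in range(n1 + 1):
        for j2 in range(n2 + 1):
            tot = j1 + j2
            if tot > n_tot - tot or (2 * tot == n_tot and j1 > n1 - j1):
                folded[n1 - j1, n2 - j2] += joint[j1, j2]
            else:
                folded[j1, j2] += joint[j1, j2]
    mask = np.zeros_like(folded, dtype=bool)
    mask[0, 0] = mask[-1, -1] = True
    if mask_singletons:
        for j1 in range(n1 + 1):
            for j2 in range(n2 + 1):
                if min(j1 + j2, n_tot - j1 - j2) == 1:
                    mask[j1, j2] = True
    folded[mask] = 0.0
    return folded / folded.sum(), mask
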