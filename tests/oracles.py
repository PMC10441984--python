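"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a statistic by direct enumeration or a textbook
formulation that shares no code path with the package implementation.
"""

import itertools

import numpy as np


def tajimas_d_bruteforce(haps):
    """Tajima's D from explicit pairwise haplotype comparisons.

    ``haps`` is a (n_hap, n_sites) 0/1 matrix with no missing data.
    """
    haps = np.asarray(haps)
    n, _ = haps.shape
    diffs = [
        int(np.sum(haps[i] != haps[j]))
        for i in range(n) for j in range(i + 1, n)
    ]
    pi = np.mean(diffs)
    seg = np.array([len(set(col)) == 2 for col in haps.T])
    S = int(seg.sum())
    if S == 0:
        return np.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst_anova(g1, g2):
    """Per-site Weir-Cockerham components via the allele-indicator ANOVA.

    ``g1``/``g2`` are (n_ind,) dosage vectors (0/1/2, no missing) for one
    site in each population. Returns (a, b, c) from the mean squares
    between populations, between individuals within populations, and
    between gametes within individuals.
    """
    pops = []
    for g in (g1, g2):
        alleles = []
        for d in np.asarray(g):
            alleles.append((1, 0) if d == 1 else (d // 2, d // 2))
        pops.append(np.array(alleles, dtype=float))  # (n_ind, 2)
    n_i = np.array([p.shape[0] for p in pops], dtype=float)
    r = 2
    n_tot = n_i.sum()
    nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    grand = np.concatenate([p.ravel() for p in pops]).mean()
    # sums of squares
    ss_pop, ss_ind, ss_gam = 0.0, 0.0, 0.0
    for p in pops:
        pop_mean = p.mean()
        ss_pop += 2 * p.shape[0] * (pop_mean - grand) ** 2
        for ind in p:
            ind_mean = ind.mean()
            ss_ind += 2 * (ind_mean - pop_mean) ** 2
            ss_gam += np.sum((ind - ind_mean) ** 2)
    msp = ss_pop / (r - 1)
    msi = ss_ind / (n_tot - r)
    msg = ss_gam / n_tot
    a = (msp - msi) / (2 * nc)
    b = (msi - msg) / 2
    c = msg
    return a, b, c


def painting_cost_enumeration(target, refs, lam):
    """Minimum mosaic-copying cost by enumerating all template paths."""
    refs = np.asarray(refs)
    n_ref, n_sites = refs.shape
    best = np.inf
    for path in itertools.product(range(n_ref), repeat=n_sites):
        cost = sum(int(refs[path[i], i] != target[i]) for i in range(n_sites))
        cost += lam * sum(path[i] != path[i - 1] for i in range(1, n_sites))
        best = min(best, cost)
    return best


def roh_in_run_bruteforce(het, window_snp, window_het, threshold):
    """In-run SNP flags via direct enumeration of every covering window."""
    het = np.asarray(het)
    n = het.size
    windows = [
        (w, het[w:w + window_snp].sum() <= window_het)
        for w in range(n - window_snp + 1)
    ]
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        covering = [homo for w, homo in windows if w <= i < w + window_snp]
        if covering:
            flags[i] = (sum(covering) / len(covering)) >= threshold
    return flags


def clr_loglik_enumeration(counts, d_morgans, bg, alpha):
    """Composite log-likelihood difference at one alpha, by explicit
    summation over the background classes and the sweeping haplotype's
    allele for every site."""
    from math import comb, exp, log

    bg = np.asarray(bg, dtype=float)
    n = bg.size + 1

    def binom_pmf(k, n_, p):
        return comb(n_, k) * p**k * (1 - p) ** (n_ - k)

    ll_sweep, ll_bg = 0.0, 0.0
    for j, d in zip(counts, d_morgans):
        e = 1 - exp(-alpha * d)
        probs = np.zeros(n + 1)
        for j0 in range(1, n):
            p0 = j0 / n
            for jj in range(n + 1):
                probs[jj] += bg[j0 - 1] * (
                    p0 * binom_pmf(jj, n, e * p0 + 1 - e)
                    + (1 - p0) * binom_pmf(jj, n, e * p0)
                )
        poly = probs[1:n]
        poly = poly / poly.sum()
        ll_sweep += log(poly[j - 1])
        ll_bg += log(bg[j - 1])
    return ll_sweep - ll_bg
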