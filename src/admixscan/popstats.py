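"""Frequency-based population statistics on sliding windows.

Window grids are anchored at position 0 of each chromosome; the last
partial window is kept and flagged. All window bounds are 0-based
half-open, which makes cross-statistic joins exact.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .vcfio import SiteTable

#: KING-robust kinship thresholds separating duplicate / 1st / 2nd degree.
KING_THRESHOLDS = (0.3536, 0.1768, 0.0884)


def window_grid(L: int, win: int, step: int):
    """Yield (start, end, partial) windows tiling [0, L)."""
    start = 0
    while start < L:
        end = min(start + win, L)
        yield start, end, end - start < win
        start += step


def _per_site_counts(table: SiteTable, samples):
    idx = table.sample_indices(samples)
    g = table.gt[:, idx].astype(float)
    g[g < 0] = np.nan
    n = 2 * np.sum(~np.isnan(g), axis=1)  # haplotypes observed
    j = np.nansum(g, axis=1)  # alt allele count
    return j, n


def _windows_frame(table, values, n_sites_per_win, win, step, L=None):
    rows = []
    for chrom in dict.fromkeys(table.chrom):
        cl = L if L is not None else int(table.pos[table.chrom == chrom].max()) + 1
        for start, end, partial in window_grid(cl, win, step):
            rows.append((chrom, start, end, partial))
    return rows


def _window_stat(table: SiteTable, site_values, win, step, L, reducer):
    """Aggregate per-site values onto the window grid of each chromosome."""
    out = []
    for chrom in dict.fromkeys(table.chrom):
        mask = table.chrom == chrom
        pos = table.pos[mask]
        vals = site_values[..., mask] if site_values.ndim > 1 else site_values[mask]
        cl = L if L is not None else int(pos.max()) + 1 if pos.size else win
        for start, end, partial in window_grid(cl, win, step):
            lo, hi = np.searchsorted(pos, [start, end])
            out.append({
                "chrom": chrom, "start": start, "end": end,
                "n_sites": hi - lo, "partial": partial,
                "value": reducer(vals[..., lo:hi], end - start),
            })
    return pd.DataFrame(out)


def pi_windows(table: SiteTable, samples=None, win=50_000, step=20_000,
               L=None) -> pd.DataFrame:
    """Windowed nucleotide diversity (per-bp pi).

    Per-site pi = 2 j (n - j) / (n (n - 1)) for alt count j among n
    non-missing haplotypes; the window value sums per-site pi and divides
    by the window length in bp. Windows without genotyped sites get 0.
    """
    j, n = _per_site_counts(table, samples)
    if np.max(n, initial=0) < 2 and table.n_sites:
        raise ValueError("need at least 2 haplotypes")
    ok = n >= 2
    site_pi = np.zeros(table.n_sites)
    site_pi[ok] = 2 * j[ok] * (n[ok] - j[ok]) / (n[ok] * (n[ok] - 1))

    def red(v, span):
        return float(v.sum()) / span

    return _window_stat(table, site_pi, win, step, L, red)


# Tajima's D constants (standard a1..e2 for n haplotypes)
def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(table: SiteTable, samples=None, win=2_000, step=2_000,
              L=None) -> pd.DataFrame:
    """Tajima's D per window; windows with no segregating sites are NaN.

    Sites with missing genotypes use the window's minimum observed
    haplotype count for the constants (sites with fewer than 4 observed
    haplotypes are dropped).
    """
    j, n = _per_site_counts(table, samples)
    n_max = int(np.max(n, initial=0))
    if table.n_sites and n_max < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    usable = n >= 4
    seg = usable & (j > 0) & (j < n)
    site_pi = np.zeros(table.n_sites)
    site_pi[seg] = (2 * j[seg] * (n[seg] - j[seg])
                    / (n[seg] * (n[seg] - 1)))
    stacked = np.vstack([site_pi, seg.astype(float), n * usable])

    def red(v, span):
        pi_sum = v[0].sum()
        S = int(v[1].sum())
        if S == 0:
            return np.nan
        n_win = int(v[2][v[2] > 0].min())
        a1, e1, e2 = _tajima_constants(n_win)
        var = e1 * S + e2 * S * (S - 1)
        return (pi_sum - S / a1) / np.sqrt(var)

    return _window_stat(table, stacked, win, step, L, red)


def theta_pi_ratio(target_pi: pd.DataFrame, reference_pi: pd.DataFrame
                   ) -> pd.DataFrame:
    """ln(pi_target) - ln(pi_reference) on a matched window grid.

    Windows where either diversity is zero come back NaN (flagged by the
    ``undefined`` column).
    """
    keys = ["chrom", "start", "end"]
    if not target_pi[keys].reset_index(drop=True).equals(
            reference_pi[keys].reset_index(drop=True)):
        raise ValueError("window grids differ between target and reference")
    out = target_pi[keys + ["partial"]].copy()
    t = target_pi["value"].to_numpy(dtype=float)
    r = reference_pi["value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where((t > 0) & (r > 0), np.log(t) - np.log(r), np.nan)
    out["n_sites"] = target_pi["n_sites"].to_numpy()
    out["value"] = val
    out["undefined"] = ~np.isfinite(val)
    return out


def wc_site_components(table: SiteTable, popA, popB):
    """Per-site Weir-Cockerham variance components (a, b, c) for two
    diploid populations, plus a mask of usable (polymorphic) sites."""
    comps = []
    for pop in (popA, popB):
        idx = table.sample_indices(pop)
        g = table.gt[:, idx].astype(float)
        g[g < 0] = np.nan
        n_i = np.sum(~np.isnan(g), axis=1)  # diploids observed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_i = np.nanmean(g, axis=1) / 2
            h_i = np.nanmean(g == 1, axis=1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    if np.all(n1 == 0) or np.all(n2 == 0):
        raise ValueError("empty population")
    r = 2
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    usable = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1)
    return a, b, c, usable


def wc_fst_windows(table: SiteTable, popA, popB, win=50_000, step=20_000,
                   L=None) -> pd.DataFrame:
    """Windowed Weir-Cockerham FST, ratio-of-sums (sum a / sum (a+b+c)).

    Sites monomorphic across both populations are skipped; negative window
    values are retained (estimator convention, not clamped).
    """
    a, b, c, usable = wc_site_components(table, popA, popB)
    num = np.where(usable, a, 0.0)
    den = np.where(usable, a + b + c, 0.0)
    stacked = np.vstack([num, den, usable.astype(float)])

    def red(v, span):
        d = v[1].sum()
        return float(v[0].sum() / d) if d > 0 else np.nan

    df = _window_stat(table, stacked, win, step, L, red)
    return df


def per_site_fst(table: SiteTable, popA, popB) -> np.ndarray:
    """Per-site WC FST a/(a+b+c); NaN on unusable sites."""
    a, b, c, usable = wc_site_components(table, popA, popB)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = a / (a + b + c)
    f[~usable] = np.nan
    return f


def empirical_rank(values: np.ndarray) -> np.ndarray:
    """Upper-tail empirical rank: fraction of finite values >= each value."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    out = np.full(v.shape, np.nan)
    fv = v[finite]
    asc = np.sort(fv)
    counts = fv.size - np.searchsorted(asc, fv, side="left")
    out[finite] = counts / fv.size
    return out


def king_kinship(table: SiteTable, samples=None, min_sites=100,
                 warn_sites=1000) -> pd.DataFrame:
    """Pairwise KING-robust kinship and relationship degree classes.

    phi = (N_het_both - 2 * N_opposite_hom) / (N_het_i + N_het_j), counted
    over jointly non-missing sites. Degree classes follow the KING
    thresholds: >= 0.3536 duplicate; >= 0.1768 first; >= 0.0884 second;
    otherwise unrelated. Pairs with fewer than ``min_sites`` jointly
    observed sites get NaN.
    """
    idx = table.sample_indices(samples)
    names = [table.samples[i] for i in idx]
    g = table.gt[:, idx].astype(np.int8)
    if table.n_sites < warn_sites:
        warnings.warn(
            f"only {table.n_sites} sites; KING kinship is unstable below "
            f"~{warn_sites} informative sites")
    rows = []
    for i in range(len(idx)):
        gi = g[:, i]
        for jx in range(i + 1, len(idx)):
            gj = g[:, jx]
            ok = (gi >= 0) & (gj >= 0)
            n_ok = int(ok.sum())
            if n_ok < min_sites:
                rows.append((names[i], names[jx], n_ok, np.nan, "NA"))
                continue
            a, b = gi[ok], gj[ok]
            het_i = int(np.sum(a == 1))
            het_j = int(np.sum(b == 1))
            het_both = int(np.sum((a == 1) & (b == 1)))
            opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
            denom = het_i + het_j
            phi = (het_both - 2 * opp) / denom if denom else np.nan
            if not np.isfinite(phi):
                deg = "NA"
            elif phi >= KING_THRESHOLDS[0]:
                deg = "duplicate"
            elif phi >= KING_THRESHOLDS[1]:
                deg = "first"
            elif phi >= KING_THRESHOLDS[2]:
                deg = "second"
            else:
                deg = "unrelated"
            rows.append((names[i], names[jx], n_ok, phi, deg))
    df = pd.DataFrame(rows, columns=["sample_i", "sample_j", "n_snps",
                                     "phi", "degree"])
    df["close_relative"] = df["degree"].isin(["duplicate", "first", "second"])
    return df
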