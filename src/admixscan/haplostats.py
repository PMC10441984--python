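"""Haplotype- and runs-based statistics.

Covers LD decay with half-decay distance, runs of homozygosity by the
PLINK sliding-window-fraction rule, EHH/iHS selection scans, a
SweepFinder-style composite-likelihood-ratio scan against the genome-wide
site-frequency spectrum, and the rank-and-intersect step that combines
scans into candidate selection regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popstats import empirical_rank, window_grid
from .vcfio import SiteTable


# ---------------------------------------------------------------- LD decay

def ld_decay(table: SiteTable, samples=None, max_dist_bp=300_000,
             bin_bp=1_000):
    """Mean genotype-correlation r^2 per physical-distance bin.

    Returns ``(curve, half_decay_bp)``: curve is a DataFrame with bin left
    edges, mean r^2 and pair counts; the half-decay distance is where the
    curve first drops to half its maximum, linearly interpolated between
    bin centers.
    """
    idx = table.sample_indices(samples)
    g = table.gt[:, idx].astype(float)
    g[g < 0] = np.nan
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in dict.fromkeys(table.chrom):
        mask = table.chrom == chrom
        pos = table.pos[mask]
        if pos.size < 2:
            continue
        gc = g[mask]
        mu = np.nanmean(gc, axis=1)
        sd = np.nanstd(gc, axis=1)
        keep = sd > 0
        pos, gc, mu, sd = pos[keep], gc[keep], mu[keep], sd[keep]
        z = (gc - mu[:, None]) / sd[:, None]
        z = np.nan_to_num(z)
        n_eff = np.sum(~np.isnan(gc), axis=1)
        for i in range(len(pos) - 1):
            hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            if hi <= i + 1:
                continue
            r = z[i + 1:hi] @ z[i] / len(idx)
            r2 = r * r
            d = pos[i + 1:hi] - pos[i]
            b = np.minimum(d // bin_bp, n_bins - 1).astype(int)
            np.add.at(sums, b, r2)
            np.add.at(counts, b, 1)
    if counts.sum() == 0:
        raise ValueError("fewer than 2 usable sites within max_dist_bp")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    curve = pd.DataFrame({
        "dist_bp": np.arange(n_bins) * bin_bp,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })
    half = half_decay_distance(curve["dist_bp"].to_numpy() + bin_bp / 2,
                               mean_r2)
    return curve, half


def half_decay_distance(dist, r2):
    """First distance where r^2 falls to half the curve maximum, with
    linear interpolation between the bracketing points. NaN if never."""
    dist = np.asarray(dist, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    ok = np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    if r2.size == 0:
        return np.nan
    target = np.nanmax(r2) / 2
    below = np.nonzero(r2 <= target)[0]
    if below.size == 0:
        return np.nan
    i = below[0]
    if i == 0:
        return float(dist[0])
    x0, x1 = dist[i - 1], dist[i]
    y0, y1 = r2[i - 1], r2[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))


# ------------------------------------------------------------------- ROH

@dataclass
class ROHParams:
    """PLINK --homozyg parameters (names mirror the PLINK flags)."""

    window_snp: int = 100
    density_kb_per_snp: float = 200.0
    window_het: int = 1
    min_kb: float = 100.0
    window_threshold: float = 0.05


def roh_hit_fraction(het: np.ndarray, window_snp: int, window_het: int):
    """Per-SNP fraction of overlapping windows that are 'homozygous'.

    A window of ``window_snp`` consecutive SNPs is homozygous when it
    contains at most ``window_het`` heterozygous calls. SNPs near the
    chromosome ends are covered by fewer windows.
    """
    n = het.size
    if n < window_snp:
        return None
    het_csum = np.concatenate([[0], np.cumsum(het)])
    win_het = het_csum[window_snp:] - het_csum[:-window_snp]
    homo = (win_het <= window_het).astype(np.int64)  # window w covers [w, w+K)
    homo_csum = np.concatenate([[0], np.cumsum(homo)])
    n_win = homo.size
    snp_idx = np.arange(n)
    w_lo = np.maximum(0, snp_idx - window_snp + 1)
    w_hi = np.minimum(n_win - 1, snp_idx)
    covering = w_hi - w_lo + 1
    hits = homo_csum[w_hi + 1] - homo_csum[w_lo]
    return hits / covering


def detect_roh(table: SiteTable, sample, params: ROHParams | None = None
               ) -> pd.DataFrame:
    """Runs of homozygosity for one sample via the PLINK window rule.

    SNPs whose hit fraction reaches ``window_threshold`` are in-run;
    maximal stretches of in-run SNPs become ROH calls, then filtered by
    ``min_kb`` and by density (run kb per SNP at most
    ``density_kb_per_snp``).
    """
    p = params or ROHParams()
    si = table.sample_indices([sample])[0]
    rows = []
    for chrom in dict.fromkeys(table.chrom):
        mask = table.chrom == chrom
        pos = table.pos[mask]
        g = table.gt[mask, si]
        het = (g == 1).astype(np.int64)
        frac = roh_hit_fraction(het, p.window_snp, p.window_het)
        if frac is None:
            warnings.warn(
                f"{chrom}: fewer SNPs than window_snp; no ROH calls")
            continue
        in_run = frac >= p.window_threshold
        edges = np.diff(np.concatenate([[0], in_run.view(np.int8), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        for s, e in zip(starts, ends):
            start_bp, end_bp = int(pos[s]), int(pos[e - 1]) + 1
            n_snps = e - s
            length_kb = (end_bp - start_bp) / 1000.0
            if length_kb < p.min_kb:
                continue
            if length_kb / n_snps > p.density_kb_per_snp:
                continue
            rows.append((sample, chrom, start_bp, end_bp, n_snps, length_kb))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "n_snps", "length_kb"])


# ------------------------------------------------------------------ EHH/iHS

def _ehh_side(haps, core_carriers, core_idx, direction, pos_cm, cutoff,
              max_gap_bp, pos_bp):
    """EHH values walking away from the core for one carrier group.

    Returns (cm_offsets, ehh_values) starting at the core (offset 0,
    EHH 1), truncated at the cutoff, a gap larger than ``max_gap_bp``, or
    the chromosome edge.
    """
    n = core_carriers.size
    if n < 2:
        return None
    lab = np.zeros(n, dtype=np.int64)
    cms = [0.0]
    ehhs = [1.0]
    step = 1 if direction > 0 else -1
    i = core_idx
    n_sites = haps.shape[1]
    pair_tot = n * (n - 1)
    while True:
        i += step
        if i < 0 or i >= n_sites:
            break
        if abs(pos_bp[i] - pos_bp[i - step]) > max_gap_bp:
            break
        alleles = haps[core_carriers, i]
        lab = lab * 2 + alleles
        _, lab = np.unique(lab, return_inverse=True)
        counts = np.bincount(lab)
        ehh = float((counts * (counts - 1)).sum()) / pair_tot
        cms.append(abs(pos_cm[i] - pos_cm[core_idx]))
        ehhs.append(ehh)
        if ehh < cutoff:
            break
    return np.asarray(cms), np.asarray(ehhs)


def ehh_curve(haps, core_idx, core_allele, pos_bp, pos_cm, cutoff=0.05,
              max_gap_bp=200_000):
    """Two-sided EHH curve for the haplotypes carrying ``core_allele``."""
    carriers = np.nonzero(haps[:, core_idx] == core_allele)[0]
    left = _ehh_side(haps, carriers, core_idx, -1, pos_cm, cutoff,
                     max_gap_bp, pos_bp)
    right = _ehh_side(haps, carriers, core_idx, +1, pos_cm, cutoff,
                      max_gap_bp, pos_bp)
    return left, right


def _ihh(side) -> float:
    """Trapezoidal integral of one EHH side over genetic distance (cM)."""
    if side is None:
        return np.nan
    cms, ehhs = side
    if cms.size < 2:
        return 0.0
    return float(np.trapezoid(ehhs, cms))


def ehh_ihs(haps, pos_bp, pos_cm, anc_alleles=None, maf_min=0.05,
            max_gap_bp=200_000, cutoff=0.05, standardize_bin=0.05
            ) -> pd.DataFrame:
    """Per-SNP standardized iHS over one chromosome of phased haplotypes.

    ``anc_alleles`` gives the ancestral allele (0/1) per site; without it
    the major allele stands in as ancestral (flagged in the output).
    Unstandardized iHS = ln(iHH_ancestral / iHH_derived), standardized to
    zero mean and unit variance within derived-frequency bins.
    """
    haps = np.asarray(haps)
    n_hap, n_sites = haps.shape
    proxy = anc_alleles is None
    if proxy:
        anc_alleles = (haps.mean(axis=0) > 0.5).astype(np.int8)
    anc_alleles = np.asarray(anc_alleles)
    der = 1 - anc_alleles
    daf = np.array([(haps[:, i] == der[i]).mean() for i in range(n_sites)])
    rows = []
    for i in range(n_sites):
        if daf[i] < maf_min or daf[i] > 1 - maf_min:
            continue
        vals = {}
        skip = False
        for label, allele in (("A", anc_alleles[i]), ("D", der[i])):
            carriers = int((haps[:, i] == allele).sum())
            if carriers < 2:
                skip = True
                break
            left, right = ehh_curve(haps, i, allele, pos_bp, pos_cm,
                                    cutoff, max_gap_bp)
            vals[label] = _ihh(left) + _ihh(right)
        if skip or vals["D"] <= 0 or vals["A"] <= 0:
            continue
        rows.append((int(pos_bp[i]), float(daf[i]),
                     float(np.log(vals["A"] / vals["D"]))))
    df = pd.DataFrame(rows, columns=["pos", "daf", "ihs_raw"])
    df["anc_is_proxy"] = proxy
    # standardize within derived-frequency bins
    bins = np.floor(df["daf"].to_numpy() / standardize_bin).astype(int)
    std = np.full(len(df), np.nan)
    for b in np.unique(bins):
        sel = bins == b
        v = df.loc[sel, "ihs_raw"].to_numpy()
        if sel.sum() >= 2 and np.std(v) > 0:
            std[sel] = (v - v.mean()) / v.std()
        else:
            std[sel] = 0.0
    df["ihs"] = std
    return df


def ihs_windows(ihs_df: pd.DataFrame, chrom="chr1", win=50_000, L=None
                ) -> pd.DataFrame:
    """Windowed |iHS| summaries: mean |iHS| (primary) and the fraction of
    SNPs with |iHS| > 2 (alternate), on nonoverlapping windows."""
    pos = ihs_df["pos"].to_numpy()
    a = np.abs(ihs_df["ihs"].to_numpy())
    cl = L if L is not None else (int(pos.max()) + 1 if pos.size else win)
    rows = []
    for start, end, partial in window_grid(cl, win, win):
        lo, hi = np.searchsorted(pos, [start, end])
        seg = a[lo:hi]
        rows.append({
            "chrom": chrom, "start": start, "end": end, "n_sites": hi - lo,
            "partial": partial,
            "value": float(np.mean(seg)) if hi > lo else np.nan,
            "frac_gt2": float(np.mean(seg > 2)) if hi > lo else np.nan,
        })
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- CLR

DEFAULT_ALPHA_GRID = np.concatenate([np.geomspace(1.0, 1e5, 21), [np.inf]])


def background_sfs(counts, n_hap, smooth=True):
    """Genome-wide site-frequency spectrum over classes 1..n-1.

    Empty classes get add-one smoothing (with a warning) so the composite
    likelihood stays finite.
    """
    counts = np.asarray(counts)
    seg = counts[(counts > 0) & (counts < n_hap)]
    hist = np.bincount(seg, minlength=n_hap)[1:n_hap].astype(float)
    if smooth and (hist == 0).any():
        warnings.warn("empty SFS classes; applying add-one smoothing")
        hist += 1.0
    return hist / hist.sum()


def sweep_class_probs(bg: np.ndarray, e):
    """Sweep-distorted frequency-class probabilities at escape prob ``e``.

    Each sampled lineage escapes the sweep independently with probability
    e; a non-escaping lineage carries whatever the sweeping haplotype
    carried. Conditioning on that haplotype's allele (derived with the
    background frequency p0), the derived count is Binomial(n, e*p0 + 1-e)
    or Binomial(n, e*p0); marginalizing over the background SFS and
    re-conditioning on polymorphism gives the observable spectrum over
    classes 1..n-1. At e = 0 mass concentrates near the extreme classes;
    e -> 1 approaches (but does not equal) the background.
    """
    from scipy.stats import binom

    n = bg.size + 1
    j = np.arange(n + 1)
    p0 = np.arange(1, n) / n  # background class frequencies
    q_hit = e * p0 + (1 - e)  # sweeping haplotype was derived
    q_miss = e * p0
    pmf = (p0[:, None] * binom.pmf(j[None, :], n, q_hit[:, None])
           + (1 - p0[:, None]) * binom.pmf(j[None, :], n, q_miss[:, None]))
    mixed = bg @ pmf  # (n+1,) over counts 0..n
    poly = mixed[1:n]
    s = poly.sum()
    if s <= 0:
        return bg
    return poly / s


def _sweep_table(bg: np.ndarray, n_e=64):
    """Log class probabilities on a grid of escape probabilities.

    Returns (e_grid, table) with table[i] = log P(class | e_grid[i]);
    the final grid member is the exact background spectrum, nesting the
    no-sweep null so the CLR is never negative.
    """
    e_grid = np.linspace(0.0, 1.0, n_e)
    table = np.empty((n_e, bg.size))
    with np.errstate(divide="ignore"):
        for i, e in enumerate(e_grid[:-1]):
            table[i] = np.log(sweep_class_probs(bg, e))
        table[-1] = np.log(bg)
    return e_grid, table


def clr_window_value(counts, d_morgans, bg, alpha_grid=DEFAULT_ALPHA_GRID,
                     sweep_table=None):
    """CLR at one test point: 2 * (max_alpha logL_sweep - logL_background).

    ``counts`` are derived-allele counts (classes 1..n-1) of the window's
    segregating sites, ``d_morgans`` their distances from the test point.
    The per-site escape probability is e = 1 - exp(-alpha * d); alpha
    = inf recovers the background exactly, so the maximum is >= 0.
    """
    counts = np.asarray(counts)
    d = np.asarray(d_morgans, dtype=float)
    keep = (counts >= 1) & (counts <= bg.size)
    counts, d = counts[keep], d[keep]
    if counts.size == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        log_bg = float(np.sum(np.log(bg[counts - 1])))
    best = log_bg  # alpha -> inf member
    for alpha in alpha_grid:
        if np.isinf(alpha):
            continue
        e = 1 - np.exp(-alpha * d)
        if sweep_table is None:
            # exact per-site spectra (used on small inputs / oracles)
            ll = float(sum(
                np.log(sweep_class_probs(bg, ei)[c - 1])
                for ei, c in zip(e, counts)))
        else:
            e_grid, table = sweep_table
            ei = np.clip(np.searchsorted(e_grid, e), 0, len(e_grid) - 1)
            ll = float(np.sum(table[ei, counts - 1]))
        best = max(best, ll)
    return 2 * (best - log_bg)


def clr_scan(table: SiteTable, samples=None, win=50_000, grid_per_win=4,
             L=None, morgans_per_bp=1e-8, alpha_grid=DEFAULT_ALPHA_GRID,
             anc_alleles=None) -> pd.DataFrame:
    """SweepFinder-style CLR on nonoverlapping windows.

    The background SFS is estimated genome-wide from the same cohort; the
    per-window value is the maximum CLR over ``grid_per_win`` evenly
    spaced test points. Without ancestral alleles the alt allele is
    treated as derived (the simulator's convention).
    """
    from .popstats import _per_site_counts

    j, n = _per_site_counts(table, samples)
    n_hap = int(np.max(n, initial=0))
    j = j.astype(int)
    if anc_alleles is not None:
        flip = np.asarray(anc_alleles) == 1
        j = np.where(flip, n_hap - j, j)
    bg = background_sfs(j, n_hap)
    stab = _sweep_table(bg)
    rows = []
    for chrom in dict.fromkeys(table.chrom):
        mask = table.chrom == chrom
        pos = table.pos[mask]
        jj = j[mask]
        cl = L if L is not None else int(pos.max()) + 1
        for start, end, partial in window_grid(cl, win, win):
            lo, hi = np.searchsorted(pos, [start, end])
            seg_j, seg_pos = jj[lo:hi], pos[lo:hi]
            test_points = np.linspace(start, end, grid_per_win + 2)[1:-1]
            best = 0.0
            for tp in test_points:
                d = np.abs(seg_pos - tp) * morgans_per_bp
                best = max(best, clr_window_value(seg_j, d, bg, alpha_grid,
                                                  sweep_table=stab))
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "n_sites": hi - lo, "partial": partial,
                         "value": best})
    return pd.DataFrame(rows)


# --------------------------------------------------- rank and intersect

def rank_and_intersect(scans: dict, top_q=0.01, min_methods=2,
                       min_windows=100) -> pd.DataFrame:
    """Combine named window scans into candidate selection regions.

    Each scan gets upper-tail empirical ranks; all scans are resampled to
    the coarsest grid by maximal overlap; a coarse window is a candidate
    when its rank is within ``top_q`` in at least ``min_methods`` scans.
    Adjacent candidate windows merge into regions. The ``methods`` column
    lists which scans fired.
    """
    for name, df in scans.items():
        n_ok = int(np.isfinite(df["value"]).sum())
        if n_ok < min_windows:
            raise ValueError(
                f"scan {name!r} has {n_ok} ranked windows (<{min_windows}); "
                "empirical quantiles unstable")
    ranked = {name: df.assign(rank=empirical_rank(df["value"].to_numpy()))
              for name, df in scans.items()}
    coarse_name = max(ranked, key=lambda k: (ranked[k]["end"]
                                             - ranked[k]["start"]).max())
    coarse = ranked[coarse_name].reset_index(drop=True)
    hit_names = []
    hits = np.zeros(len(coarse), dtype=int)
    per_window_methods = [[] for _ in range(len(coarse))]
    for name, df in ranked.items():
        for i, row in coarse.iterrows():
            sel = df[df["chrom"] == row["chrom"]]
            if name == coarse_name:
                r = row["rank"]
            else:
                ov = (np.minimum(sel["end"], row["end"])
                      - np.maximum(sel["start"], row["start"]))
                if len(sel) == 0 or ov.max() <= 0:
                    continue
                r = sel.iloc[int(np.argmax(ov.to_numpy()))]["rank"]
            if np.isfinite(r) and r <= top_q:
                hits[i] += 1
                per_window_methods[i].append(name)
    cand = coarse[hits >= min_methods].copy()
    cand["methods"] = [",".join(sorted(per_window_methods[i]))
                       for i in np.nonzero(hits >= min_methods)[0]]
    # merge adjacent candidate windows into regions
    regions = []
    for _, row in cand.iterrows():
        if (regions and regions[-1]["chrom"] == row["chrom"]
                and row["start"] <= regions[-1]["end"]):
            regions[-1]["end"] = max(regions[-1]["end"], row["end"])
            regions[-1]["methods"] |= set(row["methods"].split(","))
        else:
            regions.append({"chrom": row["chrom"], "start": row["start"],
                            "end": row["end"],
                            "methods": set(row["methods"].split(","))})
    return pd.DataFrame(
        [{"chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
          "methods": ",".join(sorted(r["methods"]))} for r in regions],
        columns=["chrom", "start", "end", "methods"])
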