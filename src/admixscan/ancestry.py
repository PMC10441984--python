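"""Local-ancestry painting and ancestry-excess scanning.

Painting follows the reference-copying model: an admixed haplotype is
explained as a mosaic of reference-panel haplotypes, scored by a dynamic
program with unit mismatch cost and a switch penalty lambda; the site's
ancestry is the panel label of the copied template. Calls from a small
grid of lambda values are combined by per-site majority vote, which makes
the painting robust to the exact penalty choice.

The excess scan partitions the chromosome at every position where any
haplotype's ancestry call changes and tests each segment's ancestry
frequency against the genome-wide proportion with a one-sided Z test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_LAMBDA_GRID = (1.0, 1.5, 2.0, 3.0, 5.0)


def _viterbi_multi(target: np.ndarray, refs: np.ndarray, lams):
    """Minimum-cost template paths for several switch penalties at once.

    Cost 1 per mismatch, lambda per template switch. Returns
    (paths, costs): paths is (n_lam, n_sites) of copied reference rows,
    costs the DP optima. Running the lambda grid in one pass keeps the
    per-site Python overhead shared.
    """
    lams = np.asarray(lams, dtype=np.float64)
    n_lam = lams.size
    n_ref, n_sites = refs.shape
    mismatch = (refs != target[None, :]).astype(np.float64)  # (R, S)
    cost = np.tile(mismatch[:, 0], (n_lam, 1))  # (L, R)
    came_from_switch = np.zeros((n_sites, n_lam, n_ref), dtype=bool)
    best_prev = np.zeros((n_sites, n_lam), dtype=np.int32)
    lam_col = lams[:, None]
    for i in range(1, n_sites):
        bp = np.argmin(cost, axis=1)  # (L,)
        best_prev[i] = bp
        switch_cost = cost[np.arange(n_lam), bp][:, None] + lam_col
        use_switch = switch_cost < cost
        came_from_switch[i] = use_switch
        np.copyto(cost, switch_cost, where=use_switch)
        cost += mismatch[:, i]
    ends = np.argmin(cost, axis=1)
    totals = cost[np.arange(n_lam), ends]
    paths = np.empty((n_lam, n_sites), dtype=np.int32)
    paths[:, -1] = ends
    for i in range(n_sites - 1, 0, -1):
        cur = paths[:, i]
        switched = came_from_switch[i, np.arange(n_lam), cur]
        paths[:, i - 1] = np.where(switched, best_prev[i], cur)
    return paths, totals


def _viterbi_path(target: np.ndarray, refs: np.ndarray, lam: float):
    """Single-penalty convenience wrapper around :func:`_viterbi_multi`."""
    paths, costs = _viterbi_multi(target, refs, [lam])
    return paths[0], float(costs[0])


def paint_haplotype(target: np.ndarray, panel_haps: np.ndarray,
                    panel_labels: np.ndarray,
                    lambda_grid=DEFAULT_LAMBDA_GRID):
    """Paint one haplotype: per-site ancestry codes by majority vote over
    the lambda grid (ties resolve to the smallest lambda's call).

    Returns (codes, cost) where cost is the DP optimum at the smallest
    lambda (useful for diagnostics).
    """
    panel_labels = np.asarray(panel_labels)
    if panel_labels.size == 0:
        raise ValueError("empty reference panel")
    K = int(panel_labels.max()) + 1
    for k in range(K):
        if not np.any(panel_labels == k):
            raise ValueError(f"no reference haplotypes for ancestry {k}")
    lams = sorted(lambda_grid)
    paths, costs = _viterbi_multi(target, panel_haps, lams)
    calls = panel_labels[paths]  # (n_lambda, n_sites)
    base_cost = float(costs[0])
    onehot = np.zeros((K, calls.shape[1]), dtype=np.int32)
    for row in calls:
        onehot[row, np.arange(calls.shape[1])] += 1
    votes = onehot.max(axis=0)
    winner = onehot.argmax(axis=0)
    tie = (onehot == votes[None, :]).sum(axis=0) > 1
    winner[tie] = calls[0][tie]
    return winner.astype(np.int8), base_cost


def paint_cohort(target_haps, panel_haps, panel_labels,
                 lambda_grid=DEFAULT_LAMBDA_GRID) -> np.ndarray:
    """Paint every row of ``target_haps``; returns (n_hap, n_sites) codes."""
    return np.vstack([
        paint_haplotype(h, panel_haps, panel_labels, lambda_grid)[0]
        for h in np.asarray(target_haps)
    ])


def tracts_from_codes(codes: np.ndarray, pos_bp: np.ndarray, L: int):
    """Maximal constant-ancestry runs as bp intervals tiling [0, L).

    Boundaries fall at the midpoint between the flanking informative
    sites; the first and last tracts extend to the chromosome ends.
    """
    codes = np.asarray(codes)
    pos_bp = np.asarray(pos_bp)
    change = np.nonzero(np.diff(codes))[0]  # change after site index i
    bounds = [0]
    for i in change:
        bounds.append(int((pos_bp[i] + pos_bp[i + 1]) // 2) + 1)
    bounds.append(L)
    starts_idx = np.concatenate([[0], change + 1])
    return [(bounds[t], bounds[t + 1], int(codes[starts_idx[t]]))
            for t in range(len(bounds) - 1)]


def global_proportions(paintings, positions, chrom_lengths, K=None
                       ) -> np.ndarray:
    """Genome-wide ancestry proportions, bp-weighted over all haplotypes.

    ``paintings``/``positions``/``chrom_lengths`` are parallel lists over
    chromosomes; each painting is an (n_hap, n_sites) code matrix.
    Proportions sum to 1.
    """
    if K is None:
        K = int(max(p.max() for p in paintings)) + 1
    tot = np.zeros(K)
    for codes, pos, L in zip(paintings, positions, chrom_lengths):
        for hap in codes:
            for s, e, k in tracts_from_codes(hap, pos, L):
                tot[k] += e - s
    if tot.sum() == 0:
        raise ValueError("empty paintings")
    return tot / tot.sum()


@dataclass
class ExcessTestConfig:
    f_min: float = 0.75
    len_min: int = 1000
    alpha: float = 0.01


def segment_and_test(codes: np.ndarray, pos_bp: np.ndarray, L: int,
                     genome_p: np.ndarray, chrom="chr1", f_min=0.75,
                     len_min=1000, alpha=0.01, keep_all=False
                     ) -> pd.DataFrame:
    """Change-point segmentation plus one-sided ancestry-excess Z test.

    Segments are maximal intervals over which the cohort's per-site
    ancestry-count vector is constant; their bp bounds use the midpoint
    convention so they tile [0, L) exactly. For each segment and ancestry
    with haplotype count x of 2N: f = x/2N,
    Z = (f - p) / sqrt(p (1 - p) / 2N), p-value from the normal upper
    tail. Retained segments satisfy f >= f_min, length >= len_min and
    p < alpha; pass ``keep_all`` to get every (segment, ancestry) row with
    a ``retained`` flag instead.
    """
    codes = np.asarray(codes)
    n_hap, n_sites = codes.shape
    if n_hap < 10:
        warnings.warn("fewer than 10 haplotypes: normal approximation weak")
    K = len(genome_p)
    counts = np.zeros((K, n_sites), dtype=np.int32)
    for k in range(K):
        counts[k] = (codes == k).sum(axis=0)
    change = np.nonzero(np.any(np.diff(counts, axis=1) != 0, axis=0))[0]
    bounds = [0]
    for i in change:
        bounds.append(int((pos_bp[i] + pos_bp[i + 1]) // 2) + 1)
    bounds.append(L)
    first_site = np.concatenate([[0], change + 1])
    rows = []
    for t in range(len(bounds) - 1):
        start, end = bounds[t], bounds[t + 1]
        length = end - start
        x = counts[:, first_site[t]]
        for k in range(K):
            f = x[k] / n_hap
            p = genome_p[k]
            if not (0 < p < 1):
                continue
            z = (f - p) / np.sqrt(p * (1 - p) / n_hap)
            pval = float(norm.sf(z))
            retained = (f >= f_min) and (length >= len_min) and (pval < alpha)
            if keep_all or retained:
                rows.append((chrom, start, end, k, f, length, z, pval,
                             retained))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ancestry",
                                       "f", "length", "z", "p", "retained"])


def segment_partition(codes, pos_bp, L):
    """All change-point segments (chrom-tiling intervals), untested."""
    codes = np.asarray(codes)
    counts_change = np.any(np.diff(codes, axis=1) != 0, axis=0)
    change = np.nonzero(counts_change)[0]
    bounds = [0]
    for i in change:
        bounds.append(int((pos_bp[i] + pos_bp[i + 1]) // 2) + 1)
    bounds.append(L)
    return [(bounds[t], bounds[t + 1]) for t in range(len(bounds) - 1)]


def annotate_segments(segments: pd.DataFrame, genes) -> pd.DataFrame:
    """Attach overlapping gene ids (>= 1 bp transcript overlap) to each
    segment; adds a ``genes`` column of comma-joined ids."""
    out = segments.copy()
    gene_lists = []
    for _, row in out.iterrows():
        hits = [g.gene_id for g in genes
                if g.chrom == row["chrom"]
                and g.transcript[0] < row["end"]
                and row["start"] < g.transcript[1]]
        gene_lists.append(",".join(dict.fromkeys(hits)))
    out["genes"] = gene_lists
    return out


def genes_per_ancestry(annotated: pd.DataFrame) -> dict:
    """Deduplicated gene sets per ancestry class from annotated segments."""
    result = {}
    for k, sub in annotated.groupby("ancestry"):
        genes = []
        for s in sub["genes"]:
            genes.extend(g for g in s.split(",") if g)
        result[int(k)] = sorted(set(genes))
    return result


def missense_screen(table, effects, target_pop, ref_pop,
                    target_freq_min=0.7, ref_freq_max=0.2) -> pd.DataFrame:
    """Nonsynonymous sites at high alternate-allele frequency in the
    target population but low frequency in the reference population.

    Sites with no observed genotypes in either population are excluded
    (and counted in the ``n_excluded`` attribute of the result).
    """
    effects = np.asarray(effects, dtype=object)
    nonsyn = effects == "nonsynonymous"
    ft = table.alt_freq(target_pop)
    fr = table.alt_freq(ref_pop)
    observed = np.isfinite(ft) & np.isfinite(fr)
    keep = nonsyn & observed & (ft > target_freq_min) & (fr < ref_freq_max)
    df = pd.DataFrame({
        "chrom": table.chrom[keep],
        "pos": table.pos[keep],
        "ref": table.ref[keep],
        "alt": table.alt[keep],
        "freq_target": ft[keep],
        "freq_reference": fr[keep],
    })
    df.attrs["n_excluded"] = int((nonsyn & ~observed).sum())
    return df
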