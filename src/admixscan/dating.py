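"""Single-pulse admixture dating from weighted LD decay.

After one admixture pulse g generations ago, linkage disequilibrium
between sites at genetic distance d that is attributable to ancestry
mosaicism decays as exp(-g d) (d in Morgans). Weighting pairwise genotype
covariances by the product of inter-source allele-frequency differences
isolates that admixture LD; fitting A exp(-n d) + c to the binned curve
returns the pulse age n in generations, with uncertainty from a
leave-one-chromosome-out jackknife. A tract-length moment estimator
provides an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class DecayCurve:
    """Binned weighted-LD decay curve, split by chromosome so the fit can
    jackknife over chromosomes."""

    bin_edges_cm: np.ndarray  # left edges; uniform width
    bin_cm: float
    chrom_sums: dict = field(default_factory=dict)  # chrom -> per-bin sums
    chrom_counts: dict = field(default_factory=dict)
    d_min_cm: float = 0.5
    min_pairs: int = 50

    def values(self, exclude=None):
        """(bin centers cM, mean weighted LD, counts) over all chromosomes
        except ``exclude``; bins under ``min_pairs`` pairs are dropped."""
        sums = np.zeros_like(self.bin_edges_cm, dtype=float)
        counts = np.zeros_like(self.bin_edges_cm, dtype=np.int64)
        for chrom in self.chrom_sums:
            if chrom == exclude:
                continue
            sums += self.chrom_sums[chrom]
            counts += self.chrom_counts[chrom]
        ok = counts >= self.min_pairs
        centers = self.bin_edges_cm + self.bin_cm / 2
        with np.errstate(invalid="ignore"):
            vals = np.where(ok, sums / np.maximum(counts, 1), np.nan)
        return centers[ok], vals[ok], counts[ok]


@dataclass
class FitResult:
    amplitude: float
    n_generations: float
    se: float
    offset: float
    bins_used: int
    flag: str = "ok"  # "ok" | "no_admixture"

    def ci95(self):
        return (self.n_generations - 1.96 * self.se,
                self.n_generations + 1.96 * self.se)


def weighted_ld_curve(target_gt, panelA_haps, panelB_haps, pos_cm,
                      chrom="chr1", bin_cM=0.05, max_cM=10.0,
                      d_min_cM=0.5, curve: DecayCurve | None = None,
                      chunk=512) -> DecayCurve:
    """Accumulate one chromosome's weighted-LD curve.

    For site pairs (x, y) binned by genetic distance, the statistic is
    cov(g_x, g_y) across target individuals weighted by
    (pA - pB)(x) * (pA - pB)(y), where pA/pB are reference-panel allele
    frequencies (the target is excluded from the weights). Swapping the
    two panels leaves the curve unchanged. Call repeatedly with the same
    ``curve`` to add chromosomes.
    """
    pos_cm = np.asarray(pos_cm, dtype=float)
    if np.any(np.diff(pos_cm) < 0):
        raise ValueError("genetic map must be monotone non-decreasing")
    g = np.asarray(target_gt, dtype=float)  # (n_ind, n_sites)
    n_ind, n_sites = g.shape
    w = (np.asarray(panelA_haps).mean(axis=0)
         - np.asarray(panelB_haps).mean(axis=0))
    gc = g - g.mean(axis=0)
    m = gc * w[None, :]  # weighted centered genotypes
    n_bins = int(np.ceil(max_cM / bin_cM))
    if curve is None:
        curve = DecayCurve(
            bin_edges_cm=np.arange(n_bins) * bin_cM,
            bin_cm=bin_cM, d_min_cm=d_min_cM)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    denom = n_ind - 1
    for lo in range(0, n_sites, chunk):
        hi = min(lo + chunk, n_sites)
        far = np.searchsorted(pos_cm, pos_cm[hi - 1] + max_cM, side="right")
        block = m[:, lo:far]
        prod = (m[:, lo:hi].T @ block) / denom  # (chunk, far-lo)
        d = np.abs(pos_cm[lo:far][None, :] - pos_cm[lo:hi][:, None])
        ii, jj = np.meshgrid(np.arange(lo, hi), np.arange(lo, far),
                             indexing="ij")
        sel = (jj > ii) & (d > 0) & (d <= max_cM)
        b = np.minimum((d[sel] / bin_cM).astype(int), n_bins - 1)
        np.add.at(sums, b, prod[sel])
        np.add.at(counts, b, 1)
    curve.chrom_sums[chrom] = curve.chrom_sums.get(chrom, 0) + sums
    curve.chrom_counts[chrom] = curve.chrom_counts.get(chrom, 0) + counts
    return curve


def _fit_once(cm, vals, p0=None):
    d = cm / 100.0  # Morgans

    def model(d, A, n, c):
        return A * np.exp(-n * d) + c

    if p0 is None:
        c0 = float(vals[-1])
        A0 = max(float(vals[0]) - c0, 1e-6)
        n0 = 30.0
        p0 = (A0, n0, c0)
    popt, _ = curve_fit(model, d, vals, p0=p0,
                        bounds=([-np.inf, 0.0, -np.inf],
                                [np.inf, 5000.0, np.inf]),
                        maxfev=20000)
    return popt  # A, n, c


def fit_decay(curve: DecayCurve, d_min_cM=None, min_bins=10) -> FitResult:
    """Fit A exp(-n d) + c to the decay curve; n in generations.

    Only bins at genetic distance >= d_min (default the curve's, 0.5 cM)
    enter the fit, excluding background LD. The standard error of n comes
    from a leave-one-chromosome-out jackknife when more than one
    chromosome contributed; with a single chromosome the SE is NaN. A
    non-positive fitted amplitude flags "no_admixture".
    """
    d_min = curve.d_min_cm if d_min_cM is None else d_min_cM
    cm, vals, _ = curve.values()
    keep = cm >= d_min
    cm, vals = cm[keep], vals[keep]
    if cm.size < min_bins:
        raise ValueError(f"only {cm.size} usable bins (<{min_bins})")
    try:
        A, n, c = _fit_once(cm, vals)
    except RuntimeError as err:
        raise RuntimeError(f"decay fit did not converge: {err}") from err
    chroms = list(curve.chrom_sums)
    se = np.nan
    if len(chroms) > 1:
        jack = []
        for ch in chroms:
            cmx, vx, _ = curve.values(exclude=ch)
            kx = cmx >= d_min
            if kx.sum() < min_bins:
                continue
            try:
                jack.append(_fit_once(cmx[kx], vx[kx], p0=(A, n, c))[1])
            except RuntimeError:
                continue
        if len(jack) > 1:
            jack = np.asarray(jack)
            J = len(jack)
            se = float(np.sqrt((J - 1) / J * np.sum((jack - jack.mean()) ** 2)))
    flag = "ok" if A > 0 else "no_admixture"
    return FitResult(amplitude=float(A), n_generations=float(n), se=se,
                     offset=float(c), bins_used=int(cm.size), flag=flag)


def tract_length_date(tracts_per_hap, m_a, ancestry, morgans_per_bp,
                      L_bp, min_tracts=30):
    """Moment estimator g = 1 / ((1 - m_a) * mean tract length in Morgans).

    Adjacent same-ancestry tracts are merged into maximal runs first (a
    breakpoint that re-draws the same ancestry is invisible), and
    chromosome-end-censored runs (touching 0 or L) are excluded. Works
    per ancestry; requires 0 < m_a < 1.
    """
    if not (0 < m_a < 1):
        raise ValueError("tract dating requires 0 < m_a < 1")
    lengths = []
    for tracts in tracts_per_hap:
        merged = []
        for s, e, k in tracts:
            if merged and merged[-1][2] == k and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, k)
            else:
                merged.append((s, e, k))
        for s, e, k in merged:
            if k != ancestry or s == 0 or e == L_bp:
                continue
            lengths.append((e - s) * morgans_per_bp)
    if len(lengths) < min_tracts:
        warnings.warn(
            f"only {len(lengths)} uncensored tracts; estimate is wide")
    if not lengths:
        return np.nan
    return 1.0 / ((1 - m_a) * float(np.mean(lengths)))
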