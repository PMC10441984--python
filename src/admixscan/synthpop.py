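"""Synthetic reference panels and admixed cohorts with known ground truth.

The model: K source populations diverge from a common ancestor under the
Balding-Nichols model (beta-distributed allele frequencies around an
ancestral frequency, parameterized by FST). A target cohort derives from a
single admixture pulse g generations ago with mixing proportions m; each
admixed haplotype is a mosaic of ancestry tracts whose breakpoints follow a
Poisson process of rate g per Morgan, each tract copying one reference
haplotype of its ancestry with a per-site copy-error rate eps. There is no
post-admixture drift, so realized ancestry proportions and tract lengths
carry the exact single-pulse signal the dating and painting modules are
built to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .vcfio import SiteTable

# Default mixing proportions and pulse age follow the admixture history the
# package is designed around: a 4-way taurine/indicine-style cross with a
# dominant and a secondary source and two trace sources, dated a few dozen
# generations back.
DEFAULT_M = (0.556, 0.332, 0.068, 0.044)
DEFAULT_G = 38.27


@dataclass
class SimConfig:
    """Parameters of one synthetic admixture scenario.

    Attributes
    ----------
    K : number of source ancestries
    F : Balding-Nichols divergence of each source from the common ancestor
    n_ref : reference haplotypes per source panel
    n_adm : admixed diploid individuals in the target cohort
    L_bp : chromosome length in bp
    n_sites : SNPs per chromosome
    cM_per_Mb : constant recombination rate (1 cM/Mb default)
    m : mixing proportions, length K, sums to 1
    g : generations since the single admixture pulse
    eps : per-site copy-error (mutation/genotyping) probability
    seed : RNG seed; identical configs give identical output
    n_chrom : number of independent chromosomes
    """

    K: int = 4
    F: float = 0.2
    n_ref: int = 30
    n_adm: int = 30
    L_bp: int = 50_000_000
    n_sites: int = 20_000
    cM_per_Mb: float = 1.0
    m: tuple = DEFAULT_M
    g: float = DEFAULT_G
    eps: float = 0.001
    seed: int = 0
    n_chrom: int = 1

    def __post_init__(self):
        self.m = tuple(float(x) for x in self.m)
        if len(self.m) != self.K:
            raise ValueError("m must have length K")
        if abs(sum(self.m) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if not (0 <= self.F < 1) or not (0 <= self.eps < 1):
            raise ValueError("F and eps must lie in [0, 1)")
        if self.g < 1:
            raise ValueError("g must be >= 1")

    @property
    def L_morgans(self) -> float:
        return self.L_bp / 1e6 * self.cM_per_Mb / 100.0

    def bp_to_morgans(self, bp):
        return np.asarray(bp, dtype=float) / 1e6 * self.cM_per_Mb / 100.0


@dataclass
class PanelChrom:
    """One chromosome of reference panels: positions, frequencies, haplotypes."""

    chrom: str
    pos_bp: np.ndarray  # 0-based, strictly increasing
    p_anc: np.ndarray  # ancestral frequency per site
    freqs: np.ndarray  # (K, n_sites) source allele frequencies
    haps: np.ndarray  # (K, n_ref, n_sites) int8


@dataclass
class Panels:
    cfg: SimConfig
    chroms: list  # of PanelChrom

    @property
    def K(self):
        return self.cfg.K


@dataclass
class PlantedFeature:
    kind: str  # "excess" | "sweep" | "roh"
    chrom: str
    start: int
    end: int
    ancestry: int = 0
    f: float = 0.0
    samples: tuple = ()


@dataclass
class TruthSet:
    """Simulator output: target haplotypes plus everything needed to grade
    a downstream method against the truth."""

    cfg: SimConfig
    panels: Panels
    target_haps: list  # per chrom: (2*n_adm, n_sites) int8
    tracts: list  # per chrom: list per haplotype of (start_bp, end_bp, k)
    planted: list = field(default_factory=list)

    @property
    def n_hap(self):
        return 2 * self.cfg.n_adm

    def realized_proportions(self) -> np.ndarray:
        """Tract-length-weighted ancestry shares across the whole cohort."""
        tot = np.zeros(self.cfg.K)
        for chrom_tracts in self.tracts:
            for hap in chrom_tracts:
                for s, e, k in hap:
                    tot[k] += e - s
        return tot / tot.sum()

    def target_sitetable(self, chrom_idx=0) -> SiteTable:
        """Phased SiteTable of the admixed cohort for one chromosome."""
        pc = self.panels.chroms[chrom_idx]
        haps = self.target_haps[chrom_idx]
        return _haps_to_sitetable(pc, haps, prefix="adm")

    def panel_sitetable(self, chrom_idx=0, ancestry=None) -> SiteTable:
        """Phased SiteTable of one reference panel (or all panels)."""
        pc = self.panels.chroms[chrom_idx]
        ks = range(self.cfg.K) if ancestry is None else [ancestry]
        haps = np.concatenate([pc.haps[k] for k in ks], axis=0)
        names = [f"anc{k}_s{i}" for k in ks
                 for i in range(self.cfg.n_ref // 2)]
        return _haps_to_sitetable(pc, haps, names=names)

    def write(self, outdir) -> None:
        """Emit phased VCFs, truth-tract BED and a JSON manifest."""
        import os
        from .vcfio import write_vcf

        os.makedirs(outdir, exist_ok=True)
        for ci in range(len(self.panels.chroms)):
            write_vcf(self.target_sitetable(ci),
                      os.path.join(outdir, f"target_{ci}.vcf"))
        for k in range(self.cfg.K):
            for ci, pc in enumerate(self.panels.chroms):
                st = _haps_to_sitetable(pc, pc.haps[k], prefix=f"anc{k}_s")
                write_vcf(st, os.path.join(outdir, f"panel{k}_{ci}.vcf"))
        with open(os.path.join(outdir, "truth_tracts.bed"), "w") as fh:
            for ci, chrom_tracts in enumerate(self.tracts):
                name = self.panels.chroms[ci].chrom
                for h, hap in enumerate(chrom_tracts):
                    for s, e, k in hap:
                        fh.write(f"{name}\t{s}\t{e}\thap{h}_anc{k}\n")
        manifest = {
            "config": asdict(self.cfg),
            "realized_proportions": self.realized_proportions().tolist(),
            "g": self.cfg.g,
            "planted": [asdict(p) for p in self.planted],
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)


def _haps_to_sitetable(pc: PanelChrom, haps, prefix="s", names=None) -> SiteTable:
    n_hap, n_sites = haps.shape
    if n_hap % 2:
        raise ValueError("odd haplotype count cannot be paired into diploids")
    n_dip = n_hap // 2
    phased = haps.T.reshape(n_sites, n_dip, 2).astype(np.int8)
    if names is None:
        names = [f"{prefix}{i}" for i in range(n_dip)]
    return SiteTable(
        chrom=np.array([pc.chrom] * n_sites, dtype=object),
        pos=pc.pos_bp.copy(),
        ref=np.full(n_sites, "A", dtype="U1"),
        alt=np.full(n_sites, "G", dtype="U1"),
        info={},
        gt=phased.sum(axis=2).astype(np.int8),
        phased=phased,
        samples=list(names),
    )


def make_panels(cfg: SimConfig) -> Panels:
    """Draw site positions, source frequencies and panel haplotypes.

    Per site: ancestral frequency ~ Uniform(0.05, 0.95); each source's
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (exactly p when F = 0); panel
    haplotypes are Bernoulli draws from the source frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = []
    for ci in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.L_bp, size=cfg.n_sites, replace=False))
        p_anc = rng.uniform(0.05, 0.95, size=cfg.n_sites)
        freqs = np.empty((cfg.K, cfg.n_sites))
        for k in range(cfg.K):
            if cfg.F == 0:
                freqs[k] = p_anc
            else:
                scale = (1 - cfg.F) / cfg.F
                freqs[k] = rng.beta(p_anc * scale, (1 - p_anc) * scale)
        haps = (rng.random((cfg.K, cfg.n_ref, cfg.n_sites))
                < freqs[:, None, :]).astype(np.int8)
        chroms.append(PanelChrom(
            chrom=f"chr{ci + 1}",
            pos_bp=pos.astype(np.int64),
            p_anc=p_anc,
            freqs=freqs,
            haps=haps,
        ))
    return Panels(cfg=cfg, chroms=chroms)


def _draw_tracts(rng, cfg) -> list:
    """Tract breakpoints for one haploid chromosome: Poisson(g / Morgan)."""
    L = cfg.L_bp
    morgans_per_bp = cfg.cM_per_Mb / 1e6 / 100.0
    breaks = [0]
    x = 0.0
    while True:
        x += rng.exponential(1.0 / cfg.g) / morgans_per_bp
        if x >= L:
            break
        breaks.append(int(round(x)))
    breaks.append(L)
    ks = rng.choice(cfg.K, size=len(breaks) - 1, p=cfg.m)
    return [(breaks[i], breaks[i + 1], int(ks[i]))
            for i in range(len(breaks) - 1) if breaks[i + 1] > breaks[i]]


def simulate_cohort(cfg: SimConfig, panels: Panels) -> TruthSet:
    """Generate the admixed target cohort by mosaic copying from the panels."""
    rng = np.random.default_rng((cfg.seed, 1))
    all_haps, all_tracts = [], []
    for pc in panels.chroms:
        n_hap = 2 * cfg.n_adm
        haps = np.empty((n_hap, cfg.n_sites), dtype=np.int8)
        chrom_tracts = []
        for h in range(n_hap):
            tracts = _draw_tracts(rng, cfg)
            for s, e, k in tracts:
                sl = np.searchsorted(pc.pos_bp, [s, e])
                donor = rng.integers(cfg.n_ref)
                seg = pc.haps[k, donor, sl[0]:sl[1]]
                if cfg.eps > 0:
                    flip = rng.random(seg.shape) < cfg.eps
                    seg = np.where(flip, 1 - seg, seg)
                haps[h, sl[0]:sl[1]] = seg
            chrom_tracts.append(tracts)
        all_haps.append(haps)
        all_tracts.append(chrom_tracts)
    return TruthSet(cfg=cfg, panels=panels, target_haps=all_haps,
                    tracts=all_tracts)


def _retract(tracts, start, end, ancestry):
    """Overwrite the ancestry of [start, end) within one haplotype's tracts."""
    out = []
    for s, e, k in tracts:
        if e <= start or s >= end:
            out.append((s, e, k))
            continue
        if s < start:
            out.append((s, start, k))
        if e > end:
            out.append((end, e, k))
    out.append((start, end, ancestry))
    out.sort()
    merged = []
    for s, e, k in out:
        if merged and merged[-1][2] == k and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, k)
        else:
            merged.append((s, e, k))
    return [tuple(t) for t in merged]


def plant_features(truth: TruthSet, features) -> TruthSet:
    """Inject positive-control signals into an existing TruthSet (in place).

    kind="excess": fraction f of haplotypes re-copy [start, end) from the
    given ancestry. kind="sweep": fraction f of haplotypes are replaced by
    one donor haplotype over the interval. kind="roh": the listed diploids
    get identical haplotype pairs over the interval.
    """
    rng = np.random.default_rng((truth.cfg.seed, 2))
    chrom_names = [pc.chrom for pc in truth.panels.chroms]
    for feat in features:
        for other in truth.planted:
            if (other.chrom == feat.chrom and other.kind != feat.kind
                    and other.start < feat.end and feat.start < other.end):
                raise ValueError(
                    "overlapping planted features of different kinds")
        ci = chrom_names.index(feat.chrom)
        pc = truth.panels.chroms[ci]
        if not (0 <= feat.start < feat.end <= truth.cfg.L_bp):
            raise ValueError("planted interval outside chromosome")
        sl = np.searchsorted(pc.pos_bp, [feat.start, feat.end])
        haps = truth.target_haps[ci]
        n_hap = haps.shape[0]
        if feat.kind == "excess":
            n_pick = int(np.ceil(feat.f * n_hap))
            picks = rng.choice(n_hap, size=n_pick, replace=False)
            for h in picks:
                donor = rng.integers(truth.cfg.n_ref)
                haps[h, sl[0]:sl[1]] = pc.haps[feat.ancestry, donor,
                                               sl[0]:sl[1]]
                truth.tracts[ci][h] = _retract(
                    truth.tracts[ci][h], feat.start, feat.end, feat.ancestry)
        elif feat.kind == "sweep":
            donor = pc.haps[feat.ancestry, rng.integers(truth.cfg.n_ref),
                            sl[0]:sl[1]]
            n_pick = int(np.ceil(feat.f * n_hap))
            picks = rng.choice(n_hap, size=n_pick, replace=False)
            for h in picks:
                haps[h, sl[0]:sl[1]] = donor
        elif feat.kind == "roh":
            for d in feat.samples:
                haps[2 * d + 1, sl[0]:sl[1]] = haps[2 * d, sl[0]:sl[1]]
        else:
            raise ValueError(f"unknown feature kind {feat.kind!r}")
        truth.planted.append(feat)
    return truth
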