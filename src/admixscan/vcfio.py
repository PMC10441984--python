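"""VCF input/output, site filtering, and gene-context classification.

All internal coordinates are 0-based half-open; conversion to and from the
1-based coordinates of VCF and GFF3 happens only at the file boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR", "DP")

#: GATK-style hard-filter criteria: (INFO key, comparator, threshold).
#: A site failing ANY criterion is removed; a missing metric means the
#: criterion is not applied (GATK VariantFiltration behaviour).
HARD_FILTERS = (
    ("QD", "lt", 2.0),
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
    ("SOR", "gt", 3.0),
)

SITE_CLASSES = ("exonic", "UTR", "intronic", "upstream_downstream", "intergenic")


@dataclass
class SiteTable:
    """Biallelic SNP records with genotypes for a sample cohort.

    Attributes
    ----------
    chrom : array of str, one per site
    pos : int array, 0-based positions (strictly increasing within a chrom)
    ref, alt : single-base allele arrays
    info : dict mapping INFO keys to float arrays (NaN where absent)
    gt : (n_sites, n_samples) int8 alt-dosage matrix, -1 for missing
    phased : optional (n_sites, n_samples, 2) int8 ordered allele pairs
    samples : sample names, one per gt column
    n_skipped : records dropped on read (indels / multi-allelic)
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    info: dict
    gt: np.ndarray
    phased: np.ndarray | None
    samples: list
    n_skipped: int = 0

    def __post_init__(self):
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.phased is not None and self.gt.size:
            both = np.all(self.phased >= 0, axis=2)
            ds = self.phased.sum(axis=2)
            if not np.array_equal(ds[both], self.gt[both]):
                raise ValueError("dosage inconsistent with phased alleles")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "SiteTable":
        """Row-subset by boolean mask or index array."""
        return SiteTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            info={k: v[mask] for k, v in self.info.items()},
            gt=self.gt[mask],
            phased=None if self.phased is None else self.phased[mask],
            samples=list(self.samples),
            n_skipped=self.n_skipped,
        )

    def sample_indices(self, samples=None) -> np.ndarray:
        if samples is None:
            return np.arange(self.n_samples)
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[s] for s in samples], dtype=int)

    def haplotypes(self, samples=None) -> np.ndarray:
        """Return (2*n_samples, n_sites) phased haplotype matrix."""
        if self.phased is None:
            raise ValueError("table carries no phased genotypes")
        idx = self.sample_indices(samples)
        h = self.phased[:, idx, :]  # (sites, samples, 2)
        return h.transpose(1, 2, 0).reshape(2 * len(idx), self.n_sites)

    def alt_freq(self, samples=None) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing genotypes."""
        idx = self.sample_indices(samples)
        g = self.gt[:, idx].astype(float)
        g[g < 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=1) / 2.0


def read_phased_vcf(path, sample_subset=None, require_phased=True) -> SiteTable:
    """Read biallelic SNPs from a VCF 4.x file into a SiteTable.

    Indel and multi-allelic records are skipped and counted in
    ``n_skipped``. With ``require_phased`` an unphased non-homozygous
    genotype raises, naming the offending sample and site.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    if sample_subset is not None:
        missing = set(sample_subset) - set(vcf.samples)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)
    if sample_subset is not None and not samples:
        raise KeyError("no samples matched the requested subset")

    chroms, poss, refs, alts = [], [], [], []
    info = {k: [] for k in INFO_KEYS}
    gts, phs = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        for k in INFO_KEYS:
            val = v.INFO.get(k)
            info[k].append(np.nan if val is None else float(val))
        row_gt = np.full(len(samples), -1, dtype=np.int8)
        row_ph = np.full((len(samples), 2), -1, dtype=np.int8)
        for i, (a0, a1, phased) in enumerate(
            (g[0], g[1], g[2]) for g in v.genotypes
        ):
            if a0 < 0 or a1 < 0:
                continue
            row_gt[i] = a0 + a1
            if phased or a0 == a1:
                row_ph[i] = (a0, a1)
            elif require_phased:
                raise ValueError(
                    f"unphased heterozygote for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}"
                )
        gts.append(row_gt)
        phs.append(row_ph)

    n = len(poss)
    table = SiteTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype="U1"),
        alt=np.array(alts, dtype="U1"),
        info={k: np.array(v, dtype=float) for k, v in info.items()},
        gt=(np.array(gts, dtype=np.int8) if n else
            np.empty((0, len(samples)), dtype=np.int8)),
        phased=(np.array(phs, dtype=np.int8) if n else
                np.empty((0, len(samples), 2), dtype=np.int8))
        if require_phased else None,
        samples=samples,
        n_skipped=n_skipped,
    )
    return table


def write_vcf(table: SiteTable, path) -> None:
    """Write a SiteTable back to a VCF 4.2 text file (phased if available)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(table.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        for k in INFO_KEYS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(table.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for i in range(table.n_sites):
            parts = []
            for k in INFO_KEYS:
                v = table.info.get(k, None)
                if v is not None and np.isfinite(v[i]):
                    parts.append(f"{k}={v[i]:g}")
            info_s = ";".join(parts) or "."
            if table.phased is not None:
                def fmt(j):
                    a0, a1 = table.phased[i, j]
                    return "./." if a0 < 0 else f"{a0}|{a1}"
            else:
                def fmt(j):
                    d = table.gt[i, j]
                    return "./." if d < 0 else ["0/0", "0/1", "1/1"][d]
            gts = "\t".join(fmt(j) for j in range(table.n_samples))
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i] + 1}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t{info_s}\tGT\t{gts}\n"
            )


def apply_hard_filters(table: SiteTable, depth_bounds=(1 / 3, 3.0)) -> SiteTable:
    """Remove sites failing the GATK-style hard filters or the depth bounds.

    A site is dropped if any INFO criterion in :data:`HARD_FILTERS` fails
    (strict inequalities, exactly as printed), or if its depth falls below
    ``depth_bounds[0]`` times or above ``depth_bounds[1]`` times the
    cohort-mean depth. Missing metrics leave their criterion unapplied.
    """
    lo, hi = depth_bounds
    if lo < 0 or hi < 0:
        raise ValueError("depth bounds must be non-negative")
    keep = np.ones(table.n_sites, dtype=bool)
    for key, op, thr in HARD_FILTERS:
        v = table.info.get(key)
        if v is None:
            continue
        with np.errstate(invalid="ignore"):
            fail = (v < thr) if op == "lt" else (v > thr)
        keep &= ~(fail & np.isfinite(v))
    dp = table.info.get("DP")
    if dp is not None and np.isfinite(dp).any():
        mean_dp = np.nanmean(dp)
        with np.errstate(invalid="ignore"):
            fail = (dp < lo * mean_dp) | (dp > hi * mean_dp)
        keep &= ~(fail & np.isfinite(dp))
    return table.subset(keep)


@dataclass
class GeneModel:
    """Minimal transcript model: intervals 0-based half-open on one strand."""

    gene_id: str
    chrom: str
    strand: str
    transcript: tuple  # (start, end)
    exons: list = field(default_factory=list)  # [(start, end)]
    cds: list = field(default_factory=list)  # [(start, end, frame)]

    def __post_init__(self):
        ts, te = self.transcript
        for s, e in self.exons:
            if s < ts or e > te:
                raise ValueError(f"{self.gene_id}: exon outside transcript span")
        for s, e, _ in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS interval outside exons")


def read_gff3(path) -> list:
    """Parse gene models from a GFF3 file (gene/mRNA/exon/CDS features)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            for ex in db.children(t, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
            for c in db.children(t, featuretype="CDS"):
                frame = int(c.frame) if c.frame not in (None, ".") else 0
                cds.append((c.start - 1, c.end, frame))
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                transcript=(g.start - 1, g.end),
                exons=sorted(set(exons)),
                cds=sorted(set(cds)),
            )
        )
    return genes


def _in_any(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e, *_ in intervals)


def _cds_effect(site_pos, ref, alt, gene: GeneModel, ref_seq: str):
    """Classify a CDS substitution as synonymous or nonsynonymous.

    ``ref_seq`` is the full chromosome sequence (0-based). Returns None if
    the site is not inside a CDS interval of the gene.
    """
    cds_sorted = sorted(gene.cds)
    if gene.strand == "-":
        cds_order = cds_sorted[::-1]
    else:
        cds_order = cds_sorted
    # Build spliced CDS and locate the site within it
    offset, site_cds_idx = 0, None
    for s, e, _ in cds_order:
        if s <= site_pos < e:
            if gene.strand == "+":
                site_cds_idx = offset + (site_pos - s)
            else:
                site_cds_idx = offset + (e - 1 - site_pos)
        offset += e - s
    if site_cds_idx is None:
        return None
    frames = [f for s, e, f in cds_order]
    if frames and frames[0] not in (0,):
        site_cds_idx -= frames[0]
        if site_cds_idx < 0:
            return None
    seq = "".join(
        ref_seq[s:e] if gene.strand == "+"
        else str(Seq(ref_seq[s:e]).reverse_complement())
        for s, e, _ in cds_order
    )
    if frames and frames[0]:
        seq = seq[frames[0]:]
    codon_i = site_cds_idx // 3
    within = site_cds_idx % 3
    codon = seq[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:
        return None
    base = alt if gene.strand == "+" else str(Seq(alt).complement())
    mutant = codon[:within] + base + codon[within + 1:]
    ref_base = ref if gene.strand == "+" else str(Seq(ref).complement())
    if codon[within].upper() != ref_base.upper():
        raise ValueError(
            f"{gene.gene_id}: reference allele mismatch at {site_pos}"
        )
    same = Seq(codon).translate() == Seq(mutant).translate()
    return "synonymous" if same else "nonsynonymous"


def classify_sites(table: SiteTable, genes, flank_bp=1000, ref_seq=None):
    """Assign each site exactly one functional class.

    Precedence: exonic > UTR > intronic > upstream/downstream > intergenic.
    When CDS intervals (with frame) and a reference sequence are supplied,
    exonic sites falling in a CDS also get a synonymous/nonsynonymous effect
    in the returned ``effect`` array (None elsewhere).

    Returns ``(classes, effect)`` — two object arrays of length n_sites.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    for g in genes:
        seen = {}
        for s, e, f in g.cds:
            key = (s, e)
            if key in seen and seen[key] != f:
                raise ValueError(f"contradictory CDS frames in gene {g.gene_id}")
            seen[key] = f
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    classes = np.empty(table.n_sites, dtype=object)
    effect = np.full(table.n_sites, None, dtype=object)
    for i in range(table.n_sites):
        pos = int(table.pos[i])
        best = "intergenic"
        rank = {c: r for r, c in enumerate(SITE_CLASSES)}
        for g in by_chrom.get(table.chrom[i], []):
            ts, te = g.transcript
            if ts <= pos < te:
                if _in_any(pos, g.exons):
                    if _in_any(pos, g.cds):
                        cls = "exonic"
                        if ref_seq is not None:
                            seq = ref_seq[g.chrom] if isinstance(ref_seq, dict) else ref_seq
                            eff = _cds_effect(pos, table.ref[i], table.alt[i], g, seq)
                            if eff is not None:
                                effect[i] = eff
                    elif g.cds:
                        cls = "UTR"
                    else:
                        cls = "exonic"
                else:
                    cls = "intronic"
            elif ts - flank_bp <= pos < te + flank_bp:
                cls = "upstream_downstream"
            else:
                continue
            if rank[cls] < rank[best]:
                best = cls
        classes[i] = best
    return classes, effect
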