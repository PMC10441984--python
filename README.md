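# admixscan

Admixture-aware population genomics for phased SNP data: local-ancestry
painting against labelled reference panels, ancestry-excess segment
testing, composite selection scans, ROH/LD/kinship diagnostics, and
single-pulse admixture dating — with a bundled simulator of admixed
cohorts so every stage can be exercised end-to-end with known truth.

The package is aimed at analyses of hybrid populations such as crosses
between the two domestic cattle lineages (*Bos taurus taurus* ×
*Bos taurus indicus*), where the questions are: *which* ancestral
lineage contributed each genomic segment, *when* the mixing happened,
and *which* regions were subsequently favoured by selection.

## What it computes

**Local ancestry.** Each admixed haplotype is modelled as a mosaic copy
of reference-panel haplotypes. A dynamic program charges 1 per allele
mismatch and a penalty λ per template switch; the ancestry call at a
site is the panel label of the copied template, majority-voted over
λ ∈ {1, 1.5, 2, 3, 5}. Genome-wide ancestry proportions are
tract-length-weighted shares.

**Ancestry-excess segments.** The genome is partitioned at every
position where any haplotype's ancestry call changes. For a segment
where *x* of 2*N* haplotypes carry ancestry *a* with genome-wide
proportion *p<sub>a</sub>*,

> Z = (x/2N − p_a) / √(p_a(1 − p_a)/2N)

one-sided; segments with frequency ≥ 0.75, length ≥ 1 kb and P < 0.01
are reported as high-frequency ancestral fragments.

**Admixture dating.** After a single pulse *g* generations ago,
ancestry-driven LD between sites at genetic distance *d* Morgans decays
as e<sup>−gd</sup>. The weighted-LD statistic — genotype covariance
weighted by the product of inter-source allele-frequency differences —
is binned by distance and fitted with A·e<sup>−nd</sup> + c; n̂ is the
pulse age, with a leave-one-chromosome-out jackknife SE. A tract-length
moment estimator, ĝ = 1/((1 − m_a)·L̄_a), provides a cross-check.

**Selection scans.** Windowed nucleotide diversity π, Tajima's D,
θπ-ratio (ln π_target − ln π_reference), Weir–Cockerham F_ST
(ratio-of-sums), per-SNP standardized iHS from integrated EHH, and a
SweepFinder-style composite likelihood ratio against the genome-wide
SFS. Windows in the empirical top 1% of two or more scans are merged
into candidate selection regions.

**Diagnostics.** PLINK window-rule ROH detection, LD decay with
half-decay distance, and KING-robust kinship with degree classes.

**Simulator.** K source populations diverge under the Balding–Nichols
model at tunable F_ST; an admixed cohort arises from one pulse with
mixing proportions m and exponential ancestry-tract lengths (rate g per
Morgan); haplotypes copy panel members with a per-site error rate.
Sweeps, ancestry-excess intervals and autozygous segments can be
planted as positive controls.

## Worked example

```sh
python examples/date_admixture.py
```

```text
true pulse age: 38.0 generations
fitted:         38.05 +/- 3.31 (95% CI 31.6-44.5, flag=ok)
```

A two-way 60/40 cohort simulated with a pulse 38 generations ago is
dated from its weighted-LD decay: the fitted decay rate (in
generations) brackets the truth within the jackknife interval.

```sh
python examples/selection_scan.py
```

```text
4 candidate region(s) in the top 1% of both scans:
chrom    start      end methods
 chr1 20000000 20150000 clr,ihs
 chr1 20200000 20300000 clr,ihs
 chr1 20350000 20400000 clr,ihs
 chr1 20500000 20600000 clr,ihs
planted sweep interval: chr1 20,000,000-20,600,000
```

All candidate regions fall inside the planted 600-kb partial sweep:
the haplotype-based (|iHS|) and SFS-based (CLR) scans agree on the
control signal. `examples/simulate_and_paint.py` and
`examples/roh_and_kinship.py` demonstrate painting/proportion recovery
and the ROH/LD/kinship diagnostics the same way.

A one-command end-to-end run on a bundled scenario:

```sh
admixscan demo --seed 1 --out demo_out
```

writes tract BEDs, excess-segment and scan TSVs, candidate regions and
a `summary.json` (global proportions, dated pulse age, candidate
count); identical seeds give byte-identical outputs.

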