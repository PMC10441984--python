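# Methods

This note records the models behind each stage, the defaults and why,
the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Coordinate and data conventions

All internal coordinates are 0-based half-open; VCF (1-based) and GFF3
conversion happens only at the file boundary. The in-memory container
is a `SiteTable`: biallelic SNPs with INFO metrics, an alt-dosage
matrix, and (when phased) ordered allele pairs whose sum must equal the
dosage. Window grids anchor at position 0 of each chromosome with the
last partial window kept and flagged, so grids from different
statistics join exactly.

## Site filtering and classification

Hard filters follow the GATK convention: a site is removed when
QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0 or SOR > 3.0 (strict inequalities, exactly as
printed), or when its depth falls below 1/3× or above 3× the
cohort-mean depth. A missing INFO metric leaves its criterion
unapplied, matching how GATK VariantFiltration treats absent
annotations, and the filter is idempotent.

Gene-context classes are assigned with the precedence
exonic > UTR > intronic > upstream/downstream > intergenic; the
up/downstream flank is 1,000 bp (the common annotation-tool
convention). When a site hits several transcripts the highest-
precedence class wins — annotation tools differ here, so the rule is
fixed and stated rather than inferred. With CDS intervals, frames and a
reference sequence, coding substitutions are translated (standard
codon table, strand-aware) into synonymous/nonsynonymous calls; the
missense screen keeps nonsynonymous sites with alternate-allele
frequency > 0.7 in the target population and < 0.2 in the reference
population. The published screen phrases both cut-offs as "MAF", which
cannot literally exceed 0.5; alternate-allele frequency is the reading
implemented.

## Synthetic cohorts

`SimConfig` defaults: K = 4 sources at Balding–Nichols divergence
F = 0.2 (strongly diverged lineages, e.g. taurine vs indicine groups),
n_ref = 30 haplotypes per panel, n_adm = 30 diploids, one 50-Mb
chromosome with 20,000 SNPs at a constant 1 cM/Mb, mixing proportions
m = (0.556, 0.332, 0.068, 0.044) — a dominant and a secondary source
plus two trace sources, the admixture makeup the package is designed
around — a single pulse g = 38.27 generations ago, and a per-site
copy-error rate of 0.001 (roughly genotyping/mutation noise).

Per site, the ancestral frequency is Uniform(0.05, 0.95) and each
source's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) (exactly p when
F = 0); panel haplotypes are Bernoulli draws. Admixed haplotypes take
tract breakpoints from a Poisson process of rate g per Morgan, draw
each tract's ancestry independently from m, and copy one uniformly
chosen panel haplotype of that ancestry with error rate eps.
`TruthSet.tracts` stores the raw Poisson segments; consecutive
same-ancestry segments are therefore separate entries (their mean
length is 1/g Morgans), and consumers that need maximal same-ancestry
runs (the tract-length dater) merge them first.

What the generator does **not** emulate: within-source haplotype
structure (sites are in linkage equilibrium given the source
frequencies, so there is no short-range background LD and the only LD
in the target is admixture LD plus founder sharing), post-admixture
drift, phase error, and realistic SFS shape (site frequencies are
intermediate-heavy rather than neutral-coalescent). Consequently,
passing tests demonstrate correct recovery of the admixture signal
under the stated model — not performance under background LD or
phasing noise. Because the cohort copies from a finite founder panel,
cohort members can show genuine founder-sharing kinship; the KING
calibration tests therefore use independent panel draws.

Planted features are positive controls: "excess" re-copies an interval
from one ancestry's panel into a fraction f of haplotypes, "sweep"
replaces a fraction f of haplotypes with a single donor haplotype, and
"roh" makes a diploid's two haplotypes identical over the interval.

## Local ancestry painting

The painter solves min-cost mosaic copying over all reference
haplotypes: per-site cost 1 for an allele mismatch, λ per template
switch, optimum by Viterbi-style dynamic programming with exact
traceback (the switch-cost structure lets the minimization over
predecessors collapse to a single argmin per site, so the DP is
O(sites × references)). Calls from λ ∈ {1, 1.5, 2, 3, 5} are combined
by per-site majority vote, ties resolving to the smallest λ; the vote
makes calls robust to the penalty choice, in the bagging spirit of
reference-copying painters. Adding references can only lower the
optimum. Phase error is not modelled: input is assumed correctly
phased (the simulator's phase is exact).

Tract bp bounds use the midpoint convention between flanking
informative sites, extended to the chromosome ends, so tracts and
excess segments tile the chromosome exactly and bp-weighted
proportions are well defined.

## Ancestry-excess test

Segments are maximal intervals over which the cohort's per-site
ancestry-count vector is constant. Each (segment, ancestry) pair gets a
one-sided Z test of the haplotype frequency against the genome-wide
proportion (binomial normal approximation, no multiple-testing
correction, matching the raw P < 0.01 convention); retained fragments
additionally need frequency ≥ 0.75 and length ≥ 1,000 bp. At 2N = 60
haplotypes the test is conservative (the discrete binomial tail under
a plug-in genome-wide proportion gives an achieved type-I rate below
the nominal 1%), which the pooled null-replicate test in the suite
measures. Segment-level hits are strongly autocorrelated along the
genome — the count vector is a slowly mixing random walk — so null
calibration is only meaningful pooled over replicate cohorts.

## Selection statistics

* **π**: per-site 2j(n−j)/(n(n−1)) summed over a 50-kb window with
  20-kb step and divided by window length (per-bp diversity).
* **Tajima's D**: standard constants, 2-kb nonoverlapping windows,
  NaN where S = 0; per-window n is the minimum observed haplotype
  count; sites with fewer than 4 observed haplotypes are dropped.
* **θπ-ratio**: ln π_target − ln π_reference on the π grid; NaN where
  either π is 0.
* **F_ST**: two-population diploid Weir–Cockerham components with
  ratio-of-sums aggregation (the "weighted" convention); negative
  values retained.
* **iHS**: EHH per core allele by incremental haplotype-group
  refinement, truncated at EHH < 0.05 or a gap > 200 kb (standard
  scan defaults, stated since the source pipeline leaves them
  implicit); iHH by trapezoidal integration over genetic distance;
  iHS = ln(iHH_A/iHH_D) standardized within derived-frequency bins of
  width 0.05; cores below 5% derived frequency (or with < 2 carriers)
  skipped. Window summaries on the 50-kb CLR grid: mean |iHS|
  (primary) and the fraction of |iHS| > 2 (alternate) — both are
  emitted because the summary statistic is a genuine free choice.
* **CLR**: the background SFS is the genome-wide frequency-class
  distribution (add-one smoothing for empty classes). The sweep model
  is a one-parameter escape process: each sampled lineage escapes the
  sweep independently with probability e = 1 − exp(−α·d); a
  non-escaping lineage carries the sweeping haplotype's allele
  (derived with the background class frequency). Marginalizing over
  the background SFS and re-conditioning on polymorphism gives the
  distorted spectrum; the CLR at a test point is
  2(max_α log L_sweep − log L_background) with α over a log grid of
  21 values in [1, 10⁵] per Morgan plus the exact-background member,
  which nests the null and keeps CLR ≥ 0. Scans precompute the
  spectrum on a 64-point escape-probability grid (nearest lookup);
  small inputs and oracles use the exact per-site spectrum. Window
  value = max over 4 evenly spaced test points per 50-kb window.
* **Intersection**: per scan, upper-tail empirical ranks; scans are
  resampled to the coarsest grid by maximal overlap; a window is a
  candidate when ranked within the top 1% in at least two scans, and
  adjacent candidates merge. Ranking refuses scans with fewer than
  100 windows (empirical quantiles too unstable). Empirical ranks
  stand in for "P < 0.01" throughout, since no parametric null is
  available for these statistics.

## ROH, LD decay, kinship

ROH follows the PLINK window rule with the published parameter set
(window-snp 100, density 200 kb/SNP, window-het 1, min 100 kb,
window-threshold 0.05): windows of 100 consecutive SNPs are
"homozygous" with ≤ 1 heterozygous call; a SNP's hit fraction is the
homozygous share of windows covering it; SNPs at fraction ≥ 0.05 form
runs, filtered by length and density.

LD decay is mean genotype-correlation r² per physical-distance bin;
the half-decay distance is where the curve first reaches half its
maximum, linearly interpolated. Independent sites leave a sampling
floor of about 1/(n_ind − 1), so a curve that never falls to half its
maximum returns NaN rather than an extrapolation.

KING-robust kinship: φ = (N_het,het − 2·N_opp-hom)/(N_het,i + N_het,j)
over jointly observed sites, with degree classes at the published
thresholds 0.3536/0.1768/0.0884; pairs with < 100 joint sites are NaN.

## Admixture dating

The weighted-LD statistic for a site pair is the cross-individual
covariance of target dosages weighted by (p_A − p_B) at both sites,
with panel frequencies computed once from the reference panels (the
target never enters the weights, and swapping panels leaves the
product unchanged). Pairs are binned at 0.05 cM up to 10 cM; bins with
fewer than 50 pairs are dropped; the fit A·e^(−n·d) + c runs on bins
≥ 0.5 cM (excluding short-range background LD, the standard practice)
by bounded nonlinear least squares with n ∈ [0, 5000]. The amplitude
is treated as free, so no ALDER-style normalization of the statistic
is needed; a non-positive fitted amplitude flags "no dateable
admixture". The SE is a leave-one-chromosome-out jackknife (refit per
deletion); with one chromosome it is NaN. The tract-length
cross-check merges adjacent same-ancestry tracts into maximal runs,
drops chromosome-end-censored runs, and applies
ĝ = 1/((1 − m_a)·L̄_a) with L̄ in Morgans.

## Problem sizes and reproducibility

The bundled experiments run at desk scale: recovery of the 4-way
mixing proportions paints 60 haplotypes over four 50-Mb chromosomes of
20,000 SNPs each (four chromosomes keep the cohort's
realized-proportion sampling noise, SD ≈ 0.01 per component, well
inside the ±0.03 recovery band); dating uses ten 50-Mb chromosomes.
All randomness flows from a single integer seed through
`numpy.random.default_rng`, and the end-to-end demo is byte-identical
across runs with the same seed.

## Known limitations

Single-pulse, two-reference dating only (no multi-pulse models); no
probabilistic (posterior) local ancestry or phase-error correction; no
XP-EHH/nSL; empirical ranks rather than calibrated P values for the
selection scans; the CLR is a desk-scale composite-likelihood model,
not a numerical clone of SweepFinder2; and the simulator's linkage
equilibrium within sources means background-LD robustness is untested
by construction.
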