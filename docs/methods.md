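# Methods

`rohscan` implements a whole-genome autozygosity analysis for diploid SNP
genotype data: runs-of-homozygosity (ROH) detection, pedigree and genomic
inbreeding coefficients, ROH island and cold-spot discovery, an EHH/iHS
selection scan on phased haplotypes, and LD-decay effective-population-size
estimation.  A transmission simulator with exact identity-by-descent (IBD)
ground truth makes every stage testable without external data.

## ROH detection

The caller reproduces the classic sliding-window recipe popularized by
PLINK's `--homozyg`:

1. slide a window of `window_snps` (50) SNPs one SNP at a time along each
   chromosome and individual; a window is *homozygous* if it contains at most
   `window_max_het` (1) heterozygous and `window_max_missing` (5) missing
   calls;
2. a SNP is ROH-eligible if at least `window_hit_fraction` (5%) of the
   windows containing it are homozygous; SNPs within a window length of a
   chromosome end are judged on the windows that actually exist;
3. maximal runs of eligible SNPs become candidates, split where adjacent
   SNPs are more than `max_gap_kb` (1000) apart;
4. candidates are kept if they contain ≥ `min_snps` (100) SNPs, span ≥
   `min_length_kb` (1000), and average ≤ `max_kb_per_snp` (50) per SNP.

Segment endpoints are the positions of the first and last eligible SNP, so
heterozygous calls can sit inside an emitted segment (that is the point of
the window allowance: tolerance to genotyping error).  The defaults are the
PLINK v1.07 defaults; every knob is exposed in `ROHParams`.  Two edge
behaviours are deliberate, documented choices because no published text pins
them down: edge SNPs use only realizable windows, and runs are never bridged
across a sub-threshold SNP.  A 1 Mb minimum at ~1 cM/Mb targets inbreeding up
to ~50 ancestral generations, since an IBD segment from an ancestor `g`
generations back has expected genetic length 1/(2g) Morgan
(`expected_roh_length`).

`call_roh_exact` re-derives the same definition with explicit per-window
enumeration in plain loops (no prefix-sum vectorization) and exists purely as
an independent cross-check; the test suite asserts segment-set equality on
randomized planted datasets.

## Inbreeding coefficients

* **F_PED** — recursive kinship (tabular method) with memoization:
  kinship(a,a) = (1+F(a))/2, kinship(a,b) descends the younger individual,
  unknown parents contribute 0.  F(x) = kinship(sire, dam).  An independent
  Monte-Carlo allele-drop oracle lives in the tests.
* **F_ROH** = L_ROH / L_auto, optionally restricted to a length class
  (1–5 Mb, 5–10 Mb, >10 Mb; classes are additive to machine precision).
  `l_auto_bp` defaults to the SNP-covered span, sum over chromosomes of
  (max − min + 1), and is user-overridable because published analyses often
  use a fixed genome length for the denominator.
* **F_SNP1–3** — variance of additive genotypes, excess homozygosity, and
  correlation of uniting gametes, computed marker-by-marker against
  current-sample allele frequencies.  Monomorphic SNPs are excluded (h = 0);
  per sample, missing calls are skipped with n reduced.  These estimators are
  centred on the current population and can be negative; under
  Hardy-Weinberg sampling all three average zero (verified at n = 500,
  m = 5000 within ±0.01).

The eight coefficients are assembled per sample and compared by Pearson
correlation over complete cases.  On planted-homozygosity data the two
homozygosity-driven estimators (F_SNP2, and F_SNP3 which blends the same
signal) track F_ROH far better than the additive-variance estimator F_SNP1,
which the tests assert as a qualitative invariant; the finer ordering
between F_SNP2 and F_SNP3 is seed-dependent under the synthetic generator
and is not asserted — on real data it is shaped by the allele-frequency
spectrum, which the generator idealizes.  A related algebraic fact worth
knowing: with in-sample allele frequencies and complete data, the
*population means* of the three estimators are identical, so they separate
only in how they rank individuals.

## Islands and cold-spots

Per SNP, incidence = number of individuals with ≥ 1 ROH spanning the
position.  The island threshold is the empirical order statistic at rank
⌈(1 − f)·m⌉ (f = 0.005 by default) with ties kept, so at least ⌈f·m⌉ SNPs
always qualify; maximal runs of strictly map-adjacent island SNPs merge into
regions.  Cold-spots are maximal runs of zero-incidence SNPs, reported by
span descending.  A constant incidence track is rejected as degenerate
rather than thresholded arbitrarily.

## EHH / iHS

EHH(x) = Σ_h C(n_h,2)/C(n_c,2) over distinct extended haplotypes among the
n_c carriers of a core allele, computed outward in both directions.  iHH is
the trapezoidal integral of EHH over genetic distance (constant cM/Mb map,
default 1), truncated at the EHH cutoff (0.05) with linear interpolation to
the crossing.  The raw score ln(iHH_A/iHH_D) is standardized to mean 0/sd 1
within derived-allele-frequency bins of width 0.05 (bins with fewer than 10
scored SNPs stay unstandardized), and transformed to
p_iHS = −log10(1 − 2|Φ(iHS) − 0.5|); |iHS| > Φ⁻¹(1 − 0.005/2) = 2.81 flags
candidates at two-sided p < 0.005.

Choices where the field varies: the ancestral allele comes from the map's
`anc_allele` (synthetic truth, or a VCF `AA` tag); if absent the major
allele is used with a loud warning, which makes signs unreliable but leaves
|iHS| usable.  SNPs whose EHH reaches a chromosome end above the cutoff are
flagged truncated and excluded by default.  Within-bin standardization is
exact on the fit set, and swapping allele labels negates the raw score
exactly — both are asserted.  Under neutral, exchangeable haplotypes the
fraction of |iHS| > 2.81 is ~0.5% (tested at ≥ 5000 scored SNPs, ±0.4%).

## LD and Ne

Composite LD: r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples — the haplotype-free measure genotype toolkits
default to.  The sample-size adjustment subtracts 1/(β·n) (β = 2 unphased,
1 phased), floored at 0.  Pairs are enumerated within chromosomes up to a
distance cap, optionally subsampled per left SNP (seeded) for runtime, and
binned by physical distance (default 50 log-spaced bins over 50 kb–10 Mb;
no published binning exists to copy, so the default is documented rather
than inferred).

Each bin's midpoint distance maps to a recombination fraction c through
Haldane's function c = (1 − e^(−2d))/2 (options: Sved & Feldman hyperbolic
c = d/(1+2d), or linear).  Ne per bin inverts Sved's drift-recombination
expectation E[r²_adj] = 1/(α + 4 Ne c):

    Ne(t) = (4c)⁻¹ (1/r²_adj − α),   t = 1/(2c)

with α = 1 (drift only; 2 and 2.2 add a mutation correction).  Bins with
non-positive adjusted LD are kept but flagged undefined.  The estimator is
exact by construction on bins generated from the expectation itself, which
the tests verify to machine precision at planted Ne of 88 and 3018.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale (a few chromosomes of 10–100 Mb rather than a 2.26 Gb genome):

* **Map** — one SNP per 13.6 kb (jittered), biallelic, MAF ≥ 0.05.
* **Founder LD** — a first-order copying process: each haplotype copies its
  previous SNP's allele with probability ρ, else draws fresh from the site
  frequency (uniform in the MAF range).  Adjacent-site correlation ≈ ρ
  decays geometrically with SNP separation.  Columns drifting outside the
  declared MAF bounds are repaired by flipping the minimal number of random
  alleles.  This is deliberately *not* a coalescent: it gives tunable,
  decaying LD with reproducible seeds, but its decay shape and its
  relationship between LD and any "true" Ne are not population-genetically
  calibrated — which is why the Ne stage is validated by analytic round-trip
  rather than by simulation accuracy.
* **Gene drop** — founders receive two pool haplotypes; every transmission
  recombines with a Poisson(chromosome length in Morgan) number of
  crossovers placed uniformly (Haldane, no interference) at a constant
  1 cM/Mb.  Founder-haplotype origin is tracked per segment; true autozygous
  tracts are maximal runs where an individual's two copies share an origin,
  so E[f_true] equals the pedigree inbreeding coefficient (verified for
  selfing, 0.5, and full sibs, 0.25, over 500 replicates).
* **plant_roh** — direct tract planting for calibration: per individual,
  tracts (exponential lengths, mean 4.11 Mb, floored at 1 Mb — the observed
  segment-length scale of livestock sequence data) are placed at random SNP
  positions until the target fraction is reached.  The final tract is
  clipped to the remaining deficit (never below the minimum), and placement
  stops when the deficit falls under half the minimum tract, so realized
  fractions track targets within ~1% at 150 Mb genomes.  Heterozygous sites
  inside a tract collapse onto one allele drawn with probability equal to
  the allele dosage/2, i.e. copying one of the individual's own gametes —
  this preserves allele frequencies in expectation.
* **plant_sweep** — a fraction of haplotypes is overwritten with one shared
  core around a focal SNP, the textbook footprint iHS is designed to find.
* **inject_noise** — independent missingness and homozygote→heterozygote
  miscalls, the error mode the ROH window allowance exists to absorb.

What the generator does **not** emulate: mutation, crossover interference,
realistic site-frequency spectra, demography-shaped LD, sex chromosomes, or
genotype-calling error correlated along reads.  Passing tests therefore
demonstrate the correctness of the algorithms and their calibration under
idealized conditions, not expected performance on any particular real
population.

## QC and conventions

Marker QC follows livestock sequence-data practice: MAF ≥ 0.05, per-variant
call rate strictly > 0.30 (the permissive threshold is applied per variant;
a per-sample call-rate vector is reported so users can screen samples
separately), autosomes only.  MAF uses non-missing calls.  Internal
coordinates are 1-based inclusive; BED export is 0-based half-open.  All
generators and subsampling accept seeds and are bit-reproducible; the
pipeline rerun under one seed/config produces byte-identical outputs.

## Problem sizes

The test suite and the acceptance script use desk-scale problems chosen to
make the Monte-Carlo tolerances meaningful: 50-individual × ~5000-SNP
datasets (100 replicates) for caller/oracle equivalence, 150 individuals
across three planted fractions for F_ROH recovery, 500 gene-drop replicates
for pedigree expectations, 500 × 5000 Hardy-Weinberg genotypes for the
F_SNP null, and ~5600 scored SNPs on 100 neutral haplotypes for iHS
calibration.
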