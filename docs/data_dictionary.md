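# Output data dictionary

All pipeline outputs are tab-separated text (TSV), BED3, YAML or JSON under
the configured output directory.  Coordinates are 1-based inclusive bp
except in BED files (0-based half-open).

## roh_segments.tsv — one row per called ROH
| column | meaning |
|---|---|
| sample | individual id |
| chrom | chromosome label |
| start_bp / end_bp | positions of the first/last eligible SNP of the segment |
| n_snps | SNPs inside the segment |
| length_bp | end_bp − start_bp + 1 |
| length_class | `1-5`, `5-10` or `>10` (Mb) |

`roh_segments.bed` is the same set as BED3.

## roh_summary.tsv — per length class (+ Total row)
| column | meaning |
|---|---|
| length_class | class label |
| count | number of segments |
| pct_of_count | 100 × count / all segments |
| mean_mb / sd_mb | segment length mean and sd (Mb) |
| coverage_pct | 100 × Σ class length / (n_samples × l_auto_bp) |

## inbreeding.tsv — one row per sample
`f_ped` (pedigree kinship of parents), `f_roh_1_5`, `f_roh_5_10`,
`f_roh_gt10`, `f_roh_all` (length-class F_ROH; the parts sum to the total),
`f_snp1`, `f_snp2`, `f_snp3` (marker-based estimators; may be negative).
`inbreeding_summary.tsv`: mean/min/max/sd/n per column.
`inbreeding_correlations.tsv`: Pearson matrix over complete cases.

## roh_incidence.tsv — one row per QC-passing SNP
| column | meaning |
|---|---|
| chrom, pos_bp | SNP position |
| count | individuals with ≥1 ROH covering the SNP |
| proportion | count / n_samples |

## roh_islands.tsv
| column | meaning |
|---|---|
| chrom, start_bp, end_bp | island bounds (positions of SNPs) |
| length_bp | end − start + 1 |
| mean_abs_ihs | mean \|standardized iHS\| of scored SNPs inside (empty if no scan) |
| n_snps | island SNPs |

`roh_islands.bed`: the same regions as BED3.

## roh_coldspots.tsv
chrom, start_bp, end_bp, n_snps, span_bp — maximal zero-incidence runs,
sorted by span descending.

## ihs.tsv — one row per scanned SNP
| column | meaning |
|---|---|
| chrom, pos_bp, index | SNP position and column index |
| daf | derived-allele frequency |
| ihh_a / ihh_d | integrated EHH for ancestral/derived allele (Morgan) |
| ihs_raw | ln(ihh_a / ihh_d) |
| ihs_std | within-frequency-bin standardized score |
| p_ihs | −log10 two-sided normal p-value of ihs_std |
| flag | empty, `truncated` (chromosome end hit above the EHH cutoff) or `skipped` |

## ld_decay.tsv — one row per distance bin
dist_lo_bp, dist_hi_bp, mean_r2 (raw composite r²), mean_r2adj
(sample-size-adjusted), n_pairs, c_t (recombination fraction of the bin
midpoint under the configured map function).

## ne_trajectory.tsv — one row per usable bin
t_gen (generations ago, 1/(2c)), ne (point estimate; empty if undefined),
c_t, mean_r2adj, n_pairs, defined (boolean).

## heterozygosity.json
ho_mean/ho_sd/he_mean/he_sd — unweighted across-SNP mean ± sd of observed
and expected heterozygosity.

## Simulation outputs
`simulated.vcf` — genotypes (GT only, `AA` INFO tag for the ancestral
allele).  `truth_tracts.tsv`: sample, chrom, start_bp, end_bp, origin
(founder haplotype id; −1 for directly planted tracts).  `truth_f.tsv`:
sample, f_true (true autozygous fraction).

## Run metadata
`config_echo.yaml` — the exact configuration used; `run.log` — timestamped
log with package version, seed and stage progress.
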