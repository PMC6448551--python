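"""ROH islands and cold-spots from per-SNP ROH incidence.

Plants one 2 Mb window shared by 80% of individuals on top of ~10% random
background autozygosity.  The incidence track counts how many individuals
carry a ROH over each SNP; the top 0.5% of SNPs merge into islands
(candidate selection footprints) and zero-incidence runs are cold-spots.
"""

import numpy as np

import rohscan as rs

vmap, cl = rs.make_map({"1": 60_000_000}, seed=11)
pool = rs.sample_founders(50, vmap, rho=0.8, seed=12, chrom_lengths=cl)
base = rs.diploids_from_pool(pool, 50, seed=13)
ds, _ = rs.plant_roh(base, 0.10, seed=14)

# overwrite a shared homozygous window at 20-22 Mb in 40/50 individuals
calls = ds.calls.copy()
pos = vmap.pos_bp
lo, hi = np.searchsorted(pos, [20_000_000, 22_000_000])
carriers = np.random.default_rng(15).choice(50, 40, replace=False)
calls[carriers[:, None], np.arange(lo, hi)] = 2 * pool.haplotypes[0, lo:hi].astype(np.int8)
ds = rs.GenotypeDataset(ds.samples, vmap, calls, ds.l_auto_override_bp)

rohset = rs.call_roh(ds)
track = rs.snp_roh_incidence(rohset, vmap, ds.n_samples)
islands, threshold = rs.detect_islands(track, top_fraction=0.005)
print(f"island threshold: a SNP must lie in a ROH in "
      f">= {100*threshold:.0f}% of individuals")
for isl in islands:
    print(f"  island chr{isl.chrom}:{isl.start_bp}-{isl.end_bp} "
          f"({isl.length_bp/1e6:.2f} Mb, {isl.n_snps} SNPs)")

cold = rs.detect_coldspots(track)
print(f"\n{len(cold)} cold-spots; longest spans "
      f"{cold.iloc[0].span_bp/1e6:.2f} Mb ({cold.iloc[0].n_snps} SNPs) — "
      "regions never autozygous in any individual")
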