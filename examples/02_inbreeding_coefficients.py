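"""Eight inbreeding coefficients on one dataset and their correlations.

Gene-drops founder haplotypes through a small inbred pedigree so that
pedigree (F_PED), ROH-based (F_ROH by length class) and marker-based
(F_SNP1-3) coefficients can all be computed on the same individuals.
F_PED for full-sib offspring is exactly 0.25; the genomic coefficients
scatter around it because recombination makes realized autozygosity vary.
"""

import numpy as np

import rohscan as rs
from rohscan.io import Pedigree

# founders F0..F9; two generations of full-sib-ish matings
rng = np.random.default_rng(5)
records = {f"F{i}": (None, None) for i in range(10)}
for k in range(15):
    s, d = rng.choice([f"F{i}" for i in range(10)], 2, replace=False)
    records[f"G1_{k}"] = (s, d)
for k in range(20):
    s, d = rng.choice([f"G1_{i}" for i in range(15)], 2, replace=False)
    records[f"G2_{k}"] = (s, d)
ped = Pedigree(records)

vmap, cl = rs.make_map({"1": 80_000_000, "2": 80_000_000}, seed=6)
pool = rs.sample_founders(10, vmap, rho=0.8, seed=7, chrom_lengths=cl)
ds, truth = rs.gene_drop(ped, pool, seed=8)

rohset = rs.call_roh(ds)
table = rs.inbreeding_table(ds, rohset, ped=ped)
print("per-sample coefficients (last generation):")
print(table.tail(5).round(3))
print("\nPearson correlations between the eight coefficients:")
print(rs.inbreeding_correlations(table).round(2))
print("\nr(true autozygosity, F_ROH_all):",
      round(float(np.corrcoef(truth.f_true[ds.samples],
                              table['f_roh_all'])[0, 1]), 3))
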