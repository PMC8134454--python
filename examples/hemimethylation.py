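"""Hairpin-bisulfite hemimethylation analysis with UMI deduplication.

Simulates hairpin-ligated strand pairs (both strands of each molecule in one
read, UMI in the loop, PCR duplicates, UMI sequencing errors), clusters UMIs
with the directional rule, collapses duplicates and quantifies per-CpG
strand discordance.
"""

import numpy as np

import methdrift as md

cfg = md.SimConfig(seed=3, reads_per_sample=5000, hemi_rate=0.1,
                   pcr_duplication_mean=5.0, umi_error_rate=0.01)
amp = md.random_amplicon("DOK6_like", 7, seed=3)
sim = md.simulate_hairpin(cfg, amp, passage=10)
print(f"library: {sim.n_molecules} molecules -> {len(sim.reads)} PCR-amplified reads")

counts: dict[str, int] = {}
for r in sim.reads:
    counts[r.umi] = counts.get(r.umi, 0) + 1
clusters = md.cluster_umis(counts, max_mismatch=1)
deduped = md.dedupe_by_umi(sim.reads, clusters)
print(f"directional UMI clustering: {len(counts)} distinct UMIs -> "
      f"{len(clusters)} clusters ({len(deduped)} consensus molecules)")

rates = md.hemimethylation_rates(deduped)
print("\nper-CpG hemimethylation after dedupe (true strand-flip rate 0.10):")
for i, row in rates.iterrows():
    print(f"  CpG {i}: rate {row['rate']:.3f}  "
          f"(mm {int(row['n_mm'])}, uu {int(row['n_uu'])}, "
          f"discordant {int(row['n_discordant'])})")
print(f"  mean {rates['rate'].mean():.3f}")
# Discordant dyads (methylated on one strand only) recover the simulated
# 10% hemimethylation despite ~5x PCR duplication and 1% UMI errors - the
# UMI consensus removes amplification bias before counting molecules.
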