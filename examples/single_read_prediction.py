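"""Single-read passage prediction and drift-vs-writer discrimination.

Simulates bisulfite amplicon reads over a 9-CpG amplicon, fits per-CpG
methylation-vs-passage lines on training samples, assigns each held-out read
its maximum-likelihood passage on the integer grid 0..50, and contrasts the
neighbor-correlation structure of independent drift against a targeted
epigenetic writer.
"""

import numpy as np

import methdrift as md
from methdrift.io import SampleSheet
from methdrift.patterns import pattern_spectrum, predict_reads

cfg = md.SimConfig(seed=1, slope_range=(0.01, 0.03))
amp = md.random_amplicon("GRM7_like", 9, seed=1)

train_passages = [1, 3, 5, 7, 9, 11, 13]
train = {f"t{p}": md.simulate_reads(cfg, amp, p, sample_id=f"t{p}") for p in train_passages}
sheet = SampleSheet.from_records(
    {"sample_id": f"t{p}", "passage": p, "donor": "D1", "cell_type": "MSC"}
    for p in train_passages
)
model = md.fit_single_read_model(train, sheet)

held_out = md.simulate_reads(cfg, amp, 8, sample_id="held_out_p8")
preds = predict_reads(model, held_out)
spec = pattern_spectrum(held_out)
print(f"held-out sample (true passage 8, {held_out.n_reads} reads):")
print(f"  mean single-read prediction: {preds.mean_passage:.2f} passages")
print(f"  distinct patterns: {len(spec.frequencies)}, "
      f"Shannon H' = {md.shannon_index(spec):.3f} nats")
# Individual reads are noisy (a 9-CpG epiallele carries little information),
# but their mean dates the sample to within a few passages of the truth.

off = ~np.eye(9, dtype=bool)
drift = md.neighbor_correlation(
    md.simulate_reads(md.SimConfig(seed=1, reads_per_sample=10_000,
                                   slope_range=(0.01, 0.03)), amp, 8)
).to_numpy()
writer = md.neighbor_correlation(
    md.simulate_reads(md.SimConfig(seed=1, reads_per_sample=10_000,
                                   model="targeted_writer", writer_error=0.05), amp, 8)
).to_numpy()
print(f"\nneighbor correlation at 10,000 reads:")
print(f"  independent drift: max |r| = {np.nanmax(np.abs(drift[off])):.3f}")
print(f"  targeted writer:   min  r  = {np.nanmin(writer[off]):.3f}")
# Near-zero correlation between neighboring CpGs is the single-molecule
# fingerprint of stochastic drift; a targeted writer methylates the whole
# region coherently and drives every pairwise correlation toward 1.
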