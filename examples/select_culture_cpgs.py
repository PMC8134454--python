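"""Identify culture-associated CpGs and build the best 2+2 clock.

Simulates a beta-matrix cohort with planted linear drift, runs the selection
pipeline (chromosome filter -> correlation filter -> slope filter -> ranked
candidates) and searches the best two-hyper + two-hypo multivariable model.
"""

import methdrift as md

sim = md.simulate_cohort(md.SimConfig(seed=7))
print(f"cohort: {len(sim.beta.cpg_ids)} CpGs x {len(sim.beta.sample_ids)} samples, "
      f"passages {int(sim.sheet.passages().min())}-{int(sim.sheet.passages().max())}")

beta = md.filter_cpgs_by_chromosome(sim.beta, {"chrX", "chrY"})
stats = md.correlate_cpgs(beta, sim.sheet)

loose = md.filter_candidates(stats, r_cut=0.7)
strict = md.filter_candidates(stats, r_cut=0.8, slope_cut=0.015, top_n=15)
print(f"|r| > 0.7: {len(loose.hyper)} hyper- / {len(loose.hypo)} hypomethylated candidates")
print(f"|r| > 0.8 and |slope| > 0.015 (top 15): {len(strict.hyper)} / {len(strict.hypo)}")

truth_drift = set(sim.truth.index[sim.truth.direction != "stable"])
recovered = set(loose.hyper) | set(loose.hypo)
print(f"planted drifting CpGs recovered: {len(recovered & truth_drift)}/{len(truth_drift)}, "
      f"false positives: {len(recovered - truth_drift)}")

model = md.best_subset_model(beta, sim.sheet, strict, n_hyper=2, n_hypo=2)
print(f"best 2+2 subset: {model.cpg_ids}")
print("  coefficients:", ", ".join(f"{c:+.2f}" for c in model.coefficients),
      f" intercept {model.intercept:+.2f}")
# The exhaustive search picks the CpG quartet whose joint linear fit of
# passage has minimal residual error - the synthetic analog of combining
# ALOX12/DOK6/LTC4S/TNNI3K into one pyrosequencing clock.
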