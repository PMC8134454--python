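"""Reproduce the published cohort statistics from the original data.

The original pyrosequencing tables (training n=44, validation n=83), BBA-seq
pattern tables and 450k array profiles are not redistributable with this
package; place them under data/published/ in the package's own formats:

    pyro_training.tsv / pyro_training_samples.csv
    pyro_validation.tsv / pyro_validation_samples.csv
    bba_patterns.tsv / bba_panel.json / bba_samples.csv
    beta_450k.tsv / beta_450k_samples.csv

Beta matrices are TSV (cpg_id + one column per sample, fractions in [0,1] —
divide pyrosequencing percentages by 100); sample sheets are CSV with
sample_id and passage columns.  With the files in place this script refits
the four-CpG clock (training/CV/validation R2), runs the single-read
predictor on the BBA-seq patterns, and counts the |r| > 0.7 candidates on
the array cohort.
"""

from pathlib import Path

import numpy as np

import methdrift as md
from methdrift.io import read_pattern_table
from methdrift.patterns import fit_single_read_model, predict_sample_from_reads

DATA = Path(__file__).resolve().parent.parent / "data" / "published"

if not DATA.exists():
    raise SystemExit(
        f"no data under {DATA} — see this script's docstring for the expected "
        "layout; the original tables must be obtained separately."
    )

cpgs = list(md.published_model().cpg_ids)

m = md.read_beta_matrix(DATA / "pyro_training.tsv")
s = md.read_sample_sheet(DATA / "pyro_training_samples.csv")
model = md.train_model(m, s, cpgs)
pred = md.predict_passage(model, m)
r2, rmse, mae = md.evaluate_predictions(
    pred.to_numpy(), s.passages(pred.index).to_numpy(float)
)
print(f"training fit: R2={r2:.2f} RMSE={rmse:.2f} MAE={mae:.2f}")

rep = md.cross_validate(m, s, cpgs, folds=10, repeats=10, seed=0)
print(f"10x10-fold CV: R2={rep.r2:.2f} RMSE={rep.rmse:.2f}")

mv = md.read_beta_matrix(DATA / "pyro_validation.tsv")
sv = md.read_sample_sheet(DATA / "pyro_validation_samples.csv")
predv = md.predict_passage(model, mv)
r2v, _, _ = md.evaluate_predictions(predv.to_numpy(), sv.passages(predv.index).to_numpy(float))
print(f"validation: R2={r2v:.2f}")

if (DATA / "bba_patterns.tsv").exists():
    panel = md.read_amplicon_panel(DATA / "bba_panel.json")
    sets = {r.sample_id: r for r in read_pattern_table(DATA / "bba_patterns.tsv", panel)}
    sb = md.read_sample_sheet(DATA / "bba_samples.csv")
    sr_model = fit_single_read_model(sets, sb)
    means = {sid: predict_sample_from_reads(sr_model, rps) for sid, rps in sets.items()}
    r2_sr, _, _ = md.evaluate_predictions(
        np.array(list(means.values())), sb.passages(list(means)).to_numpy(float)
    )
    print(f"single-read predictor (training): R2={r2_sr:.2f}")
    grm7 = [r for r in sets.values() if r.amplicon.name == "GRM7"]
    if grm7:
        C = md.neighbor_correlation(grm7).to_numpy()
        off = ~np.eye(C.shape[0], dtype=bool)
        print(f"GRM7 max neighbor correlation: {np.nanmax(C[off]):.2f}")

if (DATA / "beta_450k.tsv").exists():
    m450 = md.read_beta_matrix(DATA / "beta_450k.tsv")
    s450 = md.read_sample_sheet(DATA / "beta_450k_samples.csv")
    cand = md.filter_candidates(md.correlate_cpgs(m450, s450), r_cut=0.7)
    print(f"|r| > 0.7 candidates: {len(cand.hyper)} hyper / {len(cand.hypo)} hypo")
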