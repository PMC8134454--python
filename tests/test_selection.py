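import itertools

import numpy as np
import pandas as pd
import pytest

from methdrift.clock import PassageModel, r2_variance_explained
from methdrift.io import BetaMatrix, SampleSheet
from methdrift.selection import (
    CandidateSet,
    best_subset_model,
    correlate_cpgs,
    detect_outlier_samples,
    estimate_hydroxymethylation,
    filter_candidates,
    mean_hydroxymethylation,
    stats_table,
)
from methdrift.simulate import SimConfig, simulate_cohort

from conftest import make_sheet


def beta_from(vals, cpgs=None, samples=None):
    vals = np.asarray(vals, dtype=float)
    cpgs = cpgs or [f"cg{i}" for i in range(vals.shape[0])]
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    return BetaMatrix(pd.DataFrame(vals, index=cpgs, columns=samples))


class TestCorrelateCpgs:
    def test_perfect_linear_drift(self):
        passages = np.arange(1, 11)
        m = beta_from([0.01 * passages])
        stats = correlate_cpgs(m, make_sheet(passages))
        st = stats[0]
        assert st.pearson_r == pytest.approx(1.0)
        assert st.slope_m == pytest.approx(0.01)
        assert st.direction == "hyper"

    def test_constant_beta_flagged_undefined(self):
        m = beta_from([[0.5] * 5])
        stats = correlate_cpgs(m, make_sheet([1, 2, 3, 4, 5]))
        assert np.isnan(stats[0].pearson_r)
        assert stats[0].direction == "none"

    def test_brute_force_pearson_oracle(self):
        rng = np.random.default_rng(3)
        passages = [1, 3, 5, 8, 12]
        vals = rng.uniform(0.1, 0.9, (4, 5))
        m = beta_from(vals)
        stats = correlate_cpgs(m, make_sheet(passages))
        p = np.array(passages, dtype=float)
        for i, st in enumerate(stats):
            y = vals[i]
            num = float(np.sum((p - p.mean()) * (y - y.mean())))
            r = num / np.sqrt(np.sum((p - p.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            slope = num / float(np.sum((p - p.mean()) ** 2))
            assert st.pearson_r == pytest.approx(r, abs=1e-12)
            assert st.slope_m == pytest.approx(slope, abs=1e-12)
            assert st.intercept == pytest.approx(y.mean() - slope * p.mean(), abs=1e-12)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.random((3, 6))
        passages = [1, 2, 4, 6, 9, 11]
        m = beta_from(vals)
        sheet = make_sheet(passages)
        stats = correlate_cpgs(m, sheet)
        perm = [3, 0, 5, 1, 4, 2]
        m2 = BetaMatrix(m.values.iloc[:, perm])
        stats2 = correlate_cpgs(m2, sheet)
        for a, b in zip(stats, stats2):
            assert a.pearson_r == pytest.approx(b.pearson_r, abs=1e-12)

    def test_identical_passages_raise(self):
        m = beta_from([[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError, match="identical"):
            correlate_cpgs(m, make_sheet([5, 5, 5]))


class TestFilterCandidates:
    def test_planted_cohort_full_recovery(self):
        sim = simulate_cohort(SimConfig(seed=11))
        stats = correlate_cpgs(sim.beta, sim.sheet)
        cand = filter_candidates(stats, r_cut=0.7)
        truth = sim.truth
        assert set(cand.hyper) == set(truth.index[truth.direction == "hyper"])
        assert set(cand.hypo) == set(truth.index[truth.direction == "hypo"])

    def test_noiseless_data_survives_extreme_cut(self):
        sim = simulate_cohort(SimConfig(seed=1, noise_sd=0.0))
        stats = correlate_cpgs(sim.beta, sim.sheet)
        cand = filter_candidates(stats, r_cut=1.0 - 1e-9)
        assert len(cand.hyper) == 10 and len(cand.hypo) == 10

    def test_top_n_bounds_each_direction(self):
        sim = simulate_cohort(SimConfig(seed=2, n_drift_hyper=20, n_drift_hypo=20))
        stats = correlate_cpgs(sim.beta, sim.sheet)
        cand = filter_candidates(stats, r_cut=0.7, top_n=15)
        assert len(cand.hyper) <= 15 and len(cand.hypo) <= 15

    def test_monotone_in_r_cut(self):
        sim = simulate_cohort(SimConfig(seed=3, noise_sd=0.05))
        stats = correlate_cpgs(sim.beta, sim.sheet)
        prev_h, prev_l = None, None
        for r_cut in (0.5, 0.7, 0.9):
            cand = filter_candidates(stats, r_cut=r_cut)
            if prev_h is not None:
                assert set(cand.hyper) <= prev_h
                assert set(cand.hypo) <= prev_l
            prev_h, prev_l = set(cand.hyper), set(cand.hypo)

    def test_slope_filter_drops_shallow_drifts(self):
        passages = np.arange(1, 11)
        m = beta_from([0.3 + 0.005 * passages, 0.1 + 0.03 * passages])
        stats = correlate_cpgs(m, make_sheet(passages))
        cand = filter_candidates(stats, r_cut=0.8, slope_cut=0.02)
        assert cand.hyper == ("cg1",)

    def test_invalid_r_cut(self):
        with pytest.raises(ValueError, match="r_cut"):
            filter_candidates([], r_cut=1.5)

    def test_ordering_by_abs_r_descending(self):
        sim = simulate_cohort(SimConfig(seed=5, noise_sd=0.03))
        stats = correlate_cpgs(sim.beta, sim.sheet)
        by_id = {st.cpg_id: st for st in stats}
        cand = filter_candidates(stats, r_cut=0.5)
        rs = [abs(by_id[c].pearson_r) for c in cand.hyper]
        assert rs == sorted(rs, reverse=True)


class TestBestSubsetModel:
    def _planted(self, seed=7, n_decoys=4):
        rng = np.random.default_rng(seed)
        n = 20
        betas = rng.uniform(0.05, 0.95, (2 + n_decoys, n))
        betas[1] = rng.uniform(0.05, 0.45, n)  # keep the target passage positive
        passage = 10 + 5 * betas[0] - 20 * betas[1]
        cpgs = ["cg_a", "cg_b"] + [f"cg_d{i}" for i in range(n_decoys)]
        m = beta_from(betas, cpgs=cpgs)
        sheet = make_sheet(passage)
        return m, sheet, passage

    def test_planted_linear_model_recovered(self):
        m, sheet, passage = self._planted()
        cand = CandidateSet(hyper=("cg_a", "cg_d0", "cg_d1"), hypo=("cg_b", "cg_d2", "cg_d3"),
                            r_cut=0.7)
        model = best_subset_model(m, sheet, cand)
        assert "cg_a" in model.cpg_ids and "cg_b" in model.cpg_ids
        coef = dict(zip(model.cpg_ids, model.coefficients))
        assert coef["cg_a"] == pytest.approx(5.0, abs=1e-8)
        assert coef["cg_b"] == pytest.approx(-20.0, abs=1e-8)
        pred = model.predict(m.values.loc[list(model.cpg_ids)].to_numpy().T)
        assert r2_variance_explained(pred, passage) == pytest.approx(1.0, abs=1e-10)

    def test_single_subset_equals_plain_ols(self):
        from methdrift.clock import train_model

        m, sheet, _ = self._planted(n_decoys=2)
        cand = CandidateSet(hyper=("cg_a", "cg_d0"), hypo=("cg_b", "cg_d1"), r_cut=0.7)
        best = best_subset_model(m, sheet, cand)
        direct = train_model(m, sheet, sorted(["cg_a", "cg_d0", "cg_b", "cg_d1"]))
        assert best.cpg_ids == direct.cpg_ids
        np.testing.assert_allclose(best.coefficients, direct.coefficients, atol=1e-9)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        n = 18
        betas = rng.uniform(0, 1, (8, n))
        passage = rng.uniform(1, 15, n)
        cpgs = [f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
        m = beta_from(betas, cpgs=cpgs)
        sheet = make_sheet(passage)
        cand = CandidateSet(hyper=tuple(cpgs[:4]), hypo=tuple(cpgs[4:]), r_cut=0.7)
        model = best_subset_model(m, sheet, cand)

        # independent brute force over every 2+2 subset
        best_rss, best_subset = np.inf, None
        for hyp in itertools.combinations(sorted(cpgs[:4]), 2):
            for lo in itertools.combinations(sorted(cpgs[4:]), 2):
                subset = tuple(sorted(hyp + lo))
                X = m.values.loc[list(subset)].to_numpy().T
                A = np.column_stack([np.ones(n), X])
                coef, *_ = np.linalg.lstsq(A, passage, rcond=None)
                rss = float(((passage - A @ coef) ** 2).sum())
                if rss < best_rss:
                    best_rss, best_subset = rss, subset
        assert model.cpg_ids == best_subset

    def test_nesting_property(self):
        sim = simulate_cohort(SimConfig(seed=21, noise_sd=0.03))
        stats = correlate_cpgs(sim.beta, sim.sheet)
        cand = filter_candidates(stats, r_cut=0.7, top_n=4)
        model = best_subset_model(sim.beta, sim.sheet, cand)
        passages = sim.sheet.passages(sim.beta.sample_ids).to_numpy(float)
        pred = model.predict(sim.beta.values.loc[list(model.cpg_ids)].to_numpy().T)
        best_r2 = r2_variance_explained(pred, passages)
        for cpg in cand.hyper + cand.hypo:
            x = sim.beta.values.loc[cpg].to_numpy()
            A = np.column_stack([np.ones(len(x)), x])
            coef, *_ = np.linalg.lstsq(A, passages, rcond=None)
            r2_uni = r2_variance_explained(A @ coef, passages)
            assert best_r2 >= r2_uni - 1e-12

    def test_too_few_candidates_raise(self):
        m, sheet, _ = self._planted()
        cand = CandidateSet(hyper=("cg_a",), hypo=("cg_b", "cg_d0"), r_cut=0.7)
        with pytest.raises(ValueError, match="candidates"):
            best_subset_model(m, sheet, cand)


class TestOutlierDetection:
    def _linear_cohort(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        passages = np.tile(np.arange(1, 11), n // 10)
        betas = np.vstack(
            [
                0.1 + 0.02 * passages + rng.normal(0, 0.005, n),
                0.9 - 0.02 * passages + rng.normal(0, 0.005, n),
            ]
        )
        m = beta_from(np.clip(betas, 0, 1), cpgs=["cgH", "cgL"])
        model = PassageModel(("cgH", "cgL"), np.array([25.0, -25.0]), 1.0)
        return m, make_sheet(passages), model

    def test_clean_data_has_no_outliers(self):
        m, sheet, model = self._linear_cohort()
        assert detect_outlier_samples(m, sheet, model, alpha=0.05) == []

    def test_displaced_sample_is_flagged(self):
        m, sheet, model = self._linear_cohort(seed=1)
        # displace one sample's passage far beyond the residual scale
        tbl = sheet.table.copy()
        tbl.loc["s7", "passage"] = tbl.loc["s7", "passage"] + 30
        bad_sheet = SampleSheet(tbl)
        flagged = detect_outlier_samples(m, bad_sheet, model, alpha=0.05)
        assert flagged == ["s7"]

    def test_studentized_residual_oracle(self):
        # recompute the Bonferroni outlier test from first principles
        from scipy import stats as sps

        m, sheet, model = self._linear_cohort(seed=2)
        tbl = sheet.table.copy()
        tbl.loc["s3", "passage"] = tbl.loc["s3", "passage"] + 25
        sheet = SampleSheet(tbl)
        X = m.values.to_numpy().T
        y = sheet.passages(m.sample_ids).to_numpy(float)
        A = np.column_stack([np.ones(len(y)), X])
        H = A @ np.linalg.inv(A.T @ A) @ A.T
        resid = y - H @ y
        n, p = A.shape
        s2 = resid @ resid / (n - p)
        h = np.diag(H)
        # externally studentized residuals
        s2_i = (s2 * (n - p) - resid**2 / (1 - h)) / (n - p - 1)
        t = resid / np.sqrt(s2_i * (1 - h))
        pvals = 2 * sps.t.sf(np.abs(t), df=n - p - 1)
        bonf = np.minimum(pvals * n, 1.0)
        expected = [sid for sid, b in zip(m.sample_ids, bonf) if b < 0.05]
        assert detect_outlier_samples(m, sheet, model, alpha=0.05) == expected

    def test_alpha_zero_returns_empty(self):
        m, sheet, model = self._linear_cohort()
        assert detect_outlier_samples(m, sheet, model, alpha=0.0) == []


class TestHydroxymethylation:
    def test_identical_inputs_give_zero(self, toy_beta):
        hmc = estimate_hydroxymethylation(toy_beta, toy_beta)
        assert (hmc.to_numpy() == 0).all()

    def test_simple_difference(self):
        bs = beta_from([[0.5]])
        ox = beta_from([[0.2]])
        hmc = estimate_hydroxymethylation(bs, ox)
        assert hmc.iloc[0, 0] == pytest.approx(0.3)

    def test_negative_estimates_kept(self):
        bs = beta_from([[0.2]])
        ox = beta_from([[0.5]])
        assert estimate_hydroxymethylation(bs, ox).iloc[0, 0] == pytest.approx(-0.3)

    def test_mean_over_cpg_set_matches_brute_force(self):
        rng = np.random.default_rng(9)
        bs = beta_from(rng.random((5, 3)))
        ox = beta_from(rng.random((5, 3)))
        hmc = estimate_hydroxymethylation(bs, ox)
        subset = ["cg1", "cg3"]
        expected = np.mean(
            [hmc.loc[c, s] for c in subset for s in hmc.columns]
        )
        assert mean_hydroxymethylation(hmc, subset) == pytest.approx(expected, abs=1e-12)

    def test_id_mismatch_raises(self):
        bs = beta_from([[0.5]], cpgs=["cgA"])
        ox = beta_from([[0.5]], cpgs=["cgB"])
        with pytest.raises(ValueError, match="cgA|cgB"):
            estimate_hydroxymethylation(bs, ox)


def test_stats_table_columns():
    sim = simulate_cohort(SimConfig(seed=1, n_cpgs=20))
    stats = correlate_cpgs(sim.beta, sim.sheet)
    tbl = stats_table(stats)
    assert list(tbl.columns) == ["r", "slope", "intercept", "n", "direction"]
    assert len(tbl) == 20
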