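import numpy as np
import pytest

from methdrift.io import MISSING, ReadPatternSet
from methdrift.patterns import (
    SingleReadModel,
    cpg_passage_correlation,
    fit_single_read_model,
    neighbor_correlation,
    pattern_spectrum,
    predict_read,
    predict_reads,
    predict_sample_from_reads,
    shannon_index,
)
from methdrift.simulate import SimConfig, random_amplicon, simulate_reads

from conftest import make_sheet


@pytest.fixture(scope="module")
def amp4():
    return random_amplicon("pat4", 4, seed=0)


def rps_from(amp, rows, sample_id="s"):
    return ReadPatternSet.from_reads(amp, sample_id, np.asarray(rows, dtype=np.int8))


class TestPatternSpectrum:
    def test_identical_reads_single_pattern(self, amp4):
        spec = pattern_spectrum(rps_from(amp4, [[1, 0, 1, 0]] * 10))
        assert spec.frequencies == {"1010": 1.0}
        assert spec.total_reads == 10

    def test_two_equal_patterns_split_evenly(self, amp4):
        spec = pattern_spectrum(rps_from(amp4, [[1, 1, 1, 1]] * 2 + [[0, 0, 0, 0]] * 2))
        assert spec.frequencies == {"0000": 0.5, "1111": 0.5}

    def test_counting_oracle_on_random_reads(self, amp4):
        rng = np.random.default_rng(0)
        reads = rng.integers(0, 2, (100, 4)).astype(np.int8)
        spec = pattern_spectrum(rps_from(amp4, reads))
        from collections import Counter

        expected = Counter("".join(map(str, row)) for row in reads)
        for pat, freq in spec.frequencies.items():
            assert freq == pytest.approx(expected[pat] / 100)
        assert sum(spec.frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_reads_with_missing_states_excluded_and_counted(self, amp4):
        rows = [[1, 1, 1, 1], [1, MISSING, 0, 1], [0, 0, 0, 0]]
        spec = pattern_spectrum(rps_from(amp4, rows))
        assert spec.total_reads == 2
        assert spec.n_excluded == 1

    def test_no_complete_reads_raises(self, amp4):
        with pytest.raises(ValueError, match="complete"):
            pattern_spectrum(rps_from(amp4, [[1, MISSING, 1, 1]]))


class TestShannonIndex:
    def test_degenerate_spectrum_is_zero(self, amp4):
        assert shannon_index(pattern_spectrum(rps_from(amp4, [[1, 0, 0, 1]] * 5))) == 0.0

    def test_uniform_spectrum_is_log_n(self):
        assert shannon_index([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_computed_mixed_spectrum(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.03972...
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397207708399179, abs=1e-9)

    def test_bounds_over_random_spectra(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = rng.integers(1, 20)
            p = rng.dirichlet(np.ones(k))
            h = shannon_index(p)
            assert -1e-12 <= h <= np.log(k) + 1e-12

    def test_invalid_proportions_raise(self):
        with pytest.raises(ValueError):
            shannon_index([0.5, 0.6])


class TestNeighborCorrelation:
    def test_coherent_reads_fully_correlated(self, amp4):
        rps = rps_from(amp4, [[1, 1, 1, 1]] * 5 + [[0, 0, 0, 0]] * 5)
        C = neighbor_correlation(rps).to_numpy()
        np.testing.assert_allclose(C, 1.0, atol=1e-12)

    def test_phi_coefficient_closed_form(self):
        amp = random_amplicon("pat2", 2, seed=0)
        rows = [[1, 1]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 40
        C = neighbor_correlation(rps_from(amp, rows))
        assert C.iloc[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_independent_states_near_zero(self, amp4):
        rng = np.random.default_rng(2)
        reads = (rng.random((10_000, 4)) < 0.5).astype(np.int8)
        C = neighbor_correlation(rps_from(amp4, reads)).to_numpy()
        off = C[~np.eye(4, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.05

    def test_zero_variance_cpg_flagged_nan(self, amp4):
        rows = [[1, 1, 0, 1], [1, 0, 1, 0], [1, 1, 1, 0]]
        with pytest.warns(UserWarning, match="zero variance"):
            C = neighbor_correlation(rps_from(amp4, rows))
        assert C.iloc[0].isna().all()

    def test_pooling_across_samples(self, amp4):
        a = rps_from(amp4, [[1, 1, 1, 1]] * 3, "sa")
        b = rps_from(amp4, [[0, 0, 0, 0]] * 3, "sb")
        C = neighbor_correlation([a, b]).to_numpy()
        np.testing.assert_allclose(C, 1.0, atol=1e-12)


class TestCpgPassageCorrelation:
    def test_perfectly_drifting_fractions(self, amp4):
        # methylated fraction rises exactly with passage at CpG 0, flat elsewhere
        sets = {}
        passages = [2, 4, 6, 8]
        for p in passages:
            k = p  # p reads methylated at CpG0 out of 10
            rows = [[1, 1, 0, 0]] * k + [[0, 1, 0, 0]] * (10 - k)
            sets[f"s{p}"] = rps_from(amp4, rows, f"s{p}")
        sheet = make_sheet(passages, prefix="s_ignored")
        import pandas as pd
        from methdrift.io import SampleSheet

        sheet = SampleSheet.from_records(
            {"sample_id": f"s{p}", "passage": p, "donor": "D1", "cell_type": "MSC"}
            for p in passages
        )
        r = cpg_passage_correlation(sets, sheet)
        assert r.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(r.iloc[1])  # constant fraction 1.0 -> undefined

    def test_requires_three_samples(self, amp4):
        sets = {"a": rps_from(amp4, [[1, 0, 1, 0]]), "b": rps_from(amp4, [[1, 1, 1, 1]])}
        from methdrift.io import SampleSheet

        sheet = SampleSheet.from_records(
            [{"sample_id": "a", "passage": 1}, {"sample_id": "b", "passage": 2}]
        )
        with pytest.raises(ValueError, match="3 samples"):
            cpg_passage_correlation(sets, sheet)


class TestFitSingleReadModel:
    def _sets_with_exact_fractions(self, amp, passages, frac_fn, n_reads=100):
        sets = {}
        for p in passages:
            rows = []
            for i in range(amp.n_cpgs):
                pass  # build per-read matrix below
            k = np.round(np.array([frac_fn(i, p) for i in range(amp.n_cpgs)]) * n_reads)
            X = np.zeros((n_reads, amp.n_cpgs), dtype=np.int8)
            for i in range(amp.n_cpgs):
                X[: int(k[i]), i] = 1
            sets[f"s{p}"] = ReadPatternSet.from_reads(amp, f"s{p}", X)
        from methdrift.io import SampleSheet

        sheet = SampleSheet.from_records(
            {"sample_id": f"s{p}", "passage": p, "donor": "D", "cell_type": "MSC"}
            for p in passages
        )
        return sets, sheet

    def test_exact_line_recovered(self, amp4):
        sets, sheet = self._sets_with_exact_fractions(
            amp4, [0, 10, 20, 30], lambda i, p: 0.1 + 0.01 * p
        )
        model = fit_single_read_model(sets, sheet)
        np.testing.assert_allclose(model.intercepts, 0.1, atol=1e-10)
        np.testing.assert_allclose(model.slopes, 0.01, atol=1e-10)

    def test_constant_fractions_give_zero_slope(self, amp4):
        sets, sheet = self._sets_with_exact_fractions(amp4, [0, 10, 20], lambda i, p: 0.4)
        model = fit_single_read_model(sets, sheet)
        np.testing.assert_allclose(model.slopes, 0.0, atol=1e-12)

    def test_degenerate_passages_raise(self, amp4):
        from methdrift.io import SampleSheet

        sets, _ = self._sets_with_exact_fractions(amp4, [0, 10, 20], lambda i, p: 0.5)
        sheet = SampleSheet.from_records(
            {"sample_id": sid, "passage": 5, "donor": "D", "cell_type": "MSC"}
            for sid in sets
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_single_read_model(sets, sheet)

    def test_generator_slope_recovery_within_2se(self):
        cfg = SimConfig(seed=31, slope_range=(0.01, 0.03), reads_per_sample=1000)
        amp = random_amplicon("rec9", 9, seed=31)
        from methdrift.simulate import amplicon_drift_params
        from methdrift.io import SampleSheet

        a_true, b_true = amplicon_drift_params(cfg, amp)
        passages = [1, 3, 5, 7, 9, 11]
        sets = {
            f"s{p}": simulate_reads(cfg, amp, p, sample_id=f"s{p}") for p in passages
        }
        sheet = SampleSheet.from_records(
            {"sample_id": f"s{p}", "passage": p, "donor": "D", "cell_type": "MSC"}
            for p in passages
        )
        model = fit_single_read_model(sets, sheet)
        # s.e. of the OLS slope from binomial read noise at each passage
        pvec = np.array(passages, dtype=float)
        sxx = np.sum((pvec - pvec.mean()) ** 2)
        for i in range(9):
            probs = np.clip(a_true[i] + b_true[i] * pvec, 0.001, 0.999)
            var_frac = probs * (1 - probs) / cfg.reads_per_sample
            se = np.sqrt(np.sum(((pvec - pvec.mean()) / sxx) ** 2 * var_frac))
            assert abs(model.slopes[i] - b_true[i]) <= 2 * se + 1e-9


class TestPredictRead:
    def _two_cpg_model(self):
        return SingleReadModel(
            intercepts=np.array([0.1, 0.9]),
            slopes=np.array([0.01, -0.01]),
            passage_grid=np.arange(0, 51),
        )

    def _brute_force_best(self, model, x):
        best_p, best_ll = None, -np.inf
        for p in model.passage_grid:
            ll = 0.0
            for i, xi in enumerate(x):
                if xi == MISSING:
                    continue
                m = min(max(model.intercepts[i] + model.slopes[i] * p, model.clip_eps),
                        1 - model.clip_eps)
                ll += np.log(m) if xi == 1 else np.log(1 - m)
            if ll > best_ll + 1e-15:
                best_ll, best_p = ll, int(p)
        return best_p

    @pytest.mark.parametrize("read,expected", [((1, 0), 50), ((0, 1), 0)])
    def test_two_cpg_grid_brute_force(self, read, expected):
        model = self._two_cpg_model()
        best, ll = predict_read(model, np.array(read, dtype=np.int8))
        assert best == expected
        assert best == self._brute_force_best(model, read)
        assert ll.shape == (51,)

    def test_random_reads_match_brute_force(self):
        rng = np.random.default_rng(3)
        model = SingleReadModel(
            intercepts=rng.uniform(0.1, 0.9, 5),
            slopes=rng.uniform(-0.02, 0.02, 5),
            passage_grid=np.arange(0, 51),
        )
        for _ in range(20):
            x = rng.integers(0, 2, 5).astype(np.int8)
            x[rng.random(5) < 0.2] = MISSING
            if (x == MISSING).all():
                continue
            best, _ = predict_read(model, x)
            assert best == self._brute_force_best(model, x)

    def test_uninformative_model_ties_to_smallest(self):
        model = SingleReadModel(
            intercepts=np.array([0.5, 0.5]),
            slopes=np.zeros(2),
            passage_grid=np.arange(0, 51),
        )
        best, _ = predict_read(model, np.array([1, 0], dtype=np.int8))
        assert best == 0

    def test_cpg_order_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0.2, 0.8, 6), rng.uniform(-0.02, 0.02, 6)
        x = rng.integers(0, 2, 6).astype(np.int8)
        perm = rng.permutation(6)
        m1 = SingleReadModel(a, b, np.arange(0, 51))
        m2 = SingleReadModel(a[perm], b[perm], np.arange(0, 51))
        b1, ll1 = predict_read(m1, x)
        b2, ll2 = predict_read(m2, x[perm])
        assert b1 == b2
        np.testing.assert_allclose(ll1, ll2, atol=1e-12)

    def test_monotone_model_monotone_read(self):
        model = SingleReadModel(
            intercepts=np.full(4, 0.1), slopes=np.full(4, 0.01), passage_grid=np.arange(0, 51)
        )
        best, _ = predict_read(model, np.ones(4, dtype=np.int8))
        assert best == 50

    def test_all_missing_raises(self):
        model = self._two_cpg_model()
        with pytest.raises(ValueError, match="missing"):
            predict_read(model, np.array([MISSING, MISSING], dtype=np.int8))


class TestPredictSample:
    def test_constant_reads_equal_single_prediction(self):
        amp = random_amplicon("pat3", 3, seed=1)
        model = SingleReadModel(
            intercepts=np.array([0.1, 0.2, 0.3]),
            slopes=np.array([0.01, 0.015, -0.01]),
            passage_grid=np.arange(0, 51),
        )
        rps = ReadPatternSet.from_reads(amp, "s", np.tile([1, 0, 1], (7, 1)))
        single, _ = predict_read(model, np.array([1, 0, 1], dtype=np.int8))
        assert predict_sample_from_reads(model, rps) == pytest.approx(single)

    def test_mean_is_count_weighted_average(self):
        amp = random_amplicon("pat2b", 2, seed=2)
        model = SingleReadModel(
            intercepts=np.array([0.1, 0.9]), slopes=np.array([0.01, -0.01]),
            passage_grid=np.arange(0, 51),
        )
        rows = [[1, 0]] * 3 + [[0, 1]] * 1
        rps = ReadPatternSet.from_reads(amp, "s", np.array(rows, dtype=np.int8))
        preds = predict_reads(model, rps)
        manual = np.average(preds.best_passages, weights=preds.counts)
        assert preds.mean_passage == pytest.approx(manual)
        assert preds.mean_passage == pytest.approx((3 * 50 + 0) / 4)

    def test_simulated_sample_recovered_within_three_passages(self):
        cfg = SimConfig(seed=0, slope_range=(0.01, 0.03))
        amp = random_amplicon("grm7ish", 9, seed=0)
        from methdrift.io import SampleSheet

        passages = [1, 3, 5, 7, 9, 11, 13]
        sets = {f"t{p}": simulate_reads(cfg, amp, p, sample_id=f"t{p}") for p in passages}
        sheet = SampleSheet.from_records(
            {"sample_id": f"t{p}", "passage": p, "donor": "D", "cell_type": "MSC"}
            for p in passages
        )
        model = fit_single_read_model(sets, sheet)
        test_rps = simulate_reads(cfg, amp, 8, sample_id="held_out")
        mean = predict_sample_from_reads(model, test_rps)
        assert abs(mean - 8) <= 3.0
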