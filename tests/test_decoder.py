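"""Dictionary construction and correlation-weighted decoding."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

import popdecode as pp
from popdecode.decoder import DictionaryMatrix, _window_bins
from popdecode.population import SpikeCountTensor
from popdecode.stimuli import (
    BLANK,
    PatternMatrix,
    StimulusPeriod,
    TrialSchedule,
    normalize_vector,
)


def brute_force_decode(rr, RR, S_raw):
    """Independent oracle: per-row Pearson correlation with a statistics
    routine, then the correlation-weighted pattern average."""
    c = np.zeros(RR.shape[0])
    for p in range(RR.shape[0]):
        if np.ptp(RR[p]) == 0 or np.ptp(rr) == 0:
            c[p] = 0.0
        else:
            c[p] = stats.pearsonr(rr, RR[p]).statistic
    d_raw = np.zeros(S_raw.shape[1])
    for p in range(RR.shape[0]):
        d_raw += c[p] * normalize_vector(S_raw[p])
    return c, normalize_vector(d_raw)


class TestBuildDictionary:
    def test_noiseless_rows_equal_expected_windowed_rates(
        self, noiseless_dict_tensor, session10
    ):
        d = pp.build_dictionary(noiseless_dict_tensor, session10.dictionary, window=(0, 90))
        # independent recomputation straight from the long-format table
        frame = noiseless_dict_tensor.to_long_frame()
        frame["rate"] = frame["count"] / (noiseless_dict_tensor.bin_ms / 1000.0)
        id_of = {p.index: p.pattern_id for p in session10.dictionary.pattern_periods()}
        frame = frame[frame["period"].isin(id_of) & (frame["bin"] < 9)]
        frame["pattern"] = frame["period"].map(id_of)
        expected = frame.pivot_table(index="pattern", columns="site", values="rate").to_numpy()
        np.testing.assert_allclose(d.RR, expected, atol=1e-9)

    def test_rows_obey_normalization_contract(self, decoder):
        R = decoder.dictionary_.R
        live = np.ptp(decoder.dictionary_.RR, axis=1) > 0
        np.testing.assert_allclose(R[live].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(R[live], axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("window", [(0.0, 90.0), (90.0, 250.0), (0.0, 250.0)])
    def test_supported_windows(self, dict_tensor, session10, window):
        d = pp.build_dictionary(dict_tensor, session10.dictionary, window=window)
        assert d.RR.shape == (81, 16)
        assert d.window == window

    def test_misaligned_window_rejected(self, dict_tensor, session10):
        with pytest.raises(ValueError, match="aligned"):
            pp.build_dictionary(dict_tensor, session10.dictionary, window=(0.0, 95.0))

    def test_csv_round_trip(self, decoder, tmp_path):
        path = tmp_path / "dict.csv"
        decoder.dictionary_.to_csv(path)
        back = DictionaryMatrix.from_csv(path)
        np.testing.assert_allclose(back.RR, decoder.dictionary_.RR, atol=1e-9)
        assert back.window == decoder.dictionary_.window

    def test_window_bins_helper(self):
        assert _window_bins((0, 90), 10.0, 25) == (0, 9)
        with pytest.raises(ValueError):
            _window_bins((0, 300), 10.0, 25)


class TestSignificanceMask:
    @staticmethod
    def _tensor_and_schedule(evoked_rate):
        """One site; blank baseline PSTH bins alternate 1 and 3 spikes/s
        (mean 2, sd 1); pattern periods at a controlled evoked rate."""
        periods, counts = [], []
        for i in range(8):
            blank = i % 2 == 0
            periods.append(
                StimulusPeriod(i, "dictionary", BLANK if blank else i // 2, i * 250.0, 250.0)
            )
            rate = np.tile([1.0, 3.0], 13)[:25] if blank else np.full(25, evoked_rate)
            counts.append(rate * 0.01)
        tensor = SpikeCountTensor(counts=np.array(counts).T[None, :, :], bin_ms=10.0)
        return tensor, TrialSchedule(periods=periods)

    def test_clearly_evoked_site_is_significant(self):
        tensor, sched = self._tensor_and_schedule(evoked_rate=5.0)
        assert pp.significance_mask(tensor, sched).tolist() == [True]

    def test_exactly_two_sd_is_not_significant(self):
        tensor, sched = self._tensor_and_schedule(evoked_rate=4.0)  # mean + 2 sd
        assert pp.significance_mask(tensor, sched).tolist() == [False]

    def test_no_baseline_periods_rejected(self, relay_tensor):
        sched = TrialSchedule(
            periods=[StimulusPeriod(0, "dictionary", 3, 0.0, 250.0)]
        )
        tensor = SpikeCountTensor(counts=np.zeros((2, 25, 1)), bin_ms=10.0)
        with pytest.raises(ValueError, match="baseline"):
            pp.significance_mask(tensor, sched)

    def test_gain_zero_units_rarely_significant(self, kernel):
        cfg = pp.PopulationConfig(n_units=50, seed=3, gain_range=(0.0, 0.0))
        with pytest.warns(UserWarning):
            units = pp.make_population(cfg)
        sched = pp.build_schedule("dictionary", n_repeats=3, seed=4)
        tensor = pp.simulate_responses(sched, units, kernel, seed=5)
        frac = pp.significance_mask(tensor, sched).mean()
        assert frac <= 0.1

    def test_strong_population_mostly_significant(self, decoder):
        assert decoder.significance_mask_.mean() > 0.5


class TestDecodeInstant:
    def test_hand_computed_toy_dictionary(self, pmat):
        # two sites, two patterns: rr proportional to row 1 correlates +1
        # with it and -1 with the other (two-site vectors are collinear
        # after normalization)
        ids = [1, 5]
        S_raw = pmat.raw[ids]
        patterns = PatternMatrix(
            S=np.stack([normalize_vector(r) for r in S_raw]), raw=S_raw,
            pattern_ids=np.array(ids),
        )
        RR = np.array([[2.0, 0.0], [0.0, 2.0]])
        d = DictionaryMatrix(
            RR=RR, R=np.stack([normalize_vector(r) for r in RR]),
            window=(0.0, 250.0), pattern_ids=np.array(ids), n_repeats=1,
        )
        c, dec, best = pp.decode_instant(np.array([2.0, 0.0]), d, patterns)
        np.testing.assert_allclose(c, [1.0, -1.0], atol=1e-12)
        assert best == 1
        np.testing.assert_allclose(
            dec, normalize_vector(patterns.S[0] - patterns.S[1]), atol=1e-12
        )

    def test_orthogonal_template_match(self, pmat):
        ids = [1, 5]
        RR = np.array([[2.0, 1.0, 0.0], [0.0, 3.0, 0.0]])  # centered rows orthogonal
        d = DictionaryMatrix(
            RR=RR, R=np.stack([normalize_vector(r) for r in RR]),
            window=(0.0, 250.0), pattern_ids=np.array(ids), n_repeats=1,
        )
        patterns = PatternMatrix(
            S=np.stack([normalize_vector(r) for r in pmat.raw[ids]]),
            raw=pmat.raw[ids], pattern_ids=np.array(ids),
        )
        c, dec, best = pp.decode_instant(np.array([4.0, 2.0, 0.0]), d, patterns)
        np.testing.assert_allclose(c, [1.0, 0.0], atol=1e-12)
        assert best == 1
        np.testing.assert_allclose(dec, patterns.S[0], atol=1e-12)

    def test_constant_vector_decodes_to_nothing(self, decoder):
        c, d, _ = decoder.decode(np.full(16, 7.0))
        np.testing.assert_allclose(c, 0.0, atol=1e-12)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self, decoder):
        with pytest.raises(ValueError, match="sites"):
            decoder.decode(np.ones(5))

    def test_matches_brute_force_pearson_oracle(self, pmat):
        rng = np.random.default_rng(17)
        for _ in range(50):
            RR = rng.gamma(2.0, 10.0, size=(81, 16))
            d = DictionaryMatrix(
                RR=RR, R=np.stack([normalize_vector(r) for r in RR]),
                window=(0.0, 250.0), pattern_ids=np.arange(81), n_repeats=1,
            )
            rr = rng.poisson(5.0, size=16).astype(float)
            if np.ptp(rr) == 0:
                continue
            c, dec, _ = pp.decode_instant(rr, d, pmat)
            c_ref, dec_ref = brute_force_decode(rr, RR, pmat.raw)
            np.testing.assert_allclose(c, c_ref, atol=1e-10)
            np.testing.assert_allclose(dec, dec_ref, atol=1e-10)


class TestSelfConsistency:
    def test_noiseless_self_decoding_perfect(self, noiseless_dict_tensor, session10):
        dec = pp.DictionaryDecoder().fit(noiseless_dict_tensor, session10.dictionary)
        pps = session10.dictionary.pattern_periods()
        X = np.stack(
            [noiseless_dict_tensor.counts[:, :, p.index].mean(axis=1) for p in pps]
        )
        truth = np.array([p.pattern_id for p in pps])
        assert np.array_equal(dec.predict(X), truth)

    def test_noisy_self_decoding_large_majority(self, decoder, dict_tensor, session10):
        pps = session10.dictionary.pattern_periods()
        X = np.stack([dict_tensor.counts[:, :, p.index].mean(axis=1) for p in pps])
        truth = np.array([p.pattern_id for p in pps])
        # exact 81-way identification of well over half the periods
        # (chance level is 1/81)
        assert (decoder.predict(X) == truth).mean() > 0.5


def shuffled_schedule(schedule, seed):
    """Pattern labels permuted consistently: destroys the code."""
    rng = np.random.default_rng(seed)
    mapping = dict(zip(range(81), rng.permutation(81)))
    periods = [
        StimulusPeriod(
            p.index, p.paradigm,
            BLANK if p.pattern_id == BLANK else int(mapping[p.pattern_id]),
            p.onset_ms, p.duration_ms,
        )
        for p in schedule.periods
    ]
    return TrialSchedule(periods=periods)


class TestCorrelationTimecourse:
    def test_trace_metadata(self, relay_trace):
        assert relay_trace.n == 810
        assert relay_trace.time_ms[0] == 5.0 and relay_trace.time_ms[-1] == 245.0
        for arr in (relay_trace.mean_previous, relay_trace.mean_current,
                    relay_trace.mean_difference):
            assert np.all(np.abs(arr) <= 1.0)

    def test_pre_response_bins_reflect_previous_pattern(self, relay_trace):
        assert relay_trace.mean_previous[0] > 0.05
        assert abs(relay_trace.mean_current[0]) < 0.03

    def test_difference_then_current_dominance(self, relay_trace):
        t = relay_trace.time_ms
        early = (t >= 60) & (t < 150)
        late = t >= 180
        assert (
            relay_trace.mean_difference[early].mean()
            > relay_trace.mean_current[early].mean()
        )
        assert (
            relay_trace.mean_current[late].mean()
            > relay_trace.mean_difference[late].mean()
        )

    def test_crossover_exists_within_period(self, relay_trace):
        t = pp.crossover_time(relay_trace)
        assert t is not None and 0.0 < t < 250.0

    def test_label_shuffle_null_destroys_all_correlations(
        self, relay_tensor, session10, dict_tensor
    ):
        dec = pp.DictionaryDecoder().fit(
            dict_tensor, shuffled_schedule(session10.dictionary, seed=8)
        )
        trace = dec.trace(relay_tensor, session10.relay)
        for mean, sem in (
            (trace.mean_previous, trace.sem_previous),
            (trace.mean_current, trace.sem_current),
            (trace.mean_difference, trace.sem_difference),
        ):
            assert abs(mean.mean()) < 3.0 * sem.mean()

    def test_mean_and_sem_match_per_transition_decodes(
        self, decoder, relay_tensor, session10, relay_trace
    ):
        # recompute one bin's statistics from individual decode calls
        from popdecode.stimuli import contrast_of

        trans = pp.transitions(session10.relay)
        corrs = []
        for tr in trans:
            rr = relay_tensor.counts[:, 10, tr.period_index].astype(float)
            _, d, _ = decoder.decode(rr)
            corrs.append(float(d @ normalize_vector(contrast_of(tr.current_id))))
        corrs = np.array(corrs)
        assert relay_trace.mean_current[10] == pytest.approx(corrs.mean(), abs=1e-10)
        assert relay_trace.sem_current[10] == pytest.approx(
            corrs.std(ddof=1) / np.sqrt(corrs.size), abs=1e-10
        )


class TestCrossoverTime:
    @staticmethod
    def _trace(cur, diff):
        n = len(cur)
        z = np.zeros(n)
        return pp.CorrelationTrace(
            time_ms=np.arange(n) * 10.0 + 5.0,
            mean_previous=z, mean_current=np.array(cur, float),
            mean_difference=np.array(diff, float),
            sem_previous=z, sem_current=z, sem_difference=z, n=10,
        )

    def test_no_crossover_when_difference_always_dominates(self):
        trace = self._trace(cur=[0.1] * 10, diff=[0.5] * 10)
        assert pp.crossover_time(trace) is None

    def test_clean_single_crossing(self):
        diff = [0.5] * 5 + [0.1] * 5
        cur = [0.2] * 10
        trace = self._trace(cur, diff)
        assert pp.crossover_time(trace) == 55.0  # first bin after the crossing

    def test_pre_response_region_is_not_a_crossover(self):
        # current > difference initially (difference negative before the
        # response), then difference dominates and never hands back
        cur = [0.0] * 3 + [0.2] * 7
        diff = [-0.1] * 3 + [0.5] * 7
        trace = self._trace(cur, diff)
        assert pp.crossover_time(trace) is None

    def test_persistence_requirement(self):
        diff = [0.5, 0.5, 0.1, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        cur = [0.2] * 10
        assert pp.crossover_time(self._trace(cur, diff), k=3) is None
        assert pp.crossover_time(self._trace(cur, diff), k=1) == 25.0


class TestWindowSplit:
    def test_noiseless_traces_highly_correlated(
        self, noiseless_relay_tensor, noiseless_dict_tensor, session10
    ):
        _, _, r = pp.window_split_consistency(
            noiseless_relay_tensor, session10.relay,
            noiseless_dict_tensor, session10.dictionary,
        )
        assert r > 0.95

    def test_equal_windows_give_identical_traces(
        self, relay_tensor, dict_tensor, session10
    ):
        a, b, r = pp.window_split_consistency(
            relay_tensor, session10.relay, dict_tensor, session10.dictionary,
            windows=((0.0, 90.0), (0.0, 90.0)),
        )
        np.testing.assert_array_equal(a.mean_current, b.mean_current)
        assert r == pytest.approx(1.0)

    def test_shuffled_dictionary_control_collapses_amplitude(
        self, relay_tensor, dict_tensor, session10
    ):
        # a label-shuffled dictionary destroys the code: the decoded-pattern
        # correlation time course collapses toward zero.  (A single random
        # permutation keeps a small coherent leak through accidental
        # template overlap, so amplitude -- not curve shape -- is the
        # destruction metric.)
        a, _, _ = pp.window_split_consistency(
            relay_tensor, session10.relay, dict_tensor, session10.dictionary
        )
        x = a.mean_difference - a.mean_current
        null = np.zeros_like(x)
        seeds = (13, 14, 15, 16, 17)
        for seed in seeds:
            dec = pp.DictionaryDecoder(window=(0.0, 90.0)).fit(
                dict_tensor, shuffled_schedule(session10.dictionary, seed=seed)
            )
            st = dec.trace(relay_tensor, session10.relay)
            null += st.mean_difference - st.mean_current
        null /= len(seeds)
        assert np.sqrt(np.mean(null**2)) < 0.5 * np.sqrt(np.mean(x**2))


class TestDecoderEstimator:
    def test_sklearn_protocol(self):
        dec = pp.DictionaryDecoder(window=(0.0, 90.0), crossover_k=5)
        assert dec.get_params() == {"window": (0.0, 90.0), "crossover_k": 5}
        assert clone(dec).get_params() == dec.get_params()

    def test_fitted_attributes(self, decoder):
        assert decoder.dictionary_.RR.shape == (81, 16)
        assert decoder.significance_mask_.shape == (16,)
        assert decoder.pattern_matrix_.S.shape == (81, 4)

    def test_transform_returns_normalized_patterns(self, decoder):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(7, 16)).astype(float)
        D = decoder.transform(X)
        assert D.shape == (7, 4)
        norms = np.linalg.norm(D, axis=1)
        assert np.all((np.abs(norms - 1.0) < 1e-9) | (norms < 1e-9))
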