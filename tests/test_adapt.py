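"""Band selection and detection-parameter optimization from seizure events."""

import numpy as np
import pytest

import seizeflow as sf
from seizeflow.adapt import (
    DEFAULT_N_GRID,
    DEFAULT_T_GRID,
    SPECTRUM_OFFSETS,
    optimize_from_traces,
    recompute_biomarkers,
)
from seizeflow.detector import CONTEXT_HALFSPAN, EventRecord

from conftest import FPS


def make_event(event_id, freq=None, amplitude=0.6, noise=0.02, seed=0,
               active=SPECTRUM_OFFSETS):
    """Event whose context windows oscillate at ``freq`` inside ``active``.

    All 51 context windows are filled; inactive windows hold low-level
    noise only.
    """
    rng = np.random.default_rng(seed)
    ev = EventRecord(event_id=event_id, trigger_window=100, trigger_time=150.0)
    for slot, off in enumerate(range(-CONTEXT_HALFSPAN, CONTEXT_HALFSPAN + 1)):
        t = (off * 36 + np.arange(35)) / FPS
        values = rng.normal(0, noise, size=(35, 6))
        if freq is not None and off in active:
            values[:, 0] += amplitude * np.sin(2 * np.pi * freq * t)
            values[:, 1] += 0.5 * amplitude * np.sin(2 * np.pi * freq * t + 1.0)
        ev.flow_context[slot] = values
        ev.biomarker_context[slot] = np.nan  # stored values deliberately unused
    return ev


@pytest.fixture(scope="module")
def seizure_events_3hz(default_bank):
    return [make_event(i, freq=3.0, seed=100 + i) for i in range(10)]


class TestCorrectedSpectrum:
    def test_identical_events_have_unit_magnitude(self, small_bank):
        ev = make_event(0, freq=3.0, noise=0.0, seed=1)
        twin = make_event(1, freq=3.0, noise=0.0, seed=1)
        K = sf.corrected_spectrum([ev, twin], small_bank)
        nz = np.abs(K.values) > 1e-12
        assert np.allclose(np.abs(K.values[nz]), 1.0)

    def test_peak_at_the_oscillation_frequency(self, default_bank,
                                               seizure_events_3hz):
        K = sf.corrected_spectrum(seizure_events_3hz, default_bank)
        f_peak = K.frequencies[np.argmax(K.values)]
        assert f_peak == pytest.approx(3.0, rel=0.15)
        assert np.all(np.abs(K.values) <= 1 + 1e-12)

    def test_heterogeneous_events_are_penalized(self, default_bank):
        """Across-event disagreement lowers |K| against stereotyped events."""
        same = [make_event(i, freq=3.0, seed=i) for i in range(6)]
        mixed = [make_event(i, freq=3.0 if i % 2 else 8.0, seed=i)
                 for i in range(6)]
        k_same = sf.corrected_spectrum(same, default_bank).values.max()
        k_mixed = sf.corrected_spectrum(mixed, default_bank).values.max()
        assert k_mixed < k_same

    def test_incomplete_events_skipped_and_too_few_rejected(self, small_bank):
        ev = make_event(0, freq=3.0)
        gappy = make_event(1, freq=3.0)
        gappy.flow_context[CONTEXT_HALFSPAN] = None  # missing trigger window
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                sf.corrected_spectrum([ev, gappy], small_bank)


class TestSelectBand:
    def _spectrum(self, values):
        freqs = np.geomspace(0.5, 12, len(values))
        return sf.CorrectedSpectrum(freqs, np.asarray(values, float), 2)

    def test_triangular_peak_span(self):
        K = np.zeros(100)
        K[40:61] = np.concatenate([np.linspace(0.15, 1, 11),
                                   np.linspace(1, 0.15, 11)[1:]])
        cs = self._spectrum(K)
        band = sf.select_band(cs)
        assert band.fa == pytest.approx(cs.frequencies[40])
        assert band.fb == pytest.approx(cs.frequencies[60])

    def test_run_containing_global_max_wins(self):
        K = np.zeros(100)
        K[10:20] = 0.5  # secondary run
        K[60:70] = 0.9  # run holding the global max
        band = sf.select_band(self._spectrum(K))
        freqs = self._spectrum(K).frequencies
        assert band.fa == pytest.approx(freqs[60])
        assert band.fb == pytest.approx(freqs[69])

    def test_zero_threshold_takes_positive_support(self):
        K = np.full(50, -0.1)
        K[20:30] = 0.4
        band = sf.select_band(self._spectrum(K), rel_threshold=0.0)
        freqs = self._spectrum(K).frequencies
        assert band.fa == pytest.approx(freqs[20])
        assert band.fb == pytest.approx(freqs[29])

    def test_no_positive_peak_rejected(self):
        with pytest.raises(ValueError):
            sf.select_band(self._spectrum(np.full(50, -0.2)))


def flat_trace(value):
    return np.full(2 * CONTEXT_HALFSPAN + 1, float(value))


class TestFillingNumber:
    def test_saturated_event_fills_all_of_n(self):
        for N in (3, 7, 12):
            assert sf.filling_number(0.9, N, [flat_trace(1.0)]) == N

    def test_minimum_over_events(self):
        t1 = flat_trace(0.0)
        t1[CONTEXT_HALFSPAN - 6 : CONTEXT_HALFSPAN + 1] = 1.0  # 7 above
        t2 = flat_trace(0.0)
        t2[CONTEXT_HALFSPAN - 2 : CONTEXT_HALFSPAN + 1] = 1.0  # 3 above
        assert sf.filling_number(0.5, 7, [t1, t2]) == 3

    def test_exceeding_context_rejected(self):
        with pytest.raises(ValueError):
            sf.filling_number(0.5, CONTEXT_HALFSPAN + 2, [flat_trace(1.0)])

    def test_matches_independent_recount_on_grid(self):
        rng = np.random.default_rng(17)
        traces = [np.clip(rng.random(51), 0, 1) for _ in range(5)]
        for T in (0.2, 0.5, 0.8):
            for N in (2, 5, 9, 15):
                expected = min(
                    sum(tr[CONTEXT_HALFSPAN - N + 1 : CONTEXT_HALFSPAN + 1] > T)
                    for tr in traces
                )
                assert sf.filling_number(T, N, traces) == expected


class TestOptimize:
    def test_saturated_trace_closed_form(self):
        """With biomarker pinned at 1, C = T*N: argmax at grid corner."""
        result = optimize_from_traces([flat_trace(1.0)], sf.DEFAULT_BAND)
        assert result.params.T == pytest.approx(0.95)
        assert result.params.N == 15
        assert result.params.n == 15

    def test_grid_argmax_matches_brute_force(self):
        rng = np.random.default_rng(23)
        traces = []
        for _ in range(8):
            tr = np.clip(rng.normal(0.1, 0.15, 51), 0, 1)
            tr[CONTEXT_HALFSPAN - 8 : CONTEXT_HALFSPAN + 1] = rng.uniform(
                0.4, 1.0, 9
            )
            traces.append(tr)
        result = optimize_from_traces(traces, sf.DEFAULT_BAND)
        # independent argmax with explicit tie-breaking
        cells = []
        for T in DEFAULT_T_GRID:
            for N in DEFAULT_N_GRID:
                n = min(
                    sum(tr[CONTEXT_HALFSPAN - N + 1 : CONTEXT_HALFSPAN + 1] > T)
                    for tr in traces
                )
                if n >= 1:
                    cells.append((T * (2 * n - N), T, -N, N, n))
        c, T, _, N, n = max(cells)
        assert result.params.T == pytest.approx(T)
        assert result.params.N == N
        assert result.params.n == n

    def test_too_few_events_refused(self, small_bank):
        events = [make_event(i, freq=3.0, seed=i) for i in range(4)]
        with pytest.raises(ValueError):
            sf.optimize_params(events, small_bank, sf.DEFAULT_BAND, min_events=10)

    def test_preservation_guarantee_on_random_training_sets(self):
        """Every training seizure stays detected under the optimized params."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            traces = []
            for _ in range(6):
                tr = np.clip(rng.normal(0.05, 0.1, 51), 0, 1)
                width = int(rng.integers(5, 12))
                tr[CONTEXT_HALFSPAN - width + 1 : CONTEXT_HALFSPAN + 1] = (
                    rng.uniform(0.45, 1.0, width)
                )
                traces.append(tr)
            result = optimize_from_traces(traces, sf.DEFAULT_BAND)
            p = result.params
            for tr in traces:
                events = sf.detect_offline(tr[: CONTEXT_HALFSPAN + 1], p)
                assert events, "a training seizure would be missed"


class TestEndToEndAdaptation:
    def test_band_recovery_from_constructed_events(self, default_bank,
                                                   seizure_events_3hz):
        result = sf.adapt_parameters(seizure_events_3hz, default_bank)
        assert result.band.fa <= 3.0 <= result.band.fb
        # the optimized criterion remains a valid detection rule
        assert 1 <= result.params.n <= result.params.N

    def test_adaptation_is_stable_on_stationary_data(self, default_bank):
        """Re-optimizing under the optimized parameters barely moves them.

        Events detected with the learned settings on statistically
        identical data should yield a band within one grid step and a
        (T, N) within (0.05, 2) of the previous optimum.
        """
        from seizeflow import pipeline

        def run_trial(seed, config):
            program = sf.make_trial_program(
                seed=seed, duration=1100, n_seizures=10, n_normal=0,
                n_tremor=0, seizure_freq_range=(3.0, 3.0),
            )
            res = pipeline.run(None, config,
                               rates=program.truth_series().values)
            return [e for e in res.events if e.context_complete(15)]

        cfg = sf.PipelineConfig()
        first = sf.adapt_parameters(run_trial(501, cfg), default_bank)
        cfg2 = sf.PipelineConfig(band=(first.band.fa, first.band.fb),
                                 T=first.params.T, N=first.params.N,
                                 n=first.params.n)
        second = sf.adapt_parameters(run_trial(502, cfg2), default_bank)
        grid_step = 12 / 0.5  # ratio spanned by the geometric grid
        assert abs(np.log(second.band.fa / first.band.fa)) < np.log(grid_step) / 199 * 3
        assert abs(np.log(second.band.fb / first.band.fb)) < np.log(grid_step) / 199 * 3
        assert abs(second.params.T - first.params.T) <= 0.05
        assert abs(second.params.N - first.params.N) <= 2

    def test_biomarkers_recomputed_under_new_band(self, default_bank):
        """Filling numbers must follow the band, not stored biomarker values."""
        ev = make_event(0, freq=3.0, seed=5)
        narrow = sf.FrequencyBand(2.5, 3.6)
        off_band = sf.FrequencyBand(7.0, 11.0)
        tr_narrow = recompute_biomarkers([ev], default_bank, narrow)[0]
        tr_off = recompute_biomarkers([ev], default_bank, off_band)[0]
        assert tr_narrow[CONTEXT_HALFSPAN] > 0.4
        assert tr_off[CONTEXT_HALFSPAN] < 0.2
        assert tr_narrow[CONTEXT_HALFSPAN] > tr_off[CONTEXT_HALFSPAN] + 0.3
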