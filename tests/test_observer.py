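"""Synthetic observers: decision rules, channel curves, dataset simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsegap import (
    GapObserverParams,
    RateObserverParams,
    RateStimulusSpec,
    build_exp1_schedule,
    gap_pc,
    generate_rate_sequence,
    simulate_dataset,
    simulate_gap_trial,
    simulate_rate_response,
)
from pulsegap.observer import _decide_slow
from pulsegap.sdt import zm_bias, zm_sensitivity
from pulsegap.stimuli import GapTrialSpec, _sample_ipis


def _noiseless(criterion=158.0):
    return RateObserverParams(
        sigma_sense_ms={"V": 0.0, "T": 0.0},
        persistence_ms={"V": 0.0, "T": 0.0},
        criterion_ms=criterion,
        lapse=0.0,
        subject_cv=0.0,
        criterion_jitter_cv=0.0,
    )


def _error_rates(modality, level, params, n=20_000, seed=0):
    """Monte-Carlo (miss, fa) for the rate observer in one noise cell."""
    rng = np.random.default_rng(seed)
    out = {}
    for rate in (4, 6):
        spec = RateStimulusSpec(rate, level)
        ipis = _sample_ipis(spec.nominal_ipi_ms, spec.sigma_ms, n * 9, rng).reshape(n, 9)
        rho = np.full(n, params.persistence_ms[modality])
        sig = np.full(n, params.sigma_sense_ms[modality])
        out[rate] = _decide_slow(ipis, rho, sig, params, rng).mean()
    return 1.0 - out[4], out[6]  # miss rate, false-alarm rate


class TestRateObserver:
    def test_noiseless_observer_categorizes_perfectly(self):
        params = _noiseless()
        slow_seq = generate_rate_sequence(RateStimulusSpec(4, 0.0), 10, rng=0)
        fast_seq = generate_rate_sequence(RateStimulusSpec(6, 0.0), 10, rng=0)
        for trial in range(5):
            assert simulate_rate_response(slow_seq, "V", params, rng=trial)[0] == "slow"
            assert simulate_rate_response(fast_seq, "T", params, rng=trial)[0] == "fast"

    def test_single_pulse_rejected(self):
        seq = generate_rate_sequence(RateStimulusSpec(4, 0.0), 1, rng=0)
        with pytest.raises(ValueError):
            simulate_rate_response(seq, "V", _noiseless(), rng=0)

    def test_more_sensory_noise_lowers_sensitivity(self):
        quiet = RateObserverParams(
            sigma_sense_ms={"V": 20.0, "T": 20.0}, lapse=0.0, subject_cv=0.0
        )
        noisy = RateObserverParams(
            sigma_sense_ms={"V": 90.0, "T": 90.0}, lapse=0.0, subject_cv=0.0
        )
        a = {}
        for name, params in [("quiet", quiet), ("noisy", noisy)]:
            miss, fa = _error_rates("T", 0.10, params)
            a[name] = zm_sensitivity(1 - miss, fa)
        assert a["noisy"] < a["quiet"]

    def test_more_stimulus_noise_lowers_sensitivity(self):
        params = RateObserverParams(lapse=0.0, subject_cv=0.0)
        a = {}
        for level in (0.0, 0.40):
            miss, fa = _error_rates("T", level, params)
            a[level] = zm_sensitivity(1 - miss, fa)
        assert a[0.40] < a[0.0]

    def test_persistence_asymmetry_biases_visual_toward_fast(self):
        # rho_V >> rho_T with matched sensory noise: visual criterion b > 1
        # and 4-Hz visual trains suffer more errors than 6-Hz ones
        params = RateObserverParams(
            sigma_sense_ms={"V": 50.0, "T": 50.0},
            persistence_ms={"V": 40.0, "T": 5.0},
            lapse=0.0,
            subject_cv=0.0,
        )
        miss_v, fa_v = _error_rates("V", 0.10, params)
        miss_t, fa_t = _error_rates("T", 0.10, params)
        b_v = zm_bias(1 - miss_v, fa_v)
        b_t = zm_bias(1 - miss_t, fa_t)
        assert b_v > 1.1
        assert b_v > b_t
        assert miss_v > fa_v  # more errors on 4-Hz than 6-Hz visual trials


class TestGapChannel:
    def test_channel_midpoint_is_three_quarters(self):
        params = GapObserverParams(lapse=0.0)
        assert gap_pc(params.tau_ms["T"], "T", params) == pytest.approx(0.75)
        assert gap_pc(params.tau_ms["V"], "V", params) == pytest.approx(0.75)

    def test_asymptotes(self):
        params = GapObserverParams(lapse=0.0)
        assert gap_pc(1e6, "T", params) == pytest.approx(1.0)
        assert gap_pc(0.0, "V", params) == pytest.approx(0.5, abs=1e-4)

    def test_full_tactile_reliance_collapses_to_tactile_channel(self):
        params = GapObserverParams(tactile_reliance=1.0)
        gaps = np.linspace(0, 40, 50)
        assert np.allclose(gap_pc(gaps, "VT", params), gap_pc(gaps, "T", params))

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            gap_pc(-1.0, "T", GapObserverParams())

    @given(
        lapse=st.floats(0.0, 0.1),
        pi=st.floats(0.0, 1.0),
        tau_t=st.floats(1.0, 10.0),
        tau_v=st.floats(5.0, 30.0),
        slope=st.floats(0.5, 10.0),
    )
    def test_probability_correct_nondecreasing_in_gap(self, lapse, pi, tau_t, tau_v, slope):
        params = GapObserverParams(
            tau_ms={"V": tau_v, "T": tau_t},
            slope_ms={"V": slope, "T": slope},
            lapse=lapse,
            tactile_reliance=pi,
        )
        gaps = np.linspace(0, 64, 200)
        for modality in ("V", "T", "VT"):
            p = gap_pc(gaps, modality, params)
            assert np.all(np.diff(p) >= -1e-12)
            assert np.all((p >= 0.5 - lapse - 1e-12) & (p <= 1 - lapse + 1e-12))

    def test_trial_outcomes_follow_channel_probability(self):
        params = GapObserverParams(lapse=0.0)
        huge = GapTrialSpec(32, "T", dp_first=True)
        rng = np.random.default_rng(0)
        choices = [simulate_gap_trial(huge, params, rng) for _ in range(200)]
        assert all(c == ("first", True) for c in choices)
        # zero-information channel: correctness converges to the 2AFC guess rate
        chance = GapObserverParams(
            tau_ms={"V": 1e9, "T": 1e9}, slope_ms={"V": 4.0, "T": 4.0}, lapse=0.0
        )
        trial = GapTrialSpec(2, "V", dp_first=False)
        correct = np.array(
            [simulate_gap_trial(trial, chance, rng)[1] for _ in range(10_000)]
        )
        assert correct.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(10_000))


class TestSimulateDataset:
    def test_row_count_and_determinism(self, exp1_schedule):
        params = RateObserverParams()
        a = simulate_dataset(exp1_schedule, params, 2, np.random.default_rng(9))
        b = simulate_dataset(exp1_schedule, params, 2, np.random.default_rng(9))
        assert len(a) == 2 * 800
        assert a.equals(b)

    def test_zero_premature_rate_produces_none(self, exp1_schedule):
        from pulsegap import apply_exclusions

        table = simulate_dataset(
            exp1_schedule,
            RateObserverParams(),
            3,
            np.random.default_rng(2),
            premature_rate=0.0,
            no_response_rate=0.0,
        )
        _, summary = apply_exclusions(table, experiment=1)
        assert summary["n_excluded"].sum() == 0

    def test_experiment_mismatch_rejected(self, exp1_schedule):
        with pytest.raises(ValueError):
            simulate_dataset(exp1_schedule, GapObserverParams(), 2, 0)

    def test_gap_rows_have_valid_choices(self, exp2_small_table):
        t = exp2_small_table
        assert len(t) == 6 * 450
        answered = t[t["response"] != "none"]
        # choice is consistent with presentation order and correctness
        expect = np.where(
            answered["correct"] == answered["dp_first"].astype(bool), "first", "second"
        )
        assert (answered["response"] == expect).all()
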