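"""Exclusion rules and the nonparametric A/b estimators."""

import numpy as np
import pandas as pd
import pytest

from pulsegap import (
    RateObserverParams,
    apply_exclusions,
    estimate_sdt,
    rates_from_counts,
    simulate_dataset,
    tabulate_sdt,
    zm_bias,
    zm_sensitivity,
)
from pulsegap.sdt import SDTCounts


def _mini_table(rows):
    base = {
        "subject_id": "S01",
        "experiment": 1,
        "block": 0,
        "trial_index": 0,
        "modality": "V",
        "rate_hz": 4,
        "noise_level": 0.0,
        "gap_ms": np.nan,
        "dp_first": np.nan,
        "ipi_sequence": ";".join(["200"] * 9),
        "response": "slow",
        "correct": True,
        "rt_ms": 2500.0,
        "pulses_observed": 10,
        "seed": 0,
    }
    return pd.DataFrame([{**base, **r, "trial_index": i} for i, r in enumerate(rows)])


class TestExclusions:
    def test_no_response_trials_removed_and_tallied(self):
        table = _mini_table(
            [{}, {"response": "none", "rt_ms": np.nan}] * 3
        )
        kept, summary = apply_exclusions(table, experiment=1)
        assert len(kept) == 3
        assert summary.set_index("reason").loc["no_response", "n_excluded"] == 3

    def test_premature_response_excluded_in_rate_task(self):
        # second pulse onsets at 50 + 200 = 250 ms; a 150-ms response carries
        # no rate information
        table = _mini_table([{"rt_ms": 150.0}, {"rt_ms": 251.0}])
        kept, summary = apply_exclusions(table, experiment=1)
        assert len(kept) == 1
        assert summary.set_index("reason").loc["premature", "n_excluded"] == 1

    def test_short_rt_retained_in_gap_task(self):
        table = _mini_table(
            [{"experiment": 2, "rt_ms": 80.0, "response": "first", "gap_ms": 8.0,
              "ipi_sequence": "", "rate_hz": np.nan}]
        )
        kept, _ = apply_exclusions(table, experiment=2)
        assert len(kept) == 1

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(_mini_table([{}]), experiment=3)

    def test_trial_accounting_conserved(self, exp1_small_table):
        kept, summary = apply_exclusions(exp1_small_table, experiment=1)
        assert len(kept) + summary["n_excluded"].sum() == len(exp1_small_table)


class TestTabulation:
    def test_counts_follow_definitions(self):
        rows = (
            [{"response": "slow", "rate_hz": 4}] * 30
            + [{"response": "fast", "rate_hz": 4}] * 10
            + [{"response": "slow", "rate_hz": 6}] * 8
            + [{"response": "fast", "rate_hz": 6}] * 32
        )
        counts = tabulate_sdt(_mini_table(rows))
        row = counts.iloc[0]
        assert (row["n_hit"], row["n_miss"], row["n_fa"], row["n_cr"]) == (30, 10, 8, 32)

    def test_gap_table_rejected(self):
        table = _mini_table([{"experiment": 2}])
        with pytest.raises(ValueError):
            tabulate_sdt(table)

    def test_noiseless_observer_never_errs(self, exp1_schedule):
        params = RateObserverParams(
            sigma_sense_ms={"V": 0.0, "T": 0.0},
            persistence_ms={"V": 0.0, "T": 0.0},
            criterion_ms=158.0,
            lapse=0.0,
            subject_cv=0.0,
            criterion_jitter_cv=0.0,
        )
        table = simulate_dataset(
            exp1_schedule, params, 1, np.random.default_rng(0),
            no_response_rate=0.0, premature_rate=0.0,
        )
        # jittered IPIs can legitimately cross the criterion at high noise;
        # the guaranteed-noiseless case is the isochronous cell
        iso = table[table["noise_level"] == 0.0]
        counts = tabulate_sdt(iso)
        assert (counts["n_miss"] == 0).all() and (counts["n_fa"] == 0).all()


class TestRates:
    def test_interior_rates_unchanged(self):
        assert rates_from_counts(SDTCounts(30, 10, 8, 32)) == (0.75, 0.20)
        assert rates_from_counts(SDTCounts(20, 20, 20, 20)) == (0.5, 0.5)

    def test_boundary_correction(self):
        H, F = rates_from_counts(SDTCounts(40, 0, 0, 40))
        assert H == pytest.approx(1 - 1 / 80)
        assert F == pytest.approx(1 / 80)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            rates_from_counts(SDTCounts(0, 0, 5, 5))


class TestZhangMueller:
    @pytest.mark.parametrize(
        "H, F, expected",
        [
            (0.5, 0.5, 0.5),
            (0.9, 0.1, 0.94),          # upper-left branch
            (0.3, 0.3, 0.5),           # both-below-half branch
            (0.7, 0.7, 0.5),           # both-above-half branch
        ],
    )
    def test_sensitivity_examples(self, H, F, expected):
        assert zm_sensitivity(H, F) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "H, F, expected",
        [
            (0.75, 0.25, 1.0),
            (0.8, 0.1, 1.8 / 1.4),
            (0.4, 0.2, 0.56 / 0.36),
        ],
    )
    def test_bias_examples(self, H, F, expected):
        assert zm_bias(H, F) == pytest.approx(expected)

    @pytest.mark.parametrize("H, F", [(0.0, 0.5), (1.0, 0.5), (0.5, -0.1), (0.5, 1.2)])
    def test_out_of_range_rates_rejected(self, H, F):
        with pytest.raises(ValueError):
            zm_sensitivity(H, F)
        with pytest.raises(ValueError):
            zm_bias(H, F)

    def test_chance_diagonal_gives_half(self):
        h = np.linspace(0.01, 0.99, 199)
        assert np.allclose(zm_sensitivity(h, h), 0.5, atol=1e-12)

    def test_neutral_criterion_on_equal_error_diagonal(self):
        h = np.linspace(0.501, 0.999, 250)
        assert np.allclose(zm_bias(h, 1 - h), 1.0, atol=1e-12)

    def test_branch_continuity(self):
        eps = 1e-11
        f = np.linspace(0.01, 0.49, 49)
        # crossing H = 0.5
        assert np.allclose(
            zm_sensitivity(0.5 - eps, f), zm_sensitivity(0.5 + eps, f), atol=1e-9
        )
        assert np.allclose(zm_bias(0.5 - eps, f), zm_bias(0.5 + eps, f), atol=1e-9)
        # crossing F = 0.5
        h = np.linspace(0.51, 0.99, 49)
        assert np.allclose(
            zm_sensitivity(h, 0.5 - eps), zm_sensitivity(h, 0.5 + eps), atol=1e-9
        )
        assert np.allclose(zm_bias(h, 0.5 - eps), zm_bias(h, 0.5 + eps), atol=1e-9)

    def test_error_direction_correspondence(self):
        # b > 1 iff misses exceed false alarms (1 - H > F), b < 1 iff the
        # reverse, across the three above-chance branches; excluded: the
        # sub-chance reflection (which does not preserve this reading) and
        # exactly-chance cells H = F, where b = 1 by construction
        grid = np.linspace(0.02, 0.98, 49)
        H, F = np.meshgrid(grid, grid)
        H, F = H.ravel(), F.ravel()
        keep = H > F + 1e-9
        H, F = H[keep], F[keep]
        b = zm_bias(H, F)
        misses_exceed = (1 - H) > F + 1e-12
        fas_exceed = (1 - H) < F - 1e-12
        assert np.all(b[misses_exceed] > 1)
        assert np.all(b[fas_exceed] < 1)

    def test_sensitivity_monotone_in_rates(self):
        h = np.linspace(0.05, 0.95, 91)
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            a = zm_sensitivity(h, np.full_like(h, f))
            assert np.all(np.diff(a) > 0)
        f = np.linspace(0.05, 0.95, 91)
        for hh in (0.1, 0.3, 0.5, 0.7, 0.9):
            a = zm_sensitivity(np.full_like(f, hh), f)
            assert np.all(np.diff(a) < 0)

    def test_subchance_reflection(self):
        assert zm_sensitivity(0.2, 0.7) == pytest.approx(1 - zm_sensitivity(0.7, 0.2))
        assert zm_bias(0.2, 0.7) == pytest.approx(1 / zm_bias(0.7, 0.2))


class TestEstimatePipeline:
    def test_ten_cells_per_subject(self, exp1_small_table):
        kept, _ = apply_exclusions(exp1_small_table, experiment=1)
        est = estimate_sdt(kept)
        assert est.groupby("subject_id").size().eq(10).all()
        assert est["A"].between(0, 1).all()
        assert (est["b"] > 0).all()

    def test_miss_heavy_observer_yields_b_above_one(self, exp1_schedule):
        # strong visual persistence pushes 4-Hz trains under the criterion:
        # misses dominate and the estimated criterion exceeds 1
        params = RateObserverParams(
            persistence_ms={"V": 45.0, "T": 5.0},
            lapse=0.0,
            subject_cv=0.0,
            criterion_jitter_cv=0.0,
        )
        table = simulate_dataset(
            exp1_schedule, params, 2, np.random.default_rng(3),
            no_response_rate=0.0, premature_rate=0.0,
        )
        est = estimate_sdt(table)
        v = est[est["modality"] == "V"]
        assert (v["b"] > 1).mean() > 0.8
        assert v.groupby("noise_level")["b"].mean().min() > 1
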