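"""Synthetic observers for the rate-categorization and gap-detection tasks.

Neither task comes with a generative response model; these observers are the
minimal stochastic models that reproduce the qualitative structure the
analyses are designed to detect, so that every downstream stage can be tested
end-to-end on simulated subjects.

Rate observer
-------------
Each physical IPI is perceived shortened by a modality-specific *persistence*
amount rho (the sensory response to a pulse outlasts the pulse, filling in
the start of the following empty interval; visual persistence > tactile), and
corrupted by additive Gaussian sensory noise.  The decision statistic is a
geometrically weighted mean of the perceived IPIs (earlier intervals weighted
more); the observer responds "slow" when the statistic exceeds a criterion
``c`` and lapses (responds at random) with a small probability.  Because
visual persistence shortens perceived IPIs, 4-Hz visual trains are pushed
toward the criterion and mistaken "fast" responses dominate — the mechanism
behind a decision criterion b > 1 on visual trials.

Gap observer
------------
Each unimodal channel m detects the gap with probability
``p_m(x) = 0.5 + (0.5 - lapse) * Phi((x - tau_m) / slope_m)``,
a probit channel whose ``tau_m`` is the gap at channel d' = 1 (75% correct at
zero lapse).  Bimodal trials are judged by the tactile channel alone with
probability ``tactile_reliance`` (pi) and by the visual channel otherwise — a
probability mixture, not optimal integration, because empirically the bimodal
threshold sits slightly *above* the tactile threshold, which variance-weighted
averaging cannot produce.

Both observers support between-subject heterogeneity via ``subject_cv``:
per-subject lognormal scale factors (unit mean) on the sensory parameters.
Without heterogeneity, across-subject accuracy correlations are pure binomial
noise and the unimodal-bimodal dominance analysis has nothing to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stimuli import (
    GAP_SET_MS,
    MODALITIES_EXP1,
    MODALITIES_EXP2,
    PULSE_MS,
    ExperimentSchedule,
    GapTrialSpec,
    PulseSequence,
    parse_ipi_sequence,
)

__all__ = [
    "RateObserverParams",
    "GapObserverParams",
    "simulate_rate_response",
    "gap_pc",
    "true_gap_threshold",
    "simulate_gap_trial",
    "simulate_dataset",
]


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal factors with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=size)


@dataclass(frozen=True)
class RateObserverParams:
    """Generative parameters of the rate-categorization observer.

    sigma_sense_ms : per-modality SD (ms) of additive perceptual noise on
        each IPI.
    persistence_ms : per-modality shortening rho (ms) applied to each
        perceived IPI; visual default exceeds tactile.
    criterion_ms : cutoff c on the weighted mean perceived IPI; "slow" iff
        statistic > c.
    lapse : probability of a uniformly random response.
    weight_decay : geometric decay of per-interval evidence weights
        (w_i proportional to decay**i, earlier intervals weighted more).
    subject_cv : between-subject lognormal CV applied to sigma_sense and
        persistence.
    criterion_jitter_cv : between-subject lognormal CV of the criterion;
        kept smaller than subject_cv because criterion displacement also
        erodes measured sensitivity.
    """

    sigma_sense_ms: dict = field(default_factory=lambda: {"V": 60.0, "T": 50.0})
    persistence_ms: dict = field(default_factory=lambda: {"V": 25.0, "T": 5.0})
    criterion_ms: float = 152.0
    lapse: float = 0.02
    weight_decay: float = 0.8
    subject_cv: float = 0.15
    criterion_jitter_cv: float = 0.08

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sigma_sense_ms.values()):
            raise ValueError("sensory noise SDs must be >= 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if not 0 < self.weight_decay <= 1:
            raise ValueError("weight_decay must be in (0, 1]")
        if any(v >= 116.0 for v in self.persistence_ms.values()):
            raise ValueError("persistence must be below the 6-Hz nominal IPI (116 ms)")

    @property
    def experiment(self) -> int:
        return 1


@dataclass(frozen=True)
class GapObserverParams:
    """Generative parameters of the 2IFC gap-detection observer.

    tau_ms : per-channel gap (ms) at which channel discriminability d' = 1.
    slope_ms : per-channel internal-noise SD (ms) of the probit channel.
    lapse : probability of a random response (halves the upper asymptote gap).
    tactile_reliance : pi, probability a bimodal trial is judged by the
        tactile channel alone.
    subject_cv : between-subject lognormal CV applied to each channel's tau.
    """

    tau_ms: dict = field(default_factory=lambda: {"V": 15.5, "T": 5.0})
    slope_ms: dict = field(default_factory=lambda: {"V": 4.0, "T": 4.0})
    lapse: float = 0.02
    tactile_reliance: float = 0.85
    subject_cv: float = 0.25

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.tau_ms.values()):
            raise ValueError("tau must be > 0")
        if any(v <= 0 for v in self.slope_ms.values()):
            raise ValueError("slope must be > 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if not 0 <= self.tactile_reliance <= 1:
            raise ValueError("tactile_reliance must be in [0, 1]")

    @property
    def experiment(self) -> int:
        return 2


def _interval_weights(n: int, decay: float) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def _decide_slow(
    ipis: np.ndarray,
    rho: np.ndarray,
    sigma: np.ndarray,
    params: RateObserverParams,
    rng: np.random.Generator,
    criterion_ms: float | None = None,
) -> np.ndarray:
    """Vectorized rate decision: True where the observer answers "slow".

    ``ipis`` is (n_trials, n_intervals); ``rho`` and ``sigma`` broadcast over
    trials; ``criterion_ms`` overrides the population criterion (used for
    per-subject jitter).
    """
    n_trials, n_int = ipis.shape
    perceived = np.maximum(0.0, ipis - rho[:, None]) + rng.normal(
        0.0, 1.0, size=ipis.shape
    ) * sigma[:, None]
    w = _interval_weights(n_int, params.weight_decay)
    stat = perceived @ w
    c = params.criterion_ms if criterion_ms is None else criterion_ms
    slow = stat > c
    if params.lapse > 0:
        lapse_mask = rng.random(n_trials) < params.lapse
        slow = np.where(lapse_mask, rng.random(n_trials) < 0.5, slow)
    return slow


def simulate_rate_response(
    seq: PulseSequence,
    modality: str,
    params: RateObserverParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, int]:
    """Simulate one rate-categorization response.

    Returns ``(response, pulses_observed)``; the fixed-horizon observer uses
    every interval, so ``pulses_observed`` equals the pulse count.
    """
    if seq.n_pulses < 2:
        raise ValueError("rate judgment needs at least two pulses (one IPI)")
    if modality not in MODALITIES_EXP1:
        raise ValueError(f"modality {modality!r} not in {MODALITIES_EXP1}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ipis = np.asarray(seq.ipis_ms)[None, :]
    slow = _decide_slow(
        ipis,
        np.array([params.persistence_ms[modality]]),
        np.array([params.sigma_sense_ms[modality]]),
        params,
        rng,
    )[0]
    return ("slow" if slow else "fast"), seq.n_pulses


def gap_pc(gap_ms, modality: str, params: GapObserverParams, tau_factors: dict | None = None):
    """Probability of a correct 2IFC response at a given gap duration.

    Unimodal channels follow the probit form documented in the module
    docstring; the bimodal condition is the tactile-reliance mixture.
    ``tau_factors`` optionally rescales each channel's tau (used for
    per-subject heterogeneity).  Accepts scalar or array gaps.
    """
    gap = np.asarray(gap_ms, dtype=float)
    if np.any(gap < 0):
        raise ValueError("gap durations must be >= 0")
    if modality not in MODALITIES_EXP2:
        raise ValueError(f"modality {modality!r} not in {MODALITIES_EXP2}")
    factors = tau_factors or {}

    def channel(m: str) -> np.ndarray:
        tau = params.tau_ms[m] * factors.get(m, 1.0)
        z = (gap - tau) / params.slope_ms[m]
        return 0.5 + (0.5 - params.lapse) * norm.cdf(z)

    if modality == "VT":
        pi = params.tactile_reliance
        p = pi * channel("T") + (1 - pi) * channel("V")
    else:
        p = channel(modality)
    return float(p) if np.isscalar(gap_ms) else p


def true_gap_threshold(
    modality: str, params: GapObserverParams, target_pc: float = 0.76
) -> float:
    """Gap at which the *generating* curve reaches ``target_pc`` correct.

    Closed form for unimodal channels; bracketed root-finding for the bimodal
    mixture.  This is the ground-truth value a threshold estimator should
    recover from simulated data.
    """
    if not 0.5 < target_pc < 1 - params.lapse:
        raise ValueError("target_pc must lie inside the attainable range")
    if modality in ("V", "T"):
        z = norm.ppf((target_pc - 0.5) / (0.5 - params.lapse))
        return float(params.tau_ms[modality] + params.slope_ms[modality] * z)
    from scipy.optimize import brentq

    hi = max(params.tau_ms.values()) + 20 * max(params.slope_ms.values())
    return float(brentq(lambda x: gap_pc(x, modality, params) - target_pc, 0.0, hi))


def simulate_gap_trial(
    trial: GapTrialSpec,
    params: GapObserverParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, bool]:
    """Simulate one 2IFC trial: returns (choice, correct).

    ``choice`` names the interval reported to contain the double pulse.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    correct = bool(rng.random() < gap_pc(trial.gap_ms, trial.modality, params))
    if correct:
        choice = "first" if trial.dp_first else "second"
    else:
        choice = "second" if trial.dp_first else "first"
    return choice, correct


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def simulate_dataset(
    schedule: ExperimentSchedule,
    params: RateObserverParams | GapObserverParams,
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
    no_response_rate: float | None = None,
    premature_rate: float | None = None,
) -> pd.DataFrame:
    """Simulate a full trial table: every subject runs the given schedule.

    Small fractions of trials are flagged as response failures so that the
    exclusion stage is exercised: defaults are 0.4% no-response plus 0.2%
    premature responses for the rate task, and 0.9% no-response for the gap
    task.  Returns a tidy table, one row per subject x trial.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if schedule.experiment != params.experiment:
        raise ValueError(
            f"schedule is for experiment {schedule.experiment} but params are for "
            f"experiment {params.experiment}"
        )
    if schedule.experiment == 1:
        if no_response_rate is None:
            no_response_rate = 0.004
        if premature_rate is None:
            premature_rate = 0.002
        return _simulate_exp1(schedule, params, n_subjects, rng, no_response_rate, premature_rate)
    if no_response_rate is None:
        no_response_rate = 0.009
    if premature_rate not in (None, 0, 0.0):
        raise ValueError("premature responses are only simulated for experiment 1")
    return _simulate_exp2(schedule, params, n_subjects, rng, no_response_rate)


def _simulate_exp1(
    schedule: ExperimentSchedule,
    params: RateObserverParams,
    n_subjects: int,
    rng: np.random.Generator,
    no_response_rate: float,
    premature_rate: float,
) -> pd.DataFrame:
    trials = schedule.trials
    ipis = np.vstack([parse_ipi_sequence(s) for s in trials["ipi_sequence"]])
    n_trials = len(trials)
    modality = trials["modality"].to_numpy()
    rate = trials["rate_hz"].to_numpy()
    base_rho = np.where(modality == "V", params.persistence_ms["V"], params.persistence_ms["T"])
    base_sigma = np.where(
        modality == "V", params.sigma_sense_ms["V"], params.sigma_sense_ms["T"]
    )
    durations = ipis.sum(axis=1) + ipis.shape[1] * PULSE_MS + PULSE_MS
    second_onset = PULSE_MS + ipis[:, 0]

    frames = []
    for sid in _subject_ids(n_subjects):
        f_sigma, f_rho = _unit_mean_lognormal(rng, params.subject_cv, 2)
        (f_crit,) = _unit_mean_lognormal(rng, params.criterion_jitter_cv, 1)
        slow = _decide_slow(
            ipis,
            base_rho * f_rho,
            base_sigma * f_sigma,
            params,
            rng,
            criterion_ms=params.criterion_ms * f_crit,
        )
        response = np.where(slow, "slow", "fast")
        # motor latency on top of the full train; RTs are not analyzed
        rt = durations + rng.lognormal(np.log(350.0), 0.3, size=n_trials)
        premature = rng.random(n_trials) < premature_rate
        if premature.any():
            k = int(premature.sum())
            rt[premature] = rng.uniform(0.0, second_onset[premature])
            response[premature] = np.where(rng.random(k) < 0.5, "slow", "fast")
        none = rng.random(n_trials) < no_response_rate
        response = np.where(none, "none", response)
        rt[none] = np.nan
        df = trials.copy()
        df.insert(0, "subject_id", sid)
        df["response"] = response
        df["correct"] = (response == np.where(rate == 4, "slow", "fast")) & ~none
        df["rt_ms"] = rt
        df["pulses_observed"] = ipis.shape[1] + 1
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _simulate_exp2(
    schedule: ExperimentSchedule,
    params: GapObserverParams,
    n_subjects: int,
    rng: np.random.Generator,
    no_response_rate: float,
) -> pd.DataFrame:
    trials = schedule.trials
    n_trials = len(trials)
    gap = trials["gap_ms"].to_numpy(dtype=float)
    modality = trials["modality"].to_numpy()
    dp_first = trials["dp_first"].to_numpy(dtype=bool)

    frames = []
    for sid in _subject_ids(n_subjects):
        f_t, f_v = _unit_mean_lognormal(rng, params.subject_cv, 2)
        factors = {"T": f_t, "V": f_v}
        p = np.empty(n_trials)
        for m in MODALITIES_EXP2:
            mask = modality == m
            if mask.any():
                p[mask] = gap_pc(gap[mask], m, params, tau_factors=factors)
        correct = rng.random(n_trials) < p
        choice = np.where(correct == dp_first, "first", "second")
        rt = rng.lognormal(np.log(600.0), 0.35, size=n_trials)
        none = rng.random(n_trials) < no_response_rate
        choice = np.where(none, "none", choice)
        rt[none] = np.nan
        df = trials.copy()
        df.insert(0, "subject_id", sid)
        df["response"] = choice
        df["correct"] = correct & ~none
        df["rt_ms"] = rt
        df["pulses_observed"] = 2
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
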