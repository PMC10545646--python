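"""Pulse-train stimulus construction and trial scheduling.

Two tasks share the stimulus vocabulary defined here:

* **Rate categorization** (experiment 1): trains of up to ten 50-ms pulses at a
  nominal rate of 4 Hz ("slow") or 6 Hz ("fast"), with each inter-pulse
  interval (IPI) independently jittered by zero-mean Gaussian noise whose
  standard deviation scales with the nominal period, ``sigma = level * k``
  (``k`` = 250 ms at 4 Hz, 166 ms at 6 Hz).  Jittered IPIs are redrawn until
  they exceed a 1-ms floor, so the IPI distribution is a truncated normal with
  no atom at the bound.
* **Gap detection** (experiment 2): a 2IFC pair per trial — a double pulse
  (two 50-ms pulses separated by a gap of 2, 4, 8, 16 or 32 ms) against a
  single continuous pulse matched in total duration (100 ms + gap).

Schedules are exactly balanced: experiment 1 has 16 alternating-modality
blocks of 50 trials with 5 trials per rate x noise cell per block (so 20% of
the 800 trials are isochronous); experiment 2 has 9 blocks of 50 trials,
three per modality, with 10 trials per gap per block (30 per modality x gap
cell).  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RATES_HZ",
    "NOISE_LEVELS",
    "NOMINAL_PERIOD_MS",
    "PULSE_MS",
    "N_PULSES_MAX",
    "IPI_FLOOR_MS",
    "GAP_SET_MS",
    "RateStimulusSpec",
    "PulseSequence",
    "GapTrialSpec",
    "ExperimentSchedule",
    "noise_sigma",
    "sample_ipi",
    "generate_rate_sequence",
    "sequence_duration",
    "build_exp1_schedule",
    "build_exp2_schedule",
]

RATES_HZ: tuple[int, ...] = (4, 6)
NOISE_LEVELS: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.40)
#: nominal period k in ms; 6 Hz uses the rounded 166 ms, not 1000/6
NOMINAL_PERIOD_MS: dict[int, float] = {4: 250.0, 6: 166.0}
PULSE_MS: float = 50.0
N_PULSES_MAX: int = 10
IPI_FLOOR_MS: float = 1.0
GAP_SET_MS: tuple[int, ...] = (2, 4, 8, 16, 32)
SP_BASE_MS: float = 100.0  # single-pulse duration = SP_BASE_MS + gap

MODALITIES_EXP1: tuple[str, ...] = ("V", "T")
MODALITIES_EXP2: tuple[str, ...] = ("V", "T", "VT")

#: trial timing metadata (ms unless noted); recorded for completeness, not
#: used by any analysis stage.
EXP1_TIMING: dict[str, float] = {
    "alert_tone_ms": 500.0,
    "tone_to_sequence_ms": 500.0,
    "response_window_s": 8.0,
    "iti_s": 1.0,
}
EXP2_TIMING: dict[str, float] = {
    "alert_tone_ms": 200.0,
    "tone_to_sequence_ms": 800.0,
    "inter_stimulus_s": 1.0,
    "response_window_s": 2.0,
    "iti_s": 0.5,
}

_MAX_REJECTION_ROUNDS = 1000


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class RateStimulusSpec:
    """Parameters of one rate-categorization pulse train."""

    rate_hz: int
    noise_level: float
    pulse_ms: float = PULSE_MS
    n_pulses_max: int = N_PULSES_MAX
    ipi_floor_ms: float = IPI_FLOOR_MS

    def __post_init__(self) -> None:
        if self.rate_hz not in NOMINAL_PERIOD_MS:
            raise ValueError(f"unsupported rate {self.rate_hz!r}; expected one of {RATES_HZ}")
        if not any(np.isclose(self.noise_level, lv) for lv in NOISE_LEVELS):
            raise ValueError(
                f"unsupported noise level {self.noise_level!r}; expected one of {NOISE_LEVELS}"
            )

    @property
    def nominal_period_ms(self) -> float:
        """k, the nominal period (250 ms at 4 Hz, 166 ms at 6 Hz)."""
        return NOMINAL_PERIOD_MS[self.rate_hz]

    @property
    def nominal_ipi_ms(self) -> float:
        """Nominal empty interval between pulses (200 or 116 ms)."""
        return self.nominal_period_ms - self.pulse_ms

    @property
    def sigma_ms(self) -> float:
        """Jitter SD, ``noise_level * k``."""
        return noise_sigma(self.rate_hz, self.noise_level)


@dataclass(frozen=True)
class PulseSequence:
    """A realized pulse train: onset times, pulse duration, and IPIs.

    Onsets are in ms from first-pulse onset (= 0).  IPIs are empty
    offset-to-next-onset intervals, ``ipis_ms[i] = onsets[i+1] - (onsets[i] +
    pulse_ms)``.
    """

    pulse_onsets_ms: tuple[float, ...]
    pulse_ms: float
    ipis_ms: tuple[float, ...]
    spec: RateStimulusSpec

    def __post_init__(self) -> None:
        onsets = np.asarray(self.pulse_onsets_ms)
        if len(onsets) == 0:
            raise ValueError("a pulse sequence needs at least one pulse")
        if len(onsets) > self.spec.n_pulses_max:
            raise ValueError("more pulses than the spec allows")
        if len(self.ipis_ms) != len(onsets) - 1:
            raise ValueError("need exactly one IPI per adjacent pulse pair")
        if len(onsets) > 1:
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("pulse onsets must be strictly increasing")
            implied = np.diff(onsets) - self.pulse_ms
            if not np.allclose(implied, self.ipis_ms):
                raise ValueError("IPIs inconsistent with onsets")
            if np.any(np.asarray(self.ipis_ms) <= self.spec.ipi_floor_ms):
                raise ValueError("IPI at or below the floor")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_ms)


@dataclass(frozen=True)
class GapTrialSpec:
    """One 2IFC gap-detection trial."""

    gap_ms: float
    modality: str
    dp_first: bool

    def __post_init__(self) -> None:
        if self.gap_ms not in GAP_SET_MS:
            raise ValueError(f"gap {self.gap_ms!r} not in {GAP_SET_MS}")
        if self.modality not in MODALITIES_EXP2:
            raise ValueError(f"modality {self.modality!r} not in {MODALITIES_EXP2}")

    @property
    def sp_duration_ms(self) -> float:
        """Single-pulse duration, matched to the double pulse: 100 + gap."""
        return SP_BASE_MS + self.gap_ms


@dataclass
class ExperimentSchedule:
    """Ordered trial list for one subject-session of either experiment."""

    experiment: int
    trials: pd.DataFrame
    seed: int
    counterbalance_id: str = "V_first"
    timing: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def noise_sigma(rate_hz: int, noise_level: float) -> float:
    """Jitter SD in ms: ``noise_level * k`` with k the nominal period.

    >>> noise_sigma(4, 0.40)
    100.0
    """
    if rate_hz not in NOMINAL_PERIOD_MS:
        raise ValueError(f"unsupported rate {rate_hz!r}; expected one of {RATES_HZ}")
    if not any(np.isclose(noise_level, lv) for lv in NOISE_LEVELS):
        raise ValueError(f"unsupported noise level {noise_level!r}; expected one of {NOISE_LEVELS}")
    return float(noise_level) * NOMINAL_PERIOD_MS[rate_hz]


def _sample_ipis(
    nominal_ipi: float,
    sigma: float,
    size: int,
    rng: np.random.Generator,
    floor: float = IPI_FLOOR_MS,
) -> np.ndarray:
    """Draw jittered IPIs by rejection so every IPI > floor (no clipping atom)."""
    if sigma == 0:
        return np.full(size, nominal_ipi)
    out = nominal_ipi + rng.normal(0.0, sigma, size=size)
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = out <= floor
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out[bad] = nominal_ipi + rng.normal(0.0, sigma, size=n_bad)
    raise RuntimeError("IPI rejection sampling failed to terminate")


def sample_ipi(
    spec: RateStimulusSpec,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
):
    """Sample IPIs: nominal + N(0, sigma^2), redrawn until > the 1-ms floor.

    With ``size=None`` returns a scalar; otherwise an array of draws.
    At noise level 0 the nominal IPI is returned exactly.
    """
    rng = _as_rng(rng)
    n = 1 if size is None else int(size)
    draws = _sample_ipis(spec.nominal_ipi_ms, spec.sigma_ms, n, rng, spec.ipi_floor_ms)
    return float(draws[0]) if size is None else draws


def generate_rate_sequence(
    spec: RateStimulusSpec,
    n_pulses: int = N_PULSES_MAX,
    rng: np.random.Generator | int | None = None,
) -> PulseSequence:
    """Build a pulse train with ``n_pulses`` pulses and jittered IPIs."""
    if not 1 <= n_pulses <= spec.n_pulses_max:
        raise ValueError(f"n_pulses must be in [1, {spec.n_pulses_max}], got {n_pulses}")
    rng = _as_rng(rng)
    ipis = _sample_ipis(spec.nominal_ipi_ms, spec.sigma_ms, n_pulses - 1, rng, spec.ipi_floor_ms)
    onsets = np.concatenate([[0.0], np.cumsum(ipis + spec.pulse_ms)])
    return PulseSequence(
        pulse_onsets_ms=tuple(onsets.tolist()),
        pulse_ms=spec.pulse_ms,
        ipis_ms=tuple(ipis.tolist()),
        spec=spec,
    )


def sequence_duration(seq: PulseSequence) -> float:
    """Total span in ms from first-pulse onset to last-pulse offset."""
    return float(seq.pulse_onsets_ms[-1] + seq.pulse_ms - seq.pulse_onsets_ms[0])


def _format_ipis(ipis: Sequence[float]) -> str:
    return ";".join(f"{v:.6g}" for v in ipis)


def parse_ipi_sequence(text: str) -> np.ndarray:
    """Inverse of the semicolon-joined IPI encoding used in trial CSVs."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return np.array([])
    return np.asarray([float(tok) for tok in str(text).split(";")])


def build_exp1_schedule(
    seed: int = 0,
    counterbalance: str = "V_first",
    n_blocks: int = 16,
    trials_per_cell_per_block: int = 5,
) -> ExperimentSchedule:
    """Rate-categorization schedule: alternating-modality blocks, balanced cells.

    Defaults give 16 blocks x 50 trials = 800 trials, 40 per modality x rate x
    noise cell, with exactly 20% isochronous trials.
    """
    if counterbalance not in ("V_first", "T_first"):
        raise ValueError("counterbalance must be 'V_first' or 'T_first'")
    rng = np.random.default_rng(seed)
    first, second = ("V", "T") if counterbalance == "V_first" else ("T", "V")
    rows = []
    trial_index = 0
    for block in range(n_blocks):
        modality = first if block % 2 == 0 else second
        cells = [
            (rate, level)
            for rate in RATES_HZ
            for level in NOISE_LEVELS
            for _ in range(trials_per_cell_per_block)
        ]
        order = rng.permutation(len(cells))
        for idx in order:
            rate, level = cells[idx]
            spec = RateStimulusSpec(rate_hz=rate, noise_level=level)
            ipis = _sample_ipis(spec.nominal_ipi_ms, spec.sigma_ms, N_PULSES_MAX - 1, rng)
            rows.append(
                {
                    "experiment": 1,
                    "block": block,
                    "trial_index": trial_index,
                    "modality": modality,
                    "rate_hz": rate,
                    "noise_level": level,
                    "gap_ms": np.nan,
                    "dp_first": np.nan,
                    "ipi_sequence": _format_ipis(ipis),
                    "seed": seed,
                }
            )
            trial_index += 1
    return ExperimentSchedule(
        experiment=1,
        trials=pd.DataFrame(rows),
        seed=seed,
        counterbalance_id=counterbalance,
        timing=dict(EXP1_TIMING),
    )


def build_exp2_schedule(
    seed: int = 0,
    blocks_per_modality: int = 3,
    trials_per_gap_per_block: int = 10,
) -> ExperimentSchedule:
    """Gap-detection schedule: modality-blocked, gap-balanced 2IFC trials.

    Defaults give 9 blocks x 50 trials = 450 trials, 30 per modality x gap
    cell; presentation order (double pulse first or second) is randomized per
    trial.
    """
    rng = np.random.default_rng(seed)
    block_modalities = np.repeat(MODALITIES_EXP2, blocks_per_modality)
    block_modalities = block_modalities[rng.permutation(len(block_modalities))]
    rows = []
    trial_index = 0
    for block, modality in enumerate(block_modalities):
        gaps = np.repeat(GAP_SET_MS, trials_per_gap_per_block)
        gaps = gaps[rng.permutation(len(gaps))]
        dp_first = rng.random(len(gaps)) < 0.5
        for gap, first_flag in zip(gaps, dp_first):
            rows.append(
                {
                    "experiment": 2,
                    "block": block,
                    "trial_index": trial_index,
                    "modality": modality,
                    "rate_hz": np.nan,
                    "noise_level": np.nan,
                    "gap_ms": float(gap),
                    "dp_first": bool(first_flag),
                    "ipi_sequence": "",
                    "seed": seed,
                }
            )
            trial_index += 1
    return ExperimentSchedule(
        experiment=2,
        trials=pd.DataFrame(rows),
        seed=seed,
        counterbalance_id="na",
        timing=dict(EXP2_TIMING),
    )
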