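"""Trial exclusions and nonparametric signal-detection estimates (A, b).

The rate task is scored as a yes/no detection problem: a *hit* is a "slow"
response to a 4-Hz train and a *false alarm* is a "slow" response to a 6-Hz
train.  Sensitivity A (ROC-area-like, 0.5 = chance) and decision criterion b
(1 = neutral; b > 1 means mistaken "fast" responses outnumbered mistaken
"slow" responses) are the nonparametric estimators of Zhang & Mueller, chosen
over parametric d'/c because the jittered IPI distributions of the two rates
have unequal variance.

With H >= F the three branches are::

    F <= 1/2 <= H:   A = 3/4 + (H-F)/4 - F(1-H)
                     b = (5 - 4H) / (1 + 4F)
    F <= H < 1/2:    A = 3/4 + (H-F)/4 - F/(4H)
                     b = (H^2 + H) / (H^2 + F)
    1/2 < F <= H:    A = 3/4 + (H-F)/4 - (1-H)/(4(1-F))
                     b = ((1-F)^2 + (1-H)) / ((1-F)^2 + (1-F))

Sub-chance cells (H < F, never observed empirically) are handled by
reflection: A(H,F) = 1 - A(F,H) and b(H,F) = 1/b(F,H), flagged in the output.
Boundary rates of 0 or 1 are corrected to 1/(2N) and 1 - 1/(2N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import PULSE_MS, parse_ipi_sequence

__all__ = [
    "SDTCounts",
    "apply_exclusions",
    "tabulate_sdt",
    "rates_from_counts",
    "zm_sensitivity",
    "zm_bias",
    "estimate_sdt",
]


@dataclass(frozen=True)
class SDTCounts:
    """Hit/miss/false-alarm/correct-rejection counts for one cell."""

    n_hit: int
    n_miss: int
    n_fa: int
    n_cr: int

    def __post_init__(self) -> None:
        if min(self.n_hit, self.n_miss, self.n_fa, self.n_cr) < 0:
            raise ValueError("counts must be non-negative")


def apply_exclusions(table: pd.DataFrame, experiment: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop invalid trials and tally the reasons.

    Experiment 1 removes no-response trials and *premature* responses (RT
    before the onset of the second pulse, i.e. before any rate information).
    Experiment 2 removes only no-response trials; short-RT 2IFC trials are
    valid measurements and are retained.

    Returns ``(filtered_table, summary)`` where the summary has one row per
    exclusion reason with counts and proportions of the input table.
    """
    if experiment not in (1, 2):
        raise ValueError(f"unknown experiment {experiment!r}")
    table = table.copy()
    n_total = len(table)
    no_resp = table["response"] == "none"
    reasons = pd.Series("none", index=table.index)
    reasons[no_resp] = "no_response"
    if experiment == 1:
        first_ipi = np.array(
            [parse_ipi_sequence(s)[0] if s else np.nan for s in table["ipi_sequence"]]
        )
        second_onset = PULSE_MS + first_ipi
        premature = (~no_resp) & (table["rt_ms"].to_numpy() < second_onset)
        reasons[premature] = "premature"
    table["exclusion_reason"] = reasons.to_numpy()
    kept = table[table["exclusion_reason"] == "none"].copy()
    tallies = (
        table["exclusion_reason"].value_counts().reindex(["no_response", "premature"]).fillna(0)
    )
    if experiment == 2:
        tallies = tallies[["no_response"]]
    summary = pd.DataFrame(
        {
            "reason": tallies.index,
            "n_excluded": tallies.to_numpy(dtype=int),
            "proportion": tallies.to_numpy() / max(n_total, 1),
        }
    )
    return kept, summary


def tabulate_sdt(table: pd.DataFrame) -> pd.DataFrame:
    """Count hits/misses/false alarms/correct rejections per subject x modality x noise.

    Expects an experiment-1 table after exclusions.  A hit is "slow" to 4 Hz;
    a false alarm is "slow" to 6 Hz.
    """
    if not (table["experiment"] == 1).all():
        raise ValueError("SDT tabulation is defined for experiment-1 tables only")
    if (table["response"] == "none").any():
        raise ValueError("apply exclusions before tabulating")
    t = table.copy()
    t["slow"] = t["response"] == "slow"
    t["is_4hz"] = t["rate_hz"] == 4
    grouped = t.groupby(["subject_id", "modality", "noise_level"], sort=True)
    rows = []
    for (sid, mod, level), g in grouped:
        slow, is4 = g["slow"].to_numpy(), g["is_4hz"].to_numpy()
        rows.append(
            {
                "subject_id": sid,
                "modality": mod,
                "noise_level": level,
                "n_hit": int((slow & is4).sum()),
                "n_miss": int((~slow & is4).sum()),
                "n_fa": int((slow & ~is4).sum()),
                "n_cr": int((~slow & ~is4).sum()),
            }
        )
    return pd.DataFrame(rows)


def rates_from_counts(counts: SDTCounts) -> tuple[float, float]:
    """Hit and false-alarm rates with 1/(2N) boundary correction.

    A rate of exactly 0 is replaced by 1/(2N) and a rate of 1 by 1 - 1/(2N),
    where N is the number of trials of that type in the cell; interior rates
    are untouched.
    """
    n_sig = counts.n_hit + counts.n_miss
    n_noise = counts.n_fa + counts.n_cr

    def corrected(k: int, n: int) -> float:
        if n == 0:
            raise ValueError("empty cell: no trials of the required type")
        r = k / n
        if r == 0.0:
            return 1.0 / (2 * n)
        if r == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r

    return corrected(counts.n_hit, n_sig), corrected(counts.n_fa, n_noise)


def _check_rates(H, F) -> tuple[np.ndarray, np.ndarray]:
    H = np.asarray(H, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any((H <= 0) | (H >= 1) | (F <= 0) | (F >= 1)):
        raise ValueError("rates must lie strictly inside (0, 1); apply boundary correction")
    return H, F


def _zm_A_upper(H: np.ndarray, F: np.ndarray) -> np.ndarray:
    """A for H >= F (three-branch form)."""
    base = 0.75 + (H - F) / 4.0
    return np.select(
        [(F <= 0.5) & (H >= 0.5), H < 0.5, F > 0.5],
        [base - F * (1 - H), base - F / (4 * H), base - (1 - H) / (4 * (1 - F))],
    )


def _zm_b_upper(H: np.ndarray, F: np.ndarray) -> np.ndarray:
    """b for H >= F (three-branch form)."""
    return np.select(
        [(F <= 0.5) & (H >= 0.5), H < 0.5, F > 0.5],
        [
            (5 - 4 * H) / (1 + 4 * F),
            (H**2 + H) / (H**2 + F),
            ((1 - F) ** 2 + (1 - H)) / ((1 - F) ** 2 + (1 - F)),
        ],
    )


def zm_sensitivity(H, F):
    """Nonparametric sensitivity A in [0, 1]; 0.5 at chance (H = F).

    Sub-chance inputs (H < F) are reflected: ``1 - A(F, H)``.  Accepts
    scalars or arrays.
    """
    Ha, Fa = _check_rates(H, F)
    upper = _zm_A_upper(np.maximum(Ha, Fa), np.minimum(Ha, Fa))
    out = np.where(Ha >= Fa, upper, 1.0 - upper)
    return float(out) if np.isscalar(H) and np.isscalar(F) else out


def zm_bias(H, F):
    """Nonparametric criterion b > 0; 1 when misattribution errors balance.

    b > 1 iff misses exceed false alarms (1 - H > F).  Sub-chance inputs are
    handled by the reciprocal of the swapped estimate, ``1 / b(F, H)``.
    """
    Ha, Fa = _check_rates(H, F)
    upper = _zm_b_upper(np.maximum(Ha, Fa), np.minimum(Ha, Fa))
    out = np.where(Ha >= Fa, upper, 1.0 / upper)
    return float(out) if np.isscalar(H) and np.isscalar(F) else out


def estimate_sdt(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell SDT estimates for an excluded experiment-1 trial table.

    Returns one row per subject x modality x noise level with counts,
    boundary-corrected rates H and F, sensitivity A, criterion b, and a
    ``reflected`` flag marking sub-chance (H < F) cells.
    """
    counts = tabulate_sdt(table)
    H = np.empty(len(counts))
    F = np.empty(len(counts))
    for i, row in counts.iterrows():
        H[i], F[i] = rates_from_counts(
            SDTCounts(row["n_hit"], row["n_miss"], row["n_fa"], row["n_cr"])
        )
    out = counts.copy()
    out["H"] = H
    out["F"] = F
    out["A"] = zm_sensitivity(H, F)
    out["b"] = zm_bias(H, F)
    out["reflected"] = H < F
    return out
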