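"""Secondary statistics: criterion tests, simple effects, within-subject
error bars, and unimodal-bimodal dominance analysis.

These are the routine inferential steps applied to per-subject estimates:

* one-sample t-tests of the decision criterion b against the neutral value 1,
  Bonferroni-corrected over the 10 modality x noise cells;
* paired t-tests for a simple effect of modality at each noise level;
* Cousineau-Morey within-subject standard errors for repeated-measures
  error bars;
* Pearson correlation and OLS slope (tested against 1, the unimodal-dominance
  prediction) between unimodal and bimodal accuracy across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "test_bias_neutral",
    "simple_effect_modality",
    "within_subject_se",
    "unimodal_bimodal_relation",
]


def test_bias_neutral(
    estimates: pd.DataFrame,
    value_col: str = "b",
    null_value: float = 1.0,
    n_comparisons: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample t-tests of b against neutrality, Bonferroni-adjusted.

    ``estimates`` is a long table with columns ``subject_id``, ``modality``,
    ``noise_level`` and ``value_col``.  The Bonferroni factor defaults to the
    number of modality x noise cells (10 in the full design); adjusted
    p-values are capped at 1 and confidence intervals widened to
    ``1 - alpha/m``.
    """
    cells = list(estimates.groupby(["modality", "noise_level"], sort=True))
    m = n_comparisons if n_comparisons is not None else len(cells)
    rows = []
    for (mod, level), g in cells:
        vals = g[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError("need at least two subjects per cell for a t-test")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        n = len(vals)
        if sd == 0.0:
            # no spread: the test is degenerate; p reflects whether the
            # constant equals the null exactly
            t = np.nan
            p_raw = 1.0 if np.isclose(mean, null_value) else 0.0
            ci = (mean, mean)
            degenerate = True
        else:
            t, p_raw = stats.ttest_1samp(vals, null_value)
            tcrit = stats.t.ppf(1 - (alpha / m) / 2, df=n - 1)
            half = tcrit * sd / np.sqrt(n)
            ci = (mean - half, mean + half)
            degenerate = False
        rows.append(
            {
                "modality": mod,
                "noise_level": level,
                "mean": mean,
                "t": float(t) if np.isfinite(t) else np.nan,
                "df": n - 1,
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * m)),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def simple_effect_modality(
    estimates: pd.DataFrame,
    value_col: str = "A",
    modalities: tuple[str, str] = ("T", "V"),
) -> pd.DataFrame:
    """Paired t-test of ``modalities[0] - modalities[1]`` at each noise level.

    Requires both modalities for every subject at every level (paired data).
    P-values are reported unadjusted.
    """
    a, b = modalities
    wide = estimates.pivot_table(
        index=["subject_id", "noise_level"], columns="modality", values=value_col
    )
    if wide[[a, b]].isna().any().any():
        raise ValueError("unpaired data: every subject needs both modalities at each level")
    rows = []
    for level, g in wide.reset_index().groupby("noise_level", sort=True):
        diff = (g[a] - g[b]).to_numpy(dtype=float)
        n = len(diff)
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1))
        if sd == 0.0:
            t, p = np.nan, (1.0 if np.isclose(mean, 0.0) else 0.0)
            ci = (mean, mean)
        else:
            t, p = stats.ttest_rel(g[a], g[b])
            half = stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n)
            ci = (mean - half, mean + half)
        rows.append(
            {
                "noise_level": level,
                "contrast": f"{a} - {b}",
                "mean_diff": mean,
                "t": float(t) if np.isfinite(t) else np.nan,
                "df": n - 1,
                "p": float(p),
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
    return pd.DataFrame(rows)


def within_subject_se(matrix: pd.DataFrame) -> pd.Series:
    """Cousineau-Morey within-subject SE per condition.

    ``matrix`` is subjects x conditions with no missing cells.  Each row is
    centered on its subject mean (grand mean added back) and the per-condition
    SE of the centered scores is inflated by the Morey factor
    ``sqrt(C / (C - 1))``.
    """
    if matrix.isna().any().any():
        raise ValueError("within-subject SE requires a complete subject x condition matrix")
    n, c = matrix.shape
    if c < 2:
        raise ValueError("need at least two conditions (Morey correction undefined for C=1)")
    centered = matrix.sub(matrix.mean(axis=1), axis=0) + matrix.to_numpy().mean()
    return centered.std(ddof=1) / np.sqrt(n) * np.sqrt(c / (c - 1))


def unimodal_bimodal_relation(unimodal, bimodal) -> dict:
    """Across-subject relation between unimodal and bimodal accuracy.

    Returns the Pearson correlation (and its test), R^2, the OLS slope of
    bimodal on unimodal, and a t-test of the slope against 1 — the prediction
    if bimodal judgments were driven entirely by that unimodal channel.
    """
    x = np.asarray(unimodal, dtype=float)
    y = np.asarray(bimodal, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired subject accuracies")
    if np.std(x) == 0:
        raise ValueError("zero variance in the unimodal predictor; correlation undefined")
    lr = stats.linregress(x, y)
    n = len(x)
    if lr.stderr == 0:
        # perfectly collinear data: the slope test is degenerate
        t_slope = np.nan
        p_slope = 1.0 if np.isclose(lr.slope, 1.0) else 0.0
        degenerate = True
    else:
        t_slope = (lr.slope - 1.0) / lr.stderr
        p_slope = 2 * stats.t.sf(abs(t_slope), df=n - 2)
        degenerate = False
    return {
        "r": float(lr.rvalue),
        "r2": float(lr.rvalue**2),
        "p_correlation": float(lr.pvalue),
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "slope_se": float(lr.stderr),
        "t_slope_vs_1": float(t_slope) if np.isfinite(t_slope) else np.nan,
        "p_slope_vs_1": float(p_slope),
        "n": n,
        "degenerate": degenerate,
    }
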