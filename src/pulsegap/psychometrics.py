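"""2AFC psychometric-function fitting and gap-threshold estimation.

The gap-detection data are binomial counts of correct responses at each gap
duration.  The model is a two-parameter logistic with the 2AFC guess rate
fixed at 0.5::

    p(x) = 0.5 + 0.5 * logistic(beta0 + beta1 * x)

fit by maximum likelihood (quasi-Newton on the binomial log-likelihood with
analytic gradient, fixed start (0, 0.1), gradient tolerance 1e-8, so fits are
deterministic).  The gap-detection threshold is the inverse of the fitted
curve at a target proportion correct, by default 0.76 — the unbiased 2IFC
performance at d' = 1, ``Phi(1/sqrt(2))``.  Standard errors come from a
nonparametric bootstrap that resamples trials with replacement within each
gap cell; since trials within a cell are exchangeable Bernoulli outcomes this
is realized as a binomial redraw of each cell count at its observed
proportion.

No lapse parameter is estimated (matching the two-parameter model the
threshold definition assumes); a small generative lapse shows up as a slight
upward threshold bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "pc2afc_from_dprime",
    "fit_pf_2afc",
    "threshold_from_fit",
    "bootstrap_threshold_se",
    "fit_group_pfs",
    "fit_subject_pfs",
]

_START = np.array([0.0, 0.1])
_GTOL = 1e-8


def pc2afc_from_dprime(dprime: float) -> float:
    """Unbiased 2IFC proportion correct at a given d': ``Phi(d'/sqrt(2))``.

    >>> round(pc2afc_from_dprime(1.0), 2)
    0.76
    """
    if dprime < 0:
        raise ValueError("d' must be >= 0")
    return float(norm.cdf(dprime / np.sqrt(2.0)))


@dataclass
class PsychometricFit:
    """A fitted 2AFC logistic: linear predictor beta0 + beta1 * gap (ms)."""

    beta0: float
    beta1: float
    converged: bool
    loglik: float
    n_trials: dict = field(default_factory=dict)
    scope: str = "group"
    modality: str | None = None
    threshold_ms: float | None = None
    se_ms: float | None = None
    ci_low_ms: float | None = None
    ci_high_ms: float | None = None

    def predict(self, gap_ms):
        """Fitted probability correct at the given gap duration(s)."""
        return 0.5 + 0.5 * expit(self.beta0 + self.beta1 * np.asarray(gap_ms, dtype=float))


def _nll_and_grad(theta: np.ndarray, x: np.ndarray, k: np.ndarray, n: np.ndarray):
    eta = theta[0] + theta[1] * x
    q = expit(eta)
    p = 0.5 + 0.5 * q
    # p in (0.5, 1): log terms are safe once clipped away from the asymptote
    p = np.clip(p, 1e-12, 1 - 1e-12)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    dp_deta = 0.5 * q * (1 - q)
    common = -(k / p - (n - k) / (1 - p)) * dp_deta
    return nll, np.array([common.sum(), (common * x).sum()])


def fit_pf_2afc(
    gaps_ms,
    n_correct,
    n_total,
    scope: str = "group",
    modality: str | None = None,
) -> PsychometricFit:
    """Maximum-likelihood fit of the guess-rate-0.5 logistic to cell counts.

    ``gaps_ms``, ``n_correct`` and ``n_total`` are parallel per-level arrays.
    Complete separation (e.g. all levels answered perfectly) yields a fit
    flagged ``converged=False`` from which no threshold is derived.
    """
    x = np.asarray(gaps_ms, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    keep = n > 0
    x, k, n = x[keep], k[keep], n[keep]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct gap levels with trials")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("n_correct must lie in [0, n_total]")
    order = np.argsort(x)
    x, k, n = x[order], k[order], n[order]

    # The 2AFC link makes the likelihood non-concave; a single fixed start can
    # land in a negative-slope local minimum when low gaps sit near chance.
    # Run the fixed start plus a deterministic linearized start and keep the
    # better optimum.
    q = np.clip(2 * (k / n) - 1, 1e-3, 1 - 1e-3)
    z = np.log(q / (1 - q))
    slope = np.polyfit(x, z, 1)
    starts = [_START, np.array([slope[1], slope[0]])]
    res = None
    for start in starts:
        cand = minimize(
            _nll_and_grad,
            start,
            args=(x, k, n),
            jac=True,
            method="BFGS",
            options={"gtol": _GTOL, "maxiter": 500},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    beta0, beta1 = map(float, res.x)
    eta = beta0 + beta1 * x
    # runaway linear predictor at the data => separation, no finite MLE
    separated = bool(np.all(k == n)) or bool(np.max(np.abs(eta)) > 30)
    # BFGS may stop on precision loss at the optimum; judge by the gradient
    _, grad = _nll_and_grad(res.x, x, k, n)
    converged = (bool(res.success) or float(np.linalg.norm(grad)) < 1e-3) and not separated
    return PsychometricFit(
        beta0=beta0,
        beta1=beta1,
        converged=converged,
        loglik=-float(res.fun),
        n_trials={float(g): int(m) for g, m in zip(x, n)},
        scope=scope,
        modality=modality,
    )


def threshold_from_fit(fit: PsychometricFit, target_pc: float = 0.76) -> float:
    """Invert a converged fit at ``target_pc``: x* with fitted p(x*) = target.

    Closed form: ``x* = (logit(2*target - 1) - beta0) / beta1``.
    """
    if not 0.5 < target_pc < 1:
        raise ValueError("target_pc must be in (0.5, 1)")
    if not fit.converged:
        raise ValueError("cannot derive a threshold from a non-converged fit")
    if fit.beta1 <= 0:
        raise ValueError("cannot derive a threshold from a non-increasing fit")
    return float((logit(2 * target_pc - 1) - fit.beta0) / fit.beta1)


def bootstrap_threshold_se(
    gaps_ms,
    n_correct,
    n_total,
    n_boot: int = 5000,
    rng: np.random.Generator | int | None = None,
    target_pc: float = 0.76,
) -> dict:
    """Bootstrap SE and percentile CI of the gap threshold.

    Trials are resampled with replacement within each gap cell (implemented
    as a binomial redraw of the cell count at its observed proportion).
    Resamples whose refit fails to converge or has a non-positive slope are
    dropped and counted; if more than 20% fail a warning is attached.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(gaps_ms, dtype=float)
    k = np.asarray(n_correct, dtype=int)
    n = np.asarray(n_total, dtype=int)
    phat = k / n
    thresholds = []
    n_failed = 0
    k_star = rng.binomial(n[None, :], phat[None, :], size=(n_boot, len(x)))
    for b in range(n_boot):
        fit = fit_pf_2afc(x, k_star[b], n)
        if fit.converged and fit.beta1 > 0:
            thresholds.append(threshold_from_fit(fit, target_pc))
        else:
            n_failed += 1
    thresholds = np.asarray(thresholds)
    frac_failed = n_failed / n_boot
    warn = frac_failed > 0.20
    if warn:
        warnings.warn(
            f"{frac_failed:.0%} of bootstrap resamples failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(thresholds) < 2:
        raise RuntimeError("too few converged bootstrap resamples to form an SE")
    return {
        "se_ms": float(np.std(thresholds, ddof=1)),
        "ci_low_ms": float(np.percentile(thresholds, 2.5)),
        "ci_high_ms": float(np.percentile(thresholds, 97.5)),
        "n_failed": int(n_failed),
        "warn_nonconvergence": bool(warn),
    }


def _counts_by_gap(table: pd.DataFrame) -> pd.DataFrame:
    g = table.groupby("gap_ms", sort=True)["correct"]
    return pd.DataFrame({"gap_ms": g.sum().index, "n_correct": g.sum().to_numpy(), "n_total": g.count().to_numpy()})


def fit_group_pfs(
    table: pd.DataFrame,
    target_pc: float = 0.76,
    n_boot: int = 0,
    rng: np.random.Generator | int | None = None,
    aggregate: str = "pooled",
) -> list[PsychometricFit]:
    """Group-level fit per modality from an excluded gap-task trial table.

    ``aggregate='pooled'`` (default) pools trials across subjects;
    ``'subject-mean'`` averages per-subject proportions per gap and fits the
    averaged curve with the mean per-cell trial count as weight.  Thresholds
    are attached to each converged fit; bootstrap SEs when ``n_boot > 0``.
    """
    if aggregate not in ("pooled", "subject-mean"):
        raise ValueError("aggregate must be 'pooled' or 'subject-mean'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fits = []
    for modality, sub in table.groupby("modality", sort=True):
        if aggregate == "pooled":
            counts = _counts_by_gap(sub)
        else:
            per_subj = sub.groupby(["subject_id", "gap_ms"])["correct"].mean().reset_index()
            mean_p = per_subj.groupby("gap_ms")["correct"].mean()
            n_per = sub.groupby("gap_ms")["correct"].count() / sub["subject_id"].nunique()
            counts = pd.DataFrame(
                {
                    "gap_ms": mean_p.index,
                    "n_correct": (mean_p * n_per).to_numpy(),
                    "n_total": n_per.to_numpy(),
                }
            )
        fit = fit_pf_2afc(
            counts["gap_ms"], counts["n_correct"], counts["n_total"], scope="group", modality=modality
        )
        if fit.converged and fit.beta1 > 0:
            fit.threshold_ms = threshold_from_fit(fit, target_pc)
            if n_boot > 0:
                boot = bootstrap_threshold_se(
                    counts["gap_ms"],
                    np.round(counts["n_correct"]).astype(int),
                    counts["n_total"].astype(int),
                    n_boot=n_boot,
                    rng=rng,
                    target_pc=target_pc,
                )
                fit.se_ms = boot["se_ms"]
                fit.ci_low_ms = boot["ci_low_ms"]
                fit.ci_high_ms = boot["ci_high_ms"]
        fits.append(fit)
    return fits


def fit_subject_pfs(
    table: pd.DataFrame, target_pc: float = 0.76
) -> tuple[list[PsychometricFit], pd.DataFrame]:
    """Independent per-subject fits plus per-subject mean accuracy.

    Returns ``(fits, accuracy)`` where ``accuracy`` has one row per subject x
    modality with mean proportion correct pooled over all gap levels.
    Subjects with fewer than two usable gap levels in a modality are skipped
    (their fit is simply absent from the list).
    """
    fits = []
    for (sid, modality), sub in table.groupby(["subject_id", "modality"], sort=True):
        counts = _counts_by_gap(sub)
        if (counts["n_total"] > 0).sum() < 2:
            continue
        fit = fit_pf_2afc(
            counts["gap_ms"], counts["n_correct"], counts["n_total"], scope="subject", modality=modality
        )
        fit.subject_id = sid
        if fit.converged and fit.beta1 > 0:
            fit.threshold_ms = threshold_from_fit(fit, target_pc)
        fits.append(fit)
    accuracy = (
        table.groupby(["subject_id", "modality"], sort=True)["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    return fits, accuracy
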