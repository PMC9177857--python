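"""Lick-based behavioral metrics for the go/no-go odor task.

A go-response is at least three licks within the anticipatory window
(1.5-2.8 s after odor onset) or within the reward window (2.8-4.1 s),
evaluated per window.  CS100 and CS50 are "Go" cues (go -> Hit, otherwise
Miss); CS0 is the "No-go" cue (go -> False alarm, otherwise Correct
rejection).  Session performance is the percentage of Hit plus Correct
rejection trials; sessions above 80% meet the study inclusion criterion.

The outcome-history regression models anticipatory lick counts on CS50
trials as Poisson with a log link, log(mu_t) = beta . X, where column n of
X codes the outcome of the n-th previous CS50 trial as +1 (rewarded) or -1
(unrewarded), n = 1..6.  A satiety variant codes the n-th previous
CS100/CS0 trial instead (+1 for the always-rewarded CS100, -1 for CS0).
Coefficients are standardized as beta*_n = beta_n * sd(X[:, n]) / sd(y)
and reported as exp(beta*_n) - 1, one regression per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ANTICIPATORY_WINDOW = (1.5, 2.8)
REWARD_WINDOW = (2.8, 4.1)
GO_LICK_CRITERION = 3
PERFORMANCE_CRITERION = 80.0
HISTORY_DEPTH = 6

GO_CUES = ("CS100", "CS50")


def _count(licks: np.ndarray, window: tuple) -> int:
    licks = np.asarray(licks, dtype=float)
    return int(np.sum((licks >= window[0]) & (licks < window[1])))


def classify_trial(lick_times: np.ndarray, cs: str) -> str:
    """Classify one trial as Hit / Miss / FalseAlarm / CorrectRejection.

    ``lick_times`` are seconds relative to odor onset.  The >=3-lick
    criterion is evaluated separately in the anticipatory and reward
    windows; meeting it in either window is a go-response.
    """
    go = (
        _count(lick_times, ANTICIPATORY_WINDOW) >= GO_LICK_CRITERION
        or _count(lick_times, REWARD_WINDOW) >= GO_LICK_CRITERION
    )
    if cs in GO_CUES:
        return "Hit" if go else "Miss"
    if cs == "CS0":
        return "FalseAlarm" if go else "CorrectRejection"
    raise ValueError(f"unknown CS label {cs!r}")


def classify_session(seq: pd.DataFrame, licks: pd.DataFrame) -> pd.DataFrame:
    """Classify every trial of a session.

    ``licks`` has a single column ``time_s`` of absolute lick times.
    Returns ``seq`` with added columns ``outcome_class`` and
    ``anticipatory_count`` (licks in the delay window).
    """
    times = licks["time_s"].to_numpy()
    classes, counts = [], []
    for onset, cs in zip(seq["onset"], seq["cs"]):
        rel = times[(times >= onset - 2.0) & (times <= onset + 6.0)] - onset
        classes.append(classify_trial(rel, cs))
        counts.append(_count(rel, ANTICIPATORY_WINDOW))
    out = seq.copy()
    out["outcome_class"] = classes
    out["anticipatory_count"] = counts
    return out


def session_performance(classes) -> float:
    """Percent of Hit + Correct rejection trials."""
    classes = list(classes)
    if not classes:
        raise ValueError("empty session")
    good = sum(c in ("Hit", "CorrectRejection") for c in classes)
    return 100.0 * good / len(classes)


def anticipatory_rate(
    classified: pd.DataFrame, window: tuple = ANTICIPATORY_WINDOW
) -> pd.DataFrame:
    """Per-trial anticipatory lick rate in Hz (count / window length)."""
    dur = window[1] - window[0]
    out = classified.copy()
    out["anticipatory_rate"] = out["anticipatory_count"] / dur
    return out


def history_split(classified: pd.DataFrame) -> dict:
    """CS50 trials split by the outcome of the previous CS50 trial."""
    cs50 = classified[classified["cs"] == "CS50"].reset_index(drop=True)
    prev = cs50["rewarded"].shift(1)
    return {
        "R": cs50[prev == True],  # noqa: E712
        "N": cs50[prev == False],  # noqa: E712
    }


def satiety_split(classified: pd.DataFrame) -> dict:
    """CS50 trials split by whether the immediately preceding trial was CS100 or CS0."""
    prev_cs = classified["cs"].shift(1)
    cs50 = classified["cs"] == "CS50"
    return {
        "prior_CS100": classified[cs50 & (prev_cs == "CS100")],
        "prior_CS0": classified[cs50 & (prev_cs == "CS0")],
    }


def build_history_design(
    classified: pd.DataFrame,
    mode: str = "history",
    n_back: int = HISTORY_DEPTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (y, X) for the Poisson outcome-history regression.

    ``y`` holds anticipatory lick counts of CS50 trials that have a full
    n-back history; column n of ``X`` is the +1/-1 outcome code of the
    n-th previous reference trial.  ``mode="history"`` references previous
    CS50 trials (cue-specific outcome history); ``mode="satiety"``
    references previous CS100/CS0 trials (+1 for CS100, -1 for CS0).
    Trials too early to have ``n_back`` references are dropped.
    """
    if mode == "history":
        ref = classified[classified["cs"] == "CS50"].reset_index(drop=True)
        codes = np.where(ref["rewarded"].to_numpy(), 1.0, -1.0)
        targets = np.arange(len(ref))
        counts = ref["anticipatory_count"].to_numpy()
    elif mode == "satiety":
        # targets are CS50 trials; references are the interleaved CS100/CS0
        is_ref = classified["cs"].isin(["CS100", "CS0"]).to_numpy()
        ref_codes = np.where(classified["cs"].to_numpy() == "CS100", 1.0, -1.0)[is_ref]
        n_ref_before = np.cumsum(is_ref)
        cs50_pos = np.flatnonzero((classified["cs"] == "CS50").to_numpy())
        rows, y = [], []
        for p in cs50_pos:
            k = n_ref_before[p] - (1 if is_ref[p] else 0)
            if k >= n_back:
                rows.append(ref_codes[k - np.arange(1, n_back + 1)])
                y.append(classified["anticipatory_count"].iloc[p])
        return np.asarray(y, dtype=float), np.asarray(rows, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows, y = [], []
    for i in targets:
        if i >= n_back:
            rows.append(codes[i - np.arange(1, n_back + 1)])
            y.append(counts[i])
    return np.asarray(y, dtype=float), np.asarray(rows, dtype=float)


def poisson_history_regression(
    y: np.ndarray,
    X: np.ndarray,
    add_intercept: bool = True,
) -> dict:
    """Fit the Poisson GLM and return standardized, transformed coefficients.

    Returns a dict with raw ``beta`` per lag, ``beta_star`` =
    exp(beta_n * sd(X[:, n]) / sd(y)) - 1, and a validity flag.  A session
    with zero count variance or a zero-variance regressor column cannot be
    standardized and is flagged invalid (NaN coefficients).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n_lags = X.shape[1]
    sd_y = y.std(ddof=0)
    sd_x = X.std(axis=0, ddof=0)
    if sd_y == 0 or np.any(sd_x == 0):
        return {
            "beta": np.full(n_lags, np.nan),
            "beta_star": np.full(n_lags, np.nan),
            "valid": False,
            "reason": "zero variance in counts or a regressor column",
        }
    design = sm.add_constant(X) if add_intercept else X
    try:
        fit = sm.GLM(y, design, family=sm.families.Poisson()).fit()
    except Exception as exc:  # pragma: no cover - convergence failure path
        return {
            "beta": np.full(n_lags, np.nan),
            "beta_star": np.full(n_lags, np.nan),
            "valid": False,
            "reason": f"fit failed: {exc}",
        }
    beta = fit.params[-n_lags:]
    beta_std = beta * sd_x / sd_y
    return {
        "beta": np.asarray(beta),
        "beta_star": np.expm1(beta_std),
        "valid": True,
        "reason": "",
    }


def group_history_test(per_session_beta_star: np.ndarray) -> pd.DataFrame:
    """One-sample t test per lag across sessions on the standardized coefficients."""
    arr = np.asarray(per_session_beta_star, dtype=float)
    rows = []
    for lag in range(arr.shape[1]):
        col = arr[:, lag]
        col = col[np.isfinite(col)]
        t, p = stats.ttest_1samp(col, 0.0)
        rows.append({"lag": lag + 1, "mean": col.mean(), "t": t, "p": p, "n": len(col)})
    return pd.DataFrame(rows)
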