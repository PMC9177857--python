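"""Pupillometry preprocessing and the pupil observation model.

The pupil dilates with reward expectation and with surprise.  Dilation on
each trial is summarized by three window averages of the percent change
from the pre-trial baseline: d(0) over -2..0 s, d(1) over 0..2.7 s, and
d(2) over 2.7..5.4 s relative to odor onset.  The observation model links
those averages to the TD model's state values and prediction errors,

    d(t) = sum_{tau=0..t} a_tau * V(s_{t-tau})
         + sum_{tau=0..t-1} b_tau * |delta(t-tau)|,

with t in {0, 1, 2}, V(s2) = 0, and free coefficients (a0, a1, a2) on the
values and (b0, b1) on the absolute prediction errors.  For a fixed
learning rate alpha the model is linear in (a, b); fitting therefore
combines a 1-D search over alpha with an exact least-squares solve of the
coefficients, and the learning rate reported for a study is the average of
the per-session estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .td import run_td_session

#: analysis windows in seconds relative to odor onset
WINDOW_D0 = (-2.0, 0.0)
WINDOW_D1 = (0.0, 2.7)
WINDOW_D2 = (2.7, 5.4)
#: trials with a step larger than this (percent points) between two
#: consecutive frames are excluded entirely (blinks, detection failures)
FRAME_JUMP_LIMIT = 5.0


@dataclass
class PupilModelParams:
    """Fitted observation-model parameters.

    ``alpha`` is the TD learning rate; ``a`` = (a0, a1, a2) weight current
    and past state values; ``b`` = (b0, b1) weight current and past
    absolute prediction errors.
    """

    alpha: float
    a: np.ndarray
    b: np.ndarray
    loss: float = np.nan
    n_trials_used: int = 0
    identifiable: bool = True

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (3,) or self.b.shape != (2,):
            raise ValueError("a must have length 3 and b length 2")
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.b)):
            raise ValueError("coefficients must be finite")


def preprocess_pupil(
    trace: pd.DataFrame,
    seq: pd.DataFrame,
    fs: float = 20.0,
    window: tuple = (WINDOW_D0[0], WINDOW_D2[1]),
) -> pd.DataFrame:
    """Convert a raw pupil-diameter trace to per-trial percent change.

    For each trial the diameter is expressed as percent change from the
    mean over the -2..0 s baseline window.  A trial is excluded when the
    percent-change series jumps by more than 5 percentage points between
    two consecutive frames anywhere in the trial window (blink artifacts),
    or when its window is not fully covered by the trace.

    Parameters
    ----------
    trace:
        Columns ``time_s`` and ``diameter`` (raw units) sampled at ``fs``.
    seq:
        Trial table with ``trial_index`` and ``onset``.

    Returns
    -------
    DataFrame with one row per trial: ``trial_index``, ``excluded``,
    ``reason`` and object columns ``t_rel`` / ``pct`` holding the aligned
    sample arrays for the retained trials.
    """
    t = trace["time_s"].to_numpy()
    x = trace["diameter"].to_numpy()
    lo, hi = window
    rows = []
    for idx, onset in zip(seq["trial_index"], seq["onset"]):
        sel = (t >= onset + lo - 0.5 / fs) & (t <= onset + hi + 0.5 / fs)
        if not sel.any() or t[sel][0] > onset + lo + 1.0 / fs or t[sel][-1] < onset + hi - 1.0 / fs:
            rows.append({"trial_index": idx, "excluded": True,
                         "reason": "window outside trace", "t_rel": None, "pct": None})
            continue
        tt = t[sel] - onset
        xx = x[sel]
        base = xx[(tt >= WINDOW_D0[0] - 1e-9) & (tt <= WINDOW_D0[1] + 1e-9)].mean()
        pct = 100.0 * (xx - base) / base
        if np.any(np.abs(np.diff(pct)) > FRAME_JUMP_LIMIT):
            rows.append({"trial_index": idx, "excluded": True,
                         "reason": "frame-to-frame jump > 5%", "t_rel": None, "pct": None})
            continue
        rows.append({"trial_index": idx, "excluded": False, "reason": "",
                     "t_rel": tt, "pct": pct})
    return pd.DataFrame(rows)


def window_average(t_rel: np.ndarray, pct: np.ndarray) -> tuple[float, float, float]:
    """Mean percent change in the three trial windows (d0, d1, d2)."""
    t_rel = np.asarray(t_rel, dtype=float)
    pct = np.asarray(pct, dtype=float)
    out = []
    for lo, hi in (WINDOW_D0, WINDOW_D1, WINDOW_D2):
        sel = (t_rel >= lo - 1e-9) & (t_rel < hi - 1e-9)
        if not sel.any():
            raise ValueError(f"trial trace does not cover window {lo}..{hi} s")
        out.append(float(pct[sel].mean()))
    return tuple(out)


def trial_windows(processed: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`window_average` to every retained trial."""
    rows = []
    for _, r in processed.iterrows():
        if r["excluded"]:
            continue
        d0, d1, d2 = window_average(r["t_rel"], r["pct"])
        rows.append({"trial_index": r["trial_index"], "d0": d0, "d1": d1, "d2": d2})
    return pd.DataFrame(rows)


def pupil_design_row(t: int, v_s0: float, v_cs: float, ad1: float, ad2: float) -> np.ndarray:
    """Regressor row (a0, a1, a2, b0, b1) for window ``t`` of one trial.

    The value sum runs over tau = 0..t (states s_t back to s_0) and the
    prediction-error sum over tau = 0..t-1; V(s2) = 0 by construction.
    """
    row = np.zeros(5)
    if t == 0:
        row[0] = v_s0                       # a0 * V(s0)
    elif t == 1:
        row[0] = v_cs                       # a0 * V(s1)
        row[1] = v_s0                       # a1 * V(s0)
        row[3] = ad1                        # b0 * |delta1|
    elif t == 2:
        row[0] = 0.0                        # a0 * V(s2) = 0
        row[1] = v_cs                       # a1 * V(s1)
        row[2] = v_s0                       # a2 * V(s0)
        row[3] = ad2                        # b0 * |delta2|
        row[4] = ad1                        # b1 * |delta1|
    else:
        raise ValueError("t must be 0, 1 or 2")
    return row


def pupil_forward(params: PupilModelParams, trace: pd.DataFrame) -> np.ndarray:
    """Model-predicted (d0, d1, d2) for every trial of a TD trace.

    ``trace`` is the output of :func:`olfrl.td.run_td_session`.  Returns an
    (n_trials, 3) array.
    """
    coef = np.concatenate([params.a, params.b])
    out = np.empty((len(trace), 3))
    for i, r in enumerate(trace.itertuples()):
        for t in range(3):
            out[i, t] = pupil_design_row(
                t, r.V_s0, r.V_cs, abs(r.delta1), abs(r.delta2)
            ) @ coef
    return out


def _design_and_target(seq, windows, alpha, init, per_type_average):
    trace = run_td_session(seq, alpha=alpha, init=init)
    merged = windows.merge(
        trace[["trial_index", "cs", "V_s0", "V_cs", "delta1", "delta2"]],
        on="trial_index",
    )
    if per_type_average:
        merged = (
            merged.assign(absd1=lambda d: d["delta1"].abs(),
                          absd2=lambda d: d["delta2"].abs())
            .groupby("cs", as_index=False)
            .mean(numeric_only=True)
        )
        merged["delta1"] = merged["absd1"]
        merged["delta2"] = merged["absd2"]
    X, y = [], []
    for r in merged.itertuples():
        for t, d in enumerate((r.d0, r.d1, r.d2)):
            X.append(pupil_design_row(t, r.V_s0, r.V_cs, abs(r.delta1), abs(r.delta2)))
            y.append(d)
    return np.asarray(X), np.asarray(y)


def inner_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact least-squares solve of the linear coefficients; returns (coef, SSE)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_session(
    seq: pd.DataFrame,
    windows: pd.DataFrame,
    init: str | dict = "zeros",
    alpha_grid: np.ndarray | None = None,
    per_type_average: bool = False,
    refine_tol: float = 1e-6,
) -> PupilModelParams:
    """Fit the observation model to one session's window averages.

    The learning rate is scanned on a grid; at each candidate the TD model
    is run and the coefficients solved in closed form, and the best grid
    point is refined with a bounded 1-D minimization.  Trials excluded in
    preprocessing simply do not appear in ``windows`` and contribute
    nothing to the loss.
    """
    if alpha_grid is None:
        alpha_grid = np.arange(0.02, 0.99, 0.02)
    losses = np.empty(len(alpha_grid))
    for i, a in enumerate(alpha_grid):
        X, y = _design_and_target(seq, windows, a, init, per_type_average)
        _, losses[i] = inner_fit(X, y)
    best = int(np.argmin(losses))
    span = losses.max() - losses.min()
    identifiable = bool(span > refine_tol * max(losses.max(), 1e-12))

    lo = alpha_grid[max(best - 1, 0)]
    hi = alpha_grid[min(best + 1, len(alpha_grid) - 1)]

    def loss_at(a):
        X, y = _design_and_target(seq, windows, a, init, per_type_average)
        return inner_fit(X, y)[1]

    if identifiable and hi > lo:
        res = minimize_scalar(loss_at, bounds=(lo, hi), method="bounded",
                              options={"xatol": refine_tol})
        alpha_hat = float(res.x)
    else:
        alpha_hat = float(alpha_grid[best])
    X, y = _design_and_target(seq, windows, alpha_hat, init, per_type_average)
    coef, sse = inner_fit(X, y)
    return PupilModelParams(
        alpha=alpha_hat, a=coef[:3], b=coef[3:], loss=sse,
        n_trials_used=len(windows), identifiable=identifiable,
    )


def fit_pupil_model(
    sessions: list,
    init: str | dict = "zeros",
    joint: bool = False,
    **kw,
) -> dict:
    """Fit the model over several sessions.

    ``sessions`` is a list of ``(seq, windows)`` pairs.  By default each
    session is fitted independently and the study-level learning rate is
    the mean of the per-session estimates; with ``joint=True`` one loss
    summed over sessions is minimized instead (one shared parameter set).

    Returns ``{"alpha": ..., "per_session": [PupilModelParams, ...]}``.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if joint:
        alpha_grid = kw.pop("alpha_grid", None)
        if alpha_grid is None:
            alpha_grid = np.arange(0.02, 0.99, 0.02)

        def joint_loss(a):
            total = 0.0
            for seq, win in sessions:
                X, y = _design_and_target(seq, win, a, init, kw.get("per_type_average", False))
                total += inner_fit(X, y)[1]
            return total

        losses = [joint_loss(a) for a in alpha_grid]
        best = int(np.argmin(losses))
        lo = alpha_grid[max(best - 1, 0)]
        hi = alpha_grid[min(best + 1, len(alpha_grid) - 1)]
        res = minimize_scalar(joint_loss, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        fits = [fit_session(seq, win, init=init,
                            alpha_grid=np.array([float(res.x)]), **kw)
                for seq, win in sessions]
        return {"alpha": float(res.x), "per_session": fits}
    fits = [fit_session(seq, win, init=init, **kw) for seq, win in sessions]
    return {"alpha": float(np.mean([f.alpha for f in fits])), "per_session": fits}
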