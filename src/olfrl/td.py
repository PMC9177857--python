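"""Trial-based TD(0) model of reward prediction and prediction error.

Each trial is reduced to three timepoints: baseline (t = 0, state ``s0``),
odor presentation (t = 1, one state per cue), and outcome (t = 2, state
``s2`` whose value is fixed at 0 because the trial ends there).  The
prediction error compares successive value predictions,

    delta_t = r_t + V(s_t) - V(s_{t-1}),

and each delta updates the value of the *previous* state,

    V(s_{t-1}) <- V(s_{t-1}) + alpha * delta_t,

with learning rate ``alpha``.  Reward ``r`` is binary and can only occur at
t = 2, so the prediction error at outcome is ``delta2 = r - V(CS)``.  There
is no eligibility trace and no discounting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import CS_TYPES, TaskConfig, generate_trial_sequence

#: initial state values for sessions of already-trained animals (scanner
#: sessions): each cue starts at its true reward probability.
TRAINED_INIT = {"s0": 0.0, "CS0": 0.0, "CS50": 0.5, "CS100": 1.0}
#: naive initial values used for learning simulations.
ZERO_INIT = {"s0": 0.0, "CS0": 0.0, "CS50": 0.0, "CS100": 0.0}

#: learning rate estimated from the pupillometry sessions.
DEFAULT_ALPHA = 0.28


def initial_values(init: str | dict = "zeros") -> dict:
    """Resolve an initial-value specification to a state->value dict."""
    if isinstance(init, dict):
        vals = dict(ZERO_INIT)
        vals.update(init)
        return vals
    if init == "zeros":
        return dict(ZERO_INIT)
    if init in ("fmri", "trained"):
        return dict(TRAINED_INIT)
    raise ValueError(f"unknown init mode {init!r}")


def td_step(
    values: dict,
    cs: str,
    rewarded: bool,
    alpha: float,
    pre_update_deltas: bool = True,
) -> tuple[float, float]:
    """Run one trial of the TD(0) recursion, updating ``values`` in place.

    Within the trial, ``delta1`` (at cue onset) and ``delta2`` (at outcome)
    are computed from the values as they stood at trial start, then both
    updates are applied (``pre_update_deltas=True``, the default).  With
    ``pre_update_deltas=False`` the value of the cue state is updated by
    ``delta1`` handling before ``delta2`` is computed; since ``delta1``
    never updates the cue state itself the two conventions coincide here,
    but the flag keeps the alternative explicit.

    Returns ``(delta1, delta2)``.
    """
    if cs not in CS_TYPES:
        raise ValueError(f"unknown CS label {cs!r}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    v0 = values["s0"]
    v1 = values[cs]
    r2 = 1.0 if rewarded else 0.0
    delta1 = 0.0 + v1 - v0  # r1 = 0
    if pre_update_deltas:
        delta2 = r2 + 0.0 - v1  # V(s2) = 0
        values["s0"] = v0 + alpha * delta1
        values[cs] = v1 + alpha * delta2
    else:
        values["s0"] = v0 + alpha * delta1
        delta2 = r2 + 0.0 - values[cs]
        values[cs] = values[cs] + alpha * delta2
    return delta1, delta2


def run_td_session(
    seq: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    init: str | dict = "zeros",
) -> pd.DataFrame:
    """Apply the TD(0) recursion over a session.

    Parameters
    ----------
    seq:
        Trial table with columns ``cs`` and ``rewarded``.
    alpha:
        Learning rate in (0, 1].
    init:
        ``"zeros"`` for learning simulations, ``"fmri"``/``"trained"``
        for sessions of trained animals (values start at 0, 0.5, 1 for
        CS0, CS50, CS100), or an explicit dict.

    Returns
    -------
    pandas.DataFrame aligned to ``seq`` with per-trial columns:
    ``V_s0`` and ``V_cs`` (values *at presentation*, before this trial's
    update), ``delta1``, ``delta2`` and ``r2``.
    """
    values = initial_values(init)
    out = {k: [] for k in ("V_s0", "V_cs", "delta1", "delta2", "r2")}
    for cs, rewarded in zip(seq["cs"], seq["rewarded"]):
        out["V_s0"].append(values["s0"])
        out["V_cs"].append(values[cs])
        d1, d2 = td_step(values, cs, bool(rewarded), alpha)
        out["delta1"].append(d1)
        out["delta2"].append(d2)
        out["r2"].append(1.0 if rewarded else 0.0)
    trace = seq.reset_index(drop=True).copy()
    for k, v in out.items():
        trace[k] = v
    return trace


def simulate_sessions(
    n_sessions: int = 100,
    alpha: float = DEFAULT_ALPHA,
    config: TaskConfig | None = None,
    init: str | dict = "zeros",
    seed: int | None = None,
) -> dict:
    """Simulate the TD model on freshly generated sessions and average.

    Returns a dict with:

    - ``per_type``: DataFrame indexed by within-cue presentation number,
      columns ``(cs, V_mean)``, ``(cs, V_sem)``, ``(cs, absdelta2_mean)``:
      the learning curves averaged across sessions.
    - ``final_third``: DataFrame per cue with mean and SEM of V and
      ``|delta2|`` over the last third of each session's trials.
    - ``traces``: list of per-session trace DataFrames.
    """
    if config is None:
        config = TaskConfig()
    ss = np.random.SeedSequence(seed)
    traces = []
    for child in ss.spawn(n_sessions):
        seq = generate_trial_sequence(config, rng=np.random.default_rng(child))
        traces.append(run_td_session(seq, alpha=alpha, init=init))

    per_type = {}
    final_rows = []
    cutoff = config.n_trials - config.n_trials // 3  # last third by trial index
    for cs in CS_TYPES:
        v_curves, d_curves, v_final, d_final = [], [], [], []
        for tr in traces:
            sel = tr[tr["cs"] == cs]
            v_curves.append(sel["V_cs"].to_numpy())
            d_curves.append(np.abs(sel["delta2"].to_numpy()))
            late = sel[sel["trial_index"] > cutoff]
            v_final.append(late["V_cs"].mean())
            d_final.append(np.abs(late["delta2"]).mean())
        n_min = min(len(c) for c in v_curves)
        v_mat = np.vstack([c[:n_min] for c in v_curves])
        d_mat = np.vstack([c[:n_min] for c in d_curves])
        per_type[cs] = pd.DataFrame(
            {
                "V_mean": v_mat.mean(axis=0),
                "V_sem": v_mat.std(axis=0, ddof=1) / np.sqrt(v_mat.shape[0]),
                "absdelta2_mean": d_mat.mean(axis=0),
                "absdelta2_sem": d_mat.std(axis=0, ddof=1) / np.sqrt(d_mat.shape[0]),
            },
            index=pd.RangeIndex(1, n_min + 1, name="presentation"),
        )
        vf = np.asarray(v_final)
        df_ = np.asarray(d_final)
        final_rows.append(
            {
                "cs": cs,
                "V_mean": vf.mean(),
                "V_sem": vf.std(ddof=1) / np.sqrt(len(vf)),
                "absdelta2_mean": df_.mean(),
                "absdelta2_sem": df_.std(ddof=1) / np.sqrt(len(df_)),
            }
        )
    return {
        "per_type": per_type,
        "final_third": pd.DataFrame(final_rows).set_index("cs"),
        "traces": traces,
    }


def split_by_history(trace: pd.DataFrame) -> dict:
    """Group CS50 trials by the outcome of the *previous* CS50 trial.

    Interleaved CS100/CS0 trials are ignored when looking back.  The first
    CS50 trial of a session has no history and is excluded.

    Returns a dict with per-group DataFrames (``"R"`` / ``"N"``) and their
    mean presented value ``V_cs`` (NaN for an empty group).
    """
    cs50 = trace[trace["cs"] == "CS50"].reset_index(drop=True)
    if len(cs50) == 0:
        return {"R": cs50, "N": cs50, "mean_R": float("nan"), "mean_N": float("nan")}
    prev_rewarded = cs50["rewarded"].shift(1)
    grp_r = cs50[prev_rewarded == True]  # noqa: E712  (shift() yields object NaN)
    grp_n = cs50[prev_rewarded == False]  # noqa: E712
    return {
        "R": grp_r,
        "N": grp_n,
        "mean_R": grp_r["V_cs"].mean() if len(grp_r) else float("nan"),
        "mean_N": grp_n["V_cs"].mean() if len(grp_n) else float("nan"),
    }
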