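"""Odor-guided go/no-go task structure and pseudo-random trial sequences.

The task presents one of three odor cues (conditioned stimuli) per trial,
each predicting water reward with a fixed probability: CS100 (always
rewarded), CS50 (rewarded on half of the trials), CS0 (never rewarded).
A trial consists of 1 s of odor, a 1.7 s waiting period, and outcome
delivery 2.7 s after odor onset.  Trial onsets are jittered uniformly
between 10 and 12 s.  Sequences are pseudo-random: the three cues appear
equally often, no cue repeats more than three times in a row, and no more
than three consecutive trials are rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CS_TYPES = ("CS100", "CS50", "CS0")

DEFAULT_REWARD_PROBS = {"CS100": 1.0, "CS50": 0.5, "CS0": 0.0}

#: trial epoch landmarks, seconds relative to odor onset
ODOR_DURATION = 1.0
WAIT_DURATION = 1.7
US_TIME = ODOR_DURATION + WAIT_DURATION  # 2.7 s


class SequenceError(RuntimeError):
    """Raised when a trial sequence satisfying all constraints cannot be built."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one conditioning session.

    Parameters
    ----------
    reward_probs:
        Mapping from cue label to reward probability in [0, 1].
    odor_duration, wait_duration:
        Cue and waiting epoch lengths in seconds; the outcome is delivered
        at ``odor_duration + wait_duration`` after cue onset.
    iti_range:
        (low, high) bounds in seconds of the uniformly jittered interval
        between successive trial onsets.
    n_trials:
        Trials per session; must be divisible by 3 so the cues can appear
        equally often (150 for training sessions, 120 for scanner sessions).
    max_stim_run:
        Maximum number of consecutive identical cues.
    max_reward_run:
        Maximum number of consecutive rewarded trials.
    reward_balance:
        ``"exact"`` (default) draws each cue's rewards from a finite pool
        of ``round(p * n_cue)`` rewarded assignments, so the realized
        reward frequency matches the programmed probability exactly per
        session even under the run constraint; ``"bernoulli"`` draws each
        reward independently and re-draws offending trials, which biases
        the CS50 frequency a few percent below nominal.
    """

    reward_probs: dict = field(default_factory=lambda: dict(DEFAULT_REWARD_PROBS))
    odor_duration: float = ODOR_DURATION
    wait_duration: float = WAIT_DURATION
    iti_range: tuple = (10.0, 12.0)
    n_trials: int = 150
    max_stim_run: int = 3
    max_reward_run: int = 3
    reward_balance: str = "exact"
    seed: int | None = None

    def __post_init__(self):
        for cs, p in self.reward_probs.items():
            if cs not in CS_TYPES:
                raise ValueError(f"unknown CS label {cs!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward probability for {cs} outside [0, 1]: {p}")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range low > high")
        if self.n_trials % 3 != 0:
            raise ValueError("n_trials must be divisible by 3 for equal cue counts")
        if self.max_stim_run < 1 or self.max_reward_run < 1:
            raise ValueError("run constraints must be >= 1")
        if self.reward_balance not in ("exact", "bernoulli"):
            raise ValueError("reward_balance must be 'exact' or 'bernoulli'")

    @property
    def us_time(self) -> float:
        return self.odor_duration + self.wait_duration


def scanner_config(seed: int | None = None, **kw) -> TaskConfig:
    """A 120-trial session as run in the scanner (40 trials per cue)."""
    kw.setdefault("n_trials", 120)
    return TaskConfig(seed=seed, **kw)


def training_config(seed: int | None = None, **kw) -> TaskConfig:
    """A 150-trial training session (50 trials per cue)."""
    kw.setdefault("n_trials", 150)
    return TaskConfig(seed=seed, **kw)


def _trailing_run(seq: list, value) -> int:
    n = 0
    for x in reversed(seq):
        if x != value:
            break
        n += 1
    return n


def _draw_session(rng: np.random.Generator, config: TaskConfig):
    """One attempt at a constrained sequence; None on a dead end."""
    n_each = config.n_trials // 3
    counts = {cs: n_each for cs in CS_TYPES}
    balanced = config.reward_balance == "exact"
    # finite reward pools: drawing without replacement keeps each cue's
    # session-level reward frequency at its programmed probability
    pool_r = {cs: int(round(config.reward_probs[cs] * n_each)) for cs in CS_TYPES}
    cs_seq: list[str] = []
    rew_seq: list[bool] = []
    rew_run = 0
    for _ in range(config.n_trials):
        allowed = [
            cs
            for cs in CS_TYPES
            if counts[cs] > 0
            and _trailing_run(cs_seq, cs) < config.max_stim_run
        ]
        if rew_run >= config.max_reward_run:
            # only cues that can still yield an unrewarded trial may follow
            # three consecutive rewards
            if balanced:
                allowed = [cs for cs in allowed if counts[cs] - pool_r[cs] > 0]
            else:
                allowed = [cs for cs in allowed if config.reward_probs[cs] < 1.0]
        if not allowed:
            return None
        weights = np.array([counts[cs] for cs in allowed], dtype=float)
        u = rng.random() * weights.sum()
        cs = allowed[int(np.searchsorted(np.cumsum(weights), u, side="right"))]
        if balanced:
            rewarded = rng.random() * counts[cs] < pool_r[cs]
        else:
            rewarded = rng.random() < config.reward_probs[cs]
        if rewarded and rew_run >= config.max_reward_run:
            # re-draw of the reward indicator can only settle on "unrewarded"
            rewarded = False
        cs_seq.append(cs)
        rew_seq.append(bool(rewarded))
        rew_run = rew_run + 1 if rewarded else 0
        counts[cs] -= 1
        if balanced and rewarded:
            pool_r[cs] -= 1
    return cs_seq, rew_seq


def generate_trial_sequence(
    config: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
    max_restarts: int = 1000,
) -> pd.DataFrame:
    """Generate one pseudo-random session satisfying all sequence constraints.

    Cues are drawn sequentially from the remaining cue pool (weighted by the
    remaining count of each cue, so the per-cue totals are exact) while
    excluding any cue that would extend an identical-cue run beyond
    ``max_stim_run``.  Rewards are drawn per the cue's reward probability;
    when a draw would extend a rewarded run beyond ``max_reward_run`` the
    draw is re-sampled, which for probabilities below 1 deterministically
    yields an unrewarded trial.  This enforcement slightly depresses the
    local reward frequency right after three rewarded trials; the marginal
    frequency is preserved to within sampling error.  A dead end (no legal
    cue remains) restarts the whole session; an unsatisfiable configuration
    raises :class:`SequenceError` rather than truncating.

    Returns
    -------
    pandas.DataFrame
        Columns ``trial_index`` (1-based), ``cs``, ``rewarded``, ``onset``
        (seconds from session start).
    """
    if config is None:
        config = TaskConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for _ in range(max_restarts):
        drawn = _draw_session(rng, config)
        if drawn is not None:
            cs_seq, rew_seq = drawn
            lo, hi = config.iti_range
            itis = rng.uniform(lo, hi, size=config.n_trials)
            onsets = np.cumsum(itis)
            return pd.DataFrame(
                {
                    "trial_index": np.arange(1, config.n_trials + 1),
                    "cs": cs_seq,
                    "rewarded": rew_seq,
                    "onset": onsets,
                }
            )
    raise SequenceError(
        f"no sequence satisfying the run constraints found in {max_restarts} restarts"
    )


def validate_sequence(seq: pd.DataFrame, config: TaskConfig | None = None) -> None:
    """Assert all sequence invariants; raise ``ValueError`` on violation."""
    if config is None:
        config = TaskConfig(n_trials=len(seq))
    if len(seq) != config.n_trials:
        raise ValueError("trial count mismatch")
    counts = seq["cs"].value_counts()
    n_each = config.n_trials // 3
    for cs in CS_TYPES:
        if counts.get(cs, 0) != n_each:
            raise ValueError(f"{cs} appears {counts.get(cs, 0)} times, expected {n_each}")
    d = np.diff(seq["onset"].to_numpy())
    if not np.all(d > 0):
        raise ValueError("onsets not strictly increasing")
    lo, hi = config.iti_range
    if np.any(d < lo - 1e-9) or np.any(d > hi + 1e-9):
        raise ValueError("inter-trial interval outside configured range")
    if longest_run(seq["cs"].to_numpy()) > config.max_stim_run:
        raise ValueError("identical-cue run too long")
    if longest_run(seq["rewarded"].to_numpy(), value=True) > config.max_reward_run:
        raise ValueError("rewarded run too long")


def longest_run(values: np.ndarray, value=None) -> int:
    """Length of the longest run of identical entries (or of `value`)."""
    values = np.asarray(values)
    if len(values) == 0:
        return 0
    best = run = 1 if (value is None or values[0] == value) else 0
    for prev, cur in zip(values[:-1], values[1:]):
        if cur == prev and (value is None or cur == value):
            run += 1
        else:
            run = 1 if (value is None or cur == value) else 0
        best = max(best, run)
    return best
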