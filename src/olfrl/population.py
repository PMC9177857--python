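"""Population-vector analyses of simultaneously recorded units.

A population vector holds the firing rate of every unit in a time bin
centered at t.  Because single sessions yield few units, session-specific
vectors are concatenated into a global pseudo-population by matching
trials across sessions on (CS type, within-type presentation order and,
for CS50, trial outcome); sessions with supernumerary CS50 trials of one
outcome contribute only the first ``min across sessions`` of them.

Derived quantities: Euclidean deviation of the population vector from its
baseline configuration (window -2 to -1.25 s before odor onset, averaged
across trials), Pearson correlation between population vectors of trials
of different CS types (overlap of the recruited unit sets), and
time-embedded (m delayed coordinates) PCA trajectories of the
trial-averaged vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

BASELINE_WINDOW = (-2.0, -1.25)
#: sliding bins used for display traces
DISPLAY_BIN = dict(width=0.5, step=0.125)
#: non-overlapping bins used for statistics
STATS_BIN = dict(width=0.25, step=0.25)

#: trial categories used for cross-session matching
CATEGORIES = ("CS100", "CS50-R", "CS50-N", "CS0")


def trial_category(cs: str, rewarded: bool) -> str:
    return f"CS50-{'R' if rewarded else 'N'}" if cs == "CS50" else cs


def time_bins(window: tuple, width: float, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Centers and start edges of sliding bins covering ``window``."""
    starts = np.arange(window[0], window[1] - width + 1e-9, step)
    return starts + width / 2.0, starts


def bin_unit(
    spikes: pd.DataFrame,
    trial_indices: np.ndarray,
    starts: np.ndarray,
    width: float,
) -> np.ndarray:
    """Firing rate (Hz) of one unit: trials x bins.

    ``spikes`` has columns ``trial_index`` and ``spike_time`` (seconds
    relative to odor onset).
    """
    out = np.zeros((len(trial_indices), len(starts)))
    grouped = dict(iter(spikes.groupby("trial_index")["spike_time"])) if len(spikes) else {}
    starts = np.asarray(starts, dtype=float)
    for i, tr in enumerate(trial_indices):
        st = grouped.get(tr)
        if st is None:
            continue
        st = np.sort(st.to_numpy())
        out[i] = np.searchsorted(st, starts + width) - np.searchsorted(st, starts)
    return out / width


@dataclass
class PopulationVectorSet:
    """Binned rate tensors per trial category, concatenated across sessions.

    ``rates[cat]`` has shape (units, trials, bins); ``baseline`` is the
    per-unit baseline vector B; ``bin_centers`` the bin centers in
    seconds relative to odor onset.
    """

    rates: dict
    baseline: np.ndarray
    bin_centers: np.ndarray
    unit_ids: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.baseline)


def build_population_vectors(
    sessions: list,
    window: tuple = (-2.5, 6.0),
    width: float = DISPLAY_BIN["width"],
    step: float = DISPLAY_BIN["step"],
) -> PopulationVectorSet:
    """Concatenate sessions into a matched-trial population tensor.

    ``sessions`` is a list of ``(trials, rasters)`` pairs where ``trials``
    is a trial table (``trial_index``, ``cs``, ``rewarded``) and
    ``rasters`` maps unit id to a spike DataFrame (``trial_index``,
    ``spike_time`` relative to odor onset).  Trials are matched across
    sessions by category and presentation order; each category keeps the
    minimum trial count available over sessions, dropping the last trials
    of richer sessions.
    """
    if not sessions:
        raise ValueError("need at least one session")
    centers, starts = time_bins(window, width, step)
    # per session: ordered trial indices per category
    per_session_trials = []
    for trials, _ in sessions:
        cats = {}
        for cat in CATEGORIES:
            if cat.startswith("CS50-"):
                want_r = cat.endswith("R")
                sel = trials[(trials["cs"] == "CS50") & (trials["rewarded"] == want_r)]
            else:
                sel = trials[trials["cs"] == cat]
            cats[cat] = sel["trial_index"].to_numpy()
        per_session_trials.append(cats)
    n_keep = {
        cat: min(len(c[cat]) for c in per_session_trials) for cat in CATEGORIES
    }
    if n_keep["CS50-R"] == 0 and n_keep["CS50-N"] == 0:
        raise ValueError("no CS50 trials common to all sessions")

    rates = {cat: [] for cat in CATEGORIES}
    base_starts = np.array([BASELINE_WINDOW[0]])
    base_width = BASELINE_WINDOW[1] - BASELINE_WINDOW[0]
    baseline, unit_ids = [], []
    for (trials, rasters), cats in zip(sessions, per_session_trials):
        all_trials = trials["trial_index"].to_numpy()
        for uid, spk in rasters.items():
            unit_ids.append(uid)
            for cat in CATEGORIES:
                keep = cats[cat][: n_keep[cat]]
                rates[cat].append(bin_unit(spk, keep, starts, width))
            b = bin_unit(spk, all_trials, base_starts, base_width)
            baseline.append(b.mean())
    tensor = {
        cat: np.stack(rates[cat], axis=0) if rates[cat] else np.zeros((0, 0, len(starts)))
        for cat in CATEGORIES
    }
    return PopulationVectorSet(
        rates=tensor,
        baseline=np.asarray(baseline),
        bin_centers=centers,
        unit_ids=unit_ids,
    )


def pair_average(rates: np.ndarray) -> np.ndarray:
    """Average consecutive trial pairs: (units, trials, bins) -> (units, trials//2, bins).

    An odd trailing trial is dropped.
    """
    n = rates.shape[1] // 2
    if n == 0:
        raise ValueError("need at least 2 trials to pair-average")
    return 0.5 * (rates[:, 0 : 2 * n : 2, :] + rates[:, 1 : 2 * n : 2, :])


def distance_from_baseline(
    pvs: PopulationVectorSet, categories=None, pair_averaged: bool = True
) -> dict:
    """Euclidean distance of each (pseudo-)trial's population vector from B.

    Returns ``{category: array (trials, bins)}``.
    """
    if categories is None:
        categories = CATEGORIES
    out = {}
    B = pvs.baseline[:, None, None]
    for cat in categories:
        r = pvs.rates[cat]
        if pair_averaged:
            r = pair_average(r)
        out[cat] = np.sqrt(np.sum((r - B) ** 2, axis=0))
    return out


def cross_type_correlation(
    pvs: PopulationVectorSet,
    cats_a,
    cats_b,
    pair_averaged: bool = True,
) -> np.ndarray:
    """Mean Pearson r per time bin between trials of two CS types.

    ``cats_a`` / ``cats_b`` are category names or lists of them (e.g.
    ``["CS50-R", "CS50-N"]`` for all CS50 trials).  At each bin, every
    trial vector of type A is correlated with every trial vector of type B
    and the coefficients averaged; pairs where either vector has zero
    variance across units are skipped.
    """
    if pvs.n_units < 2:
        raise ValueError("correlation needs at least 2 units")
    if isinstance(cats_a, str):
        cats_a = [cats_a]
    if isinstance(cats_b, str):
        cats_b = [cats_b]

    def stack(cats):
        mats = [pvs.rates[c] for c in cats if pvs.rates[c].shape[1] > 0]
        r = np.concatenate(mats, axis=1)
        return pair_average(r) if pair_averaged else r

    A, Bm = stack(cats_a), stack(cats_b)
    n_bins = A.shape[2]
    out = np.full(n_bins, np.nan)
    for t in range(n_bins):
        va = A[:, :, t]  # units x trials
        vb = Bm[:, :, t]
        va_c = va - va.mean(axis=0, keepdims=True)
        vb_c = vb - vb.mean(axis=0, keepdims=True)
        sa = np.sqrt(np.sum(va_c**2, axis=0))
        sb = np.sqrt(np.sum(vb_c**2, axis=0))
        num = va_c.T @ vb_c  # trials_a x trials_b
        with np.errstate(invalid="ignore", divide="ignore"):
            rmat = num / np.outer(sa, sb)
        valid = np.isfinite(rmat)
        if valid.any():
            out[t] = rmat[valid].mean()
    return out


def embed_trajectories(
    mean_rates: dict, m: int = 4, delay: int = 1, n_components: int = 3
) -> dict:
    """Time-embedded PCA trajectories of trial-averaged population vectors.

    ``mean_rates`` maps trial type to a (units, T) matrix.  Each matrix is
    augmented with ``m`` delayed copies (delay of ``delay`` bins), PCA is
    fitted on the concatenation over trial types so all trajectories share
    axes, and each is projected onto the leading components.

    Returns ``{"trajectories": {type: (T-(m-1)*delay, n_components)},
    "pca": fitted PCA, "explained_variance_ratio": ...}``.
    """
    embedded = {}
    for cat, X in mean_rates.items():
        X = np.asarray(X, dtype=float)
        T = X.shape[1]
        span = (m - 1) * delay
        if T <= span:
            raise ValueError(f"need more than {span} time bins for m={m}, delay={delay}")
        rows = [X[:, k * delay : T - span + k * delay] for k in range(m)]
        embedded[cat] = np.vstack(rows)  # (units*m, T-span)
    stacked = np.hstack(list(embedded.values())).T  # samples x features
    n_components = min(n_components, min(stacked.shape))
    pca = PCA(n_components=n_components)
    pca.fit(stacked)
    return {
        "trajectories": {cat: pca.transform(E.T) for cat, E in embedded.items()},
        "pca": pca,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
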