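"""Single-unit response classification and coding tests.

Units are characterized by firing rates in four task windows relative to
odor onset (baseline -1.5..-0.5 s, CS 0..1 s, waiting 1..2.5 s, US
2.7..3.7 s).  Responsiveness compares window rates to baseline across
trials with multiple-testing correction.  Functional clusters are found by
sliding-window auROC profiles (response distribution vs a pooled baseline
window, -1.8..-1.4 s) concatenated over the four trial conditions,
reduced by PCA and grouped by hierarchical clustering; clusters are then
assigned to transient / ramping / inhibited / sustained archetypes from
their mean profiles.

Coding tests on per-trial rates grouped by cue (R0, R50, R100): monotonic
reward-prediction coding (both adjacent cue comparisons significant in the
value order), single-cue dominance, population-level coding of the
non-monotonic remainder, reward surprise (the firing-rate jump at outcome
is larger for unexpectedly rewarded CS50 trials than for CS100 trials),
outcome discrimination between rewarded and unrewarded CS50 trials, and
the chance level n_discriminative / 3! for any strict cue ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .population import bin_unit, time_bins

TASK_WINDOWS = {
    "baseline": (-1.5, -0.5),
    "cs_win": (0.0, 1.0),
    "wait": (1.0, 2.5),
    "us": (2.7, 3.7),
}
#: US rate-jump windows: rate before outcome and the two post-outcome windows
PRIOR_WINDOW = (2.2, 2.7)
AFTER_WINDOW_SHORT = (2.7, 3.2)
AFTER_WINDOW_LONG = (3.2, 4.5)

AUROC_BASELINE_WINDOW = (-1.8, -1.4)
AUROC_BIN = dict(width=0.5, step=0.125)
AUROC_CONDITIONS = ("CS0", "CS50-N", "CS50-R", "CS100")

ALPHA_LEVEL = 0.05


# ---------------------------------------------------------------------------
# window rates

def window_rates(
    spikes: pd.DataFrame, trials: pd.DataFrame, windows: dict | None = None
) -> pd.DataFrame:
    """Per-trial firing rate (Hz) of one unit in each named window.

    ``spikes`` has columns ``trial_index`` / ``spike_time`` (relative to
    odor onset); ``trials`` supplies ``trial_index``, ``cs``, ``rewarded``.
    """
    if windows is None:
        windows = TASK_WINDOWS
    out = trials[["trial_index", "cs", "rewarded"]].reset_index(drop=True).copy()
    idx = out["trial_index"].to_numpy()
    for name, (lo, hi) in windows.items():
        r = bin_unit(spikes, idx, np.array([lo]), hi - lo)
        out[name] = r[:, 0]
    return out


def rate_by_cs(rates: pd.DataFrame, column: str) -> dict:
    """Per-cue per-trial rate arrays {R0, R50, R100} for one window column."""
    return {
        "R0": rates.loc[rates["cs"] == "CS0", column].to_numpy(),
        "R50": rates.loc[rates["cs"] == "CS50", column].to_numpy(),
        "R100": rates.loc[rates["cs"] == "CS100", column].to_numpy(),
    }


# ---------------------------------------------------------------------------
# responsiveness

def _paired_pvalue(window: np.ndarray, base: np.ndarray, method: str) -> float:
    diff = np.asarray(window, float) - np.asarray(base, float)
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 1.0
    if method == "sign":
        # Friedman over two paired conditions reduces to the sign test
        k = int(np.sum(nz > 0))
        return stats.binomtest(k, len(nz), 0.5).pvalue
    if method == "wilcoxon":
        return stats.wilcoxon(diff[diff != 0]).pvalue
    raise ValueError(f"unknown method {method!r}")


def test_responsiveness(
    unit_rates: dict,
    method: str = "sign",
    alpha: float = ALPHA_LEVEL,
    windows: tuple = ("cs_win", "wait", "us"),
) -> pd.DataFrame:
    """Label every unit x trial type x window as excited / inhibited / none.

    ``unit_rates`` maps unit id to a :func:`window_rates` table.  P values
    from the paired baseline comparison are Benjamini-Hochberg corrected
    across all (unit, type, window) tests jointly; direction comes from
    the sign of the median rate difference.
    """
    rows = []
    for uid, rates in unit_rates.items():
        for cs in ("CS100", "CS50", "CS0"):
            sel = rates[rates["cs"] == cs]
            for w in windows:
                wr = sel[w].to_numpy()
                br = sel["baseline"].to_numpy()
                p = _paired_pvalue(wr, br, method)
                rows.append(
                    {
                        "unit": uid,
                        "cs": cs,
                        "window": w,
                        "p": p,
                        "median_diff": float(np.median(wr - br)),
                    }
                )
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    table["label"] = "none"
    sig = table["p_adj"] < alpha
    table.loc[sig & (table["median_diff"] > 0), "label"] = "excited"
    table.loc[sig & (table["median_diff"] < 0), "label"] = "inhibited"
    return table


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# auROC profiles and clustering

def auroc(window_samples: np.ndarray, baseline_samples: np.ndarray) -> float:
    """Area under the ROC curve comparing two rate distributions.

    Midrank convention: ties contribute 1/2.  Returns a value in [0, 1];
    0.5 means the window rates do not deviate from baseline.
    """
    x = np.asarray(window_samples, dtype=float)
    y = np.asarray(baseline_samples, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


@dataclass
class AuROCProfileSet:
    """Concatenated per-condition auROC traces for a set of units."""

    matrix: np.ndarray  # units x (n_conditions * n_bins)
    bin_centers: np.ndarray
    conditions: tuple
    unit_ids: list


def auroc_profile(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    window: tuple = (-1.0, 5.5),
    width: float = AUROC_BIN["width"],
    step: float = AUROC_BIN["step"],
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window auROC trace of one unit, concatenated over conditions.

    At each step the across-trial distribution of rates in the 500 ms
    window is compared with the pooled baseline-window (-1.8..-1.4 s)
    distribution of the same condition's trials.  Conditions are ordered
    CS0, unrewarded CS50, rewarded CS50, CS100.  Returns ``(profile,
    bin_centers)`` where ``profile`` has length 4 * n_bins.
    """
    centers, starts = time_bins(window, width, step)
    segments = []
    for cond in AUROC_CONDITIONS:
        if cond.startswith("CS50-"):
            want = cond.endswith("R")
            sel = trials[(trials["cs"] == "CS50") & (trials["rewarded"] == want)]
        else:
            sel = trials[trials["cs"] == cond]
        idx = sel["trial_index"].to_numpy()
        base = bin_unit(
            spikes, idx, np.array([AUROC_BASELINE_WINDOW[0]]),
            AUROC_BASELINE_WINDOW[1] - AUROC_BASELINE_WINDOW[0],
        )[:, 0]
        rates = bin_unit(spikes, idx, starts, width)
        segments.append(np.array([auroc(rates[:, j], base) for j in range(len(starts))]))
    return np.concatenate(segments), centers


def auroc_profiles(rasters: dict, trials: pd.DataFrame, **kw) -> AuROCProfileSet:
    """:func:`auroc_profile` over a population of units."""
    mats, ids = [], []
    centers = None
    for uid, spk in rasters.items():
        prof, centers = auroc_profile(spk, trials, **kw)
        mats.append(prof)
        ids.append(uid)
    return AuROCProfileSet(
        matrix=np.vstack(mats),
        bin_centers=centers,
        conditions=AUROC_CONDITIONS,
        unit_ids=ids,
    )


def _profile_window_mean(profiles: AuROCProfileSet, row: np.ndarray, lo: float, hi: float) -> float:
    """Mean auROC over bins with centers in [lo, hi), pooled over conditions."""
    nb = len(profiles.bin_centers)
    sel = (profiles.bin_centers >= lo) & (profiles.bin_centers < hi)
    vals = [row[k * nb : (k + 1) * nb][sel] for k in range(len(profiles.conditions))]
    return float(np.nanmean(np.concatenate(vals)))


def classify_cluster_profile(profiles: AuROCProfileSet, mean_profile: np.ndarray) -> str:
    """Assign a cluster-mean auROC profile to a functional archetype.

    Rules (auROC 0.5 = baseline): below baseline during the task windows
    -> inhibited; rising through the waiting period to an elevated late
    level -> ramping; elevated at CS without the ramp -> transient;
    elevated otherwise -> sustained.
    """
    cs = _profile_window_mean(profiles, mean_profile, 0.0, 1.0)
    wait_early = _profile_window_mean(profiles, mean_profile, 1.0, 1.75)
    wait_late = _profile_window_mean(profiles, mean_profile, 1.75, 2.45)
    task = _profile_window_mean(profiles, mean_profile, 0.0, 2.5)
    if task < 0.45:
        return "inhibited"
    if wait_late > 0.55 and wait_late > wait_early + 0.05 and wait_late >= cs - 0.05:
        return "ramping"
    if cs > 0.55 and cs > wait_late + 0.05:
        return "transient"
    if task > 0.55:
        return "sustained"
    return "untuned"


def cluster_units(
    profiles: AuROCProfileSet,
    n_pcs: int = 5,
    cutoff: float = 0.5,
    cutoff_mode: str = "normalized",
    linkage_method: str = "average",
) -> dict:
    """Hierarchical clustering of units on PCA-reduced auROC profiles.

    The concatenated profiles are reduced to their first ``n_pcs``
    principal components (fewer if the data are rank deficient) and
    clustered agglomeratively on Euclidean distance.  With
    ``cutoff_mode="normalized"`` the tree is cut at ``cutoff`` times the
    maximum linkage height; with ``"absolute"`` at ``cutoff`` itself.
    Each flat cluster is then assigned a functional archetype from its
    mean profile.

    Returns ``{"labels", "groups", "linkage", "pca", "cluster_archetype"}``.
    """
    X = profiles.matrix.copy()
    X = np.nan_to_num(X, nan=0.5)
    n_pcs_eff = min(n_pcs, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_pcs_eff)
    pcs = pca.fit_transform(X)
    Z = hierarchy.linkage(pcs, method=linkage_method, metric="euclidean")
    thresh = cutoff * Z[:, 2].max() if cutoff_mode == "normalized" else cutoff
    labels = hierarchy.fcluster(Z, t=thresh, criterion="distance")
    archetype = {}
    for lab in np.unique(labels):
        mean_prof = X[labels == lab].mean(axis=0)
        archetype[int(lab)] = classify_cluster_profile(profiles, mean_prof)
    groups = np.array([archetype[int(l)] for l in labels])
    return {
        "labels": labels,
        "groups": groups,
        "linkage": Z,
        "pca": pca,
        "cluster_archetype": archetype,
    }


# ---------------------------------------------------------------------------
# coding tests

def _ranksum_greater(hi: np.ndarray, lo: np.ndarray, alpha: float = ALPHA_LEVEL) -> bool:
    """Two-tailed rank-sum significance with the difference in the stated direction."""
    hi = np.asarray(hi, float)
    lo = np.asarray(lo, float)
    if len(hi) == 0 or len(lo) == 0:
        return False
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    direction = res.statistic > len(hi) * len(lo) / 2.0  # auROC > 0.5
    return bool(res.pvalue < alpha and direction)


def test_monotonic_rp(
    r0: np.ndarray,
    r50: np.ndarray,
    r100: np.ndarray,
    inhibited: bool = False,
    alpha: float = ALPHA_LEVEL,
    min_trials: int = 5,
) -> dict:
    """Monotonic reward-prediction coding and single-cue dominance.

    A unit is ``monotonic`` when {R0} < {R50} and {R50} < {R100} (both
    two-tailed rank-sum tests significant; inequalities reversed for
    inhibited units).  When monotonicity fails, the strongest cue response
    must beat the second strongest to earn a ``dominant-<CS>`` label;
    otherwise ``neither``.
    """
    groups = {"CS0": np.asarray(r0, float), "CS50": np.asarray(r50, float),
              "CS100": np.asarray(r100, float)}
    if any(len(g) < min_trials for g in groups.values()):
        return {"label": "neither", "flag": "insufficient trials"}
    lo, mid, hi = groups["CS0"], groups["CS50"], groups["CS100"]
    if inhibited:
        mono = _ranksum_greater(lo, mid, alpha) and _ranksum_greater(mid, hi, alpha)
    else:
        mono = _ranksum_greater(mid, lo, alpha) and _ranksum_greater(hi, mid, alpha)
    if mono:
        return {"label": "monotonic", "flag": ""}
    order = sorted(groups, key=lambda c: groups[c].mean(), reverse=not inhibited)
    strongest, second = order[0], order[1]
    if inhibited:
        dominant = _ranksum_greater(groups[second], groups[strongest], alpha)
    else:
        dominant = _ranksum_greater(groups[strongest], groups[second], alpha)
    if dominant:
        return {"label": f"dominant-{strongest}", "flag": ""}
    return {"label": "neither", "flag": ""}


def distributed_coding_test(per_trial_sums: dict, alpha: float = ALPHA_LEVEL) -> dict:
    """Population-level monotonic coding of summed rates across cue types.

    ``per_trial_sums`` maps ``R0`` / ``R50`` / ``R100`` to per-trial summed
    rates of the unit set (e.g. the non-monotonic remainder of the
    transient cluster).  One-way ANOVA across cues with Tukey HSD
    comparisons; the population is monotonic when the means are value
    ordered and both adjacent Tukey comparisons are significant.
    """
    g = [np.asarray(per_trial_sums[k], float) for k in ("R0", "R50", "R100")]
    if any(len(x) == 0 for x in g):
        return {"monotonic": False, "flag": "empty group"}
    f, p = stats.f_oneway(*g)
    tuk = stats.tukey_hsd(*g)
    means = [x.mean() for x in g]
    ordered = means[0] < means[1] < means[2]
    sig_adjacent = tuk.pvalue[0, 1] < alpha and tuk.pvalue[1, 2] < alpha
    return {
        "anova_F": float(f),
        "anova_p": float(p),
        "means": {"R0": means[0], "R50": means[1], "R100": means[2]},
        "tukey_p_R0_R50": float(tuk.pvalue[0, 1]),
        "tukey_p_R50_R100": float(tuk.pvalue[1, 2]),
        "monotonic": bool(ordered and sig_adjacent and p < alpha),
        "flag": "",
    }


def rate_jumps(
    rates_prior: np.ndarray, rates_after: np.ndarray
) -> np.ndarray:
    """Per-trial firing-rate jump at outcome: rate after US minus rate before."""
    return np.asarray(rates_after, float) - np.asarray(rates_prior, float)


def test_reward_surprise(
    jumps_cs50_rewarded: np.ndarray,
    jumps_cs100: np.ndarray,
    inhibited: bool = False,
    alpha: float = ALPHA_LEVEL,
) -> bool:
    """Reward-surprise criterion for one post-outcome window.

    Requires (a) a positive mean rate jump on rewarded CS50 trials and
    (b) the CS50 jumps exceeding the CS100 jumps in a two-tailed rank-sum
    test; both inequalities reversed for inhibited units.
    """
    d50 = np.asarray(jumps_cs50_rewarded, float)
    d100 = np.asarray(jumps_cs100, float)
    if len(d50) == 0 or len(d100) == 0:
        return False
    if inhibited:
        return d50.mean() < 0 and _ranksum_greater(d100, d50, alpha)
    return d50.mean() > 0 and _ranksum_greater(d50, d100, alpha)


def test_reward_surprise_unit(
    rates: pd.DataFrame, inhibited: bool = False, alpha: float = ALPHA_LEVEL
) -> bool:
    """Reward surprise tested in both post-outcome windows (short and long).

    ``rates`` must carry columns ``prior``, ``after_short``, ``after_long``
    from :func:`us_window_rates` along with ``cs`` / ``rewarded``.
    """
    cs50r = rates[(rates["cs"] == "CS50") & rates["rewarded"]]
    cs100 = rates[rates["cs"] == "CS100"]
    for after in ("after_short", "after_long"):
        d50 = rate_jumps(cs50r["prior"], cs50r[after])
        d100 = rate_jumps(cs100["prior"], cs100[after])
        if test_reward_surprise(d50, d100, inhibited=inhibited, alpha=alpha):
            return True
    return False


def us_window_rates(spikes: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial rates in the pre-outcome and the two post-outcome windows."""
    return window_rates(
        spikes,
        trials,
        windows={
            "prior": PRIOR_WINDOW,
            "after_short": AFTER_WINDOW_SHORT,
            "after_long": AFTER_WINDOW_LONG,
        },
    )


def test_outcome_discrimination(
    rates: pd.DataFrame, inhibited: bool = False, alpha: float = ALPHA_LEVEL
) -> bool:
    """Does the post-outcome rate separate rewarded from unrewarded CS50 trials?

    One-directional by design: rewarded above unrewarded for excited
    units, below for inhibited units; tested in either post-outcome
    window.
    """
    cs50r = rates[(rates["cs"] == "CS50") & rates["rewarded"]]
    cs50n = rates[(rates["cs"] == "CS50") & ~rates["rewarded"].astype(bool)]
    for after in ("after_short", "after_long"):
        a, b = cs50r[after].to_numpy(), cs50n[after].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        ok = _ranksum_greater(b, a, alpha) if inhibited else _ranksum_greater(a, b, alpha)
        if ok:
            return True
    return False


def chance_level_monotonic(unit_rate_groups: list, alpha: float = ALPHA_LEVEL) -> dict:
    """Observed vs chance counts of strict cue-response orderings.

    ``unit_rate_groups`` is a list of per-unit dicts {R0, R50, R100} of
    per-trial rates.  A unit is discriminative when all three pairwise
    rank-sum tests are significant; with 3! = 6 equally likely strict
    orderings, each specific ordering is expected in
    n_discriminative / 6 units by chance.
    """
    orderings = {p: 0 for p in permutations(("R0", "R50", "R100"))}
    n_disc = 0
    for g in unit_rate_groups:
        pairs = [("R0", "R50"), ("R0", "R100"), ("R50", "R100")]
        ps = [
            stats.mannwhitneyu(g[a], g[b], alternative="two-sided").pvalue
            for a, b in pairs
        ]
        if all(p < alpha for p in ps):
            n_disc += 1
            order = tuple(sorted(g, key=lambda c: np.mean(g[c]), reverse=True))
            orderings[order] += 1
    return {
        "n_discriminative": n_disc,
        "chance_per_ordering": n_disc / 6.0,
        "observed": {" > ".join(k): v for k, v in orderings.items()},
    }


def history_satiety_effects(groups: dict, alpha: float = ALPHA_LEVEL) -> dict:
    """ANOVA with Tukey comparisons over the four CS50 subgroups.

    ``groups`` maps the subgroup names ``lastR`` / ``lastN`` (outcome
    history) and ``priorCS100`` / ``priorCS0`` (satiety) to per-trial
    response values (rates or population distances).  Returns the overall
    ANOVA and the Tukey p values for the history pair and the satiety
    pair; empty subgroups skip the corresponding comparison.
    """
    names = ["lastR", "lastN", "priorCS100", "priorCS0"]
    arrs = {k: np.asarray(groups.get(k, []), float) for k in names}
    present = [k for k in names if len(arrs[k]) > 0]
    if len(present) < 2:
        return {"flag": "fewer than two non-empty subgroups"}
    f, p = stats.f_oneway(*[arrs[k] for k in present])
    tuk = stats.tukey_hsd(*[arrs[k] for k in present])
    idx = {k: i for i, k in enumerate(present)}
    out = {"anova_F": float(f), "anova_p": float(p), "flag": ""}
    if "lastR" in idx and "lastN" in idx:
        pv = float(tuk.pvalue[idx["lastR"], idx["lastN"]])
        out["history_p"] = pv
        out["history_significant"] = pv < alpha
        out["history_diff"] = float(arrs["lastR"].mean() - arrs["lastN"].mean())
    if "priorCS100" in idx and "priorCS0" in idx:
        pv = float(tuk.pvalue[idx["priorCS100"], idx["priorCS0"]])
        out["satiety_p"] = pv
        out["satiety_significant"] = pv < alpha
        out["satiety_diff"] = float(arrs["priorCS100"].mean() - arrs["priorCS0"].mean())
    return out
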