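"""Miniature event-related GLM engine for task BOLD data.

Cue (CS) and outcome (US) timepoints are modeled as zero-duration events
("stick functions") convolved with a fast-peaking rodent hemodynamic
response function; events need not align with volume acquisitions, so
convolution is done on an oversampled time grid and sampled at volume
onsets.  Three design variants mirror the univariate analyses:

- GLM 1: one regressor for all CS events, parametrically modulated by the
  TD value V(CS); four US regressors, one per outcome type (reward after
  CS100, reward after CS50, no reward after CS50, no reward after CS0).
- GLM 2: separate CS100 / CS50 / CS0 regressors, the CS50 regressor
  parametrically modulated by the previous CS50 outcome (+1/-1); four US
  regressors.
- GLM 3: three CS regressors, one US regressor with two parametric
  modulators, -V(CS) and binary reward r, deliberately not orthogonalized
  against each other.
- beta-series: every CS and US event of every trial gets its own
  regressor, yielding per-trial beta estimates for connectivity.

All variants add an HRF-convolved lick-event regressor, a cerebrospinal
fluid nuisance series when available, and a constant.  Modulator columns
are mean-centered over their events.  Session maps are combined with
voxel-wise one-sample t tests and Benjamini-Hochberg correction per tail;
beta-series connectivity is Pearson correlation between region-averaged
per-trial betas, Fisher z-transformed for group inference and reported as
the hyperbolic tangent of the mean z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .task import US_TIME

TR = 1.3  # seconds per volume
US_TYPES = ("US_R100", "US_R50", "US_N50", "US_N0")
FD_THRESHOLD = 0.05  # mm, low-motion event criterion


def mouse_hrf(
    dt: float, duration: float = 8.0, peak_time: float = 1.0, shape: float = 4.0
) -> np.ndarray:
    """Fast-peaking gamma hemodynamic kernel, normalized to unit peak.

    Rodent hemodynamics peak around 1 s, much earlier than the human
    canonical response; ``peak_time`` and ``shape`` are configurable.
    """
    if peak_time <= 0:
        raise ValueError("peak time must be positive")
    scale = peak_time / (shape - 1.0)
    t = np.arange(0.0, duration, dt)
    kernel = stats.gamma.pdf(t, a=shape, scale=scale)
    return kernel / kernel.max()


def convolve_events(
    onsets: np.ndarray,
    amplitudes: np.ndarray | None,
    n_vols: int,
    tr: float = TR,
    oversample: int = 16,
    hrf_kw: dict | None = None,
) -> np.ndarray:
    """HRF-convolved stick series sampled at volume onset times.

    Events are placed on a grid of ``tr / oversample`` resolution, so
    event times need not coincide with acquisitions.
    """
    onsets = np.asarray(onsets, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    dt = tr / oversample
    n_fine = n_vols * oversample
    sticks = np.zeros(n_fine)
    for t0, a in zip(onsets, amplitudes):
        k = int(round(t0 / dt))
        if 0 <= k < n_fine:
            sticks[k] += a
    kernel = mouse_hrf(dt, **(hrf_kw or {}))
    conv = np.convolve(sticks, kernel)[:n_fine]
    return conv[::oversample]


@dataclass
class DesignMatrix:
    """Time x regressor matrix with column-role bookkeeping."""

    X: pd.DataFrame
    tr: float
    event_columns: list = field(default_factory=list)
    modulator_columns: list = field(default_factory=list)
    nuisance_columns: list = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy()

    @property
    def columns(self) -> list:
        return list(self.X.columns)


def us_event_type(cs: str, rewarded: bool) -> str:
    if cs == "CS100":
        return "US_R100"
    if cs == "CS50":
        return "US_R50" if rewarded else "US_N50"
    if cs == "CS0":
        return "US_N0"
    raise ValueError(f"unknown CS label {cs!r}")


def _center(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return values - values.mean()


def build_design(
    seq: pd.DataFrame,
    n_vols: int,
    variant: str = "glm1",
    td: pd.DataFrame | None = None,
    lick_times: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    tr: float = TR,
    oversample: int = 16,
    hrf_kw: dict | None = None,
) -> DesignMatrix:
    """Assemble the design matrix for one session.

    ``seq`` supplies trial onsets, cues and outcomes; ``td`` (required for
    GLM 1 and GLM 3) is a TD trace run with the trained-animal initial
    values so the parametric modulator carries V(CS).  US events occur
    2.7 s after odor onset.
    """
    variant = variant.lower().replace("-", "").replace("_", "")
    kw = dict(n_vols=n_vols, tr=tr, oversample=oversample, hrf_kw=hrf_kw)
    cs_on = seq["onset"].to_numpy()
    us_on = cs_on + US_TIME
    cols = {}
    event_cols, mod_cols = [], []

    def add_us_by_type():
        for ut in US_TYPES:
            sel = np.array(
                [us_event_type(c, bool(r)) == ut for c, r in zip(seq["cs"], seq["rewarded"])]
            )
            cols[ut] = convolve_events(us_on[sel], None, **kw)
            event_cols.append(ut)

    if variant == "glm1":
        if td is None:
            raise ValueError("GLM 1 requires a TD trace for the V(CS) modulator")
        cols["CS"] = convolve_events(cs_on, None, **kw)
        event_cols.append("CS")
        cols["CSxV"] = convolve_events(cs_on, _center(td["V_cs"].to_numpy()), **kw)
        mod_cols.append("CSxV")
        add_us_by_type()
    elif variant == "glm2":
        for cs in ("CS100", "CS50", "CS0"):
            sel = (seq["cs"] == cs).to_numpy()
            cols[cs] = convolve_events(cs_on[sel], None, **kw)
            event_cols.append(cs)
        # previous-CS50-outcome modulator on CS50 events; the first CS50
        # trial has no history and does not contribute
        cs50_sel = (seq["cs"] == "CS50").to_numpy()
        outcomes = seq.loc[cs50_sel, "rewarded"].to_numpy().astype(float)
        hist = np.where(outcomes[:-1] > 0, 1.0, -1.0)
        amps = np.zeros(cs50_sel.sum())
        amps[1:] = hist - hist.mean()
        cols["CS50xHist"] = convolve_events(cs_on[cs50_sel], amps, **kw)
        mod_cols.append("CS50xHist")
        add_us_by_type()
    elif variant == "glm3":
        if td is None:
            raise ValueError("GLM 3 requires a TD trace for the -V(CS) modulator")
        for cs in ("CS100", "CS50", "CS0"):
            sel = (seq["cs"] == cs).to_numpy()
            cols[cs] = convolve_events(cs_on[sel], None, **kw)
            event_cols.append(cs)
        cols["US"] = convolve_events(us_on, None, **kw)
        event_cols.append("US")
        cols["USxnegV"] = convolve_events(us_on, _center(-td["V_cs"].to_numpy()), **kw)
        cols["USxr"] = convolve_events(
            us_on, _center(seq["rewarded"].to_numpy().astype(float)), **kw
        )
        mod_cols += ["USxnegV", "USxr"]
    elif variant == "betaseries":
        for i, (t_cs, t_us) in enumerate(zip(cs_on, us_on), start=1):
            cols[f"CS_{i:03d}"] = convolve_events(np.array([t_cs]), None, **kw)
            cols[f"US_{i:03d}"] = convolve_events(np.array([t_us]), None, **kw)
            event_cols += [f"CS_{i:03d}", f"US_{i:03d}"]
    else:
        raise ValueError(f"unknown design variant {variant!r}")

    nuisance = []
    if lick_times is not None:
        cols["licks"] = convolve_events(np.asarray(lick_times, float), None, **kw)
        nuisance.append("licks")
    if csf is not None:
        cols["csf"] = np.asarray(csf, dtype=float)
        nuisance.append("csf")
    cols["constant"] = np.ones(n_vols)
    nuisance.append("constant")
    return DesignMatrix(
        X=pd.DataFrame(cols),
        tr=tr,
        event_columns=event_cols,
        modulator_columns=mod_cols,
        nuisance_columns=nuisance,
    )


@dataclass
class BetaMap:
    """Voxel-wise OLS estimates for one session."""

    betas: pd.DataFrame  # regressor x voxel
    resid_var: np.ndarray
    df: int
    columns: list


def _collinear_columns(X: np.ndarray, columns: list) -> list:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [c for c, b in zip(columns, bad) if b]


def fit_glm(Y: np.ndarray, design: DesignMatrix | pd.DataFrame) -> BetaMap:
    """Ordinary least squares per voxel.

    ``Y`` is a (time x voxels) matrix (flatten 4-D images first, e.g. with
    :func:`image_to_matrix`).  Raises on a rank-deficient design, naming
    the collinear columns.
    """
    if isinstance(design, DesignMatrix):
        X = design.values
        columns = design.columns
    else:
        X = np.asarray(design)
        columns = list(design.columns)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, columns)
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - p
    resid_var = (resid**2).sum(axis=0) / max(df, 1)
    return BetaMap(
        betas=pd.DataFrame(beta, index=columns),
        resid_var=resid_var,
        df=df,
        columns=columns,
    )


def image_to_matrix(img, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a 4-D NIfTI image (or array) to time x voxels plus the voxel index."""
    data = np.asanyarray(img.dataobj) if hasattr(img, "dataobj") else np.asarray(img)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    vox = np.flatnonzero(mask.ravel())
    Y = data.reshape(-1, data.shape[3])[vox].T
    return Y, vox


def benjamini_hochberg_mask(p: np.ndarray, q: float) -> np.ndarray:
    """Boolean rejection mask of the Benjamini-Hochberg step-up procedure."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p)
    thresh = q * np.arange(1, n + 1) / n
    below = p[order] <= thresh
    mask = np.zeros(n, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        mask[order[: k + 1]] = True
    return mask


def group_stats(
    session_values: np.ndarray, q: float = 0.025
) -> dict:
    """Voxel-wise one-sample t over sessions with per-tail FDR control.

    ``session_values`` is (sessions x voxels) of contrast values.  Returns
    t and p maps plus ``mask_pos`` / ``mask_neg``, each controlled at FDR
    level ``q`` within its tail (two-sided testing at 2q overall).
    """
    session_values = np.asarray(session_values, dtype=float)
    if session_values.shape[0] < 2:
        raise ValueError("group statistics need at least 2 sessions")
    t, _ = stats.ttest_1samp(session_values, 0.0, axis=0)
    df = session_values.shape[0] - 1
    p_pos = stats.t.sf(t, df)
    p_neg = stats.t.cdf(t, df)
    return {
        "t": t,
        "df": df,
        "mask_pos": benjamini_hochberg_mask(p_pos, q),
        "mask_neg": benjamini_hochberg_mask(p_neg, q),
        "p_pos": p_pos,
        "p_neg": p_neg,
    }


def intersect_maps(*masks: np.ndarray) -> np.ndarray:
    """Voxel-wise logical AND of equally shaped masks."""
    shapes = {np.shape(m) for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    out = np.ones(shapes.pop(), dtype=bool)
    for m in masks:
        out &= np.asarray(m, dtype=bool)
    return out


def percent_signal_change(
    betamap: BetaMap,
    column: str,
    labels: np.ndarray,
    voxel_index: np.ndarray,
    kernel_peak: float = 1.0,
) -> pd.DataFrame:
    """Percent signal change per region, scaled by the regional baseline.

    PSC = 100 * beta * kernel peak / (mean constant-term beta of the
    region), so regions with a weak baseline signal (ventral areas under a
    surface coil) are not shrunk by a whole-brain scaler.
    """
    event_beta = betamap.betas.loc[column].to_numpy()
    const_beta = betamap.betas.loc["constant"].to_numpy()
    region_of_voxel = labels.ravel()[voxel_index]
    rows = []
    for region in np.unique(region_of_voxel):
        if region == 0:
            continue
        sel = region_of_voxel == region
        c = const_beta[sel].mean()
        if c == 0:
            rows.append({"region": region, "psc": np.nan, "flag": "zero baseline"})
            continue
        rows.append(
            {
                "region": region,
                "psc": 100.0 * event_beta[sel].mean() * kernel_peak / c,
                "flag": "",
            }
        )
    return pd.DataFrame(rows)


def framewise_displacement(motion: pd.DataFrame | np.ndarray) -> np.ndarray:
    """FD per volume: sum of absolute first differences of the six parameters.

    The first frame, having no predecessor, gets FD = 0.
    """
    arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion parameters must be (volumes x 6)")
    fd = np.zeros(arr.shape[0])
    fd[1:] = np.abs(np.diff(arr, axis=0)).sum(axis=1)
    return fd


def stratify_events(
    onsets: np.ndarray,
    fd: np.ndarray,
    tr: float = TR,
    threshold: float = FD_THRESHOLD,
) -> np.ndarray:
    """Label each event low-motion (True) by the FD of the frame at and after it."""
    onsets = np.asarray(onsets, dtype=float)
    low = np.zeros(len(onsets), dtype=bool)
    for i, t0 in enumerate(onsets):
        k = int(t0 // tr)
        frames = fd[k : k + 2]
        low[i] = len(frames) > 0 and bool(np.all(frames <= threshold))
    return low


def extract_beta_series(
    betamap: BetaMap,
    seq: pd.DataFrame,
    labels: np.ndarray,
    voxel_index: np.ndarray,
    event: str = "CS",
    cs_type: str | None = None,
    rewarded: bool | None = None,
) -> pd.DataFrame:
    """Region-averaged per-trial betas from a beta-series fit.

    Selects the trials matching ``cs_type`` (and ``rewarded`` when given)
    and returns a (trials x regions) DataFrame of the region-mean betas of
    their ``event`` ("CS" or "US") regressors.
    """
    sel = np.ones(len(seq), dtype=bool)
    if cs_type is not None:
        sel &= (seq["cs"] == cs_type).to_numpy()
    if rewarded is not None:
        sel &= seq["rewarded"].to_numpy() == rewarded
    trial_ids = seq.loc[sel, "trial_index"].to_numpy()
    region_of_voxel = labels.ravel()[voxel_index]
    regions = [r for r in np.unique(region_of_voxel) if r != 0]
    rows = []
    for tid in trial_ids:
        b = betamap.betas.loc[f"{event}_{int(tid):03d}"].to_numpy()
        rows.append([b[region_of_voxel == r].mean() for r in regions])
    return pd.DataFrame(rows, index=trial_ids, columns=regions)


def beta_series_connectivity(
    session_series: list,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> dict:
    """Group-level beta-series correlation between regions.

    ``session_series`` is a list of (trials x regions) DataFrames, one per
    session, for a single event type.  Per session the Pearson correlation
    matrix is computed and Fisher z-transformed; constant series are
    skipped (NaN).  Group inference is a one-sample t test on z per region
    pair, Bonferroni-corrected over pairs by default; the group
    correlation is the hyperbolic tangent of the mean z.
    """
    if not session_series:
        raise ValueError("no sessions given")
    regions = list(session_series[0].columns)
    n = len(regions)
    zs = np.full((len(session_series), n, n), np.nan)
    for s, bs in enumerate(session_series):
        arr = bs.to_numpy(dtype=float)
        if arr.shape[0] < 10:
            raise ValueError("need at least 10 events per session for connectivity")
        sd = arr.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(arr.T)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, 1.0)
        zs[s] = np.arctanh(np.clip(r, -0.999999, 0.999999))
    mean_z = np.nanmean(zs, axis=0)
    group_r = np.tanh(mean_z)
    n_pairs = n * (n - 1) // 2
    pmat = np.full((n, n), np.nan)
    sig = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            col = zs[:, i, j]
            col = col[np.isfinite(col)]
            if len(col) < 2:
                continue
            _, p = stats.ttest_1samp(col, 0.0)
            pmat[i, j] = pmat[j, i] = p
            thr = alpha / n_pairs if correction == "bonferroni" else alpha
            sig[i, j] = sig[j, i] = p < thr
    return {
        "regions": regions,
        "group_r": pd.DataFrame(group_r, index=regions, columns=regions),
        "p": pd.DataFrame(pmat, index=regions, columns=regions),
        "significant": pd.DataFrame(sig, index=regions, columns=regions),
    }
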