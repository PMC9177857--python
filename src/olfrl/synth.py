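"""Synthetic sessions with the statistical structure the analyses assume.

Generators for every downstream data modality: anticipatory licking that
scales with cue value and carries outcome-history and satiety effects,
pupil traces following the observation model, unit populations built from
functional archetypes (transient cue responses, value-scaled ramps with
history modulation, task inhibition, sustained activity), raw multichannel
voltage with inserted spike templates, and event-related BOLD series from
a design matrix with AR(1) noise.  Everything is reproducible bit-exact
from a seed.  Trial sequences themselves come from
:func:`olfrl.task.generate_trial_sequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import bandpass
from .fmri import DesignMatrix
from .pupil import (WINDOW_D0, WINDOW_D1, WINDOW_D2, PupilModelParams,
                    pupil_forward)
from .td import run_td_session

#: window in which anticipatory licking builds up (delay period)
ANTICIPATION_WINDOW = (1.0, 2.8)
CONSUMPTION_WINDOW = (2.8, 4.1)

REWARD_PROB = {"CS100": 1.0, "CS50": 0.5, "CS0": 0.0}


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _poisson_segment(rng, rate, t0, t1):
    """Homogeneous Poisson event times on [t0, t1) at `rate` Hz."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


# ---------------------------------------------------------------------------
# licking

@dataclass
class BehaviorParams:
    """Rates (Hz) and modulation weights of the synthetic licking agent.

    ``base_lick_rate`` applies throughout the trial; anticipatory licking
    adds ``anticipatory_gain * V(CS)`` during the delay; rewarded trials
    append a consumption burst.  On CS50 trials the anticipatory rate
    shifts by +/- ``history_weight`` with the previous CS50 outcome, and a
    reward on the immediately preceding trial subtracts
    ``satiety_weight``.
    """

    base_lick_rate: float = 0.4
    anticipatory_gain: float = 6.0
    consumption_rate: float = 8.0
    history_weight: float = 0.8
    satiety_weight: float = 0.5

    def __post_init__(self):
        for name in ("base_lick_rate", "anticipatory_gain", "consumption_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.history_weight) or not np.isfinite(self.satiety_weight):
            raise ValueError("modulation weights must be finite")


def simulate_agent_behavior(
    seq: pd.DataFrame,
    params: BehaviorParams | None = None,
    td: pd.DataFrame | None = None,
    rng=None,
) -> pd.DataFrame:
    """Draw lick times from an inhomogeneous Poisson process.

    ``td`` supplies the per-trial cue value V(CS) (defaults to a TD run
    with trained-animal initial values on ``seq``).  Negative instantaneous
    rates arising from strong satiety/history suppression are clamped to
    zero.  Returns a DataFrame with a single column ``time_s`` of absolute
    lick times.
    """
    params = params or BehaviorParams()
    rng = _rng(rng)
    if td is None:
        td = run_td_session(seq, init="trained")
    licks = []
    last_cs50_rewarded = None
    prev_rewarded = False
    for row, v in zip(seq.itertuples(), td["V_cs"]):
        onset = row.onset
        # tonic licking over the trial span
        licks.append(onset - 2.0 + _poisson_segment(rng, params.base_lick_rate, 0.0, 8.0))
        rate = params.anticipatory_gain * v
        if row.cs == "CS50" and last_cs50_rewarded is not None and params.history_weight:
            rate += params.history_weight * (1.0 if last_cs50_rewarded else -1.0)
        if prev_rewarded:
            rate -= params.satiety_weight
        rate = max(rate, 0.0)
        licks.append(onset + _poisson_segment(rng, rate, *ANTICIPATION_WINDOW))
        if row.rewarded:
            licks.append(
                onset + _poisson_segment(rng, params.consumption_rate, *CONSUMPTION_WINDOW)
            )
        if row.cs == "CS50":
            last_cs50_rewarded = bool(row.rewarded)
        prev_rewarded = bool(row.rewarded)
    return pd.DataFrame({"time_s": np.sort(np.concatenate(licks))})


# ---------------------------------------------------------------------------
# pupil

DEFAULT_PUPIL_PARAMS = PupilModelParams(
    alpha=0.28, a=np.array([0.0, 6.0, 2.0]), b=np.array([10.0, 3.0])
)


def simulate_pupil(
    seq: pd.DataFrame,
    params: PupilModelParams | None = None,
    noise_sd: float = 0.5,
    fs: float = 20.0,
    init: str | dict = "zeros",
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a percent-change pupil trace from the observation model.

    The TD model is run on ``seq`` at ``params.alpha``; each trial's three
    window averages follow the observation model plus i.i.d. Gaussian
    noise of ``noise_sd`` percent, and the continuous 20 Hz trace renders
    them piecewise-constant over the three windows (so recomputing the
    window means recovers the generated values exactly).

    Returns ``(trace, windows)``: the trace has ``time_s`` / ``pct_change``;
    ``windows`` has per-trial ``trial_index`` / ``d0`` / ``d1`` / ``d2``.
    """
    params = params or DEFAULT_PUPIL_PARAMS
    rng = _rng(rng)
    trace_td = run_td_session(seq, alpha=params.alpha, init=init)
    d_clean = pupil_forward(params, trace_td)
    d_obs = d_clean + rng.normal(0.0, noise_sd, size=d_clean.shape)
    t_end = seq["onset"].iloc[-1] + WINDOW_D2[1] + 2.0
    t = np.arange(0.0, t_end, 1.0 / fs)
    pct = np.zeros_like(t)
    for (_, onset), d in zip(seq[["trial_index", "onset"]].itertuples(index=False), d_obs):
        for (lo, hi), val in zip((WINDOW_D0, WINDOW_D1, WINDOW_D2), d):
            sel = (t - onset >= lo - 1e-9) & (t - onset < hi - 1e-9)
            pct[sel] = val
    windows = pd.DataFrame(
        {
            "trial_index": seq["trial_index"].to_numpy(),
            "d0": d_obs[:, 0],
            "d1": d_obs[:, 1],
            "d2": d_obs[:, 2],
        }
    )
    return pd.DataFrame({"time_s": t, "pct_change": pct}), windows


# ---------------------------------------------------------------------------
# spiking populations

@dataclass
class PopulationArchetypes:
    """Mixing weights and effect sizes of the synthetic unit population.

    ``weights`` gives the archetype proportions (transient cue responses,
    value-scaled ramping during the wait, task-inhibited, sustained,
    unmodulated baseline units); they must sum to 1.  ``history_gain``
    adds an outcome-history shift to the ramp amplitude of CS50 trials in
    ramping units only.  US responses of excited archetypes scale with
    reward surprise (1 - reward probability), so unexpectedly rewarded
    CS50 trials evoke larger jumps than CS100 trials.
    """

    weights: dict = field(
        default_factory=lambda: {
            "transient": 0.35,
            "ramping": 0.30,
            "inhibited": 0.20,
            "sustained": 0.10,
            "baseline": 0.05,
        }
    )
    baseline_range: tuple = (1.5, 4.5)
    transient_gain: float = 9.0
    ramping_gain: float = 7.0
    inhibition_depth: float = 0.8
    sustained_gain: float = 3.0
    history_gain: float = 2.0
    us_gain: float = 8.0
    frac_monotonic: float = 0.5
    #: probability that a single-cue unit prefers CS0 / CS50 / CS100 —
    #: responder counts scale with cue value, so the summed population
    #: response stays value-ordered
    preference_probs: tuple = (0.1, 0.35, 0.55)

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype weights must sum to 1, got {total}")


#: per-trial raster window, seconds relative to odor onset
RASTER_WINDOW = (-3.0, 6.0)


def _trial_rate_segments(arch, kind, unit, cs, rewarded, hist_state):
    """Piecewise-constant rate segments (t0, t1, rate) added to baseline."""
    v = REWARD_PROB[cs]
    segs = []
    if kind == "transient":
        if unit["monotonic"]:
            amp = unit["gain"] * (0.2 + 0.8 * v)
        else:
            amp = unit["gain"] if cs == unit["preferred"] else 0.0
        segs.append((0.0, 1.0, amp))
    elif kind == "ramping":
        amp = unit["gain"] * v
        if cs == "CS50" and hist_state is not None:
            amp += unit["history_gain"] * (1.0 if hist_state else -1.0)
        amp = max(amp, 0.0)
        # linear ramp 1 -> 2.5 s approximated in 6 x 0.25 s steps
        for k in range(6):
            t0 = 1.0 + 0.25 * k
            segs.append((t0, t0 + 0.25, amp * (k + 0.5) / 6.0))
    elif kind == "inhibited":
        depth = unit["depth"] * (0.4 + 0.6 * v)
        segs.append((0.0, 2.7, -depth * unit["baseline"]))
    elif kind == "sustained":
        segs.append((0.0, 2.7, unit["gain"] * (0.2 + 0.8 * v)))
    # US response
    if rewarded and kind in ("transient", "ramping", "sustained"):
        surprise = 1.05 - v
        segs.append((2.7, 3.7, unit["us_gain"] * surprise))
    if rewarded and kind == "inhibited":
        surprise = 1.05 - v
        segs.append((2.7, 3.7, -unit["us_gain"] * surprise * 0.3))
    return segs


def simulate_population(
    seq: pd.DataFrame,
    archetypes: PopulationArchetypes | None = None,
    n_units: int = 60,
    rng=None,
) -> dict:
    """Simulate a session's unit rasters as inhomogeneous Poisson spikes.

    Returns ``{"rasters": {unit_id: DataFrame(trial_index, spike_time)},
    "unit_table": DataFrame(unit, archetype, baseline, ...)}``; spike
    times are seconds relative to odor onset within ``RASTER_WINDOW``.
    """
    arch = archetypes or PopulationArchetypes()
    rng = _rng(rng)
    kinds = list(arch.weights)
    probs = np.array([arch.weights[k] for k in kinds])
    rasters, units = {}, []
    for u in range(n_units):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        unit = {
            "baseline": rng.uniform(*arch.baseline_range),
            "gain": {
                "transient": arch.transient_gain,
                "ramping": arch.ramping_gain,
                "sustained": arch.sustained_gain,
            }.get(kind, 0.0) * rng.uniform(0.7, 1.3),
            "depth": arch.inhibition_depth,
            "history_gain": arch.history_gain if kind == "ramping" else 0.0,
            "us_gain": arch.us_gain * rng.uniform(0.7, 1.3),
            "monotonic": bool(rng.random() < arch.frac_monotonic),
            "preferred": ("CS0", "CS50", "CS100")[
                rng.choice(3, p=np.asarray(arch.preference_probs))
            ],
        }
        uid = f"u{u:03d}"
        rows_tr, rows_t = [], []
        hist_state = None
        for row in seq.itertuples():
            base = unit["baseline"]
            segs = [(RASTER_WINDOW[0], RASTER_WINDOW[1], 0.0)]
            extra = _trial_rate_segments(arch, kind, unit, row.cs, bool(row.rewarded), hist_state)
            # carve the trial window into the baseline span plus additive segments
            times = [_poisson_segment(rng, base, *RASTER_WINDOW)]
            for t0, t1, r in extra:
                if r > 0:
                    times.append(_poisson_segment(rng, r, t0, t1))
                elif r < 0:
                    # inhibition: thin the baseline spikes in the segment
                    keep_p = max(0.0, 1.0 + r / base) if base > 0 else 0.0
                    t_all = times[0]
                    in_seg = (t_all >= t0) & (t_all < t1)
                    drop = in_seg & (rng.random(len(t_all)) > keep_p)
                    times[0] = t_all[~drop]
            st = np.sort(np.concatenate(times))
            rows_tr.append(np.full(len(st), row.trial_index))
            rows_t.append(st)
            if row.cs == "CS50":
                hist_state = bool(row.rewarded)
        rasters[uid] = pd.DataFrame(
            {
                "trial_index": np.concatenate(rows_tr).astype(int),
                "spike_time": np.concatenate(rows_t),
            }
        )
        units.append({"unit": uid, "archetype": kind, **{k: unit[k] for k in
                      ("baseline", "gain", "monotonic", "preferred")}})
    return {"rasters": rasters, "unit_table": pd.DataFrame(units)}


# ---------------------------------------------------------------------------
# raw voltage

def spike_template(fs: float = 30_000.0, width_ms: float = 1.2) -> np.ndarray:
    """Biphasic extracellular spike template with unit negative peak."""
    n = int(width_ms * 1e-3 * fs)
    t = np.arange(n) / fs * 1e3  # ms
    wave = -np.exp(-((t - 0.25) ** 2) / (2 * 0.08**2)) + 0.45 * np.exp(
        -((t - 0.65) ** 2) / (2 * 0.18**2)
    )
    return wave / np.abs(wave).max()


def simulate_voltage(
    spike_times: np.ndarray,
    n_channels: int = 4,
    duration: float | None = None,
    fs: float = 30_000.0,
    noise_sd: float = 1.0,
    amp_mad: float = 10.0,
    spike_channel: int | np.ndarray = 0,
    common_mode: np.ndarray | None = None,
    rng=None,
) -> np.ndarray:
    """Gaussian noise plus inserted spike templates (channels x samples).

    Spike amplitude is ``amp_mad`` times the median absolute deviation of
    the band-passed noise, so detectability is stated on the detector's
    own threshold scale.  ``common_mode`` (same length as the trace) is
    added to every channel to emulate movement artifacts.
    """
    rng = _rng(rng)
    spike_times = np.asarray(spike_times, dtype=float)
    if duration is None:
        duration = (spike_times.max() if len(spike_times) else 0.0) + 0.1
    n = int(round(duration * fs))
    x = rng.normal(0.0, noise_sd, size=(n_channels, n))
    mad = float(np.median(np.abs(bandpass(x[0], fs=fs))))
    unit = spike_template(fs)
    # calibrate so the *band-passed* template peaks at amp_mad x MAD,
    # compensating the filter's attenuation of the sharp waveform
    padded = np.zeros(len(unit) + 2000)
    padded[1000 : 1000 + len(unit)] = unit
    attenuation = float(np.abs(bandpass(padded, fs=fs)).max())
    tmpl = unit * amp_mad * mad / attenuation
    chans = np.broadcast_to(np.asarray(spike_channel), spike_times.shape)
    for t0, ch in zip(spike_times, chans):
        k = int(round(t0 * fs))
        seg = tmpl[: max(0, min(len(tmpl), n - k))]
        if k >= 0 and len(seg):
            x[int(ch), k : k + len(seg)] += seg
    if common_mode is not None:
        x += np.asarray(common_mode, dtype=float)[None, :n]
    return x


# ---------------------------------------------------------------------------
# BOLD

def region_labels(grid_shape: tuple, n_regions: int) -> np.ndarray:
    """Label a voxel grid with ``n_regions`` equal contiguous slabs (0 = none)."""
    labels = np.zeros(grid_shape, dtype=np.int16)
    flat = labels.ravel()
    n_vox = flat.size
    per = n_vox // (n_regions + 1)  # leave a background share
    for r in range(1, n_regions + 1):
        flat[(r - 1) * per : r * per] = r
    return labels


def ar1_noise(rng, shape: tuple, sd: float, coef: float = 0.3) -> np.ndarray:
    """AR(1) noise along the last axis with stationary sd ``sd``."""
    e = rng.normal(0.0, sd * np.sqrt(1.0 - coef**2), size=shape)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = coef * out[..., t - 1] + e[..., t]
    return out


def simulate_bold(
    design: DesignMatrix,
    region_betas: pd.DataFrame,
    grid_shape: tuple = (24, 24, 4),
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    ar_coef: float = 0.3,
    rng=None,
) -> dict:
    """Generate a 4-D BOLD phantom from a design matrix.

    ``region_betas`` is a (regions x regressors) table; missing regressors
    default to 0 and the constant column to ``baseline``.  Every voxel of
    a region shares the region's betas; background voxels only carry the
    baseline.  Noise is AR(1) along time.

    Returns ``{"data": (x, y, z, t) array, "labels": (x, y, z) int array,
    "truth": full beta table}``.
    """
    rng = _rng(rng)
    X = design.values
    n_vols, _ = X.shape
    n_regions = len(region_betas)
    labels = region_labels(grid_shape, n_regions)
    truth = pd.DataFrame(
        0.0, index=region_betas.index, columns=design.columns
    )
    for col in region_betas.columns:
        truth[col] = region_betas[col]
    if "constant" in design.columns and "constant" not in region_betas.columns:
        truth["constant"] = baseline
    data = np.zeros(grid_shape + (n_vols,))
    flat = data.reshape(-1, n_vols)
    lab_flat = labels.ravel()
    for i, region in enumerate(truth.index, start=1):
        series = X @ truth.loc[region].to_numpy()
        flat[lab_flat == i] = series
    flat[lab_flat == 0] = baseline
    if noise_sd > 0:
        data += ar1_noise(rng, grid_shape + (n_vols,), noise_sd, ar_coef)
    return {"data": data, "labels": labels, "truth": truth}


def to_nifti(data: np.ndarray, affine: np.ndarray | None = None):
    """Wrap an array in a NIfTI image (identity affine by default)."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
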