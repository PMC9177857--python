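"""Spike detection from multichannel extracellular voltage and unit QC.

Preprocessing follows the tetrode pipeline used for awake head-fixed
recordings: the per-sample median over channels of a recording site is
subtracted to remove common-mode movement artifacts, the signal is
band-passed 300-5000 Hz (4th-order Butterworth, applied forward-backward
so spike timestamps are not shifted), and spiking events are local maxima
of the filtered signal exceeding 7.5x the median absolute deviation of
that channel, with a 1 ms minimum peak separation.  Events detected on
several channels of the same tetrode within the refractory distance are
collapsed to the channel with the largest peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

SAMPLE_RATE = 30_000.0
MAD_THRESHOLD = 7.5
MIN_PEAK_DISTANCE_MS = 1.0
WAVEFORM_WINDOW = (-10, 21)  # samples around the peak, inclusive -> 32 samples
REFRACTORY_MS = 2.0
MAX_VIOLATION_RATIO = 0.02
BASELINE_RATE_CUTOFF = {"Tu": 5.0, "aPC": 10.0}


@dataclass
class DetectedUnit:
    """A sorted unit with the fields the QC rules operate on."""

    spike_times: np.ndarray
    region: str
    baseline_rate: float
    waveforms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def violation_ratio(self) -> float:
        return refractory_violation_ratio(self.spike_times)


def median_subtract(block: np.ndarray) -> np.ndarray:
    """Subtract the per-sample median across channels (channels x time)."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[0] < 2:
        raise ValueError("need a channels x time matrix with >= 2 channels")
    return block - np.median(block, axis=0, keepdims=True)


def bandpass(
    block: np.ndarray,
    fs: float = SAMPLE_RATE,
    low: float = 300.0,
    high: float = 5000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the time axis."""
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(block, dtype=float), axis=-1)


def _channel_mad(x: np.ndarray) -> float:
    # raw MAD of the filtered trace, without the Gaussian consistency factor
    return float(np.median(np.abs(x - np.median(x))))


def detect_spikes(
    filtered: np.ndarray,
    fs: float = SAMPLE_RATE,
    threshold_mad: float = MAD_THRESHOLD,
    min_distance_ms: float = MIN_PEAK_DISTANCE_MS,
    tetrodes: list | None = None,
    polarity: str = "abs",
) -> pd.DataFrame:
    """Detect threshold-crossing peaks on a filtered channels x time block.

    The amplitude threshold is ``threshold_mad`` times the per-channel
    median absolute deviation.  ``polarity`` selects whether peaks are
    sought on the absolute signal (default) or only on negative-going
    deflections (``"neg"``).  ``tetrodes`` is a list of channel-index
    groups; within a group, events closer than the minimum peak distance
    are merged and assigned the timestamp of the highest peak.

    Returns a DataFrame with ``sample``, ``time_s``, ``channel`` and
    ``amplitude`` (absolute peak height), sorted by time.
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    n_ch, _ = filtered.shape
    if tetrodes is None:
        tetrodes = [list(range(n_ch))]
    dist = max(int(round(min_distance_ms * 1e-3 * fs)), 1)
    per_channel = []
    for ch in range(n_ch):
        x = filtered[ch]
        sig = np.abs(x) if polarity == "abs" else -x
        thr = threshold_mad * _channel_mad(x)
        peaks, props = find_peaks(sig, height=thr, distance=dist)
        per_channel.append(
            pd.DataFrame(
                {"sample": peaks, "channel": ch, "amplitude": props["peak_heights"]}
            )
        )
    events = pd.concat(per_channel, ignore_index=True)
    if events.empty:
        return pd.DataFrame(columns=["sample", "time_s", "channel", "amplitude"])
    kept = []
    for group in tetrodes:
        ev = events[events["channel"].isin(group)].sort_values("sample")
        if ev.empty:
            continue
        samples = ev["sample"].to_numpy()
        amps = ev["amplitude"].to_numpy()
        chans = ev["channel"].to_numpy()
        # greedy merge: within each cluster of peaks closer than `dist`,
        # keep the single largest peak across channels
        cluster_start = 0
        for i in range(1, len(ev) + 1):
            if i == len(ev) or samples[i] - samples[i - 1] > dist:
                sl = slice(cluster_start, i)
                j = cluster_start + int(np.argmax(amps[sl]))
                kept.append((samples[j], chans[j], amps[j]))
                cluster_start = i
    out = pd.DataFrame(kept, columns=["sample", "channel", "amplitude"])
    out["time_s"] = out["sample"] / fs
    return out.sort_values("sample").reset_index(drop=True)[
        ["sample", "time_s", "channel", "amplitude"]
    ]


def extract_waveforms(
    filtered: np.ndarray, events: pd.DataFrame, window: tuple = WAVEFORM_WINDOW
) -> np.ndarray:
    """Extract per-event waveforms (-10..+21 samples around each peak)."""
    filtered = np.atleast_2d(filtered)
    lo, hi = window
    n = hi - lo + 1
    out = np.zeros((len(events), n))
    T = filtered.shape[1]
    for i, (s, ch) in enumerate(zip(events["sample"], events["channel"])):
        a, b = int(s) + lo, int(s) + hi + 1
        seg = filtered[int(ch), max(a, 0) : min(b, T)]
        out[i, max(0, -a) : max(0, -a) + len(seg)] = seg
    return out


def refractory_violation_ratio(
    spike_times: np.ndarray, refractory_ms: float = REFRACTORY_MS
) -> float:
    """Fraction of spikes whose preceding inter-spike interval is < 2 ms."""
    st = np.sort(np.asarray(spike_times, dtype=float))
    if len(st) < 2:
        return 0.0
    return float(np.sum(np.diff(st) < refractory_ms * 1e-3) / len(st))


def unit_qc(unit: DetectedUnit) -> tuple[bool, str]:
    """Apply the inclusion rules for putative principal neurons.

    Units with >= 2% refractory-period violations are rejected as
    contaminated.  Tu units with baseline rate >= 5 Hz are rejected as
    putative fast-spiking neurons; aPC units with baseline >= 10 Hz
    likewise.  Returns ``(include, reason)``.
    """
    if unit.region not in BASELINE_RATE_CUTOFF:
        raise ValueError(f"unknown region {unit.region!r}")
    if unit.violation_ratio >= MAX_VIOLATION_RATIO:
        return False, f"refractory violations {unit.violation_ratio:.1%} >= 2%"
    cutoff = BASELINE_RATE_CUTOFF[unit.region]
    if unit.baseline_rate >= cutoff:
        return False, (
            f"baseline rate {unit.baseline_rate:.1f} Hz >= {cutoff:.0f} Hz "
            f"({unit.region} fast-spiking cutoff)"
        )
    return True, "included"
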