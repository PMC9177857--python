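"""Plain-text readers and writers for the session file layout.

A session directory holds ``trials.tsv`` (trial_index, cs, rewarded,
onset_s), ``licks.tsv`` (time_s), ``pupil.tsv`` (time_s, pct_change),
``units/<id>.tsv`` (trial_index, spike_time_s relative to odor onset) and
``truth.json`` with the generative parameters.  Raw voltage is a
little-endian int16 channels x samples binary with a JSON sidecar giving
gain and sample rate; BOLD volumes are NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_trials(path, seq: pd.DataFrame) -> None:
    out = seq.rename(columns={"onset": "onset_s"})
    out.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"onset_s": "onset"})
    df["rewarded"] = df["rewarded"].astype(bool)
    return df


def write_licks(path, licks: pd.DataFrame) -> None:
    licks.to_csv(path, sep="\t", index=False)


def read_licks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pupil(path, trace: pd.DataFrame) -> None:
    trace.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_pupil(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_units(dirpath, rasters: dict) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for uid, spk in rasters.items():
        spk.rename(columns={"spike_time": "spike_time_s"}).to_csv(
            d / f"{uid}.tsv", sep="\t", index=False, float_format="%.5f"
        )


def read_units(dirpath) -> dict:
    out = {}
    for f in sorted(Path(dirpath).glob("*.tsv")):
        df = pd.read_csv(f, sep="\t").rename(columns={"spike_time_s": "spike_time"})
        out[f.stem] = df
    return out


def write_voltage(path, block: np.ndarray, fs: float, gain_uv: float = 1.0) -> None:
    """Write channels x samples int16 binary plus a JSON sidecar."""
    path = Path(path)
    scaled = np.clip(np.round(np.asarray(block) / gain_uv), -32768, 32767).astype("<i2")
    scaled.tofile(path)
    sidecar = {"n_channels": int(block.shape[0]), "sample_rate": fs, "gain_uv": gain_uv}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_voltage(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path, dtype="<i2").reshape(meta["n_channels"], -1)
    return raw.astype(float) * meta["gain_uv"], meta


def write_truth(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
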