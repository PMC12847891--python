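"""File formats: EDF recordings, hypnogram sidecars, peak and histogram tables.

Recordings are exchanged as EDF (one file per subject, signals in
microvolts) with a plain-CSV hypnogram sidecar (``<stem>_hypnogram.csv``
with columns ``epoch_index,stage``). EDF reading goes through mne; writing
uses a small built-in EDF encoder (16-bit, one-second data records), which
round-trips against mne's reader to within one digitization step.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import StagedRecording, normalize_stage
from .socoupling import CoupledHistogram

__all__ = [
    "write_edf",
    "read_edf",
    "write_hypnogram",
    "read_hypnogram",
    "write_ground_truth",
    "write_histogram",
    "read_histogram",
]


def _pad(text: str, n: int) -> bytes:
    b = str(text).encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str | Path, rec: StagedRecording) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    The sampling rate must be a whole number of samples per second. Physical
    units are microvolts; a trailing partial second is dropped. The stage
    sequence goes to the hypnogram sidecar, not into the EDF.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    n_sig = len(rec.channel_names)
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")

    data = rec.samples[:, : n_rec * spr]
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.01, 1.0)
    dig_max, dig_min = 32767, -32768
    # EDF convention: physical = (digital - dig_min) * range_ratio + phys_min
    scale = 2 * phys_max / (dig_max - dig_min)
    offset = -phys_max - dig_min * scale

    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X synthetic", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_sig)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(n_sig), 4),
    ])
    fields = [
        [_pad(f"EEG {ch}", 16) for ch in rec.channel_names],
        [_pad("AgAgCl electrode", 80)] * n_sig,
        [_pad("uV", 8)] * n_sig,
        [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [_pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [_pad(str(dig_min), 8)] * n_sig,
        [_pad(str(dig_max), 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(spr), 8)] * n_sig,
        [_pad("", 32)] * n_sig,
    ]
    header += b"".join(b"".join(f) for f in fields)

    digital = np.clip(np.round((data - offset[:, None]) / scale[:, None]),
                      dig_min, dig_max).astype("<i2")
    # interleave per one-second record: (n_rec, n_sig, spr)
    interleaved = digital.reshape(n_sig, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(interleaved.tobytes())
    return path


def read_edf(path: str | Path, hypnogram: str | Path | None = None,
             subject: str = "") -> StagedRecording:
    """Read an EDF recording (via mne) plus its hypnogram sidecar.

    Channel labels are normalized to bare 10-20 names ("EEG C3-M2" -> "C3").
    A missing sidecar yields a stage-less recording (unusable for condition
    masking) with a warning. Signals with unequal rates are resampled by mne
    to the lowest common rate.
    """
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"EDF file missing or empty: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6          # Volts -> microvolts
    names = []
    for ch in raw.ch_names:
        name = ch.removeprefix("EEG ").strip()
        name = name.split("-")[0].strip()
        names.append(name or ch)

    if hypnogram is None:
        cand = path.with_name(path.stem + "_hypnogram.csv")
        hypnogram = cand if cand.exists() else None
    if hypnogram is None:
        warnings.warn(f"no hypnogram sidecar for {path.name}; recording is "
                      "stage-less and cannot be condition-masked")
        stages: list[str] = []
    else:
        stages = read_hypnogram(hypnogram)
    max_epochs = int(data.shape[1] / (30 * raw.info["sfreq"]))
    return StagedRecording(data, float(raw.info["sfreq"]), names,
                           stages[:max_epochs],
                           subject=subject or path.stem)


def write_hypnogram(path: str | Path, stages: list[str]) -> Path:
    path = Path(path)
    pd.DataFrame({"epoch_index": range(len(stages)), "stage": stages}
                 ).to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path) -> list[str]:
    df = pd.read_csv(path)
    return [normalize_stage(s) for s in df["stage"]]


def write_ground_truth(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def write_histogram(path_base: str | Path, hist: CoupledHistogram) -> tuple[Path, Path]:
    """Persist one histogram as a TSV matrix plus a JSON sidecar."""
    base = Path(path_base)
    tsv = base.with_suffix(".tsv")
    cols = [f"{a:.6g}..{b:.6g}" for a, b in zip(hist.coupling_edges[:-1],
                                                hist.coupling_edges[1:])]
    rows = [f"{a:.6g}..{b:.6g}" for a, b in zip(hist.freq_edges[:-1],
                                                hist.freq_edges[1:])]
    pd.DataFrame(hist.values, index=rows, columns=cols).to_csv(tsv, sep="\t")
    meta = {
        "kind": hist.kind, "channel": hist.channel, "condition": hist.condition,
        "subject": hist.subject, "n_peaks": hist.n_peaks,
        "freq_edges": list(map(float, hist.freq_edges)),
        "coupling_edges": list(map(float, hist.coupling_edges)),
        "minutes_per_coupling_bin": (None if hist.minutes_per_coupling_bin is None
                                     else list(map(float, hist.minutes_per_coupling_bin))),
    }
    js = base.with_suffix(".json")
    js.write_text(json.dumps(meta, indent=1))
    return tsv, js


def read_histogram(path_base: str | Path) -> CoupledHistogram:
    base = Path(path_base)
    values = pd.read_csv(base.with_suffix(".tsv"), sep="\t", index_col=0).to_numpy()
    meta = json.loads(base.with_suffix(".json").read_text())
    minutes = meta["minutes_per_coupling_bin"]
    return CoupledHistogram(
        kind=meta["kind"], freq_edges=np.array(meta["freq_edges"]),
        coupling_edges=np.array(meta["coupling_edges"]), values=values,
        minutes_per_coupling_bin=None if minutes is None else np.array(minutes),
        channel=meta["channel"], condition=meta["condition"],
        subject=meta["subject"], n_peaks=meta["n_peaks"])
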