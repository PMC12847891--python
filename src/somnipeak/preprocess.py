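"""Preprocessing of staged sleep-EEG recordings.

Brings raw multi-channel recordings to the analysis-ready state: anti-aliased
down-sampling to the working rate (default 100 Hz), zero-phase 0.1-40 Hz
band-pass filtering, re-referencing, conservative bad-channel rejection, and
per-sample condition masks for the three analysis conditions (NREM+REM
combined, NREM-only, REM-only).

Zero-phase (forward-backward) IIR filtering is used throughout because group
delay would bias the slow-oscillation phase estimates computed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "StagedRecording",
    "ConditionMask",
    "EPOCH_S",
    "STAGES",
    "NREM_STAGES",
    "CONDITIONS",
    "normalize_stage",
    "resample",
    "bandpass",
    "rereference",
    "reject_channels",
    "condition_mask",
]

EPOCH_S = 30.0
STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_STAGES = frozenset({"N1", "N2", "N3"})
CONDITIONS = ("NREM+REM", "NREM", "REM")

#: Normalization table for stage-label synonyms found in hypnogram exports.
STAGE_SYNONYMS = {
    "W": "W", "WAKE": "W", "0": "W", "S0": "W",
    "N1": "N1", "1": "N1", "S1": "N1", "NREM1": "N1",
    "N2": "N2", "2": "N2", "S2": "N2", "NREM2": "N2",
    "N3": "N3", "3": "N3", "S3": "N3", "4": "N3", "S4": "N3", "NREM3": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
}


def normalize_stage(label: str) -> str:
    """Map a raw hypnogram label onto the canonical W/N1/N2/N3/REM set."""
    key = str(label).strip().upper()
    try:
        return STAGE_SYNONYMS[key]
    except KeyError:
        raise ValueError(f"unrecognized sleep-stage label: {label!r}") from None


@dataclass
class StagedRecording:
    """A multi-channel EEG recording with per-epoch AASM stage labels.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        10-20 labels, typically from {F3, F4, C3, C4, O1, O2}; unique.
    stages : list of str
        One canonical stage label per 30-s epoch.
    reference : str
        Description of the current reference ("as-recorded", "common-average",
        ...).
    subject : str
        Subject identifier (used for bookkeeping in cohort analyses).
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    stages: list[str]
    reference: str = "as-recorded"
    subject: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("one channel name per sample row required")
        n_epoch_samples = len(self.stages) * EPOCH_S * self.fs
        if self.samples.shape[1] < n_epoch_samples:
            raise ValueError(
                f"{len(self.stages)} epochs need >= {n_epoch_samples:.0f} "
                f"samples, got {self.samples.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]

    def stage_of_sample(self) -> np.ndarray:
        """Stage label per sample; samples past the last scored epoch get 'W'.

        Epoch e covers the half-open sample range [e*30*fs, (e+1)*30*fs).
        """
        out = np.full(self.n_samples, "W", dtype=object)
        spe = int(round(EPOCH_S * self.fs))
        for e, st in enumerate(self.stages):
            out[e * spe:(e + 1) * spe] = st
        return out


@dataclass
class ConditionMask:
    """Boolean per-sample selection for one analysis condition."""

    condition: str
    mask: np.ndarray
    fs: float

    @property
    def minutes(self) -> float:
        return int(self.mask.sum()) / (self.fs * 60.0)


def resample(rec: StagedRecording, target_fs: float = 100.0) -> StagedRecording:
    """Down-sample with anti-alias filtering (polyphase FIR).

    Upsampling is refused: the pipeline only ever moves to a coarser grid.
    """
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz not supported")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return replace(rec, samples=out, fs=target_fs)


def bandpass(rec: StagedRecording, low: float = 0.1, high: float = 40.0) -> StagedRecording:
    """Zero-phase band-pass as a high-pass/low-pass Butterworth cascade.

    Separate sections (4th-order high-pass, 6th-order low-pass, each run
    forward-backward) stay numerically well conditioned when the band edges
    are extreme relative to the sampling rate (0.1 Hz at 100-256 Hz), where
    a single combined band-pass SOS loses stop-band attenuation; the
    low-pass order gives > 20 dB one octave above the edge after the
    forward-backward doubling.
    """
    if not (0.0 < low < high < rec.fs / 2.0):
        raise ValueError(f"band ({low}, {high}) violates 0 < low < high < fs/2")
    hp = sps.butter(4, low, btype="highpass", fs=rec.fs, output="sos")
    lp = sps.butter(6, high, btype="lowpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(hp, rec.samples, axis=1)
    out = sps.sosfiltfilt(lp, out, axis=1)
    return replace(rec, samples=out)


def rereference(rec: StagedRecording, scheme: str = "common-average") -> StagedRecording:
    """Re-reference: 'common-average', 'none', or 'constant' (no-op on a
    recording already referenced to linked mastoids or similar)."""
    if scheme in ("none", "constant", "linked-mastoid-like"):
        return rec
    if scheme == "common-average":
        if len(rec.channel_names) < 2:
            warnings.warn("common-average reference needs >= 2 channels; "
                          "leaving the recording unreferenced")
            return rec
        out = rec.samples - rec.samples.mean(axis=0, keepdims=True)
        return replace(rec, samples=out, reference="common-average")
    raise ValueError(f"unknown reference scheme: {scheme!r}")


def reject_channels(
    rec: StagedRecording,
    flat_sd_uv: float = 0.1,
    flat_epoch_frac: float = 0.05,
    outlier_robust_sd: float = 8.0,
) -> tuple[StagedRecording, list[str]]:
    """Reject at most one persistently artefactual channel per recording.

    A channel is flagged when it is flat-lined (per-epoch SD below
    ``flat_sd_uv`` in more than ``flat_epoch_frac`` of epochs) or an amplitude
    outlier (its robust SD exceeds ``outlier_robust_sd`` times the median
    robust SD of the other channels). If several channels are flagged only
    the worst one is removed, with a warning: small clinical cohorts cannot
    afford losing more.
    """
    if len(rec.channel_names) < 2:
        raise ValueError("need >= 2 channels to run rejection")
    spe = int(round(EPOCH_S * rec.fs))
    n_ep = max(1, rec.n_samples // spe)
    ep = rec.samples[:, : n_ep * spe].reshape(len(rec.channel_names), n_ep, spe)
    flat_frac = (ep.std(axis=2) < flat_sd_uv).mean(axis=1)

    # amplitude outliers: a channel whose robust scale dwarfs the other
    # channels' (leave-one-out median, so one degenerate channel cannot
    # poison the reference)
    ch_mad = 1.4826 * np.median(
        np.abs(rec.samples - np.median(rec.samples, axis=1, keepdims=True)),
        axis=1)
    n_ch = len(rec.channel_names)
    peak_z = np.zeros(n_ch)
    for i in range(n_ch):
        ref = np.median(np.delete(ch_mad, i))
        if ref > 0.1:                 # reference itself must not be flat
            peak_z[i] = ch_mad[i] / ref

    # badness score: how far past either criterion each channel goes
    badness = np.maximum(flat_frac / flat_epoch_frac, peak_z / outlier_robust_sd)
    flagged = np.where(badness > 1.0)[0]
    if flagged.size == 0:
        return rec, []
    if flagged.size > 1:
        warnings.warn(
            f"{flagged.size} channels exceeded artefact criteria; removing only "
            "the worst (at most one channel per recording is excluded)"
        )
    worst = int(flagged[np.argmax(badness[flagged])])
    keep = [i for i in range(len(rec.channel_names)) if i != worst]
    rejected = [rec.channel_names[worst]]
    out = replace(
        rec,
        samples=rec.samples[keep],
        channel_names=[rec.channel_names[i] for i in keep],
    )
    return out, rejected


def condition_mask(rec: StagedRecording, condition: str) -> ConditionMask:
    """Per-sample mask for one of the three analysis conditions.

    NREM selects N1|N2|N3 samples, REM selects REM, NREM+REM their union;
    wake is never selected.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    per_sample = rec.stage_of_sample()
    if condition == "NREM":
        sel = NREM_STAGES
    elif condition == "REM":
        sel = {"REM"}
    else:
        sel = NREM_STAGES | {"REM"}
    mask = np.isin(per_sample, list(sel))
    return ConditionMask(condition=condition, mask=mask, fs=rec.fs)
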