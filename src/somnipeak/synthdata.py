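"""Synthetic staged-PSG cohort generator with ground-truth event lists.

Emulates the features of overnight sleep EEG that the SO-coupling analysis
relies on: a 30-s staged hypnogram (first-order Markov chain), 1/f broadband
background, a slow-oscillation (SO) component confined to 0.3-1.5 Hz whose
amplitude depends on sleep stage (N3 > N2 > N1 ~ REM), and transient
oscillatory bursts in 4-25 Hz whose occurrence rate depends on the SO-power
percentile and whose timing follows a von Mises preference for an SO phase
(trough = 0 radians convention).

Every event inserted is logged with its true SO phase and true SO-power
percentile at insertion, so downstream detection, histogramming and
statistics can be checked against a recoverable target. Identical seeds give
bit-identical cohorts.

Group templates perturb the control coupling structure qualitatively in the
directions reported for clinical cohorts (reduced fast-sigma density at high
SO power, phase dispersion, extra theta/low-alpha density); the magnitudes
are free simulator parameters chosen for testability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import i0e

from .preprocess import EPOCH_S, STAGES, NREM_STAGES, StagedRecording

__all__ = [
    "CouplingSpec",
    "GroupSpec",
    "HypnogramParams",
    "SOTruth",
    "GroundTruth",
    "generate_hypnogram",
    "generate_background",
    "generate_so",
    "inject_transients",
    "generate_cohort",
    "default_groups",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("F3", "F4", "C3", "C4", "O1", "O2")

#: stage -> SO amplitude gain; slow oscillations dominate deep NREM.
SO_STAGE_GAIN = {"W": 0.25, "N1": 0.5, "N2": 1.0, "N3": 2.0, "REM": 0.4}

#: microvolts per unit of the internal (background SD = 1) signal scale.
UV_PER_UNIT = 15.0


@dataclass(frozen=True)
class CouplingSpec:
    """Generative description of one transient-event class.

    ``event_rate_per_min`` is the target rate per minute of eligible sleep in
    an SO-power quartile with multiplier 1; ``power_rate_multipliers`` scales
    it per quartile (bottom to top). Event timing is drawn so accepted SO
    phases follow von Mises(``phase_mu``, ``phase_kappa``); ``phase_kappa = 0``
    is uniform. ``event_amplitude`` is in units of the broadband background SD.
    """

    name: str
    band_low_hz: float
    band_high_hz: float
    event_rate_per_min: float
    power_rate_multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    phase_mu: float = 0.0
    phase_kappa: float = 0.0
    event_duration_s: float = 0.8
    event_amplitude: float = 3.0
    stages: frozenset[str] = frozenset({"N2", "N3"})

    def __post_init__(self) -> None:
        if not (4.0 <= self.band_low_hz < self.band_high_hz <= 25.0):
            raise ValueError("event band must lie within the 4-25 Hz analysis range")
        if any(m < 0 for m in self.power_rate_multipliers):
            raise ValueError("power_rate_multipliers must be >= 0")
        if self.phase_kappa < 0:
            raise ValueError("phase_kappa must be >= 0")
        if not (-np.pi <= self.phase_mu < np.pi):
            raise ValueError("phase_mu must lie in [-pi, pi)")
        bad = set(self.stages) - (NREM_STAGES | {"REM"})
        if bad:
            raise ValueError(f"events may only be gated to N1/N2/N3/REM, got {bad}")


@dataclass(frozen=True)
class HypnogramParams:
    """First-order Markov hypnogram model over 30-s epochs.

    ``dwell_epochs`` sets the expected bout length per stage (self-transition
    probability 1 - 1/dwell); ``weights`` are the relative probabilities of
    entering each stage when leaving the current one (and of the initial
    stage). ``ensure_nrem``/``ensure_rem`` patch the tail of the sequence if
    the chain happened to produce none, so short simulated nights still
    contain the requested states.
    """

    dwell_epochs: dict = field(default_factory=lambda: {
        "W": 1.5, "N1": 1.5, "N2": 5.0, "N3": 3.5, "REM": 3.0})
    weights: dict = field(default_factory=lambda: {
        "W": 0.2, "N1": 0.8, "N2": 3.0, "N3": 1.5, "REM": 1.0})
    ensure_nrem: bool = True
    ensure_rem: bool = False


@dataclass
class GroupSpec:
    """One simulated diagnostic group."""

    name: str
    n_subjects: int
    coupling_specs: list[CouplingSpec]
    so_amplitude_scale: float = 2.0
    hypnogram_params: HypnogramParams = field(default_factory=HypnogramParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class SOTruth:
    """Ground-truth slow-oscillation state of one simulated recording."""

    signal: np.ndarray         # SO component, internal units
    phase_rad: np.ndarray      # [-pi, pi), trough = 0
    envelope: np.ndarray       # instantaneous SO amplitude, >= 0
    fs: float
    stage_per_sample: np.ndarray


@dataclass
class GroundTruth:
    """Cohort-level ground truth: injected events and hypnograms."""

    events: pd.DataFrame       # subject, channel, time_s, freq_hz, phase_rad, power_pct
    hypnograms: dict           # subject -> list of stage labels


def generate_hypnogram(duration_s: float, params: HypnogramParams, seed: int) -> list[str]:
    """Sample a stage sequence (one label per 30-s epoch), deterministically."""
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 (at least two 30-s epochs)")
    w = {s: float(params.weights.get(s, 0.0)) for s in STAGES}
    if any(v < 0 for v in w.values()):
        raise ValueError("stage weights must be nonnegative")
    total_w = sum(w.values())
    if total_w == 0:
        raise ValueError("stage weights must not all be zero")
    rng = np.random.default_rng(seed)
    n_epochs = int(duration_s // EPOCH_S)

    labels = [s for s in STAGES if w[s] > 0]
    probs = np.array([w[s] for s in labels]) / total_w
    current = labels[rng.choice(len(labels), p=probs)]
    seq = []
    for _ in range(n_epochs):
        seq.append(current)
        dwell = max(1.0, float(params.dwell_epochs.get(current, 2.0)))
        if rng.random() < 1.0 - 1.0 / dwell:
            continue
        others = [s for s in labels if s != current]
        if not others:
            continue
        op = np.array([w[s] for s in others])
        current = others[rng.choice(len(others), p=op / op.sum())]

    if params.ensure_nrem and not any(s in NREM_STAGES for s in seq):
        if any(w[s] > 0 for s in NREM_STAGES):
            best = max(NREM_STAGES, key=lambda s: w[s])
            seq[-1] = best
    if params.ensure_rem and "REM" not in seq and w["REM"] > 0:
        idx = -1 if seq[-1] not in NREM_STAGES or not params.ensure_nrem else -2
        seq[idx] = "REM"
    return seq


def generate_background(n_samples: int, fs: float, slope: float = 1.0,
                        seed: int = 0) -> np.ndarray:
    """Zero-mean 1/f^slope noise with unit SD (spectral shaping in the FFT)."""
    if n_samples <= 0 or fs <= 0:
        raise ValueError("n_samples and fs must be positive")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-slope / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to [-pi, pi)."""
    return np.mod(phi + np.pi, 2 * np.pi) - np.pi


def _stage_per_sample(stages: list[str], n_samples: int, fs: float) -> np.ndarray:
    out = np.full(n_samples, "W", dtype=object)
    spe = int(round(EPOCH_S * fs))
    for e, st in enumerate(stages):
        out[e * spe:(e + 1) * spe] = st
    return out


def generate_so(stages: list[str], fs: float, so_amplitude_scale: float = 2.0,
                seed: int = 0, mode: str = "noise", sinusoid_hz: float = 0.75,
                duration_s: float | None = None) -> SOTruth:
    """Synthesize the slow-oscillation component and its ground-truth state.

    'noise' mode: Gaussian noise band-passed to 0.3-1.5 Hz and scaled by a
    per-stage gain (N3 > N2 > N1 ~ REM), smoothed over 2 s at stage changes.
    'sinusoid' mode: a pure cosine at ``sinusoid_hz`` with constant amplitude
    ``so_amplitude_scale``, for phase-convention checks.

    The true phase uses the trough = 0 convention: analytic-signal angle of
    the narrowband waveform minus pi, wrapped to [-pi, pi).
    """
    if not stages:
        raise ValueError("stage sequence must be nonempty")
    if fs < 10:
        raise ValueError("fs must be >= 10 Hz to carry the SO band")
    if duration_s is None:
        duration_s = len(stages) * EPOCH_S
    n = int(round(duration_s * fs))
    stage_ps = _stage_per_sample(stages, n, fs)

    if mode == "sinusoid":
        t = np.arange(n) / fs
        carrier = np.cos(2 * np.pi * sinusoid_hz * t)
        phase = _wrap_phase(2 * np.pi * sinusoid_hz * t - np.pi)
        env = np.full(n, abs(so_amplitude_scale))
        return SOTruth(so_amplitude_scale * carrier, phase, env, fs, stage_ps)
    if mode != "noise":
        raise ValueError(f"unknown SO mode {mode!r}")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = sps.butter(4, [0.3, 1.5], btype="bandpass", fs=fs, output="sos")
    narrow = sps.sosfiltfilt(sos, white)
    sd = narrow.std()
    if sd > 0:
        narrow = narrow / sd

    gain = np.array([SO_STAGE_GAIN[s] for s in stage_ps], dtype=float)
    ramp = int(round(2.0 * fs))
    if ramp > 1:
        kern = np.hanning(ramp)
        gain = np.convolve(gain, kern / kern.sum(), mode="same")
    gain *= so_amplitude_scale

    analytic = sps.hilbert(narrow)
    phase = _wrap_phase(np.angle(analytic) - np.pi)
    env = gain * np.abs(analytic)
    return SOTruth(gain * narrow, phase, env, fs, stage_ps)


def _so_power_truth(so: SOTruth, window_s: float = 30.0) -> np.ndarray:
    """Sliding-window SO bandpower of the clean SO signal.

    Uses the same measurement operator as the analysis (zero-phase
    0.3-1.5 Hz band-pass, then a 30-s moving average of the squared
    narrowband signal), so the ground-truth percentile is defined on the
    identical scale the pipeline later estimates from the noisy recording.
    """
    from .socoupling import so_bandpass

    narrow = so_bandpass(so.signal, so.fs)
    win = int(round(window_s * so.fs))
    win = max(1, min(win, len(so.signal)))
    kern = np.ones(win) / win
    return np.convolve(narrow ** 2, kern, mode="same")


def inject_transients(base: np.ndarray, so: SOTruth, spec: CouplingSpec,
                      seed: int, noise_sd: float = 1.0) -> tuple[np.ndarray, pd.DataFrame]:
    """Insert Hann-windowed oscillatory bursts with the requested coupling.

    Candidate times form a Poisson process on eligible (permitted-stage)
    samples; each candidate is accepted with probability proportional to its
    SO-power-quartile rate multiplier times the von Mises density at its SO
    phase (rejection sampling). The candidate rate is pre-inflated by the
    two mean acceptance factors so that the expected accepted rate in
    quartile q is ``event_rate_per_min * power_rate_multipliers[q]``.

    The SO state that drives the coupling (and is logged as ground truth) is
    the *measurable* one: the 0.3-1.5 Hz phase and sliding-window bandpower
    of the base recording itself, computed with the same operators the
    analysis uses. Events are thereby tied to the SO state an analysis of
    the finished recording can actually observe.

    Returns the signal with bursts added and the event log (time_s, freq_hz,
    phase_rad, power_pct of each accepted event).
    """
    fs = so.fs
    n = len(base)
    if len(so.signal) != n:
        raise ValueError("SO truth must cover the signal span")
    rng = np.random.default_rng(seed)

    eligible = np.isin(so.stage_per_sample, list(spec.stages))
    elig_idx = np.flatnonzero(eligible)
    cols = ["time_s", "freq_hz", "phase_rad", "power_pct"]
    if elig_idx.size == 0:
        return base.copy(), pd.DataFrame(columns=cols)

    from scipy.stats import rankdata

    from .socoupling import so_bandpass

    narrow = so_bandpass(np.asarray(base, dtype=float), fs)
    if np.allclose(narrow, 0.0):
        # no SO content (e.g. zero-amplitude test signals): fall back to the
        # clean SO reference for phase and power
        phase_ref = so.phase_rad
        power = _so_power_truth(so)
    else:
        analytic = sps.hilbert(narrow)
        phase_ref = _wrap_phase(np.angle(analytic) - np.pi)
        win = max(1, min(int(round(30.0 * fs)), n))
        power = np.convolve(narrow ** 2, np.ones(win) / win, mode="same")
    pct = np.full(n, np.nan)
    r = rankdata(power[elig_idx], method="average")
    pct[elig_idx] = (r - 0.5) / elig_idx.size * 100.0
    quart = np.clip((pct[elig_idx] // 25).astype(int), 0, 3)

    mults = np.asarray(spec.power_rate_multipliers, dtype=float)
    max_mult = mults.max()
    if max_mult == 0:
        return base.copy(), pd.DataFrame(columns=cols)
    elig_min = elig_idx.size / (fs * 60.0)
    expected_total = spec.event_rate_per_min * mults.mean() * elig_min
    if expected_total * spec.event_duration_s > 0.5 * elig_min * 60.0:
        raise ValueError(
            "infeasible spec: expected bursts would cover more than half of "
            "the eligible time"
        )

    # mean acceptance of the phase rejection step over uniform phases is
    # I0(kappa) * exp(-kappa); pre-inflate so target rates are preserved.
    phase_accept_mean = float(i0e(spec.phase_kappa))
    lam = spec.event_rate_per_min * max_mult / phase_accept_mean
    n_cand = rng.poisson(lam * elig_min)
    if n_cand == 0:
        return base.copy(), pd.DataFrame(columns=cols)

    cand = rng.integers(0, elig_idx.size, size=n_cand)
    phases = phase_ref[elig_idx[cand]]
    accept_p = (mults[quart[cand]] / max_mult) * np.exp(
        spec.phase_kappa * (np.cos(phases - spec.phase_mu) - 1.0))
    keep = rng.random(n_cand) < accept_p
    idx = elig_idx[cand[keep]]
    idx.sort()

    out = base.copy()
    half = int(round(spec.event_duration_s * fs / 2))
    L = 2 * half + 1                   # odd length: energy centred on the event sample
    win = np.hanning(L)
    t_local = (np.arange(L) - half) / fs
    events = []
    for i in idx:
        f = rng.uniform(spec.band_low_hz, spec.band_high_hz)
        ph0 = rng.uniform(0, 2 * np.pi)
        lo, hi = i - half, i + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        burst = (spec.event_amplitude * noise_sd * win
                 * np.cos(2 * np.pi * f * t_local + ph0))
        out[s0:s1] += burst[s0 - lo:L - (hi - s1)]
        events.append((i / fs, f, phase_ref[i], pct[i]))
    ev = pd.DataFrame(events, columns=cols)
    return out, ev


def default_groups(scale_n: float = 1.0) -> list[GroupSpec]:
    """Default five-group cohort template.

    Control coupling structure: trough-locked fast sigma (12-15 Hz) whose
    rate grows with SO power, up-slope slow sigma (10-12 Hz) concentrated at
    the highest SO power, and phase-uniform theta (4-8 Hz) present in all
    sleep stages. Patient templates perturb it qualitatively:

    - NT1: fast-sigma top-quartile rate multiplier halved.
    - iRBD: same halving plus fast-sigma phase concentration halved.
    - NREMP: fast-sigma phase concentration quartered, rates unchanged.
    - FM: an extra phase-uniform 4-10 Hz (theta/low-alpha) event class.

    ``scale_n`` shrinks subject counts for quick runs (minimum 2 per group).
    """
    fast = CouplingSpec("fast_sigma", 12.0, 15.0, 4.0, (0.25, 0.75, 1.5, 3.5),
                        phase_mu=0.0, phase_kappa=4.0)
    slow = CouplingSpec("slow_sigma", 10.0, 12.0, 2.0, (0.4, 0.8, 1.2, 3.0),
                        phase_mu=2.0, phase_kappa=2.0)
    theta = CouplingSpec("theta", 4.0, 8.0, 2.0, (1.0, 1.0, 1.0, 1.0),
                         phase_kappa=0.0,
                         stages=frozenset({"N1", "N2", "N3", "REM"}))
    extra_fm = CouplingSpec("theta_low_alpha", 4.0, 10.0, 2.0,
                            (1.0, 1.0, 1.0, 1.0), phase_kappa=0.0,
                            stages=frozenset({"N1", "N2", "N3"}))

    nt1_fast = replace(fast, power_rate_multipliers=(0.25, 0.75, 1.5, 1.75))
    irbd_fast = replace(nt1_fast, phase_kappa=2.0)
    nremp_fast = replace(fast, phase_kappa=1.0)

    def n_of(n):
        return max(2, int(round(n * scale_n)))

    hyp = HypnogramParams(ensure_rem=True)
    return [
        GroupSpec("control", n_of(39), [fast, slow, theta], hypnogram_params=hyp),
        GroupSpec("NREMP", n_of(16), [nremp_fast, slow, theta], hypnogram_params=hyp),
        GroupSpec("NT1", n_of(16), [nt1_fast, slow, theta], hypnogram_params=hyp),
        GroupSpec("iRBD", n_of(17), [irbd_fast, slow, theta], hypnogram_params=hyp),
        GroupSpec("FM", n_of(11), [fast, slow, theta, extra_fm], hypnogram_params=hyp),
    ]


def generate_cohort(groups: list[GroupSpec], channels=DEFAULT_CHANNELS,
                    duration_s: float = 600.0, fs: float = 100.0,
                    seed: int = 0, background_slope: float = 1.0,
                    ) -> tuple[list[StagedRecording], GroundTruth, list[str]]:
    """Simulate a multi-group cohort.

    Each subject gets one hypnogram and one slow-oscillation realization
    shared across channels (the SO is a global cortical rhythm), with
    independent broadband background and independent event draws per channel.
    Per-subject/per-channel seeds are spawned deterministically from the
    master seed. Signals are scaled to microvolts.

    Returns (recordings, ground truth, group label per recording).
    """
    if not groups:
        raise ValueError("need at least one group")
    if not channels:
        raise ValueError("need at least one channel")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")

    ss = np.random.SeedSequence(seed)
    recs: list[StagedRecording] = []
    labels: list[str] = []
    all_events = []
    hypnos: dict[str, list[str]] = {}
    n = int(round(duration_s * fs))

    subj_counter = 0
    for g in groups:
        for k in range(g.n_subjects):
            subject = f"{g.name}_{k:03d}"
            sub_ss = np.random.SeedSequence(seed, spawn_key=(subj_counter,))
            seeds = sub_ss.generate_state(2 + len(channels) * (1 + len(g.coupling_specs)))
            seeds = (seeds % (2 ** 31)).astype(int)
            si = iter(seeds)

            stages = generate_hypnogram(duration_s, g.hypnogram_params, next(si))
            hypnos[subject] = stages
            so = generate_so(stages, fs, g.so_amplitude_scale, next(si),
                             duration_s=duration_s)

            chans = np.empty((len(channels), n))
            for ci, ch in enumerate(channels):
                bg = generate_background(n, fs, background_slope, next(si))
                sig = bg + so.signal
                for cs in g.coupling_specs:
                    sig, ev = inject_transients(sig, so, cs, next(si), noise_sd=1.0)
                    if len(ev):
                        ev.insert(0, "channel", ch)
                        ev.insert(0, "subject", subject)
                        all_events.append(ev)
                chans[ci] = sig * UV_PER_UNIT
            recs.append(StagedRecording(chans, fs, list(channels), stages,
                                        subject=subject))
            labels.append(g.name)
            subj_counter += 1

    cols = ["subject", "channel", "time_s", "freq_hz", "phase_rad", "power_pct"]
    events = (pd.concat(all_events, ignore_index=True)[cols]
              if all_events else pd.DataFrame(columns=cols))
    return recs, GroundTruth(events, hypnos), labels
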