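"""Self-validation experiments on synthetic data.

Each function builds a synthetic scenario with a known ground truth, runs
the relevant slice of the analysis pipeline, and returns the measured
quantity, so that detector correctness, coupling recovery, statistical
calibration, reliability and classification power can be checked end to end
without clinical recordings. The experiment scales (durations, event rates,
repetition counts) are chosen to give stable estimates on a single CPU in
minutes; the cohort structure (five groups of 39/16/16/17/11 subjects)
follows the study design the pipeline targets.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import derive_seed
from .decompose import FeatureMatrix, build_matrix, fit_pca
from .evaluate import match_components, permutation_test, split_half
from .groupstats import run_group_stats
from .preprocess import StagedRecording, condition_mask
from .socoupling import (annotate_peaks, base_so_series, circular_mean_phase,
                         compute_so_series, phase_histogram, power_histogram)
from .synthdata import (CouplingSpec, GroupSpec, HypnogramParams,
                        default_groups, generate_background, generate_cohort,
                        generate_so, inject_transients)
from .tfpeaks import (Spectrogram, TFPeakConfig, brute_force_peaks,
                      detect_tfpeaks, extract_peaks, peaks_to_frame,
                      watershed_segment)

__all__ = [
    "watershed_oracle_agreement",
    "trough_locked_phase",
    "phase_recovery",
    "rate_recovery",
    "conservation_error",
    "detection_performance",
    "null_kw_calibration",
    "null_permutation_uniformity",
    "nt1_contrast",
    "reliability_motif_rate",
    "reliability_noise_median",
]

FS = 100.0

#: detector used in the cohort-level experiments: coarser 0.1 s spectrogram
#: step (still 8 frames across a 0.8 s burst) to keep multi-cohort runs fast.
FAST_DETECTOR = TFPeakConfig(step_s=0.1)


# --------------------------------------------------------------------------
# watershed vs brute force
# --------------------------------------------------------------------------

def _random_bump_surface(seed: int, shape=(200, 100)) -> np.ndarray:
    """Noise-free dB surface with k <= 10 isolated Gaussian bumps."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 11))
    img = np.full(shape, -20.0)
    tt, ff = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < k and tries < 5000:
        tries += 1
        ci = int(rng.integers(10, shape[0] - 10))
        cj = int(rng.integers(8, shape[1] - 8))
        if all(abs(ci - a) > 20 or abs(cj - b) > 12 for a, b in placed):
            placed.append((ci, cj))
            amp = rng.uniform(5, 15)
            img += (amp + 20) * np.exp(-(((tt - ci) / rng.uniform(2, 4)) ** 2
                                         + ((ff - cj) / rng.uniform(1.5, 3)) ** 2))
    return img


def watershed_oracle_agreement(n_trials: int = 100, seed: int = 0) -> float:
    """Fraction of random noise-free bump surfaces on which watershed peak
    locations equal the brute-force local-maxima scan exactly."""
    ok = 0
    for t in range(n_trials):
        img = _random_bump_surface(derive_seed(seed, "bumps", t))
        flat = Spectrogram(img, np.arange(img.shape[0], dtype=float),
                           np.arange(img.shape[1], dtype=float), db=True)
        labels = watershed_segment(flat)
        peaks = extract_peaks(labels, flat, fmin=0, fmax=img.shape[1],
                              dur_min_s=0, dur_max_s=np.inf,
                              bw_min_hz=0, bw_max_hz=np.inf)
        got = sorted((p.time_s, p.freq_hz) for p in peaks)
        if got == sorted(brute_force_peaks(flat)):
            ok += 1
    return ok / n_trials


# --------------------------------------------------------------------------
# coupling recovery through the full detection + histogram path
# --------------------------------------------------------------------------

def _annotated_peaks(sig: np.ndarray, stages: list[str],
                     config: TFPeakConfig | None = None):
    rec = StagedRecording(sig[None, :], FS, ["C3"], stages)
    cmask = condition_mask(rec, "NREM")
    so = compute_so_series(sig, FS, cmask)
    pf = peaks_to_frame(detect_tfpeaks(sig, FS, config))
    ann, _ = annotate_peaks(pf, so)
    return ann, so


def trough_locked_phase(seed: int, n_min: int = 45, amp: float = 4.0,
                        stride: int = 2) -> tuple[float, int]:
    """Insert bursts exactly at the troughs of a pure 0.75 Hz SO and recover
    the circular-mean phase from the pipeline's phase histogram.

    Every ``stride``-th trough carries one burst (stride 2 keeps bursts
    ~2.7 s apart, well separated at the spectrogram's ~1 s smearing).
    Returns (circular mean in rad, number of annotated peaks).
    """
    stages = ["N2"] * (2 * n_min)
    so = generate_so(stages, FS, 2.0, 0, mode="sinusoid")
    n = len(so.signal)
    sig = generate_background(n, FS, 1.0, derive_seed(seed, "bg")) + so.signal
    f0 = 0.75
    troughs = np.arange(0.5 / f0, n / FS - 1, 1 / f0)[::stride]
    rng = np.random.default_rng(derive_seed(seed, "bursts"))
    L = 81
    win = np.hanning(L)
    tl = (np.arange(L) - L // 2) / FS
    for tt in troughs:
        i = int(round(tt * FS))
        f = rng.uniform(12, 15)
        sig[i - L // 2:i + L // 2 + 1] += amp * win * np.cos(
            2 * np.pi * f * tl + rng.uniform(0, 2 * np.pi))
    ann, _ = _annotated_peaks(sig, stages)
    hist = phase_histogram(ann)
    return circular_mean_phase(hist, 10, 17), len(ann)


def phase_recovery(seed: int, kappa: float = 4.0, mu: float = 0.0,
                   n_min: int = 40, rate: float = 20.0) -> tuple[float, int]:
    """Recover a von Mises phase preference through detection + histogram.

    Returns (circular mean of the sigma rows of the phase histogram, number
    of annotated peaks).
    """
    stages = ["N2"] * (2 * n_min)
    so = generate_so(stages, FS, 2.0, derive_seed(seed, "so"))
    sig0 = generate_background(len(so.signal), FS, 1.0,
                               derive_seed(seed, "bg")) + so.signal
    spec = CouplingSpec("sigma", 12.0, 15.0, rate, (1, 1, 1, 1),
                        phase_mu=mu, phase_kappa=kappa)
    sig, _ = inject_transients(sig0, so, spec, derive_seed(seed, "inj"))
    ann, _ = _annotated_peaks(sig, stages)
    hist = phase_histogram(ann)
    return circular_mean_phase(hist, 10, 17), len(ann)


def rate_recovery(seed: int, n_min: int = 470, rate: float = 3.5,
                  multipliers=(1.0, 1.0, 1.0, 2.0),
                  so_scale: float = 3.0) -> tuple[float, int]:
    """Recover the top/bottom SO-power-quartile density ratio.

    The SO is simulated at a high amplitude (``so_scale`` = 3 background
    SDs) so the recovery isolates the coupling mechanism rather than the
    SO-power estimation noise. Returns (density ratio between the top and
    bottom quartile columns of the sigma rows, number of injected events).
    """
    stages = ["N2"] * (2 * n_min)
    so = generate_so(stages, FS, so_scale, derive_seed(seed, "so"))
    sig0 = generate_background(len(so.signal), FS, 1.0,
                               derive_seed(seed, "bg")) + so.signal
    spec = CouplingSpec("sigma", 12.0, 15.0, rate, tuple(multipliers),
                        phase_kappa=0.0)
    sig, ev = inject_transients(sig0, so, spec, derive_seed(seed, "inj"))
    ann, so_series = _annotated_peaks(sig, stages, FAST_DETECTOR)
    hist = power_histogram(ann, so_series)
    rows = (hist.freq_edges[:-1] >= 10.0) & (hist.freq_edges[1:] <= 17.0)
    dens = hist.values[rows].sum(axis=0)
    return float(dens[-1] / dens[0]), len(ev)


def conservation_error(seed: int, n_subjects: int = 3,
                       duration_s: float = 300.0) -> tuple[float, float]:
    """Power-histogram conservation and phase-histogram normalization.

    Runs a small single-group cohort through detection and both histograms;
    returns (max relative error of density*minutes vs peak counts, max
    absolute deviation of phase-histogram sums from 1).
    """
    groups = [GroupSpec("g", n_subjects, default_groups()[0].coupling_specs)]
    recs, _, _ = generate_cohort(groups, channels=("C3",),
                                 duration_s=duration_s, seed=seed)
    max_rel, max_phase = 0.0, 0.0
    for rec in recs:
        sig = rec.channel("C3")
        cmask = condition_mask(rec, "NREM")
        so = compute_so_series(sig, rec.fs, cmask)
        pf = peaks_to_frame(detect_tfpeaks(sig, rec.fs, FAST_DETECTOR))
        ann, _ = annotate_peaks(pf, so)
        ph = power_histogram(ann, so)
        if ph.n_peaks:
            tot = float((ph.values * ph.minutes_per_coupling_bin[None, :]).sum())
            max_rel = max(max_rel, abs(tot - ph.n_peaks) / ph.n_peaks)
        pp = phase_histogram(ann)
        if pp.n_peaks:
            max_phase = max(max_phase, abs(pp.values.sum() - 1.0))
    return max_rel, max_phase


def detection_performance(seed: int, n_min: int = 10) -> tuple[float, float]:
    """Detector recall on injected bursts and false alarms on burst-free EEG.

    Builds one N2 recording with the control template's three event classes,
    measures the fraction of injected events matched by a detected TF-peak
    within +/-0.5 s and +/-1.5 Hz, and the peaks/min detected on the same
    background without any bursts. Returns (recall, false positives/min).
    """
    stages = ["N2"] * (2 * n_min)
    so = generate_so(stages, FS, 2.0, derive_seed(seed, "so"))
    clean = generate_background(len(so.signal), FS, 1.0,
                                derive_seed(seed, "bg")) + so.signal
    sig = clean.copy()
    events = []
    for i, cs in enumerate(default_groups()[0].coupling_specs):
        sig, ev = inject_transients(sig, so, cs, derive_seed(seed, "inj", i))
        events.append(ev[["time_s", "freq_hz"]].to_numpy())
    truth = np.concatenate(events)
    peaks = detect_tfpeaks(sig, FS)
    pt = np.array([p.time_s for p in peaks])
    pf = np.array([p.freq_hz for p in peaks])
    hits = sum(bool(np.any((np.abs(pt - t) <= 0.5) & (np.abs(pf - f) <= 1.5)))
               for t, f in truth)
    fp = len(detect_tfpeaks(clean, FS)) / n_min
    return hits / len(truth), fp


# --------------------------------------------------------------------------
# statistical calibration on null cohorts
# --------------------------------------------------------------------------

GROUP_SIZES = {"control": 39, "NREMP": 16, "NT1": 16, "iRBD": 17, "FM": 11}


def _null_labels() -> list[str]:
    out: list[str] = []
    for g, n in GROUP_SIZES.items():
        out += [g] * n
    return out


def null_kw_calibration(n_reps: int = 200, seed: int = 0, n_cells: int = 84,
                        n_components: int = 10) -> tuple[np.ndarray, float]:
    """Kruskal-Wallis calibration on score-level null cohorts.

    Each replicate draws all five groups' histogram features from the same
    distribution, runs PCA and the full KW + BY-FDR + Mann-Whitney cascade,
    and records the first component's raw KW p plus whether any component
    survived the cascade. Returns (raw p-values, fraction of replicates with
    at least one post-cascade false positive).
    """
    labels = _null_labels()
    n_sub = len(labels)
    p_first = np.empty(n_reps)
    any_fp = 0
    for r in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, "null", r))
        X = rng.standard_normal((n_sub, n_cells))
        fm = FeatureMatrix(
            data=(X - X.mean(0)) / X.std(0), subjects=[str(i) for i in range(n_sub)],
            col_means=X.mean(0), col_sds=X.std(0),
            constant_cols=np.zeros(n_cells, bool))
        cs = fit_pca(fm, n_components)
        fam = run_group_stats(cs.scores, labels)
        p_first[r] = fam.table["p_raw"].iloc[0]
        sig = False
        for c, pw in fam.pairwise.items():
            if bool(pw["significant"].any()):
                sig = True
        any_fp += int(sig)
    return p_first, any_fp / n_reps


def null_permutation_uniformity(n_reps: int = 40, seed: int = 0,
                                n_perm: int = 149) -> np.ndarray:
    """Permutation-test p-values on null two-group data (should be uniform)."""
    p_vals = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, "permnull", r))
        X = rng.standard_normal((40, 5))
        labels = ["a"] * 12 + ["b"] * 28
        rep = permutation_test(X, labels, "a", n_perm=n_perm,
                               seed=derive_seed(seed, "permseed", r))
        p_vals[r] = rep.p_perm
    return p_vals


# --------------------------------------------------------------------------
# effect detection at study-like n
# --------------------------------------------------------------------------

def nt1_contrast(seed: int, duration_s: float = 600.0, n_perm: int = 200,
                 n_pca: int = 10, condition: str = "NREM",
                 feature_bin_hz: float = 3.0) -> tuple[float, float]:
    """One-vs-all detection of the NT1-like perturbation at study-like n.

    Simulates the default five-group cohort (39/16/16/17/11 subjects; the
    NT1 template halves the fast-sigma rate multiplier in the top SO-power
    quartile), runs detection and both coupling histograms on one channel in
    the NREM-only condition (the perturbed events are N2/N3-gated), fits PCA
    per histogram kind, and runs the permutation-tested one-vs-all
    classifier for the NT1 group on the concatenated power + phase scores.
    Classification features use 3-Hz frequency bins: at desk-scale
    durations, coarser bins trade frequency detail for per-cell counts.
    Returns (mean CV AUC, permutation p).
    """
    groups = default_groups()
    recs, _, labels = generate_cohort(groups, channels=("C3",),
                                      duration_s=duration_s, fs=FS,
                                      seed=derive_seed(seed, "cohort"))
    from .socoupling import default_freq_edges, phase_histogram as _ph

    edges = default_freq_edges(feature_bin_hz)
    hp, hh = [], []
    for rec in recs:
        sig = rec.channel("C3")
        cmask = condition_mask(rec, condition)
        so = compute_so_series(sig, rec.fs, cmask)
        pf = peaks_to_frame(detect_tfpeaks(sig, rec.fs, FAST_DETECTOR))
        ann, _ = annotate_peaks(pf, so)
        hp.append(power_histogram(ann, so, freq_edges=edges, channel="C3",
                                  condition=condition, subject=rec.subject))
        hh.append(phase_histogram(ann, freq_edges=edges, channel="C3",
                                  condition=condition, subject=rec.subject))
    sp = fit_pca(build_matrix(hp), n_pca).scores
    sh = fit_pca(build_matrix(hh), n_pca).scores
    rep = permutation_test(np.c_[sp, sh], labels, "NT1", n_perm=n_perm,
                           seed=derive_seed(seed, "perm"))
    return rep.mean_auc, rep.p_perm


# --------------------------------------------------------------------------
# split-half reliability
# --------------------------------------------------------------------------

def _motif_matrix(seed: int, n_sub: int = 40, n_cells: int = 84,
                  snr: float = 5.0) -> FeatureMatrix:
    """Score matrix with one strong shared loading motif plus noise."""
    rng = np.random.default_rng(seed)
    motif = rng.standard_normal(n_cells)
    motif /= np.linalg.norm(motif)
    w = rng.standard_normal(n_sub)[:, None]
    X = snr * w * motif[None, :] + rng.standard_normal((n_sub, n_cells))
    Z = (X - X.mean(0)) / X.std(0)
    return FeatureMatrix(Z, [str(i) for i in range(n_sub)], X.mean(0),
                         X.std(0), np.zeros(n_cells, bool))


def reliability_motif_rate(n_splits: int = 50, seed: int = 0,
                           snr: float = 5.0, threshold: float = 0.75) -> float:
    """Fraction of random split-halves whose top matched component clears the
    reliability threshold on a cohort with a strong shared motif."""
    fm = _motif_matrix(derive_seed(seed, "motif"), snr=snr)
    labels = ["a"] * 20 + ["b"] * 20
    full = fit_pca(fm, 5)
    hits = 0
    for s in range(n_splits):
        idx_a, idx_b = split_half(labels, derive_seed(seed, "split", s))
        ok = True
        for idx in (idx_a, idx_b):
            sub = replace(fm, data=fm.data[idx],
                          subjects=[fm.subjects[i] for i in idx])
            half = fit_pca(sub, 5)
            _, _, r = match_components(full.loadings[:1], half.loadings)
            ok = ok and (r[0] > threshold)
        hits += int(ok)
    return hits / n_splits


def reliability_noise_median(n_seeds: int = 50, seed: int = 0) -> float:
    """Median top-component split-half |r| over pure-noise cohorts."""
    rs = []
    for s in range(n_seeds):
        rng = np.random.default_rng(derive_seed(seed, "noise", s))
        X = rng.standard_normal((20, 84))
        Z = (X - X.mean(0)) / X.std(0)
        fm = FeatureMatrix(Z, [str(i) for i in range(20)], X.mean(0),
                           X.std(0), np.zeros(84, bool))
        labels = ["a"] * 10 + ["b"] * 10
        full = fit_pca(fm, 5)
        worst = 1.0
        for idx in split_half(labels, derive_seed(seed, "nsplit", s)):
            sub = replace(fm, data=fm.data[idx],
                          subjects=[fm.subjects[i] for i in idx])
            half = fit_pca(sub, 5)
            _, _, r = match_components(full.loadings[:1], half.loadings)
            worst = min(worst, r[0])
        rs.append(worst)
    return float(np.median(rs))
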