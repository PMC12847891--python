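"""End-to-end orchestration: simulate/load -> preprocess -> detect ->
histogram -> decompose -> stats -> reliability -> classification -> report.

Every stage draws its randomness from a seed derived deterministically from
the master seed and a stable key path, so two runs with the same
configuration and seed produce byte-identical tables. A provenance manifest
(config hash, seed, library versions, drop counters) accompanies every
results directory.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as spio
from .config import PipelineConfig, derive_seed, save_config
from .decompose import (ComponentSet, FeatureMatrix, build_matrix, fit_ica,
                        fit_ica_with_fallback, fit_pca, group_patterns,
                        orient_components)
from .evaluate import permutation_test, reliability
from .groupstats import run_group_stats
from .preprocess import (CONDITIONS, StagedRecording, bandpass, condition_mask,
                         reject_channels, rereference, resample)
from .socoupling import (annotate_peaks, base_so_series, compute_so_series,
                         default_freq_edges, phase_histogram, power_histogram,
                         rem_iqr_filter)
from .synthdata import default_groups, generate_cohort
from .tfpeaks import TFPeakConfig, detect_tfpeaks, peaks_to_frame

log = logging.getLogger("somnipeak")

__all__ = ["PipelineResult", "run_pipeline", "summarize"]


@dataclass
class PipelineResult:
    """In-memory view of one pipeline run."""

    out_dir: Path
    histograms: dict                 # (channel, condition, kind) -> {subject: hist}
    component_sets: dict             # (channel, condition, kind, method) -> ComponentSet
    feature_matrices: dict           # (channel, condition, kind) -> FeatureMatrix
    stats: dict                      # (channel, condition, kind, method) -> StatsFamily
    reliability: dict                # (channel, kind) -> ReliabilityReport
    classifiers: dict                # (channel, kind, target) -> ClassifierReport
    patterns: dict                   # kind -> PatternCatalogue
    group_labels: dict               # subject -> group
    dropped: dict                    # counters


def _preprocess_one(rec: StagedRecording, cfg: PipelineConfig,
                    dropped: dict) -> StagedRecording:
    rec = resample(rec, cfg.preprocess.target_fs)
    rec = bandpass(rec, cfg.preprocess.band_low_hz, cfg.preprocess.band_high_hz)
    rec = rereference(rec, cfg.preprocess.reference)
    if cfg.preprocess.reject and len(rec.channel_names) >= 2:
        rec, rejected = reject_channels(rec)
        if rejected:
            dropped.setdefault("channels", []).append((rec.subject, rejected))
    return rec


def _detector_config(cfg: PipelineConfig) -> TFPeakConfig:
    d = cfg.detector
    return TFPeakConfig(**{f: getattr(d, f) for f in TFPeakConfig.__dataclass_fields__})


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 input_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis.

    With ``input_dir`` None a cohort is simulated from the default group
    templates (scaled by ``cfg.simulate.scale_n``) and, if configured,
    round-tripped through EDF + hypnogram files under ``out_dir/cohort``.
    Otherwise every ``*.edf`` under ``input_dir`` is loaded with its
    hypnogram sidecar; group labels are read from ``groups.csv``
    (subject,group) in the same directory.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dropped: dict = {}

    if input_dir is None:
        groups = default_groups(cfg.simulate.scale_n)
        recs, gt, labels = generate_cohort(
            groups, channels=tuple(cfg.simulate.channels),
            duration_s=cfg.simulate.duration_s, fs=cfg.simulate.fs,
            seed=derive_seed(cfg.seed, "simulate"),
            background_slope=cfg.simulate.background_slope)
        if cfg.simulate.write_edf:
            cdir = out / "cohort"
            cdir.mkdir(exist_ok=True)
            spio.write_ground_truth(cdir / "ground_truth.tsv", gt.events)
            pd.DataFrame({"subject": [r.subject for r in recs],
                          "group": labels}).to_csv(cdir / "groups.csv", index=False)
            loaded = []
            for rec in recs:
                spio.write_edf(cdir / f"{rec.subject}.edf", rec)
                spio.write_hypnogram(cdir / f"{rec.subject}_hypnogram.csv",
                                     rec.stages)
                loaded.append(spio.read_edf(cdir / f"{rec.subject}.edf",
                                            subject=rec.subject))
            recs = loaded
    else:
        input_dir = Path(input_dir)
        if not input_dir.is_dir():
            raise FileNotFoundError(f"input directory not found: {input_dir}")
        gmap = pd.read_csv(input_dir / "groups.csv").set_index("subject")["group"]
        recs, labels = [], []
        for edf in sorted(input_dir.glob("*.edf")):
            rec = spio.read_edf(edf)
            recs.append(rec)
            labels.append(str(gmap.get(rec.subject, "unknown")))

    group_of = {r.subject: g for r, g in zip(recs, labels)}
    log.info("cohort: %d recordings", len(recs))

    # ---- preprocessing + detection + histograms -------------------------
    det_cfg = _detector_config(cfg)
    freq_edges = default_freq_edges(cfg.histogram.freq_step_hz)
    hists: dict = {}
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for rec in recs:
        rec = _preprocess_one(rec, cfg, dropped)
        frames = []
        for ch in rec.channel_names:
            sig = rec.channel(ch)
            peaks = detect_tfpeaks(sig, rec.fs, det_cfg, channel=ch)
            pf = peaks_to_frame(peaks)
            frames.append(pf)
            base = base_so_series(sig, rec.fs, cfg.histogram.power_window_s,
                                  cfg.histogram.power_step_s)
            for condition in CONDITIONS:
                cmask = condition_mask(rec, condition)
                min_needed = cfg.histogram.power_window_s * rec.fs
                if cmask.mask.sum() < min_needed:
                    dropped.setdefault("empty_condition", []).append(
                        (rec.subject, ch, condition))
                    continue
                so = compute_so_series(sig, rec.fs, cmask,
                                       cfg.histogram.power_window_s,
                                       cfg.histogram.power_step_s, base=base)
                ann, n_drop = annotate_peaks(pf, so)
                dropped["peaks_outside_mask"] = dropped.get(
                    "peaks_outside_mask", 0) + n_drop
                ann = rem_iqr_filter(ann, condition)
                ph = power_histogram(ann, so, freq_edges,
                                     cfg.histogram.n_power_bins, ch,
                                     condition, rec.subject)
                pph = phase_histogram(ann, freq_edges,
                                      cfg.histogram.n_phase_bins, ch,
                                      condition, rec.subject)
                hists.setdefault((ch, condition, "power"), {})[rec.subject] = ph
                hists.setdefault((ch, condition, "phase"), {})[rec.subject] = pph
        pd.concat(frames, ignore_index=True).to_csv(
            peaks_dir / f"{rec.subject}_peaks.tsv", sep="\t", index=False)
    log.info("detection + histograms done in %.1f s", time.time() - t0)

    # ---- decomposition --------------------------------------------------
    fms: dict = {}
    csets: dict = {}
    for key, by_subj in sorted(hists.items()):
        ch, condition, kind = key
        subjects = sorted(by_subj)
        if len(subjects) < 3:
            dropped.setdefault("skipped_sets", []).append(key)
            continue
        fm = build_matrix([by_subj[s] for s in subjects])
        if not np.any(fm.data):
            dropped.setdefault("degenerate_sets", []).append(key)
            continue
        fms[key] = fm
        sub_labels = [group_of[s] for s in subjects]
        pca = fit_pca(fm, cfg.decompose.n_pca)
        seed_ica = derive_seed(cfg.seed, "ica", *key)
        if kind == "power":
            ica = fit_ica(fm, min(cfg.decompose.n_ica_power,
                                  fm.data.shape[0] - 1), seed=seed_ica)
        else:
            ica = fit_ica_with_fallback(
                fm, tuple(cfg.decompose.ica_phase_candidates), seed=seed_ica)
        control = cfg.stats.control
        if control in sub_labels:
            pca = orient_components(pca, sub_labels, control)
            ica = orient_components(ica, sub_labels, control)
        csets[key + ("PCA",)] = pca
        csets[key + ("ICA",)] = ica

    # ---- statistics ------------------------------------------------------
    stats: dict = {}
    stats_rows = []
    for key, cs in sorted(csets.items()):
        ch, condition, kind, method = key
        sub_labels = [group_of[s] for s in cs.subjects]
        if cfg.stats.control not in sub_labels:
            continue
        fam = run_group_stats(cs.scores, sub_labels, cfg.stats.control,
                              cfg.stats.alpha_fdr, cfg.stats.alpha_pairwise,
                              cfg.stats.posthoc_gate)
        stats[key] = fam
        t = fam.table.copy()
        t.insert(0, "method", method)
        t.insert(0, "kind", kind)
        t.insert(0, "condition", condition)
        t.insert(0, "channel", ch)
        stats_rows.append(t)
    if stats_rows:
        pd.concat(stats_rows, ignore_index=True).to_csv(
            out / "stats.tsv", sep="\t", index=False,
            float_format="%.10g")

    # ---- pattern catalogues ---------------------------------------------
    patterns: dict = {}
    for kind, prefix in (("power", "Pow"), ("phase", "Pha")):
        sets = [cs for key, cs in sorted(csets.items())
                if key[2] == kind and key[3] == "PCA"]
        if len(sets) >= 2:
            patterns[kind] = group_patterns(sets, cfg.decompose.pattern_threshold,
                                            prefix)

    # ---- reliability (NREM+REM, per channel and kind) --------------------
    rel: dict = {}
    for key, fm in sorted(fms.items()):
        ch, condition, kind = key
        if condition != "NREM+REM" or fm.data.shape[0] < 6:
            continue
        sub_labels = [group_of[s] for s in fm.subjects]
        rel[(ch, kind)] = reliability(fm, sub_labels,
                                      derive_seed(cfg.seed, "split", ch, kind),
                                      cfg.evaluate.n_top_reliability)

    # ---- classification (NREM+REM, PCA scores) ---------------------------
    clf: dict = {}
    clf_rows = []
    for key, cs in sorted(csets.items()):
        ch, condition, kind, method = key
        if condition != "NREM+REM" or method != "PCA":
            continue
        sub_labels = [group_of[s] for s in cs.subjects]
        targets = [g for g in dict.fromkeys(sub_labels) if g != cfg.stats.control]
        for tg in targets:
            if sub_labels.count(tg) < cfg.evaluate.n_folds:
                continue
            rep = permutation_test(
                cs.scores, sub_labels, tg, cfg.evaluate.n_perm,
                cfg.evaluate.n_folds,
                derive_seed(cfg.seed, "clf", ch, kind, tg),
                cfg.evaluate.ridge_c, cfg.evaluate.smoothed_p)
            clf[(ch, kind, tg)] = rep
            clf_rows.append({"channel": ch, "kind": kind, "target": tg,
                             "mean_auc": rep.mean_auc, "p_perm": rep.p_perm,
                             "n_perm": rep.n_perm})
    if clf_rows:
        pd.DataFrame(clf_rows).to_csv(out / "classification.tsv", sep="\t",
                                      index=False, float_format="%.10g")

    # ---- manifest + summary ----------------------------------------------
    import sklearn
    import scipy
    manifest = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__, "pandas": pd.__version__},
        "dropped": {k: (v if isinstance(v, int) else len(v))
                    for k, v in dropped.items()},
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    save_config(cfg, out / "config.yaml")

    rel_rows = [{"channel": ch, "kind": kind,
                 "r_top": float(min(r.r_half_a[0], r.r_half_b[0]))
                 if len(r.r_half_a) else np.nan,
                 "labels": ",".join(r.labels)}
                for (ch, kind), r in sorted(rel.items())]
    if rel_rows:
        pd.DataFrame(rel_rows).to_csv(out / "reliability.tsv", sep="\t",
                                      index=False, float_format="%.10g")

    result = PipelineResult(out, hists, csets, fms, stats, rel, clf, patterns,
                            group_of, dropped)
    (out / "summary.txt").write_text(summarize(out))
    return result


def summarize(results_dir: str | Path) -> str:
    """Human-readable digest of a completed (or partial) run."""
    out = Path(results_dir)
    lines = [f"somnipeak results: {out}"]
    stats_p = out / "stats.tsv"
    if stats_p.exists():
        df = pd.read_csv(stats_p, sep="\t")
        grp = (df.groupby(["channel", "condition", "kind", "method"])
               ["fdr_rejected"].agg(["sum", "count"]))
        lines.append("\nFDR-surviving components (per channel/condition/kind/method):")
        for idx, row in grp.iterrows():
            lines.append(f"  {'/'.join(map(str, idx))}: "
                         f"{int(row['sum'])}/{int(row['count'])}")
    else:
        lines.append("  [no stats table found]")
    clf_p = out / "classification.tsv"
    if clf_p.exists():
        df = pd.read_csv(clf_p, sep="\t")
        lines.append("\nOne-vs-all classification (NREM+REM PCA scores):")
        for _, r in df.iterrows():
            lines.append(f"  {r['channel']}/{r['kind']} vs {r['target']}: "
                         f"AUC={r['mean_auc']:.3f} p={r['p_perm']:.4g}")
    rel_p = out / "reliability.tsv"
    if rel_p.exists():
        df = pd.read_csv(rel_p, sep="\t")
        lines.append("\nSplit-half reliability (top component |Spearman r|):")
        for _, r in df.iterrows():
            lines.append(f"  {r['channel']}/{r['kind']}: r={r['r_top']:.3f}")
    man_p = out / "manifest.json"
    if man_p.exists():
        man = json.loads(man_p.read_text())
        lines.append(f"\nconfig {man['config_hash']} seed {man['seed']} "
                     f"runtime {man.get('runtime_s', '?')} s")
    else:
        warnings.warn("incomplete run: no manifest found")
    return "\n".join(lines) + "\n"
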