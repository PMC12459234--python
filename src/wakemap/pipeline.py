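"""End-to-end orchestration: simulate → preprocess → spectral → source →
latency → slow waves → stats → report.

Each stage reads its upstream artifacts from the run directory and
writes its own, plus a manifest echoing every decision knob (config,
seed, versions) so a run can be repeated exactly.  Stages raise
:class:`DependencyError` when an upstream artifact is missing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BAND_NAMES
from .fixtures import fixture
from .forward import make_leadfield
from .inverse import build_inverse, source_band_power
from .io import load_cohort, save_cohort
from .latency import CONTROL_WINDOW, DEFAULT_WINDOW, cohort_latency_map
from .preprocessing import preprocess, screen_emg
from .slow_waves import aggregate_cohort, detect_sw_trial
from .spectral import band_power, channel_mean, detect_band_peak, normalize_wake
from .stats import cluster_permutation, stage_contrasts


class DependencyError(RuntimeError):
    """An upstream stage has not produced its artifacts yet."""


@dataclass
class RunConfig:
    fixture: str = "nrem_spontaneous_74"
    n_sources: int = 300
    background_window: tuple = (-45.0, -30.0)
    search_window: tuple = (-15.0, 15.0)
    latency_window: tuple = DEFAULT_WINDOW
    control_window: tuple = CONTROL_WINDOW
    peak_k: float = 2.0
    large_p2p_uv: float = 75.0
    alpha: float = 0.05
    n_perm: int = 1000
    latency_band: str = "beta"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg


def _write_manifest(outdir: Path, stage: str, cfg: RunConfig, seed: int) -> None:
    payload = {"stage": stage, "seed": seed, "config": asdict(cfg),
               "version": __version__}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()).hexdigest()[:16]
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2))


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing artifact {path.name}: run '{stage}' first")
    return path


def run_simulate(cfg: RunConfig, seed: int, outdir: Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = fixture(cfg.fixture, seed=seed)
    save_cohort(cohort, outdir / "cohort")
    _write_manifest(outdir, "simulate", cfg, seed)
    return outdir / "cohort"


def _load(outdir: Path):
    return load_cohort(_need(Path(outdir) / "cohort", "simulate"))


def run_preprocess(cfg: RunConfig, seed: int, outdir: Path) -> Path:
    outdir = Path(outdir)
    cohort = _load(outdir)
    rows = []
    for tr in cohort.trials:
        sr = screen_emg(tr)
        rows.append({"subject_id": tr.subject_id, "trial_id": tr.trial_id,
                     "emg_envelope_max": sr.emg_envelope_max,
                     "baseline_mean": sr.baseline_mean,
                     "baseline_sd": sr.baseline_sd, "rejected": sr.rejected})
    pd.DataFrame(rows).to_csv(outdir / "screen_emg.tsv", sep="\t", index=False)
    _write_manifest(outdir, "preprocess", cfg, seed)
    return outdir / "screen_emg.tsv"


def run_spectral(cfg: RunConfig, seed: int, outdir: Path) -> Path:
    outdir = Path(outdir)
    cohort = _load(outdir)
    _need(outdir / "screen_emg.tsv", "preprocess")
    screens = pd.read_csv(outdir / "screen_emg.tsv", sep="\t")
    # the EMG screen excludes arousal trials only: arousals must be free of
    # muscle activation, whereas awakenings are aligned to movement onset
    drop = set(screens.loc[screens["rejected"], "trial_id"])
    tc_rows, peak_rows = [], []
    for tr in cohort.trials:
        if tr.condition == "arousal" and tr.trial_id in drop:
            continue
        bpt = band_power(preprocess(tr))
        bpt = normalize_wake(bpt, cohort.wake_refs[tr.subject_id])
        tc = channel_mean(bpt, layout=cohort.layout)
        for bi, band in enumerate(tc.band_names):
            for e, v in zip(tc.epoch_times, tc.values[bi]):
                tc_rows.append({"subject_id": tr.subject_id, "trial_id": tr.trial_id,
                                "band": band, "epoch_time": e, "power_ratio": v})
            ev = detect_band_peak(tc, band, cfg.background_window, cfg.peak_k,
                                  cfg.search_window)
            peak_rows.append({"subject_id": tr.subject_id, "trial_id": tr.trial_id,
                              "band": band, "detected": ev.detected,
                              "latency": ev.latency, "height": ev.height})
    pd.DataFrame(tc_rows).to_csv(outdir / "band_timecourses.tsv", sep="\t", index=False)
    pd.DataFrame(peak_rows).to_csv(outdir / "band_peaks.tsv", sep="\t", index=False)
    _write_manifest(outdir, "spectral", cfg, seed)
    return outdir / "band_peaks.tsv"


def run_source_latency(cfg: RunConfig, seed: int, outdir: Path) -> Path:
    outdir = Path(outdir)
    cohort = _load(outdir)
    lf = make_leadfield(cohort.layout, cfg.n_sources, seed=seed)
    inv = build_inverse(lf)
    by_subject: dict[str, list] = {}
    for tr in cohort.trials:
        stc = source_band_power(preprocess(tr), inv)
        by_subject.setdefault(tr.subject_id, []).append(stc)
    gmap = cohort_latency_map(by_subject, cfg.latency_band, cfg.latency_window)
    ctrl = cohort_latency_map(by_subject, cfg.latency_band, cfg.control_window)
    df = pd.DataFrame({"unit_id": gmap.unit_id,
                       "rank_norm": gmap.rank_norm,
                       "rank_norm_control": ctrl.rank_norm,
                       "ap_coord": lf.source_ap_coord})
    df.to_csv(outdir / "latency_map.tsv", sep="\t", index=False)
    meta = {"band": cfg.latency_band, "window": list(cfg.latency_window),
            "control_window": list(cfg.control_window), "level": "group"}
    (outdir / "latency_map.json").write_text(json.dumps(meta))
    _write_manifest(outdir, "latency", cfg, seed)
    return outdir / "latency_map.tsv"


def run_slowwaves(cfg: RunConfig, seed: int, outdir: Path) -> Path:
    outdir = Path(outdir)
    cohort = _load(outdir)
    ev_rows = []
    for tr in cohort.trials:
        for e in detect_sw_trial(tr):
            ev_rows.append({"subject_id": tr.subject_id, "trial_id": tr.trial_id,
                            **{k: getattr(e, k) for k in
                               ("channel", "zc1", "neg_peak_time", "zc2", "duration",
                                "neg_amp", "p2p_amp", "slope1", "slope2",
                                "n_neg_peaks", "is_large")}})
    pd.DataFrame(ev_rows).to_csv(outdir / "slow_waves.tsv", sep="\t", index=False)
    stats_df = aggregate_cohort(cohort)
    stats_df.to_csv(outdir / "sw_window_stats.tsv", sep="\t", index=False)
    _write_manifest(outdir, "slowwaves", cfg, seed)
    return outdir / "slow_waves.tsv"


def run_stats(cfg: RunConfig, seed: int, outdir: Path) -> Path:
    outdir = Path(outdir)
    cohort = _load(outdir)
    _need(outdir / "band_timecourses.tsv", "spectral")
    rated = [tr for tr in cohort.trials if tr.sleepiness is not None]
    out: dict = {}
    if len(rated) >= 10:
        from .spectral import epoch_band_power

        inner = np.flatnonzero(cohort.layout.innermost)
        b_i = BAND_NAMES.index("beta")
        y = np.array([tr.sleepiness for tr in rated], dtype=float)
        subj = np.array([tr.subject_id for tr in rated])
        tod = np.array([tr.time_of_night for tr in rated])
        # per-channel pre-onset beta power as units
        feats = []
        for tr in rated:
            pw = epoch_band_power(np.asarray(tr.data[inner], dtype=np.float64), tr.fs)
            feats.append(pw[:, b_i, 30:60].mean(axis=1))
        x = np.array(feats)
        adj = cohort.layout.adjacency[np.ix_(inner, inner)]
        res = cluster_permutation(y, x, subj, adj, time_of_night=tod,
                                  n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seed)
        out["pre_beta_clusters"] = {
            "n_clusters": len(res.clusters),
            "n_significant": int(sum(s for _, _, s in res.clusters)),
            "threshold": res.threshold,
        }
        sc = stage_contrasts(y, np.array([tr.stage for tr in rated]), subj,
                             time_of_night=tod)
        out["stage_effect"] = {"chi2": sc.chi2, "df": sc.df, "p": sc.p,
                               "stage_means": sc.stage_means}
    (outdir / "stats.json").write_text(json.dumps(out, indent=2))
    _write_manifest(outdir, "stats", cfg, seed)
    return outdir / "stats.json"


def run_report(cfg: RunConfig, seed: int, outdir: Path) -> dict:
    outdir = Path(outdir)
    peaks = pd.read_csv(_need(outdir / "band_peaks.tsv", "spectral"), sep="\t")
    det = peaks[peaks["detected"]]
    summary = {"fixture": cfg.fixture,
               "n_trials": int(peaks["trial_id"].nunique()),
               "median_peak_latency": {
                   band: float(det.loc[det["band"] == band, "latency"].median())
                   for band in BAND_NAMES
                   if (det["band"] == band).any()},
               "detection_rate": {
                   band: float(peaks.loc[peaks["band"] == band, "detected"].mean())
                   for band in BAND_NAMES}}
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
    return summary


STAGES = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "spectral": run_spectral,
    "source": run_source_latency,
    "latency": run_source_latency,
    "slowwaves": run_slowwaves,
    "stats": run_stats,
    "report": run_report,
}

ALL_ORDER = ("simulate", "preprocess", "spectral", "source", "slowwaves",
             "stats", "report")
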