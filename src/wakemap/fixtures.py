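"""Named, reproducible synthetic cohorts.

The registry pins the composition of the study-condition cohorts used
throughout the test suite:

``nrem_spontaneous_74``
    74 NREM spontaneous-awakening trials (55 N2, 19 N3) across 19
    subjects.  69 trials carry both a delta and a beta transient; 63 of
    those have the delta transient earlier (delta -1 s, beta +6 s) and
    6 have it later (delta +8 s, beta +6 s); 3 trials carry beta only
    and 2 delta only.  Alpha transients at 0 s in every trial.

``rem_spontaneous_37``
    37 REM trials across 17 subjects with a beta transient at +8 s and
    no delta or alpha transient.

``gradient_anterior_lead``
    NREM cohort whose beta transient latency follows an anterior-leading
    gradient (latent +6 s anterior, slope 4 s across the AP axis).

``sw_inserted``
    Light-N2 cohort with large canonical biphasic slow waves inserted
    at known channels and times, for detector recall/precision checks.

``sleepiness_cohort`` / ``null_sleepiness_cohort``
    Provoked-awakening cohorts with (respectively without) the
    sleepiness rating model's EEG-feature effects and stage ordering.
"""

from __future__ import annotations

import numpy as np

from .layout import make_layout
from .simulate import (Cohort, CohortConfig, RatingModel, TrialConfig,
                       make_wake_reference, simulate_cohort, simulate_trial)

_NREM_LAT_EARLY = {"delta": -1.0, "alpha": 0.0, "beta": 6.0}
_NREM_LAT_LATE = {"delta": 8.0, "alpha": 0.0, "beta": 6.0}     # delta after beta
_NREM_LAT_BETA_ONLY = {"alpha": 0.0, "beta": 6.0}
_NREM_LAT_DELTA_ONLY = {"delta": -1.0, "alpha": 0.0}

# the delta-only trials must, by construction, show no beta peak; their
# low-frequency bursts are kept moderate because the epoch-boundary
# truncation of a very large burst leaks sinc tails into the beta bins
# of the rectangular-window FFT (still >5 SD above background for their
# own bands)
_DELTA_ONLY_AMPS = {"delta": 22.0, "theta": 20.0, "alpha": 20.0,
                    "sigma": 20.0, "beta": 15.0}


def _nrem_spontaneous_74(seed: int) -> Cohort:
    layout = make_layout(64, seed=101)
    rng = np.random.default_rng(seed)
    # per-trial transient composition: 63 delta-early, 6 delta-late,
    # 3 beta-only, 2 delta-only = 74 trials
    lat_seq = ([_NREM_LAT_EARLY] * 63 + [_NREM_LAT_LATE] * 6
               + [_NREM_LAT_BETA_ONLY] * 3 + [_NREM_LAT_DELTA_ONLY] * 2)
    order = np.random.default_rng(2024).permutation(len(lat_seq))
    lat_seq = [lat_seq[i] for i in order]
    stages = ["N2"] * 55 + ["N3"] * 19
    stages = [stages[i] for i in order]

    trials = []
    wake_refs = {}
    # 19 subjects; 74 = 17 * 4 + 2 * 3 trials
    per_subject = [4] * 17 + [3] * 2
    k = 0
    for s, n_tr in enumerate(per_subject):
        sid = f"S{s + 1:02d}"
        wake_refs[sid] = make_wake_reference(layout, sid, seed=int(rng.integers(2**31)))
        for j in range(n_tr):
            missing_beta = "beta" not in lat_seq[k]
            tc = TrialConfig(stage=stages[k], condition="spontaneous_awakening",
                             transient_latency=dict(lat_seq[k]),
                             wake_beta_rms=0.0 if missing_beta else 3.0)
            if missing_beta:
                tc.transient_amp = dict(_DELTA_ONLY_AMPS)
            trials.append(simulate_trial(
                layout, tc, seed=int(rng.integers(2**31)), subject_id=sid,
                trial_id=f"{sid}_T{j + 1}", time_of_night=float(rng.uniform(0.5, 7.5))))
            k += 1
    return Cohort(name="nrem_spontaneous_74", layout=layout,
                  trials=trials, wake_refs=wake_refs)


def _rem_spontaneous_37(seed: int) -> Cohort:
    layout = make_layout(64, seed=101)
    rng = np.random.default_rng(seed)
    trials = []
    wake_refs = {}
    per_subject = [3] * 3 + [2] * 14        # 37 trials over 17 subjects
    for s, n_tr in enumerate(per_subject):
        sid = f"S{s + 1:02d}"
        wake_refs[sid] = make_wake_reference(layout, sid, seed=int(rng.integers(2**31)))
        for j in range(n_tr):
            tc = TrialConfig(stage="REM", condition="spontaneous_awakening",
                             transient_latency={"beta": 8.0})
            trials.append(simulate_trial(
                layout, tc, seed=int(rng.integers(2**31)), subject_id=sid,
                trial_id=f"{sid}_T{j + 1}", time_of_night=float(rng.uniform(3.0, 7.5))))
    return Cohort(name="rem_spontaneous_37", layout=layout,
                  trials=trials, wake_refs=wake_refs)


def _gradient_anterior_lead(seed: int) -> Cohort:
    layout = make_layout(64, seed=101)
    cfg = CohortConfig(
        n_subjects=12,
        trials_per_subject={"N2": 2},
        condition="spontaneous_awakening",
        trial_cfg=TrialConfig(
            transient_latency={"delta": -1.0, "alpha": 0.0, "beta": 6.0},
            ap_gradient_slope=4.0),
        name="gradient_anterior_lead")
    return simulate_cohort(layout, cfg, seed)


def _sw_inserted(seed: int) -> Cohort:
    layout = make_layout(64, seed=101)
    rng = np.random.default_rng(seed)
    inner = np.flatnonzero(layout.innermost)
    trials = []
    wake_refs = {}
    for s in range(8):
        sid = f"S{s + 1:02d}"
        wake_refs[sid] = make_wake_reference(layout, sid, seed=int(rng.integers(2**31)))
        for j in range(2):
            chans = rng.choice(inner, size=8, replace=False)
            times = np.sort(rng.uniform(-50.0, 50.0, size=8))
            while np.any(np.diff(times) < 3.0):       # keep waves well separated
                times = np.sort(rng.uniform(-50.0, 50.0, size=8))
            # canonical type-I-like waves: large AND steep
            waves = [(layout.channel_id[c], float(t0),
                      float(rng.uniform(100.0, 140.0)), float(rng.uniform(0.45, 0.65)))
                     for c, t0 in zip(chans, times)]
            tc = TrialConfig(stage="N2", delta_osc_amp=5.0, pink_rms=6.0,
                             wake_pink_rms=6.0,
                             transient_latency={"alpha": 0.0, "beta": 6.0},
                             inserted_waves=waves)
            trials.append(simulate_trial(
                layout, tc, seed=int(rng.integers(2**31)), subject_id=sid,
                trial_id=f"{sid}_T{j + 1}", time_of_night=float(rng.uniform(0.5, 7.5))))
    return Cohort(name="sw_inserted", layout=layout, trials=trials, wake_refs=wake_refs)


def _sleepiness_cohort(seed: int, null: bool = False) -> Cohort:
    layout = make_layout(24, seed=101)
    model = RatingModel() if not null else RatingModel(
        intercepts={"N2": 2.5, "N3": 2.5, "REM": 2.5}, b_beta=0.0, b_delta=0.0)
    cfg = CohortConfig(
        n_subjects=15 if not null else 10,
        trials_per_subject={"N2": 2, "N3": 2, "REM": 2},
        condition="provoked_awakening",
        # vary the pre-t0 background level across trials so the rating
        # model's EEG features have physical (not just sampling) spread
        trial_cfg_sequence=[
            TrialConfig(transient_latency={"delta": -1.0, "alpha": 0.0, "beta": 6.0},
                        pink_rms=p, delta_osc_amp=a_d)
            for (p, a_d) in [(8.0, 10.0), (10.0, 15.0), (12.0, 22.0),
                             (9.0, 28.0), (13.0, 18.0)]
        ],
        rating_model=model,
        name="null_sleepiness_cohort" if null else "sleepiness_cohort")
    return simulate_cohort(layout, cfg, seed)


def _tiny_demo(seed: int) -> Cohort:
    """Two-subject miniature cohort for pipeline smoke runs."""
    layout = make_layout(24, seed=101)
    cfg = CohortConfig(
        n_subjects=2, trials_per_subject={"N2": 1},
        condition="spontaneous_awakening",
        trial_cfg=TrialConfig(
            transient_latency={"delta": -1.0, "alpha": 0.0, "beta": 6.0}),
        name="tiny_demo")
    return simulate_cohort(layout, cfg, seed)


_REGISTRY = {
    "tiny_demo": _tiny_demo,
    "nrem_spontaneous_74": _nrem_spontaneous_74,
    "rem_spontaneous_37": _rem_spontaneous_37,
    "gradient_anterior_lead": _gradient_anterior_lead,
    "sw_inserted": _sw_inserted,
    "sleepiness_cohort": lambda seed: _sleepiness_cohort(seed, null=False),
    "null_sleepiness_cohort": lambda seed: _sleepiness_cohort(seed, null=True),
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def fixture(name: str, seed: int = 0) -> Cohort:
    """Build a registered cohort. Unknown names raise ``KeyError``."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}") from None
    return builder(seed)
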