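"""Peak-latency maps: extraction, rank normalization, group medians,
and the two randomization controls.

For each unit (source voxel or channel) the latency is the epoch-center
time of the maximum band power inside the analysis window (default
-10 to +45 s around the alignment event; first occurrence on ties).
Per map, units are ranked by latency (average ranks on ties) and the
ranks mapped affinely onto a 1-10 scale: 1 = earliest, 10 = latest.
Per-trial maps are averaged within subject; the group map is the
per-unit median of subject maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

DEFAULT_WINDOW = (-10.0, 45.0)
CONTROL_WINDOW = (-45.0, -30.0)


@dataclass
class LatencyMap:
    unit_id: list[str]
    latency: np.ndarray | None     # s per unit; None for group maps
    rank_norm: np.ndarray          # in [1, 10] per unit
    level: str                     # subject | group
    window: tuple[float, float]
    band: str = ""


def peak_latency(power: np.ndarray, epoch_times: np.ndarray,
                 window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Per-unit latency of maximum power. ``power`` is units x epochs."""
    if window[1] <= window[0]:
        raise ValueError("empty latency window")
    sel = (epoch_times >= window[0]) & (epoch_times < window[1])
    if not np.any(sel):
        raise ValueError("latency window outside the trial")
    seg = power[:, sel]
    return epoch_times[sel][np.argmax(seg, axis=1)]


def rank_normalize(latencies: np.ndarray) -> np.ndarray:
    """Average-rank latencies, mapped to 1 + 9 (rank - 1) / (V - 1).

    Ties share their mean rank; an all-tied input maps every unit to
    the scale midpoint 5.5.  Invariant under strictly monotone
    transforms of the latencies.
    """
    v = latencies.size
    if v < 2:
        raise ValueError("need at least 2 units to rank")
    ranks = ss.rankdata(latencies, method="average")
    if np.all(latencies == latencies[0]):
        return np.full(v, 5.5)
    return 1.0 + 9.0 * (ranks - 1.0) / (v - 1.0)


def trial_latency_map(stc, band: str,
                      window: tuple[float, float] = DEFAULT_WINDOW,
                      unit_ids: list[str] | None = None) -> LatencyMap:
    """Rank-normalized latency map of one trial's SourceTimecourse (or
    any object with ``power`` units x bands x epochs and ``epoch_times``)."""
    bi = stc.band_names.index(band)
    lat = peak_latency(stc.power[:, bi, :], stc.epoch_times, window)
    ids = unit_ids or [f"v{i}" for i in range(lat.size)]
    return LatencyMap(unit_id=ids, latency=lat, rank_norm=rank_normalize(lat),
                      level="subject", window=window, band=band)


def subject_mean_map(maps: list[LatencyMap]) -> LatencyMap:
    """Within-subject mean of per-trial rank maps."""
    _check_units(maps)
    rn = np.mean([m.rank_norm for m in maps], axis=0)
    m0 = maps[0]
    return LatencyMap(unit_id=m0.unit_id, latency=None, rank_norm=rn,
                      level="subject", window=m0.window, band=m0.band)


def group_median_map(subject_maps: list[LatencyMap]) -> LatencyMap:
    """Per-unit median of subject rank maps."""
    _check_units(subject_maps)
    rn = np.median([m.rank_norm for m in subject_maps], axis=0)
    m0 = subject_maps[0]
    return LatencyMap(unit_id=m0.unit_id, latency=None, rank_norm=rn,
                      level="group", window=m0.window, band=m0.band)


def _check_units(maps) -> None:
    if not maps:
        raise ValueError("no maps given")
    ids = maps[0].unit_id
    for m in maps[1:]:
        if m.unit_id != ids:
            raise ValueError("latency maps cover different unit sets")


def cohort_latency_map(stcs_by_subject: dict, band: str,
                       window: tuple[float, float] = DEFAULT_WINDOW) -> LatencyMap:
    """Group median map from per-subject lists of source time courses."""
    subj_maps = []
    for sid in sorted(stcs_by_subject):
        trial_maps = [trial_latency_map(stc, band, window)
                      for stc in stcs_by_subject[sid]]
        subj_maps.append(subject_mean_map(trial_maps))
    return group_median_map(subj_maps)


def random_window_map(stcs_by_subject: dict, band: str,
                      window: tuple[float, float] = CONTROL_WINDOW) -> LatencyMap:
    """Negative control: the same machinery on a pre-awakening sleep window."""
    if not stcs_by_subject:
        raise ValueError("empty trial collection")
    return cohort_latency_map(stcs_by_subject, band, window)


def random_reference_map(n_maps: int = 19, n_units: int = 300,
                         seed: int = 0) -> LatencyMap:
    """Median of ``n_maps`` rank maps of i.i.d. uniform latencies —
    the visual baseline simulating the median of N subjects' maps if
    peak latencies were completely random."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    maps = np.stack([rank_normalize(rng.uniform(0, 1, n_units))
                     for _ in range(n_maps)])
    return LatencyMap(unit_id=[f"v{i}" for i in range(n_units)], latency=None,
                      rank_norm=np.median(maps, axis=0), level="group",
                      window=(0.0, 0.0), band="random")
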