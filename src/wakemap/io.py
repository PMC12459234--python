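"""Cohort serialization: one HDF5 container per subject (signals,
ground truth, metadata), a TSV event table, and a JSON layout file."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .layout import ChannelLayout
from .simulate import Cohort, Trial, TrialGroundTruth, WakeReference


def save_layout(layout: ChannelLayout, path: Path) -> None:
    obj = {
        "channel_id": layout.channel_id,
        "position": layout.position.tolist(),
        "ap_coord": layout.ap_coord.tolist(),
        "adjacency": [list(map(int, row)) for row in
                      np.argwhere(np.triu(layout.adjacency))],
        "innermost": layout.innermost.astype(int).tolist(),
        "mastoid_ids": layout.mastoid_ids,
        "emg_ids": layout.emg_ids,
    }
    Path(path).write_text(json.dumps(obj))


def load_layout(path: Path) -> ChannelLayout:
    obj = json.loads(Path(path).read_text())
    n_scalp = len(obj["ap_coord"])
    adj = np.zeros((n_scalp, n_scalp), dtype=bool)
    for a, b in obj["adjacency"]:
        adj[a, b] = adj[b, a] = True
    return ChannelLayout(
        channel_id=obj["channel_id"],
        position=np.asarray(obj["position"]),
        ap_coord=np.asarray(obj["ap_coord"]),
        adjacency=adj,
        innermost=np.asarray(obj["innermost"], dtype=bool),
        mastoid_ids=obj["mastoid_ids"],
        emg_ids=obj["emg_ids"],
    )


def save_cohort(cohort: Cohort, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_layout(cohort.layout, outdir / "layout.json")

    rows = []
    by_subject: dict[str, list[Trial]] = {}
    for tr in cohort.trials:
        by_subject.setdefault(tr.subject_id, []).append(tr)
        rows.append({"subject_id": tr.subject_id, "trial_id": tr.trial_id,
                     "condition": tr.condition, "stage": tr.stage,
                     "time_of_night": tr.time_of_night,
                     "sleepiness": tr.sleepiness if tr.sleepiness is not None else ""})
    pd.DataFrame(rows).to_csv(outdir / "events.tsv", sep="\t", index=False)

    for sid, trials in by_subject.items():
        with h5py.File(outdir / f"{sid}.h5", "w") as f:
            f.attrs["subject_id"] = sid
            f.attrs["cohort"] = cohort.name
            wr = cohort.wake_refs.get(sid)
            if wr is not None:
                f.create_dataset("wake_band_power", data=wr.band_power)
            for tr in trials:
                g = f.create_group(f"trials/{tr.trial_id}")
                g.create_dataset("data", data=tr.data, compression="gzip",
                                 compression_opts=1)
                g.attrs.update({"fs": tr.fs, "t0_index": tr.t0_index,
                                "condition": tr.condition, "stage": tr.stage,
                                "time_of_night": tr.time_of_night})
                if tr.sleepiness is not None:
                    g.attrs["sleepiness"] = tr.sleepiness
                if tr.truth is not None:
                    tg = g.create_group("truth")
                    tg.attrs["ap_gradient_slope"] = tr.truth.ap_gradient_slope
                    tg.attrs["has_delta_peak"] = tr.truth.has_delta_peak
                    tg.attrs["has_beta_peak"] = tr.truth.has_beta_peak
                    tg.attrs["delta_before_beta"] = tr.truth.delta_before_beta
                    tg.attrs["emg_activation"] = tr.truth.emg_activation
                    tg.attrs["latent_peak_latency"] = json.dumps(
                        tr.truth.latent_peak_latency)
                    tg.attrs["inserted_waves"] = json.dumps(tr.truth.inserted_waves)


def load_cohort(indir: Path, name: str = "") -> Cohort:
    indir = Path(indir)
    layout = load_layout(indir / "layout.json")
    trials: list[Trial] = []
    wake_refs: dict[str, WakeReference] = {}
    for h5path in sorted(indir.glob("*.h5")):
        with h5py.File(h5path, "r") as f:
            sid = f.attrs["subject_id"]
            name = name or str(f.attrs.get("cohort", ""))
            if "wake_band_power" in f:
                wake_refs[sid] = WakeReference(
                    subject_id=sid, band_power=f["wake_band_power"][()])
            for tid in f["trials"]:
                g = f[f"trials/{tid}"]
                truth = None
                if "truth" in g:
                    tg = g["truth"]
                    truth = TrialGroundTruth(
                        latent_peak_latency=json.loads(tg.attrs["latent_peak_latency"]),
                        ap_gradient_slope=float(tg.attrs["ap_gradient_slope"]),
                        inserted_waves=[tuple(w) for w in
                                        json.loads(tg.attrs["inserted_waves"])],
                        has_delta_peak=bool(tg.attrs["has_delta_peak"]),
                        has_beta_peak=bool(tg.attrs["has_beta_peak"]),
                        delta_before_beta=bool(tg.attrs["delta_before_beta"]),
                        emg_activation=bool(tg.attrs["emg_activation"]))
                trials.append(Trial(
                    data=g["data"][()], fs=int(g.attrs["fs"]),
                    t0_index=int(g.attrs["t0_index"]),
                    condition=str(g.attrs["condition"]), stage=str(g.attrs["stage"]),
                    subject_id=sid, trial_id=tid,
                    time_of_night=float(g.attrs["time_of_night"]), layout=layout,
                    sleepiness=(int(g.attrs["sleepiness"])
                                if "sleepiness" in g.attrs else None),
                    truth=truth))
    return Cohort(name=name, layout=layout, trials=trials, wake_refs=wake_refs)
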