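"""File formats: HDF5 for tensors, JSON/CSV for results and tables."""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .preprocess import TrialTensor
from .synthdata import GroundTruthNetwork, RawRecording

__all__ = [
    "dump_json",
    "load_json",
    "read_networks_json",
    "read_raw_hdf5",
    "read_tensors_hdf5",
    "write_networks_json",
    "write_raw_csv",
    "write_raw_hdf5",
    "write_tensors_hdf5",
]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def write_raw_hdf5(raw: RawRecording, path) -> None:
    """One dataset per subject x odor, with protocol attributes at the root."""
    with h5py.File(path, "w") as fh:
        fh.attrs["sampling_rate"] = raw.sampling_rate
        fh.attrs["stimulus_onset"] = raw.stimulus_onset
        fh.attrs["stimulus_offset"] = raw.stimulus_offset
        fh.attrs["glomerulus_ids"] = list(raw.glomerulus_ids)
        fh.attrs["odor_names"] = list(raw.odor_names)
        fh.create_dataset("mask", data=raw.mask)
        if raw.subject_latencies is not None:
            fh.create_dataset("subject_latencies", data=raw.subject_latencies)
        if raw.responsive is not None:
            fh.attrs["responsive"] = json.dumps(raw.responsive)
        S, O = raw.fluorescence.shape[:2]
        for s in range(S):
            for o in range(O):
                ds = fh.create_dataset(
                    f"fluorescence/subject{s:02d}/{raw.odor_names[o]}",
                    data=raw.fluorescence[s, o])
                ds.attrs["subject"] = s
                ds.attrs["odor"] = raw.odor_names[o]


def read_raw_hdf5(path) -> RawRecording:
    with h5py.File(path, "r") as fh:
        odor_names = tuple(str(x) for x in fh.attrs["odor_names"])
        glom_ids = tuple(str(x) for x in fh.attrs["glomerulus_ids"])
        mask = fh["mask"][()].astype(bool)
        subjects = sorted(fh["fluorescence"].keys())
        F = np.stack([
            np.stack([fh[f"fluorescence/{sub}/{od}"][()] for od in odor_names])
            for sub in subjects])
        latencies = fh["subject_latencies"][()] \
            if "subject_latencies" in fh else None
        responsive = json.loads(fh.attrs["responsive"]) \
            if "responsive" in fh.attrs else None
        return RawRecording(
            fluorescence=F, mask=mask,
            sampling_rate=float(fh.attrs["sampling_rate"]),
            stimulus_onset=float(fh.attrs["stimulus_onset"]),
            stimulus_offset=float(fh.attrs["stimulus_offset"]),
            glomerulus_ids=glom_ids, odor_names=odor_names,
            responsive=responsive, subject_latencies=latencies)


def write_raw_csv(raw: RawRecording, path) -> None:
    """Long-format export: subject, odor, trial, glomerulus, time_s, F."""
    S, O, R, M, T = raw.fluorescence.shape
    t = np.arange(T) / raw.sampling_rate
    frames = []
    for s in range(S):
        for o in range(O):
            for m in range(M):
                if not raw.mask[s, m]:
                    continue
                for r in range(R):
                    frames.append(pd.DataFrame({
                        "subject": s, "odor": raw.odor_names[o], "trial": r,
                        "glomerulus": raw.glomerulus_ids[m], "time_s": t,
                        "F": raw.fluorescence[s, o, r, m]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_networks_json(networks, labels, path) -> None:
    """Ground truth to JSON: adjacency as [source, target, weight] lists."""
    labels = list(labels)

    def net_dict(net: GroundTruthNetwork):
        m = net.n_nodes
        return [[labels[i], labels[j], float(net.weights[i, j])]
                for i in range(m) for j in range(m) if net.adjacency[i, j]]

    if isinstance(networks, Mapping) and "background" in networks:
        payload = {"labels": labels,
                   "background": net_dict(networks["background"]),
                   "odor_specific": {str(k): net_dict(v) for k, v in
                                     networks["odor_specific"].items()}}
    elif isinstance(networks, Mapping):
        payload = {"labels": labels,
                   "per_odor": {str(k): net_dict(v)
                                for k, v in networks.items()}}
    else:
        payload = {"labels": labels, "links": net_dict(networks)}
    dump_json(payload, path)


def read_networks_json(path):
    payload = load_json(path)
    labels = payload["labels"]
    idx = {lab: k for k, lab in enumerate(labels)}
    m = len(labels)

    def from_links(links):
        adj = np.zeros((m, m), dtype=bool)
        w = np.zeros((m, m))
        for src, dst, weight in links:
            adj[idx[src], idx[dst]] = True
            w[idx[src], idx[dst]] = weight
        return GroundTruthNetwork(adjacency=adj, weights=w)

    if "background" in payload:
        return {"background": from_links(payload["background"]),
                "odor_specific": {int(k): from_links(v) for k, v in
                                  payload["odor_specific"].items()}}
    if "per_odor" in payload:
        return {int(k): from_links(v) for k, v in payload["per_odor"].items()}
    return from_links(payload["links"])


def write_tensors_hdf5(tensors: Mapping[str, TrialTensor], path) -> None:
    """Store one TrialTensor per component under its component name."""
    with h5py.File(path, "w") as fh:
        for name, t in tensors.items():
            grp = fh.create_group(name)
            grp.create_dataset("dff", data=t.dff)
            grp.create_dataset("mask", data=t.mask)
            grp.attrs["sampling_rate"] = t.sampling_rate
            grp.attrs["time_zero"] = t.time_zero
            grp.attrs["component"] = t.component
            grp.attrs["glomerulus_ids"] = list(t.glomerulus_ids)
            grp.attrs["odor_names"] = list(t.odor_names)


def read_tensors_hdf5(path) -> dict[str, TrialTensor]:
    out = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            grp = fh[name]
            out[name] = TrialTensor(
                dff=grp["dff"][()], mask=grp["mask"][()].astype(bool),
                sampling_rate=float(grp.attrs["sampling_rate"]),
                time_zero=float(grp.attrs["time_zero"]),
                glomerulus_ids=tuple(str(x) for x in
                                     grp.attrs["glomerulus_ids"]),
                odor_names=tuple(str(x) for x in grp.attrs["odor_names"]),
                component=str(grp.attrs["component"]))
    return out
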