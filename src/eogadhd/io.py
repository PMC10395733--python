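"""Plain-text readers and writers for recordings, truth logs and manifests.

Recordings travel as tab-separated text with a ``time_s  eog_h  eog_v``
header, mirroring the two-channel ``.txt`` export of the original
acquisition setup.  Truth logs are JSON sidecars; cohort manifests are CSV.
All writers format floats explicitly so repeated runs with the same seed
produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortSpec, EogRecording, SubjectProfile, TruthSaccade

__all__ = [
    "write_recording",
    "read_recording",
    "write_truth",
    "read_truth",
    "write_manifest",
    "read_manifest",
    "load_cohort_spec",
]

_FLOAT_FMT = "%.6f"


def write_recording(rec: EogRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.rate
    data = np.column_stack([t, rec.horizontal, rec.vertical])
    np.savetxt(
        path, data, fmt=_FLOAT_FMT, delimiter="\t",
        header="time_s\teog_h\teog_v", comments="",
    )


def read_recording(path, subject_id: str = "", group: str = "") -> EogRecording:
    df = pd.read_csv(path, sep="\t")
    expected = ["time_s", "eog_h", "eog_v"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: recording too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    return EogRecording(
        rate=round(rate, 6),
        horizontal=df["eog_h"].to_numpy(float),
        vertical=df["eog_v"].to_numpy(float),
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def write_truth(truth: list[TruthSaccade], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(s) for s in truth], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> list[TruthSaccade]:
    with open(path) as fh:
        return [TruthSaccade(**d) for d in json.load(fh)]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "cgd_response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def load_cohort_spec(path) -> CohortSpec:
    """Read a cohort description from YAML.

    Layout::

        groups:
          HC:       {n: 36, p_track: 0.321, p_cgd: 0.3902}
          ADHD_pre: {n: 53, p_track: 0.278, p_cgd: 0.0462, noise_sd: 0.02}

    Any :class:`~eogadhd.simulate.SubjectProfile` field may be overridden
    per group; unspecified fields keep the profile defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "groups" not in raw:
        raise ValueError(f"{path}: cohort spec must have a top-level 'groups' map")
    sizes: dict[str, int] = {}
    profiles: dict[str, SubjectProfile] = {}
    for group, params in raw["groups"].items():
        params = dict(params)
        sizes[group] = int(params.pop("n"))
        profiles[group] = SubjectProfile(**params)
    return CohortSpec(sizes=sizes, profiles=profiles)
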