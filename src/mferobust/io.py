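"""Reading real recordings (EDF) and cohort manifests.

An EDF manifest is a CSV with columns ``path,subject_id,group`` (group is
``HS`` or ``AD``; paths are resolved relative to the manifest). Channels
are matched against the 19 labels of the 10-20 system case-insensitively;
recordings missing any of them are rejected. Reading goes through ``mne``
(the ``edf`` extra), imported lazily so the synthetic pipeline has no hard
dependency on it.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .cohort import CHANNELS_1020, Cohort, CohortSpec, Group, Recording

__all__ = ["load_edf_recording", "load_edf_cohort"]


def load_edf_recording(path: str | Path, subject_id: str, group: str,
                       channels: tuple[str, ...] = CHANNELS_1020) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne; install the 'edf' extra") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    lookup = {name.strip().upper(): name for name in raw.ch_names}
    picked = []
    for label in channels:
        if label.upper() not in lookup:
            raise ValueError(f"{path}: channel {label} not found")
        picked.append(lookup[label.upper()])
    data = raw.get_data(picks=picked) * 1e6  # volts -> microvolts
    return Recording(subject_id=subject_id, group=Group(group),
                     data=np.asarray(data, dtype=float), fs=float(raw.info["sfreq"]),
                     channel_names=channels)


def load_edf_cohort(manifest: str | Path,
                    channels: tuple[str, ...] = CHANNELS_1020) -> Cohort:
    manifest = Path(manifest)
    recordings: list[Recording] = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            path = Path(row["path"])
            if not path.is_absolute():
                path = manifest.parent / path
            recordings.append(load_edf_recording(
                path, row["subject_id"], row["group"], channels))
    if not recordings:
        raise ValueError(f"empty manifest: {manifest}")
    fs = recordings[0].fs
    n_hs = sum(r.group is Group.HS for r in recordings)
    n_ad = len(recordings) - n_hs
    spec = CohortSpec(n_per_group=max(2, min(n_hs, n_ad)),
                      n_channels=len(channels), fs=fs,
                      duration=recordings[0].duration)
    return Cohort(spec=spec, recordings=recordings)
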