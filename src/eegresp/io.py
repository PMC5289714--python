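"""Reading and writing recordings, cohorts and feature matrices.

Recordings travel as plain CSV (one column per channel, one row per sample,
with a ``# fs=...`` comment line) next to a cohort-level ``metadata.csv``.
EDF files are read through :mod:`mne` when it is installed; EDF export is
not provided because no EDF writer library is part of the dependency set.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .selection import FeatureMatrix
from .synthetic_cohort import EEGRecording

_INSTANCE_COLS = ("subject_id", "condition", "group", "sex")


def write_recording_csv(rec: EEGRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.6f")
    if rec.event_log is not None:
        pd.DataFrame(rec.event_log, columns=["sample", "stimulus"]).to_csv(
            path.with_suffix(".events.csv"), index=False)


def read_recording_csv(path, subject_id: str = "?", group: str = "?",
                       sex: str = "?", condition: str = "?") -> EEGRecording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(header.split("=", 1)[1])
        labels = tuple(fh.readline().strip().split(","))
        data = np.loadtxt(fh, delimiter=",").T
    events = None
    ev_path = path.with_suffix(".events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        events = list(zip(ev["sample"].astype(int), ev["stimulus"]))
    return EEGRecording(subject_id, group, sex, condition, labels, fs, data,
                        event_log=events)


def read_recording_edf(path, subject_id: str = "?", group: str = "?",
                       sex: str = "?", condition: str = "?") -> EEGRecording:
    """Load an EDF file (requires mne); data returned in microvolt."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(subject_id, group, sex, condition,
                        tuple(raw.ch_names), float(raw.info["sfreq"]),
                        raw.get_data() * 1e6)


def write_cohort(recordings: list[EEGRecording], metadata: pd.DataFrame,
                 outdir) -> Path:
    """One CSV per subject x condition plus a metadata table with file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.condition}.csv"
        write_recording_csv(rec, outdir / fname)
        meta_row = metadata.loc[metadata["subject_id"] == rec.subject_id].iloc[0]
        rows.append(dict(subject_id=rec.subject_id, group=rec.group, sex=rec.sex,
                         pre_bdi=meta_row["pre_bdi"], post_bdi=meta_row["post_bdi"],
                         condition=rec.condition, file=fname))
    pd.DataFrame(rows).to_csv(outdir / "metadata.csv", index=False)
    return outdir


def read_cohort(indir) -> tuple[list[EEGRecording], pd.DataFrame]:
    indir = Path(indir)
    table = pd.read_csv(indir / "metadata.csv")
    recs = []
    for row in table.itertuples():
        reader = read_recording_edf if str(row.file).endswith(".edf") else read_recording_csv
        recs.append(reader(indir / row.file, subject_id=row.subject_id,
                           group=row.group, sex=row.sex, condition=row.condition))
    meta = table.drop_duplicates("subject_id")[
        ["subject_id", "group", "sex", "pre_bdi", "post_bdi"]].reset_index(drop=True)
    return recs, meta


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Instance metadata + feature columns in one CSV, feature metadata beside it."""
    path = Path(path)
    inst = fm.instance_meta.reindex(columns=list(_INSTANCE_COLS))
    wide = pd.concat(
        [inst, pd.DataFrame(fm.values, columns=[f"f{i}" for i in range(fm.n_features)])],
        axis=1)
    wide.to_csv(path, index=False)
    fm.feature_meta.to_csv(path.with_suffix(".meta.csv"), index=False)


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    wide = pd.read_csv(path)
    inst = wide[list(_INSTANCE_COLS)]
    values = wide.drop(columns=list(_INSTANCE_COLS)).to_numpy(dtype=float)
    meta = pd.read_csv(path.with_suffix(".meta.csv"))
    return FeatureMatrix(values, meta, inst)
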