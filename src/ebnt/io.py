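"""Reading and writing cohorts, connectivity matrices and result tables.

Cohorts are stored as one HDF5 file per subject (dataset ``data``,
attributes for rate/labels/group) plus a CSV manifest; connectivity
matrices as square CSVs with channel labels as header, optionally
accompanied by a long-format edge table.  EDF recordings are read
through MNE when it is installed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .recording import Recording

__all__ = [
    "save_cohort", "load_cohort", "save_recording", "load_recording",
    "write_matrix_csv", "read_matrix_csv", "edge_table", "read_edf",
]


def save_recording(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["sample_rate"] = recording.sample_rate
        f.attrs["channel_labels"] = recording.channel_labels
        f.attrs["group"] = -1 if recording.group is None else recording.group


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        group = int(f.attrs["group"])
        return Recording(
            subject_id=str(f.attrs["subject_id"]),
            data=f["data"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            group=None if group == -1 else group,
        )


def save_cohort(recordings: list[Recording], out_dir: str | Path,
                seed: int | None = None) -> Path:
    """One HDF5 per subject plus a ``manifest.csv``; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["subject_id", "group", "path", "seed"])
        for rec in recordings:
            fname = f"{rec.subject_id}.h5"
            save_recording(rec, out_dir / fname)
            writer.writerow([rec.subject_id, rec.group, fname,
                             "" if seed is None else seed])
    return manifest


def load_cohort(cohort_dir: str | Path) -> list[Recording]:
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    return [load_recording(cohort_dir / row["path"])
            for _, row in manifest.iterrows()]


def write_matrix_csv(cm: ConnectivityMatrix, path: str | Path) -> None:
    labels = cm.channel_labels or [f"ch{i:03d}" for i in range(cm.n_channels)]
    pd.DataFrame(cm.matrix, index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path: str | Path, subject_id: str = "unknown",
                    band: str = "broadband") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        subject_id=subject_id,
        band=band,
        matrix=df.to_numpy(dtype=float),
        n_segments_averaged=0,
        channel_labels=[str(c) for c in df.columns],
    )


def edge_table(cms: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Long-format edge list: subject, band, ch_i, ch_j, pli."""
    rows = []
    for cm in cms:
        labels = cm.channel_labels or \
            [f"ch{i:03d}" for i in range(cm.n_channels)]
        iu = np.triu_indices(cm.n_channels, k=1)
        for i, j in zip(*iu):
            rows.append({
                "subject": cm.subject_id, "band": cm.band,
                "ch_i": labels[i], "ch_j": labels[j],
                "pli": cm.matrix[i, j],
            })
    return pd.DataFrame(rows)


def read_edf(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read an EDF file into a Recording (requires the optional MNE
    dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        subject_id=subject_id or Path(path).stem,
        data=raw.get_data(),
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )
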