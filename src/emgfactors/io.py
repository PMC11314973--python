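"""Dataset interchange: JSON manifest plus per-record delimited signals.

The manifest indexes every record (subject, factor, level, motion, trial,
sampling rate, sample count, relative path); each signal file is plain
CSV, one column per channel, with a single leading comment line.  Real
recordings exported to the same layout can be substituted for the
synthetic data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import LABEL_COLUMNS, feature_column_names
from .simulate import Recording

MANIFEST_NAME = "manifest.json"


def write_manifest(manifest: dict, path) -> None:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    """Load and validate a dataset manifest.

    Fails if a referenced signal file is missing or if two records share
    the same (subject, kind, level, motion, trial) key.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    seen = set()
    for rec in manifest["records"]:
        key = (rec["subject_id"], rec["factor_kind"], rec["factor_level"],
               rec["motion"], rec["trial_index"])
        if key in seen:
            raise ValueError(f"duplicate manifest record {key}")
        seen.add(key)
        if rec["fs"] != manifest["fs"]:
            raise ValueError(f"record {key} fs {rec['fs']} != dataset fs "
                             f"{manifest['fs']}")
    for rec in manifest["records"]:
        if not (root / rec["path"]).exists():
            raise FileNotFoundError(
                "signal file missing for record "
                f"{rec['subject_id']}/{rec['factor_level']}/{rec['motion']}"
                f"/t{rec['trial_index']}: {rec['path']}")
    return manifest


def write_dataset(recordings, manifest: dict, outdir) -> Path:
    """Write signal CSVs and the manifest; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    by_path = {r["path"]: r for r in manifest["records"]}
    for rec, row in zip(recordings, manifest["records"]):
        header = (f"# subject={row['subject_id']} kind={row['factor_kind']} "
                  f"level={row['factor_level']} motion={row['motion']} "
                  f"trial={row['trial_index']} fs={row['fs']}")
        np.savetxt(outdir / row["path"], rec.samples, delimiter=",",
                   fmt="%.9e", header=header.lstrip("# "), comments="# ")
    assert len(by_path) == len(manifest["records"])
    mpath = outdir / MANIFEST_NAME
    write_manifest(manifest, mpath)
    return mpath


def load_recording(manifest_path, record: dict) -> Recording:
    root = Path(manifest_path).parent
    samples = np.loadtxt(root / record["path"], delimiter=",", comments="#",
                         ndmin=2)
    if samples.shape[0] != record["n_samples"]:
        raise ValueError(
            f"{record['path']}: {samples.shape[0]} rows, manifest says "
            f"{record['n_samples']}")
    return Recording(samples=samples, fs=record["fs"],
                     motion=record["motion"],
                     factor_kind=record["factor_kind"],
                     factor_level=record["factor_level"],
                     trial_index=record["trial_index"],
                     subject_id=record["subject_id"])


def read_dataset(dataset_dir):
    """Read a dataset directory back into (recordings, manifest)."""
    mpath = Path(dataset_dir) / MANIFEST_NAME
    manifest = read_manifest(mpath)
    recordings = [load_recording(mpath, rec) for rec in manifest["records"]]
    return recordings, manifest


def write_features(features: pd.DataFrame, path) -> None:
    """Feature table as CSV: label columns then feature-major columns."""
    cols = [c for c in LABEL_COLUMNS if c in features.columns]
    cols += feature_column_names(features)
    features[cols].to_csv(path, index=False, float_format="%.12g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)
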