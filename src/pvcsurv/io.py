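"""Plain-text persistence for recordings, annotations, summaries and cohorts.

Formats (all CSV with headers, documented here as the column dictionary):

* recording: ``sample_index,mv`` plus a JSON sidecar-free header comment is
  avoided — metadata (fs, phase bounds) travels in ``<stem>.meta.json``.
* beats: ``sample_index,label,morph_id,qrs_duration_ms`` with label N/V.
* cohort: one row per participant, columns as produced by
  :func:`pvcsurv.synthetic.generate_cohort`.
* analysis config: YAML mapping onto :class:`pvcsurv.survival.AnalysisConfig`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic.ecg import BeatSet, EcgRecording
from .survival.analysis import AnalysisConfig

__all__ = [
    "write_recording",
    "read_recording",
    "write_beats",
    "read_beats",
    "write_cohort",
    "read_cohort",
    "load_analysis_config",
]

_CATEGORICALS = {
    "exercise_category": ["0", "1-5", "6-10", "11-20", ">20"],
    "recovery_category": ["0", "1-5", ">5"],
}


def write_recording(path: str | Path, rec: EcgRecording) -> None:
    path = Path(path)
    pd.DataFrame({"sample_index": np.arange(rec.n_samples), "mv": rec.samples}).to_csv(path, index=False)
    meta = {"fs": rec.fs, "phase_bounds": rec.phase_bounds.tolist()}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_recording(path: str | Path) -> EcgRecording:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return EcgRecording(df["mv"].to_numpy(), meta["fs"], np.asarray(meta["phase_bounds"]))


def write_beats(path: str | Path, beats: BeatSet) -> None:
    beats.to_dataframe().to_csv(path, index=False)


def read_beats(path: str | Path, fs: float) -> BeatSet:
    df = pd.read_csv(path)
    return BeatSet(
        df["sample_index"].to_numpy(),
        df["label"].to_numpy(),
        df.get("morph_id", pd.Series(np.zeros(len(df)))).to_numpy(),
        df.get("qrs_duration_ms", pd.Series(np.full(len(df), 92.0))).to_numpy(),
        fs,
    )


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col, cats in _CATEGORICALS.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col].astype(str), categories=cats)
    return df


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "exclusions" in raw:
        raw["exclusions"] = tuple(raw["exclusions"])
    return AnalysisConfig(**raw)
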