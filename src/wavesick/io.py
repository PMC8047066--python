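"""Disk formats: CSV recordings with JSON sidecars, questionnaire and
cohort tables.

Recordings are stored one file per modality per measurement as plain
CSV (time rows x channel columns, full float precision) next to a JSON
sidecar holding the sampling rate and channel labels; measurements live
in ``<subject>_<protocol>/`` directories.  Every writer has a paired
reader that reproduces values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .indexes import SYMPTOMS, QuestionnaireResponse
from .protocols import PROTOCOLS
from .recording import Measurement, Recording

_MODALITIES = ("eeg", "emg", "hr")


def write_recording(directory: Path, stem: str, rec: Recording) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        directory / f"{stem}.csv",
        rec.samples.T,
        fmt="%.17g",
        delimiter=",",
        header=",".join(rec.labels),
        comments="",
    )
    (directory / f"{stem}.json").write_text(
        json.dumps({"rate": rec.rate, "labels": list(rec.labels)})
    )


def read_recording(directory: Path, stem: str) -> Recording:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    data = np.loadtxt(directory / f"{stem}.csv", delimiter=",", skiprows=1, ndmin=2)
    return Recording(data.T, float(meta["rate"]), tuple(meta["labels"]))


def questionnaire_frame(
    cohort: Sequence[tuple[Measurement, QuestionnaireResponse]],
) -> pd.DataFrame:
    """One row per measurement: subject_id, protocol + 13 symptom scores."""
    rows = []
    for meas, resp in cohort:
        rows.append(
            {
                "subject_id": meas.subject_id,
                "protocol": meas.protocol.name,
                **{s: resp[s] for s in SYMPTOMS},
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    cohort: Sequence[tuple[Measurement, QuestionnaireResponse]],
    out_dir: Path,
    write_recordings: bool = True,
) -> Path:
    """Write a simulated cohort: questionnaire CSV plus (optionally) a
    per-measurement directory of recording CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    questionnaire_frame(cohort).to_csv(out_dir / "questionnaire.csv", index=False)
    if write_recordings:
        for meas, _resp in cohort:
            d = out_dir / f"{meas.subject_id}_{meas.protocol.name}"
            write_recording(d, "eeg", meas.eeg)
            write_recording(d, "emg", meas.emg)
            write_recording(d, "hr", meas.hr)
    return out_dir


def read_measurements(in_dir: Path) -> list[Measurement]:
    """Rebuild measurements from a cohort directory written by
    :func:`write_cohort` (sorted by subject then protocol)."""
    in_dir = Path(in_dir)
    out = []
    for d in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        sid, _, pname = d.name.rpartition("_")
        if pname not in PROTOCOLS or not sid:
            continue
        out.append(
            Measurement(
                subject_id=sid,
                protocol=PROTOCOLS[pname],
                eeg=read_recording(d, "eeg"),
                emg=read_recording(d, "emg"),
                hr=read_recording(d, "hr"),
            )
        )
    return out


def read_questionnaire(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(SYMPTOMS) - set(frame.columns)
    if missing:
        raise ValueError(f"questionnaire file lacks symptom columns: {sorted(missing)}")
    return frame
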