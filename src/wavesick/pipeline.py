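"""End-to-end orchestration: simulate -> extract -> score -> join ->
screen -> benchmark, with manifests and per-subject change reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .benchmark import DEFAULT_LABELS, MODEL_NAMES, benchmark_all
from .features import FEATURE_NAMES, extract_features
from .indexes import (
    SYMPTOMS,
    compute_indexes,
    marginals_report,
    responses_from_frame,
)
from .io import write_recording
from .simulate import CouplingConfig, iter_subject_measurements, preset_config
from .stats import format_significance_table, significance_matrix

#: |delta| below this counts as "unchanged" for continuous features.
CHANGE_TOLERANCE = 1e-9


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run; unknown
    keys are rejected and the whole config is serialised into the run
    manifest."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_subjects: int = 28
    preset: Literal["null", "weak", "strong"] = "strong"
    missing: list[tuple[str, str]] | None = None  # None -> study layout
    write_recordings: bool = False
    tie_is_positive: bool = True
    stats_mode: Literal["auto", "exact", "normal"] = "auto"
    labels: list[str] = Field(default_factory=lambda: list(DEFAULT_LABELS))
    models: list[str] = Field(default_factory=lambda: list(MODEL_NAMES))
    cv_folds: int = 10
    cv_seeds: int = 10


def simulate_cohort_tables(
    n_subjects: int,
    missing=None,
    config: CouplingConfig | None = None,
    recordings_dir: Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return its feature and questionnaire
    tables, streaming subject-by-subject so recordings never
    accumulate in memory (full-size EEG is ~30 MB per measurement).

    When ``recordings_dir`` is given, each measurement's recordings are
    also written to ``<subject>_<protocol>/`` CSVs on the way through.
    """
    feat_rows, q_rows = [], []
    for subject in iter_subject_measurements(n_subjects, missing, config):
        baseline = next(
            (m.eeg for m, _ in subject if m.protocol.name == "P0"), None
        )
        for meas, resp in subject:
            key = {"subject_id": meas.subject_id, "protocol": meas.protocol.name}
            feat_rows.append({**key, **extract_features(meas, baseline)})
            q_rows.append({**key, **{s: resp[s] for s in SYMPTOMS}})
            if recordings_dir is not None:
                d = Path(recordings_dir) / f"{meas.subject_id}_{meas.protocol.name}"
                write_recording(d, "eeg", meas.eeg)
                write_recording(d, "emg", meas.emg)
                write_recording(d, "hr", meas.hr)
    return pd.DataFrame(feat_rows), pd.DataFrame(q_rows)


def build_cohort_table(features: pd.DataFrame, questionnaire: pd.DataFrame,
                       tie_is_positive: bool = True) -> pd.DataFrame:
    """Join the feature table with the binary indexes and SumMS on
    (subject_id, protocol).  Never drops rows silently: a mismatch in
    keys raises."""
    responses = responses_from_frame(questionnaire)
    idx = compute_indexes(responses, tie_is_positive=tie_is_positive)
    idx = pd.concat(
        [questionnaire[["subject_id", "protocol"]].reset_index(drop=True), idx], axis=1
    )
    merged = features.merge(idx, on=["subject_id", "protocol"], how="inner", validate="1:1")
    if len(merged) != len(features) or len(merged) != len(idx):
        raise ValueError(
            f"feature/questionnaire key mismatch: {len(features)} feature rows, "
            f"{len(idx)} questionnaire rows, {len(merged)} joined"
        )
    return merged


def change_report(cohort: pd.DataFrame, questionnaire: pd.DataFrame) -> pd.DataFrame:
    """Per-subject direction of change of every feature and symptom
    between the static baseline and each wave protocol.

    Returns a tidy table (subject_id, protocol, variable, kind,
    direction) with direction in {up, down, unchanged}.  Subjects
    without a P0 row are skipped.
    """
    merged = cohort.merge(
        questionnaire, on=["subject_id", "protocol"], how="left", validate="1:1"
    )
    rows = []
    for sid, grp in merged.groupby("subject_id", sort=True):
        grp = grp.set_index("protocol")
        if "P0" not in grp.index:
            continue
        base = grp.loc["P0"]
        for prot in ("P1", "P3"):
            if prot not in grp.index:
                continue
            cur = grp.loc[prot]
            for kind, names, tol in (
                ("feature", FEATURE_NAMES, CHANGE_TOLERANCE),
                ("symptom", SYMPTOMS, 0),
            ):
                for name in names:
                    delta = cur[name] - base[name]
                    if not np.isfinite(delta):
                        direction = "n/a"
                    elif abs(delta) <= tol:
                        direction = "unchanged"
                    else:
                        direction = "up" if delta > 0 else "down"
                    rows.append(
                        dict(subject_id=sid, protocol=prot, variable=name,
                             kind=kind, direction=direction)
                    )
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def run_all(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    """Execute the full pipeline and write every artifact under
    ``out_dir``; reruns with the same config reproduce identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out_dir / name
        frame.to_csv(path, index=kw.pop("index", False), **kw)
        artifacts[name] = path

    sim_cfg = preset_config(config.preset, seed=config.seed)
    features, questionnaire = simulate_cohort_tables(
        config.n_subjects,
        config.missing,
        sim_cfg,
        recordings_dir=(out_dir / "recordings") if config.write_recordings else None,
    )
    save("questionnaire.csv", questionnaire)
    save("features.csv", features)

    table = build_cohort_table(features, questionnaire, config.tie_is_positive)
    save("cohort.csv", table)

    responses = responses_from_frame(questionnaire)
    sym_marg, idx_marg = marginals_report(responses)
    save("marginals_symptoms.csv", sym_marg, index=True)
    save("marginals_indexes.csv", idx_marg, index=True)

    tidy = significance_matrix(table, mode=config.stats_mode)
    save("significance.csv", tidy)
    save("significance_table.csv", format_significance_table(tidy), index=True)

    base = config.seed % 2**31
    seeds = [(base + i) % 2**31 for i in range(config.cv_seeds)]
    report = benchmark_all(
        table,
        labels=tuple(config.labels),
        models=tuple(config.models),
        k=config.cv_folds,
        seeds=seeds,
    )
    save("metrics.csv", report.metrics)
    for label, imp in report.importances.items():
        save(f"importance_{label}.csv", imp)

    save("change_report.csv", change_report(table, questionnaire))

    n_eeg_missing = int(table[list(FEATURE_NAMES[:5])].isna().any(axis=1).sum())
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "config_hash": _config_hash(config),
        "version": __version__,
        "cv_seeds": seeds,
        "n_measurements": int(len(table)),
        "n_rows_missing_eeg": n_eeg_missing,
        "best_model": report.best_model,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest.json"] = path
    return artifacts
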