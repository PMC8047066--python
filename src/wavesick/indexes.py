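"""Binary motion-sickness indexes from 13-item symptom questionnaires.

After each protocol the subject rates 13 typical motion-sickness
symptoms on a 0/1/2 ordinal scale.  Eight binary indexes summarise the
cohort:

* ``I_GenDis`` and ``I_Dizz`` use the single general-discomfort and
  dizziness/vertigo responses directly;
* ``I_Stom``, ``I_Head`` and ``I_Fatig`` average fixed symptom groups
  (stomach-related, head-related, fatigue-related);
* ``I_PV`` (physiological/vegetative) and ``I_NM`` (neurological/muscle
  strain) average larger overlapping groups that both include general
  discomfort;
* ``I_MS`` uses the weighted sum ``SumMS`` of all 13 answers,

    SumMS = 0.2*GenDis + 0.2*Dizz + 0.2*sum(stomach five)
            + 0.2*sum(fatigue three) + 0.2*sum(head three).

Each per-measurement scalar is binarised cohort-relatively: the
threshold is one third of the cohort maximum, and a measurement is
labelled 1 when its value reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SYMPTOMS: tuple[str, ...] = (
    "general_discomfort",
    "dizziness_vertigo",
    "stomach_awareness",
    "sweating",
    "nausea",
    "salivation",
    "burping",
    "headache",
    "fullness_of_head",
    "blurred_vision",
    "fatigue",
    "eye_strain",
    "difficulty_focusing",
)

_STOM = ("stomach_awareness", "sweating", "nausea", "salivation", "burping")
_HEAD = ("headache", "fullness_of_head", "blurred_vision")
_FATIG = ("fatigue", "eye_strain", "difficulty_focusing")

#: Symptom groups behind each averaged index; the two direct indexes map
#: to single-symptom "groups" and are not averaged.
GROUPS: dict[str, tuple[str, ...]] = {
    "I_GenDis": ("general_discomfort",),
    "I_Dizz": ("dizziness_vertigo",),
    "I_Stom": _STOM,
    "I_Head": _HEAD,
    "I_Fatig": _FATIG,
    "I_PV": _STOM + ("general_discomfort",),
    "I_NM": _FATIG + _HEAD + ("general_discomfort",),
}

DIRECT_INDEXES = ("I_GenDis", "I_Dizz")
INDEX_NAMES: tuple[str, ...] = (
    "I_GenDis",
    "I_Dizz",
    "I_Stom",
    "I_Head",
    "I_Fatig",
    "I_PV",
    "I_NM",
    "I_MS",
)

#: Largest attainable SumMS (all answers 2): 0.2 * (2 + 2 + 10 + 6 + 6).
SUM_MS_MAX = 5.2


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Thirteen ordinal symptom scores, each in {0, 1, 2}."""

    scores: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.scores) != set(SYMPTOMS):
            raise ValueError("exactly the 13 canonical symptoms are required")
        for name, v in self.scores.items():
            if int(v) != v or not 0 <= int(v) <= 2:
                raise ValueError(f"score for {name} must be an integer in 0..2")

    def __getitem__(self, symptom: str) -> int:
        return int(self.scores[symptom])

    def as_series(self) -> pd.Series:
        return pd.Series({s: int(self.scores[s]) for s in SYMPTOMS}, dtype=int)


def group_score(response: QuestionnaireResponse, group: str) -> float:
    """Per-measurement scalar for one index: group mean, or the direct
    response for the two single-symptom indexes."""
    if group not in GROUPS:
        raise KeyError(f"unknown symptom group {group!r}")
    members = GROUPS[group]
    if group in DIRECT_INDEXES:
        return float(response[members[0]])
    return float(np.mean([response[m] for m in members]))


def sum_ms(response: QuestionnaireResponse) -> float:
    """Weighted sum of all 13 answers feeding the overall index I_MS."""
    return 0.2 * (
        response["general_discomfort"]
        + response["dizziness_vertigo"]
        + sum(response[s] for s in _STOM)
        + sum(response[s] for s in _FATIG)
        + sum(response[s] for s in _HEAD)
    )


def cohort_binarize(
    values: Sequence[float] | np.ndarray,
    *,
    threshold: float | None = None,
    tie_is_positive: bool = True,
) -> np.ndarray:
    """Split a cohort of nonnegative scalars at one third of its maximum.

    Parameters
    ----------
    values
        One scalar per measurement, all >= 0.
    threshold
        Freeze the cut point instead of recomputing max/3 — used to score
        new measurements against a reference cohort.
    tie_is_positive
        A value exactly at the threshold is labelled 1 (default); the
        printed worked examples are insensitive to this choice because
        their scores are integers.

    Returns
    -------
    ndarray of int
        0/1 label per measurement.  An all-zero cohort has threshold 0
        and is labelled all 0 (no symptoms, no positives).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty cohort")
    if (v < 0).any():
        raise ValueError("index values must be nonnegative")
    t = v.max() / 3.0 if threshold is None else float(threshold)
    if t <= 0:
        return np.zeros(v.size, dtype=int)
    above = v >= t if tie_is_positive else v > t
    return above.astype(int)


def compute_indexes(
    responses: Sequence[QuestionnaireResponse],
    *,
    tie_is_positive: bool = True,
) -> pd.DataFrame:
    """Eight binary indexes (plus SumMS) for a cohort of responses.

    Binarisation is cohort-relative: thresholds are one third of the
    maximum over *these* responses, recomputed per call.
    """
    if len(responses) == 0:
        raise ValueError("empty cohort")
    out = {}
    for name in INDEX_NAMES:
        if name == "I_MS":
            vals = [sum_ms(r) for r in responses]
        else:
            vals = [group_score(r, name) for r in responses]
        out[name] = cohort_binarize(vals, tie_is_positive=tie_is_positive)
    out["SumMS"] = [sum_ms(r) for r in responses]
    return pd.DataFrame(out)


def marginals_report(
    responses: Sequence[QuestionnaireResponse],
    indexes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort marginals: % of 0/1/2 per symptom and % of 0/1 per index."""
    if indexes is None:
        indexes = compute_indexes(responses)
    n = len(responses)
    sym = pd.DataFrame(
        {
            s: [
                100.0 * sum(r[s] == k for r in responses) / n
                for k in (0, 1, 2)
            ]
            for s in SYMPTOMS
        },
        index=["pct_0", "pct_1", "pct_2"],
    ).T
    idx = pd.DataFrame(
        {
            name: [
                100.0 * float((indexes[name] == 0).mean()),
                100.0 * float((indexes[name] == 1).mean()),
            ]
            for name in INDEX_NAMES
        },
        index=["pct_0", "pct_1"],
    ).T
    return sym, idx


def responses_from_frame(frame: pd.DataFrame) -> list[QuestionnaireResponse]:
    """Rebuild response objects from a questionnaire table (one row per
    measurement, the 13 symptom columns present)."""
    return [
        QuestionnaireResponse({s: int(row[s]) for s in SYMPTOMS})
        for _, row in frame.iterrows()
    ]


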