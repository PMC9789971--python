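"""Center of Cancellation (CoC) scoring and neglect classification.

Cancellation tasks (letter cancellation: 60 'A' targets among distractor
letters; bells test: 35 bell icons among distractor icons) are standard
pen-and-paper screens for spatial neglect. The CoC summarises the spatial
bias of the marks as a single number: the mean horizontal position of the
*detected* targets relative to the mean position of *all* targets, with
horizontal positions min-max normalised to [-1, +1] (left to right). A
patient who finds every target scores exactly 0; one who cancels only the
right half of the sheet scores strongly positive. Per-task CoC scores are
averaged into a compound severity estimate, and neglect is diagnosed when
either task exceeds its published cut-off (letter > 0.083, bells > 0.081,
strict).

A sheet with zero detections has no defined centre; the score is flagged
missing (NaN) rather than silently zeroed. For cohort simulation an optional
policy maps it to +1 ("maximal neglect") instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataContractError

LETTER_CUTOFF = 0.083
BELLS_CUTOFF = 0.081

TASKS = ("letter", "bells")


@dataclass
class CancellationSheet:
    """One completed cancellation sheet.

    ``x_mm`` is horizontal target position relative to the sheet centre
    (rightward positive), ``y_mm`` vertical; ``detected`` flags the targets
    the patient marked. Vertical positions play no role in the CoC but are
    kept because raw response files carry them.
    """

    task_name: str
    x_mm: np.ndarray
    y_mm: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        if self.task_name not in TASKS:
            raise DataContractError(f"unknown task {self.task_name!r}")
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.detected)):
            raise DataContractError("target columns have unequal lengths")
        if len(self.x_mm) < 2:
            raise DataContractError("a sheet needs at least 2 targets")
        if np.ptp(self.x_mm) == 0:
            raise DataContractError("all targets at identical x: CoC undefined")


def coc(sheet: CancellationSheet, zero_detection_policy: str = "missing") -> float:
    """Center of Cancellation of one sheet.

    Horizontal positions are linearly mapped so the leftmost target sits at
    -1 and the rightmost at +1; the CoC is the mean normalised position of
    the detected targets minus the mean over all targets. Always in [-1, 1].

    ``zero_detection_policy``: ``"missing"`` (default) returns NaN when no
    target was detected; ``"max_neglect"`` returns +1.0.
    """
    if zero_detection_policy not in ("missing", "max_neglect"):
        raise DataContractError(f"unknown policy {zero_detection_policy!r}")
    if not sheet.detected.any():
        return 1.0 if zero_detection_policy == "max_neglect" else math.nan
    x = sheet.x_mm
    u = -1.0 + 2.0 * (x - x.min()) / (x.max() - x.min())
    return float(u[sheet.detected].mean() - u.mean())


def compound_coc(coc_letter: float | None, coc_bells: float | None) -> float:
    """Arithmetic mean of the per-task CoC values that are present."""
    vals = [v for v in (coc_letter, coc_bells) if v is not None and not math.isnan(v)]
    if not vals:
        raise DataContractError("no per-task CoC available for the compound score")
    return float(np.mean(vals))


def classify_neglect(
    coc_letter: float | None,
    coc_bells: float | None,
    letter_cutoff: float = LETTER_CUTOFF,
    bells_cutoff: float = BELLS_CUTOFF,
) -> bool:
    """True iff either task exceeds its cut-off (strict inequality)."""
    letter_ok = coc_letter is not None and not math.isnan(coc_letter)
    bells_ok = coc_bells is not None and not math.isnan(coc_bells)
    if not letter_ok and not bells_ok:
        raise DataContractError("no per-task CoC available for classification")
    positive = False
    if letter_ok:
        positive = positive or coc_letter > letter_cutoff
    if bells_ok:
        positive = positive or coc_bells > bells_cutoff
    return positive


@dataclass
class BehaviorRecord:
    """Per-patient behavioural summary entering the statistics."""

    patient_id: str
    coc_letter: float = math.nan
    coc_bells: float = math.nan
    coc_compound: float = field(default=math.nan)
    neglect: bool = field(default=False)

    @classmethod
    def from_task_scores(
        cls, patient_id: str, coc_letter: float | None, coc_bells: float | None
    ) -> "BehaviorRecord":
        compound = compound_coc(coc_letter, coc_bells)
        neglect = classify_neglect(coc_letter, coc_bells)
        return cls(
            patient_id=patient_id,
            coc_letter=math.nan if coc_letter is None else float(coc_letter),
            coc_bells=math.nan if coc_bells is None else float(coc_bells),
            coc_compound=compound,
            neglect=neglect,
        )


def record_from_sheets(
    patient_id: str, sheets: list[CancellationSheet], **coc_kwargs
) -> BehaviorRecord:
    """Score a patient's sheets (at most one per task) into a BehaviorRecord."""
    scores: dict[str, float] = {}
    for sheet in sheets:
        if sheet.task_name in scores:
            raise DataContractError(f"duplicate {sheet.task_name} sheet for {patient_id}")
        scores[sheet.task_name] = coc(sheet, **coc_kwargs)
    return BehaviorRecord.from_task_scores(
        patient_id, scores.get("letter"), scores.get("bells")
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_sheets_csv(path: str | Path) -> dict[str, list[CancellationSheet]]:
    """Read raw cancellation responses: columns patient_id, task, x_mm, y_mm, detected."""
    df = pd.read_csv(path)
    out: dict[str, list[CancellationSheet]] = {}
    for (pid, task), grp in df.groupby(["patient_id", "task"], sort=True):
        out.setdefault(str(pid), []).append(
            CancellationSheet(
                task_name=str(task),
                x_mm=grp["x_mm"].to_numpy(),
                y_mm=grp["y_mm"].to_numpy(),
                detected=grp["detected"].astype(bool).to_numpy(),
            )
        )
    return out


def records_to_frame(records: list[BehaviorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "coc_letter": [r.coc_letter for r in records],
            "coc_bells": [r.coc_bells for r in records],
            "coc_compound": [r.coc_compound for r in records],
            "neglect": [r.neglect for r in records],
        }
    )


def write_records_csv(records: list[BehaviorRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[BehaviorRecord]:
    df = pd.read_csv(path)
    return [
        BehaviorRecord(
            patient_id=str(r.patient_id),
            coc_letter=float(r.coc_letter),
            coc_bells=float(r.coc_bells),
            coc_compound=float(r.coc_compound),
            neglect=bool(r.neglect),
        )
        for r in df.itertuples(index=False)
    ]
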