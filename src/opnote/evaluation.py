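"""Weighted-F1 scoring and the per-step evaluation report.

The video-level task is binary per step and heavily class-imbalanced
(core steps appear in almost every video, some optional steps in very
few), so the score of record is the support-weighted mean of the
per-class F1 scores:

    wF1 = (n_pos * F1_pos + n_neg * F1_neg) / N

with F1 of a class defined as 0 when its precision + recall is 0.  Step
scores are then mean-averaged *unweighted* across steps (each step counts
once) and reported with the population standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

__all__ = ["weighted_f1", "evaluate", "EvaluationReport"]


def weighted_f1(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Support-weighted two-class F1 of binary predictions.

    Raises
    ------
    ValueError
        On empty or length-mismatched inputs.
    """
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise ValueError("cannot score empty vectors")
    return float(
        f1_score(yt, yp, average="weighted", labels=[0, 1], zero_division=0)
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Per-step weighted F1 with the across-step summary."""

    per_step_f1: dict[int, float]
    mean_f1: float
    sd_f1: float
    split: str = "test"
    stage: str = "discriminator"
    n_videos: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "step_id": sorted(self.per_step_f1),
                "weighted_f1": [
                    self.per_step_f1[s] for s in sorted(self.per_step_f1)
                ],
            }
        )
        df["split"] = self.split
        df["stage"] = self.stage
        return df

    def summary(self) -> dict:
        return {
            "split": self.split,
            "stage": self.stage,
            "n_steps": len(self.per_step_f1),
            "n_videos": self.n_videos,
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
        }


def evaluate(
    predictions: Mapping[int, Mapping[str, bool]],
    truth: Mapping[int, Mapping[str, bool]],
    split: str = "test",
    stage: str = "discriminator",
) -> EvaluationReport:
    """Score per-step video classifications against ground-truth presence.

    ``predictions`` and ``truth`` map ``step_id -> video_id -> bool`` over
    aligned video sets.  Returns the per-step weighted F1 over videos and
    its unweighted mean and population standard deviation across steps.

    Raises
    ------
    ValueError
        If the step sets or any step's video sets disagree.
    """
    if set(predictions) != set(truth):
        extra = set(predictions) ^ set(truth)
        raise ValueError(f"step sets disagree between predictions and truth: {sorted(extra)}")
    per_step: dict[int, float] = {}
    n_videos = 0
    for sid in sorted(truth):
        vids = sorted(truth[sid])
        if sorted(predictions[sid]) != vids:
            raise ValueError(f"step {sid}: video sets disagree")
        n_videos = len(vids)
        y_true = [int(truth[sid][v]) for v in vids]
        y_pred = [int(predictions[sid][v]) for v in vids]
        per_step[sid] = weighted_f1(y_true, y_pred)
    scores = np.array(list(per_step.values()))
    return EvaluationReport(
        per_step_f1=per_step,
        mean_f1=float(scores.mean()),
        sd_f1=float(scores.std(ddof=0)),
        split=split,
        stage=stage,
        n_videos=n_videos,
    )
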