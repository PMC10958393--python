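"""Stage III: clinical-coherence rules over per-video step predictions.

Some steps only make sense in the context of another: confirming the
sellar landmarks with neuronavigation (S11) presupposes that the landmarks
were identified (S09 or S10).  The accumulator enforces these reliance
rules: a positive prediction for a reliant step is flipped to negative
unless at least one of the steps it relies on was also predicted positive.

The default semantics is a *single simultaneous pass*: every rule reads
the original discriminator predictions, not already-corrected ones.  The
default catalog contains one mutual reliance (haemostasis S17 and its
instruments S18/S19), for which a single pass is not idempotent; an
iterate-to-fixed-point variant is available via ``fixed_point=True`` for
sensitivity analysis.  Rules only ever flip positive predictions to
negative — they never create positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .catalog import StepCatalog, reliance_rules

__all__ = ["StepPredictionVector", "apply_rules"]

_MAX_FIXED_POINT_ITER = 64


@dataclass(frozen=True)
class StepPredictionVector:
    """One boolean per catalog step for one video.

    ``provenance`` records where the vector came from: ``"discriminator"``
    (raw Stage-II output) or ``"accumulated"`` (after rule application).
    """

    video_id: str
    predictions: Mapping[int, bool]
    provenance: str = "discriminator"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "predictions",
            {int(k): bool(v) for k, v in self.predictions.items()},
        )
        if self.provenance not in ("discriminator", "accumulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def positives(self) -> set[int]:
        return {sid for sid, v in self.predictions.items() if v}


def _check_coverage(preds: StepPredictionVector, catalog: StepCatalog) -> None:
    missing = set(catalog.step_ids) - set(preds.predictions)
    if missing:
        raise ValueError(
            f"video {preds.video_id}: prediction vector missing catalog "
            f"steps {sorted(missing)}"
        )
    unknown = set(preds.predictions) - set(catalog.step_ids)
    if unknown:
        raise ValueError(
            f"video {preds.video_id}: predictions for unknown steps "
            f"{sorted(unknown)}"
        )


def _one_pass(pred: dict[int, bool], rules: Mapping[int, frozenset[int]]) -> dict[int, bool]:
    out = dict(pred)
    for sid, requires in rules.items():
        if pred[sid] and not any(pred[r] for r in requires):
            out[sid] = False
    return out


def apply_rules(
    preds: StepPredictionVector,
    catalog: StepCatalog,
    fixed_point: bool = False,
) -> StepPredictionVector:
    """Flip reliant positives whose required steps are all negative.

    With ``fixed_point=False`` (default) a single simultaneous pass is
    made, every rule reading the original predictions.  With
    ``fixed_point=True`` passes are repeated until no prediction changes.

    Raises
    ------
    ValueError
        If the vector does not cover the catalog steps exactly.
    """
    _check_coverage(preds, catalog)
    rules = reliance_rules(catalog)
    current = dict(preds.predictions)
    out = _one_pass(current, rules)
    if fixed_point:
        for _ in range(_MAX_FIXED_POINT_ITER):
            if out == current:
                break
            current, out = out, _one_pass(out, rules)
    return StepPredictionVector(
        video_id=preds.video_id, predictions=out, provenance="accumulated"
    )
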