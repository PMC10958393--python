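"""Render the "smart" operation note from accumulated step predictions.

The note follows the minimum information set of the Royal College of
Surgeons' good-practice guidance — basic information, surgical procedure,
post-operative plan — with the procedure narrative automated from the
step classifications and an optional 3-phase duration analytic computed
from a per-frame phase timeline.  Sections that cannot be automated are
emitted as clearly marked manual placeholders, and every note carries a
footer reminding that final checks rest with the surgical team.

Statement grammar
-----------------
Catalog statements may contain continuation slots (``[NN]``): when step NN
is also positive its statement is spliced in at that position, otherwise
the slot renders as nothing and any dangling connective ("with", "and",
"using") is stripped before the terminal period.  The renderer never
invents clinical text: every sentence is a concatenation of catalog
statement fragments plus whitespace and punctuation.

One deliberate grammar fallback exists: a spongostan placement (S20)
continues the haemostasis sentence (S17) but is not formally reliant on
it, so when S20 is positive and S17 negative the S17 stem is borrowed to
form a standalone haemostasis sentence, flagged on the rendered sentence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .accumulator import StepPredictionVector
from .catalog import StepCatalog, StepDefinition

__all__ = [
    "PhaseDurationChart",
    "RenderedSentence",
    "OperationNote",
    "render_procedure_text",
    "phase_durations",
    "render_note",
    "statement_pieces",
    "audit_note_statements",
]

PHASE_NAMES = {1: "Nasal phase", 2: "Sellar phase", 3: "Closure phase"}

_MARKER = re.compile(r"\[(\d{1,2})\]")
_CONNECTIVES = {"with", "and", "using"}
_MANUAL = "[MANUAL ENTRY]"

_BASIC_INFO_FIELDS = (
    "patient_identifier",
    "date_of_operation",
    "operating_surgeon",
    "assistant",
    "anaesthetist",
    "procedure_title",
)


@dataclass(frozen=True)
class PhaseDurationChart:
    """Seconds spent in each of the three surgical phases."""

    durations_s: dict[int, float]
    total_s: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.durations_s.values()):
            raise ValueError("phase durations must be non-negative")
        if abs(sum(self.durations_s.values()) - self.total_s) > 1e-9:
            raise ValueError("phase durations must sum to the total")


@dataclass(frozen=True)
class RenderedSentence:
    """One sentence of the procedure narrative."""

    phase_id: int
    step_ids: tuple[int, ...]
    text: str
    fallback: bool = False


def _strip_trailing_connective(core: str) -> str:
    """Drop dangling connectives/punctuation left by omitted continuations."""
    core = core.rstrip()
    while core:
        if core[-1] in ",;":
            core = core[:-1].rstrip()
            continue
        words = core.split()
        if words and words[-1].lower() in _CONNECTIVES:
            core = core[: -len(words[-1])].rstrip()
            continue
        break
    return core


def _finalize_sentence(text: str) -> str:
    t = re.sub(r"\s+", " ", text).strip()
    t = re.sub(r"\s+([.,;])", r"\1", t)
    t = re.sub(r"\.{2,}", ".", t)
    t = t.replace(" with and ", " with ")
    core = t[:-1] if t.endswith(".") else t
    core = _strip_trailing_connective(core)
    if not core:
        return ""
    if core[0].islower():
        core = core[0].upper() + core[1:]
    return core + "."


def _fragment(step: StepDefinition) -> str:
    """A statement prepared for splicing into a continuation slot: trailing
    period removed (interior punctuation is handled at finalization)."""
    frag = step.statement.strip()
    return frag[:-1] if frag.endswith(".") else frag


def _strip_leading_and(text: str) -> str:
    return re.sub(r"^(and|And)\s+", "", text.strip())


def statement_pieces(step: StepDefinition) -> list[str]:
    """Normalized literal text pieces of a step's statement.

    The statement is split at continuation slots; each piece is whitespace
    normalized with leading "and" and dangling trailing connectives or
    punctuation removed.  The pieces are exactly the text a rendered note
    contains whenever the step is positive, regardless of which
    continuations accompany it — useful for auditing rendered notes.
    """
    pieces = []
    for raw in _MARKER.split(step.statement)[::2]:  # even slots are literals
        t = re.sub(r"\s+", " ", raw).strip()
        t = _strip_leading_and(t)
        t = _strip_trailing_connective(t.rstrip("."))
        if t:
            pieces.append(t)
    return pieces


def render_procedure_text(
    preds: StepPredictionVector, catalog: StepCatalog
) -> list[RenderedSentence]:
    """Render the procedure narrative from an accumulated prediction vector.

    Steps are visited in catalog order.  A positive step not already
    consumed as a continuation (or as the partner of a joint statement)
    emits its statement with each continuation slot replaced by the
    referenced step's statement when that step is positive, or by nothing
    otherwise.  Joint partners (the sellar-landmark pair) emit their
    shared statement at most once, when either partner is positive.

    Raises
    ------
    ValueError
        If the vector's provenance is not ``"accumulated"`` or it does not
        cover the catalog.
    """
    if preds.provenance != "accumulated":
        raise ValueError(
            "procedure text is rendered from accumulated predictions; "
            f"got provenance {preds.provenance!r}"
        )
    pred = preds.predictions
    missing = set(catalog.step_ids) - set(pred)
    if missing:
        raise ValueError(f"prediction vector missing steps {sorted(missing)}")
    unknown = set(pred) - set(catalog.step_ids)
    if unknown:
        raise ValueError(f"predictions reference unknown steps {sorted(unknown)}")

    parent_of = {
        ref: step.step_id for step in catalog for ref in step.continuation_refs
    }
    consumed: set[int] = set()
    sentences: list[RenderedSentence] = []
    for step in catalog:
        sid = step.step_id
        if sid in consumed:
            continue
        involved = [sid]
        if step.joint_with is not None:
            if not (pred[sid] or pred[step.joint_with]):
                continue
            consumed.add(step.joint_with)
            involved = [s for s in (sid, step.joint_with) if pred[s]]
        elif not pred[sid]:
            continue

        fallback = False
        text = step.statement
        parent_id = parent_of.get(sid)
        if parent_id is not None:
            # Reached unconsumed: this continuation's parent was not emitted.
            parent = catalog.get(parent_id)
            if parent_id == 17:
                # Borrow the haemostasis stem for an orphaned instrument
                # continuation (the spongostan case).
                stem = re.sub(
                    r"\s+", " ", _MARKER.sub(" ", parent.statement)
                ).strip(" .")
                text = f"{stem} {_strip_leading_and(_fragment(step))}"
            else:
                text = _strip_leading_and(step.statement)
            fallback = True

        for ref in step.continuation_refs:
            if pred[ref]:
                replacement = _fragment(catalog.get(ref))
                consumed.add(ref)
                involved.append(ref)
            else:
                replacement = ""
            text = text.replace(f"[{ref:02d}]", replacement, 1)

        final = _finalize_sentence(text)
        if final:
            sentences.append(
                RenderedSentence(
                    phase_id=step.phase_id,
                    step_ids=tuple(involved),
                    text=final,
                    fallback=fallback,
                )
            )
    return sentences


def phase_durations(
    phase_timeline: Sequence[int] | np.ndarray, frame_rate: float = 1.0
) -> PhaseDurationChart:
    """Aggregate a per-frame phase timeline into the 3-phase duration chart.

    Raises
    ------
    ValueError
        On an empty timeline or a label outside {1, 2, 3}.
    """
    labels = np.asarray(phase_timeline, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("phase timeline is empty")
    unknown = set(np.unique(labels)) - {1, 2, 3}
    if unknown:
        raise ValueError(f"unknown phase labels {sorted(unknown)}")
    durations = {
        p: float((labels == p).sum() / frame_rate) for p in (1, 2, 3)
    }
    return PhaseDurationChart(
        durations_s=durations, total_s=float(labels.size / frame_rate)
    )


@dataclass(frozen=True)
class OperationNote:
    """The structured operation note: manual placeholders, the automated
    procedure narrative, analytics, and the sign-off footer."""

    video_id: str
    basic_info: dict[str, str]
    sentences: tuple[RenderedSentence, ...]
    postop_plan: str
    analytics: PhaseDurationChart | None
    footer: str
    metadata: dict[str, str] = field(default_factory=dict)

    def sentence_texts(self) -> list[str]:
        return [s.text for s in self.sentences]

    def to_dict(self) -> dict:
        return {
            "video_id": self.video_id,
            "basic_info": dict(self.basic_info),
            "procedure": [
                {
                    "phase_id": s.phase_id,
                    "phase": PHASE_NAMES[s.phase_id],
                    "step_ids": list(s.step_ids),
                    "text": s.text,
                    "fallback": s.fallback,
                }
                for s in self.sentences
            ],
            "analytics": (
                {
                    "phase_durations_s": {
                        str(p): self.analytics.durations_s[p] for p in (1, 2, 3)
                    },
                    "total_s": self.analytics.total_s,
                }
                if self.analytics is not None
                else None
            ),
            "postop_plan": self.postop_plan,
            "footer": self.footer,
            "metadata": dict(self.metadata),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [f"# Operation note — {self.video_id}", ""]
        lines.append("## Basic information")
        lines.append("")
        for key in _BASIC_INFO_FIELDS:
            pretty = key.replace("_", " ").capitalize()
            lines.append(f"- {pretty}: {self.basic_info.get(key, _MANUAL)}")
        lines.append("")
        lines.append("## Surgical procedure")
        for phase_id in (1, 2, 3):
            phase_sentences = [s for s in self.sentences if s.phase_id == phase_id]
            if not phase_sentences:
                continue
            lines.append("")
            lines.append(f"### {PHASE_NAMES[phase_id]}")
            lines.append("")
            for s in phase_sentences:
                flag = "  *(check wording)*" if s.fallback else ""
                lines.append(f"{s.text}{flag}")
        lines.append("")
        lines.append("## Video analytics")
        lines.append("")
        if self.analytics is None:
            lines.append("Phase duration chart unavailable (no phase timeline).")
        else:
            for p in (1, 2, 3):
                mins = self.analytics.durations_s[p] / 60.0
                lines.append(f"- {PHASE_NAMES[p]}: {mins:.1f} min")
            lines.append(f"- Total: {self.analytics.total_s / 60.0:.1f} min")
        lines.append("")
        lines.append("## Post-operative plan")
        lines.append("")
        lines.append(self.postop_plan)
        lines.append("")
        lines.append(f"*{self.footer}*")
        lines.append("")
        return "\n".join(lines)


def render_note(
    preds: StepPredictionVector,
    catalog: StepCatalog,
    phase_timeline: Sequence[int] | np.ndarray | None = None,
    metadata: Mapping[str, str] | None = None,
) -> OperationNote:
    """Assemble the full operation note for one video.

    Sections that cannot be automated (basic information, post-operative
    plan) are emitted as manual placeholders; the analytics section is
    marked unavailable when no phase timeline is supplied.
    """
    sentences = render_procedure_text(preds, catalog)
    analytics = (
        phase_durations(phase_timeline) if phase_timeline is not None else None
    )
    return OperationNote(
        video_id=preds.video_id,
        basic_info={k: _MANUAL for k in _BASIC_INFO_FIELDS},
        sentences=tuple(sentences),
        postop_plan=_MANUAL,
        analytics=analytics,
        footer="Automatically generated draft — final checks are always to be "
        "completed by the surgical team.",
        metadata=dict(metadata or {}),
    )


def audit_note_statements(
    note_text: str,
    presence: Mapping[int, bool],
    catalog: StepCatalog,
) -> dict[str, list[int]]:
    """Audit a rendered note against a step-presence vector.

    Returns ``{"missing": [...], "unexpected": [...]}`` where *missing*
    steps are present but have a statement piece absent from the note and
    *unexpected* steps are absent yet have a statement piece appearing in
    it.  Joint partners are treated as one statement (expected if either
    partner is present) and the haemostasis stem is exempted from the
    unexpected check when an orphaned spongostan sentence legitimately
    borrows it.
    """
    text = note_text.lower()  # orphaned continuations are re-capitalized
    missing: list[int] = []
    unexpected: list[int] = []
    for step in catalog:
        sid = step.step_id
        expected = bool(presence.get(sid, False))
        if step.joint_with is not None:
            expected = expected or bool(presence.get(step.joint_with, False))
        pieces = statement_pieces(step)
        if not pieces:
            continue
        if expected:
            if not all(p.lower() in text for p in pieces):
                missing.append(sid)
        else:
            if sid == 17 and any(
                presence.get(ref, False) for ref in step.continuation_refs
            ):
                continue  # stem borrowed by an orphaned continuation
            if any(p.lower() in text for p in pieces):
                unexpected.append(sid)
    return {"missing": missing, "unexpected": unexpected}
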