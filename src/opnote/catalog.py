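"""The surgical step catalog.

A *step* is a granular unit of endoscopic pituitary surgery — an anatomical
landmark being reached, a surgical action, or an instrument being used —
whose presence in a recorded video the pipeline detects.  The default
catalog bundles the 27 consensus-defined steps of the transsphenoidal
approach, grouped into three phases (nasal, sellar, closure), each carrying
the operative-note statement emitted when the step is detected.

Two pieces of structure in the statements matter downstream:

* **Continuation slots.**  A marker such as ``[03]`` inside a statement
  means: if step 3 is also positive, splice step 3's statement in at that
  position; otherwise render nothing there.  These are parsed at load time
  into :attr:`StepDefinition.continuation_refs`.
* **Reliance.**  ``reliant_on`` lists steps at least one of which (OR
  semantics) must be positive for this step's positive prediction to be
  clinically coherent; the accumulator enforces this.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "Category",
    "CatalogError",
    "StepDefinition",
    "StepCatalog",
    "load_catalog",
    "reliance_rules",
]

_MARKER = re.compile(r"\[(\d{1,2})\]")


class Category(str, Enum):
    """Step category: core steps occur in most surgeries, optional steps in
    a minority, and instrument steps run concurrently with a core step."""

    CORE = "core"
    OPTIONAL = "optional"
    INSTRUMENT = "instrument"


class CatalogError(ValueError):
    """A catalog source violates the step-catalog contract."""


@dataclass(frozen=True)
class StepDefinition:
    """One surgical step and its operative-note statement.

    Parameters
    ----------
    step_id
        Integer identity (1-27 in the default catalog).
    phase_id
        Surgical phase, 1 (nasal), 2 (sellar) or 3 (closure).
    category
        ``core``, ``optional`` or ``instrument``.
    reliant_on
        Steps at least one of which must be positive for this step to be
        positive (empty when the step is unconditional).
    statement
        Verbatim note statement, possibly containing ``[NN]`` continuation
        slots.
    continuation_refs
        Step ids referenced by continuation slots, in order of appearance.
    joint_with
        Partner step sharing this exact statement (the statement is emitted
        at most once when either partner is positive), or ``None``.
    """

    step_id: int
    phase_id: int
    category: Category
    reliant_on: frozenset[int]
    statement: str
    continuation_refs: tuple[int, ...]
    joint_with: int | None = None

    @property
    def label(self) -> str:
        """Conventional zero-padded label, e.g. ``S03``."""
        return f"S{self.step_id:02d}"


@dataclass(frozen=True)
class StepCatalog:
    """An ordered, validated collection of :class:`StepDefinition`."""

    steps: tuple[StepDefinition, ...]
    _by_id: Mapping[int, StepDefinition] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_by_id", {s.step_id: s for s in self.steps}
        )
        _validate(self)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[StepDefinition]:
        return iter(self.steps)

    def __contains__(self, step_id: int) -> bool:
        return step_id in self._by_id

    def get(self, step_id: int) -> StepDefinition:
        try:
            return self._by_id[step_id]
        except KeyError:
            raise CatalogError(f"unknown step id {step_id}") from None

    @property
    def step_ids(self) -> tuple[int, ...]:
        return tuple(s.step_id for s in self.steps)

    def to_records(self) -> list[dict]:
        """Serialize to the flat record form accepted by :func:`load_catalog`."""
        records = []
        for s in self.steps:
            rec: dict = {
                "step": s.step_id,
                "phase": s.phase_id,
                "category": s.category.value,
                "statement": s.statement,
            }
            if s.reliant_on:
                rec["reliant"] = sorted(s.reliant_on)
            if s.joint_with is not None:
                rec["joint_with"] = s.joint_with
            records.append(rec)
        return records

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_records(), sort_keys=False, allow_unicode=True)
        )


def _validate(catalog: StepCatalog) -> None:
    seen: set[int] = set()
    for s in catalog.steps:
        if s.step_id in seen:
            raise CatalogError(f"duplicate step id {s.step_id}")
        seen.add(s.step_id)
    for s in catalog.steps:
        if s.phase_id not in (1, 2, 3):
            raise CatalogError(
                f"step {s.step_id}: phase {s.phase_id} outside 1-3"
            )
        for r in s.reliant_on:
            if r not in seen:
                raise CatalogError(
                    f"step {s.step_id}: reliant on unknown step {r}"
                )
        for r in s.continuation_refs:
            if r not in seen:
                raise CatalogError(
                    f"step {s.step_id}: statement continues into unknown step {r}"
                )
        if s.joint_with is not None:
            if s.joint_with not in seen:
                raise CatalogError(
                    f"step {s.step_id}: joint partner {s.joint_with} unknown"
                )
            partner = catalog._by_id[s.joint_with]
            if partner.joint_with != s.step_id:
                raise CatalogError(
                    f"step {s.step_id}: joint_with not symmetric with "
                    f"step {s.joint_with}"
                )
            if partner.statement != s.statement:
                raise CatalogError(
                    f"steps {s.step_id}/{s.joint_with}: joint partners must "
                    "share one statement"
                )


def _parse_record(rec: Mapping) -> StepDefinition:
    try:
        step_id = int(rec["step"])
        phase_id = int(rec["phase"])
        category = Category(rec["category"])
        statement = str(rec["statement"])
    except (KeyError, ValueError) as exc:
        raise CatalogError(f"malformed step record {rec!r}: {exc}") from exc
    refs = tuple(int(m) for m in _MARKER.findall(statement))
    reliant = frozenset(int(r) for r in rec.get("reliant", ()) or ())
    joint = rec.get("joint_with")
    return StepDefinition(
        step_id=step_id,
        phase_id=phase_id,
        category=category,
        reliant_on=reliant,
        statement=statement,
        continuation_refs=refs,
        joint_with=int(joint) if joint is not None else None,
    )


def load_catalog(source: str | Path | Iterable[Mapping] = "default") -> StepCatalog:
    """Load a step catalog.

    Parameters
    ----------
    source
        ``"default"`` for the bundled 27-step catalog, a path to a YAML
        file of step records, or an iterable of record mappings.

    Raises
    ------
    CatalogError
        On duplicate ids, dangling reliance/continuation references, a
        phase outside 1-3, or asymmetric joint statements; the message
        names the offending step.
    """
    if isinstance(source, str) and source == "default":
        text = (
            resources.files("opnote").joinpath("data/step_catalog.yaml").read_text()
        )
        records = yaml.safe_load(text)
    elif isinstance(source, (str, Path)):
        records = yaml.safe_load(Path(source).read_text())
    else:
        records = list(source)
    if not isinstance(records, list) or not records:
        raise CatalogError("catalog source must be a non-empty list of step records")
    return StepCatalog(steps=tuple(_parse_record(r) for r in records))


def reliance_rules(catalog: StepCatalog) -> dict[int, frozenset[int]]:
    """Non-empty reliance sets, ``step_id -> {step_ids}`` with OR semantics:
    the keyed step is coherent if *at least one* member of its set is positive."""
    return {s.step_id: s.reliant_on for s in catalog if s.reliant_on}
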