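"""Operation-note rendering: continuation grammar, joint statements,
phase durations and the Markdown/JSON twins."""

import json

import numpy as np
import pytest

from opnote import (
    StepPredictionVector,
    apply_rules,
    audit_note_statements,
    phase_durations,
    render_note,
    render_procedure_text,
    statement_pieces,
)


def _vec(catalog, positives):
    preds = {s.step_id: (s.step_id in positives) for s in catalog}
    return StepPredictionVector("v1", preds, "accumulated")


class TestContinuationGrammar:
    def test_continuation_spliced_when_both_positive(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {2, 3}), catalog)
        assert s.text == (
            "The sphenoid ostium was identified and opened using "
            "Kerrison's rongeurs."
        )
        assert s.step_ids == (2, 3)

    def test_continuation_omitted_and_sentence_closed(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {2}), catalog)
        assert s.text == "The sphenoid ostium was identified."

    def test_mid_sentence_continuation_with_trailing_tail(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {4, 5}), catalog)
        assert s.text == (
            "The septum was then displaced and a partial posterior "
            "septectomy performed until the opposite ostium was seen."
        )

    def test_interior_period_of_spliced_fragment_dropped(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {6, 7}), catalog)
        assert s.text == (
            "The sphenoid sinus was opened, with removal of sphenoid "
            "septations and mucosa to expose the face of the sella."
        )

    def test_dangling_connective_stripped(self, catalog):
        # Haemostasis with no instrument continuations at all (possible
        # only pre-accumulation, via a catalog without reliance rules).
        from opnote import load_catalog

        records = [
            {k: v for k, v in rec.items() if k != "reliant"}
            for rec in catalog.to_records()
        ]
        free = load_catalog(records)
        [s] = render_procedure_text(_vec(free, {17}), free)
        assert s.text == "Haemostasis was achieved."


class TestJointStatement:
    @pytest.mark.parametrize("positives", [{9}, {10}, {9, 10}])
    def test_shared_statement_emitted_once(self, catalog, positives):
        sentences = render_procedure_text(_vec(catalog, positives), catalog)
        assert len(sentences) == 1
        assert sentences[0].text == (
            "The sella, carotid prominence, optic prominence, and "
            "optic-carotid recesses were then identified on both sides."
        )

    def test_joint_statement_with_confirmations(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {9, 10, 11}), catalog)
        assert s.text.endswith("on both sides and confirmed using neuronavigation.")


class TestFallbacks:
    def test_orphan_spongostan_borrows_haemostasis_stem(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {20}), catalog)
        assert s.text == "Haemostasis was achieved with a spongostan placement."
        assert s.fallback is True

    def test_orphan_generic_continuation_standalone(self, catalog):
        [s] = render_procedure_text(_vec(catalog, {5}), catalog)
        assert s.text == "A partial posterior septectomy performed."
        assert s.fallback is True


def test_all_negative_renders_nothing(catalog):
    assert render_procedure_text(_vec(catalog, set()), catalog) == []


def test_requires_accumulated_provenance(catalog):
    vec = StepPredictionVector(
        "v1", {s.step_id: False for s in catalog}, "discriminator"
    )
    with pytest.raises(ValueError, match="accumulated"):
        render_procedure_text(vec, catalog)


def test_unknown_steps_rejected(catalog):
    preds = {s.step_id: False for s in catalog}
    preds[99] = True
    with pytest.raises(ValueError, match="99"):
        render_procedure_text(
            StepPredictionVector("v1", preds, "accumulated"), catalog
        )


def test_all_positive_note_contains_every_statement_piece_exactly_once(catalog):
    vec = _vec(catalog, set(range(1, 28)))
    note = render_note(vec, catalog)
    text = note.to_markdown().lower()
    for step in catalog:
        if step.step_id == 10:  # shares its statement with step 9
            continue
        for piece in statement_pieces(step):
            assert text.count(piece.lower()) == 1, (step.step_id, piece)


def test_random_coherent_vectors_audit_clean(catalog):
    rng = np.random.default_rng(0)
    for _ in range(100):
        positives = {int(s) for s in rng.integers(1, 28, size=12)}
        raw = StepPredictionVector(
            "v1", {s.step_id: s.step_id in positives for s in catalog}
        )
        vec = apply_rules(raw, catalog)
        note = render_note(vec, catalog)
        audit = audit_note_statements(note.to_markdown(), vec.predictions, catalog)
        assert audit == {"missing": [], "unexpected": []}


def test_adding_a_positive_never_removes_rendered_fragments(catalog):
    base = {2, 9, 13, 15, 17, 18, 27}
    grown = base | {3, 21}
    text_base = " ".join(
        s.text for s in render_procedure_text(_vec(catalog, base), catalog)
    ).lower()
    text_grown = " ".join(
        s.text for s in render_procedure_text(_vec(catalog, grown), catalog)
    ).lower()
    for sid in base:
        for piece in statement_pieces(catalog.get(sid)):
            assert piece.lower() in text_base
            assert piece.lower() in text_grown


class TestPhaseDurations:
    def test_counts_frames_per_phase(self):
        chart = phase_durations([1, 1, 2, 3])
        assert chart.durations_s == {1: 2.0, 2: 1.0, 3: 1.0}
        assert chart.total_s == 4.0

    def test_single_phase_timeline(self):
        chart = phase_durations([2] * 7)
        assert chart.durations_s == {1: 0.0, 2: 7.0, 3: 0.0}

    def test_durations_always_sum_to_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            timeline = rng.integers(1, 4, size=int(rng.integers(1, 200)))
            chart = phase_durations(timeline)
            assert sum(chart.durations_s.values()) == chart.total_s

    def test_unknown_phase_label_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            phase_durations([1, 4])
        with pytest.raises(ValueError, match="empty"):
            phase_durations([])


class TestRenderNote:
    def test_markdown_and_json_sentence_lists_identical(self, catalog):
        note = render_note(_vec(catalog, {1, 2, 3, 15}), catalog,
                           phase_timeline=[1, 1, 2, 3])
        doc = json.loads(note.to_json())
        json_sentences = [p["text"] for p in doc["procedure"]]
        md = note.to_markdown()
        assert json_sentences == note.sentence_texts()
        assert all(t in md for t in json_sentences)

    def test_analytics_marked_unavailable_without_timeline(self, catalog):
        note = render_note(_vec(catalog, {1}), catalog)
        assert note.analytics is None
        assert "unavailable" in note.to_markdown()
        assert json.loads(note.to_json())["analytics"] is None

    def test_manual_placeholders_and_signoff_footer(self, catalog):
        md = render_note(_vec(catalog, {1}), catalog).to_markdown()
        assert "[MANUAL ENTRY]" in md
        assert "final checks are always to be completed" in md
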