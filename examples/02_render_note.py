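"""From step predictions to an operation note.

Builds a plausible per-video step prediction vector, passes it through the
clinical-rule accumulator, and renders the operative note.  Note how the
unsupported neuronavigation prediction (S11 without S09/S10) is flipped,
and how continuations splice into their parent sentences.
"""

from opnote import StepPredictionVector, apply_rules, load_catalog, render_note

catalog = load_catalog()

positives = {1, 2, 3, 6, 8, 11, 13, 14, 15, 16, 17, 18, 21, 27}
preds = StepPredictionVector(
    video_id="example-video",
    predictions={s.step_id: s.step_id in positives for s in catalog},
)

accumulated = apply_rules(preds, catalog)
flipped = sorted(preds.positives() - accumulated.positives())
print(f"accumulator flipped steps: {['S%02d' % s for s in flipped]}")
# S11 is flipped: neuronavigation cannot be reported when the sellar
# landmarks (S09/S10) were not detected.

note = render_note(
    accumulated,
    catalog,
    phase_timeline=[1] * 1200 + [2] * 2400 + [3] * 900,  # 1 fps frames
)
print()
print(note.to_markdown())
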