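"""Tour of the bundled 27-step catalog.

Loads the default step catalog for endoscopic pituitary surgery and prints
its structure: the three phases, the category of each step, and the
clinical reliance rules the accumulator enforces.
"""

from opnote import load_catalog, reliance_rules

catalog = load_catalog()
print(f"{len(catalog)} surgical steps in 3 phases\n")

for phase_id, phase_name in ((1, "Nasal"), (2, "Sellar"), (3, "Closure")):
    print(f"Phase {phase_id} — {phase_name}")
    for step in catalog:
        if step.phase_id != phase_id:
            continue
        extra = ""
        if step.reliant_on:
            extra = f"  (reliant on {'/'.join(f'S{r:02d}' for r in sorted(step.reliant_on))})"
        print(f"  {step.label} [{step.category.value:10s}]{extra}")
    print()

print("Reliance rules (OR semantics — one positive partner suffices):")
for sid, requires in sorted(reliance_rules(catalog).items()):
    partners = " or ".join(f"S{r:02d}" for r in sorted(requires))
    print(f"  S{sid:02d} requires {partners}")

# The reliance rules are what keep a predicted note clinically coherent:
# e.g. "confirmed using neuronavigation" (S11) cannot appear unless the
# sellar landmarks were identified (S09 or S10).
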