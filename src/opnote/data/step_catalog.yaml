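# Default 27-step catalog for endoscopic transsphenoidal pituitary surgery.
#
# Each record is one surgical step.  `statement` is the operative-note text
# emitted when the step is detected in a video.  A square-bracket marker
# such as "[03]" inside a statement is a continuation slot: when step 3 is
# also positive, its statement is spliced in at that position; when it is
# negative the slot renders as nothing.  `reliant` lists the steps (OR
# semantics) at least one of which must be positive for this step's
# positive prediction to stand.  Steps 9 and 10 are distinct steps that
# share a single statement (`joint_with`), emitted at most once.
#
# Phases: 1 = nasal, 2 = sellar, 3 = closure.
- step: 1
  phase: 1
  category: core
  statement: "The middle and superior turbinates were laterally displaced using a freer elevator."
- step: 2
  phase: 1
  category: core
  statement: "The sphenoid ostium was identified [03]."
- step: 3
  phase: 1
  category: core
  reliant: [2]
  statement: "and opened using Kerrison's rongeurs."
- step: 4
  phase: 1
  category: optional
  statement: "The septum was then displaced [05] until the opposite ostium was seen."
- step: 5
  phase: 1
  category: optional
  statement: "and a partial posterior septectomy performed."
- step: 6
  phase: 1
  category: core
  statement: "The sphenoid sinus was opened, with removal of sphenoid septations [07] to expose the face of the sella. [08]"
- step: 7
  phase: 1
  category: core
  statement: "and mucosa."
- step: 8
  phase: 1
  category: instrument
  statement: "A high-speed drill was required to achieve this."
- step: 9
  phase: 2
  category: core
  joint_with: 10
  statement: "The sella, carotid prominence, optic prominence, and optic-carotid recesses were then identified on both sides [11] [12]."
- step: 10
  phase: 2
  category: core
  joint_with: 9
  statement: "The sella, carotid prominence, optic prominence, and optic-carotid recesses were then identified on both sides [11] [12]."
- step: 11
  phase: 2
  category: instrument
  reliant: [9, 10]
  statement: "and confirmed using neuronavigation."
- step: 12
  phase: 2
  category: instrument
  reliant: [9, 10]
  statement: "and confirmed using a Micro Doppler probe."
- step: 13
  phase: 2
  category: core
  statement: "The sella was carefully opened using a rongeurs."
- step: 14
  phase: 2
  category: core
  statement: "A cruciate durotomy was performed using a retractable scalpel."
- step: 15
  phase: 2
  category: core
  statement: "The tumour was seen immediately on entering the sella and removed in a piecemeal fashion using currettes and pituitary rongeurs."
- step: 16
  phase: 2
  category: core
  statement: "The cleared pituitary fossa was visualised, and the diaphragm had descended."
- step: 17
  phase: 3
  category: core
  reliant: [18, 19, 20]
  statement: "Haemostasis was achieved with [18] [19] [20]."
- step: 18
  phase: 3
  category: instrument
  reliant: [17]
  statement: "a surgiflo."
- step: 19
  phase: 3
  category: instrument
  reliant: [17]
  statement: "a bipolar cautery."
- step: 20
  phase: 3
  category: instrument
  statement: "and a spongostan placement."
- step: 21
  phase: 3
  category: optional
  statement: "A fat graft was harvested from the left lower quadrant of the abdomen and placed over the defect."
- step: 22
  phase: 3
  category: optional
  statement: "A MedPor implant was then sized and placed."
- step: 23
  phase: 3
  category: optional
  statement: "A fascia lata graft was then harvested, and placed over the construct."
- step: 24
  phase: 3
  category: optional
  statement: "Evicel was used."
- step: 25
  phase: 3
  category: optional
  statement: "Adherus dural sealant was applied."
- step: 26
  phase: 3
  category: optional
  statement: "Bismuth soaked ribbon gauze was then used to pack the nasal cavity and support the repair."
- step: 27
  phase: 3
  category: core
  statement: "Debris was cleared from the nasal cavity and choana."
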