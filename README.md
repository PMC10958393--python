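# opnote

**Surgical-workflow recognition to automated operation notes for
endoscopic pituitary surgery videos.**

Operation notes are the written record of a surgery, and writing them by
hand under clinical time pressure makes them error-prone and incomplete.
When the surgery is recorded — endoscopic pituitary surgery is captured
end-to-end by the endoscope itself — the steps actually performed can be
detected from the video and turned into a draft note automatically.

`opnote` implements a three-stage architecture for deciding which of 27
consensus-defined surgical steps (anatomical landmarks, actions and
instrument uses, grouped into nasal / sellar / closure phases) are present
in a video, and for rendering the result into a structured operative note:

1. **Frame classification** — one binary classifier per step scores every
   1 fps frame with a probability that the step is visible.  The
   classifier is a pluggable contract; a deterministic mock with
   configurable noise and *flicker* stands in for a CNN so the later
   stages can be exercised without one.
2. **Discriminators (video classification)** — each step's frame sequence
   is reduced to a scalar *discrimination number* δ and the step is
   predicted present in the video iff **δ ≥ τ**, the *discrimination
   threshold*.  Six families are provided: the count of positive frames
   (*binary integer*), the sum of frame probabilities (*probability
   integer*), the longest consecutive positive run (*chain integer*), and
   each divided by the frame count (*binary / probability / chain
   fraction*).  τ is fitted per step by linear grid search from 0,
   maximizing the support-weighted F1

       wF1 = (n₊·F1₊ + n₋·F1₋) / N

   of the resulting video classifications, with ties broken toward the
   smallest τ.  Intersection/union ensembles of two fitted families are
   supported.
3. **Accumulator (multi-label coherence)** — clinical reliance rules flip
   positive predictions that contradict the rest of the vector (e.g.
   "confirmed using neuronavigation" cannot stand without the sellar
   landmarks being identified).  Rules are applied in one simultaneous
   pass reading the original predictions; an iterate-to-fixed-point
   variant is available.

The note renderer assembles the detected steps' statements — including a
bracket-continuation grammar that splices dependent statements into their
parent sentence and a shared statement for the joint sellar-landmark pair
— into an RCS-style note (basic information, surgical procedure,
post-operative plan) enriched with a 3-phase duration chart, as Markdown
plus a machine-readable JSON twin.  A synthetic-video simulator generates
datasets with the statistical shape of a real annotated collection
(lognormal video lengths around a 74-minute median, core ≫ optional /
instrument step presence, 1–11-minute step durations, frame-score noise
and flicker) so the whole pipeline runs end-to-end with no data download.

## Worked example

`examples/02_render_note.py` builds a prediction vector, applies the
accumulator and renders the note:

```
accumulator flipped steps: ['S11']
...
### Nasal phase

The middle and superior turbinates were laterally displaced using a freer elevator.
The sphenoid ostium was identified and opened using Kerrison's rongeurs.
The sphenoid sinus was opened, with removal of sphenoid septations to expose
the face of the sella. A high-speed drill was required to achieve this.
...
## Video analytics

- Nasal phase: 20.0 min
- Sellar phase: 40.0 min
- Closure phase: 15.0 min
- Total: 75.0 min
```

S11 ("confirmed using neuronavigation") was predicted by the
discriminator but flipped by the accumulator because neither S09 nor S10
(sellar landmark identification) was positive.  The S02 sentence shows
the continuation grammar: S03's fragment "and opened using Kerrison's
rongeurs" is spliced into S02's statement because both were detected.

`examples/03_fit_discriminators.py` fits all six families on a small
noisy synthetic collection (40 videos, 2% flicker) and scores 8 held-out
videos:

```
mean test weighted-F1 across the 27 steps:
  binary_integer         0.829 ± 0.185
  binary_fraction        0.996 ± 0.022
  probability_integer    0.716 ± 0.196
  probability_fraction   0.964 ± 0.074
  chain_integer          0.990 ± 0.035
  chain_fraction         1.000 ± 0.000
```

Fraction families divide δ by the video length and therefore tolerate the
wide spread of video durations; integer families share one absolute
threshold across short and long videos and score lower — the ordering the
method is designed around.

## Command line

```sh
opnote simulate --out data/ --n-videos 97 --seed 0      # synthetic dataset
opnote run --data data/ --out results/ --family probability_fraction
opnote fit / predict / accumulate / render / evaluate   # individual stages
```

`opnote run` fits on the 77 training videos, classifies the 20 held-out
videos, applies the accumulator, writes one Markdown + JSON note per test
video and an evaluation table (per-step weighted F1, mean ± sd across
steps, both stages and splits).

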