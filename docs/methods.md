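# Methods

## Model

The network is a perception-coordination hierarchy with three neuron
kinds. A *feature neuron* is a prototype `{w, σ}`; its activation function
is the indicator `‖y − w‖ ≤ θ` (Euclidean areas) or `dtw(y, w) < θ`
(syllable areas, where `w` is a stored MFCC/coefficient template and the
distance is classic boundary-matched monotone DTW with per-frame Euclidean
cost and unit steps). `σ` counts activations and drives the only weight
rule in the system, the winner-take-all incremental mean
`σ ← σ+1, w ← w + (y − w)/σ`, which keeps `w` equal to the arithmetic mean
of everything the neuron absorbed. A *concept neuron* fires when all its
connected feature neurons fire — as a set for visual concepts, as an exact
sequence for words (the sequence must match in length and order; a longer
utterance is a different word). An *association neuron* fires when any one
of its connected concepts fires; its connections are counted triples
`c_(m,i,n)` binding two concepts of different channels through the hub.

Weights of a feature neuron are an **ordered list of groups**. Group 0 is
the original receptive field and is never re-dimensioned; receptor
expansions append native groups; embedded modalities append tagged groups
with their own activation counters. All distances and updates address an
explicit group selection (original / native / embedded), which is what
makes the non-hijacking guarantees testable as bit-identity rather than
as approximate stability.

### Dimensionality increase

When a stage adds `m` receptors to an `n`-receptor channel, each sample
splits into `(y_I, y_II)`. Winner A is the arg-min over *all* area neurons
in the original space; winner B is the arg-min over already-expanded
neurons in the full space. If B fires, it absorbs the full vector (B
inhibits A). If only A fires and A has not expanded, A absorbs `y_I` and
appends a group initialised to `y_II`. Otherwise a full-dimension neuron
`{(y_I, y_II), 1}` is created. One deliberate refinement: an
already-expanded A whose full-space activation fails falls through to
creation rather than expanding twice — this is exactly what splits the
confusable pair into two trichromat colour neurons while a second
expansion would be ill-defined.

### Association and channel expansion

Binding a concept pair follows four cases on the hub sets reachable from
each concept: both empty → one new hub with a 1-to-1 circuit; only one
side known → a user question (accepted: connect through every hub of the
known side; declined: a rejected name is dropped, a rejected view is kept
alone on a fresh single-link hub); both known with a common hub →
strengthen the common connections (`ρ+1`); both known but disjoint → ask,
and on acceptance connect through the union of hubs. When an entirely new
channel joins, the same four cases run *without* questions — existing hubs
simply grow synapses to the new channel's concepts, which immediately
gives a reverse pathway (the hub then fires from the new channel alone).
Questions are routed through an oracle object (scripted list, synthetic
ground truth, or interactive prompt) so batch runs are reproducible.

### Modality embedding

An exogenous sample `x_e` reaches its host through a guidance signal
`x_g`: `x_g` is matched in the guidance channel (inference only), the
activated hubs descend through the target channel's concepts to the host
feature area. Hosts gain a tagged group initialised to `f_exog(x_e)`;
later samples update it with `w ← w + δ(f_exog(x_e) − w)`. Both the
`δ = 1/σ` rule (default, the incremental mean) and a fixed-`δ` rule are
provided. When the guidance activates several hosts, all of them are
embedded by default (a config flag restricts to the lowest-id host).
Embedded groups are evaluated with their own threshold and distance
(absolute DTW threshold 9 for ultrasonic sequences).

## Feature extraction

* **Shape** — the object mask's pixel-edge ("crack") boundary is resampled
  to 256 points by arc length and Fourier-transformed as a complex signal;
  the descriptor is the magnitudes of harmonics `+1, −1, +2, −2, …`
  (32 by default), DC dropped, scaled by the dominant first harmonic.
  Magnitudes give rotation/start-point invariance; the scaling gives scale
  invariance. The crack boundary (rather than an iso-level contour) is
  used because it is an exact similarity under integer mask upsampling,
  making scale invariance exact instead of approximate.
* **Colour** — per-channel histograms (8 bins each) over mask pixels,
  each channel block normalized to sum to 1 independently so a newly added
  receptor appends a block without rescaling old dimensions; channels
  ordered grey, G, B, R as they become available.
* **Audition** — syllable endpointing by short-time energy (25 ms frames,
  10 ms hop) with zero-crossing refinement of run edges; 12 MFCCs per
  frame (pre-emphasis 0.97, Hamming window, 26 mel filters, orthonormal
  DCT-II, energy term kept as coefficient 0). Matched syllable templates
  are frozen (only `σ` increments): an incremental mean is undefined
  across variable-length alignments.
* **Gustation** — flavour vectors (sweet, sour, bitter, salty, umami) pass
  through unchanged.

## Parameters

| parameter | default | meaning |
|---|---|---|
| shape / colour threshold | ¼·‖w‖₂ (relative) | response range of visual feature neurons, resolved against the current weight norm at match time |
| audible syllable threshold | 200 (DTW, absolute) | match-or-create boundary for MFCC templates |
| ultrasonic threshold | 9 (DTW, absolute) | same, for coefficient-sequence templates |
| flavour threshold | 0.015 (absolute) | basic-flavour neuron response range |
| descriptors / bins / MFCCs | 32 / 8 / 12 | feature dimensionalities |
| edge max age | 50 | competitive-Hebbian edge pruning horizon |
| passes per stage | 2 | presentations of the object list per stage |
| δ (embedding) | 1/σ | embedded-group learning rate |

The thresholds are the study settings; the feature dimensionalities and
the window/hop sizes are conventional speech/vision defaults and live in
`RunConfig`.

## Synthetic world

The generator emulates the staged study conditions: ten presentations of
nine objects. Shapes are radial-cosine blobs `r(φ) = R(1 + A cos mφ)`
with a distinct harmonic order `m ∈ {2, …, 10}` per object (`A = 0.45`,
`0.35` for the pair), which keeps Fourier descriptors far apart; jitter is
rotation and ±8 % scale (both invariant for the descriptor) plus pixel
discretization. Colours are constant planes at histogram-bin centres with
σ = 0.02 pixel noise. The first two presentations are a bright and a dark
view of one object: same shape, same grey/G/B levels, different R — they
share one audible and one ultrasonic name and carry two flavour variants,
so the dichromat stages merge them and only the R receptor separates
them. Audible names are two harmonic bursts (token-keyed base frequency,
geometric spacing 300 Hz·1.28^i, Hann envelope, σ = 0.003 noise) separated
by silence; ultrasonic names are token-keyed coefficient-sequence
prototypes (deterministic per token) with σ = 0.05 noise, emitted directly
in feature space. Flavour samples are the spec vector plus σ = 0.002
noise, clipped non-negative; the noise scale was calibrated once so that
within-object distances stay well below the 0.015 flavour threshold at any
seed (the separability guarantee below), while learned flavour weights
still approximate the spec values.

**Separability guarantee.** With default noise, for every channel:
within-object feature distance < area threshold < between-object distance.
A calibration test asserts this directly. Everything the end-to-end tests
show therefore concerns the *mechanisms* (expansion, binding, embedding,
stability) under separable inputs; the generator does not emulate
occlusion, lighting, speaker variation, or any overlap structure that
would make the match-or-create rule itself fail on real data.

## Numerical and design choices

* Arg-min ties break toward the smaller neuron id; ids are global
  monotone integers; areas are created lazily when a channel first
  appears. Together these make a run a pure function of (config, seed):
  two identically-seeded runs serialize byte-identically.
* Euclidean activation is inclusive (`≤ θ`), DTW activation strict
  (`< θ`), following the respective decision rules' conventions.
* Relative thresholds resolve against the current `‖w‖₂` of the weight
  group being tested, at match time.
* A concept activated together with features of an area it has no links in
  grows links to them (concept-level synapse growth); matching tests only
  the areas present in both the concept and the event set. This keeps
  earlier-stage (partial) inputs activating their concepts after the
  system has grown — without it, replaying a grey-only sample after the
  colour stage would spawn a duplicate shape-only concept.
* When a partial input matches several expanded neurons whose
  original-space prototypes lie within each other's threshold (the
  confusable pair after the split), its attribution between them is
  genuinely ambiguous; replay-stability checks therefore assert exact
  doubling of `σ`/`ρ` everywhere except inside such twin groups, where the
  group sums double exactly.
* Serialization is a single sorted-key JSON document (schema-versioned);
  arrays round-trip exactly through Python float repr.

## Known limitations

* Syllable templates never average; a drifting pronunciation would
  eventually fall outside the frozen template's threshold.
* Embedding has no novelty check: two different exogenous patterns guided
  to the same host average into a mixture that may match neither. The
  world avoids this by giving the two confusable views one shared name.
* Self-organization edges are topology metadata only; they never gate
  activation.
* No forgetting, merging or splitting of neurons; counters only grow.
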