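# craet

An online multimodal learning network whose neurons can **grow new
synapses at run time**. It models how a perceptual system absorbs three
kinds of extension without retraining and without disturbing what it
already knows:

1. **new sensory receptors in an existing channel** — e.g. a colour-blind
   visual system gaining green/blue and later red receptors: feature
   neurons extend their weight vectors from `R^n` to `R^(n+m)`
   (*dimensionality increase*),
2. **a whole new perceptual channel** — e.g. audition or gustation coming
   online: multimodal association neurons grow connections to the new
   channel's concepts (*response-modal expansion*), and
3. **a guided exogenous modality** — a signal with no receptor of its own,
   routed by a guidance cue to host neurons that store it in a dedicated
   synapse group (*modality embedding*).

It is aimed at computational-neuroscience and lifelong-learning work where
the question is not "how well does a fixed architecture fit" but "can a
running system integrate channels it was never built for".

## The model

The network is hierarchical and modularised:

* **Feature neurons** `N_i = {w_i, σ_i}` in primary sensory areas fire when
  an input feature `y` satisfies `D(y, w_i) ≤ θ` (Euclidean distance for
  shape / colour / flavour vectors, dynamic time warping for syllable
  templates). Learning is match-or-create: the arg-min winner within `θ`
  absorbs the input by the winner-take-all incremental mean
  `σ ← σ+1, w ← w + (y − w)/σ`; otherwise a new neuron `{y, 1}` records it.
  Areas also keep a competitive-Hebbian edge map (winner/runner-up edges
  with aging) as topology metadata.
* **Concept neurons** in unimodal association areas are AND-circuits over
  feature neurons — order-independent for visual concepts (shape + colour),
  order-dependent for words (syllable sequences).
* **Association neurons** in the multimodal area are OR-hubs binding
  concepts across channels through counted connection triples
  `c_(m,i,n) = {N_m, N_i^A, N_n, ρ}`. Binding follows a four-case logic on
  which of the two concepts already reaches the hub level; ambiguous cases
  ask a yes/no question (answered by a scripted list, the synthetic ground
  truth, or interactively).

When a stage adds receptors, the four-case **dimensionality-increasing
step** routes each input between the original space and the extended
space, expanding a familiar neuron's weights as `w_a ← (w_a, y_II)` —
group 0 is never rewritten, so responses computed on the original synapses
are bit-identical before and after (the *non-hijacking* property). The
same principle applies at the hub level (Eq.-style channel expansion) and
for embedded modalities (a separate synapse group with its own counter,
updated by `w ← w + δ (f_exog(x_e) − w)`, `δ = 1/σ` by default).

Feature extraction uses normalized Fourier descriptors of the object
boundary (translation / rotation / scale / start-point invariant), per-
channel colour histograms over the object mask, short-time-energy +
zero-crossing syllable endpointing with MFCC features, and pass-through
flavour vectors.

## Worked example

The staged protocol grows a sensory system on a synthetic world of ten
object presentations (nine objects; the first two are a bright and a dark
view of one pear-like object that differ **only** in the red channel):
grey images → +G/B receptors → +R receptor → audible names → ultrasonic
names → tastes.

```bash
craet train --seed 0 --network-out net.json --report-out report.json
```

prints

```
recall visual->auditory: 1.000
recall auditory->visual: 1.000
recall visual->gustatory: 1.000
recall gustatory->visual: 1.000
network saved to net.json
```

i.e. after one staged run, every concept recalls its counterparts in the
other channels perfectly, in both directions. Inspecting the circuit of
one association hub:

```bash
craet report --network net.json --assoc-id 60
```

```
association neuron 60
  [auditory]
    concept 57 (order_dependent)
      feature 55 in syllable (pos 0, rho 2, sigma 6, dim 276)
      feature 56 in syllable (pos 1, rho 2, sigma 4, dim 276)
    concept 131 (order_dependent)
      feature 129 in ultrasonic (pos 0, rho 2, sigma 4, dim 120)
      feature 130 in ultrasonic (pos 1, rho 2, sigma 4, dim 120)
  [gustatory]
    concept 174 (order_independent)
      feature 173 in flavor (pos 0, rho 2, sigma 2, dim 5)
  [visual]
    concept 29 (order_independent)
      feature 28 in shape (pos 0, rho 12, sigma 12, dim 32)
      feature 45 in color (pos 1, rho 10, sigma 10, dim 24)
  connections:
    29 <-> 57 (rho 2)
    29 <-> 131 (rho 2)
    29 <-> 174 (rho 2)
```

one object's full cross-modal circuit: its visual concept (shape + colour
features), its audible and ultrasonic names, and its taste, all bound
through one hub whose `ρ`/`σ` counters record every activation. The other
subcommands: `craet gen` writes the synthetic world to disk
(PNG/WAV/CSV + manifest), `craet embed` plants exogenous samples into host
neurons via guidance signals, `craet recall` ranks cross-modal recalls.

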