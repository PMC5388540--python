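# objcode

Analyses of transformation-tolerant object coding in visual cortical
spiking data, implemented end to end and exercised on synthetic
recordings.

## The problem

Along an object-processing (ventral-like) visual pathway, neurons are
expected to (1) shed low-level information about the luminous energy a
stimulus drops into their receptive field (RF), and (2) gain the
ability to signal object *identity* across identity-preserving
transformations — position, size, rotation and luminance changes.
Quantifying both trends from spike counts requires careful machinery:
stimulus-energy metrics built from measured RFs, mutual-information
decompositions that disentangle correlated stimulus attributes, and
decoders that distinguish *linear separability* of two objects' view
sets from true *generalization* to untrained views.  This package
implements that machinery for a standard experimental design — a
battery of 10 objects x 38 views (380 conditions) shown under a
tangent-screen projection, ~26 trials per condition, spike counts in
150 ms windows — together with a Poisson spiking simulator that
generates area-graded synthetic populations (V1-like through LL-like)
so every stage is testable without recordings.

## What is computed

For a neuron with response R (spike count, discretized into three
equi-populated bins) and stimuli S:

* **Total stimulus information** I(R;S) = Σₛ P(s) Σᵣ P(r|s) log₂ P(r|s)/P(r),
  over the neuron's 230-condition subset (23 views x 10 objects).
* **Energy decomposition** I(R;S) = I(R;L) + I(R;S′|L), where L is the
  *RF luminance* — the stimulus image weighted by the neuron's raw RF
  map, normalized to the full-field maximum, discretized into 23
  equi-populated bins.  The fraction of energy-independent information
  is f_high = I(R;S′|L) / I(R;S).  An analogous decomposition uses
  *RF contrast* C (SD of RF-weighted luminances inside the RF).
* **Invariance decomposition** I(R;S) = I(R;O) + I(R;T|O) for object
  pairs, where I(R;O) pools all views of each object into a single
  response distribution (view-invariant object information).
* All information terms are corrected for limited-sampling bias with
  the asymptotic term BIAS = [Σₛ(Rₛ−1) − (R−1)] / (2N ln2), and tested
  against permutation nulls.
* **Single-cell decoding**: a quadratic-discriminant threshold r_th
  (zero of the Gaussian log-posterior ratio) classifies counts as one
  of two objects; 5-fold cross-validated separability, train-one-view
  generalization (overall, per transformation axis, and parametrically
  along position and size), with matched chance controls that shuffle
  object labels only *within* each transformation.
* **Population decoding**: pseudo-population vectors (N units, M
  sampled trials per condition, 19 aligned views per object) read out
  by linear SVMs (C = 1): 5-fold separability, exhaustive 19x19
  train-view generalization, and an arbitrary-group control.
* **Screening and statistics**: visually-driven and
  stimulus-informative unit selection, response-latency estimation,
  spike-isolation quality subsetting, medians +/- bootstrap SE and
  1-tailed Mann-Whitney area comparisons with Holm-Bonferroni
  correction.

Pairs of objects enter the decoding/invariance analyses only when the
ratio of their mean RF luminances exceeds a threshold (ThLumRatio), so
that raw brightness differences cannot masquerade as invariant object
information.

## Worked example

```python
import numpy as np
from objcode import build_stimulus_set, simulate_session, single_cell_metrics
from objcode.simulate import DEFAULT_AREA_PROFILES, make_area_population

stimset = build_stimulus_set()                      # 380 object views
v1 = make_area_population(DEFAULT_AREA_PROFILES["V1like"], 1, seed=0)
ll = make_area_population(DEFAULT_AREA_PROFILES["LLlike"], 1, seed=0)
recs = simulate_session(stimset, v1 + ll, n_trials=26, seed=0)

for rec in recs:
    m = single_cell_metrics(rec, stimset, th_lum_ratio=0.7, seed=0)
    print(f"{m['neuron_id']}: I(R;S)={m['I_RS']:.3f} bits, "
          f"f_high={m['f_high']:.2f}, "
          f"separability={m['separability_net_info']:.3f} bits, "
          f"generalization={m['generalization_net_info']:.3f} bits "
          f"({m['n_pairs']} pairs)")
```

prints

```
V1like-000: I(R;S)=0.432 bits, f_high=0.07, separability=0.009 bits, generalization=0.007 bits (24 pairs)
LLlike-000: I(R;S)=0.235 bits, f_high=0.93, separability=0.118 bits, generalization=0.116 bits (21 pairs)
```

The V1-like unit carries more total stimulus information but almost
all of it is luminance-driven (f_high = 0.07) and it barely supports
luminance-controlled object discrimination.  The LL-like unit carries
less total information, but it is almost entirely energy-independent
(f_high = 0.93) and supports an order of magnitude more
chance-subtracted decoding, with generalization nearly equal to
separability — the signature of a transformation-tolerant identity
code.

A `click` CLI mirrors the library
(`objcode simulate | screen | info | suite | report`); see
`objcode --help`.

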