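# Methods

This note records the scientific and numerical choices behind the package:
what each stage assumes, which knobs matter, and what the synthetic
benchmark does and does not establish.

## Problem setting

The target is binary emotional arousal: class 0 (low — neutral, calm, sad)
versus class 1 (high — happy, angry, fearful, disgusted, surprised).
Inputs are multimodal time series on a shared 10 ms grid: per-channel
audio band energies from stereo speech and facial blendshape activation
tracks. The pipeline is a spiking reservoir shaped by a brain template:
rather than learning an input embedding, it *places* features at
anatomically motivated positions and lets distance-dependent recurrent
dynamics plus spike-timing-dependent plasticity (STDP) turn temporal
structure into spatial activation patterns that a simple classifier can
separate.

## Feature extraction

* **Banks.** Per audio channel: 40-band log mel spectrogram (default),
  12-band mel-FFT, 12-band linear-FFT, or 12 MFCCs; all over 50–8000 Hz,
  hop 10 ms. The window is 25 ms Hann — standard speech framing; only the
  10 ms hop is pinned by the multimodal grid. Mel filters
  are HTK-scale (mel = 2595·log10(1 + f/700)) triangles; log compression
  is log(1e-10 + E), so silence sits at a finite floor. MFCCs are DCT-II
  cepstra c1..c12 of a 26-filter log mel bank.
* **Auxiliary descriptors** (for inspection/visualisation, not fed to the
  reservoir): per-frame RMS energy, amplitude-weighted spectral centroid,
  L2 spectral flux, and summed energy below 345 Hz (fundamental and lower
  harmonics).
* **Blendshapes.** The canonical schema is the 52-name ARKit blendshape
  set in a fixed face-region order (brow, eye, cheek, nose, jaw, mouth,
  tongueOut). It contains no separate "neutral" channel: the standard
  52-coefficient set already sums to 52 without one, and a neutral
  baseline carries no movement information. Values are clipped to [0, 1]
  and duplicated into identical left/right copies (the mapping is
  bilateral; no lateral asymmetry is modelled).
* **Synchronisation** truncates both modalities to the shorter duration
  and stacks audio rows before visual rows (80 + 104 = 184).

## Step-Forward encoding

Per feature, baseline B starts at the first sample; x(t) > B + θ emits +1
(B += θ), x(t) < B − θ emits −1 (B −= θ), else 0 — strict inequalities,
and at most one spike per step even when the deviation exceeds 2θ. These
conventions make the tracking bound provable: if per-step changes never
exceed θ, the decoded signal (baseline plus cumulative θ-weighted spikes)
stays within θ of the original for all t (induction on the step).

θ defaults to 0.5 × the feature's training-set standard deviation
(floored at 1e-6): θ is a free parameter of the encoder, and per-feature
scaling keeps spike rates comparable across bands with very different
dynamic ranges. Reconstruction fidelity is reported as normalised MSE —
per-feature MSE divided by the variance of the original (not signal
power; 0/0 ≡ 0), averaged over features.

## Brain template and connectivity

* **Geometry.** Neurons live in two mirrored hemispheric half-ellipsoids
  (semi-axes 72 × 92 × 62 mm, centre (0, −16, 4), a 2 mm interhemispheric
  gap) in MNI-like axes. STS boxes per hemisphere: |X| 28–60, Y −62..−42,
  Z −11..16 mm. A1 boxes: |X| 35–55, Y −38..−8, Z 0..14 mm — an elongated
  Heschl-like slab whose long axis supports the principal-component
  tonotopic gradient; the box is the package's own reading of "A1 on the
  superior temporal plane", drawn to be anatomically plausible rather
  than taken from an atlas.
* **Stratified sampling.** Uniform sampling of 3108 points in a
  brain-sized volume would leave each A1 box with ~15 neurons — too few
  for 40 bands. The per-region counts are therefore a package choice:
  a quota per region (2 % of n per A1 hemisphere,
  2.6 % per STS hemisphere; floors 40 and 52) is sampled uniformly
  inside each box and the remainder uniformly in the half-ellipsoids.
* **Connectivity.** Directed edge i→j with probability
  p₀·exp(−d²/σ²), σ = 15 mm. p₀ is calibrated (bisection; closed form
  when no clipping binds) so the expected density of nonzero directed
  connections is 0.4 % — the centre of the 0.3–0.5 % operating band; the
  binomial fluctuation at n = 3108 is ~0.002 percentage points, so
  realised densities stay well inside the band. 20 % of neurons are
  inhibitory (the usual excitatory/inhibitory convention in this family
  of reservoir architectures); all outgoing weights of a
  neuron share its sign, with magnitudes uniform in [0.05, 0.25].
  Distances are Euclidean in mm, no periodic boundary, no
  self-connections.

## Input mappings

* **Tonotopic (audio → A1).** Per hemisphere: PCA principal axis of the
  A1 cloud, neurons projected to u ∈ [0, 1], folded to τ = |2u − 1|. The
  cortical frequency gradient is mirror-symmetric (high → low → high
  along Heschl's gyrus), so band 1 (≈50 Hz) targets τ = 0 (the centre)
  and band 40 (≈8 kHz) targets τ = 1 (the ends). Bands greedily take the
  free neuron nearest their evenly spaced τ target, in band order, ties
  to the lower index. Left-channel bands occupy mapping slots 1–40,
  right-channel bands 41–80. A one-neuron-per-band mapping cannot be
  simultaneously "evenly spaced on the gradient" and "low at centre, high
  at ends" on an unfolded axis; the folded-axis reading reconciles the
  two and is a design decision, not a claim about any other
  implementation.
* **Topographic (visual → STS).** Blendshapes ordered by facial height
  class (brow > eye > nose > cheek > mouth > jaw/tongue, stable within
  class); STS neurons per hemisphere sorted by Z descending; rank-to-rank
  assignment, identical ordering in both hemispheres. Dorsal neurons thus
  encode upper-face, ventral neurons lower-face movements.

## Reservoir dynamics and STDP

Leaky integrate-and-fire per 10 ms step: v ← λ·v + synaptic input +
input injection, fire at v ≥ θ_f, reset, refractory. Defaults: threshold
0.5, leak λ = 0.9, refractory 1 step, reset 0, input gain 0.6 — chosen so
one input spike (0.6) alone crosses threshold and modest recurrent input
sustains propagation. Negative
input spikes inject negative current (the signed-event stream stays
scalar; the positive/negative separation is recovered at state-vector
level by split counts). Synaptic transmission has a one-step delay.

STDP: A₊ = A₋ = 0.01, τ₊ = τ₋ = 2 steps (20 ms), nearest-neighbour
pairing, w_max = 1. The coincident case t_pre = t_post is undefined in
the exponential form; this implementation takes the potentiation limit
+A₊. Updates change magnitudes only — the sparsity pattern is fixed at
initialisation, and clipping preserves each pre-synaptic neuron's sign
class ([0, w_max] excitatory, [−w_max, 0] inhibitory). Training is
incremental (weights carry across samples, one pass by default), so the
final cube depends on sample order; recall mode never modifies weights
and is bit-reproducible.

## State vectors and classification

Extraction rules as in the README; the DeSNN modulation exponent is the
neuron's **first-spike timestep** (0-based), not its rank among neurons —
"timing of its first spike" is read literally; the rank-order reading is
a known alternative. A silent neuron contributes −d_down·T.

Before classification, state vectors are z-scored per feature with
training statistics (spike counts and DeSNN values have heterogeneous
scales) and classes are balanced by duplicating minority-class training
samples. The learned prototype initialises at the class centroids — so 0
epochs reproduces the centroid classifier exactly — and refines them by
full-batch Adam (lr 0.01, 300 epochs) on the cross-entropy of cosine
similarities at temperature τ = 0.1, re-normalising after every step;
cosine similarity is used throughout the prototype family. Optional
seeded Gaussian init jitter (default 0) provides the randomness for
multi-seed stability sweeps, summarised as mean ± sample std with a
normal-approximation 95 % CI (1.96·std/√n; the t-based alternative
differs negligibly at 30 seeds). WWKNN uses k = 5 and floors within-class
variance at 1e-8. Default confidence thresholds: 0.65 visual, 0.55
audio, 0.60 multimodal. Report percentages are rounded half-up to one
decimal; with every sample rejected, selective accuracy is undefined and
reported as a null sentinel.

## Explainability

Association counts are computed on the **input-channel** rasters at lag
1 (10 ms), diagonal excluded; reservoir-level association is out of
scope. The ten mel groups are contiguous 4-band spans of the 40-band mel
axis — an even split of the mel scale, with the resulting Hz boundaries
recorded in the group labels (the lowest spans ≈50–310 Hz). Face groups: brow, eye, cheek/nose, jaw, upper-mouth,
lower-mouth (tongueOut with lower-mouth). For class comparison, each
class's edge weights are normalised by its total count before
differencing, so classes with different overall spike budgets remain
comparable.

## Synthetic data: what it emulates, what it does not

The generator emulates the *statistical shape* of the real inputs: a
smooth 1/f-like baseline log-energy decay over mel bands, a shared slow
utterance envelope, AR(1) temporal noise (ρ = 0.8, sd 0.5), left/right
channels as common signal plus small independent noise, and blendshape
tracks as sums of 2–5 smooth bumps clipped to [0, 1]. The class contrast
is a +2-noise-SD log-energy offset on the upper half of the mel bands
(high-arousal speech carries relatively more high-frequency energy) and
a 1.5× amplitude multiplier on mouth-region blendshapes. Samples default
to 3.5 s.

It does **not** emulate: actor/speaker identity structure, class
imbalance, phonetic content, pitch contours, co-articulation between
audio and face, or visual left/right asymmetry. Passing end-to-end tests
therefore demonstrates that the machinery — encoding, mapping, reservoir,
state extraction, selective classification — preserves and recovers a
planted class signal at realistic dimensionalities; it does not certify
accuracy on recorded emotional speech.

## Problem sizes used in tests

The default reservoir is 3108 neurons (used for all geometry, mapping and
density checks). End-to-end classification tests run a reduced
configuration — 800 neurons, 300-step samples, 100 training / 60 test
samples (200 test samples for the label-shuffle control, averaged over
10 permutations) — chosen as the smallest setting at which every region
quota, both mappings, and the full training/recall loop are exercised.
The shuffle control refits only the classifier: STDP is unsupervised, so
shuffled labels cannot change the reservoir stage.

## Known limitations

* The LIF/STDP constants are package defaults; absolute spike rates and
  weight trajectories are therefore not comparable across
  implementations, only the qualitative LTP/LTD and density properties.
* The greedy tonotopic selection is optimal only when τ targets are well
  separated relative to neuron spacing (always the case at the default
  region quotas); it is not a global assignment solver.
* Incremental STDP makes training order-dependent by design; only recall
  is order-free.
* The "DeSNN connection-weights" hybrid state-vector variant and full
  from-scratch SVM training are intentionally out of scope.
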