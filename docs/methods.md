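# Methods

This note records the models, conventions and numerical choices behind
`cardiocs`, and what the synthetic studies do and do not establish.

## Signal model and segmentation

The package assumes a single-lead ECG sampled at `fs` Hz (360 Hz throughout
the defaults) quantised at 11 bits/sample. Two framings feed the two
compression schemes:

* **Raw frames** (PSCCS): consecutive, non-overlapping 300-sample slices.
  300 samples ≈ 0.83 s, roughly one beat at ~70 bpm, but frames are not
  aligned to beats — the R wave may sit anywhere or be absent. A trailing
  remainder shorter than one frame is discarded.
* **Cardiac patterns** (CPCS): beat *i* spans
  `[mid(R_{i-1}, R_i), mid(R_i, R_{i+1})]` (inclusive raw-sample bounds) and
  is cubic-spline-resampled to 301 samples. The first and last beats lack an
  adjacent half-interval and are dropped. The R location inside the pattern
  is the raw R index mapped through the affine span→[0, 300] map, rounded to
  the nearest integer.

**R-wave centering.** A pattern is optionally re-centered by resampling
`x[0..r]` onto 151 samples and `x[r..300]` onto 151 samples sharing the R
knot, so the R peak lands on index 150 (sample 151, 1-based). The knot value
is preserved exactly (splines interpolate their endpoints); the transform is
inverted from the stored left/right segment lengths. The binding contract is
the measured round-trip error — at most 1% of the peak amplitude on
synthetic beats — not the choice of interpolant. Centering cannot guarantee
that the *discrete* maximum of the centered pattern is exactly at 150: a
narrow R peak resampled onto the 301 grid sits up to half a sample off, and
a wide flat peak on a noisy beat can put the discrete max one sample aside.
Tests therefore assert the knot amplitude dominates the segment maximum to
within this discretisation rather than an exact argmax.

**R detection** is a Pan-Tompkins-style pipeline: 2nd-order Butterworth
band-pass 5–15 Hz (zero-phase), derivative, squaring, 150 ms moving-window
integration, then peak picking with a 0.2 s refractory period and a
threshold at 25% of the upper quartile of candidate peak heights (anchoring
on the upper quartile keeps the threshold inside the QRS cluster rather
than among P/T-wave candidates). Detections are refined to the raw-signal
maximum within ±100 ms. Any detector meeting the scored sensitivity/PPV
property (≥ 0.99 on noisy synthetic beats) is interchangeable; annotation
pass-through is available for exact reproduction on annotated records.

## Dictionaries and sensing matrices

All reconstruction dictionaries are overcomplete (atoms ≥ frame length) and
their columns are ℓ2-normalized by default; the original norms are kept, so
reconstructions are on the original amplitude scale (the coefficients absorb
the norms) and an unnormalized build is available for replication studies.
Undercomplete dictionaries are permitted for diagnostics but logged. Every
builder records which frames/beats it consumed so test sets are drawn
strictly from the remainder; the pipelines assert this disjointness on each
run.

Sensing matrices: (i) i.i.d. standard Gaussian; (ii) 0/1 Bernoulli(p = 0.5)
with palindromic rows — for odd N the centre entry belongs to the generated
half — with all-zero rows redrawn and no rescaling or centering of entries;
(iii) dictionary-optimized, `Φ_opt = Φ · Dᵀ`, where `D` is an N×N matrix of
N distinct atoms drawn uniformly without replacement (indices kept in atom
order, so selecting every atom of an N-atom dictionary reduces to `Φ·Ψᵀ`); a
selection singular to working precision is redrawn once. The measurement
counts for the nominal compression labels are m = 75, 30, 20 for 4:1, 10:1,
15:1 on 300-sample frames; the same row counts are used for 301-sample
patterns, whose bit-count CR is then 301/20 ≈ 15.05 under the "15:1" label —
reported CR always comes from bit counts, never from the label.

## Basis pursuit

Reconstruction solves `min ‖α‖₁ s.t. Θα = y` with `Θ = Φ·Ψ` formed
explicitly (at most 75 × 1472), as a linear program via the positive/negative
splitting `α = α⁺ − α⁻`, solved by HiGHS through
`scipy.optimize.linprog` with feasibility tolerances of 1e-8. The equality
form assumes noiseless measurements. A relaxed mode replaces the equality by
per-measurement bounds `|y − Θα|_i ≤ ε/√m`, which keeps the problem linear
while guaranteeing `‖y − Θα‖₂ ≤ ε`; it is intended for noisy field records
and is off by default. Solver failures raise with the attained residual —
never a silent NaN.

Measured behaviour of the solver core (frozen in the test suite): 1-sparse
signals at m = 20, N = 300, 700 Gaussian atoms are recovered to PRD ≤ 0.1%;
3-sparse supports are recovered exactly in ≥ 48/50 trials at m = 60; on
instances small enough to enumerate (12 atoms), the BP objective never
exceeds the best exact-feasible sparse solution found by brute-force support
enumeration. Note that 3-sparse recovery at m = 20 is *not* reliable
(~70–75% observed), consistent with `m = O(k log(N/k))` having unfavourable
constants at this size; properties are asserted only in the regimes that
hold.

## Classification

* **alpha-max**: the beat class is that of the mega-dictionary atom with the
  largest |α̂|; ties break toward the lowest atom index; an all-zero α̂ is an
  explicit "unclassifiable" outcome, and the pipeline then falls back to the
  mega-dictionary reconstruction.
* **KNN** (default k = 1, Euclidean): trained either on the compressed
  mega-dictionary atoms (to pick the class dictionary before reconstruction)
  or on the raw atoms (to grade reconstructed beats). A model trained under
  one sensing matrix refuses measurements from another.
* **MLP**: one hidden layer of 10 units, SGD backpropagation, learning rate
  0.01, at most 500 epochs, seeded initialisation; non-convergence warns but
  returns the model. Accuracy properties are asserted only on separable
  synthetic data.

## Synthetic data: what it emulates, what it does not

Templates are sums of Gaussian bumps (P/QRS/T stand-ins) on a canonical
301-sample grid with the R peak at index 150; eight classes differ in bump
layout, widths, amplitudes and polarity (wide-QRS, tall-T, deep-Q,
secondary-R′, absent-P, low-amplitude variants). R-bump widths are spread
geometrically and several classes carry polarity signatures so all 28
pairwise zero-lag correlations stay below 0.99. Records are built by
resampling template halves onto each beat's RR-dependent support — exactly
the inverse of the centering transform, making generator and preprocessing
mutually consistent — then adding a mixture of three sub-0.5 Hz sinusoids
(baseline wander) and i.i.d. Gaussian noise. Defaults: ~70 bpm
(`mean_rr = 60/70 s`), RR jitter SD 40 ms, noise SD 0.02 mV, wander
amplitude 0.05 mV, uniform class weights. RR draws are clipped away from
zero and a configuration whose 4σ jitter reaches a non-positive RR is
rejected.

The generator is deliberately *not* a physiological simulator: no dynamical
ECG model, no ectopic timing structure (class labels are i.i.d. rather than
rhythm-dependent), no electrode artefacts, single lead only. Passing tests
therefore establish the correctness and the comparative behaviour of the
pipeline (orderings of matrices, dictionaries, preprocessing), not clinical
performance on real arrhythmia recordings — absolute PRD levels on synthetic
beats at the reduced dictionary sizes are substantially higher than a
700-atom real-data study would give.

## Study conditions for the comparative suites

The seed-averaged ordering studies run at a reduced problem size chosen so
the whole chain still operates in its intended regime (overcomplete
dictionaries, disjoint train/test pools): balanced records of 8 × 350 beats,
mega-dictionary of 8 × 40 atoms, class-specific and patient dictionaries of
301–310 atoms, 24 test beats per configuration, ten seeds. Under these
conditions the asserted orderings are: dictionary-optimized Φ < Gaussian and
Bernoulli in mean PRD (fixed dictionary); centered < non-centered;
class-specific (oracle classes) < mega; PRD strictly increasing across
compression labels 4:1 → 10:1 → 15:1.

## Known limitations

* WFDB support is a minimal native reader/writer (header, signal formats 16
  and 212, MIT-format annotation reading); annotation writing and other
  signal formats are out of scope.
* The mega-dictionary builder requires all eight classes; records missing a
  class cannot use the mega/class-specific branches.
* Compression-ratio bookkeeping ignores the side information of the
  centering transform (two segment lengths per beat) and assumes equal bit
  depth for samples and measurements; no quantisation or entropy coding of
  the measurements is modelled.
* Basis pursuit forms Θ densely; fine at these sizes, not for much larger
  dictionaries.
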