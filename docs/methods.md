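# Methods

## The measurement model

Ghost motion imaging (GMI) measures a moving object compressively: a cell
flowing at constant speed crosses a static structured-illumination mask
`H` (flow extent `F` × lateral extent `W` pixels) while a single-pixel
detector integrates the transmitted (or scattered, or absorbed) light.
With the default geometry — exactly one pattern pixel of object translation
per sample, i.e. `sample_period = pitch / flow_speed` — sample `t` of the
waveform is

```
G[t] = gain * Σ_{i,j} I[i, j] · H[t − (h−1) + i, j] + background
```

where `I` is the cell's 2D contrast map (`h` × `w`, flow axis first) and
out-of-range mask rows contribute zero (the entry and exit of the cell are
recorded in full, so the waveform has `F + h − 1` samples).  This is the
column-summed 'full' discrete cross-correlation of mask and map: linear in
the object, shift-equivariant along the flow axis, and exactly checkable
against a brute-force double-loop sum — which the test suite and the
acceptance script both do.  The five modality names (dGMI, ssGMI, bsGMI,
fsGMI, bfGMI) differ only in which contrast map they read and which
independent pattern they use; the measurement math is shared.

Masks are i.i.d. Bernoulli(fill) binary patterns, default 128 × 32 at
fill 0.5.  The true optical transfer functions and pattern statistics of a
physical instrument are not modeled; Bernoulli masks are a declared
stand-in with the same compressive character.  A multi-fringe detector is
modeled as the average of `n_fringes` independent sub-masks.

Because the measurement is linear, stacking waveforms from several
independent patterns gives a linear system `A vec(I) = G`; the
`reconstruct` module certifies the forward model's information content by
recovering phantoms exactly (relative error < 1e-6) from at least
pixel-count rows, using dense least squares with optional Tikhonov ridge.
The classification pipeline never forms images — that is the point of the
method — but the certification shows the waveforms are image-equivalent.

## Cell phantoms

A phantom is a stack of small 2D maps on a 64 × 32 canvas at 0.5 µm/pixel:

* **transmission** — an elliptical cell body (major axis `diameter/pitch`
  pixels along flow) with a denser nucleus (area fraction
  `nucleus_fraction`, 1.5× density), scaled by `optical_density`;
* **scatter** — uniform within the support at half the body density;
* **absorption** — 0.8 × transmission;
* one **fluorescence** map per stain channel, normalized so the map total
  equals the stain amount exactly (labeling thresholds then act on stain
  chemistry, not cell size).

`granularity` applies unit-mean multiplicative gamma speckle (per-pixel
standard deviation = granularity) to transmission and scatter.  The
speckle is renormalized to conserve each map's total: texture redistributes
intensity inside the cell without changing its integral.  This is the load-
bearing design choice behind the separation benchmark — scalar channels
(map totals) are texture-blind by construction, while the waveform, which
samples the interior structure through the mask, is not.
`membrane_irregularity` perturbs the boundary radius with normalized
low-order harmonics (orders 3–6), the standard cytology correlate of
blebbing; apoptotic-like phantoms combine reduced diameter, raised
irregularity and raised granularity.

Phantoms are 2D projections; no z-structure, refraction, diffraction or
organelle realism is attempted.  Phantom realism is a stand-in for real
morphology, not a claim about it: passing benchmarks show the pipeline
recovers the structure the generator put in, not that real cell types are
separable.

All randomness is counter-seeded: event `i` of a population draws from
`SeedSequence(entropy=spec.seed, spawn_key=(i,))`, so identical specs give
bitwise-identical streams and single events can be regenerated in
isolation.

## Acquisition chain

Detection noise is scaled Poisson (photon budget `shot_scale` counts per
signal unit; measured value `Poisson(s·x)/s`) plus additive Gaussian read
noise.  The benchmark default is `shot_scale = 4`, `read_sigma = 0.5` —
roughly 5% relative shot noise at typical waveform amplitudes, enough to
blur per-sample values without drowning texture.

Every channel then passes a single-pole recursive high-pass
`y[t] = α(y[t−1] + x[t] − x[t−1])` with `α = 0.995` (time constant ≈ 200
samples), initialized with `x[−1] = x[0]`, `y[−1] = 0` so constant inputs
map to exactly zero from the first sample.  The trigger is the first run of
at least `trigger_min_run = 3` samples strictly above
`trigger_threshold = 5` on the filtered FSC channel; hysteresis and re-arm
dead time are not modeled.  A fixed 128-sample window starting 8 samples
before the trigger is cut from every channel of the event (common clock, so
channels stay aligned), zero-padded at the edges.  FSC pulse height, width
(samples above half height) and area feed the debris/doublet machinery;
programmatically merged doublets separate from singlets by width at
AUC > 0.95.  Each simulated phantom becomes exactly one event or one
counted dropout.

## Supervision and splits

Labels come from fluorescence thresholds (strictly greater than), exactly
as a sorter would gate them; polygon gates count their boundary as inside
and operate on raw scalar values.  Hierarchical schemes apply an ordered
list of keep/assign gates, first matching assign gate wins, counts
conserved exactly.  Balanced splits draw a fixed number of events per class
without replacement (train and test disjoint); fraction splits are
stratified with per-class rounding.

## Classifiers

**SVM (binary).**  Features are the concatenated waveform segments and/or
scalars, standardized per feature by a normalizer fitted on training data
only.  Hyperparameters are grid-searched by mean AUC over 5 stratified
inner folds — C ∈ {1e−2 … 1e3}, γ ∈ {1e−4 … 10} (RBF only) — with ties
broken toward smaller C then smaller γ, then refit on all training data.
Evaluation repeats a balanced 300 + 300 per-class sampling 10 times and
reports both the mean ± sd of per-trial AUCs and the AUC of the vertically
averaged ROC (101-point uniform FPR grid, linear interpolation); the two
summaries agree to within 0.02 on the shipped benchmark but are distinct
quantities.  Recovery-at-FPR is linear interpolation of TPR on a (mean)
ROC.  Linear models export to a raw-feature `(w, b)` pair — the form a
real-time gate array would evaluate as one dot product per event.

**CNN (multiclass).**  Five convolutional blocks (same-padded conv,
batch normalization, ReLU, max-pool 2) over the stacked waveform channels;
the flattened output is concatenated with the standardized scalar features
and passed through one fully connected layer (ReLU) and a softmax head.
Concatenating the scalars *before* the fully connected layer is the chosen
reading of a genuinely ambiguous design point — it is the only placement
where the FC layer can mix scalar and waveform information ahead of the
softmax; the alternative (concatenation after the FC transform, directly
into the softmax layer) is available as `concat_mode="after_fc"`.
Training is Adam on categorical cross-entropy with early stopping: if the
validation loss has not improved in 30 epochs, training stops and the
best-validation snapshot (including batch-norm running statistics) is
adopted.  The forward/backward passes are implemented directly on numpy
and verified by finite-difference gradient checks.

Default training settings follow the reference recipe (learning rate 1e−5,
batch ceiling 1024, 500 epochs).  The shipped six-class benchmark instead
uses learning rate 1e−3, at most 150 epochs, and channel widths
(8, 16, 32, 32, 32): with ~1.4k training events and batch
`min(1024, n/4)` there are only ~4 optimizer steps per epoch, so the
instrument-scale learning rate would leave the parameters essentially at
initialization, and the halved widths are ample capacity at a fraction of
the cost.  Training is deterministic given the seed up to BLAS reduction
order; observed run-to-run variation is below ±0.01 macro F1.

Multiclass evaluation reports the confusion matrix (rows true), per-class
F1 (zero when precision + recall is zero), and unweighted macro F1;
cross-validation uses stratified k-fold (default 10) with a 10% carve-out
of each fold's training portion for early stopping, reporting mean ± sd
and the best fold's confusion matrix.  Donor-transfer evaluation trains on
one batch and tests on another; batch effects (multiplicative gain,
additive morphology drift, noise scaling) are applied at the population
level.

## Shipped benchmarks

* **Two-class texture benchmark** — 1000 events per class, 50/50 mix.
  Both classes: diameter 10 ± 0.5 µm, optical density 1.0 ± 0.05.  They
  differ only in granularity (0.1 vs 0.7) and stain (2 vs 200 units of
  "green"; threshold 50).  FSC-area distributions overlap almost completely
  (two-sample KS < 0.1), so the FSC/SSC baseline hovers at chance while the
  dGMI waveform route reaches mean AUC ≈ 0.97.
* **Six-class differential** — 1500 events; neutrophil-like 40%,
  lymphocyte-like 25%, monocyte-like 12%, eosinophil-like 10%,
  basophil-like 8%, and a rare progenitor-like class at 5%.  Classes carry
  distinct (diameter, granularity, density, nucleus) combinations; 10-fold
  CV of the CNN on dGMI/bsGMI/fsGMI/bfGMI waveforms plus FSC-area and BSC
  reaches mean macro F1 ≈ 0.95.

Problem sizes (1000/class SVM benchmark, 1500-event CNN benchmark, 20
reconstruction phantoms ≤ 16 × 16, 200 forward-model instances) are the
package's reference scales: large enough for stable statistics on one CPU
core, small enough to re-run routinely.

## Numerical conventions and edge cases

* Trigger threshold comparisons and label thresholds are strict (`>`);
  polygon boundaries are inside; argmax ties go to the lowest class index.
* All-zero FSC segments yield (height, width, area) = (0, 0, 0) rather
  than an error; events with no trigger are counted dropouts.
* AUC is trapezoidal on the threshold-sweep ROC and therefore equals the
  Mann-Whitney probability of correct ranking with ties counted ½.
* Reconstruction with `ridge = 0` refuses rank-deficient systems instead
  of silently returning a minimum-norm solution.
* The FCS export writes 32-bit little-endian floats (list mode); waveforms
  are not representable in FCS and stay in the HDF5 container.

## Known limitations

* No wave optics: speckle statistics, coherence, PSFs and detector
  electronics are out of scope; noise is a generic shot + read model.
* Phantom morphology is parametric and 2D; absolute classifier scores on
  these phantoms say nothing about absolute performance on real cells.
* The CNN is CPU-bound numpy; it is sized for 1e3–1e4 events, not
  instrument-scale data.
* Throughput estimation assumes ideally spaced cells (one illumination
  length apart) and is exactly the reciprocal acquisition time; queueing,
  coincidence and dead time are not modeled.
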