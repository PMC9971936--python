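# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `rpaf`.

## Pipeline

A record travels through five stages: (1) filtering to single-label AF/NSR
records, class balancing and a record-disjoint 4/5–1/5 train/test split;
(2) per-lead resampling (polyphase, band-limited) and truncation to a
fixed-length leading segment; (3) z-scoring and conversion to a recurrence
image; (4) classification by the shallow parallel CNN; (5) metric
reporting with AF as the positive class.  Every stage draws its seed
deterministically from one master seed, so a run is a pure function of its
configuration.

## Recurrence imaging

The delay embedding uses lag τ = 1 and a 2D phase space: S_t = (X_t,
X_{t−τ}).  The default recurrence representation is the un-thresholded
distance matrix R_ij = ‖S_i − S_j‖ (Euclidean; max and Manhattan norms are
available), which preserves distance information that Heaviside
binarization R_ij = θ(ε − ‖S_i − S_j‖) discards.  In the thresholded mode
the boundary case recurs: θ(0) = 1, so the diagonal is all ones for every
ε ≥ 0.

Two conventions connect a long segment to a fixed image side, because a
10 s, 300 Hz segment would otherwise produce a ~9-million-entry matrix:

* **Decimation (default).**  The z-scored segment is uniformly decimated
  to `target_points` samples (default 300), giving a 299-sided matrix that
  renders 1:1 at the native 299-pixel input.  This is cheap but samples the
  waveform pointwise, so features much shorter than the decimated sampling
  interval (e.g. narrow QRS spikes at coarse targets) may be missed.
* **Full matrix (`full_matrix=true`).**  Every sample is embedded and the
  matrix is resized by area-average (local-mean) interpolation.  This
  preserves coarse structure of all features at the cost of an O(N²)
  distance computation; it is the convention used for the small 32-pixel
  test profiles, where decimation would be too lossy.

Rendering min-max normalizes the matrix (a zero-range matrix maps to
black), so images are invariant to positive rescaling of distances, then
applies a perceptually uniform colormap (viridis default) to produce RGB.

## ParNet-adv

The classifier follows the non-deep parallel-network design: three streams
of blocks at 1/4, 1/8 and 1/16 resolution (6/5/5 blocks), entered through a
chain of downsampling blocks, merged by two fusion blocks, and finished by
a final downsampling stage, global average pooling and a 2-class linear
head.  A stream block sums three branches — 1×1 conv + BN, a spatial
filter + BN, and a squeeze-excitation skip gate — and applies SiLU.  The
spatial filter is the factorized 1×7 → 7×1 pair (order configurable); with
`kernel_mode="square_3x3"` it is a single 3×3, reproducing plain ParNet.

**Depth convention.**  Depth is the number of parameterized stages on the
longest input→output path, counting the factorized pair as one
spatial-filter stage (it replaces one 3×3).  All three stream paths then
count 2/3/4 downsampling stages + 6/5/5 blocks + 2/2/1 fusion stages + the
final downsampling + the FC head = 12, and depth is 12 for both kernel
modes while the parameter counts differ (14 C² vs 9 C² spatial weights per
block).

**Training.**  Cross-entropy loss, Adam (β = 0.9/0.999), learning rate
0.001.  The optimizer choice is this package's own (only the loss, learning
rate and batch size are fixed by the published recipe).  Optional decoupled
weight decay is off by default.  Batch norm uses batch statistics in
training and running statistics at inference, which makes predictions
independent of batch partitioning.  The whole network is NumPy with
explicit backward passes, verified against central finite differences in
float64 (relative error < 1e-6 per layer).

**Profiles.**  Native scale is 299×299 inputs with stream widths
64/128/256 and batch 64.  Because training here is CPU-bound, tests and the
acceptance script use the `mini` profile: 32×32 inputs, widths 8/16/32,
batch 8–16, 6–12 epochs, tens of records per class.  These problem sizes
are the package's CPU test conditions; they change nothing structural
(depth, streams, kernels, procedure, thresholds are identical at all
scales).

**Multi-lead input.**  How several leads enter one network is a design
choice: the default stacks the per-lead RGB images along channels
(3 × n_leads input channels); an early-fusion alternative averages the
images (`fusion="mean"`), which keeps the input width constant across
subset sizes.

## Synthetic ECG phantom

Each beat is a sum of Gaussian bumps (P, R, S, T) at R-peak times drawn
from a truncated log-normal RR distribution (clipped to 0.3–2.0 s).
Defaults: NSR has RR mean 0.8 s with CV 0.03 and a P wave before every
QRS; AF has RR mean 0.65 s with CV 0.25, no P waves, and a continuous
f-wave — a frequency-modulated 6 Hz sinusoid whose amplitude waxes and
wanes (AM depth 0.5 at 0.5 Hz, mimicking the clinical alternation of
coarse and fine fibrillatory waves) — with per-lead amplitude peaking on
the V1 analog.  White Gaussian noise (SD 0.05 mV-like units) is added
everywhere.  Per-lead amplitude vectors for QRS, P, T and f-waves make
lead informativeness fully plantable.

What the phantom does **not** model: vectorcardiographic lead geometry,
baseline wander, muscle/electrode artefacts, ectopy, conduction disease,
or any arrhythmia other than AF.  Passing tests therefore demonstrate that
the pipeline recovers planted statistical structure, not clinical
performance.

**Planted two-lead fixture** (`planted_two_lead_config`).  For validating
the stepwise search, informativeness is planted on exactly two leads: only
the II analog carries the cardiac waveform (hence clean RR information)
and only the V1 analog carries f-waves; all other leads are pure noise.
AF records split into a coarse-f subtype (prominent f-waves, near-sinus
ventricular response) and a fine-f subtype (invisible f-waves, highly
irregular RR), so V1 alone detects only the coarse-f fraction (60% by
default), II alone only the fine-f fraction, and the pair covers the whole
population.  The fixture's amplitudes were calibrated once so that each
planted lead's information is recoverable by the mini-profile classifier
at the test problem sizes; the short 3.2 s, 50 Hz segments keep the f-wave
(4 Hz, the bottom of the physiological band) resolvable in a 32-pixel
full-matrix image.

## Lead selection

Forward stepwise search, five-fold cross-validated mean F1, strict-increase
acceptance, ties broken toward the canonical 12-lead order, Welch
two-sample t-tests against each phase's winner reported descriptively
(α = 0.05), never used for stopping.  All candidates in a run share one
fold partition, so comparisons are paired.  A fold with no positive
predictions contributes F1 = 0 (a detector that never fires is a failed
detector, not missing data).

At CPU problem sizes the selection statistics are intrinsically noisy: a
5-fold test split of ~14 records quantizes F1 in steps of ~0.1, and a
stacked extra lead changes the network's input capacity, which at tiny n
can shift scores by a few points in either direction independent of the
lead's information.  The planted-fixture tests therefore probe whether the
search recovers a strongly planted ground truth, not whether it can resolve
sub-point differences the way the published full-scale experiments could.

## Evaluation

Precision, recall, specificity, accuracy and F1 from AF-positive confusion
counts.  Zero-denominator metrics are NaN and named in the report's
`undefined` list; displays round to 4 decimals.  For balanced designs,
accuracy = (recall + specificity)/2 exactly, which the reports satisfy by
construction.  Cross-validation is stratified and record-disjoint
(inter-patient): one record contributes exactly one sample.

## Numerical choices and degenerate inputs

* z-score guards: an (effectively) constant segment maps to zeros rather
  than amplifying round-off noise (threshold 1e-12 relative to signal
  magnitude).
* Recurrence matrices are symmetrized (0.5·(D + Dᵀ)) to suppress
  floating-point asymmetry from the distance routine, and the diagonal is
  set exactly to 0 (unthresholded) or 1 (thresholded).
* Welch t-test with both groups constant: p = 1 if means agree, else 0.
* Resampling uses a rational approximation of the rate ratio accurate to
  1/1000 and trims/edge-pads to the rounded target length.
* Ceil-mode 2×2 average pooling divides border cells by the number of real
  samples, so downsampled sizes follow ceil(H/2) without bias at odd sizes.

## Known limitations

* The NumPy network trains on CPU at small scale only; no GPU path.
* WFDB record/header I/O is not implemented; records travel as CSV with a
  JSON sidecar (fs, label, record id).
* The synthetic phantom's realism limits are listed above; no claim about
  clinical datasets follows from these tests.
* Recurrence quantification statistics and embeddings of dimension > 2 are
  out of scope.
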