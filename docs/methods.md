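# Methods

This note records the scientific and numerical choices behind `seedstage`:
what the models assume, what the synthetic scenes do and do not emulate,
and where the design was genuinely open.

## Stage model and assumptions

A pot's development is modelled as a left-continuous step function through
the ordered stages Soil < FA < OC < FL, parameterised by three transition
frames t_FA < t_OC < t_FL.  Stages are *periods*, so "the OC event" means
the first frame of the OC period.  Two assumptions follow the biology and
are enforced rather than learned: stages never regress, and a stage can be
skipped in the record only if its period falls entirely between two
consecutive frames (in practice: inside the overnight gap — such events are
reported at the first morning frame and flagged `gap_adjacent`).

Frame-level classification is deliberately agnostic about the source of
the crops; everything specific to the tray geometry lives in the
preprocessing stage.

## Synthetic scenes

The generator emulates the geometry and nuisance structure of a
growth-chamber tray rig:

* a brown soil-textured tray (hue ≈ 20°) carrying a `grid_rows x
  grid_cols` pot grid (default 10 × 20 = 200 pots of 89 px), five white
  fiducial discs (centre + four grid corners), darker pot-rim lines, a
  dark bench margin, and an optional whole-tray rotation in (−45°, 45°];
* per-pot plant silhouettes by stage: FA one small closed blob, OC two
  separated elliptical cotyledon lobes, FL the two lobes plus a brighter
  third lobe offset from the cotyledon axis (hue ≈ 100°, anti-aliased
  edges);
* frame cadence 15 min over a 16-h photoperiod (64 kept frames/day);
  timestamps carry the overnight gaps, frame indices do not;
* nuisance effects with explicit knobs (`NoiseSpec`): circadian lobe
  displacement (24-h period, per-pot phase), neighbour-pot overlap,
  degenerate "tiny plant" renderings (`flip_prob`), and additive Gaussian
  sensor noise (default sd 2/255).

Transition frames are drawn per pot from uniform windows expressed as
fractions of the sequence (defaults: emergence in [0.15, 0.40]·T, FA
duration [0.08, 0.18]·T, OC duration [0.18, 0.35]·T; germination
probability 0.9), values chosen so a typical pot traverses all four stages
within a two-week recording with broad pot-to-pot spread.  All draws are
keyed on `(seed, purpose, tray, pot/frame)` tuples, so schedules, textures
and renderings are exactly reproducible.

A `difficulty` switch controls class separability through lobe separation,
third-lobe size and per-pot size jitter.  `easy` makes the four classes
separable by a small CNN — the regime for pipeline correctness tests;
`medium`/`hard` shrink lobe separation and overlap the stage size
distributions to emulate the genuinely ambiguous OC/FL boundary of real
seedlings.  What the generator does **not** emulate: species-specific leaf
morphology, illumination drift, condensation/specular artifacts, soil
disturbance, and annotation noise on period boundaries.  Passing tests on
easy scenes therefore demonstrate pipeline correctness and calibration of
the machinery, not expected field accuracy on real trays.

Soil-texture correlation lengths (Gaussian blur σ = 4 and 2 px) sit above
the bilinear interpolation kernel, so textures survive the rectification
resampling nearly unchanged; geometric fidelity tests additionally use
noise-free renderings, because per-pixel sensor noise decorrelates under
any warp and would otherwise measure noise, not geometry.

## Preprocessing

*Landmarks.*  The value channel (max over RGB) is thresholded at 200/255
(configurable; lighting is assumed controlled), components below
`min_area_px` are dropped, the five largest are kept.  The component
nearest the image centre is the central landmark (ties broken by row-major
order); the remaining four take the quadrant of their angle about it,
which tolerates rotations to ±45°.

*Orientation.*  The modulus of the 2-D FFT of the centre square (Hanning
windowed, DC and low frequencies removed, outer radius at the inscribed
circle so the square domain cannot bias the estimate) is treated as a mass
distribution.  Because a pot grid has 90° symmetry, the spectrum has two
orthogonal arms and the plain second-moment principal axis is degenerate;
the implementation folds the arms with the quadruple-angle resultant
Σ m·e^{4iφ} computed over the prominent spectral peaks (top 1 %, raised to
the 4th power), then refines once by unrotating and re-estimating.  The
folded resultant of the *unsharpened* annulus mass gates isotropy
(`OrientationUndefined` below 0.05; grid scenes measure ≈ 0.1–0.15, white
noise ≤ 0.02).  Accuracy on synthetic scenes is ≈ 0.1° over ±30°.

*Rectification.*  Rotation by −angle about the central landmark, then the
projective map sending the four corner landmarks to the corners of the
output rectangle (edge-based, so a perfectly placed tray maps by pure
translation); both steps are composed into a single bilinear resampling.
Pot crops tile the rectified grid in row-major order with half-open pixel
intervals; coordinates are 0-based, x right, y down, angles CCW-positive
on screen.

*Background removal.*  Per-pixel HSV filter: keep hue ∈ [70°, 160°] with
S ≥ 0.2 and V ≥ 0.15, zero everything else.  No morphology by default, so
the operation is idempotent.

## Networks and training

The four architectures share one conv feature extractor (3×3 kernels;
64/128/256/256 filters in the full stack, 8/16 in the `small` preset used
where many models must be trained) and one classification head (dense 512,
ReLU, dropout 0.5, softmax).  The recurrent cells implement the peephole
equations exactly as written in the README, with two documented
conventions: the output gate reads the *previous* cell state
(`output_peephole="prev"`, switchable to `"new"`, the more common
convention), and peephole weights are element-wise vectors — per unit in
the LSTM, per channel (broadcast over space) in the ConvLSTM, which makes
the ConvLSTM collapse exactly onto the LSTM at 1×1 spatial extent.

Training minimises mean softmax cross-entropy with Adam (lr 10⁻³, β =
0.9/0.999).  Inputs are scaled to [0, 1].  Weights are He-uniform where
they feed a ReLU and Glorot-uniform for recurrent and output layers; a
plain fan-in-only uniform scheme was tried first and left the full conv
stack at chance loss for several epochs (activation variance decays ~6×
per layer), so the variance-preserving scheme is the default.  Forget-gate
biases start at 1.

Temporal models train by truncated backpropagation through time: fixed
chunks (default 32 frames) processed in temporal order with the recurrent
state carried across a sequence's chunk boundaries (gradients truncated
there) and zeroed only at sequence starts.  Carrying the state matters:
with per-chunk zero states the cell never sees late-sequence state
statistics and full-sequence inference degrades badly, while inference —
which always consumes whole sequences from a zero state — matches the
carried-state training distribution exactly.  All stochasticity (init,
shuffling, dropout) is keyed on integer seeds; identical seeds give
identical loss histories.

The chained scheme scores lazily: each binary model is evaluated only on
the frames of its own tenure, the switch frame is re-scored by the
incoming model, frames before a switch are not re-labelled, and after the
first FL every remaining frame is FL.  The emitted sequence is
non-decreasing by construction.

## Post-processing

Median smoothing uses the lower median (the ⌊(n+1)/2⌋-th order statistic)
of an n-frame window of ordinal labels, n = 4 by default (one hour at
15-min cadence — also the optimum found by the shipped window sweep on
flip-noise simulations).  The window is *centered* — it spans
[t − ⌊(n−1)/2⌋, t + ⌈(n−1)/2⌉] with edge replication — because with the
lower median this makes smoothing the identity on monotone sequences and
hence the full postprocess (smooth, then running-maximum ontology clamp)
exactly idempotent.  A trailing window (ending at t, truncated at the
start, order statistic recomputed for the truncated size) is available via
`SmoothingConfig.alignment="trailing"`, but it delays every transition by
n − ⌊(n+1)/2⌋ frames per application and is therefore not the default.
Probabilities pass through smoothing untouched; only hard labels change.

## Evaluation

All metrics are one-vs-rest from the 4×4 confusion matrix; 0/0 ratios are
reported as 0 by convention.  Summary rows give mean ± sd across the four
classes (per-sequence aggregation is available in the pipeline outputs).
F1 is computed as 2·TP/(2·TP + FP + FN), which equals the harmonic mean of
precision and recall wherever both are defined — the equality is
property-tested.  The published worked-example column used to validate the
machinery prints values at two decimals with inconsistent rounding (its
Soil entry corresponds to a computed 0.9869), so agreement is asserted to
one unit in the last printed decimal.

## Problem sizes

Counting contracts run at the full published scale (2 trays × 200 pots ×
768 frames = 307 200 truth rows — labels only, no rendering).  Rendered
experiments use small trays (2×2 to 4×5 pots of 32–40 px, 20–64 frames)
so the suite trains a dozen networks within a few CPU-minutes; the
parameter-recovery experiment trains the full-width baseline CNN-LSTM on
89-px crops of a 12-pot, 64-frame scene at lr 10⁻³ and recovers event
frames with a median absolute error of ≤ 2 frames.  The five-seed
architecture comparison uses the `small` preset with degenerate-frame
noise (flip probability 0.08), the regime where temporal context provably
helps.

## Known limitations

* The generator's parametric silhouettes make easy scenes *more*
  separable than real imagery; absolute accuracies on synthetic scenes do
  not transfer to field data.
* The orientation estimator assumes a periodic pot grid dominates the
  mid-frequency spectrum; trays without visible pot structure fall back
  to `OrientationUndefined`.
* Landmarks and tray pose are assumed static within an experiment; the
  pipeline estimates them on the first frame of each tray.
* Binary chained models never revisit pre-switch frames, so a spuriously
  early switch cannot be undone (the temporal smoother mitigates but
  cannot fully repair this).
* Night gaps are handled by timestamp bookkeeping only; no probabilistic
  gap-filling of events that occur overnight is attempted.
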