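# Methods

## Problem and pipeline

`cardiokin` classifies cardiac conditions from the *motion* visible in
short-axis cine-MRI, not from anatomy or segmentation-derived indices.
The unit of analysis is one slice observed across one cardiac cycle: a
2D+t grayscale stack. The pipeline has four fitted-free preprocessing
stages and two learned stages:

1. **Temporal/spatial normalization.** The cycle is resampled to 13
   frames by selecting rounded uniformly spaced original indices
   (half-up rounding), always keeping the first and last frame so
   end-diastole and end-systole are covered. Cycles shorter than 13
   frames are extended by nearest-index repetition — the only total
   extension that adds no invented motion. Frames are center-cropped to
   square, resized bilinearly to 128×128 (configurable), and min–max
   normalized per sequence to [0, 1]; a constant sequence maps to zeros.
   Per-sequence min–max was chosen for scale invariance across scanners.
2. **Dense flow.** For each of the 12 consecutive frame pairs a dense
   displacement field `v = (u, v)` (pixels/frame) is estimated. The
   estimator is a pluggable backend behind one contract — forward flow,
   `frame_t(x) ≈ frame_t+1(x + (u,v))`, finite everywhere, clipped to a
   configurable maximum displacement. Backends are scikit-image's
   coarse-to-fine variational solvers: TV-L1 (default, higher quality)
   and iterative Lucas–Kanade (used at small image sizes where it is
   equally accurate and several times faster). Backend name and
   parameters are frozen in `FlowConfig` and persisted in run metadata;
   downstream code depends only on the contract, not the solver.
3. **Kinematic maps.** Treating the displacement field as a planar
   velocity: divergence `∂u/∂x + ∂v/∂y` (local contraction negative),
   vorticity `∂v/∂x − ∂u/∂y` (twist), and the decomposition of the
   temporal acceleration `a = v_{t+1} − v_t` into a tangential component
   `a_T = (v·a)/|v|` (speed change) and a normal component
   `a_N = |u_x a_y − u_y a_x|/|v| ≥ 0` (direction change), so that
   `a_T² + a_N² = |a|²` wherever the speed is at least `eps`. Spatial
   derivatives are centered in the interior and one-sided at borders, on
   a unit pixel grid (x = column, y = row increasing downward);
   pixel spacing in mm is carried as metadata only. Below the speed
   floor `eps` (default 1e−3 px/frame) both acceleration components are
   defined as 0, removing the |v|→0 singularity. Acceleration at the
   last of the 12 time indices reuses the final field pair so every
   channel keeps temporal depth 12. Channels are z-scored per sequence
   (constant channel → zeros) before entering the network; the Eulerian
   `∂v/∂t` is used — no material/convective term, and no strain tensors.
4. **3D convolutional representation.** Five same-padded 3×3×3
   convolutions (batch-norm + ReLU; stride schedule 1, 2, 2, 2,
   (2,4,4) with ceil-mode output sizing) collapse (12,128,128,C) to
   (1,4,4,256), followed by flatten and two 1024-unit dense layers
   (dropout 0.4 before each) and a softmax head. Downsampling by strided
   convolution rather than pooling keeps parameter counts at their
   nominal values while reproducing the shape chain, including the 3→2
   temporal and 16→4 spatial steps. Training: cross-entropy, Adam at
   lr 0.001, batch size 1, 20 epochs. Binary tasks use a 2-unit softmax
   head.
5. **Embedding + random forest (late fusion).** The post-ReLU activation
   of the *last hidden* dense layer (`dense_1`; selectable to `dense`)
   is the learned per-kinematic descriptor. One network is trained per
   kinematic channel on the fold's training patients only; the
   per-channel embeddings of a slice are concatenated in canonical order
   (a_N, div, vor, then the rest) into the fused cardiac descriptor. A
   random forest (100 trees, depth cap 60, seeded; other settings at
   scikit-learn defaults, frozen in `ForestConfig`) votes per tree; the
   vote fraction is the score and ties break to the lexicographically
   first class.
6. **Leave-one-patient-out evaluation.** One fold per patient; all of a
   patient's slices are held out together, every learned stage is
   refitted per fold on the remaining patients, and a patient-level
   label is produced by majority vote over slice predictions (ties
   lexicographic; switchable to mean-probability). Metrics are computed
   on patient-level predictions: accuracy, macro precision, macro recall
   (sensitivity), and F1 as the harmonic mean of macro precision and
   recall. Reports render as CSV and Markdown with percentages at two
   decimals.

## The network engine

No deep-learning framework is used: the network is a compact NumPy
implementation (`cardiokin.nn`) of exactly the required pieces — strided
same-padded 3D convolution (im2col), per-channel batch normalization
(with batch size 1 this normalizes over the sample's spatiotemporal
positions; running statistics serve inference), ReLU, inverted dropout,
dense layers, softmax cross-entropy, and Adam. All randomness flows from
one seeded generator, so training is bit-reproducible; gradients were
verified against central finite differences layer by layer. One
geometric constraint follows: batch normalization needs more than one
spatiotemporal position per channel, so input sizes whose shape chain
collapses to 1×1×1 before the last convolution (e.g. 32×32) are not
usable; 48×48 is the smallest supported profile, giving (1,2,2,C) at the
top of the stack.

## Architecture geometry and parameter counts

For a (12,128,128,1) input the layer chain produces exactly
(12,128,128,64), (6,64,64,128), (3,32,32,256), (2,16,16,256),
(1,4,4,256), 1024, 1024, n_classes, with per-layer trainable parameters
27·C_in·C_out + C_out (conv) and n_in·n_out + n_out (dense): 221,312 /
884,992 / 1,769,728 / 1,769,728 for the strided convolutions and
1,049,600 for the 1024→1024 dense layer. Two published figures for this
family of models are not reproducible from any kernel/channel
combination and are treated as typographical: a first-conv count of
5,842 (ours is 27·C_in·64 + 64) and a 1,049,600 count for the first
dense layer, which would require a 1024-dimensional input even though
flattening (1,4,4,256) gives 4096 (ours is 4096·1024 + 1024). The
kernel size is 3×3×3 throughout — the only size consistent with the
four reproducible convolution counts.

## Synthetic phantom cohort

The phantom replaces the left-ventricular myocardium with a bright
annulus on a dark background whose inner radius follows a
single-harmonic cycle `r(t) = r_es + (r_ed − r_es)(1 + cos 2πt/(n−1))/2`
over 13 frames, with cumulative in-plane twist and a multiplicative
angular intensity texture (8 harmonics, amplitude 0.35) that makes
rotation observable to optical flow. Class presets (radii in pixels at
image size 64):

| class | r_ed | r_es | wall | twist °/frame | extras |
|---|---|---|---|---|---|
| N    | 16 | 9    | 6  | 2.0 | — |
| MINF | 16 | 9    | 6  | 2.0 | akinetic sector (−20°, 110°) frozen at ED |
| DCM  | 22 | 20.5 | 4  | 1.0 | amplitude < 25 % of N's |
| HCM  | 14 | 8    | 12 | 2.0 | wall 2× N's |
| RV   | 12 | 10.8 | 4  | 0.5 | second hypokinetic cavity |

Cohorts draw per-sequence ±10 % uniform jitter on radii, wall thickness
and twist from substreams of one master seed (`SeedSequence.spawn`), so
cohorts are reproducible and seed-distinct. Noise is additive Gaussian
(`noise_sd`, default 0 — the clean-phantom study condition). The
phantom captures contraction amplitude, wall thickness, regional
akinesia, twist, and cavity count — the kinematic signatures the
classifier should exploit — and deliberately omits trabeculation,
papillary muscles, through-plane motion, intensity inhomogeneity, and
scanner noise statistics. Passing tests on phantoms therefore
demonstrate that the pipeline's machinery discriminates kinematically
distinct classes under leave-one-patient-out conditions; they say
nothing about accuracy on clinical cine-MRI, which additionally depends
on anatomy, image quality, and class overlap that the phantoms do not
model.

## Desk-scale profile

`PipelineConfig()` holds the reference configuration (128×128, TV-L1,
filters 64/128/256/256/256, dense 1024, 20 epochs).
`PipelineConfig.reduced()` is the profile used by the test-suite and
phantom experiments: image size 48, iterative-LK flow (radius 5),
filters 4/8/8/8/8, dense width 32, 4 epochs — chosen as the smallest
geometry the batch-norm constraint admits, with width and epochs set by
watching training-loss convergence on a separable two-class phantom
task (loss reaches ~0 within 2 epochs). With it, a 20-patient
leave-one-patient-out triage run (60 network fits) takes roughly two
minutes on one CPU.

## Numerical and design notes

- **Resampling ties** round half-up (`floor(x+0.5)`), deterministically.
- **Flow sign convention** is forward: the field maps frame *t* pixel
  positions onto frame *t+1*; antisymmetry under frame exchange holds
  approximately (to ~0.5 px median on textured fixtures).
- **Standardization leakage:** none — every preprocessing statistic
  (min–max, z-score) is per-sequence, so precomputing stacks once and
  sharing them across folds cannot leak held-out information; only the
  networks and the forest are refitted per fold.
- **Per-fold seeding** derives from CRC32 of (master seed, held-out
  patient id), and training samples are processed in sorted
  (patient, slice) order, so reports are independent of cohort ordering
  and byte-identical across identically seeded runs.
- **Fold failure** aborts the run with the held-out patient id in the
  message; a degenerate fold (single training class, e.g. a pairwise
  task with one patient per class) is an error, not a silent skip.
- **Forest scores** use scikit-learn's probability averaging over trees,
  which coincides with the vote fraction for fully confident leaves and
  is monotone with it otherwise.
- **Slice-level vs patient-level:** classification is per slice;
  aggregation to the patient happens only in evaluation (majority vote),
  keeping the descriptor pipeline agnostic to how many slices a patient
  has.

## Known limitations

- The full-width network is impractical to *train* in the NumPy engine
  at 128×128 on one CPU (inference and geometry checks are fine); the
  reduced profile is the supported training path. The architecture,
  losses and optimizer are identical at both widths.
- The flow backends are intensity-based variational solvers; in very
  low-texture regions (homogeneous blood pool) the field is
  regularization-dominated and kinematic maps there are correspondingly
  smooth.
- Multi-class end-to-end classification is supported mechanically
  (n-class softmax) but all headline experiments are binary or triage.
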