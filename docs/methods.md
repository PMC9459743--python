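# Methods

`tugseg` segments Timed Up-and-Go (TUG) trials recorded as RGB-D skeleton
trajectories into their five subtasks — sit-to-stand, walk, turn, walk
back, stand-to-sit — and extracts the six clinical events separating them.
This note documents the model, its assumptions, the synthetic stated
world, and the numerical choices a maintainer should know about.

## Pipeline

1. **Axis alignment.** Recordings arrive in an arbitrary camera frame.
   The walking axis is estimated as the first principal direction of the
   horizontal pelvis displacements (from the first frame), and the frame
   is rotated about the vertical (y) axis so that direction maps to +x
   with the outbound walk positive. The sign is resolved by the largest
   displacement excursion — the apex at the cone. Alignment is a pure
   rotation (pairwise distances preserved to 1e-9 relative) and fails
   with `AlignmentError` when the horizontal pelvis span is below 0.5 m
   (no walking happened). Convention note: the package defines its own
   aligned frame (x = walking direction, y = vertical, z = lateral);
   camera-native axis conventions are deliberately not assumed.
2. **Low-pass filter.** 4th-order Butterworth, 0.3 Hz cutoff at 30 Hz
   sampling. Default is zero-phase (forward-backward, squared magnitude
   response): a causal pass at 0.3 Hz would delay every event by a visible
   group delay, and segmentation here is offline. A `causal` mode is
   retained for ablation. The filter needs more than `3 * order` samples.
3. **Min-max normalization**, per trial and per channel, mapping each
   coordinate channel onto [0, 1]. Per-trial is the strictest reading —
   it needs no training-set statistics at inference and absorbs subject
   height and camera distance. Constant channels map to zeros with a
   warning rather than dividing by zero.
4. **Frame classification.** A dilated temporal convolutional network
   (TCN) maps an 8-frame window of the selected joint channels (default:
   pelvis x, y, z) to class probabilities for the window's centre frame
   (offset `(W-1)//2`); stride-1 windows with edge replication give one
   prediction per frame. Architecture: three temporal blocks of two
   dilated convolutions each (kernel 3; dilation 1, 2, 4 per block; zero
   same-padding), a residual connection per block (1x1 convolution when
   the width changes), and a dense softmax head on the flattened block
   output. Channel plan 32-32-48 (24,885 parameters). The reference
   architecture reports 41,879 parameters for the same kernel/window; its
   printed counts are mutually inconsistent under any single layer
   composition, so the count is recorded as context, not enforced.
   Batch normalization and dropout are omitted.
5. **Training.** Categorical cross-entropy, Adam (learning rate 7e-5),
   batch size 1024, early stopping on validation loss with patience 50
   and best-epoch weight restoration. Splits are always subject-wise:
   6:2:2 train/validation/test holdout (30:10:10 for 50 subjects) and a
   5-fold subject k-fold utility. All randomness (initialization,
   shuffling, splits) sits behind explicit integer seeds; identical seeds
   give bit-identical histories. The network and its backward pass are
   implemented directly in NumPy (float32, BLAS matmuls) — no deep
   learning framework is required at run time.
6. **Order-constrained correction.** A TUG trial follows the strict
   template sit / sit-to-stand / walk / turn / walk-back / stand-to-sit /
   sit. Frame predictions are aligned to this 7-slot template by dynamic
   programming, minimizing the summed local cost `1 - p_t(slot class)`
   over all monotone frame-to-slot assignments; hard labels enter as
   one-hot. The leading and trailing sit may be empty, the five active
   slots may not (hence T >= 5). Ties break toward the earliest feasible
   boundaries (lexicographically smallest boundary vector), which the
   test suite verifies against exhaustive enumeration. This removes
   fragmentation errors (out-of-order runs) entirely; boundary shifts
   between adjacent subtasks are inherently uncorrectable by an order
   constraint and are out of scope.
7. **Events and derived timings.** The six slot boundaries are the six
   events (StartMove, StartWalk, StartTurn, EndTurn, StartSit, EndSit),
   reported as frame-index / fps seconds. Total TUG time is EndSit -
   StartMove. Subtask durations come from boundary differences; walking
   speed is course length / walk duration. Per-subtask timing error is
   computed on durations (the duration reading of the ambiguous "MAE per
   subtask"); per-event errors are reported separately. MAE aggregates use
   the population (n) standard deviation.

Frame-level quality is scored one-vs-rest per class (precision, recall,
F1) pooled over trials (micro), plus overall accuracy. Undefined metrics
(empty denominator) are reported as `null` and excluded from averages.
Rater reliability uses ICC(2,1) — two-way random effects, absolute
agreement, single rater — the standard inter-rater choice; the
implementation is the explicit ANOVA mean-squares decomposition and is
cross-checked against `pingouin` in the tests.

## Synthetic stated world

The study's recordings are not publicly available, so the package ships a
protocol simulator. It emulates: 30 Hz sampling; the 3 m out-and-back
course; seven ordered phases with 1 s seated padding at both ends; group
total-duration means of 11.34 s (healthy young), 15.33 s (older adults)
and 43.11 s (stroke); the 45-degree trunk-tilt criterion crossing exactly
at StartMove and EndSit; minimum-jerk displacement profiles with
sinusoidal trunk pitch; pelvis-relative chest/head/hand/ankle offsets
with arm-swing and step oscillations; a random camera azimuth and offset
(so axis alignment is exercised); and isotropic Gaussian joint noise.

Values the source does not state, chosen once as realistic defaults and
not calibrated further:

| parameter | default | rationale |
|---|---|---|
| total-duration sigma | 1.2 / 1.8 / 6.0 s | healthy gait varies little; stroke timing varies a lot |
| phase fractions of active time | 15/30/10/30/15 % | symmetric out-and-back; transitions shorter than walks |
| chair / standing pelvis height | 0.45 / 0.95 m | standard chair, average adult |
| joint noise sigma | 0.01 m | centimetre-level body-tracking jitter |
| max trunk pitch | 70 degrees | comfortably brackets the 45-degree criterion |

Ground-truth labels and events derive from the phase plan, never from the
noisy signal, so noise can degrade the classifier but never the truth.
Total durations are drawn from a normal truncated to leave at least 2 s
of active time. A green synthetic test establishes that the pipeline
recovers a stated, smooth, correctly ordered world — not that it matches
the study's human cohorts, whose per-subtask statistics were never
published.

## Numerical choices and degenerate inputs

- Zero-phase filtering uses `filtfilt` with pad length
  `min(3*(order+1), T-1)`.
- The DTW dynamic program is O(7T) after a suffix-minimum table; greedy
  forward reconstruction (advance whenever optimal) yields the earliest
  boundaries.
- `fps` is inferred from the median timestamp spacing on read.
- Frame count of a simulated trial is `round(fps * total duration)`;
  event times are continuous, so extracted frame-quantized events match
  ground truth to within one frame at best.
- A model with zero temporal blocks degenerates to a dense softmax on the
  flattened window — used as an analytic test case (20 parameters for a
  3-feature, 5-class, window-1 head).
- The window/receptive-field validity check requires
  `window_size >= kernel_size`; larger dilations than the window are
  allowed (taps fall into zero padding), since the reference grid itself
  includes such cells.

## Known limitations

- The synthetic gait is kinematic, not biomechanical: no double support,
  no pathology-specific signatures beyond duration scaling, no tracking
  dropouts or occlusions.
- Training time on one CPU limits practical epochs; acceptance runs cap
  `max_epochs` (100 in the test suite, 60 in `scripts/acceptance.py`)
  below the early-stopping regime that a GPU run would allow.
- The 0.3 Hz cutoff strongly smooths the (short) turn phase; turn
  boundary errors are the dominant timing error, consistent with the
  shift-error limitation above.
- Per-class metrics pool frames across trials (micro averaging); per-trial
  macro averaging would weight short trials differently.
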