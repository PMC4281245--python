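# Methods

## The model

`scfield` simulates the competition between a saccade target and a
task-irrelevant visual distractor on the motor map of the superior
colliculus (SC), and reads out the resulting deviation of saccade direction.
The field is one-dimensional: `n = 1000` leaky-integrator nodes spanning
5 mm of tissue along the straight collicular path through the target and
distractor representations.  Lateral connectivity is Mexican-hat shaped,

    w(d) = a exp(-d^2 / 2 sigma_a^2) - b exp(-d^2 / 2 sigma_b^2) - c,

with a short-range excitation zone and two inhibition zones (a local
Gaussian surround and a global constant).  Node dynamics are

    tau du_i/dt = -u_i + (g/n) sum_j w_ij q_j + I_i,
    q_i = 1 / (1 + exp(-beta u_i)),

integrated by forward Euler.  A saccade is initiated when any node's
discharge reaches 80% of its ceiling (q = 0.8); the saccade direction is
decoded from the discharge profile at that moment and converted to visual
polar angle through the inverse collicular mapping along the chord.

### Default parameters

| parameter | value | meaning |
|---|---|---|
| `n_nodes`, `extent_mm` | 1000, 5 mm | field resolution and tissue span |
| `a, b, c` | 144, 24, 9 | kernel amplitudes (weight units) |
| `sigma_a_mm, sigma_b_mm` | 0.25, 1.5 | excitation / inhibition range |
| `tau_ms` | 10 | integrator time constant |
| `beta` | 0.08 | gain slope (potential units^-1) |
| `dt_ms` | 0.5 | Euler step (convergence below) |
| `coupling` (g) | 4.25 | recurrent coupling (see below) |
| `sigma_e_mm` | 0.53 | width of excitatory inputs |
| `e_exo`, `e_endo` | 30, 15 | visual / top-down input strength |
| `delta_exo_ms`, `delta_endo_ms` | 70, 120 | afferent delays |
| `tau_exo_ms` | 10 | decay of the visual transient |
| SNr `level` | -16 | tonic nigral inhibition, every node |
| `sigma_fix_mm` | 0.7 | fixation-zone inhibition width |
| `f` | -0.5 (weak) / -1.8 (strong) | fixation strength |
| gap / overlap offset | -150 / +150 ms | fixation removal relative to target onset |
| threshold | q = 0.8 | saccade initiation |
| decode mask | q = 0.4 | half the initiation threshold |
| trial timeout | 600 ms after target onset | flagged, not an error |

Inputs: the exogenous (visual) input is transient — it arrives 70 ms after
stimulus onset at both target and distractor and decays with a 10-ms
constant; the endogenous (top-down selection) input arrives at 120 ms, only
at the target, and is sustained until threshold crossing.  Fixation-zone
inhibition is a Gaussian centred at the chord midpoint, active from the
start of the trial, removed at threshold crossing (sustained mode) or at a
fixed offset from target onset (gap/overlap), whichever comes first.  Each
trial starts from the field equilibrated under the tonic inputs (SNr +
fixation), computed by `settle()` (step change below 1e-8, capped at
500 ms; the cap is reached with a warning — the residual drift there is of
order 1e-7 per step and has no measurable effect on trial outcomes).

### The recurrent coupling g

The kernel amplitudes, input strengths and threshold are all fixed by the
source parameter set, but that set leaves the discretization convention of
the recurrent sum open, and the two textbook conventions both fail with
these constants: under the plain mean-field average `(1/n) sum w q` the
local recurrent gain saturates near 8q (because a·sigma_a = b·sigma_b
exactly), so peak discharge asymptotes at about 0.55 and the 0.8 threshold
is unreachable; under the spatial-integral convention `dx * sum w q`
(equivalent to g = 5) bubbles become bistable and the visual transient
alone triggers saccades before the endogenous input arrives.  We therefore
expose the convention as an explicit dimensionless coupling g and calibrate
it once: g = 4.25 is the interior of the window (roughly 3.3 to 4.6) in
which saccade initiation is endogenously driven, a transient-only
distractor bubble decays rather than self-sustains, and simulated response
times fall in the 140-190 ms range.  g is a model constant, not a per-
experiment dial; all shipped results use 4.25.

### Chord placement and the deviation measure

For a separation `s` at eccentricity `R` the target and distractor sit at
polar angles -s/2 and +s/2 (mirroring the horizontal meridian), are mapped
to the SC surface with the standard logarithmic mapping (A = 3.0 deg,
Bu = 1.4 mm, Bv = 1.8 mm), and are placed symmetrically about the field
centre at their collicular distance apart.  The default sweep eccentricity
is 10 deg.  Decoded field positions are converted back to polar angle by
the closed-form inverse mapping along the chord.

The decoder is the discharge-weighted centroid of the activity bubble
containing the most active node, over nodes above half the initiation
threshold.  Restricting to the winning bubble matters: at large
separations a remnant distractor bubble can sit above the mask at crossing
time, and a global centroid would average two bubbles into a meaningless
midpoint.  Global-centroid and parabolic-peak decoders, and decoding
averaged over a short post-crossing window, are available as options; the
deviation curve is insensitive to this choice (cell-level differences are
below 0.5 deg).

The reported deviation is the decoded direction minus the *nominal target
direction*, signed positive toward the distractor.  The nominal baseline is
the faithful 1-D reduction of the distractor-absent reference condition: on
the 2-D motor map, the drift that fixation-zone inhibition imposes on a
lone target bubble is radial (it changes saccade amplitude, not direction),
so the direction decoded from an absent trial is the target direction.
Simulating the absent trial on the same chord with the midpoint-centred
fixation Gaussian would instead give that trial a directional drift with no
2-D counterpart, and referencing to it cancels precisely the
fixation-strength modulation the model is built to expose (it also moves
the sign transition from ~40 deg to ~70 deg).  Decoded-baseline referencing
remains available (`baseline="decoded"`); distractor-absent trials are
always simulated for the response-time comparisons.

### What the model produces

With the defaults, the weak-fixation deviation curve over separations
15-150 deg is (+3.1, +2.3, -1.0, -3.2, -4.4, -4.9, -4.6, -3.7, -1.9,
+0.7 deg) and the strong-fixation curve (+1.1, -0.6, -3.1, -4.8, -5.8,
-6.1, -5.5, -4.3, -2.2, +0.6): attraction by close distractors, repulsion
peaking near 90 deg and relaxing at larger separations, a toward-to-away
sign change at 40.2 deg (weak) and 24.6 deg (strong), maximum toward
deviation 3.1 deg, and a weak-minus-strong modulation that shrinks from
~2-3 deg at 15-30 deg separation to 0.1 deg at 150 deg.  Simulated response
times show the expected orderings: stronger fixation slows initiation
wherever its footprint reaches the stimuli, gap trials are faster than
overlap trials, and a distractor prolongs initiation relative to the
matched absent trial at large separations.

One cell deserves honesty: at 150 deg separation the deviation is slightly
positive (+0.7 / +0.6 deg) rather than negative.  The stimuli there sit
1.9 mm from the fixation site — beyond the direct inhibitory push (range
sigma_fix = 0.7 mm) but within reach of the *disinhibition* gradient the
fixation-induced background dip creates through the 1.5-mm inhibitory
surround, which weakly attracts the target bubble toward the field centre.
The effect is robust to the decoder, the Euler step and the boundary
treatment; it is a genuine property of this parameter set, and it means the
"repulsion at every large separation" reading holds from 45 through
135 deg but reverses by a fraction of a degree at the extreme 150-deg cell.
The corresponding acceptance test is left failing rather than weakened.

At separations of 135-150 deg the stimuli also come within ~0.7 mm of the
patch boundary, where the truncated inhibitory surround elevates background
activity; this contributes a small common drift to both bumps but does not
change any sign except as described above.

### Numerical notes

* Forward Euler at dt = 0.5 ms: halving to 0.25 ms changes the decoded
  deviation of a full trial by less than 0.001 deg (the convergence test
  budget is 0.05 deg).
* The dynamics are grid-resolution independent (mean-field normalization),
  so property tests run on a 200-node field.
* Everything is deterministic; identical configurations produce
  bit-identical trajectories.
* Mirror symmetry: reflecting all inputs about the field centre reflects
  the state to ~1e-12 (limited only by the floating-point symmetry of the
  node grid).

## Trajectory metrics

The behavioural toolkit operates on 500-Hz gaze samples in screen degrees
(origin at fixation, y up).  *Initial direction* is the angle of the vector
from the saccade start to the sample nearest a fixed latency into the
saccade (10 ms) or a fixed fraction of its duration (20%); the
nearest-sample rule is used rather than interpolation.  *Maximum curvature*
is the largest perpendicular distance of intermediate samples to the
straight start-to-end segment, first occurrence winning ties, positive
toward the distractor, optionally divided by amplitude.  Both measures can
be referenced to the mean of the matching distractor-absent cell.

The exclusion cascade mirrors the two behavioural protocols: response times
outside 80-500 ms (protocol 1) or 80-550 ms (protocol 2); initial direction
more than 30 deg from the target direction (protocol 1); start point more
than 1.5 deg (protocol 1) or 2.0 deg (protocol 2) from fixation; and, for
protocol 2, a 2.35-standard-deviation outlier rule applied per condition
cell to the records surviving the earlier rules.  The outlier criterion
judges each record against the mean and SD of the *other* survivors in its
cell and is iterated to a fixed point by default (this leave-one-out,
converged form is the variant under which a single wild value in an
otherwise clean cell is excluded, and it makes the cascade idempotent); a
single-pass switch is provided.

### The synthetic generator

`generate_fixture` builds saccades whose two deviation measures are known
by construction: the perpendicular offset from the straight path is a
linear ramp over the first 30% of the path (slope set by the requested
initial-direction offset, so the early-sample direction rules recover it
exactly), followed by cubic Hermite segments through the requested maximum
excursion.  The path is traversed at constant speed and sampled at 500 Hz;
Gaussian noise is added per sample.  What it does *not* emulate: the
bell-shaped velocity profile of real saccades, drift/tremor noise
correlations, blinks, or vendor-specific artefacts.  Tests passing on these
fixtures certify the geometry of the measures and the exclusion logic, not
robustness to real eye-tracker noise.

## Design choices that were genuinely open

* Recurrent-sum convention: exposed as g, calibrated once (above).
* Decode rule: winning-bubble centroid by default; never specified by the
  model family, alternatives shipped and tested.
* Deviation baseline: nominal target direction by default (2-D argument
  above); decoded-absent referencing available.
* Resting level of the integrator and gain offset: both 0, configurable.
* Sweep eccentricity: 10 deg (the value of the gap/overlap experiment);
  not stated for the original simulations.
* Gap/overlap fixation in fixed-offset mode also releases at threshold
  crossing if that occurs first (fixation neurons pause during saccades).
* Stimulus-size scaling across eccentricity (`scaled_stimulus_size`) uses
  the simple inverse-magnification ratio and is shipped un-asserted: it
  gives 2.14 and 3.86 deg for the 12- and 24-deg conditions, close to but
  not exactly the printed 2.2 and 3.98 deg, and the original scaling
  criterion is not recoverable.

## Known limitations

* The field is the 1-D chord; saccade amplitude effects (which live on the
  orthogonal, radial axis) are outside its scope.
* One SC is modelled; commissural interactions are not.
* The 150-deg cell's sign, and near-boundary behaviour generally, depend on
  the excised-patch truncation described above.
* Neurons are deterministic rate units; response-time distributions and
  trial-to-trial variability are not modelled.
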