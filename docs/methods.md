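# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `ecgrecon` pipeline. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Forward model and synthetic cohorts

Cardiac electrical activity is modelled as one or more current dipoles in an
infinite homogeneous volume conductor. The potential at electrode position
`r` from a dipole with moment `p` at `r0` is

    phi(r) = p . (r - r0) / (4 pi sigma |r - r0|^3)

with conductivity sigma = 0.2 S/m. Geometry is in cm, moments in mA·cm,
potentials in μV. A boundary-element torso would be more realistic, but the
homogeneous model preserves the property the reconstruction problem rests
on — surface potentials linear in the instantaneous source moment — at desk
scale, and only relative geometry matters for the pipeline's claims.

The 35-electrode grid lies on the z = 0 chest plane (7 columns × 5 rows,
5 cm pitch, column-major numbering with electrode 16 at the top of the
central column, i.e. the clavicle–sternum junction). Limb electrodes are
placed far from the grid to approximate limb-lead geometry; precordial
electrodes V1–V6 sit at plausible chest-plane positions. The numbering
convention is the unique one simultaneously consistent with the documented
example combinations {1,2,6,7}, {1,3,11,13}, {1,7,11,13}, the family counts
24/15/60, and electrode 16 at top-centre; it is isolated behind
`GridLayout.position`.

Each dipole's cycle is a sum of Gaussians per axis (P, QRS complex, T wave)
in beat-phase units, evaluated with wrap-around neighbours so the trajectory
is periodic and smooth. Default amplitudes put the R peak near 1.5 mV on
the closest grid electrodes. Two source modes:

* **single** — one dipole, used with all noise off. Every channel is then an
  exact linear combination of the three moment components; chest recordings
  have channel-space rank 3 and pooled MLR reconstruction is exact. This is
  the package's physics oracle. Subjects may still differ in heart
  *orientation*, amplitude, and rate: a shared rotation multiplies both the
  chest-lead and reference-lead maps and cancels in the transformation, so
  universality is exact in this regime. Heart *position* jitter does not
  cancel and is disabled here.
* **multi** — three dipoles (ventricular, atrial, posterior-septal) at
  different origins with different morphologies, plus per-subject heart
  position jitter (SD 0.8/0.8/0.5 cm), orientation jitter (SD 8° per Euler
  angle), lognormal amplitude scaling (σ = 0.15), beat-to-beat amplitude
  jitter (SD 5%), and additive noise: white (8 μV SD), baseline wander
  (80 μV at 0.25 Hz), powerline (15 μV at 60 Hz). The extra dipoles raise
  the chest-signal rank above 3, so three chest leads cannot reconstruct the
  12 leads perfectly — the regime in which electrode placement genuinely
  matters.

Cohort defaults emulate the measurement design under study: 14 subjects,
2 sessions of 2 min at 250 Hz; heart rate drawn per subject from
72.9 ± 8.2 beats/min (the cohort statistics of the design being emulated).
All per-subject parameters derive deterministically from a master seed.

What the generator does **not** emulate: realistic anatomy and inhomogeneous
conductivities, respiration and motion artifact, electrode-skin impedance
variation, pathological morphologies, inter-session electrode repositioning.
Consequently, passing tests demonstrate the pipeline's correctness and the
qualitative placement/shape logic under dipole physics — not clinical-grade
reconstruction accuracy on real torsos.

## Preprocessing

* Band-pass 0.5–35 Hz, order-2 Butterworth, applied forward-backward
  (`sosfiltfilt`, default padding), i.e. zero-phase with the squared
  single-pass magnitude.
* Lead algebra: I = LA−RA, II = LL−RA, III = LL−LA,
  WCT = (LA+RA+LL)/3, aVR = −(I+II)/2, aVL = (I−III)/2, aVF = (II+III)/2,
  Vi = precordial_i − WCT. Einthoven (I−II+III = 0) and Goldberger
  (aVR+aVL+aVF = 0) closures hold identically and are asserted to 1e−10.
* One random 20 s segment per recording, start drawn uniformly at least 2 s
  from the recording edges so filter transients never enter metric windows;
  segments concatenate in subject order (session 1 → training merge,
  session 2 → test merge). No cross-validation is added beyond this
  train/test session split.
* Chest leads are standardized with training-merge statistics only, reused
  on the test merge (no test leakage into a "universal" coefficient). MLR
  targets stay in μV; ANN targets are standardized with training statistics
  and predictions inverted, so RMSE is always reported in μV.

## Chest leads and combination families

Four electrodes give three bipolar chest leads by subtracting a common
reference; the lowest id in the combination is used. Any fixed reference
spans the same 3-dimensional affine lead space, so fitted-model predictions
and CC/RMSE are invariant to the choice (asserted as a test); a star rather
than chain subtraction pattern was chosen as the simplest such convention.

Families: all C(35,4) = 52,360 subsets; axis-aligned 5×5 cm squares
((7−1)(5−1) = 24); 10×10 cm squares ((7−2)(5−2) = 15); right-angled
triangles = centre electrode plus three of the four corners of a 10×10
square, four orientations per placement (60).

## Reconstruction models

* **MLR** — per-lead least squares y = bX + ε with bias; coefficients form
  a 12 × 4 matrix on standardized chest leads. Rank-deficient designs are
  rejected.
* **ANN** — feedforward 3-6-12, logistic-sigmoid hidden layer. The output
  layer is linear by default; a softmax output mode is provided for parity
  with toolbox naming conventions, but softmax constrains outputs to a
  positive simplex and cannot represent signed voltages, so it is not used
  for reported results. Weights initialize uniformly in ±1/√fan_in from the
  member seed (biases zero). Training is full-batch L-BFGS on mean squared
  error, at most 2000 iterations in principle; the study default is 200
  iterations with a relative-loss plateau stop at 1e−10, which reaches MLR
  parity on linear data and captures the nonlinearity gain on cohort data.
  Epoch losses (accepted L-BFGS iterates) are recorded and are
  non-increasing. The optimizer, iteration cap, and learning schedule are
  package defaults, not properties of the emulated design, which specifies
  only back-propagation training with random initialization.
* **Ensemble** — five members with distinct seeds; the prediction is the
  pointwise mean of member predictions. By convexity of squared error the
  ensemble's test MSE never exceeds the mean of its members' (asserted for
  every fitted combination).

For the 99-combination shape study the ANN ensembles train on every 8th
sample of the pooled training merge (8,750 of 70,000 samples). The
regression is memoryless — each training point is an independent
(chest-lead, reference-lead) pair — so decimation subsamples the joint
distribution without blurring it; the stride and the 200-iteration cap are
the package's default problem sizes and are configurable. MLR always uses
the full merge.

## Evaluation

Per (subject, lead) on the subject's 20 s test segment: Pearson CC, RMSE
(μV), R² about the reference mean, and ICC(2,1) (two-way random effects,
absolute agreement, single measures) with time samples as targets and
{reference, reconstruction} as raters, computed from the ANOVA mean squares
(vectorized; pingouin cross-checks the formula in the tests).

Selection scores aggregate subjects first: the 12 per-lead mean CCs are
averaged (**meanCC**) or minimized (**minCC**). The min is taken lead-wise
because the worst-reconstructed *lead* (typically aVL or III) is the
clinically limiting quantity; min ≤ mean holds by construction. Ties break
toward the lowest id tuple.

Statistics: Wilcoxon signed-rank between shapes on (subject × lead) pairs at
each family's best combination (exact null for ≤ 25 untied pairs, else
normal approximation with continuity correction); one-way ANOVA per lead
across the four triangle orientations of each square placement, replicates
being per-subject CCs. No multiple-testing correction is applied by
default (a flag-free design choice mirroring the emulated analysis; the
tables report raw p-values).

Positional robustness: each triangle's selection score is replaced by the
mean over its one-lattice-step shifted variants (up/down/left/right) that
stay on the grid; the unshifted position is excluded by default
(configurable), since the quantity of interest is performance *when
misplaced*. Shifted variants are themselves members of the triangle family
and reuse their own scores.

Bland–Altman agreement (bias, ±1.96 SD limits, difference-vs-mean slope) is
reported in mV at each selected combination, pooled over all leads and test
samples.

## Exhaustive scan

The all-combination MLR ranking uses pooled second-moment (Gram) matrices:
fitting raw chest leads with a bias spans the same affine space as
standardized leads, so each of the 52,360 combinations reduces to a 4×4
normal-equation solve plus per-subject moment algebra for CC/RMSE. The scan
agrees with the estimator path to 1e−8 (tested) and runs in about a minute;
it is the supported backend for the `free` family, while ANN ensembles
default to the 99 shape-family combinations.

## Numerical choices and degenerate inputs

* Constant channels are rejected wherever standardization or correlation is
  undefined; all-zero paired differences make the signed-rank test
  degenerate and raise.
* Rank deficiency of the chest-lead design raises rather than silently
  regularizing.
* The physics-oracle tolerance (CC ≥ 0.999999, R² ≥ 0.999) absorbs float64
  round-off through the filter, merge, and least-squares path; observed
  residuals are orders of magnitude smaller.
* Determinism: every stochastic step (cohort draw, segment starts, weight
  init) is keyed by explicit seeds in the config; reruns are bit-identical,
  and the run manifest checksums every output file.

## Known limitations

* The homogeneous-conductor, flat-chest geometry makes absolute CC/RMSE
  values optimistic relative to real torsos; only orderings and mechanisms
  transfer.
* The universal-coefficient premise is exactly true in the single-dipole
  regime by construction; in the multi-dipole regime inter-subject
  variation is driven by a small number of jitter parameters rather than
  true anatomical diversity.
* ICC and CC are computed on whole 20 s segments, not per beat; segment
  starts are random, so segments are not beat-aligned across subjects.
* EDF import requires the caller to map channel labels; WFDB I/O is not
  provided — CSV is the interchange format.
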