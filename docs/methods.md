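# Methods

## Scope and design

The package implements an EEG emotion-regulation analysis chain —
induced theta power, sensor cluster permutation statistics, eLORETA
source imaging, MIM functional connectivity, and behavioural
statistics — together with a synthetic cohort generator that defines
the study conditions. Real recordings of this paradigm are not
publicly deposited, so the generator is first-class code: it plants
known effects through a known forward model, and every downstream claim
is validated against that ground truth.

## Head model and forward solution

A single homogeneous conducting sphere (conductivity 0.33 S/m) carries
64 sensors at standard 10/10 angles (the actiCAP roster, FCz reference
not recorded as a data channel), radially projected onto the best-fit
sphere (radius ≈ 0.092 m). Sources live on a Fibonacci shell at 0.75 R
("cortical shell"; the inferior cap below −0.5 R is removed), default
400 voxels, configurable up to 2839. The surface potential of a
dipole is the classical closed form obtained by summing the Legendre
expansion with generating-function identities (including the log term);
a term-by-term series implementation serves as an independent oracle in
the tests (< 1e-10 relative agreement). Gains are average-referenced,
in µV per nAm. A realistic BEM/FEM geometry is deliberately out of
scope: the sphere preserves every property the pipeline relies on
(linearity, volume-conduction mixing, exact localisation for a
consistent leadfield).

A central dipole in this model produces the classical
3(q·r)/(4πσR³) surface pattern; "silent" central/radial sources are a
magnetometry property and do not occur in EEG, so the tests assert the
closed form rather than silence.

## Synthetic cohort

Defaults mirror the study design: 2 groups × 25 participants × 3
blocks × 50 trials, conditions balanced 50/50/50 with a seeded
pseudo-random order constrained to at most 3 consecutive repeats;
epochs span −6…+7 s around the instruction (picture at −3 s).
Sampling rate defaults to 250 Hz (the acquisition rate is not a
modelled quantity; filters adapt to Nyquist, and the validation runs
use 100 Hz).

Per trial, sensor data are the leadfield projection of:

* **Background**: 30 sources at random voxels with fixed random
  orientations, unit-RMS 1/f^α noise (α = 1, spectral shaping
  (f + 0.5)^(−α/2)), 20 nAm RMS each — sensor RMS ≈ 10–15 µV.
* **Evoked transients**: a damped 2-Hz wave after picture onset and
  after the instruction, identical across trials within condition
  (phase-locked), scaled to 5 µV at its best channel; the neutral
  condition is scaled by 0.8.
* **Induced theta**: narrowband (4.5–7.5 Hz) filtered complex noise
  with per-trial random phase at a right-frontal voxel (the grid voxel
  nearest a nominal MNI (41, 35, 40) mm direction), with a fixed radial
  orientation shared across participants — a cortical patch projects
  with a consistent topography, which is what makes a group-level
  sensor cluster coherent — 60 nAm RMS at all
  times, multiplied during the regulation window (1–5 s, 0.5-s cosine
  ramps) by a group gain in reappraisal trials only: 2.0 for controls,
  1.4 for the BPD group. These gains are the package's planted-effect
  design targets: large enough that an 8-versus-8 reduced cohort
  detects them reliably, qualitatively matching the study's
  control > BPD ordering. Narrowband *noise* rather than a
  deterministic tone gives the oscillation a finite coherence time, so
  stationary-segment power ratios behave like those of real rhythms.
* **Planted connectivity**: a second source (near nominal
  (45, 10, 45) mm) receives the same envelope with the analytic signal
  rotated by a fixed lag (π/2), i.e. genuinely lagged coupling that MIM
  should detect; its strength inherits the condition/group modulation
  through the shared envelope.
* Optional frontal drift (1/f³, fixed anterior topography) to exercise
  ICA cleanup; off by default.

Between-participant variability is a log-normal amplitude factor
(σ = 0.15). Behavioural ratings and ERQ facets are truncated normals
at the reported group means/SDs (BPD: reappraisal 42 ± 21, maintenance
58 ± 25, ERQ-R 21 ± 8, ERQ-S 15 ± 5; controls: 35 ± 19, 56 ± 21,
27 ± 7, 12 ± 5; bounds 0–100, 10–42, 4–28). The neutral-condition
rating is not reported in the source study; 15 ± 10 (BPD) / 12 ± 8
(controls) is used as a plausibly low level. An optional slope couples
the planted theta gain to the ERQ-R score.

What the generator does **not** emulate: realistic artifact
morphologies (blinks, muscle), inter-trial interval jitter,
non-stationary background, learning effects across blocks, realistic
anatomy. Passing tests therefore demonstrate correctness of the
*algorithms* under controlled conditions, not clinical
reproducibility.

## Preprocessing

Segmentation cuts 13-s epochs per instruction marker; trials too close
to the recording edge are dropped with a warning. Filtering is
zero-phase (forward–backward) 4th-order Butterworth: low-pass 100 Hz
(clipped below Nyquist with a warning when needed), high-pass 0.3 Hz,
band-stop 48–52 Hz, then linear detrend and demean, per epoch. Edge
effects of per-epoch filtering stay ≥ 1 s away from all analysis
windows. Bad channels are replaced by Perrin (1989) spherical splines
(m = 4, 30 Legendre terms).

Interactive artifact screening is replaced by a deterministic rule:
trials whose maximum absolute amplitude or >30-Hz variance deviates
from their **own condition's median** by more than 4 robust z units
(MAD scale with a floor of 10% of the overall median) are rejected.
Condition-centred statistics prevent a genuine condition-related
amplitude difference from biasing per-condition trial counts; the MAD
resists masking by single large artifacts. Re-referencing subtracts
the instantaneous channel mean. Ocular cleanup runs FastICA on
appended trials and zeroes components correlating with the Fp1/Fp2
mean above |r| = 0.7; if nothing crosses threshold the data are
returned untouched (a reduced-rank recompose would otherwise perturb
them for no benefit).

## Induced time–frequency analysis

The per-condition trial-averaged ERP (instruction-locked) is subtracted
before any spectral step, leaving induced activity. TFR: sliding 2-s
Hanning window, 50-ms slide, 1–30 Hz in 0.5-Hz steps, per trial, then
averaged within condition. Output times are window centres; windows
exceeding the epoch give NaN. Baseline power (−4.2…−3.2 s, i.e.
1.2–0.2 s before picture onset) is subtracted per channel × frequency.
The regulation contrast is reappraisal − maintenance, summarised per
channel as the mean over 3.5–8.5 Hz × 1–5 s.

**Spectral convention.** All tapers are normalised to unit energy
(Σw² = 1), a power-spectral-density-style convention: stationary noise
has the same expected power in the 1-s baseline and 4-s regulation
segments, so power ratios are ≈ 1 under stationarity. Under this
convention an on-grid tone of amplitude A has plateau power
A²(Σw)²/4 = A²·N/6 for a length-N periodic Hanning window — the
analytic value the tests assert to 3%.

## Sensor cluster statistics

Per-channel two-sided pooled-variance t (df = n_a + n_b − 2);
channels with p < 0.05 enter clustering; clusters are connected
components (same t sign) on a Delaunay triangulation of the 2-D
azimuthal projection (distance-threshold graphs are available);
cluster mass is Σt. The null is the per-permutation **maximum
absolute cluster mass** after full recomputation — the standard
family-wise construction for a two-sided test — and
p = (1 + b)/(1 + N). Tie comparisons use a 1e-9 relative tolerance so
summation order cannot flip an "as extreme or more extreme" count.
Default N = 10 000 (Monte-Carlo SE at p ≈ 0.05 is ≈ 0.002); the
`--paper-scale` flag raises it to 100 000.

## eLORETA source analysis

Induced single trials are re-segmented to regulation (1–5 s) and
baseline (−4.2…−3.2 s), Hanning-tapered, zero-padded to a common 4-s
length (0.5-Hz grid) and Fourier-transformed at 3.5–8.5 Hz (11 bins).
The eLORETA weights solve the fixed point W_v = sqrtm(L_vᵀ M L_v),
M = pinv(ΣL_v W_v⁻¹ L_vᵀ + αH), iterated to a relative change < 1e-6
(≤ 100 iterations); α defaults to 0.05 × trace-normalised, with α = 0
the exact-localisation limit used in validation (100% correct argmax
over 300 noiseless point sources on a 100-voxel grid). Source band
power is the squared norm of the 3-D projected coefficient, averaged
over trials, summed over bins; per condition the regulation/baseline
ratio is formed (condition-specific baselines), and the
reappraisal − maintenance ratio difference enters a voxel-wise
permutation test of the group mean difference (add-one rule,
two-sided by default, one-sided option). No multiple-comparison
correction is applied across voxels — the output metadata says so —
and significant voxels are grouped into contiguous clusters with
centroid coordinates. Contiguity on the shell grid is distance-based
(≤ 1.5 × median nearest-neighbour spacing), the shell-grid analogue of
a lattice neighbourhood.

## MIM connectivity

Source coefficients per trial/bin give cross-spectral 3×3 blocks,
averaged over trials and the 11 band bins (per-bin spectra available
behind a flag). MIM uses the trace form
tr[(Re S_ii)⁻¹ Im S_ij (Re S_jj)⁻¹ (Im S_ij)ᵀ], algebraically equal to
the sum of the three eigenvalues (asserted to 1e-12 in tests); the
trace is numerically cheaper. Near-singular Re(S_ii) blocks get a
relative ridge of 1e-12 × trace, logged. The whole-brain map averages
each voxel's MIM with all others, self-pairs excluded (MIM measures
between-area interactions). The vectorised O(V²) implementation uses
tr(P_i B P_j Bᵀ) = ‖R_i B R_j‖²_F with R = P^{1/2} and is tested
against the pairwise loop. Group inference reuses the voxel
permutation test on the per-participant reappraisal − maintenance
contrast of maps.

## Behavioural statistics

The split-plot ANOVA uses the classical SS decomposition (between:
group vs subjects-within-groups; within: condition and interaction vs
subject × condition residual), cross-checked against
`pingouin.mixed_anova` and a hand-worked example. Simple effects
(paired t per group, Bonferroni over the two groups) run only when the
interaction is significant, main effects otherwise. The regression is
OLS (statsmodels) of cluster-mean theta contrasts on ERQ-R, ERQ-S and
the rating difference, Bonferroni over the 3 predictors, with a
condition-number guard (> 1e8 → error). The source study reports
df = (1, 94) for the rating ANOVA, which implies an observation-level
model it does not specify; this package reports the classical
split-plot df (1, n − 2) instead and documents the discrepancy rather
than reverse-engineering it.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` run at desk scale,
chosen as the package's own test sizes: an 80–120-voxel grid,
8 + 8 participants × 30 trials at 100 Hz for recovery runs (50 seeds
in the test suite, 10 in the acceptance script), 500–800 permutations,
500 null datasets (12 + 12) for family-wise calibration, and a
100-voxel grid for the localisation sweep. Recovery runs skip the
artifact-cleaning stage (the simulations are artifact-free by default)
and restrict TFR computation to the baseline and regulation windows —
an exact optimisation for the summaries used. The full-scale settings
(2839 voxels, 100 000 permutations, 25 + 25 participants) remain
available through configuration.

## Numerical choices and degenerate inputs

* Permutation p-values are never 0: add-one rule, floor 1/(N + 1).
* Zero pooled variance at a channel yields ±inf t with a warning.
* Zero baseline power raises an error naming the voxel; conditions
  with < 2 trials raise before ERP subtraction.
* The truncated-normal sampler degenerates to the exact mean at σ = 0.
* eLORETA non-convergence raises with the convergence report; the
  rank-deficient (average-referenced) covariance is handled by a
  Hermitian pseudoinverse.

## Known limitations

* The sphere model cannot represent realistic conduction anisotropy;
  localisation claims transfer to realistic geometry only insofar as
  the leadfield used for inversion matches the true one.
* MIM recovery is assessed at the planted pair; whole-brain averaging
  dilutes coupling, so single-pair effects need to be strong to
  surface in the voxel-to-whole-brain map.
* The behavioural simulator draws condition means independently per
  participant, so within-participant correlation structure of real
  rating data is not reproduced; ANOVA calibration, not effect-size
  realism, is the target.
* Amygdala/subcortical sources are outside scalp-EEG scope and are not
  modelled.
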