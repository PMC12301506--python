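# Methods

`megdot` reimplements, as a fully synthetic and testable pipeline, a
multimodal analysis that asks where total-hemoglobin (HbT) responses
measured with high-density diffuse optical tomography (DOT) covary with
the features of simultaneously recorded MEG somatosensory responses.
Because the human recordings such an analysis is designed for cannot be
redistributed, the package pairs every analysis stage with a generative
model of the experiment, so the whole chain runs end to end from a
seed.

## The experiment being emulated

Electrical median-nerve stimulation is delivered in ~2 s trains at
0.5, 1, 2 or 4 Hz (2, 3, 5 or 9 pulses with onset spacing 2/1/0.5/0.25 s;
one 0.2 ms pulse lasts 0.0002 s, so every train spans 2.0002 s from
first onset to last offset).  Each train is followed by a rest of
14–65 s; 15 trains per frequency are presented in pseudorandom order,
60 blocks per ~25 min run, two runs per subject, 18 subjects.  MEG
equivalent-current-dipole (ECD) waveforms from contralateral SI and SII
show the N20m, P35m and P60m deflections and a broad SII response at
60–200 ms; their amplitudes habituate at short inter-stimulus
intervals.  A 16-source/16-detector optical probe over the left
parietal cortex records amplitudes at 758 and 824 nm.

## Synthetic data model (`synthgen`)

**Dipole waveforms.**  The SI response to one stimulus is a sum of
three Gaussian lobes centered at 21, 34 and 60 ms (widths 1.5, 2.5,
8 ms) with alternating polarity (−, +, −); SII is one broad positive
lobe at 110 ms (width 30 ms).  Default peak moments are 15/25/10/8 nAm.
Habituation multiplies every stimulus after the first by
rho_i(ISI) = 1 − exp(−ISI/tau_i) with recovery constants
tau = 0.1 s (N20m), 0.5 s (P35m), 1.0 s (P60m) and 2.0 s (SII): the
earliest deflection barely habituates while later ones suppress
strongly at 4 Hz, reproducing the qualitative frequency dependence of
somatosensory evoked fields.  White noise (default 2 nAm per epoch at
1 kHz) models residual sensor noise after source modeling.  Per-subject
lognormal jitter (sd 0.2 on amplitudes, 0.1 on taus) creates the
between-subject variability that the across-subject correlation method
exploits.

**Head phantom.**  A layered half-space: scalp 5 mm, skull 6 mm,
CSF 2 mm, gray matter 4 mm, white matter filling the remaining depth,
on a 40×40×20 grid of 2 mm voxels by default.  Tissue optical
parameters are literature values for adult head tissue at 780–800 nm.
The layer thicknesses are typical adult parietal anatomy; they matter
because gray-matter sensitivity falls exponentially with the overlying
thickness.

**Sensitivity.**  Monte Carlo photon transport is out of scope; the
absorption Jacobian is the analytic photon-measurement density of a
homogeneous diffusive medium,
J[(s,d),v] = −(1/D)·G(r_s,r_v)G(r_v,r_d)/G(r_s,r_d)·V/(4π) with
G(r) = exp(−μ_eff r)/r, μ_eff = sqrt(3 μ_a μ_s'), D = 1/(3 μ_s').  The
effective homogeneous medium is the volume average of the superficial
layers down to the bottom of the gray matter — including the
semi-infinite white-matter fill would let its very high reduced
scattering dominate attenuation along paths real photons rarely take.
The kernel reproduces the banana-shaped weighting, monotone depth
decay, and total sensitivities on the scale of physical pathlengths
(differential pathlength factor ≈ 3 at 30 mm).  Distances are floored
at one voxel to avoid the Green-function singularity.

**Neurovascular coupling ground truth.**  Inside an "SI-like" ball of
gray-matter voxels (default radius 8 mm under the probe center), ΔHbT(t)
is β times the unit-peak regressor built from the *generative*
(closed-form) per-stimulus feature values — not the extracted ones — so
the truth is independent of the feature-extraction stage.  The default
β = 10 µM peak ΔHbT is at the strong end of focal cortical activation;
ΔHbO2 = 1.25·ΔHbT and ΔHbR = −0.25·ΔHbT (typical activation polarity),
converted to per-wavelength absorption through compiled hemoglobin
extinction coefficients and projected to log-amplitude through the
Jacobian.

**Noise.**  Per-channel log-amplitude noise: white (sd 0.002 per 10 Hz
sample), a random-walk drift (step 5e-5), and cardiac/respiratory/Mayer
sinusoids (1/0.3/0.1 Hz, amplitudes 0.008/0.003/0.003) with random
phases.  With the default coupling this puts the best-channel evoked
contrast near 1e-3 optical density on physiological background —
the regime in which the real study found modest but significant
correlations (cluster r ≈ 0.4).  Amplitudes are synthesized in single
precision; the rounding is orders of magnitude below the noise floor.

What the generator does *not* emulate: cortical folding and CSF light
piping (the phantom is a slab), spatially heterogeneous or non-Gaussian
physiology, motion artifacts, MEG sensor-space effects (dipole
waveforms are generated directly), and any nonlinearity of
neurovascular coupling.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not the physiological
fidelity of the forward model.

## Analysis chain

**MEG features (`megfeat`).**  Epochs (−200 ms to last stimulus
+250 ms) are notch-filtered (50 Hz), low-pass filtered (250 Hz,
zero-phase Butterworth order 4), optionally median-blanked over
0–10 ms post-stimulus (stimulator artifact), and averaged per
frequency.  Baseline drift is removed by anchoring a piecewise-linear
function to the −10..0 ms pre-stimulus means, smoothing it with an
8 Hz low-pass and subtracting; zero-phase filtering squares the
magnitude response, so design cutoffs are raised to keep the two-pass
−3 dB points at the nominal frequencies.  SI peaks are located as the
largest local extremum of |x| inside empirical windows (begin/end
mean ± 3 SD: N20m 18±2..27±2, P35m 28±2..40±7, P60m 42±8..135±26 ms),
constrained to follow the previous peak; lobe bounds are the nearest
zero crossings (stopping one sample inside the lobe's own polarity so
adjacent windows stay disjoint), falling back to minima of |x|.  AUCs
are signed trapezoidal integrals (rectification is a flag); SII uses
the fixed 60–200 ms window and RMS features the fixed 10–200 ms window.

**Hemodynamic prediction (`hemopredict`).**  Per-stimulus feature
values become impulses at the stimulus onsets on a 20 Hz grid and are
convolved with the canonical double-gamma HRF (response delay 6 s,
undershoot delay 16 s, dispersions 1, undershoot ratio 1/6, 32 s
support).  The prescribed 0.5 s shortening of time-to-peak (HbT leads
BOLD) is applied to the response-delay parameter (6→5.5 s) rather than
as a post-hoc shift, preserving h(0)=0; a pure-shift variant can be
configured.  Regressors are decimated to 2 Hz (anti-aliased FIR,
matching the optical chain), summarized as the trapezoidal AUC over
1–9 s (Method 1) and as five samples at 1,3,5,7,9 s (Method 2, 20 per
subject over the four frequencies).

**DOT chain (`dotrecon`).**  Amplitudes are resampled to 2 Hz,
log-transformed (channels are mean-centered first; the band-pass
removes the arbitrary baseline anyway and centering avoids resampler
edge ringing), band-passed 0.01–0.33 Hz, and samples beyond 7 SD are
flagged per channel.  Block-averaged responses are estimated by FIR
deconvolution (24 taps covering −1..10.5 s per train type plus a
shared baseline column); artifact exclusion is per channel, and a train
type with no usable blocks raises a rank error.  Absorption changes
minimize ‖Jx − ΔlogA‖² + α‖Lx‖² with L the 6-neighborhood negative
Laplacian (diagonal = neighbor count ≤ 6).  The solver factorizes the
smoothness normal matrix once — exactly, through the cosine transform
that diagonalizes the grid Laplacian (reflecting boundaries), with a
tiny positive-definite ridge whose scale balances bias against
round-off in the subsequent rank-n_pairs update — and folds in JᵀJ by
the push-through identity, so thousands of right-hand sides cost two
small matrix products each.  The default α is trace(JᵀJ)/trace(LᵀL)
× α_rel with α_rel = 10, the knee of a resolution/noise trade-off
measured on matched noise-on/noise-off simulations: much smaller
values reconstruct sharper images whose voxel noise drowns regional
signal.  Hemoglobin is unmixed per voxel through the 2×2 extinction
matrix; the field of view keeps gray-matter voxels whose mean |J| over
pairs (and subjects) is at least 1% of the gray-matter maximum.

A regularized underdetermined inverse necessarily attenuates absolute
amplitude (the phantom study recovers ~15% of the true region AUC at
any α, spread over a larger support); the across-frequency *pattern*
is preserved to within ~30% — the 0.01 Hz high-pass and the FIR
baseline column absorb part of the across-frequency contrast — which
is the quantity the correlation analyses consume.

**Coupling statistics (`couplestats`).**  Method 1 correlates the
measured HbT AUC vector (one row per subject × frequency) with the
predicted-AUC column of each feature, per voxel (Pearson r, two-sided
p from the t distribution with n−2 df).  Method 2 computes one r per
subject between the 20 measured and predicted samples, stabilizes with
Fisher z = ½ln((1+r)/(1−r)) (|r| clipped at 1−1e-6), and tests the
group mean of z with a two-sided one-sample t test; the reported voxel
r is tanh(mean z).  The frequency analysis correlates the HbT AUC with
the stimulation frequency in Hz (a log2-spaced encoding is available).
Voxels below the L1/L2/L3 thresholds (0.001/0.003/0.01) form
6-connected clusters (26-connectivity by option, 6 matching the
Laplacian neighborhood); clusters below the minimum volume (default
50 mm³) are discarded; the cluster statistic is recomputed on the
voxel-averaged signal (not by averaging voxel r), and per spatial
component the level with the lowest recomputed cluster p is reported.
Cluster p values are Bonferroni-corrected with N_MC = 187 (the
estimated number of independently imageable regions); corrected
p ≥ 0.2 renders as NS and p < 0.05 earns an asterisk.  A permutation
test (group labels permuted across subjects, statistic |r_A − r_B|,
p = (1+#{≥obs})/(1+n_perm)) checks subgroup differences.

Because the synthetic null noise field after reconstruction is far
smoother than real multi-channel physiology, suprathreshold null
components are much larger than 50 mm³ here; the package therefore
ships a calibration routine that sets the minimum volume to the
smallest multiple of the voxel volume whose family-wise false-positive
rate on a null ensemble does not exceed the target (0.05), measured on
a held-out ensemble.  The 50 mm³ default remains the protocol constant;
the calibrated value is reported alongside.

**Registration (`headreg`).**  Landmark correspondence gives a
closed-form rigid (Kabsch) initialization; the 9-parameter similarity
transform (per-axis scale, Euler rotations, translation) is refined by
coordinate descent over discrete grids (scale ±10% step 1%, rotation
±15° step 1°, translation ±20 mm step 1 mm), re-computing closest
surface points at every candidate (iterative-closest-point style) and
accepting only improvements, so the cost never increases.  The cost is
the mean of the landmark error (component-wise soft threshold
max(|d_c|−τ_c,0), τ default 4 mm per axis in the 3–5 mm range, then
norms averaged — per-component clipping rather than a landmark-level
deadzone) and the surface error (exact point-to-triangle distances,
facial points below the nasion weighted 0.8).  Optodes are carried to
the atlas frame by the inverse transform.  A triangulated ellipsoid
head with landmarks and surface points serves as the registration
fixture.

## Problem sizes used by the test suite and acceptance script

Simulation sizes were chosen so the full chain exercises every stage at
meaningful statistical power: the null-calibration ensemble uses 6
subjects and 2 train repetitions per frequency per dataset (100
calibration + 200 evaluation datasets) on the default phantom; the
parameter-recovery check runs 20 cohorts at the full study conditions
(18 subjects, 15 repetitions).  Unit tests use a 24×24×16 phantom.

## Known limitations

* The slab phantom and homogeneous diffusion kernel are qualitative
  stand-ins for Monte Carlo transport in a segmented head; absolute
  sensitivities and depth profiles are only order-of-magnitude
  faithful.
* Feature attribution under collinearity is ambiguous: the six MEG
  features share most of their across-frequency structure, so a
  cluster driven by P35m coupling may be led by another feature's
  (anti-)correlated column; localization is robust, attribution is not.
* Reconstructed amplitudes are biased low and spatially smeared, as in
  any quadratically regularized DOT inverse; only relative patterns are
  interpreted.
* The Fisher-z group t test is exact only asymptotically in the 20
  per-subject samples; its null p values are uniform to ~2% sup-norm
  at the default sizes.
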