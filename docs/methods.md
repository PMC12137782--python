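# Methods

## The reconstruction problem

Multi-shell diffusion MRI samples a 4D space: 3D k-space per volume and a
q-space location (gradient direction + b-value) per volume. Acquisition time
scales with both, so `msdager` targets the regime where every volume is
heavily undersampled in k-space (simultaneous-multislice × in-plane
acceleration, total factor R·SMS up to 12 with 8 coils — beyond the parallel
-imaging limit) and the missing information is recovered from q-space
redundancy: nearby directions, and corresponding directions on other shells,
carry nearly the same image.

SMS with blipped-CAIPI is treated throughout as a 3D encoding problem: the
group of simultaneously excited slices becomes a kz (partition) axis of
length SMS with step 1/FOVz_SMS, a pattern samples every R-th ky line with a
kz blip per acquired line, and the R·SMS patterns obtained by (ky, kz)
shifts tile the grid exactly once each. The default blip of R per line gives
the standard FOVy/SMS inter-slice image shift (for gcd(R, SMS) ≠ 1 the
smallest coprime blip is used instead so that all partitions are visited).

## The q-space Gaussian process

The signal of one voxel across the Nd diffusion-weighted volumes is modelled
as u ~ N(mu, Sigma) with a separable covariance

    Sigma_ij = lambda · C_theta(theta_ij; a) · C_b(b_i, b_j; l),

where C_theta is the compact-support spherical covariance (support `a`,
radians; antipodal angular distance, so theta in [0, pi/2]) and C_b is
squared-exponential in log b with length-scale `l`. Noisy magnitude data add
a per-shell noise variance sigma_n² on the diagonal; per-shell values absorb
the shell-dependent Rician bias. The GP mean is the per-voxel per-shell mean
signal. b=0 volumes are excluded from the GP (log b is undefined) and
reconstructed by plain CG-SENSE.

Hyperparameters (a, l, lambda, sigma_n² per shell) are fitted per tissue
class (white / gray from FA/MD thresholds of a quick log-linear tensor fit;
other brain voxels reuse the gray values) by maximizing the *restricted*
marginal likelihood: the per-voxel per-shell mean is integrated out rather
than subtracted empirically. This matters — centering with the same data
removes exactly the smooth signal component and biases the plain likelihood
toward degenerate all-noise fits; REML recovers a and l reliably even at
heavy noise. Optimization is bound-constrained L-BFGS-B on log/logit
transformed parameters with three deterministic starts; voxels are
subsampled (default ≤ 2000 per class) for tractability. Bounds keep
a ∈ [0.9°, 89.5°], l ∈ [e⁻³, e³] and variances within 12 decades of the
residual scale; during reconstruction sigma_n² is additionally bounded below
by a quarter of the VST noise measurement (the fit may not claim less noise
than independently measured).

The MAP signal estimate is the GP posterior mean
u̅ = mu + Sigma (Sigma + diag sigma_n²)⁻¹ (y − mu); the near-singular Sigma
is never inverted directly.

## Rician-aware noise estimation

Magnitude data carry Rician noise; a Gaussian-assumption estimate of the
noise SD is biased low, by 35% in pure-noise regions. The variance-
stabilizing estimate here is a two-stage closed-form realization: (i) a
robust magnitude-domain SD from spatial pseudo-residuals (voxel minus the
mean of its 4 in-plane neighbors, scaled by sqrt(4/5)), pooled by a median
over volumes and a 3×3 in-plane window; (ii) an analytic Rician correction
fixed point: the local mean/SD ratio determines theta = A/sigma through
E[z] and Var[z] = xi(theta) sigma², and iterating
theta ← sqrt(xi(theta)(1+r²) − 2) converges to the value whose corrected
variance s²/xi(theta) is independent of the local signal level — the
variance-stabilization criterion, checked by an 8-bin flatness diagnostic.
Bias is within ~10% for SNR 1.875–30 and grows to ~13% at SNR ≈ 1, where the
mean/SD inversion is steepest.

The analytic SENSE g-factor (aliasing-matrix formulation on the CAIPI-
collapsed 3D problem, pseudo-inverse for the rank-deficient case) is
provided and tested, but it describes the *exact* least-squares
reconstruction. At 12× with 8 coils the practical truncated-CG SENSE solver
is implicitly regularized and amplifies noise far less (≈3× rather than
≈130×), so the pipeline corrects image-domain noise estimates by an
*effective* amplification, measured deterministically by propagating one
seeded unit-variance noise realization through the same solver. k-space and
image-space white-noise variances are equal under the unitary FFT and
unit-SoS coil maps, so sigma_k² = sigma_n² (an identity conversion, kept
explicit).

## The outer loop

Per outer iteration: VST noise estimate from the current magnitudes →
FA/MD tissue masks (support by thresholding + in-plane morphology,
re-estimated as images improve) → per-tissue REML fit → GP prediction mu →
joint quadratic solve over all DWI volumes

    u = argmin_u  sum_j ||Omega_j F S P_j u_j − d_j||² / (2 sigma_k,j²)
                + 1/2 sum_v (u_v − mu_v)^H Sigma_prior⁻¹ (u_v − mu_v)

→ MUSE-style phase-map refinement from the new iterate. sigma_k² per shell
is estimated once, from the initial SENSE reconstruction: the data-
consistency residual when the sampling is overdetermined (it measures the
noise directly and vanishes for noise-free data), otherwise the VST image-
domain estimate divided by the effective amplification.

Three numerical choices proved decisive and are deliberate design features:

- **Whitened solve.** The joint solve substitutes u = mu + L z per tissue
  class (Sigma_prior = L Lᴴ, Kronecker structure over voxels), giving an
  identity prior on z. The spherical covariance is numerically near-
  singular; applying Sigma⁻¹ directly makes the normal equations
  unsolvable by CG, while the whitened system is well conditioned. Voxels
  outside all tissue classes get a weak uncorrelated zero-mean prior at the
  object's signal-power scale — without it their null-space content is
  unconstrained and CG amplifies noise there without bound. lambda = 0
  cleanly reduces to per-direction CG-SENSE.

- **Uncertainty-honest prior width.** The joint solve's Sigma_prior is the fitted
  covariance rescaled per shell. During bootstrap iterations its marginal
  variance is held at a quarter of the per-shell signal power: the GP
  prediction inherits the statistically *invisible* null-space error of the
  images it was computed from, so a prior width at the fitted signal
  variance would be grossly overconfident and freezes the alternation at
  its starting point (in pure null-space directions any prior pins u to mu,
  so a weak prior is safe — data wins wherever sampled, mu fills the rest).
  The final iteration tightens the width to the closed-form leave-one-
  direction-out prediction error of the GP on the current images, a
  misspecification-robust empirical error bar, for a closing denoising
  pass.

- **Cross-shell coupling in the solve.** The fitted cross-shell
  length-scale on ball-and-stick data is very large (the shells'
  mean-removed signals are almost perfectly correlated), and a solve prior
  with correlation ≈ 1 transfers one shell's data-consistency corrections
  at full amplitude into the other — which damps the lower shell and
  inflates cross-shell smoothing, since the shells' *corrections* are only
  partially shared even when their *signals* co-vary. The prior used in the
  joint solve therefore caps the cross-shell length-scale (default
  `solve_l_max = 0.7`, i.e. correlation ≈ 0.6 between b = 1000 and 2000
  s/mm²); GP prediction keeps the fitted value.

- **Phase handling.** Initial phase maps use an apodized central k-space
  window (Hann, central 25% in-plane, configurable) of a SENSE
  reconstruction run to twice the usual iteration count — the deeper solve
  measurably improves the phase estimate at high acceleration. The maps are
  then re-estimated from each outer iterate (the phase-corrected images
  should be real; residual smooth phase is phase-map error). At SNR 20 and
  12× acceleration the initial maps are poor (~1.4 rad RMS) and this
  refinement is what allows the data term to restore signal amplitude.

If a fitted angular support falls below the q-space neighborhood radius the
sampling design diversified (default 30°), it is replaced by a wide 60°
support: a covariance that cannot reach any neighbor decouples the joint
solve into per-direction SENSE, defeating the method's premise.

CG-SENSE itself is run truncated (15 iterations by default): beyond the
parallel-imaging limit the exact minimum-norm solution amplifies noise
enormously, and the truncation is the customary implicit regularization, so
the iteration count is an image-quality parameter. The inner CG of the
joint solve runs to a tight tolerance (1e-8); its residual oscillates on
ill-conditioned systems (only the A-norm error is monotone), so the solver
returns the lowest-residual iterate and never stops early on residual
oscillation alone.

## The synthetic study

The phantom is a multi-slice elliptical "brain" per simultaneous-slice
group: a gray-matter rim (ball compartment, d = 0.85e-3 mm²/s), a white-
matter interior with gently curving single fibers (f = 0.6, d = 1.7e-3) and
a contiguous crossing-fiber patch (two orthogonal sticks, f = 0.3 each,
default 15% of white matter), and a CSF-like core (d = 2.5e-3). Signals
follow the ball-and-stick model
S = S0[(1−Σf)exp(−bd) + Σ f_i exp(−bd (g·v_i)²)] with a single shared
diffusivity per voxel. These parameters give DTI-equivalent FA ≈ 0.5 / 0.3
in single-fiber / crossing white matter and FA < 0.2 in the rim, so the
FA/MD tissue thresholds recover the classes. Coil maps are eight smooth
complex Gaussian lobes ringed around the FOV, normalized to unit
sum-of-squares; per-direction phase errors are low-order in-plane
polynomials (zero at b=0). Complex Gaussian noise of standard deviation
`noise_sd` per channel is added to sampled k-space entries; the SNR
convention is SNR = mean white-matter b=0 magnitude / noise_sd, so noise SD
1–16 on a reference of 30 spans SNR 30 down to 1.875. The default study is
two shells (1000/2000 s/mm²) with staggered Fibonacci-hemisphere
directions, 18 per shell, one b=0 volume, a 4×60×64 grid (ky divisible by
R·SMS = 12 so the CAIPI patterns close into exact lattices), SMS = 4 × R =
3, SNR 20. Smaller grids (4×36×32) and direction counts are used in tests
to keep runtimes reasonable; the methods and defaults are identical.

What the generator does *not* emulate: EPI distortion, T2* blur, ghosting,
eddy currents, motion between shots beyond the smooth phase error, coil
noise correlations, and anatomical detail at HCP resolution. Passing tests
therefore demonstrate the correctness and qualitative behavior of the
machinery (operator contracts, noise estimation, information transfer,
ordering of methods), not clinical image quality.

## Pattern assignment

Ref-free greedy max-diversity assignment: volumes are visited in seeded
random order and each receives the pattern least used among its already-
assigned q-space neighbors (antipodal distance < 30°, across shells), ties
broken by global usage; several restarts keep the best. The diversity score
(mean fraction of distinct patterns per neighborhood) is reported so a
design can be audited against the intent of maximally diverse aliasing in
every neighborhood. A uniform random baseline is provided for comparison.

## Evaluation

nRMSE over magnitudes; the angular covariance profile (same-shell direction
pairs, binned by antipodal angle at 5° default, normalized by the median
zero-distance variance); the cross-shell ratio (voxel-wise ratio of
direction-averaged magnitudes, lower b over higher b, median and histogram
over a mask — its decrease versus ground truth is the cross-shell-smoothing
metric); and the weighted-DICE overlap of tract-density maps, with the
support intersection taken at weights strictly above a configurable
threshold (default 0).

## Known limitations

- At 12× undersampling with 8 coils the initial SENSE images are dominated
  by unresolvable aliasing; the alternation recovers a substantial part of
  it but reconstruction error remains well above what a 32-channel in vivo
  setup would give. Quantities driven by the residual noise floor (e.g.,
  the Rician inflation of high-b direction-averaged means) are accordingly
  larger than in a higher-SNR setting.
- The cross-shell ratio-decrease metric is particularly sensitive to this
  residual error: per-shell amplitude recovery and noise floor combine into
  a shell imbalance that varies strongly between study realizations
  (roughly 3–30% across seeds at the default study scale, driven by the
  interaction of the phase-error realization with coil conditioning through
  the initial SENSE quality). Typical realizations sit near 15%, well above
  the low-single-digit values a fully converged reconstruction of this kind
  can reach.
- The greedy pattern assignment is a heuristic; it matches or beats random
  assignment on the diversity score but carries no optimality guarantee.
- The VST noise estimator degrades at SNR ≲ 1 (see above).
- Hyperparameter fits on artifact-contaminated early iterates are biased;
  the bounds and rescalings described above contain, but do not remove,
  this bias.
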