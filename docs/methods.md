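# Methods

## Signal model

A diffusion-weighted inversion-recovery spin-echo (DW-IR-SE) measurement
acquires P contrasts, each defined by an inversion time TI (ms), an echo
time TE (ms) and a diffusion weighting b (s mm^-2), at a common repetition
time TR.  Assuming every voxel contains a mixture of water pools, each
characterized by a relaxation/diffusion triplet (T1, T2, D), the real-valued
signal of contrast p is

    M_p = sum_q f_q (1 - 2 exp(-TI_p/T1_q) + exp(-TR/T1_q))
                 exp(-TE_p/T2_q) exp(-b_p D_q),

where q runs over Q candidate components on a linearly spaced grid and
f_q >= 0 are spectral amplitudes.  Precomputing the P x Q kernel K makes the
forward model a matrix product M = K F.  b is converted to ms um^-2
(1000 s mm^-2 = 1 ms um^-2) so that b D is dimensionless with D in
um^2 ms^-1.  Contrasts without an inversion pulse carry an IR factor of
exactly 1 (they are represented with TI = nan, never with a large dummy TI).

Default grids: 60 points per axis, T1 in [50, 3000] ms, T2 in [5, 300] ms,
D in [0.05, 3] um^2 ms^-1, endpoints inclusive; 2D grids enumerate
components in row-major order (first axis slowest), and the kernel, the
marginal projections and the threshold boxes all assume this order.  When a
tissue axis is absent from the grid and its encoding scan parameter is
constant across the protocol, the corresponding decay is a fixed
per-component factor and is absorbed into the non-negative amplitudes; if
the protocol *varies* that parameter, a fixed nuisance value must be given
explicitly.  This absorption matters for interpretation: a 1D T1 fit at
fixed TE = 4.5 ms estimates amplitudes f_q exp(-4.5/T2_q), i.e. signal
fractions *at the acquisition echo time*, not pure spectral fractions.  For
the default white-matter mixture this shifts a 14.0% myelin-water spectral
fraction to a ~13.0% recovered signal fraction — an inherent property of
echo-time-weighted myelin imaging, not a solver bias.

## Acquisition presets

Three 8 x 8 product protocols (64 contrasts each) are built in:

* `t1t2`: TI in {50, 85, 143, 243, 412, 697, 1181, 2000} ms x TE in
  {4.5, 7.5, 12, 20, 33, 55, 91, 150} ms, b = 0, TR = 20 s.
* `t1d`: the same TI list x b in {0, 50, 100, 200, 350, 550, 750, 1000}
  s mm^-2 at TE = 21 ms, TR = 5 s.
* `t2d`: TE in {21, 28, 37, 49, 65, 86, 113, 150} ms x the same b list,
  no inversion, TR = 5 s.

Diffusion shells use (6, 6, 6, 7, 8, 10, 12) gradient directions for the
seven non-zero b-values (one volume at b = 0; a direction count is
meaningless without diffusion weighting).

## Digital phantom

The phantom emulates a single axial brain slice with three tissue classes
arranged as concentric regions on a 48 x 48 matrix (a 156 x 156 full-scale
variant exists): a CSF core (radius 6), a gray-matter ring (6-14) and a
white-matter ring (14-21).  The GM ring is deliberately wide (8 voxels,
~11 mm at the full-scale voxel size): it stands for cortical *plus* deep
gray matter, and thin test structures would be dominated by the boundary
smoothing that the spatially regularized solvers apply across tissue
interfaces (the same edge effect appears in vivo as slightly elevated MWF in
inner white matter).

Tissue mixtures place delta components at the centers of the spectral peaks
observed in healthy brain: myelin water at (T1 = 50 ms, T2 = 30 ms,
D = 0.4 um^2 ms^-1) with a fraction of 14% in WM and 6% in GM;
intra/extra-cellular water at (1000 ms, 70 ms, 0.8 um^2 ms^-1); CSF as a
single component at (3000 ms, 300 ms, 3 um^2 ms^-1).  Components are
snapped to the nearest grid cell so that on-grid recovery is well defined.

Noise: zero-mean Gaussian with standard deviation M0/SNR is added to the
signed per-direction signals, then the absolute value is taken, emulating
magnitude data whose inversion-recovery polarity is lost.  The default
amplitude SNR is 100, a realistic figure for protocol-level simulation;
solver-level tests can request signed or noiseless data.  Diffusion is
isotropic by default (the pipeline powder-averages anyway); an axially
symmetric per-direction diffusivity is available per component
(`d_delta`), with directions from a deterministic Fibonacci sphere.

What the phantom does *not* emulate: partial-volume mixing at tissue
borders, B1/flip-angle errors, stimulated echoes, Rician noise statistics
on complex data, within-tissue parameter dispersion (each pool is a grid
delta), motion, and k-space/reconstruction effects.  Tests passing on this
phantom therefore validate the inversion chain, not robustness to every
in vivo confound.

## Preprocessing

1. **Powder averaging** — unweighted arithmetic mean over the directions of
   each b-shell (no weighting is defensible without per-direction noise
   estimates); single-direction contrasts pass through.
2. **Polarity recovery** — per voxel, every monotone sign pattern over the
   sorted inversion times (negative below a candidate null crossing,
   positive above; at most one sign change) is scored by the residual of a
   non-negative least-squares fit to a coarse signed dictionary (12 T1
   points x 6 points of the second varied axis, built with the full
   kernel); the minimizing pattern is applied.  This is a multi-exponential
   generalization of the bi-exponential fit one would use voxel-wise; the
   dictionary order is configurable.  On noiseless magnitude phantom data
   the recovered signs match the true signed signals in >= 99% of voxels.
3. **L2 normalization** — each voxel is divided by the Euclidean norm of
   its full P-vector, removing M0 and receiver gain.  Voxels below
   1e-8 x max-norm are dropped from the mask rather than amplified.
4. **1D subset extraction** — from an 8 x 8 product, the 8 contrasts with
   the *other* varied scan parameter at its minimum.  When the extracted
   subset no longer varies TI but inherits a fixed negative inversion
   weighting (e.g. the TE series at TI = 50 ms, where long-T1 water is
   still inverted), the voxel's overall sign is flipped so the data are
   representable by non-negative amplitudes; the flip is absorbed into the
   amplitudes exactly like any other fixed factor.  A consequence is that
   the 1D T2 amplitudes estimate f_q |IR(TI_min, T1_q)| -- a distorted
   marginal; see "Known limitations".

## 1D solver (ADMM)

Objective, per spectral axis and data set:

    min_{F >= 0} sum_i ||M_i - K F_i||^2
                 + lambda_s1D sum_i sum_{j in N(i)} ||F_j - F_i||^2

with N(i) the in-plane 4-neighborhood (each unordered pair appears twice,
once per direction, as the sum is written per voxel; there is no coupling
across slices).  Default lambda_s1D = 0.5.

The smooth part (data + coupling) and the non-negativity constraint are
split with ADMM (penalty rho = 1.0, residual-balancing adaptation every 10
iterations, zero initialization, relative primal/dual tolerance 1e-6, at
most 2000 iterations).  The X-update is the Sylvester system
X (K^T K + rho/2 I) + 2 lambda_s L X = M K + rho/2 (Z - U); diagonalizing
K^T K (60 x 60, once) decouples it into 60 shifted sparse-Laplacian solves,
each prefactorized per rho value — the update is exact, so the solution is
invariant to voxel enumeration order.

Because P = 8 < Q = 60, the *noiseless* uncoupled problem has non-unique
minimizers and splitting iterates converge to a spread interior solution.
When lambda_s = 0 (voxels decoupled) the result is therefore polished to
the active-set vertex: a Lawson-Hanson iteration (own implementation,
independent of the SciPy routine used as a test oracle) started from the
identified support, kept only if it does not increase the objective.  With
spatial coupling the vertex structure is not defined per voxel and no
polish is applied.

## 2D solver (Douglas-Rachford)

Objective:

    min_{F >= 0} sum_i ||M_i - K F_i||^2
                 + lambda_s2D sum_{j in N(i)} ||F_j - F_i||^2
                 + lambda_m ||pi_1 F_i - F_i^1||_1
                 + lambda_m ||pi_2 F_i - F_i^2||_1

with pi_1/pi_2 the discrete marginals (sums over the other grid axis) and
F^1, F^2 the 1D solutions.  Defaults lambda_s2D = 0.01 and lambda_m = 1000.
The five convex terms are handled by product-space (consensus)
Douglas-Rachford splitting, step 1.0, relaxation 1.0:

* data term: prox by the Woodbury identity — only a 64 x 64 Cholesky
  factorization and two thin matrix products per iteration;
* non-negativity: projection (the reported iterate is projected, so F >= 0
  after every outer iteration);
* spatial coupling: exact solve of (I + 4 t lambda_s L) X = B via banded
  Cholesky (the C-order voxel enumeration keeps the Laplacian bandwidth at
  the mask row length; sparse LU fallback for wide masks);
* marginal penalties: pi pi^T = 60 I, so the prox of the composed L1 term
  is soft-thresholding in marginal space lifted back through pi^T / 60.

Initialization is the per-voxel outer product of the two 1D marginals,
rescaled to their mean total mass (zero-init available).  The raw
(amplitude) marginals are penalized, as the objective is written; with
lambda_m = 1000 and unit-norm signals the soft threshold exceeds any
plausible marginal value, so the penalties act as near-hard constraints
balancing the two (mutually inconsistent) 1D targets.

Class defaults run up to 3000 iterations with a 1e-6 relative-change
tolerance.  The pipeline preset (`RunConfig.solver_2d`) uses 400 iterations
at 1e-5.  With the near-hard marginal locks the consensus iterate keeps
drifting very slowly along the near-degenerate directions the huge penalty
creates (the objective still decreases by fractions of a percent per 50
iterations after a thousand iterations), so "full" convergence is not a
practical operating point; 400 iterations is past the regime where the
data-fit residual has equilibrated and keeps a complete phantom run in the
minutes range.  Both values are plain config fields.  See "Known
limitations" for how the marginal locks shape the fully converged solution.

## Compartment analysis

Signal fractions are obtained by thresholded integration of the voxel
spectra over boxes in (T1, T2, D):

* myelin water: T1 in [50, 300] ms, T2 in [5, 47] ms, D in [0.05, 0.6];
* IC/EC: up to T1 = 2000 ms, T2 = 120 ms, D = 1.3;
* CSF: the remainder of the grid.

Boxes are half-open (lo, hi] with the lowest box closed at the grid
minimum, so shared edges belong to exactly one compartment; the in vivo
peak ranges (myelin water T2 ~ 20-45 ms, IC/EC T1 ~ 700-1400 ms) fall
strictly inside their boxes.  The grid is uniform, so the constant cell
size cancels and discrete integration is a plain sum.  Amplitude outside
every box (spurious off-peak mass) is discarded *before* the three
fractions are renormalized to sum to 1; voxels with zero in-box mass are
flagged instead of dividing by zero.  An assign-to-nearest-box alternative
is not provided: discarding matches the delineation-then-ignore convention
the threshold approach implies.

MWF histograms use 0.2-percentage-point bins; 1-3 Gaussian components are
fitted to the bin counts by nonlinear least squares (quantile-based
initialization), not by EM on voxel values — the fit describes the
histogram, including bin-width broadening.  Fit-quality maps report
RMSE_i = ||M_i - K F_i|| / sqrt(P) against the signals the spectrum was
fitted to (8 for 1D, 64 for 2D).

## Numerical choices and degenerate inputs

* All internal computation is float64; volumes are stored as float32 NIfTI
  with JSON sidecars carrying the protocol/grid metadata.
* Zero-signal voxels: excluded from the mask at normalization; all-zero
  spectra are flagged in fraction maps rather than normalized.
* Solvers are deterministic (zero or marginal-product initialization, no
  randomized steps); two runs of the same configuration are bit-identical,
  and phantom noise is reproducible from the seed.
* Non-convergence within the iteration budget returns the current iterate
  with `converged = False` in the log — never an exception.

## Known limitations

* **2D fit error vs 1D fit error.**  With lambda_m = 1000 the marginal
  penalties effectively pin the 2D marginals to the 1D solutions.  The 1D
  amplitudes carry absorbed-factor distortions (TE decay for the T1 subset;
  |IR(TI_min, T1)| for the T2 subset), so they are *not* exact marginals of
  the true 2D spectrum, and the locked 2D fit cannot reach the per-voxel
  noise floor.  On this phantom at SNR 100 the 1D subproblems fit their 8
  signals essentially to the noise floor, so the 2D solution shows *larger*
  voxelwise RMSE than the 1D fits — the opposite ordering is expected (and
  observed here) only when the data are noisy enough that the 1D fits sit
  well above the systematic marginal-lock residual, as is typical for in
  vivo acquisitions.
* **Myelin content of the 2D T1-T2 solution.**  The T2-subset fit is
  acquired at the minimum TI, where myelin water's inversion factor is
  +0.26 while the long-T1 pools sit near -0.9; after the sign convention
  the fitted 1D T2 spectrum carries almost no short-T2 amplitude.  Locked
  to that marginal, the 2D solution progressively sheds myelin-water mass
  as iterations accumulate: its MWF map is meaningful at the pipeline
  preset's iteration count but decays toward zero at full convergence.
  Myelin quantification should therefore rely on the 1D T1 maps (which are
  also the best-quality maps in vivo); the 2D spectra serve correlation
  analysis of the slower pools.
* The MWF recovered from a fixed-TE 1D T1 fit is the TE-weighted signal
  fraction (see "Signal model"); comparisons against spectral ground truth
  inherit a ~1 percentage-point downward shift in WM.
* Spatial regularization smooths across tissue boundaries; thin structures
  (a few voxels) show biased medians.  The phantom geometry keeps regions
  wide enough that region medians are boundary-robust.
* The polarity fit assumes a single sign change along TI per voxel; voxels
  with pathological mixtures whose net signal crosses zero twice would be
  mis-signed (not observed on the phantom mixtures).
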