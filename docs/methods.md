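# Methods

This note records the modeling assumptions, numerical choices and known
limitations of the package, module by module.

## Synthetic phantoms and sources

Phantoms are voxel grids of relative electron density (water = 1.0) with a
parallel integer tissue-label grid, axis order (z, y, x), voxel centers at
`origin + index × spacing`, all distances in mm and doses in Gy. Three
seeded patterns are generated: `uniform`, `slab` (equal-thickness layers
along z) and `concentric` (nested shells around the grid center, emulating
concentric tissue-density variation around a target). Generation is
bit-reproducible for a fixed spec + seed.

CT calibration uses a piecewise-linear HU → relative-electron-density table,
by default (−1000 → 0.001, 0 → 1.0, 1000 → 1.1, 2000 → 1.5): the air and
water anchors are CT-calibration conventions and the two supra-water points
give soft-tissue/bone-like slopes. The table is a repo convention, not a
measured scanner calibration; real deployments should substitute their own.

Sources are mono-group: `nominal_energy` ("6 MV", "Ir-192") is a label kept
as the extension point for polyenergetic spectra, which are out of scope.
External beams are collimated square fields entering on the face nearest the
beam direction; brachytherapy seeds are isotropic point emitters at a
position in mm. Prescription dose (default 2 Gy) is carried on the source
and used for normalization.

## Transport

Steady-state, single-energy-group photon transport. The time derivative and
energy integrals of the general transport equation are dropped: resolving
them would multiply the system dimension far beyond desk scale, and the
spatial/angular system is what the linear-solver pipeline consumes. The
angular and spatial discretizations are:

- **Ordinates**: equal-weight direction sets (weights sum to 4π): +z for
  n = 1 (collimated slab problems), ± coordinate axes for n ≤ 6, a
  Fibonacci-sphere design above. Equal weights keep the quadrature exactly
  normalized at any count.
- **Streaming**: first-order upwind differences, vacuum boundaries, optional
  prescribed inflow on upwind faces (used for external beams).
- **Scattering**: Henyey–Greenstein phase function with configurable `g`
  (default 0, isotropic). The discrete phase matrix is renormalized per
  incoming ordinate so scattering redistributes exactly unit probability;
  without this, coarse ordinate sets would leak or create particles.

The assembled sparse matrix reports `s` as the exact maximum nonzeros per
row. κ is the 2-norm condition number: exact dense SVD for dimensions ≤ 64,
otherwise power iteration on AᵀA and on its inverse action through an LU
factorization. Power iteration runs up to 200 iterations with a 1e-9
relative tolerance — convergence of the smallest singular value on upwind
systems is slow, and at desk scale the extra iterations cost microseconds.
The deterministic solve is a direct sparse factorization with a relative
residual check at 1e-8; it is the ground-truth oracle for the quantum
solver.

Monte Carlo transport is analog with Woodcock (delta) tracking: free paths
are sampled against the grid-maximum attenuation, candidate collisions are
real with probability μ_t/μ_max, and real collisions absorb (full local
energy deposit) with probability μ_a/μ_t or scatter through a sampled
Henyey–Greenstein angle. Analog transport keeps energy bookkeeping exact —
emitted = absorbed + escaped to machine precision — which the suite asserts;
variance-reduction techniques (splitting, Russian roulette) are deliberately
omitted because they would break this identity and are not needed at desk
scale. Uncertainty comes from 10 batches (per-voxel standard error of the
batch means).

Dose is μ_a × scalar flux, divided by relative density when a density grid
is supplied (energy per unit mass), then rescaled so a reference receives
the prescription dose. The reference is the maximum-dose voxel by default;
a reference *mask* (e.g. the beam entry layer) is the robust choice for
Monte Carlo tallies, where the global maximum is biased upward by noise —
the MC/deterministic cross-checks normalize both arms on the same mask for
this reason. The cross-method agreement fixture is absorption-dominated with
a collimated beam: with few ordinates, scattering-dominated problems exhibit
ray effects that are a property of discrete ordinates, not a defect either
arm should absorb.

## Quantum solvers

The HHL simulation is register-faithful: Hadamards on the clock, controlled
powers of exp(iAt), inverse QFT, the conditioned ancilla rotation with
constant C, exact uncomputation, and post-selection on (ancilla = 1,
clock = 0). Because applying the controlled-U^(2^k) ladder to clock value j
is algebraically U^j, the simulator applies matrix powers blockwise per
clock basis state; this is the same linear map the gate circuit produces.
Choices:

- **Evolution time**: auto-chosen as t = π/(2·λ_max), i.e. |λ|t/(2π) ≤ 1/4.
  Placing λ_max at half the register range would land it exactly on the
  two's-complement sign boundary of the clock readout and flip its sign;
  quarter scale keeps a guard band while preserving exact representation of
  eigenvalue ratios that are powers of two.
- **Rotation constant**: C = 0.9 × the smallest resolvable eigenvalue
  2π/(2^m t); if λ_min is not resolvable at the configured clock width the
  solve refuses and names the required width.
- **Non-Hermitian systems** are embedded as [[0, A], [Aᴴ, 0]] (dimension
  doubles; the solution sits in the lower block). Dimensions are padded to a
  power of two with an identity diagonal.
- **Modes**: `statevector` returns the exact post-selected amplitudes;
  `sampled` draws multinomial shots from the full register distribution, so
  only the post-selected fraction of shots (the success probability) carries
  solution statistics.
- The returned solution is rescaled from the unit-norm quantum state to the
  classical magnitude, and fidelity is reported against the classical
  sparse/dense solve.

The asymptotic cost model is log₂(N)·s²·κ²/ε with the classical O(N)
reference. A flag (`as_printed=True`) switches ε to the multiplicative
position; the inverse dependence — cost grows as precision tightens — is the
standard HHL scaling and the default.

The VQE-style fitter encodes each physical parameter in the angle of an RY
rotation on its own qubit: p_i = lo_i + (hi_i − lo_i)(⟨Z_i⟩ + 1)/2, with the
expectations read from the explicit statevector. The cost is the mean
squared dose mismatch between the forward model and the reference, minimized
by a gradient-free Nelder–Mead outer loop with a seeded initial simplex; the
recorded trace keeps best-so-far costs, hence is non-increasing by
construction. The ansatz, depth and observable are design choices of this
package: a product ansatz suffices because the cost couples parameters only
through the classical forward model.

## Dose surrogate

The encoder–decoder is fixed by its per-layer parameter counts; kernel
geometries follow from them: 3×3×3 no-bias convolutions for the 1,728 /
221,184 / 27,648 weight layers, 3×3×1 no-bias for 73,728, a 2×2×4 stride-2
no-bias transposed convolution (padding (0,0,1)) for 32,768, and a biased
3×3×1 output convolution for 289. The transposed-convolution kernel is the
weakest inference — several kernel shapes reach the same count — so the
count, not the shape, is the asserted contract. Batch-norm stages count
4 × channels (scale, offset, tracked mean, tracked variance). The network is
fully convolutional: tests run at 16³, the production default is 64³, and
counts are independent of spatial size. A dropout stage (rate 0.3) sits at
the encoder bottleneck; it is parameter-free, active in training and in
MC-dropout inference, and removable (`with_dropout=False`). A recurrent
per-fraction wrapper is not implemented: the layer table defining the
contract contains no recurrent stage, so the convolutional path is
normative.

The final convolution is zero-initialized, so an untrained network predicts
exactly zero dose — a safe baseline that also anchors the training tests.
Training minimizes mse_w·MSE + mae_w·MAE + λ‖W‖² (weights 1.0 each,
λ = 1e-4, L2 over convolution weights only) with Adam, plain SGD or SGD with
momentum 0.9. All forward/backward passes are numpy (im2col convolutions,
argmax-cached pooling, standard batch-norm backward); training is
bit-reproducible for a fixed seed on a fixed BLAS. MC-dropout uncertainty
runs T stochastic passes with dropout active at inference and reports the
per-voxel mean, sd (ddof = 1) and the 2.5/97.5 percentile interval.

Smoke-test training uses a higher learning rate (0.03) and small batches
than the production defaults: with ~50 optimizer steps, the default
lr = 0.001 cannot move the zero-initialized output head to the dose scale,
and the test measures optimization mechanics, not final accuracy.

## Hybrid refinement loop

Each iteration: predict → simulate → compare → update (one training epoch on
the freshly simulated target, then optionally a quantum-parameter refinement
callback). An update that increases the discrepancy is rolled back and the
learning-rate step halved, making accepted discrepancies non-increasing by
construction — the update-rejection policy is this package's choice where
the loop description leaves bad steps unspecified. Discrepancy metrics: MAE
(Gy, default), Dice-complement and Hausdorff at an isodose threshold; an
empty isodose volume on one side scores the grid diagonal (worst case)
rather than erroring, since an untrained model legitimately starts there.
Stopping is exact: `tolerance` when the recorded discrepancy reaches it
(checked after recording, so an infinite tolerance stops after one
iteration), else `max_iterations`. The distributed QPU/GPU deployment the
loop abstracts is reduced to sequential in-process calls with the same
interfaces.

## Dosimetric metrics

The gamma index is the standard Low-type formulation: per evaluated voxel,
the minimum over reference voxels within the search radius (3× the distance
tolerance, configurable) of √[(Δd/dose_tol)² + (Δr/dist_tol)²], with global
(% of reference max, default) or local normalization and a 10% low-dose
cutoff excluded from the pass rate. The search enumerates integer voxel
offsets sorted by distance with an early exit once the distance term alone
exceeds the current worst candidate; the suite checks exact agreement with
an exhaustive brute-force implementation. No sub-voxel interpolation is
performed — a documented possible refinement that tightens, never loosens,
gamma values.

DVH curves are cumulative (percent of structure receiving at least each bin
dose, 0.1 Gy default bins, V(0) = 100%). Dice and Hausdorff operate on
supra-threshold isodose volumes (default threshold 50% of prescription):
Dice with the both-empty = 1.0 convention, Hausdorff as the classical
max-min distance between boundary-voxel centers in mm (not a percentile
variant, matching a "maximum distance" definition). Whether such overlap
scores should instead be computed in DVH-curve space is ambiguous in the
source material; isodose volumes are implemented.

## Sensitivity and uncertainty

Sobol indices use the Saltelli scheme on scrambled Sobol' points
(n·(d+2) model calls): Saltelli-2010 for first order, Jansen for total
order. Pairwise interactions (closed second-order minus the two first-order
terms) are computed only on request. A constant model returns all-zero
indices with a zero-variance flag. FAST uses the extended-FAST search curve
x(s) = 1/2 + arcsin(sin(ωs + φ))/π with driver frequency 8, four harmonics,
unit complementary frequency, and one curve per parameter; the minimum
sample count 2·M·ω + 1 = 65 is enforced.

The default treatment-planning space is beam energy (4–10 MV, scaling
attenuation inversely), beam tilt (0–0.8 rad, entering smoothly as the
slant-path 1/cos factor), patient anatomy (density scale 0.8–1.2) and
treatment time (30–300 s). Treatment time is accepted for interface fidelity
although steady-state transport ignores it — its near-zero indices double as
the built-in dummy-parameter check. The default scalar summary is the mean
dose; first-order Saltelli estimates on this model need n ≳ 256 base samples
to stabilize, which is the command default. Posterior summaries are sample
mean, sd (n−1) and the central percentile interval.

## Workbench

A single global seed fans out to named streams via CRC-32 mixing
(`derive_seed`), so any module can be re-run independently yet
reproducibly; derived seeds stay below 2³¹. Every command echoes all
effective parameters into `manifest.json`, and identical config + seed
reproduce byte-identical primary outputs (NIfTI payloads compared after
gzip, whose header embeds a timestamp). Exit codes: 0 success, 2
config/validation error, 3 runtime failure.

## Problem sizes

The suite and the acceptance script run at deliberately small scale chosen
as this package's reference conditions: 16³ phantoms (2 mm voxels), 1–6
ordinates, 10⁵–2×10⁵ Monte Carlo histories, HHL systems of dimension ≤ 8
with 6–9 clock qubits, 20-sample surrogate trainings of 10 epochs at 16³,
Sobol base samples of 2048 on closed-form benchmarks and 256 on the
transport demo, and 10⁵ posterior draws.

## Known limitations

- Single energy group; no electron/positron transport, pair production or
  polyenergetic spectra — attenuation magnitudes are representative, not
  measured cross sections.
- Discrete ordinates at desk-scale counts show ray effects on point-source,
  scattering-dominated problems.
- The HHL simulator is noiseless; hardware noise models, error mitigation
  and QPU execution are out of scope (the fidelity/success-probability
  report is the hook where mitigation quality would surface).
- The surrogate's synthetic training corpora (slab/concentric phantoms with
  analytic or MC dose) exercise optimization and reproducibility; passing
  its tests says nothing about accuracy on clinical CT anatomy.
- Dose grids are normalized to prescription at a reference; absolute
  dosimetry (MU calibration) is not modeled.
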