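# Methods

## Model

The package simulates the transmembrane potential `u(x, t)` of a 2D slab
of cardiac tissue with the monodomain equation coupled to the two-variable
Aliev–Panfilov (A–P) ionic model:

    du/dt − div(D ∇u) + I_ion(u, w) = I_app(x, t)
    dw/dt = g(u, w)
    ∇u · n = 0 on the boundary,   u(·, 0) = w(·, 0) = 0

with

    I_ion(u, w) = K u (u − a)(u − 1) + u w
    g(u, w)     = (ε0 + c1 w / (c2 + u)) (−w − K u (u − b − 1))

Everything is integrated in rescaled units: one time unit is 12.9 ms and
the dimensionless potential maps to millivolts by `ũ = 100 u − 80`
(resting −80 mV, excited +20 mV). The conductivity tensor is
transversely isotropic, `D = σ_t I + (σ_l − σ_t) f0 ⊗ f0`, with unit fiber
field `f0`; printed conductivity products (e.g. `12.9·0.1 cm²/ms`) are
used verbatim as coefficients of the rescaled-time equation, and stimulus
windows given in ms are mapped by `t = t̃ / 12.9`.

**Gating sign convention.** The recovery variable evolves as
`dw/dt = g(u, w)` with `g` as written above. This is the classical A–P
recovery law: `w` relaxes at rest (`dw/dt = −εw` for `u = 0`) and grows
during the plateau, which is what produces repolarization and
refractoriness. The opposite sign freezes the tissue in the excited state
(verified on a single cell: `u` never returns to rest and no re-entry can
be sustained), so it cannot be the intended model. The convention is
stated in `cardiorom.ionic` and asserted by tests.

**Stimulus amplitudes** are treated as dimensionless source magnitudes of
the nondimensional equation; the ischemic scenario's Gaussian stimulus
`C exp(−‖x‖²/β)` with `β = 0.02 cm²` is applied exactly as a formula (it
is numerically a near-point source on coarse grids).

## Full order model (FOM)

Space: bilinear quadrilateral (Q1) elements on the uniform `nx × ny` node
grid, which matches the stated grid-point counts exactly. The mass matrix
is lumped (row sums; the diagonal partitions the domain area) and the
ionic terms are evaluated nodally, so the gating ODEs are collocated at
the grid nodes. The stiffness matrix encodes `−div(σ(x) D ∇·)` with
homogeneous Neumann conditions; an elementwise-constant tensor is used
(nodal modulation fields averaged per element), assembled with 2×2 Gauss
quadrature.

Time: one-step, first-order, semi-implicit. The gating variable is
advanced first by explicit Euler and its new value enters the ionic
current; diffusion is implicit (no CFL restriction from the Laplacian),
reaction explicit:

    w^{k+1} = w^k + Δt g(u^k, w^k)
    (M/Δt + A) u^{k+1} = (M/Δt) u^k − M I_ion(u^k, w^{k+1}) + M I_app(t^k)

The update order (gating first, new `w` in `I_ion`) is this package's
choice; it is documented rather than prescribed by the formulation, and it
is covered by the dt-convergence test. The system matrix is
parameter-dependent but time-independent, so one sparse LU factorization
is reused across all steps. A non-finite guard runs every 100 steps.
Times are recomputed from the step index (never accumulated), and
stimulus windows carry a 1 ns tolerance, so window-edge decisions are
identical across the FOM and the reduced solvers.

## Scenarios

Three parametrized slab families are shipped as presets, with the printed
parameter values frozen into tests:

* **Ischemic slab** (`test1`): Ω = (0, 10 cm)², the scar center
  (μ1, μ2) ∈ [3.5, 6.5]² is the parameter. The smooth factor
  ρ(x; μ) = 1 − exp(−((x1−μ1)⁴ + (x2−μ2)⁴)/(2α²)), α = 7, multiplies the
  ionic current, and σ = ρ + σ0(1−ρ) with σ0 = 10⁻⁴ multiplies D, so the
  scar core conducts (almost) nothing and has no active kinetics.
  49 training / 36 testing scar locations on staggered lattices.
* **S1–S2 re-entry** (`test2-full`, `test2-reentry`): Ω = (0, 2 cm)², an
  S1 strip stimulus (y ≤ 0.1, [0, 5] ms) followed by an S2 disk (radius
  0.2 at (1, μ), [70, 75] ms) elicits a figure-of-eight re-entry;
  snapshots are restricted to [95, 175] ms where the re-entry exists.
  13 uniform training values of μ, 12 midpoint test values.
* **Restitution variability** (`test4`): D = μ2 I + (μ1 − μ2) f0⊗f0 and
  μ3 replaces c1 in g. When μ1 < μ2 the same tensor is represented
  exactly with the roles swapped and fibers rotated 90°, keeping the
  σ_l ≥ σ_t representation valid. The printed 4×4×4 test lattice
  enumerates 64 points while 16 test instances are used; the first 16 in
  lexicographic order are taken (configurable) — the enumeration is
  internally inconsistent and no guess is made about which 16 were used.

Each preset has a `-mini` desk-scale variant (coarser grid, fewer
parameter instances, fewer stored snapshots) used by the benchmarks;
`test1-mini` is 32×32 with 9 training / 4 testing scar locations and 200
stored snapshots out of 4000 steps.

## POD-Galerkin-DEIM baseline

The linear ROM approximates `u ≈ V u_n` with `V` the leading left
singular vectors of the snapshot matrix; the retained dimension is the
smallest `n` with `Σ_{i≤n} σ_i² / Σ σ_i² > 1 − ε²_POD` (strict
inequality, as stated). Mode signs are fixed (first nonzero entry
positive) for reproducibility. With `N_c > 1`, snapshots are clustered by
k-means (k-means++ init, seeded) in full state space and one basis/DEIM
pair is built per cluster.

The ionic term is closed by DEIM: POD of the ionic-current snapshots
(recorded during the FOM runs, not recomputed) gives Φ, the greedy
residual-maximization sweep selects m interpolation nodes, and online the
term is `Φ(PᵀΦ)⁻¹ Pᵀ I_ion` evaluated only at those nodes. The gating
variable is advanced only at the active cluster's DEIM nodes; a
full-length gating vector is kept lazily so that on a cluster switch the
newly needed entries reuse their last stored values (zero if never
visited) — an explicit approximation, since the formulation does not
specify switch handling. Cluster switching picks the nearest centroid to
the reconstructed state, checked every `cluster_stride` steps. Online
setup (once per μ) projects the μ-dependent stiffness, stimulus loads
and ionic scaling onto the fitted bases; after that each step solves a
dense `n × n` system (prefactorized LU per cluster) and touches only n-
and m-sized operators — a poisoning test asserts that no other entries
of `V` are read between sample times.

## DL-ROM

The nonlinear ROM is `ũ(t; μ) = f_D(φ(t, μ))`: a feedforward network φ
maps the normalized (t, μ) to n latent coordinates and a convolutional
decoder f_D maps them to the state. An encoder compresses snapshots
during training only, tying the latent coordinates to the data through
the two-term per-sample loss

    L = ω_h/2 ‖u − ũ‖² + (1 − ω_h)/2 ‖ũ_n − u_n‖²,

averaged over samples (ω_h = 0.5 by default, exposed in config).
Evaluation never touches the encoder and never solves a dynamical system;
each (t, μ) query is independent, so trajectories can be sampled at any
time resolution and out of order.

Data preparation: snapshot columns are min–max scaled to [0, 1] with
global training statistics, reshaped to s×s squares with
s = ceil(sqrt(N)) and zero-padded; padded cells are masked out of the
reconstruction loss so the decoder spends no capacity on them. The
(t, μ) inputs are min–max scaled per component. Both normalizations are
the package's choice.

Architecture default: 4 convolutions (kernel 5×5, stride 2, channels
8/16/32/64) + dense layer to n for the encoder, a mirrored transposed-conv
stack for the decoder, and a 4×50 ELU feedforward network for φ — all
overridable; the desk benchmarks use lighter stacks (3 conv layers,
channels 4/8/16 on 32×32 data). The networks, their reverse-mode
gradients and the Adam optimizer are implemented in numpy inside the
package (`cardiorom.nn`) and verified against finite differences.

Training: Adam (default learning rate 1e-4 as in the study protocol; the
desk-scale benchmarks use 1e-3, the standard Adam default, to converge
within their reduced epoch budgets), random 8:2 train/validation split at
the individual (t, μ)-sample level (the split granularity is a package
choice), early stopping when no new strict validation minimum appears
within the patience window, best-validation weights restored. All
randomness (split, init, batch order) derives from one seed; repeated
runs are bitwise identical.

## Error indicators and outputs

* ε_rel: mean over test instances of
  sqrt(Σ_k ‖u^k − ũ^k‖² / Σ_k ‖u^k‖²).
* ε_k: per-node field |u^k − ũ^k| / ((1/N_t) Σ_k ‖u^k‖₂).
* ε_k^s: per-node percent field |u^k − ũ^k| / ‖u^k‖₁ × 100, implemented
  with the 1-norm normalization exactly as defined even though it yields
  very small percentages on large grids.
* Activation time: first upward threshold crossing, linearly interpolated
  between samples, in ms; APD: total dimensional time above threshold.
  The default threshold is u = 0.5 (≈ −30 mV), configurable; no
  particular value is prescribed by the formulation.

## Benchmarks: sizes, tolerances and what they show

The desk-scale studies in `cardiorom.benchmarks` (shared by the test
suite and `scripts/acceptance.py`) use:

* **dt convergence**: 17×17 slab, T = 30 ms, dt ladder
  (0.2, 0.1, 0.05, 0.025)/12.9, with a broad (β = 2 cm²) stimulus so the
  excitation is resolved on the coarse grid — a near-point source at this
  resolution sits at the propagation threshold, where the front responds
  discontinuously to dt and no asymptotic slope exists. Expected log-log
  slope ≈ 1 (band [0.8, 1.2]).
* **anisotropy**: 97×97 slab, planar waves along/across fibers, probe
  pair 4 cm apart; CV ratio within 10 % of sqrt(σ_l/σ_t) = sqrt 2.
* **POD reproduction**: a single FOM run stored at every step (32×32,
  T = 100 ms, 1000 snapshots) so the basis spans every visited state;
  with ε_POD = 10⁻⁶ the online trajectory reproduces the run to ~10⁻⁶,
  asserted < 10⁻³. With subsampled snapshots this bound would be
  meaningless, because the online solver visits states outside the span.
* **toy manifold**: u(t; μ) = sin(πt) μ φ(x) on 16×16; intrinsic
  dimension 2, so an n = 2 model must reach test ε_rel < 5·10⁻².
* **mini comparison**: `test1-mini`, both ROMs at n = 3 (= n_μ + 1, the
  intrinsic dimension). Three linear modes cannot represent a travelling
  depolarization front (ε_rel ≈ 1), while the nonlinear decoder can
  (ε_rel < 0.1 after 150 epochs); the benchmark asserts the ordering and
  a usable absolute accuracy, reproducing at desk scale the qualitative
  finding that motivates the method.

What passing these does **not** show: the synthetic scenarios have smooth
geometry, axis-aligned constant fibers, a phenomenological two-variable
ionic model and noise-free snapshots. Real tissue (curved geometry,
rule-based fiber fields, stiff biophysical ionic models, measurement
noise) is outside what the tests exercise; the full-scale presets also
run, but their training cost is hours, not minutes.

## Numerical choices and degenerate inputs

* Energy criterion uses the strict `>` as stated; `ε_POD` outside (0, 1)
  is rejected.
* DEIM dimension defaults to the numerical rank of the ionic snapshot
  matrix (singular values above `1e-12 σ_max`); a singular `PᵀΦ` or
  duplicate indices raise.
* k-means retries with shifted seeds if a cluster empties, then fails.
* `c2 + u` within 1e-8 of zero raises rather than silently clipping.
* Constant snapshot matrices (max = min) are rejected by the normalizer.
* Reduced-solve divergence (non-finite coordinates) aborts with the step
  index, as does the FOM guard.
* Queries outside the training (t, μ) range warn but evaluate.

## Known limitations

* 2D structured slabs only: no unstructured meshes, 3D geometries,
  bidomain equations, or biophysical ionic models.
* The numpy training loop is single-core; the full presets
  (e.g. 49 × 1000 snapshots at 64×64) train in hours, not minutes.
* The POD-Galerkin online phase reassembles and projects the μ-dependent
  stiffness, ionic scaling and stimulus loads once per parameter instance
  (an N-sized setup cost); affine/interpolated operator decompositions
  (matrix-DEIM), which would remove that setup cost, are out of scope.
* Cluster-switch gating reuse is an approximation (see above); with
  aggressive clustering on long trajectories it can degrade accuracy.
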