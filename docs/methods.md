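# Methods

This note documents the models implemented in `stenoshear`, the defaults
they ship with, and what the synthetic study conditions do and do not
establish about real data.

## Vessel geometry

A centerline is an arc-length-parameterized path `r(s)` with lumen radius
`R(s)`. The standard representation is 80 mm total length sampled at 640
points, endpoints inclusive (spacing `80/639 ≈ 0.1252 mm`); resampling
iterates spline-based arc-length reparameterization until chord spacing is
uniform to 1e-9 relative. Descriptors are computed by central finite
differences on the uniform arc grid (second-order one-sided stencils at the
ends): path length `l`, chord `c`, sinuosity `S = l/c` (1 for a straight
vessel), curvature `κ = |r′×r″|/|r′|³` and torsion
`τ = det(r′,r″,r‴)/|r′×r″|²`. Where `|r′×r″| < 1e-9` the torsion quotient is
0/0 (straight segment) and is defined as 0. Endpoint values of κ and τ are
excluded from closed-form comparisons since the one-sided stencils lose an
order.

The descriptor vector used for constraining synthesis is
`(S, ∫κ ds, max κ)`. The "integral curvature measures" of a clinically
derived shape model are not uniquely defined; total and maximum curvature
are the two stand-ins exposed here, and the default bounds
(`S ∈ [1.0, 1.6]`, `max κ ≤ 0.35 mm⁻¹`, `∫κ ds ≤ 12 rad`) were measured from
the four packaged template families (straight, single-bend, S-bend, helical)
with margin — not from a patient cohort.

Synthesis deforms a template by `n_bumps = 6` Gaussian displacement bumps
(σ = 10 mm along the arc, isotropic random directions, amplitudes drawn
`N(0, amplitude²)` with `amplitude = 1 mm` by default), then rescales and
resamples. Candidates violating the descriptor bounds are rejected and
redrawn up to a retry cap; the violated bound is reported if the cap is
exhausted. A fixed seed makes the draw bit-reproducible.

## Stenosis sculpting

Lesions carry a morphology class (concentric/eccentric × round/oval), an
area ratio `AR = A_sten/A₀ ∈ [0.1, 0.9]` (10 % severe, 30 % moderate, 50 %
mild), an axial position in [10, 70] mm, an orientation, and for eccentric
classes an offset `d` of the throat center up to 50 % of the local radius.
Round throats have `a = b = √AR·R₀`; oval throats draw an aspect ratio
`a/b ∈ [1.5, 2.5]` and solve `πab = AR·πR₀²`. The axial transition from the
nominal circle to the throat ellipse is a raised cosine over a configurable
extent (default 8 mm); the physically specified quantity is the throat geometry,
the taper shape is a package choice. Dual lesions must keep their throats at
least one axial extent apart — closer pairs would merge into a lesion shape
the blending model does not represent.

Wall nodes are placed in rotation-minimizing (double-reflection
parallel-transport) frames rather than Frenet frames, which flip on
near-straight segments. Node `(i, k)` sits at circumferential parameter
`2π(k−1)/n_θ` on station i's boundary; with `n_θ = 40` the inscribed 40-gon
underestimates the analytic ellipse area by `1 − sinc(2π/40) ≈ 0.41 %`,
within the 0.5 % discretization tolerance used by the lattice invariants.
The coordinate convention places the inlet at the origin with the inlet
tangent along +z.

## Reduced-order WSS oracle

The oracle replaces a transient 3D finite-volume CFD solution entirely; it
is a deliberately simple quasi-1D model and every performance number in this
package is measured against it, not against CFD. Its backbone is mass
conservation plus Poiseuille wall shear:

    Ū(s) = Q / A(s),   τ(s) = 4 μ_eff Ū(s) / R_eq(s),

with `Q` fixed by the 0.20 m/s cycle-averaged inlet velocity over the
nominal area and `R_eq = √(A/π)`. The effective viscosity follows the
Carreau law `μ = μ∞ + (μ₀−μ∞)[1+(λγ̇)²]^((n−1)/2)` evaluated at the local
Poiseuille wall shear rate `4Ū/R` (one fixed-point pass); the defaults
(μ₀ = 0.056 Pa·s, μ∞ = 0.00345 Pa·s, λ = 3.313 s, n = 0.3568) are standard
literature blood values. A `newtonian_mu` override gives the constant-μ mode
used by conservation tests.

Three multiplicative structures are added to the backbone:

* **Circumferential modulation** — inverse wall distance from the
  centerline point, normalized to unit ring mean. Concentric round rings
  stay uniform; oval rings peak on the minor axis (flow compression);
  eccentric rings peak on the plaque side — the side the lumen center moved
  *away* from, i.e. opposite the offset direction, where the residual gap is
  narrowest.
* **Curvature modulation** — `1 + c_κ·κR·cos(φ − φ_curv)` biases WSS toward
  the side facing the curvature normal (`c_κ = 1` by default).
* **Post-stenotic wake** — a low-WSS region downstream of each throat with
  exponential recovery over `5×` the throat diameter and depth 0.6;
  eccentric lesions confine the wake to a sector around the lumen-offset
  direction. The sector shape and depth are qualitative choices; no numeric
  claim is attached to them.

Seeded multiplicative noise (Gaussian-filtered white noise, σ = 5 % by
default in cohort generation, correlation ~8 stations axially) emulates the
mesh/interpolation irregularity of a CFD ground truth.

The inlet waveform is a two-bump parametric curve (small systolic shoulder
at 0.16 T, dominant diastolic peak at 0.62 T) renormalized so the cycle
average is exactly 0.20 m/s and the maximum 0.55 m/s; the bump centers and
widths are package choices matching the stated mean/peak, not a digitized
physiological trace. The outlet reference pressure is 13.3 kPa (100 mmHg).

## Encoding

The analysis grid excludes 5 mm transition zones at both ends: stations
`40..599` of the 640-station lattice (560 kept, nominal 0.125 mm spacing —
the kept span starts at `s ≈ 5.008 mm` because the endpoint-inclusive
spacing is `80/639`). Features per node: X, Y, Z (mm), station curvature C,
angle `A = 2π(k−1)/n_θ`, and the station's blended offset magnitude `d` and
semi-axes `a`, `b` (R₀ where nominal). Targets are log-transformed
(`log(wss + 1e-6)`) and z-scored with statistics frozen on the training
split.

The vessel graph unions 8-connected grid edges (circumferential wrap, no
axial wrap; interior grid degree exactly 8, end rings 5) with
spatial-proximity edges between non-grid-adjacent nodes, capped at 6 nearest
per node. Spatial edges carry weights `exp(−dist/ℓ)`; grid edges carry unit
weight. Both the search radius and ℓ follow the characteristic mesh spacing:
0.3 mm and 0.1 mm at the standard 0.125 mm axial spacing, scaled 4× on the
4× coarser desk grid. Message passing aggregates over the unweighted
neighbor sets (degree counts with self-loops for GCN, plain mean for
GraphSAGE); the weighted sparse operators remain available.

θᵢ, the angle entering the continuity term, is defined as the angle between
the node's circumferential position and the projection of the curvature
normal into the cross-section plane. This is one reading of "the angle
between the flow direction and the curvature plane"; it makes the
`κ cos θ` correction vanish on the curvature-neutral sides of a bent tube.

## Surrogate models

All three models run on the package's tape-based NumPy autodiff engine
(float64 throughout; Glorot-uniform initialization from explicit seeded
generators; training is single-threaded and bit-reproducible for a fixed
seed).

**MLP (dual autoencoder).** A strided-convolution encoder compresses the
8-channel input grid to a latent vector; an MLP autoencoder (hidden 256)
compresses the flattened WSS field. Candidate bottlenecks are
{32, 64, 128, 256, 512} with 128 the full-scale default. A 2×100 ReLU
mapper with dropout 0.2 connects the latents. Training is two-stage:
autoencoders first (reconstruction MSE), then the mapper (latent MSE);
validation monitors end-to-end prediction MSE. Reconstruction quality is
reported as NMAE = mean absolute error / data range. The PCA baseline is an
exact linear projection with components capped at the data rank (so the
NMAE curve flattens, rather than erroring, once the bottleneck exceeds the
number of cohort samples).

The bottleneck *sweep* is trained as a nested-capacity sequence: each wider
autoencoder is warm-started from the previous one by function-preserving
widening (new encoder columns freshly initialized, the matching decoder
rows zero-initialized, so the widened model initially computes exactly the
narrower model's reconstruction), and the best full-data reconstruction
seen during each fit is kept. Independently trained autoencoders on a
low-rank desk cohort all reach an optimizer noise floor where the curve is
not meaningful; warm-starting makes the sweep measure capacity, which is
the quantity the comparison is about — a k₂ > k₁ bottleneck can represent
every k₁ solution.

**U-Net.** Encoder blocks 64→128→256 (two 3×3 convolutions + batch norm +
ReLU each, 2×2 max pooling), a 512-channel bottleneck, transpose-convolution
(2×2, stride 2) upsampling with skip concatenation, dropout deepening
0.1→0.3, and a 1×1 linear head. Padding is cyclic circumferentially
(closed tube) and reflective axially. The composite loss adds a relative
term (λ₁ = 0.1, stabilizer 1e-3) and a smoothness penalty on prediction
gradients in both grid directions (λ₂ = 0.05). The grid must be divisible
by `2^depth`; the standard grid (560×40) supports depth 3, the desk grid
(140×20) depth 2.

**PI-GNN.** An 8→hidden input projection, alternating GCN (even) and
GraphSAGE (odd) layers with identity residual connections at matched width,
and a linear head; optional feature dropout and batch normalization can be
inserted after each message-passing layer (the desk preset uses dropout
0.1, no batch norm). GCN applies the linear map after the symmetric-normalized
aggregation, `σ(ÂHW)` — the standard operator order. The loss is

    L = L_MSE + α·L_gradient + β·L_continuity + γ(t)·L_boundary

with α = 0.1, β = 0.05 and γ ramping linearly 0.01 → 0.1 over 500 epochs
(clamped beyond). `L_gradient` compares predicted and target edge-wise
finite-difference gradients over all edges. `L_continuity` penalizes the
quasi-1D mass-conservation residual `dŷ/ds + ŷ(d ln R/ds + κ cos θ)` along
circumferential strips (central differences, interior stations).
`L_boundary` pins the inlet ring to the analytic Poiseuille value,
optionally curvature-adjusted by `1 + c_b·κR` (`c_b = 0` by default — the
adjustment form is unspecified upstream). MSE and gradient terms act on the
normalized log scale; continuity and boundary act on the Pa-scale field
divided by the training set's geometric-mean WSS, which keeps the four terms
commensurate (zero-residual cases are scale-invariant).

**Shared training.** Adam at 1e-3; ReduceLROnPlateau (factor 0.5, patience
10); early stopping (patience 30, best weights restored); max 500 epochs;
batch size 4; seeded-shuffle 80/10/10 split. Validation uses plain
normalized-scale MSE for every kind so histories are comparable.

## Desk preset and the benchmark

The full-scale configuration (640/560×40 grid, 1000-model cohort,
256-hidden PI-GNN, 64-base U-Net) is impractical on one CPU, so the package
ships a first-class desk preset: 160-station lattice (140×20 analysis grid,
0.5 mm spacing), 100-vessel cohort, 60/20/20 split, reduced model widths
(PI-GNN hidden 64 with 4 layers and dropout 0.1, U-Net base 8 depth 2, MLP
bottleneck 64) and a 30-epoch budget with early stopping (patience 10,
plateau 5). The benchmark trains all three kinds with identical budgets
across 3 seeds and compares pooled node-wise Pearson R over the held-out
cases.

Two caveats about what the desk benchmark shows. First, the oracle's fields
are far smoother than CFD, so absolute desk accuracies say nothing about
clinical-grade WSS prediction. Second, the architecture ranking itself is
scale-dependent: with only 60 training vessels on a coarse grid, the
convolutional prior of the U-Net is highly sample-efficient and, in the
package's own benchmark, remains ahead of the graph surrogate by a small
margin (pooled R differences of 0.01–0.04), while the compressed MLP trails
both by a wide margin. In particular the post-stenotic wake — geometrically
indistinguishable from healthy wall, recognizable only from long-range
axial context — is captured by the U-Net's pooled receptive field but not
by a few rounds of symmetric neighbor averaging. The large-scale ordering
reported for CFD-trained surrogates (graph > conv > compressed MLP) should
therefore not be expected to re-emerge under desk conditions; the desk
benchmark asserts it regardless and documents the outcome.

## Numerical choices and degenerate inputs

* Resampling requires ≥ 4 distinct points and positive length; duplicate
  input points are dropped before spline fitting.
* Nearest-neighbor WSS mapping breaks exact distance ties (1e-12 relative)
  toward the lowest sample index.
* Normalization refuses constant training targets (zero variance).
* Pearson-based metrics refuse constant inputs; all variances use the
  population (1/N) convention, matching the all-nodes framing of
  Bland–Altman limits (bias ± 1.96 SD). "Standard error" is the standard
  deviation of signed errors, consistent with StdError ≈ RMSE at near-zero
  bias.
* Cohort metrics are pooled over all test-case nodes; per-case reports are
  also emitted (upstream aggregation conventions are not stated, so both
  are provided).
* The 40-gon area tolerance (0.5 %) and the analytic-profile tolerance
  (1e-6, station-aligned throats) are the two levels at which throat areas
  are checked.

## Known limitations

* The oracle is not CFD: no secondary flows, no transient effects, no
  pressure field, no FFR. Wake shape parameters are qualitative.
* Idealized lesion profiles only — no calcified nodules, ulceration,
  branching, or tapering vessels.
* The eccentric circumferential-peak convention (peak opposite the
  lumen-offset direction) is a modelling choice documented in the oracle
  section; real eccentric jets can impinge on either wall depending on
  upstream curvature.
* LDDMM-style diffeomorphic deformation is replaced by the simpler
  Gaussian-bump scheme; it preserves the descriptor-constraint contract but
  not diffeomorphic guarantees (self-intersection is avoided only through
  the curvature bounds).
* Training determinism is guaranteed single-threaded; multi-threaded BLAS
  reductions may perturb results in the last bits.
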