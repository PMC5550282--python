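# Methods

`utrisim` models how the sensory epithelium of the utricle — the macula —
stops growing at a reproducible size. The working hypothesis is mechanical:
proliferating supporting cells push against an elastic surround (transitional
epithelium plus mesenchyme/cartilage), and division ceases where the
restoring pressure of that boundary balances the pressure of growth. A
competing mechanism, arrest by a secreted diffusible inhibitor, is
implemented alongside for comparison. The package contains the stochastic
tissue simulator, the closed-form elasticity that justifies treating the
two-layer surround as one effective boundary, the growth-curve and rheometry
fitting used to parameterize and validate the models, the image-analysis
procedure that locates proliferation relative to the organ boundary, and
seeded synthetic-data generators that make every stage testable without
external data.

## The cellular Potts tissue model

Cells are domains of pixels on a bounded two-dimensional hexagonal lattice
("odd-r" offset storage; Cartesian mapping `x = col + (row mod 2)/2`,
`y = row·√3/2`, so all six neighbours are at unit distance). The medium
(cell id 0) doubles as the elastic boundary (EB). The effective energy is

    H = c·J_C·L_cc + c·E·S² + Σ_σ λ_vol (v(σ) − V_T)² + Σ_σ λ_surf (s(σ) − S_T)²

with `L_cc` the number of unordered heterotypic cell–cell links, `S` the
number of unordered cell–EB links (the tissue perimeter), `v` and `s` each
cell's pixel count and heterotypic link count, and `c = 2` mapping unordered
link counts onto the conventional ordered-pair double sums. The `c·E·S²`
term replaces a per-link cell–medium contact energy: stretching an initially
unstressed elastic surround by `S` stores energy quadratic in `S`, with the
boundary Young's modulus `E` in the role of the contact coefficient. Both
sums in the contact terms use the first neighbour ring only; at large `E`
this produces the known discreteness artefacts (sharp corners, anisotropic
compression).

Dynamics are Metropolis index-copy attempts: a random target site and a
random neighbour as copy source; the copy is accepted with probability 1 if
`ΔH ≤ 0` and `exp(−ΔH/T_m)` otherwise, with `T_m` the membrane-fluctuation
amplitude. One Monte Carlo step (MCS) is `width·height` attempts and maps to
`dt = 210 s`. `ΔH` is computed incrementally from local link counts; the
test-suite asserts equality with full recomputation on ≥10⁴ random
proposals, including the annihilation of single-pixel cells (whose penalty
terms vanish rather than being evaluated at `v = 0`). Because `ΔH` is linear
in the energy parameters, rescaling them jointly with `T_m` leaves all
acceptance probabilities unchanged; this invariance is tested.

Defaults are the published simulation values: `T_m = 5`, `V_T = 40 px`,
`λ_vol = 9`, `S_T = 25 px`, `λ_surf = 1.5`, `J_C = 20`, `E = 0.069`
(elasticity-limited) or `0.055` (morphogen-limited), `dt = 210 s`,
`dA = 8.6·10⁻¹³ m²/px`, lattice `600×600`.

Design choices the energy model leaves open, and how they were resolved:

* **Medium representation.** The EB is a single unconstrained spin (no
  volume or surface penalty), the convention of the major Potts frameworks.
* **Lattice edges.** Fixed (non-periodic). The tissue is initialized
  centrally; if a cell pixel ever reaches the border the run aborts with a
  diagnostic rather than silently wrapping.
* **Attempt order.** Random target, then a random neighbour as source; the
  originating framework's exact order is not documented, and the neighbour
  conventions are known to shift fitted constants (see *Calibration*).
* **RNG.** One seeded generator per run (a compiled-kernel stream and a
  Python-level stream, both derived from the run seed); identical config and
  seed reproduce byte-identical trajectories.

## Division, quiescence, EdU, pressure

After a refractory period drawn per cell from a Gaussian (mean
`T_ref = 200 MCS`, SD `σ_ref = 50 MCS`; negative draws are redrawn), a cell
divides as soon as its volume reaches `V_T/2`. The split passes through the
centre of mass perpendicular to the principal (longest) axis; pixels are
ranked by their projection on that axis and the upper half becomes the new
cell, so daughter volumes differ by at most one pixel even for degenerate
shapes. Divisions are checked once per MCS per cell.

A cell that fails to divide for `T_div = 2000 MCS` becomes quiescent —
permanently division-incompetent — a heuristic stand-in for density-sensing
(Hippo-pathway) arrest. Without this rule the arrested tissue keeps dividing
at a very low fluctuation-driven rate; with it, growth closes completely
(both behaviours are asserted in the tests).

EdU pulse-chase is modelled as a per-cell label: divisions during the
labelling window set `[EdU] = 1` in both daughters; afterwards each division
halves the inherited level; a level is detectable while `[EdU] ≥ (1/2)⁴`.
The threshold is inclusive — the stated dilution rule makes exactly four
halvings the last detectable generation — and the boundary case is pinned in
a test. Internal cellular pressure is read out as
`P = −2 λ_vol (v − V_T)`: compressed cells (small `v`) have high pressure.

The stem-cell variant restricts division to a central patch of stem cells
(default 10% of the initial cells); each daughter remains stem with
probability 0.5, otherwise it differentiates into an ordinary supporting
cell. With retention 0.5 the stem pool is a critical branching process and
may die out at desk scale; the variant reproduces the qualitative result
that stem-only proliferation cannot sustain peripheral growth.

## The morphogen-limited variant

Each cell secretes inhibitor at rate `k_M = 0.23 s⁻¹` from the lattice site
nearest its centre of mass (the whole deposit into one site; if the rounded
centroid is not owned by the cell, the nearest owned pixel is used). The
field diffuses by forward Euler on the hexagonal 6-neighbour Laplacian
`(2/3h²)Σ(M_j − M_i)` in symmetric pairwise form, which conserves total mass
exactly and makes the boundaries no-flux — consistent with a sealed culture
chamber. Substeps per MCS are chosen so `D·dt_sub/h² ≤ 0.2` (positivity and
stability; an explicit substep override is validated against the bound).
SI units are bridged through the spatial scale: site area `dA` gives spacing
`h = √(2·dA/√3) ≈ 1.0 µm`, so the published `D = 1.19·10⁻¹⁴ m²/s` is
≈ 2.5 site²/MCS. A cell stops dividing while the concentration at its
centre-of-mass site is at or above `M_TH`; arrest is re-evaluated every MCS,
but since the field only accumulates the arrest front in practice only
advances (asserted on the recorded super-threshold area).

Two caveats are documented deliberately. First, with a literal point-source
integration and no degradation, the published absolute pair
(`k_M = 0.23 s⁻¹`, `M_TH = 0.1 pM`) arrests growth essentially immediately:
a single cell's quasi-2-D field reaches 0.1 pM near its source within
seconds (`k_M/4πD ≈ 1.5 pM`). The published field snapshots (maxima
~0.2 pM) imply an internal rescaling in the original simulation framework
that is not documented. We therefore keep the literal integrator and the SI
defaults for `D` and `k_M`, and treat the arrest threshold as the free
calibration parameter of each preset. Second, with accumulation and no-flux
boundaries the sign of the final-area-versus-D relation is not fixed a
priori; the package asserts the linearity of the relation over the swept
range and reports its R², not the sign.

## Elastic theory

In plane polar coordinates, each material (band: `E1`, matrix: `E2`, common
Poisson ratio `ν`) has displacement `u_i(r) = a_i r + b_i/r` and plane-strain
radial stress `σ_rr = E/((1+ν)(1−2ν))·(a − (1−2ν) b/r²)`. Boundary
conditions: decay at infinity (`a₂ = 0`), continuity of `u` and `σ_rr` at
`R2`, and `σ_rr(R1) = −p` for tissue pressure `p`. The integration constants
were derived symbolically and verified against the classical
pressurized-hole solution in the homogeneous limit `E1 = E2`:

    Q  = E1 + E2 − 2·E2·ν
    den = E1·(R1²(E2 − E1) + R2²·Q)
    a1 = p·R1²(1+ν)(1−2ν)(E1−E2) / den
    b1 = p·R1²R2²(1+ν)·Q / den
    b2 = 2p·R1²R2²(1−ν²)·E1 / den

The effective modulus of the single equivalent band is defined by matching
the inner displacement, `u_eff(R1) = p·R1(1+ν)/E_eff = u1(R1)`, giving

    E_eff = E1·(R1²(E1−E2) − R2²·Q) / (R1²(E1−E2)(2ν−1) − R2²·Q)

and its first-order thin-band expansion (derived symbolically; the package's
own derivation is unit-tested against the numerical Taylor expansion of the
exact expression):

    E_eff ≈ E2 + (R2−R1)·(E1−E2)·Q / (E1·R1·(1−ν))

Once growth has pushed the boundary pressure up to the homeostatic pressure
`P_H`, the equilibrium expansion is `ΔR = P_H·R1(1+ν)/E_eff ∝ 1/E_eff`, so
the equilibrium *area change* scales as `1/E_eff²` — the scaling the
simulation sweeps verify. Neither layer's Poisson ratio is constrained by
measurement; the default `ν = 0.45` (nearly incompressible soft tissue) is
always explicit in configurations.

## Growth-curve, scaling and rheometry fits

Areal growth follows `dA/dt = r(A∞ − A)`; the saturating solution
`A(t) = A∞(1 − e^{−r(t−t0)})` is fit by bounded nonlinear least squares
(optionally SEM-weighted) in normalized coordinates for conditioning, with a
log-linearized start and a small multistart over rate scalings. R² is
`1 − SS_res/SS_tot` about the mean for all fits, linear or not.
Developmental stages convert to seconds at 86 400 s/day with birth at E19.5.
Parameter recovery at the measurement-like noise level (1% relative, 8
stages, 100 replicates) shows `A∞` bias below 2% and RMSE below 5%.

Bimorph rheometry: each probe presses the gel with a known cumulative base
displacement; the plateau voltage change `ΔV` (maximum after onset minus the
pre-probe baseline mean, after a 50 ms moving-average filter so the max
statistic is not noise-dominated; the baseline window ends one filter width
before onset) converts to force `F_B = (K_F W/L)ΔV` with `K_F = 2.62 mN/V`,
`W = 6.5 mm`, `L = 22 mm`. Stress is `F_B/A₀`; the bimorph's own yield
`X_B = F_B/K_B` (`K_B = 645 N/m`) is subtracted from the base displacement
to get the gel compression and strain `ε = ΔL/L₀`; probes implying negative
compression are flagged and excluded. The modulus is the slope of
`σ = εE + σ₀`. The synthetic trace generator inverts this exact pipeline
(gel and bimorph as springs in series), so the noiseless round trip is exact
and the 2%-noise round trip recovers `E` within 5% with R² > 0.98.

## EdU boundary-distance profiles

Cohort images are Gaussian-blurred (EdU channel, default σ = 5 px),
translation-aligned on the Sox2-mask centroid (rotation registration is
deliberately off), and averaged. The epithelial outline is the zero level
set of the cohort-mean *signed distance transform* of the per-image Sox2
masks (Otsu threshold unless given). For a single mask this coincides with
its half-level contour; for a cohort it is the boundary midway between the
per-image boundaries, and—unlike the half-level contour of a plain mean
mask—it remains well defined where the mean mask plateaus at exactly one
half (two nested masks reproduce the midway circle to within a pixel in the
tests). Smoothing resamples the outline at uniform arc length and truncates
to the first 12 Fourier harmonics before periodic spline interpolation: an
exact circle passes through essentially unchanged, while pixel staircase and
3-px high-frequency zigzag flatten below 1 px. Intensity strips (default
400 samples at 1 px spacing, configurable; the synthetic fixtures use
shorter strips matched to their canvas) are taken along outward normals —
computed by cyclic central differences of the uniformly spaced strip
anchors, with orientation fixed by a point-in-polygon probe — at uniform
arc-length positions; strips leaving the image are dropped with a warning.
The profile is the mean and standard error across strips against signed
boundary distance, negative inside. On radially symmetric fixtures the
profile equals the re-indexed radial profile to 2%, and the full pipeline
recovers a synthetic proliferation ring's 15-px inward offset within 2 px.

## Synthetic data

All generators are deterministic under an explicit seed and return the
generating truth alongside the data. Growth series: the published asymptote
`A∞ = 1.8·10⁻⁷ m²` and rate `r = 3.6·10⁻⁶ s⁻¹`, growth onset placed at E15
so the curve rises between E15.5 and P2, sampled at eight standard stages
with relative Gaussian noise (default 3%, in the range implied by reported
SEMs). Voltage traces: staircase probe plateaus from the series-spring
model, white noise relative to the largest plateau. EdU cohorts: a lobed
Sox2 blob (low-frequency boundary modes), punctate EdU ring at a configured
inward offset, per-image jitter and translation. Initial tissues: the
`n·V_T` hexagonal sites nearest the lattice centre, partitioned into `n`
cells by farthest-point seeding plus Lloyd relaxation, which the engine's
brute-force audit validates. What the generators do *not* emulate: optical
point-spread functions, segmentation errors, stage-dependent measurement
protocols, non-Gaussian outliers, and any biology beyond the modelled
mechanisms; passing the closed-loop tests therefore demonstrates that the
pipelines are faithful to their own models, not that the models fit any
particular real dataset.

## Scales, presets and calibration

Full-scale conditions (600×600 lattice, ~8400 MCS ≈ E15.5→P14) take hours
per realization; the shipped presets are desk-scale reductions chosen so a
complete arrested trajectory takes seconds to tens of seconds:

* `reduced_elasticity_config` — 150×150 lattice, 15 initial cells,
  6000 MCS, `E = 0.12`; the modulus-sweep grid is `E ∈ [0.09, 0.18]`
  (6 values), placed so the stiffest case still grows well beyond the
  initial disk and the softest stays clear of the lattice edge.
* `reduced_calibrated_config` — 250×250, 20 cells, 9000 MCS, `E = 0.055`,
  with a documented target of ≈28 000 px, obtained by calibrating the
  boundary modulus so the arrested size matches a stated target — the same
  procedure by which the published modulus was fitted to the measured organ.
* `reduced_morphogen_config` — 150×150, `E = 0.05` (soft enough that the
  unconstrained tissue would outgrow the domain), published `D` and `k_M`,
  arrest threshold 300 pM calibrated for the reduced domain as described
  above; the D-sweep grid spans 0.7–1.5 × the published value, where the
  area response is close to linear.

The absolute pixel-count calibration is convention-dependent: with
first-ring neighbourhoods and this attempt order, the arrested area at a
given `E` is roughly an order of magnitude smaller than the published
full-scale value at `E = 0.069`, i.e. the effective boundary modulus
corresponding to the measured organ differs between frameworks. All scaling
*relations* (1/E², linearity in D, peripheral proliferation, pressure
gradients, growth-curve shape) are insensitive to this constant, which is
why the calibrated preset states its own pixel target rather than importing
the published one. Realization variability shrinks with tissue size: at the
calibrated preset the per-seed relative SD of final area is ≈6%, dominated
by stochastic extinction of the last division waves under the quiescence
timer, so the five-seed relative SEM is a few percent (roughly 1–4%
depending on the seed set); extrapolating by the area scaling of the
variance, the full-scale organ's expected value is ≈1%.

## Numerical details and limitations

* Energies are exact integer/float arithmetic on link counts; no cutoffs.
* The forward-Euler stability bound `α ≤ 0.25` is enforced with default
  `α ≤ 0.2`; mass balance holds to well below 0.1% over full runs.
* Refractory truncation redraw (not clipping) keeps the mean within ~0.1 MCS
  of the nominal 200.
* Division cadence (once per MCS per cell) and the median-projection split
  are internal conventions; both are covered by determinism and audit tests.
* Cell fragmentation is not prevented (standard for this model class);
  centre-of-mass sites fall back to the nearest owned pixel when a shape is
  non-convex.
* The model is strictly two-dimensional, has no apoptosis (homeostatic
  pressure enters only through the analytic equilibrium argument), no hair
  cell differentiation, and no molecular signalling; the quiescence timer is
  a phenomenological stand-in for density sensing.
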