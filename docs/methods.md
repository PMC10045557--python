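# Methods

## Model overview

`fieldnet` simulates a fitness-based preferential-attachment network in which
node fitness doubles as a Boltzmann weight.  Each node carries a quenched
energy `ε` and fitness `η = e^{−βε}`; an entrant at every step attaches `m`
distinct links with probability `Π_i ∝ η_i k_i`.  The mapping between the
grown network and equilibrium occupation statistics (Maxwell–Boltzmann,
Bose–Einstein, Fermi–Dirac) is made through the dynamic exponent
`f(ε) = e^{−β(ε−μ)}`, with the chemical potential `μ` chosen so the occupation
numbers sum to the total number of link endpoints (2E).

## How β enters growth

With a fixed fitness distribution `ρ(η)`, β never appears in the attachment
rule — `Π_i` uses η only — so temperature could not move the network between
phases.  We therefore treat the configured distribution as the quenched
disorder at reference inverse temperature β = 1: a draw `η₀` fixes the node's
energy `ε = −ln η₀` once and for all, and the operative fitness at inverse
temperature β is `η = e^{−βε} = η₀^β`.  This is the standard
temperature-dependent fitness construction for network condensation; it
reduces to the printed family at β = 1, keeps `ε = −(1/β) ln η` an exact
identity at every β, and makes β a genuine control parameter: β → 0 flattens
all fitness differences (classical preferential attachment, degree-tail
exponent 3), large β amplifies them until the minimum-energy node captures a
finite share of all endpoints.

## Fitness families

* `uniform` — η₀ uniform on (0, 1].
* `exponential(rate)` — unbounded positive fitness (energies may be negative).
* `dirac(value)` — all nodes equal: the Barabási–Albert limit at any β.
* `truncated-power(θ)` — the condensation-prone family: reference energy
  drawn with density `(θ+1) ε^θ` on [0, 1] (vanishing at the band bottom,
  the necessary condition for condensation), mapped to `η₀ = e^{−ε}` so all
  fitness mass hugs the maximum in [1/e, 1].  Default θ = 1; the ensemble
  trend tests use θ = 4 with β up to 50, which is deep in the condensed
  regime by the excited-capacity criterion.

Growth starts from a complete graph on `m + 1` nodes (guaranteeing `m`
attachable targets from step one), samples targets without replacement (no
multi-edges or self-loops), and threads a single seeded `numpy` generator
through every draw, so a config reproduces its network exactly.

## Chemical potential and condensation

The occupation sum is strictly increasing in μ for all three statistics, so
the solver brackets and bisects (Brent).  Under Bose–Einstein statistics μ is
confined below the band bottom `min ε`; condensation is declared when the
*excited* spectrum at `μ = min ε` cannot hold the endpoint budget, in which
case the excess occupation is assigned to the minimum-energy level (split
equally across exactly degenerate ground levels).  The ground level itself is
excluded from the capacity check because its occupation diverges as
`μ → min ε` and would mask the transition.  Fermi–Dirac occupations are
bounded by one per level, so a budget at or above the level count is rejected
rather than looped on.

Phase labels operationalize the asymptotic statements "f ≪ 1" and "f ≫ 1" as
order-of-magnitude thresholds: median f within ±0.05 of 1 → Bose–Einstein,
below 0.1 → Maxwell–Boltzmann, above 10 → Fermi–Dirac, otherwise crossover;
all three thresholds are arguments.  `Γ_C = T_C k_B/(n/ζ(3/2))^{2/3}` takes
the particle density as an explicit argument, since the model does not define
a density for a growing graph; ζ(3/2) comes from `scipy.special.zeta`.

## Trajectory classification

Dominant frequencies are extracted per dimension by cubic smoothing
(Savitzky–Golay local cubic least squares, window 11 — an O(n), deterministic
stand-in for smoothing splines), a Hann-windowed periodogram peak with ties
broken toward the lower frequency, and golden-section refinement of the
windowed DTFT magnitude within one bin, giving ~1e−5 relative accuracy on
clean sinusoids.  The winding triple is reduced by its smallest member, and
rationality is decided by continued-fraction approximation with denominator
at most 32 at an **absolute** tolerance of 1e−3 per ratio.  The tolerance is
absolute, not relative: golden-ratio ratios sit ~1.01e−3 from their best
admissible fraction, so a relative reading would misclassify the canonical
incommensurate triple (1, φ, φ²) as rational.

The nonlinear coherence K is the geometric mean of the three pairwise
magnitude-squared spectral coherences (Welch, 50 % overlap), each averaged
over a ±2-bin band around the pair's dominant frequencies, DC excluded.  This
realizes the normalization contract exactly: identical signals give K = 1,
independent signals tend to the estimator bias ≈ 1/L for L segments, and the
value lies in [0, 1] by construction.  Segment length is capped at 512 so
long records average ≥ 30 segments, pushing the independent-signal floor
below 0.05; at least 8 segments are required or the estimator raises.  The
literal un-normalized triple-product ratio `|C_XYZ|/(|A_X||A_Y||A_Z|)` is
available via `estimator="literal"` without the [0, 1] guarantee.

Decision table: zero variance → fixed-point; rational winding → periodic;
irrational with K ≤ 0.25 → quasiperiodic; irrational with K > 0.25 → chaotic
(threshold configurable, defaulting to the printed 0.25).  Wolfram classes:
fixed-point → I, periodic → II, chaotic → III, quasiperiodic → IV.

## The chaotic-coupled fixture

Three *identical* time-scaled Rössler oscillators
(a, b, c) = (0.28, 0.1, 8.5) — the funnel, non-phase-coherent regime — are
diffusively coupled all-to-all in x with strength 0.085, integrated by
fixed-step RK4 (natural step ≤ 0.02) from fixed initial conditions, with a
5 s transient discarded.  The coupling sits above the coherence onset but
below complete synchronization: K ≈ 0.64 at the dominant band, while the
three dominant frequencies remain distinct, so the measured winding triple
falls in a gap of the denominator-≤32 rational lattice and the verdict is
irrational — jointly yielding the chaotic label.  Complete synchronization
(phase-coherent parameters or stronger coupling) would lock the dominant
frequencies, produce a 1 : 1 : 1 rational winding, and be labelled periodic
despite K ≈ 1; the funnel regime is the fixture design that makes the
chaotic branch of the classifier reachable by an actual trajectory.  All
constants are pinned in `fieldnet.fixtures`, so the fixture is
bit-reproducible.

### What the generators do and do not emulate

The synthetic trajectories are stationary, uniformly sampled, noise-free or
lightly noised (optional Gaussian measurement noise, default off; fixture
tests use sd = 0.01).  They emulate the *qualitative signatures* the
classifier keys on — commensurate versus incommensurate line spectra,
broadband coupled chaos — not empirical neural recordings: no
nonstationarity, no 1/f background, no artifacts.  A green classification
test therefore establishes that the pipeline implements its stated decision
rules, not that the rules segment real recordings correctly.

## Landscapes, geodesics, eigenmodes

The potential surface interpolates node energies with *normalized
singular-Gaussian kernels* (modified Shepard): weights
`e^{−d²/2σ²}/d²`, normalized to sum to one.  The 1/d² singularity makes the
surface pass exactly through every anchor at any bandwidth without solving a
linear system — a plain Gaussian-RBF collocation solve becomes numerically
singular once the bandwidth exceeds the node spacing and cannot meet the
1e−9 anchoring contract — and convexity guarantees the surface never dips
below the minimum node energy.  Bandwidth defaults to half the median
nearest-neighbour distance; layouts default to a seeded force-directed
embedding.  Far from all anchors the weights underflow and the evaluation
falls back to the nearest anchor's value.

Geodesic lengths evaluate `Σ √(Δxᵀ g Δx)` per polyline segment with the
metric at segment midpoints (second-order accurate on smooth curves); the
module accepts any symmetric positive-definite metric and validates it
pointwise.  Eigenmodes are the ascending eigenpairs of the combinatorial
graph Laplacian (or a 5-point grid Laplacian), whose zero-eigenvalue
multiplicity equals the component count and whose path-graph eigenvectors
exhibit the Sturm sign-change property.

## Kinetics conventions

Natural units (k_B = h = R = 1) by default.  The activation-energy inversion
`E_a = −RT ln(k/A)` is the exact algebraic inverse of the Arrhenius law; in
the quantum regime the rate is first formed from the tunneling law
`(k_B Γ/h) f(ε)` and inverted identically, with an option to substitute Γ
for T.  "Linear Arrhenius plot" is operationalized as R² ≥ 0.995 for the
least-squares line of ln k on 1/T (configurable); a temperature-independent
tunneling floor of ≥ 0.1 A over a sufficiently wide 1/T range reliably drops
R² below any reasonable threshold.  The Landauer reset energy defaults to
`ε = −(1/β) ln(2η)` — the inserted factor of 2 yields the ln 2 quantum at
η = 1 — with the alternative reading `−(1/β) log₂ η` behind a flag.  Work
accounting `W = ΔH − TΔS` (classical) or `W = ΔH − ΓΔS` (hybrid) is computed
per switch; aggregation over an episode is left to the caller.

## Known limitations

* Growth is undirected and unweighted; no deletion or rewiring.
* Topology stops at graph Betti numbers (B₀, B₁); no clique complexes,
  torsion, or fundamental-group computation.
* The coherence estimator assumes a meaningful dominant frequency per
  dimension; broadband signals without spectral structure get a
  band-averaged value that depends on the peak-picking.
* Eigenmodes are computed on graphs and regular grids only, not on surface
  meshes.
* Ensemble trend results (condensation versus β, tail exponents) are
  finite-size: condensate fractions at n ≤ a few thousand are far below
  their thermodynamic-limit values and converge slowly.
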