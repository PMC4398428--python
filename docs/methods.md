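# Methods

This note documents the models, numerical procedures, defaults and known
limitations of the `schlogl` package.

## The model

The Schlögl model is the minimal chemical system with a first-order
nonequilibrium phase transition: a single species X exchanged with two
chemostatted reservoirs,

    A <-> X                 rates  k+1 A  (production),  k-1 x   (degradation)
    2X + B <-> 3X           rates  k-2 B x^2  (autocatalysis),  k+2 x^3

In the macroscopic (V → ∞) limit the concentration obeys the cubic rate
equation

    dx/dt = −k+2 x³ + k−2 B x² − k−1 x + k+1 A ,

which has one or three nonnegative roots; three roots (stable, unstable,
stable) between two saddle-node values of the control parameter B define the
bistable window.  The *standard parameters* used throughout are
k+1A = 0.5, k−1 = 3, k+2 = k−2 = 1 (all dimensionless); with B = 3.7 they sit
at (β, γ, v) = (0.22, 0.14, 37) in the cusp phase diagram, where
β = k−1k+2/(k−2B)², γ = k+1A k+2²/(k−2³B) and v = (k−2B/k+2)V.  The γ
formula is reproduced exactly as published even though its dimensional
bookkeeping is peculiar; it is treated as a definition, not derived.

The *generalized* scheme splits the third-order step through an explicit
dimer X₂ (2X ⇌ X₂ with k±3; X₂ → X₂+X at k−2B; X₂+X → X₂ at k+2), the only
form a pairwise particle simulation can execute.  For k+3 = k−3 its
quasi-steady dimer pool x₂ = x² reproduces the conventional cubic in the
macroscopic limit — verified here by simulation at V = 100 (mean within 0.2%
of the deterministic root).  At small volumes the dimer pool adds correlated
noise on the production channel and genuinely shifts the state *weights*
toward the high state (at B = 4.0, V = 10 the stationary mean is roughly
double the conventional scheme's); this is a property of the scheme, not an
approximation error, and all particle-level comparisons therefore use the
generalized-scheme Gillespie simulation as their reference.

## Well-mixed stochastic layer

The one-step master equation over the copy number X has birth rates
W↑(X) = k+1AV + k−2B X(X−1)/V and death rates
W↓(X) = k−1X + k+2 X(X−1)(X−2)/V².  The stationary distribution follows from
the recursion p(X+1)/p(X) = W↑(X)/W↓(X+1), evaluated in log space, truncated
at 4·x_high·V (doubled, at most three times, until the boundary carries
< 10⁻¹² of the peak mass).  A brute-force null-space solve of the truncated
generator serves as the independent oracle (total variation < 10⁻¹⁰ in the
tests).

The large-volume form p(x) ∝ N(x)·exp(−VΦ(x)) uses the closed-form
stochastic potential Φ (log/arctan expression whose derivative is
−ln[(w+1+w−2)/(w−1+w+2)]) and the volume-independent prefactor
N(x) = (k+2x²+k−1)/(x(x²+k+1A/(k−2B))).  Φ is validated against quadrature
of its own slope (10⁻⁶) and against the exact distribution: total-variation
distance to the recursion falls from 0.04 (V = 30) to 0.016 (V = 100) with
modes matching to one grid cell.

**Switching rates** are exact mean first-passage times of the birth–death
chain — reflecting at 0 (resp. the truncation boundary), absorbing at the
destination state's copy number round(x·V) — inverted to rates via the
standard nested-sum formula over the unnormalized stationary weights.  This
is exact at every volume, unlike large-V Fokker–Planck asymptotics, and is
cross-checked against dwell times of long Gillespie runs (agreement well
within a factor 2 at V = 10, B = 4.0).

**Coexistence (Maxwell-like construction).**  Two definitions are provided:
equal switching rates at a given volume (bisection on the log-rate
difference), and equality of Φ at the two stable roots (volume-independent).
At V = 30 the rate crossing sits at B = 3.698; the Φ-equality sits at
B = 3.555.  The two agree asymptotically — the exact equal-basin-mass
crossing of p(X) moves from 3.98 (V = 10) through 3.70 (V = 30) to 3.56
(V = 1000) — so "the" stochastic coexistence point is volume-dependent at
the volumes of interest, and the finite-V rate construction is the one that
matches the published value 3.7.  The deterministic quartic potential
Ψ(x) = −∫drift has equal wells at B = 3.393.

**Entropy production** is computed macroscopically as
Σᵢ(w+ᵢ−w−ᵢ)ln(w+ᵢ/w−ᵢ) and microscopically in Schnakenberg form over both
reaction channels of every edge of the chain.  Both vanish identically at
detailed balance (B = k+1Ak+2/(k−1k−2) = 1/6) and the microscopic rate per
volume converges to the macroscopic rate at the dominant root (< 2% at
V = 100).

**Bimodality.**  "Visibly bimodal" is operationalized as: two strict local
maxima of p(X), with the minor basin carrying ≥ 1% of the mass
(`min_minor_mass`); an optional `min_prominence` factor additionally
requires the peaks to exceed the intervening minimum by that ratio (default
1, i.e. off).  With the defaults the bimodal window is [3.60, 4.73] at
V = 10 and [3.39, 3.97] at V = 30.  A prominence factor of 2 gives a
noticeably narrower window (e.g. the 16%-mass high shoulder at B = 3.7,
V = 10 has prominence only 1.16 and would be dropped), which is why the
threshold is exposed rather than hard-coded.

**Gillespie simulation** uses the direct method (numba-compiled), recording
either every event or on a uniform grid; both feed the same time-weighted
occupancy statistics.  Seeds are part of the trajectory metadata and runs
are bit-reproducible.

## Diffusion renormalization

Finite diffusion slows second-order reactions.  With the encounter rate
k_D = 4πσD (σD defaults to 0.5), both members of each reversible
second-order pair (k±2, k±3) are scaled by k_D/(k+ᵢ + k_D), the forward
constant in the denominator for both, preserving the equilibrium constant.
Zeroth- and first-order channels are untouched.  The bifurcation scan on
renormalized constants shows the bistable window shifted to larger B —
diffusion delays entry into the bistable regime.  Removing the autocatalytic
channels entirely (the strong-slowdown limit) leaves the linear balance
x = k+1A/k−1 ≈ 0.17 as the only steady state.

## Particle-based reaction–diffusion

A fixed-time-step, continuous-space Smoluchowski engine for the generalized
scheme in a periodic or reflective box, or a reflective sphere with an
optional coaxial "DNA" production cylinder.  Per step (default
dt = 10⁻³ time units): Gaussian displacement per axis with std √(2D·dt) and
boundary handling; dimerization fires for unordered X–X pairs ending the
step within the dimerization binding radius (product at the pair midpoint);
catalytic removal fires for X within the catalytic radius of a dimer (at
most one per dimer per step); first-order events (X death, X₂ dissociation,
X₂ production of X) fire with probability 1−exp(−k·dt); zeroth-order
production is Poisson(k+1AV·dt), placed uniformly in the allowed region
(whole volume, or the cylinder when localization is on).

**Binding radii** are calibrated per channel so that the simulated
well-mixed rate equals the intended rate constant at the chosen dt: the
radial distribution of unreacted pairs is iterated to steady state on a grid
(absorb inside σ_b, propagate through the exact radial Gaussian kernel, hold
the far field at unit density) and σ_b is root-found so the absorbed flux
equals k·dt.  The scheme interpolates between the ballistic limit
(4/3)πσ_b³ = k·dt and the continuum Smoluchowski limit σ = k/(4πD), which
is returned directly when the rms step is ≪ σ.  An independent Monte-Carlo
pair-survival calibration cross-checks the result (agreement ~2% at the
study parameters).  Because the dimerization propensity k+3X(X−1)/V counts
ordered pairs while the engine fires once per unordered pair, the X+X
channel is calibrated to 2k+3.

**Product placement.**  Dissociation products and catalytically produced
monomers are placed at an unbinding radius σ_u = σ_b + √(2D_pair dt) (one
relative rms step beyond the binding radius), which keeps immediate
recapture rare in the operating regime where the step is comparable to the
radius; a tighter 1.1σ_b placement is available
(`SimConfig(unbinding="tight")`).  The residual bias of this choice is
bounded by the engine's central oracle: at fast diffusion (D = 30, 10 in a
V = 10 box) the monomer occupancy matches the generalized-scheme Gillespie
result with KL ≈ 0.02 on coarse bins.

Note that the engine necessarily operates with rms steps comparable to or
larger than the binding radii; demanding steps much smaller than the radii
at these rate constants and diffusivities would require dt ~ 10⁻⁶ and ~10¹⁰
steps per standard run.  Validation therefore rests on the calibrated-rate
and well-mixed-limit checks above rather than on a small-step limit.

## Spatial diagnostics

*Pair correlation*: shell counts of minimum-image distances at mesh a = L/50
(shells (r−a, r], r = a, 2a, … L/2), normalized per snapshot by N(N−1) and
by the exact shell volume (4π/3)(r³−(r−a)³) — the thin-shell form 4πr²a
would bias the first shells below 1 even for Poisson controls.  Because
snapshots with different N are averaged, g can deviate from 1 systematically
when N fluctuates strongly.  Monomer pairs closer than the dimerization
binding radius react, so g has a structural hole at the smallest r; the
slow-diffusion clustering signal appears just above that radius (peak g ≈ 2
at D = (0.3, 0.1) vs ≈ 1.1 at (3, 1) in the test conditions).

*KL divergence* adds a ½ pseudocount to every bin of both histograms before
normalizing (switchable to the raw definition), keeping it finite on empty
bins.  *Kymographs* bin monomer positions into 20 equal slabs along the
major box axis.  *Switch detection* uses hysteresis thresholds at the
midpoints between the deterministic unstable root and each stable root;
directions alternate by construction, and a run pair (started low and high)
is classified bistable when both show at least one switch in each direction
— wave velocities are deliberately not estimated.

## Localized production scenario

The localized-transcription run uses a sphere of volume 2.14 with a thin
coaxial cylinder of length 1.51 and radius 0.05 (a DNA-like region — note a
cylinder interpreted as *volume* 1.51 could not be inscribed in this
sphere), D = (30, 10), k+1A = k+2 = 50, B = 50, production confined to the
cylinder.  The resulting monomer histogram is broad and unimodal — no
bistability — in contrast to well-mixed runs at comparable driving.

## Default problem sizes in the test suite

Chosen so the whole suite runs in minutes on one CPU while keeping every
stochastic assertion comfortably powered: Gillespie-vs-exact KL at
t_max = 50,000 (KL < 0.01, measured ≈ 10⁻⁴); generalized-scheme
macroscopic-limit check at V = 100, t = 1,500; particle-vs-Gillespie KL at
B = 4.5, V = 10, D = (30, 10), t = 300 in the high-dominant basin (so basin
relaxation, not rare switching, sets the statistics); g(r) ordering from
~220 snapshots of 120-time-unit runs; spatial reversible-switch
classification at V = 5, B = 3.6, t = 400 where dwell times are ~30 time
units.  Production-scale studies (ΔB scans at t = 10,000 per point, long
kymograph runs) are available through the same functions and the `bistab`
CLI but are not executed by the tests.

## Units

Dimensionless model units map to physical units as: length in µm, time in s
(a 10,000-unit run is 2.78 h), concentration in nM, volume V = η·10 µm³.
The published conversion table is reproduced entry for entry — including
its "k+2 = B s⁻¹" line, which couples a rate constant to a concentration
and is carried verbatim as a definition.

## Known limitations

- No time-dependent master-equation solutions (stationary analytics + SSA).
- The particle engine has no crowding, surfaces or excluded volume, and
  handles at most one catalytic event per dimer per step (error < k·dt).
- The generalized scheme's small-volume weight shift means spatial results
  should be compared against generalized-scheme (not conventional) SSA.
- The phase diagram's finite-v boundary uses the bimodality criterion above;
  other published constructions of that boundary may differ in detail.
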