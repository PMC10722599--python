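# Methods

## Model

A fine-grained (FG) system of `N` particles, each a composite of many
beads, is mapped onto `N` coarse-grained (CG) sites at the centres of
mass of the particle cores. Thermodynamic consistency requires the CG
potential Φ(R^N) to reproduce the configurational distribution of the
mapped FG system; its negative gradient on site `I` equals the *mean
force* — the ensemble average of the total instantaneous force on the
frozen core unit of particle `I`. Mean forces are therefore the
training data, sampled from constrained FG simulations, and the CG
model is obtained by force matching.

Φ is represented as a sum of per-site contributions
Φ\_K = Σ\_J ω\_J G\_J(K), each a linear combination of
Behler–Parrinello symmetry functions of the site's environment within a
cutoff R\_c:

* radial: `G2(I) = Σ_{J≠I} exp(−μ (R_IJ − R_s)²) f_c(R_IJ)`
* angular: `G3(I) = 2^(1−ξ) Σ_{J<K} (1 + λ cos θ_IJK)^ξ
  exp(−μ_a (R_IJ² + R_IK² + R_JK²)) f_c(R_IJ) f_c(R_IK) f_c(R_JK)`

with the cosine cutoff `f_c(r) = [cos(π r/R_c) + 1]/2` (zero in value
and slope at R\_c). The angular convention (prefactor `2^(1−ξ)`,
Gaussian over the sum of the three squared distances, triple cutoff
product) is the standard one consistent with the published gradient
auxiliary functions; the finite-difference oracle in the test suite
validates the analytic gradients regardless of convention.

Linearity has two consequences exploited throughout:

1. fitting forces is ordinary least squares on the columns
   `−Σ_K ∂G_J(K)/∂R_{I,α}`, and
2. the scalar many-body PMF follows in closed form,
   `Φ = Σ_K Σ_J ω_J [G_J(K) − G_J(isolated)]`, with Φ → 0 at infinite
   dilution. No intercept appears anywhere: mean forces vanish on
   isolated particles, so the arbitrary constant of the PMF is fixed to
   zero by the training data containing low-density configurations.

Forces and energies share one gradient code path, so
`predict_forces ≡ −∇(evaluate_pmf)` holds identically, which is what
makes the potential usable in Metropolis Monte Carlo without any force
integration.

Units are reduced everywhere at the CG level: lengths in core diameters
σ\_c, energies in k\_BT, forces in k\_BT/σ\_c. R\_c = 2.5 σ\_c
throughout.

## Descriptor selection and fitting

Candidate pools are Cartesian products of parameter lists. The generic
pools are 330 radial candidates (22 μ × 15 R\_s) for two-body problems
and 100 radial + 64 angular (8 μ\_a × 2 λ × 4 ξ) candidates for
many-body problems.

Selection is greedy forward stepwise: the first pick maximises the
squared Pearson correlation c² with the force components; each later
pick maximises the increase of the squared coefficient of multiple
correlation R²; selection stops when the best increase falls below
`delta_r2_min` (default 1e−4). R² is computed by the
regression-residual route (variance fraction explained by a fit with
intercept), which is numerically stabler than, and tested to be
equivalent to, the matrix form **c**ᵀ**R**⁻¹**c**. The implementation
residualises the pool by Gram–Schmidt so each sweep costs
O(rows × pool); ties break to the lowest column index and all-zero
columns are removed up front. The final weights come from a *no
intercept* least squares on the selected raw columns, so ω carries
physical units; selection R² (centred) and fit R² can differ in the
third decimal.

Two caveats a user should know:

* Greedy selection recovers a planted subset exactly only when the pool
  contains no strongly coherent columns (near-duplicate parameter
  values). With near-duplicates it still reaches R² = 1 but may
  distribute weight across equivalent descriptors.
* For interactions much narrower than σ\_c the generic pools are too
  coarse. `fgsim.ao.depletion_pool` builds a pool whose Gaussian shifts
  are spaced a quarter of the depletion width qσ\_c apart and whose
  width ladder reaches a quarter of the shell; for such deep, narrow
  wells `delta_r2_min` must also be tightened (1e−6 in the package's
  q = 0.1 experiments) because truncating at 1e−4 leaves a PMF shape
  error of order 0.05 k\_BT — comparable to the three-body signal being
  measured.

## Fine-grained reference simulators

### Ligand-capped nanoparticles

Beads interact through a solvent-quality modified Lennard-Jones
potential: full repulsive core shifted by (1−s)ε below the minimum, the
attractive tail scaled by s ∈ [0, 1], truncated and shifted at
r\_c = 1.2 nm. s = 0 is the purely repulsive WCA limit (very good
solvent), s = 1 full LJ (vacuum). Bonds and angles are harmonic,
written `K(x − x₀)²` *without* the ½ because the published constants
accompany that form: σ\_b = 0.47 nm, ε = 0.8365 kcal/mol,
K\_b = 149.3787 kcal/mol/nm², b₀ = 0.47 nm, K\_θ = 2.9876 kcal/mol,
θ₀ = 180°, all converted to k\_BT at T = 300 K.

Geometry: a rigid spherical core of diameter σ\_c carries ligand chains
grafted on a seeded, randomly oriented Fibonacci lattice, initially
radial, relaxed by capped steepest descent. The full-scale
architecture (σ\_c = 4.2 nm, 275 core beads, 275 × 5 ligand beads,
1650 beads/particle, sampled for ~5×10⁷ steps) is available but
long-running; the desk-scale default used by the tests is σ\_c = 2.1 nm
with 42 ligands of 3 beads (127 "atoms" per particle), which keeps a
constrained pair scan in the minutes range.

During mean-force sampling the core unit (centre + grafting sites) is
completely frozen — a stronger constraint than freezing only the centre
of mass, chosen because core–core interactions are neglected anyway and
it removes the need for rigid-body integrators; for quasi-spherical
cores the orientational average is expected to be immaterial. Ligand
beads follow BAOAB Langevin dynamics (reduced bead mass 1, friction 2,
dt = 0.004 τ; the stiffest mode, the bond at ≈ 2K\_b, gives
ω dt ≈ 0.09). The mean force on a particle is the time average of the
bead–core repulsions on its core sphere plus the grafting bond/angle
forces on its sites; errors come from 10 block averages. Only 1–2
exclusions are applied to the nonbonded sum (directly bonded pairs).

The two-body PMF is the tail-anchored trapezoid integral
Φ²(R) = ∫\_R^Rmax F\_m dR′ of the projected, symmetrised mean force
F\_m = ½⟨(ΣF\_I − ΣF\_J)·R̂\_IJ⟩.

Desk-scale solvent conditions: s = 0.1 gives a purely repulsive pair
PMF; the attractive ("bad solvent") regime needs s = 0.9 at this
geometry because 3-bead ligands provide far less cohesive surface than
the full 5-bead corona, shifting the crossover to larger s. Both were
fixed from a calibration scan of s ∈ {0.1, 0.5, 0.9} before the
qualitative contrast was frozen into tests.

Training configurations for many-body fits are generated by
equilibrating CG sites (WCA repulsion of range σ\_NP plus a harmonic
spherical wall) over a ladder of confinement diameters, so the set
spans vanishing-force dilute states through densely packed coronas; the
recorded configurations drop the wall and are frozen for constrained
sampling.

### Colloid–polymer depletion system

Hard-sphere colloids (diameter σ\_c) among mutually ideal polymers
(diameter σ\_p = qσ\_c) excluded from radius a = (σ\_c+σ\_p)/2 around
each colloid. Ideality makes the exact mean force a contact-pressure
surface integral: F\_I = k\_BT ρ\_p ∮ n̂ [blocked] dS over colloid I's
exclusion sphere, where a surface point is "blocked" when inside a
neighbour's exclusion sphere. The integral is evaluated on a seeded
randomly oriented Fibonacci point set (quadrature mode; 1.2–4 × 10⁵
points give ≲ 0.3 % force error) or with uniform random points
(monte-carlo mode). The hard exclusion is exact — no pseudo-hard-sphere
softening — because the hard limit is the defining contract of the
model and the integral needs no differentiable stand-in.

For two colloids the force has the closed Asakura–Oosawa form
βW(r) = −η\_p^r (1+q)³/q³ [1 − 3r/(2(1+q)σ\_c) + r³/(2(1+q)³σ\_c³)]
(contact value −1.25 k\_BT at q = 1, η\_p^r = 0.5), used as the
independent oracle; for q ≤ 0.14 the many-colloid force is pairwise
additive to high accuracy, which the tests verify at q = 0.1 (≤ 1 %).

## Monte Carlo engine

Metropolis sampling with single-particle translations; in NPT one
volume move per sweep, uniform in ln V, accepted with
exp(−βΔU − βPΔV + (N+1)ln(V′/V)). Because Φ\_K depends only on sites
within R\_c of K, a translation of particle i changes Φ\_K exactly for
the set {K : |R\_K − R\_i| ≤ R\_c at the old or new position} ∪ {i};
the engine re-evaluates only that set (exact, not the conservative 2R\_c
superset) and the drift against periodic full recomputation is at
machine precision (≤ 1e−8 asserted). Translation steps are tuned toward
a 0.2–0.5 acceptance window during equilibration only and frozen for
production, preserving detailed balance. Volume moves that would shrink
any box edge below 2R\_c are rejected as outside the move's domain.
Ideal-gas checks: NPT density equals βP (exact for the V^N e^{−βPV}
measure), g(r) flat.

Fixed-geometry scans place two particles at separation 1.88 σ\_c and a
probe at offsets h (T: perpendicular bisector; L: collinear beyond one
end; SQ: a second pair at height h forming a rectangle), evaluated with
open boundaries. Φ^(3+) = Φ\_many − Φ\_pair vanishes identically when
the many-body model is effectively pairwise; scans are restricted to
hard-sphere-accessible probe positions since neither model is trained
inside the core.

## Neighbour search

All pair and triplet enumeration uses vectorised O(N²) numpy with
minimum image (refused when any box edge < 2R\_c). At the N ≤ 500 sizes
in scope this outperforms Python-level cell lists and is considerably
less code; lists are rebuilt per configuration.

## What the synthetic generators do and do not emulate

The AO simulator is *exact* for its model (ideal polymers), so passing
its tests demonstrates correct machinery, not robustness to sampling
noise. The nanoparticle simulator supplies genuinely noisy constrained
estimates like real FG reference data, but at desk scale its coronas
are thinner and its statistics shorter than production studies;
desk-scale numbers (PMF depths, the good/bad crossover value of s) are
therefore qualitative, and quantitative full-scale pair PMFs — which
need the 1650-bead architecture and orders of magnitude more sampling —
are deliberately outside what the test suite computes. Neither generator includes explicit solvent,
polydispersity, or anisotropic cores.

## Problem sizes used by the tests and acceptance script

Gradient checks: 200 random configurations, N ≤ 6, four mixed specs.
AO oracle: 250 two-colloid scans at 1.2×10⁵ surface points; q = 0.1
block: 200-distance pair set at 4×10⁵ points, 80 eight-colloid clusters
at 2.5×10⁵ points. MC: 32 particles, 2500 production sweeps (NPT).
Nanoparticle contrast: 10 distances × (2000 equilibration + 4000
sampling) Langevin steps for each of s = 0.1, 0.9. The full acceptance
run is ~10 minutes on one CPU.

## Known limitations

* Single species; no species-pair-resolved symmetry functions.
* Greedy selection is not globally optimal (see above); no regularised
  or Bayesian variants, and no uncertainty on ω.
* The MC engine is cubic-box orthorhombic only; no free-energy methods
  or bond-order analysis.
* Model files serialise floats at 17 significant digits; round trips
  are bit exact, but editing them by hand can silently change weights.
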