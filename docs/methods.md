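# Methods

## The pair potential

A molecule is a 2D point particle with one orientation angle φ and
three equivalent hydrogen-bonding arms at φ, φ±120°. The pair energy
is the sum of a 12-6 Lennard-Jones term and two independent
hydrogen-bond half-contributions,

    u = u_LJ(r) + (ε_HB/2)·U(θ_ij)·s(r) + (ε_HB/2)·U(θ_ji)·s(r),

θ_ij being the body-frame angle of the center-connecting vector seen
from molecule i.

**Orientational term.** `U` is the normalized 3-petal rose function

    U(θ) = [a₁·cos(3θ − π) + a₂·cos(6θ)] / a_max ,

with period 2π/3 and the petals phased so the global minima lie along
the arm directions (θ = 0, ±120°). `a_max` is the maximum magnitude of
the unnormalized function (found analytically on the critical points
of the cos 3θ polynomial), so the minimum of `U` is exactly −1 and a
fully aligned bond at r = r_HB has energy exactly −ε_HB. With the
shipped coefficients (a₁ = 0.6, a₂ = −0.4) a_max = 1. The factor ½ per
molecule is a deliberate convention: the quoted bond strength ε_HB is
the *full* bond; one favorably oriented molecule alone contributes
−ε_HB/2 (a "half bond").

**Switching window.** `s(r)` consists of two mirrored smoothstep
cubics t²(3−2t) meeting with value 1 and zero slope at r_HB and
falling to 0 with zero slope at r_HB ± r_fwhm. It passes through ½ at
r_HB ± r_fwhm/2, i.e. r_fwhm is literally the full width at half
maximum. The zero-slope stitches make the forces continuous.

**LJ truncation.** Cut-and-shift at 4σ_LJ. The shift (≈ 9.8·10⁻⁵ for
the mb preset) keeps the total energy continuous so NVE conservation
is a meaningful test; it also moves the nominal zero crossing and
minimum depth of u_LJ by that same tiny amount.

**Forces and torques** are the analytic gradients; with
Δ = r_j − r_i, α = atan2(Δy, Δx):

    du/dr  = u_LJ'(r) + (ε_HB/2)(U(θ_ij)+U(θ_ji))·s'(r)
    du/dα  = (ε_HB/2)·s(r)·(U'(θ_ij)+U'(θ_ji))
    f_i    = du/dr·Δ/r − du/dα·(Δy,−Δx)/r²
    τ_i    = (ε_HB/2)·s(r)·U'(θ_ij)

They are validated against central finite differences to 1e−6
relative. Because dilation leaves angles unchanged, only du/dr enters
the 2D virial: p = (2K_trans + Σ_pairs r·f_r)/(2A), cross-checked
against a −dU/dA finite difference.

Pair sums are evaluated by a full O(N²) loop (numba-compiled, with a
vectorized numpy reference implementation kept as an independent
cross-check in the tests). At the N ≤ 256 scales this package targets,
that outruns a cell list, which would be a pure performance device
here.

## NPT molecular dynamics

Velocity Verlet advances positions and orientations with dt = 0.001
(reduced time). Defaults mirror the production protocol: 100,000
equilibration steps with exact velocity rescaling and a Berendsen
barostat, then 20 sampling series of 100,000 steps with the Bussi
stochastic velocity rescale and the stochastic cell rescale (both
couplings: thermostat 0.01, barostat 0.1), 200 molecules. Choices the
protocol leaves open, fixed here:

* mass m = 1, moment of inertia I = m·r_HB²/4 = 0.25 — I only sets the
  rotational timescale, not equilibrium averages;
* rotational degrees of freedom are thermostated with translation,
  dof = 3N − 2 after center-of-mass momentum removal (the COM velocity
  is zeroed at setup and conserved thereafter);
* the stochastic cell rescale integrates d ln A by Euler–Maruyama with
  unit compressibility parameter; proposals with non-positive area are
  rejected;
* unwrapped coordinates are carried alongside wrapped ones (and are
  rescaled with the cell) so mean-squared displacements are free of
  periodic-image jumps.

Validation: NVE drift < 10⁻⁴ relative over 10⁴ steps at dt = 0.001
(196 molecules, hydrogen-bonded crystal); second-order convergence of
the drift in dt; the 2D ideal-gas NPT equation of state
⟨A⟩ = (N+1)T/p reproduced within 5%; thermostated kinetic temperature
within 2%.

## Constant-pressure nested sampling

The sampler maintains K live configurations (positions as fractional
coordinates of a square cell, orientations, area). Iteration i removes
the configuration with the highest enthalpy H = U + pV, records it as
level H_i with enclosed log-volume log χ_i = i·log(K/(K+1)), and
replaces it with a clone of a random survivor walked under the hard
constraint H < H_lim: per walk step, one ln V move (accepted with the
V^(N+1) Jacobian weight, V ≤ V₀) and N single-particle
translation+rotation moves. Step sizes auto-tune toward 50%
acceptance. The cell is isotropically rescalable; shear degrees of
freedom are omitted, which may shift solid–solid transition estimates
— a fully deformable (shearable) cell would be the more general
choice.

The initial live set is drawn from the exact constrained prior
(V ∝ V^N on (0, V₀], uniform positions), V₀ = 100·N·r_HB² so that
p·V₀ ≫ k_BT for all analysis temperatures. Production defaults are
N = 32, K = 500, L = 5000 walk steps, 500,000 iterations; the test
suite uses desk-scale versions (N ≤ 4, K ≤ 200, L ≈ 30, a few thousand
iterations). L matters: with L ≲ 10 the clone does not decorrelate and
the compression estimate biases ⟨H⟩ low; L ≈ 30 is the smallest length
at which the single-particle oracle is reproduced within its errors.

Analysis reweights levels with trapezoid widths
w_i ∝ (χ_{i−1} − χ_{i+1})/2 · exp(−H_i/T) (log-sum-exp stabilized).
Per-level areas are recorded so κ_T and α_P follow from V–V and V–H
covariances; C_p = Var(H)/T² + dof/2 with dof = 3N (the kinetic
prefactor of the partition function only adds a temperature-smooth
constant that cancels in extrema). Temperatures where over half the
weight sits on the last level are flagged truncated. The statistical
error of ⟨H⟩(T) is estimated by resampling the stochastic level
compressions t_j ~ Beta(K, 1). Validation: the N = 1 ideal gas against
the closed form ⟨H⟩ = 2T, and an LJ dimer against an independent NPT
Metropolis oracle, both within 3σ of combined errors.

## Observables

* **ADF**: for every ordered pair in a shell |r − r_target| ≤ 0.05
  around one of the five structural distances (0.7 LJ contact, 1.0
  direct HB, 1.73 shared-neighbor, 2.0, 3.0), the angle between
  molecule i's nearest arm and the connecting line, folded into
  [−60°, 60°) by the 3-fold arm symmetry; 75 bins of 1.6°, normalized
  to unit integral. All five distances are histogrammed in a single
  pass over the pair table. Peak counting uses prominence-filtered
  local maxima with periodic wrap at the ±60° seam.
* **Diffusion**: Einstein relation, D = (MSD slope)/4 fitted on lags
  spanning 10–50% of the trajectory; block-wise for errors. Frozen
  configurations give D = 0 by construction.
* **Hydrogen bonds**: a pair is bonded when its full HB energy is
  below −ε_HB/2 — an energetic criterion, chosen over a geometric one
  because the model defines bonding energetically. Per-molecule counts
  clip at 3 for the 0/1/2/3-bond fractions.
* **ψ₃/ψ₆ bond order**: per molecule, the magnitude of the
  bond-averaged exp(ikφ_bond), then averaged over molecules; neighbor
  cutoff at the first g(r) minimum (fallback 1.35·r_HB). The
  per-molecule-magnitude form is required for the honeycomb (a global
  complex average cancels between the two sublattices); its price is a
  1/√m noise floor at m neighbors, ≈ 0.58 for a random gas at
  first-shell cutoffs — the crystal/fluid contrast, not the absolute
  value, carries the signal.
* **Orientation cosine**: ⟨cos 3φ⟩ — the bare cosine is not invariant
  under the molecule's 3-fold symmetry.
* **Radial structure factor**: height of the first g(r) peak beyond
  0.5σ_LJ (the term is used loosely in the field; this definition is
  isolated behind one function).
* **Response functions**: NPT fluctuation formulas C_p = Var(H)/T²,
  κ_T = Var(A)/(T⟨A⟩), α_P = Cov(A,H)/(T²⟨A⟩), computed within each
  sampling block and averaged; the block scatter is the error. H here
  is the full instantaneous enthalpy (potential + kinetic + pA), so no
  separate kinetic term is added.

## Descriptors

The ADF descriptor concatenates the five ADFs down-sampled to every
third bin: 5 × 25 = 125 dimensions, deliberately not standardized
(all ADFs share one scale). The 125-dimension total is the contract
and dictates the binning — a 3° walk over the ±60° window would keep
41 points per distance, 205 in total — so the native binning here is
75 bins of 1.6°, and stride 3 yields exactly 25 per distance. Retained
bins are copied verbatim, no interpolation.

The property vector holds the 15 quantities (enthalpy, density, κ_T,
α_P, C_p, diffusion, radial structure factor, orientation cosine, mean
HB count, four HB fractions, ψ₃, ψ₆) in a fixed documented column
order, standardized column-wise to mean 0 / variance 1; constant
columns map to all-zero rather than NaN. `drop_feature` removes a
column (the intelligent pipeline drops diffusion) and re-standardizes
from the raw values.

## Phase-diagram pipelines

Dimensionality reduction always targets 3 components; the standard
algorithms are delegated to scikit-learn with the production
hyperparameters as defaults (Isomap: 100 neighbors, capped at n−1;
t-SNE: perplexity 20, early exaggeration 12, learning rate 100, 3000
iterations, PCA init, exact method for determinism; metric MDS).
Every stochastic stage takes an explicit seed. Clustering: k-means++
(10 restarts), Ward on standardized embedding coordinates
("normalized Euclidean"), DBSCAN (min_samples 80 in embedded space, 60
for diffusion peeling).

Two DBSCAN eps policies coexist deliberately. The diffusion peeling
selects eps from the elbow of the descending sorted k-distance curve
(maximum second difference after smoothing, with the extreme head and
tail excluded) — on 1D diffusion data the elbow is sharp and
reliable. For embedded-space clustering the sensible manual practice
is to vary the distance and keep the value that minimizes unassigned
points while the clustering stays meaningful; `eps_scan` automates
exactly that
(scan the k-distance range, maximize cluster count, break ties by
fewest noise points). The elbow rule is wrong in that setting: on
t-SNE islands whose diameter is comparable to the k-th-neighbor
distance it returns merging values.

**Sequential diffusion peeling** z-normalizes the remaining diffusion
values each round, runs 1D DBSCAN, removes the noise points as the
current (most mobile, most scattered) state group, and repeats three
times: gas, liquid-a, liquid-b, then the solid remainder, with group
ids ordered by descending mean diffusion. The procedure presumes
hierarchical scales — each successive state's diffusion band roughly
an order of magnitude tighter than the previous — which is what the
model's physics produces; bands of comparable width would peel
together.

**Agreement** between label grids: merge maps are applied (typical
use: merging the two liquid parts, and the high-pressure solids above
p* = 10), predicted clusters are matched one-to-one to reference
phases by the Hungarian assignment on the contingency table (majority
mapping can double-count), and unassigned points always count as
disagreement; a flag can exclude them from the denominator instead.
The metric is verified against exhaustive enumeration of assignments
on all small partitions.

What the planted fixtures do and do not show: the generative fixtures
(ADF templates with noise; diffusion hierarchies with planted solid
signatures, sized like production grids — hundreds of phase points,
~100+ points per solid sub-phase so the DBSCAN core sizes are
meaningful) verify that the pipelines recover structure that is
present by construction. They do not show that short MD on a coarse
grid produces descriptors as clean as full 2.1-million-step
production runs; that gap is covered, qualitatively only, by the
reduced grid below.

## The reduced phase-diagram grid

The desk-scale headline run (tests and `scripts/acceptance.py`)
simulates an 8–9 × 6–8 point (T*, p*) grid of the mb parametrization
with 64 (48 in the test suite) molecules, 8000 equilibration and
5 × 2000 sampling steps per point — roughly three orders of magnitude
less sampling than the full production protocol. Two concessions make that budget
meaningful, both package design choices: points in the expected solid
region (T* ≤ 0.11, or p* ≥ 14 at any T*) start from ideal lattices
(honeycomb below p* = 4, triangular packing above) rather than random
gas, the standard cold-start when a crystal cannot nucleate within the
budget; all other points start random, as in the full protocol. The
headline checks are then qualitative: diffusion peeling must place the
gas corner in the most mobile group and the four solid representative
conditions — (p*, T*) = (0.01, 0.10), (1.0, 0.06), (8.0, 0.05),
(20.0, 0.06) — in the least mobile group, and the ADF pipeline
(Isomap to 3D, then k-means with k = 7 — on the reduced grid the
continuous Isomap embedding clusters more reliably with k-means than
with Ward linkage) must assign those four conditions to distinct
clusters. The headline checks stop at this qualitative
level deliberately: a quantitative agreement fraction needs a
machine-readable reference diagram, and the only reference for this
model is a manually drawn figure.

## Known limitations

* The nested-sampling cell is square and isotropic; solid–solid
  boundaries sensitive to cell shear are beyond it.
* Short grid MD equilibrates fluids well but solids only from the
  lattice cold starts; cluster boundaries on the reduced grid are
  indicative, not converged.
* The Euler–Maruyama cell rescale and the global thermostat introduce
  O(dt/τ) discretization bias, negligible at the shipped couplings.
* `run_grid` caches per point by a content hash of the grid spec; any
  protocol change invalidates the whole cache by design.
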