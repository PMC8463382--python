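# Methods

This note records the models, conventions, numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Difference densities and charge partitioning

Volumetric data live on regular (possibly non-orthogonal) voxel
lattices in atomic units (Bohr, e/Bohr³). Integration is a midpoint
Riemann sum — each stored value owns one voxel of volume
|det(axis vectors)| — with no sub-voxel interpolation; the
grid-refinement tests (20³ → 40³ → 80³ on analytic Gaussians) bound the
resulting discretization error instead. Cube files are accepted in both
sign dialects (negative atom count = molecular-orbital cube, negative
voxel counts = Angstrom units) and always written back in Bohr.

The per-atom charge change ΔQ is the integral of Δρ = ρ_red − ρ_ox
"around" each atom. Since the integration neighborhood of the original
analysis is not specified, two partitions are provided and labelled in
the output: **nearest-atom** (Voronoi; the default — deterministic,
exhaustive, so ΣΔQ equals the total integral exactly, ties broken by
lowest atom index) and **spheres(radius)** (voxels within the radius of
any selected atom go to the closest selected atom; the remainder is
reported as unassigned; no default radius). Grids from the two redox
states must share a lattice; mismatches are rejected rather than
resampled, because resampling would silently shift ΔQ.

## Site detection and truncated models

[2Fe–2S] sites are Fe pairs (≤ 3.5 Å apart) sharing two non-protein
sulfurs within 2.6 Å of both irons; protein S/N/O side-chain atoms
within 2.6 Å of either iron are ligand donors. The 2.6 Å cutoff covers
the longest reported Fe-donor bond (0.246 nm) with margin. Fe_Y is the
iron with a His-nitrogen donor.

Truncation levels: **1** = cluster core + ligand side chains from C_β,
each C_β capped to a methyl by one added H (1.09 Å along the C_β→C_α
direction); **2** = full ligating residues plus backbone N/CA/C/O of
residues spanning between consecutive ligands of the same chain (their
side chains replaced by an H at the C_β position), ACE/NME caps at
segment termini; **3** = cluster core + every residue with any atom
within 4.0 Å of any core atom (whole residue included; the granularity
is a package choice), ACE/NME caps. Cap atoms are placed at standard
bond lengths from existing backbone geometry and are bookkept
separately from structure atoms, so nesting checks (level 1 ⊆ level 3)
compare structure atoms only. His protonation is carried as metadata
only; formal model charges (−2 oxidized / −3 reduced for 3Cys:1His with
thiolates, caps neutral) are stored, not validated.

Geometry tables use nm (PDB I/O stays in Å). Superposition is Kabsch
(SVD with reflection guard); the test suite checks it against an
independent quaternion (Kearsley) oracle to 1e-8.

## Seminario force constants

For bond i–j the 3×3 interatomic Hessian block H_ij is negated and
eigendecomposed; k_raw = Σ_m |λ_m| · |v_m·û_ij|, averaged over the i→j
and j→i blocks (both are computed; their difference is available in the
parameter metadata). Negative eigenvalue contributions enter by
absolute value — the standard practice for metal-site extraction — and
the policy is recorded in the output. k_raw is a d²E/dr²-scale spring
constant, so the emitted force constant is K_r = k_raw/2 under the
AMBER convention E = K_r (r − R_min)², in kJ/mol/nm²
(1 Hartree/Bohr² = 9.37583×10⁵ kJ/mol/nm²). R_min is the current
interatomic distance.

Seminario extraction is exact for pure pairwise harmonic bond models
and first-order accurate in the presence of angle cross-terms. The
synthetic three-atom toy therefore uses Fe–S-scale geometry (bond
lengths ≈ 4.25 Bohr, stretch constants 18 000–25 000 kJ/mol/nm²) with a
bend of 100 kJ/mol/rad², a realistic metal-angle stiffness that keeps
the cross-term contamination below 0.5%; much stiffer bends would leave
the first-order regime for any Seminario implementation.

## RESP charges

Charges minimize Σ_p (V_p − Σ_a q_a/r_pa)² + a Σ_a (√(q_a²+b²) − b)
subject to the total-charge constraint and symmetry-class equalities,
via iterated reweighted KKT solves (convergence |Δq| < 1e-8,
deterministic). Defaults: hyperbolic width b = 0.1 e, restraint
a = 0.0005 a.u. (community defaults), hydrogens exempt from the
restraint but present in the fit. A two-stage refit (heavy atoms
frozen) is available but off by default. Merz–Kollman probe shells use
a Fibonacci spiral at 1.4/1.6/1.8/2.0 × the Bondi van der Waals radius
(Fe assigned 1.3 Å, the usual metal-site choice), pruned of points
inside any other atom's shell at the same scale; an optional seed
applies a global random rotation to the spiral.

## Coevolution and the allostery screen

Sequences are weighted by 1/(number of sequences at ≥ 80% identity,
self included). For columns i, j, rows with a gap in either column are
dropped (gaps never form a 21st symbol), and the score is Pearson's
chi-squared on the weighted 20×20 joint counts against the
independence expectation. Raw scores are min–max rescaled to [0, 1]
over the off-diagonal (rank order preserved; a rank-quantile
alternative is provided since the upstream rescaling used by public
servers is unpublished).

The screen keeps pairs that pass, conjunctively: normalized score
> 0.7, membership in the top 30% of all off-diagonal scores, sequence
separation ≥ 5, and minimal heavy-atom distance ≥ 5 Å in the
representative structure ("not in close proximity" is operationalized
by these two geometric defaults; both are exposed and recorded in the
report header). A flag relaxes the score/top-fraction conjunction to
either filter alone, since the order and interplay of the two published
thresholds is ambiguous.

## Conformational clustering

GROMOS scheme: under a pairwise Kabsch-RMSD cutoff on backbone atoms
(N, CA, C; 0.11 nm default), repeatedly take the frame with the most
neighbors (ties → lowest frame index), form a cluster of it plus its
neighbors, remove them, repeat. Neighbors use ≤ cutoff (non-strict;
boundary equality is measure-zero in float data). The seed frame is the
representative; no re-fitting to centroids. Correctness is established
by exact agreement with a brute-force re-counting oracle on hundreds of
random small matrices.

## Lability kinetics

Traces are normalized by the mean of their first three points (robust
to single-point noise at t = 0). Each normalized trace is fit with a
flat model and with A(t) = a₀·(c + (1 − c)e^{−kt}), c ∈ [0, 1], k ≥ 0;
the free amplitude a₀ absorbs the scale offset the leading-window
normalization introduces for fast decays (without it the rate estimate
is biased low by up to tens of percent at coarse sampling). Model
choice is by small-sample AICc, and a trace is called **labile** only
if the exponential wins *and* the fitted total loss
(1 − c)(1 − e^{−k·t_end}) is at least 0.2. The underlying temperature
experiments are qualitative (release vs no release at 310/313/315/318 K
monitored at 458 nm); the rate fit and the 0.2-loss rule are this
package's operationalization and are labelled as such in reports. A
temperature panel flags a monotone rate–temperature trend when the
Spearman correlation of (T, k̂) equals 1 for a sample label.

## Synthetic data: what it does and does not show

Generators take an explicit seed, use one private random stream per
call, and emit ground truth alongside the data (written, not
recomputed, so test oracles stay independent of library code paths).
Default study conditions: difference densities carry exactly one
planted electron (0.5 e on the Fe_Y analog, 0.2 e per bridging sulfur,
0.1 e on the His-nitrogen analog — the qualitative localization pattern
of the one-electron reduction); decay panels span 310–318 K with rates
of 0.01–0.2/min, plateau 0.1, Gaussian noise σ = 0.01 on 60 points over
180 min; MSAs use 200 sequences × 100 columns with uniform background;
conformer sets hide 3 basins (0.3 nm displacement fields, 0.01 nm
within-basin spread) behind random rigid motions; the mock structure
plants an ideal-geometry 3Cys:1His site (Fe–S^Cys 2.25 Å, Fe–N^His
2.0 Å), a distal loop ~20 Å away and a contact pair at ~4 Å for the
allostery screen, all labelled synthetic.

These benchmarks demonstrate algorithmic correctness (parameter
recovery, oracle agreement, filter logic), not physical fidelity:
densities are isotropic Gaussians rather than DFT densities, Hessians
are exactly harmonic, MSAs have no phylogenetic structure beyond
optional identity clusters, and decay noise is homoscedastic Gaussian.
Passing them says the machinery computes what it claims on data whose
answer is known; conclusions about real proteins still inherit the
approximations of the upstream QM/MD/experimental inputs.

## Problem sizes

Default verification sizes: 40³ voxel grids (analytic integral error
< 1e-4 e), 50 random densities for conservation, 200 random matrices
for the clustering oracle, 100 MSA replicates for detection power, 100
fit replicates per rate and 1000 null traces for the kinetics rates —
sizes at which every Monte Carlo margin in the tests is stable across
seeds.
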