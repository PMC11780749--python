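# Methods

## Model

`gridbind` models the association of two rigid molecules, A and B, as
overdamped (Smoluchowski) diffusion of B's pose relative to A.  With A's
center of mass fixed at the origin and its principal axes of inertia
aligned with the coordinate axes, the configuration space is
SE(3) = R+ x S^2 x SO(3): the center-of-mass distance r, the direction
(theta, phi) of B's center of mass, and B's orientation, parametrized by a
unit quaternion q on the upper half of S^3 (the antipode -q describes the
same rotation and is folded away).

The space is discretized into N_d = N_r x N_s x N_o Voronoi cells — the
product of an equidistant radial grid, an icosahedral-subdivision grid on
S^2 and a tesseract-subdivision grid on the quaternion sphere.  On this
grid the Fokker-Planck operator is discretized by the square-root
approximation (SqRA): for adjacent cells a ~ b,

    Q_ab = D * S_ab / (h_ab * V_a) * sqrt(pi_b / pi_a),
    sqrt(pi_b / pi_a) = exp(-(V_eff(x_b) - V_eff(x_a)) / (2 kB T)),

with h the center-to-center distance, S the interface area, V_a the cell
volume and V_eff the cell-center energy.  Diagonal entries make row sums
vanish.  The construction satisfies detailed balance with respect to
pi_a ∝ V_a exp(-V_eff(x_a)/kB T) exactly, so the spectrum is real; the
generator relates to a Markov-state-model transition matrix through
P(tau) = exp(Q tau) (same eigenvectors; lambda_i = exp(kappa_i tau);
implied timescales t_i = -1/kappa_i).

Assumptions: (i) both molecules rigid; (ii) cells small enough that the
energy is roughly constant within a cell; (iii) isotropic diffusion — a
single scalar D drives translational and rotational moves alike.  The
last assumption is a known simplification: rotational diffusion of a
non-spherical molecule is a tensor coupled to its moments of inertia.
The weight `alpha` of the rotation metric (distances x alpha, border
areas x alpha^2, volumes x alpha^3) is exposed for sensitivity checks and
defaults to 1.

## Grid geometry

* Radial cells are slabs between midpoint boundaries; the innermost
  boundary is 0 and the outermost extends half a spacing beyond the last
  radius, so the outer cells have the same thickness as interior ones.
  The outer boundary is reflecting: no transitions into the bulk are
  modeled.
* S^2 cells are spherical Voronoi polygons; their areas come from the
  spherical-excess formula applied to the ordered Voronoi vertex loop
  (cross-checked against scipy's area routine and against Monte-Carlo
  assignment in the tests).  Interfaces between angular neighbors are
  circular-sector differences (beta/2)(R_out^2 - R_in^2); by default beta
  is the angle between the two cell-center directions, with an optional
  `voronoi_edge` mode that uses the shared Voronoi-edge arc instead.
* S^3 cells are Voronoi cells of the antipodally doubled quaternion set
  (2 N_o points), so no rotation cell is cut by the truncation to the
  upper half-sphere.  Borders between adjacent cells (cells sharing >= 3
  Voronoi vertices) lie on great 2-spheres; an SVD rotation annihilates
  the fourth coordinate and the border area follows from the spherical
  excess of the flattened polygon (the smaller of the two complementary
  polygons).  The border area between two rotations accumulates the
  congruent contributions of both antipodal cell copies.
* S^3 cell volumes have no general closed form; they are estimated by
  assigning uniform S^3 samples (normalized Gaussian 4-vectors, default
  5000, seeded) to the nearest doubled-set center and multiplying the
  sample fraction by the total hypersurface 2 pi^2.  The fraction
  estimator is unbiased and reproduces the uniform value 2 pi^2/(2 N_o)
  for symmetric grids within binomial error; the canonical cell volume is
  the average over the two congruent antipodal copies, so canonical
  volumes sum to pi^2 — consistent with rotations covering half the
  quaternion sphere.
* Arbitrary grid sizes are reached by pruning the smallest subdivision
  level with enough points: iteratively remove the point (preferring the
  highest subdivision generation, so polytope vertices go last) whose
  nearest-neighbor distance in the retained set is smallest, ties broken
  by lexicographic coordinate order.  The rule is deterministic and keeps
  the retained set at least as well separated as random removal.

## Energies

Within the rigid-body approximation the effective cell potential is the
intermolecular energy of the pose at the cell center — one evaluation per
cell.  The built-in evaluator sums Coulomb (f_elec = 138.935458
kJ mol^-1 nm e^-2) and Lennard-Jones terms with Lorentz-Berthelot mixing
and no cutoff (grid radii are at most a few nm; a cutoff flag exists).
Any external engine can replace it, either through the callable hook of
`evaluate_grid` or by importing a plain-text per-cell energy table.

**Energy capping.**  Boltzmann factors are guarded by clipping cell
energies at (minimum finite energy + 500 kJ/mol) before differencing;
coincident-atom clashes (`+inf` sentinel) land exactly at the clipped
maximum.  Every pairwise difference is then within +-500 kJ/mol, uphill
rates across a full-cap interface are ~e^-100 (numerically zero), and —
unlike clipping the pairwise differences themselves — the generator stays
exactly reversible with respect to the clipped Boltzmann distribution.
The two guards differ only for pairs of cells that are *both* at least
500 kJ/mol above the global minimum, whose Boltzmann weight (< e^-200) is
far below double-precision resolution.

## Eigensolver

The cap leaves escape rates from clipped cells at ~e^{+100} times the
diffusive scale, so the symmetrized generator
diag(pi)^(1/2) Q diag(pi)^(-1/2) has entries spanning ~45 orders of
magnitude.  A dense symmetric eigensolve cannot resolve the slow spectrum
against such a norm (absolute eigenvalue error ~ norm x machine epsilon),
so whenever the diagonal dynamic range exceeds 1e8 the package switches
to shift-invert Lanczos at sigma slightly above zero, with the shifted
matrix symmetrically equilibrated to unit diagonal before solving.
Solves use a sparse LU of the equilibrated matrix below 25,000 cells and
a Jacobi-preconditioned conjugate gradient above (the equilibrated
operator is well conditioned even though the raw one is not).  On the
64,000-cell water grid the slow spectrum from this path agrees with the
LU reference at 16,800 cells to ~4e-11 and takes about 2.5 minutes on one
CPU.

## Metastable analysis

The dominant eigenvectors are clustered with k-means (k = 12 by default,
10 restarts, seeded).  Clustering operates on the probability-weighted
(left) eigenvectors phi_i = diag(pi) psi_i with unit-L2-normalized
columns.  The weighting matters: right eigenvectors are membership
functions that assign O(1) values to entire exchange sectors, so k-means
splits the low-probability background along them; weighting by pi
collapses all low-probability cells onto the origin of eigenvector space,
and the background — over 99.7% of cells for the water dimer — forms a
single cluster while binding minima and transition regions split off.
This matches the convention in which the rate matrix is written
column-normalized and its "right" eigenvectors are the probability-
weighted ones.

## Trajectory assignment and MSMs

Frames of a two-molecule trajectory are assigned to grid cells in three
steps after aligning each frame to A's principal frame (mass-weighted
Kabsch): nearest radial layer for the COM distance, nearest direction
point, nearest quaternion (rotational metric, double cover folded).
Frames beyond the outer boundary either go to the outermost radial layer
("assign_outer") or stay unassigned ("omit"); transition counts touching
an unassigned frame are dropped.  Counting is sliding-window; detailed
balance is enforced by count symmetrization (C + C^T)/2 — the minimal
reversible estimator; the transition matrix is row-normalized over
visited states.

## Synthetic fixtures and what the tests show

The `water_like` fixture is a rigid three-site water (O-H 0.09572 nm,
H-O-H 104.52 deg, charges -0.834/+0.417/+0.417 e, oxygen-only LJ
sigma = 0.31506 nm, eps = 0.63627 kJ/mol).  The standard study grid is
N_r = 10 radii on 0.2-0.4 nm with N_s = N_o = 80 (64,000 cells),
T = 300 K, friction coupling tau_c = 0.1 ps, effective mass = B's total
mass (the choice of effective mass and of a shared translational/
rotational D is a convention, not a prediction; absolute timescales
depend linearly on it and are validated only through their exact 1/D
scaling).  The fixture exercises the full pipeline without any external
engine, but it is a vacuum dimer on a grid confined to the first
coordination shell: no solvent, no bulk escape, no internal flexibility.
Passing tests therefore validate the discretization, the rate algebra
and the spectral machinery — not force-field accuracy for real water.

Monte-Carlo geometry oracles in the test suite (sphere-area assignment,
border-area sampling on the bisecting great sphere, binomial volume
checks) run at fixed seeds with 3-sigma bands (4-sigma where one bound
covers up to 162 simultaneous cells).

## Numerical choices and degenerate inputs

* Quaternion canonicalization threshold 1e-12; unit-norm tolerance 1e-9;
  grid deduplication tolerance 1e-10; Voronoi-vertex merge tolerance 1e-8.
* Principal-frame signs are molecule-intrinsic (mass-weighted coordinate
  skewness, falling back to the farthest atom's sign), making alignment
  invariant under rigid pre-rotations; near-degenerate inertia moments
  warn that the in-plane axes rest on the numerical tie-break.
* N_r = 1 uses the half-spacing rule with the radius itself as spacing;
  N_s = 1 is a single full-sphere direction cell; N_o = 1 a single
  rotation cell of volume pi^2.
* k-means ties in `top_populated_cells` break by cell index.
* The 1-D `chain_geometry` helper (h = a, S = 1, V = a) exposes the
  assembly to closed-form finite-difference spectra for testing.

## Known limitations

* Isotropic scalar diffusion; no anisotropic rotational diffusion tensor.
* Reflecting outer boundary; association/dissociation through the bulk is
  outside the model.
* Cell energies are single-point evaluations; no relaxation or restrained
  averaging of clashes (external tables can supply refined energies).
* S^3 volumes are Monte-Carlo estimates; their sampling noise enters V_a
  in the rate prefactor (detailed balance is unaffected, since the
  stationary distribution uses the same volumes).
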