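# Methods and conventions

This note records the model definitions, parameter choices and numerical
conventions behind hydroflex, and what the synthetic-fixture tests do and
do not establish about real trajectories.

## Coordinate frame and geometry

All analyses run in the laboratory frame with the z axis as the membrane
normal. Positions along z are shifted by a configurable origin
(`ChannelGeometry.z_origin`) so the membrane mirror plane sits at z = 0;
when unset, the origin is the z of the lipid centre of mass averaged over
the analysis window (falling back to the protein CoM for membrane-free
systems). Frames are stored wrapped as read; only the permeation analysis
needs continuity and handles wrap jumps explicitly. Boxes are orthorhombic
only — the membrane systems this tool targets are built that way — and the
minimum-image convention is applied per axis.

Trajectory superposition (used only inside the flexibility module, and as
a standalone RMSD utility) is a mass-weighted Kabsch fit via SVD with the
determinant-corrected rotation, so the returned rotation is always proper.
Density and permeation analyses deliberately run *without* global fitting:
the two-slab criterion and the z-profiles are defined in the membrane
frame, not the protein frame.

## Permeation counting

Two planes separated by Δ = 25 Å sit symmetrically about z = 0, with
detection slabs of thickness δ = 5 Å outside them. The tracked point is
the water residue's centre of mass. Per water, a finite-state machine
implements: prime on first observation inside either slab; record one
event on later observation in the opposite slab; abandon the episode on

1. a periodic-wrap jump, |z(t) − z(t−1)| > L_z/2 between consecutive
   frames;
2. a between-planes frame whose lateral distance from the channel axis
   exceeds `cylinder_radius` (default 10 Å) — the operational test for
   protein–membrane interface pathways, since a water sneaking along the
   lipid–protein seam leaves the channel lumen laterally. The axis is the
   protein's mass-weighted xy centre, recomputed every frame;
3. any frame beyond either slab (|z| ≥ Δ/2 + δ).

Rule 3 is deliberately symmetric: abandoning only on the origin side would
let a water that overshoots *past* the destination slab in a single
sampling interval complete later, and counting would then depend on the
direction of time. With the symmetric rule, the count within each
barrier-free stretch of frames equals the number of alternations in the
sequence of slab visits, which makes time reversal swap inward/outward
counts exactly — a property the test suite checks against an independent
episode-enumeration oracle. A water crossing the whole protein undetected
within one frame interval indicates under-sampling, not a permeation
observation.

One event maximum per priming episode; after completion the water
immediately re-primes with the destination slab as the new origin, so an
oscillating water contributes one event per alternation, never two per
pass. Events are windowed by completion time into half-open 100-ns bins
(the final window truncated at the trajectory end, closed there). Lateral
distances are computed without xy minimum-imaging: the protein is assumed
whole and near the box centre, which holds for membrane setups and for all
generated fixtures.

## Density profiles, channel opening, wettability

"Number density" means the mean molecule (water CoM) or atom count per bin
per frame — no kernel smoothing, no volume normalisation; the convention
is declared in the outputs, and profile sums therefore equal mean counts
in the profiled region exactly. Water profiles are restricted to the
channel cylinder; per-component atom profiles are not.

The channel opening is `min over bins of (count × 7.1 Å²)` within a search
range, where 7.1 Å² is the cross-section of one water molecule. For the
product to be an area, the profile must be computed with a slab thickness
of one water diameter, 2.8 Å, which is what the `opening` subcommand uses;
the estimator also reports the z of the minimising bin.

Residue wettability w_r is the fraction of a residue's atoms (heavy and
hydrogen alike) that come within r_c = 4 Å (inclusive) of a permeating
water's CoM at any analysed frame inside a transit interval
[t\*, t\*+τ], accumulated separately for outward and inward transits.
Contacts outside transit intervals are ignored. The per-domain tally
counts residues with w_r strictly greater than 0.9.

## Interaction energies and geometry

E = Σ_{i∈A, j∈B} [ 332.0636 q_i q_j / r_ij +
ε_ij((r_min,ij/r_ij)¹² − 2(r_min,ij/r_ij)⁶) ] with CHARMM combining rules
ε_ij = √(ε_i ε_j), r_min,ij = r_min,i/2 + r_min,j/2, vacuum dielectric and
minimum-image distances. The default is the full double sum over all
pairs — any screening or truncation would be an additional model choice —
but a plain 12-Å truncated mode is provided for comparison with
simulation-style cutoffs. Charges come from the PSF; Lennard-Jones
parameters from a flat per-atom-name TSV. A topology read without a PSF
has its charges defaulted to zero and is flagged, and the energy code
refuses to run on it rather than silently returning zeros.

Radius of gyration is the mass-weighted
√(Σ m_i |r_i − r_CoM|²/Σ m_i) per frame. Channel-lining layer selections
take protein residues whose time-mean CoM falls in a z layer and within a
lateral cutoff of the mean channel axis.

## PCA flexibility framework

Bead models:

* `four_bead_domain` — the bundle and hash domains are each split at the
  domain's mass-weighted mean z (atoms assigned by their own time-mean z),
  producing bundle-upper/lower and hash-upper/lower CoM beads with summed
  masses. A helix lying entirely in one half triggers a warning but the
  bead is still formed from the remaining atoms.
* `binding_site_residues` — the n (default 18) protein residues whose
  time-mean CoM is nearest the binding-site centre (given explicitly or as
  the ligand's mean CoM), one CoM bead per residue. The proximity rule is
  parameterised so an explicit residue list can be reproduced exactly.

Bead series are optionally rigid-body fitted (two-pass mass-weighted
Kabsch onto the mean). The covariance of the concatenated 3M bead
coordinates uses the ensemble (1/n) normalisation; eigenvalues are clipped
at zero (the matrix is PSD up to round-off) and sorted descending, with
eigenvector signs fixed by making the largest-magnitude component
positive. Modes with λ < 1e−10 Å² are reported as frozen: infinite
stiffness, zero flexibility. kBT uses k_B = 0.0019872041 kcal/(mol·K) and
T = 303.15 K, the simulation temperature of the target systems. A warning
is issued when n_frames ≤ 3M.

The vibrational weight of mode i is
w_vi = 1 − Σ_k (e_i · r̂_k)², where {r̂_k} is an orthonormal basis of the
rigid-body subspace at the mean structure: three uniform translations and
three infinitesimal rotations about the principal inertia axes through the
CoM, orthonormalised by SVD (a collinear structure leaves 5 basis vectors,
with a warning). This directly measures the residual mixing between
rotational and vibratory modes that fitting cannot always remove in
low-dimensional bead models; both mechanisms (fitting and weighting) are
available and the drift tests exercise each.

Projected flexibility uses the *squared* inner product,
σ_P = (1/kBT) Σ λ_i w_vi (P·e_i)². An unsquared sum would be
sign-indeterminate (eigenvector signs are arbitrary) and would not reduce
to σ_P = σ_i in the P = e_i limit; the squared form makes σ_P a quadratic
form, P^T C_w P / kBT, independent of basis choice within degenerate
eigenspaces, and summing it over any orthonormal basis recovers σ when
w_vi ≡ 1. The three rocking-bundle patterns are defined on the four-bead
model with x̂ the unit in-plane vector from hash CoM to bundle CoM and ẑ
the channel axis: A (alternating opening) = (B_up:+x̂, B_low:−x̂,
H_up:−x̂, H_low:+x̂), B (up–down slide) = (B:+ẑ, H:−ẑ),
C (simultaneous opening) = (B:+x̂, H:−x̂), each normalised; A, B, C are
mutually orthogonal by construction.

Segment analysis runs an independent fit + PCA + weighting per
non-overlapping time window (default 200 ns). The segment count is the
nearest integer to span/width (minimum 1): a trailing remainder shorter
than half a window joins the last segment, a longer one becomes its own
shortened segment, and a trajectory shorter than one window is analysed
as a single shortened segment with a warning.

## Synthetic fixtures: what they do and do not show

The channel generator scripts every water's CoM path and therefore knows
the exact event list: complete transits (monotone z between the slab
centres, inside the cylinder), partial excursions, interface decoys
(crossing at lateral distance cylinder_radius + 4), wrap decoys (a single
slab-to-slab teleport exceeding L_z/2) and bulk waters (random z walk,
clamped laterally outside the cylinder so they can never complete). A
0.2-Å jitter (clamped at 0.6 Å) keeps distance computations off-grid;
the clamping margins (slab half-width 2.5 Å, cylinder margin 4 Å) are
chosen so jitter can never change a frame's classification, which is what
keeps the ground truth exact. The default box is 44 × 44 × 50 Å — the z
height must exceed Δ + 2δ = 35 Å and, for wrap decoys to be genuine
wraps, stay below 2(Δ + δ) = 60 Å. The Gaussian bead generator draws
i.i.d. frames from a prescribed PSD covariance about a fixed mean
structure, optionally composing a rigid z-rotation drift, and returns the
analytic eigenpairs; the helper `vibrational_covariance` builds targets
orthogonal to the rigid-body subspace so the expected σ is exactly
Σλ/kBT.

These fixtures validate the *detection and decomposition machinery*
exactly, but they are kinematic: no forces, no thermostat, no diffusive
recrossing statistics, no solvent structure, no correlated protein
motion. Passing them shows the criteria are implemented correctly, not
that any particular biological system permeates water; applied to real
trajectories the counts additionally depend on sampling interval (a
transit faster than the frame spacing can be missed — the same
under-sampling the symmetric beyond-slab rule guards against).

Test problem sizes were chosen to exercise the estimators well inside
their asymptotic regimes while keeping the suite fast: 100 randomized
permeation systems of up to ~60 waters × 200 frames for the oracle sweep,
10⁴ frames for Gaussian eigenvalue recovery (sampling error ~√(2/n) ≈ 1.4%
per eigenvalue against the 5% tolerance), 500-frame/50° arcs for the
rotation-drift fixtures (small enough for the tangent-space rigid-body
model to apply), and 20 fixtures for the all-pairs wettability scan.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* No osmotic/diffusive permeability coefficients (p_f/p_d), no
  collective-coordinate permeation estimators, no ion-permeation counting.
* No pore-radius (HOLE-style) profiling; the orifice estimator is the
  density-minimum proxy described above.
* Lateral distances ignore xy periodic images (valid when the protein is
  whole and central in the box).
* MMPBSA-style binding free energies, PME reciprocal-space electrostatics
  and bonded terms are out of scope; the pairwise energies are raw
  force-field interaction energies, not free energies.
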