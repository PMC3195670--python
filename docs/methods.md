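# Methods

`helixpack` analyses ensembles and trajectories of two-transmembrane-helix
systems — the kind produced by many independent coarse-grained
self-assembly simulations of a receptor TM dimer (the worked case
throughout is an integrin alphaIIb/beta3-like pair) — and classifies their
packing geometry, packing modes, conformational stability and helix/helix
interface.  This note records the models, conventions, parameter choices
and limitations.

## Signed crossing angle and handedness

For each conformation the two helix axes are fitted independently as the
dominant principal direction of the centred Calpha coordinates, sign-fixed
N-to-C; the anchor is the centroid and the segment extent is taken from the
extreme axial projections.  A straight-axis model is appropriate for
single-span TM helices; kinked or curved helices are out of scope.

The crossing angle Omega is the acute angle between the axes, reported in
(-90, +90] with a sign given by the chirality triple product

    sign(Omega) = sign( (d_a x d_b) . u ),

where `d_a`, `d_b` are the axis directions and `u` points from the closest
approach point on helix a to that on helix b, computed on the *finite* axis
segments (infinite-line closest points can fall outside the membrane span
of short TM helices).  This product is invariant under swapping the
helices and under flipping either axis direction, and changes sign under
mirror reflection — so negative Omega means right-handed (RH) packing and
positive means left-handed (LH), the convention under which GxxxG-mediated
dimers such as alphaIIb/beta3 measure near -30 degrees.  Frames within
`sign_tolerance` (default 2 degrees) of zero are handedness-indeterminate
and are excluded from RH/LH fractions and from angle spreads; a
consequence is that a spread whose true endpoint is 0 degrees is reported
censored at about -2 (or +2) degrees.

Superpositions use the closed-form least-squares rigid fit (proper
rotations only, determinant +1), delegated to
`scipy.spatial.transform.Rotation.align_vectors`; RMSD series superpose
the chosen backbone selection frame by frame.

## Ensemble analysis

**Angle distribution.**  One angle per frame, flattened over members with
per-member weights `1/n_frames` so each simulation contributes equally.
Handedness fractions are sign classes over determinate frames, not fitted
mixtures — matching how RH/LH populations are usually quoted.  Histograms
use 5-degree bins over (-90, +90].

**Spatial density map.**  Each member's reference-helix backbone is
Kabsch-fitted onto a canonical reference — the reference helix axis on +z
through the origin, azimuth pinned by rotating its N-terminal Calpha into
the +x half-plane (the azimuth must be pinned or the map smears).  The
mobile helix's backbone positions are then projected onto the bilayer (xy)
plane and accumulated on a grid (default 1 A cells, sized from the data
plus a margin so the total mass is always 1), again with equal per-member
mass.  Maxima — the packing modes — are found on a 3x3-smoothed copy and
basins assigned by descending-order steepest ascent.  Two merge rules
prevent a single elongated density ridge (a tilted helix projects to a
band ~2 sin(Omega) x half-length long) from fragmenting into spurious
modes: peaks closer than 3 A merge, and a peak whose prominence above its
connecting saddle is less than half its height is absorbed into the higher
neighbour.  Distinct packing modes are separated by near-empty density and
survive both rules.  Modes below 5% basin mass are flagged minor.  All
thresholds are parameters.

Note an intrinsic property of backbone-density maps: for an extended,
tilted helix the density maximum need not coincide with the projected axis
centroid (the footprint is a band/ring, not a point).  Parameter-recovery
tests of peak *positions* therefore use compact constructions (small helix
radius, near-vertical axes) where the construction centre is the true
density mode; basin-mass recovery is tested at the realistic default
geometry, where it is insensitive to the footprint shape.

**Representative structures.**  The representative of a mode is the member
whose mobile-helix projected centroid lies nearest the mode position, ties
broken by lowest member index.

**Convergence.**  The check formalizes "does half the data give the same
answer": the mean, over seeded random subsamples without replacement, of
the Jensen-Shannon divergence (in bits; scipy returns the JS *distance*,
which is squared) between the subsample's and the full ensemble's
crossing-angle histograms.  Default: fraction 0.5, 20 draws, converged
below 0.05 bits.  Divergence is exactly 0 at fraction 1.

## Stability assessment

The stable/unstable vocabulary of membrane-protein model assessment is made
explicit: a run is **stable** when the mean RMSD over the final window
(default: last 25% of frames) sits below `stable_threshold` (default 3 A,
the usual plateau criterion) *and* the Theil-Sen slope over the final half
is below `drift_threshold` (default 0.05 A/ns) in magnitude; **unstable**
when the plateau exceeds the threshold while still rising (the
steadily-climbing 5-7 A after ~30 ns signature); anything else is
indeterminate.  Theil-Sen is used so single spikes cannot flip the call.
The windows and thresholds are configuration, not constants of nature.

Dimerization events in assembly runs are defined at helix scale: the first
frame from which the closest approach between the fitted axis *segments*
stays below `contact_distance` (default 8 A — a documented choice) for at
least `persistence` (default 10) consecutive frames.  Axis-level contact
mirrors the coarse-grained notion of an encounter better than any
atom-atom minimum distance.

Pairwise trajectory comparison superposes every cross pair of frames from
the final windows (default halves) of two runs; two runs that converged to
the same structure give cross-RMSDs within their own fluctuation range.

## Interface analysis

Contacts are inter-chain residue pairs within a cutoff.  With full
atomistic chains the distance is the minimum heavy-atom distance (4.5 A
default); when either chain carries only backbone-level atoms (CA/CB, as
in coarse-grained or generator output) a Calpha-Calpha residue-centre
distance with a 7 A default is auto-selected and recorded on the result.

Residue orientation asks whether a side chain points at the partner helix:
the Calpha-to-Cbeta direction (for glycine, which has none: the outward
radial vector from the residue's own helix axis through the Calpha) and
the Calpha-to-partner-axis direction are both projected onto the plane
normal to the own helix axis; below 60 degrees is "toward", above 120
"away", otherwise "lateral".  These thresholds formalize the qualitative
toward/away language used for interface glycines (G972/G976-like) in RH
vs LH dimers.  Interface agreement between two structures is the Jaccard
index of their interface residue sets (defined as 1 when both are empty).

## Synthetic generators

The generators emulate the *study conditions* of a CG self-assembly
campaign, not its physics — no forcefield, lipids or thermodynamics.

* **Ideal helix**: 1.5 A rise, 100 degrees twist per residue, 2.3 A Calpha
  radius (textbook values); optional pseudo-Cbeta 1.5 A radially outward
  on non-glycines gives every residue a side-chain direction.  The built
  coordinates are re-aligned so the *fitted* principal axis is exactly +z
  (a finite helix's principal axis is otherwise tilted a few tenths of a
  degree by partial-turn asymmetry), which removes a systematic bias from
  all angle targets.  Default sequences are poly-leucine threaded with the
  published marker residues: chain A (alphaIIb-like) residues 963-986 with
  G972/G976, chain B (beta3-like) residues 692-714 with M701/I704/G708.
* **Dimer**: helix B is spun so a chosen face points at A, tilted about
  the interhelix connector by the target Omega (which sets the signed
  crossing angle by construction), and placed at the axis separation
  (default 10 A — the smallest clash-free separation for the idealized
  CA/CB geometry across the +-60 degree Omega range; any atom pair closer
  than 2 A is rejected as infeasible).
* **Mode-mixture ensemble**: members sample a packing mode by weight, an
  angle from Normal(mean, sd), and a placement azimuth around the
  *reference* helix with arc-length jitter (default 1.5 A).  Defaults are
  the published 70/30 RH/LH weights with the RH mode at -30 degrees
  (sd 8) and the glycine face buried, and an LH mode at +30 degrees
  (sd 10) on the opposite reference face with the glycine face turned
  away; the LH centre and both spreads are documented assumptions chosen
  to reproduce the qualitative bimodality, not published values.
* **Assembly trajectory**: frame 0 places the axis centroids exactly 60 A
  apart in the bilayer plane; the relative centre then performs a seeded
  2D random walk (default step sd 1 A/frame, 1 ns/frame) with small tilt
  jitter applied about each helix's own Calpha centroid so the separation
  series is untouched.  With `bind_frame` set, the approach is steered
  (floored safely above the contact cutoff) so the first sub-cutoff frame
  is exactly the requested one, and the pair is held bound afterwards.
* **Drift trajectory**: a fixed random per-atom displacement field is
  scaled per frame — quickly to a plateau, or linearly (ramp) — with the
  terminal scale calibrated by root-finding so the *post-superposition*
  all-atom RMSD equals the requested value; per-frame Gaussian noise
  (default 0.2 A) adds fluctuation.
* **Rotation scan**: member i spins the designated helix by i x increment
  (default 15 degrees) about its own fitted axis, all other coordinates
  bit-identical.

All generators are deterministic under a fixed seed, and every
construction truth (mode label, true angle, azimuth, bind frame, scan
rotation) is stored in member metadata/provenance, so downstream analyses
are tested as parameter recovery.

What the generators do *not* emulate — and hence what passing tests do not
show about real data: realistic backbone irregularity and side-chain
packing, membrane deformation, kinetics, correlated frames within a
trajectory, and the broad anisotropic basins of real free-energy surfaces.
They establish that the *analysis* recovers known geometry and mixture
structure, not that any simulation is right.

## Pipeline and reproducibility

The pipeline validates its YAML configuration before any I/O, runs
angles -> density/modes -> representatives -> stability -> interface ->
convergence, writes a run directory (resolved config, delimited tables,
plain-text density grid, plots, JSON report), and re-raises any failure
with the stage named.  All randomness derives from the single top-level
seed through `numpy.random.SeedSequence` child streams in fixed order, so
a rerun with the same config and seed reproduces the report exactly.
Problem sizes used by the shipped checks (1000-member ensembles,
a few-hundred-frame trajectories) run in seconds and were chosen as the
smallest sizes at which the published fractions are recovered within
their sampling error.

## Known limitations

* Straight-axis helix model; no kinks, no per-residue helix parameters.
* The density map is 2D occupancy, not a free-energy surface; no kernel
  density estimation.
* The NMR-ensemble benchmark (deposited structure 2K9J) requires the user
  to supply the coordinates (`data/2k9j_tm.pdb`); they are not
  redistributed with the package.
* Backbone-only contact mode approximates residue proximity by Calpha
  distance; buried surface areas and packing scores are out of scope.
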