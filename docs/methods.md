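# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Units and conventions

Coordinates are Å, times ps, masses amu throughout. Diffusion
coefficients are reported in m²/s via 1 Å²/ps = 10⁻⁸ m²/s. Atom,
molecule and frame indices are 0-based; all bin and window intervals
are half-open `[a, b)` unless a closing value is stated. Only
orthorhombic periodic cells are supported (triclinic input is
rejected): the minimum-image convention is then exact per component,
`d → d − L·round(d/L)`, with the half-box tie resolved so each
component lies in `[−L/2, L/2)`. Per-frame (NPT-style) boxes are
accepted; the MSD uses the stored unwrapped coordinates with no
affine box-fluctuation correction, which is second-order at ambient
conditions and desk scale.

Unwrapping reconstructs continuous paths by accumulating *integer*
image counts per atom (frame 0 unchanged), so floating error does not
grow along the trajectory and wrap∘unwrap is the identity to within
one rounding of the final addition. A frame-to-frame step reaching
L/2 makes the unwrap ambiguous and triggers a warning naming the atom
and frame; trajectories must be sampled densely enough that true
motion stays below half a box length per frame.

## Mean-squared displacement and Einstein diffusion

The MSD is computed on molecular centres of mass (a molecular
property; using atoms would add libration noise) and averaged over
molecules and over multiple time origins (default origin stride: one
frame). For origin stride 1 the per-molecule MSD uses the standard
FFT autocorrelation identity (O(T log T)); strided origins use a
direct vectorized loop. Both are exactly equivalent to the literal
double loop over origins and lags, which the test-suite asserts on
small inputs.

The Fickian window is the longest contiguous lag interval whose local
log₁₀MSD-vs-log₁₀τ slope (centred moving window of ±3 points,
truncated at the ends) stays inside `[0.9, 1.1]`, subject to a
minimum extent of 0.5 decades; ties go to the earliest interval.
A pure ballistic curve (slope 2) therefore yields no window, and a
linear-to-plateau curve yields an upper bound just below the
crossover. The default maximum lag entering detection and fitting is
10% of the trajectory span — long lags average over few origins and
are statistically starved.

D is obtained by ordinary least squares of MSD against lag over the
window, *with* an intercept (absorbing any short-time ballistic or
cage offset), as slope/6 in three dimensions. The quoted uncertainty
is the standard error of D refitted on five disjoint molecule blocks;
when too few molecules are available for blocking, the OLS slope
standard error is used instead. Block standard errors from a handful
of blocks are themselves noisy (χ-distributed with few degrees of
freedom); the tests therefore compare them to independent-rerun
spreads only within a factor of three.

## Hydrogen bonds

A hydrogen bond is a (donor D, hydrogen H, acceptor A) triplet with
minimum-image H···A distance strictly below 2.8 Å, donor angle
∠(D–H···A) at the hydrogen of at least 120°, and acceptor angle
∠(H···A–X) of at least 90° against **every** heavy neighbour X of the
acceptor; an acceptor with no heavy neighbour (bare ion, water
oxygen) passes the acceptor test vacuously. Donors and acceptors are
N/O atoms flagged in the topology; a donor-flagged hydrogen must have
exactly one bonded heavy atom. Same-molecule pairs are excluded for
water and allowed for polymer when donor and acceptor are more than
three covalent bonds apart (crosslinked chains can fold back onto
themselves).

Candidate pairs come from a periodic k-d tree
(`scipy.spatial.cKDTree(boxsize=…)`) at the distance cutoff; every
criterion is then re-evaluated exactly on minimum-image vectors, so
the result is identical to a brute-force triple loop (asserted on 200
random scenes). Threshold comparisons are resolved at a fixed
numerical resolution of 10⁻⁹ Å and 10⁻⁷ degrees: coordinates placed
by construction exactly on a threshold acquire rounding of order
10⁻¹⁵ from scene placement and wrapping, and without a resolution the
boundary side would be arbitrary. Counts are classified water–water /
polymer–polymer / polymer–water from the species of the donor and
acceptor molecules (filler counts as polymer), and the per-frame
identity N_T = N_ww + N_pp + N_pw holds by construction; the
difference form N_pw = N_T − N_pp − N_ww is exposed separately and
errors on inconsistent (negative) input.

## Water clusters

Two waters are linked when their O–O minimum-image distance is at
most the cutoff; clusters are connected components found by
union–find over periodic k-d-tree neighbour pairs. The default
cutoff, 3.5 Å, is the first minimum of the bulk-water O–O pair
correlation function; both the cutoff and the linkage site (oxygen)
are configuration-exposed because dense-matrix studies do not agree
on a single convention. Clusters are ordered by descending size, ties
by smallest member molecule id, so output is bit-stable. Cluster
identity is per-frame only; no lineage is tracked across frames.

The mass-weighted radius of gyration of a cluster,
rg = √(Σ mᵢ|rᵢ − r_cm|²/Σ mᵢ) over all atoms of the member molecules,
is computed after unwrapping the cluster into one periodic image by a
breadth-first traversal of its linkage graph (each molecule's H atoms
ride on its oxygen by a minimum-image shift). A cluster spanning at
least half the box is periodically ambiguous and triggers a warning.
For the rigid three-site water used by the generator the
intramolecular mass-weighted rg is 0.313 Å — dominated by the oxygen
offset from the centre of mass, since hydrogens carry little mass.

## Density projections

Molecular centres of mass are binned on one or two box axes
(half-open bins), counts are averaged over frames and divided by the
bin length/area, giving a number density (or mass density in amu) per
Å or Å². Bin widths are adjusted so an integer number of bins exactly
tiles the box edge, which makes integer-factor refinement exactly
re-aggregable and the normalisation identity
Σ values × bin measure = mean selected count per frame exact in
number mode. The uniformity score is the coefficient of variation
(population sd / mean) of the bin values: 0 for a flat map, √(k−1)
when all weight sits in one of k bins. Default bin width: 1 Å.

## Equilibration drift

For scalar series (energies, density) the drift statistic is the
least-squares slope over the tail (default: latter half); the check
passes when the accumulated drift over the tail span is within 1% of
the tail mean. Near-zero-mean series fall back to an absolute
threshold that the caller must provide.

## Synthetic generator

The generator emulates, at desk scale, the statistical structure the
analyses consume — not the physics that produces it:

* **Brownian walkers**: per-axis Gaussian steps of variance 2·D·dt
  (exact variance bookkeeping beats realism for an oracle), default
  dt = 5 ps matching a typical trajectory recording interval. An
  ensemble MSD then has expectation 6·D·k·dt at lag k·dt. Step
  standard deviations above L/4 are rejected (unwrap ambiguity by
  construction). Walkers are rigid ideal waters (O–H 0.9572 Å,
  H–O–H 104.52°) translated without rotation; internal motion is
  irrelevant to every analysis here.
* **Ballistic / confined modes** give the closed-form τ² law and a
  plateaued MSD (specular radial reflection inside a sphere), used to
  exercise the Fickian-window logic from both sides.
* **Planted cluster scenes** grow each cluster as a connected chain
  (links at 0.7–0.95 × cutoff, pair floor 2.3 Å) and place cluster
  centres with minimum-image separations exceeding
  r₁ + r₂ + gap, so the planted partition is the unique single-linkage
  answer; a boundary-spanning variant recentres the largest cluster
  on a box corner before wrapping.
* **Planted H-bond scenes** realize each requested (distance, donor
  angle, acceptor angle) exactly in local coordinates; auxiliary atoms
  completing the fragments (second water hydrogen, hydroxyl carbon)
  are placed on the correct bonding cone at the azimuth farthest from
  the partner fragment, and triplets sit on a 50 Å grid, so the
  detected census equals the requested list. Only the planted
  hydrogen/acceptor are role-flagged for the same reason.

Identical spec + seed gives bit-identical output. What the generator
does **not** emulate: force-field interactions, excluded volume
between walkers, rotational diffusion, polymer matrix structure, or
hydrodynamic finite-size effects. Passing parameter-recovery tests
therefore demonstrates the correctness of the estimators on data
satisfying their model assumptions, not the fidelity of any MD
engine.

## Problem sizes in the verification suite

Diffusion recovery is checked at literature-scale coefficients
(1.79 × 10⁻¹² and 2.50 × 10⁻¹² m²/s with 500 walkers × 2000 frames;
4.37 × 10⁻⁹ m²/s with 3000 walkers × 1200 frames, the ensemble size
typical of a bulk-water reference system) with a 5% relative
tolerance — comfortably above the sampling error at these sizes.
Oracle-equivalence suites run at sizes where brute force is instant
(≤ 10 molecules × 50 frames for the MSD double loop, 200 scenes of
≤ 60 atoms for the H-bond triple loop, 200 molecules for all-pairs
clustering, 27-image checks for the minimum image).

## Pipeline determinism

`run_pipeline` writes per-stage CSV/JSON artifacts plus a manifest
with a SHA-256 checksum per output and a hash of the analysis
configuration (excluding the output location). Wall-clock timings are
logged and returned but kept out of the artifacts, so identical
config + inputs + seed produce byte-identical files. Stage failures
are recorded with context and do not stop independent stages.

## Known limitations

* Orthorhombic cells only; no velocities/forces; no binary trajectory
  formats (DCD/XTC).
* No Green–Kubo (velocity-autocorrelation) diffusion route, no
  per-axis anisotropic D, no finite-size hydrodynamic corrections.
* Geometric hydrogen bonds only — no energetic definitions and no
  lifetime/autocorrelation kinetics.
* Cluster statistics are per-frame; percolation and lineage analyses
  are out of scope.
* PDB carries no time metadata: a frame spacing `dt` must be supplied
  when reading.
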