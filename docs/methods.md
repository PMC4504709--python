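# Methods

`ifdimer` quantifies the structure of intermediate-filament (IF) keratin
dimers — specifically the epithelial K1/K10 heterodimer — from atomic
coordinates.  The dimer has a tri-domain architecture: a disordered
N-terminal head (subdomains E1-V1-H1), a central coiled-coil rod
(1A-L1-1B-L12-2A-L2-2B) and a disordered C-terminal tail (H2-V2-E2).  The
package computes per-residue coiled-coil geometry, head/tail globule
placement, residue contact statistics, and the configuration machinery
used to initialise folded head/tail models.  Every estimator is validated
against synthetic structures with known ground truth.

## Coiled-coil profile

For a two-stranded coiled-coil the chains K1 (type II) and K10 (type I)
wind as minor α-helices about a common superhelical axis.  Per residue
index *i* (relative to the subdomain N-terminus, chains aligned
in-register):

- **Chain axis path p_N(i).**  Estimated from the Cα positions of the four
  consecutive residues i−1 … i+2 by the second-difference bisector
  construction: the discrete second difference of three consecutive
  points on a helix points at the local axis with magnitude
  2·r·(1 − cos θ), where θ is the twist per residue; θ is read off the
  angle between consecutive second differences projected perpendicular to
  the local axis direction (the cross product of the two second
  differences).  Each residue's axis point averages the two four-residue
  windows that centre on it.  The construction is exact on an ideal helix
  (numerically ≤ 1e-14 Å) and, with 0.1 Å Gaussian coordinate noise,
  stays within ≈0.25 Å of the true axis.
- **Central axis** P(i) = (p_K1(i) + p_K10(i))/2 and **local radius**
  R(i) = (|p_K1(i) − P(i)| + |p_K10(i) − P(i)|)/2.
- **Local rotation Ψ(i).**  The mean of four signed dihedral estimates:
  for each chain and for each of the steps i−1→i and i→i+1, the angle
  swept by the chain-to-axis vector about the local central-axis
  direction.  The arithmetic mean is used (the weighting of the four
  estimates is a free choice; equal weights are the natural one).  The
  sign convention is fixed once: Ψ < 0 ⇔ left-handed supercoil; a
  coordinate reflection flips the sign exactly.
- **Local pitch** λ(i) = ½(|P(i+1) − P(i)| + |P(i) − P(i−1)|) ·
  360/|Ψ(i)°| — local rise per residue divided by the fractional turn per
  residue.  An alternative printed form of this relation multiplies by
  the fractional turn instead of dividing by it; that form yields sub-Å
  values inconsistent with the ~170 Å pitch of IF coiled-coils, so the
  physical (divide) form is implemented.  Where |Ψ| < Ψ_min the strands
  are effectively parallel and λ is reported *indeterminate* rather than
  as a huge number.  Default Ψ_min = 0.5°/residue (pitch ≈ 1100 Å),
  configurable.
- **Major axes and hinge angles.**  A subdomain's major axis runs from
  the central-axis point at its 2nd residue to the point at its
  3rd-to-last residue (exactly the first and last defined axis points of
  the window).  The hinge angle across a linker is, by default, the
  interior angle cos⁻¹(u·v) between the N→C major axes of the flanking
  subdomains, in [0°, 180°]; a "paper" convention returning 360° − that
  value is available by flag.  The two conventions are exposed rather
  than silently reconciled because reported hinge values (e.g. ~107°
  across L1) match the interior magnitude while the printed formula maps
  into [180°, 360°].

Parameter recovery is verified as a closed loop against the Crick
generator: for r0 ∈ [3, 8] Å, pitch ∈ [100, 300] Å and both handednesses,
the profile recovers the radius within 2%, the pitch within 5%, and the
handedness exactly on every interior residue.

## Head/tail globule placement

Globule placement relative to the rod is described by two coordinates:

- **Axial displacement d**: projection of the vector V (rod anchor →
  globule Cα centroid) onto the outward unit anchor axis M.  For the
  head, the anchor is the 1A central-axis point at its 2nd residue and M
  points away from the rod (beyond the 1A N-terminus); for the tail the
  anchor is the 2B axis point at its 3rd-to-last residue and M points
  beyond the C-terminus.  d > 0 therefore always means "projected out
  past the rod end".
- **Radial orientation θr**: the angle, in the plane perpendicular to M,
  between the projection of V and the reference O that points from the
  inter-chain midpoint toward the K1 chain.  θr = 0° is the K1 side,
  ±90° between the chains, 180° the K10 side.  θr is reported signed via
  the right-hand rule about M (the underlying arccos definition is
  unsigned; the unsigned value is |θr|).  When the centroid lies on the
  axis θr is undefined and flagged.

Positions are classified into Category I (d > +band, projected out along
the dimer axis), Category II (|d| ≤ band, at right angles to the rod
end) and Category III (d < −band, folded down onto the rod).  The band is
a free classification parameter, default ±10 Å; no quantitative threshold
is established in the literature, only the three qualitative categories.

Shape metrics: radius of gyration over backbone atoms (N, Cα, C, O when
present, Cα otherwise), end-to-end distance from the chain terminus Cα to
the rod anchor, and principal extents (max-minus-min spread along each
principal axis of the centered point cloud, descending).

## Contact statistics

- **Cα contact maps**: a residue pair is in contact when its Cα–Cα
  distance is *strictly* below the cutoff (default 12 Å; the boundary
  case is excluded, an explicit reading of "less than").  Intra-chain
  pairs with |i − j| ≤ 2 are excluded as trivially close.  Pairs are
  classed K1-K1, K10-K10 or K1-K10.  The production implementation is
  k-d-tree indexed and tested for exact equality with a naive all-pairs
  oracle.
- **Probability aggregation**: default per-model weighting — each model
  contributes its within-model contact fraction and models are averaged
  with equal weight, so models with different frame counts contribute
  equally.  Per-frame pooling is available as the alternative weighting;
  both are exposed because ensemble analyses can defensibly pool either
  way.  Either way, a pair's denominator includes only models whose
  structure contains both residues: truncated models (head-1A-L1-1B only)
  never dilute tail-region probabilities.
- **Typed side-chain contacts**: each residue-type pair maps to at most
  one interaction class with precedence acid-base > hydrogen-bond >
  aromatic > hydrophobic, and the contact is tested against that class's
  cutoff only, so a pair can never be double-counted.  Default reference
  atoms and cutoffs (all configurable via a TSV): acid-base 4.0 Å between
  acid carboxylate O and base side-chain N; hydrogen bond 3.5 Å between
  polar side-chain heavy atoms, with every candidate site tested for the
  double-site residues Ser/Thr/Gln/Asn; aromatic 7.0 Å between ring
  centroids; hydrophobic 5.4 Å between the closest side-chain carbons.
  These defaults are this package's own declared substitutes for a
  published supplementary table that is not machine-readable; they are
  not reconstructions of it.
- **Ideal knobs-into-holes count**: with a heptad register (letters a–g,
  cycling within segments; segment breaks model stutters), each a-knob of
  one chain packs against the partner chain's d-position of the same
  heptad (relative offset +3) and each d-knob against the partner's
  a-position (offset −3).  Every knob contributes one interaction, so one
  aligned heptad yields 4.  The pairing rule is frozen here so the count
  is reproducible; other defensible rules exist.
- **Hydrogen bonds**: heavy-atom criteria — N/O pairs from different
  residues within 3.5 Å, a C–O···X acceptor angle ≥ 120° whenever the
  acceptor's bonded carbon is known (this rejects the short but
  badly-aligned i→i+3 backbone pairs of an α-helix while keeping all
  i→i+4 bonds), and |i − j| ≥ 3 for intra-chain backbone-backbone pairs.
  With explicit hydrogens absent (the usual case here) the
  distance+acceptor-angle rule is the whole criterion.

## Model-building machinery

Backbones are constructed from per-residue (φ, ψ, ω) specifications by
natural-extension (NeRF) placement with canonical geometry (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°;
carbonyl O anti to the next amide N).  Re-measuring dihedrals from the
built coordinates reproduces the specification to ≤ 1e-4° (tested on
random legal specs).  The nine-residue hairpin turn uses φ = −162.5°,
ψ = 162.5°, ω = 180°.

The 25 initial configurations are the product of five fold orientations
(A: both chains to the K1 face; B: both to the K10 face; C: crossed;
D: own face; E: extended) and five turn shifts n ∈ {−5, 0, 3, 5, 10}
relative to the base windows K1:103–111 / K10:86–94 (head) and
K1:534–542 / K10:498–506 (tail).  "Shifted toward the rod" means
increasing residue numbers for the head (the rod is C-terminal to it) and
decreasing for the tail.  The split into 10 full-dimer and 15 truncated
models is shipped as an editable allocation table (n ∈ {0, 5} → full);
the published per-cell assignment is given only graphically, so any
10/15 split over the 25 distinct cells is valid input.  Full models fold
head and tail in the same direction.  Truncated chains end at K1:328 /
K10:296 with a harmonic Cα–Cα restraint (equilibrium 14.37 Å, force
constant 1000 in the source's printed unit "kcal (Å mol)⁻¹", recorded
verbatim and flagged, since the conventional unit for a harmonic spring
is kcal mol⁻¹ Å⁻²).  Disulfides are never created.  Running any
molecular dynamics is out of scope: the package consumes coordinates, it
does not produce trajectories.

## Synthetic generators (what they emulate, what they do not)

- **Crick coiled-coils**: Cα traces of two minor α-helices (radius
  2.26 Å, arc rise 1.51 Å/residue, 3.6 residues/turn — the canonical
  values, which reproduce the 3.8 Å Cα spacing) wound about a superhelix
  of prescribed radius, pitch and handedness, chain 2 phase-offset 180°.
- **Ideal α-helices**, for the axis estimator.
- **Globules**: self-avoiding random walks (3.8 Å step, 4.0 Å exclusion,
  a centroid bias keeping the walk compact) rescaled about the centroid
  so the realized radius of gyration equals the target exactly; targets
  that would force residue pairs below 2 Å are rejected as unattainable.
- **Jittered ensembles**: i.i.d. Gaussian coordinate noise per frame,
  giving analytically predictable contact frequencies.
- **Assembled dimers**: globules rigidly placed at requested (d, θr)
  with a configurable radial offset (15 Å default; θr is undefined on the
  axis, so a nonzero offset is required to realise a prescribed θr).

All generators are pure functions of their parameters and one explicit
seed.  They emulate geometry only: no side-chain packing, no energetics,
no sequence realism beyond what a test requests.  Passing tests therefore
demonstrate that the *estimators* are correct and self-consistent, not
that any particular biological structure is correct; conclusions about
real keratin require real coordinates as input.

## Numerical choices and degenerate inputs

- Axis points need residues i−1 … i+2; the first and last one-two
  residues of a range have no axis point and are reported missing, never
  extrapolated.
- Degenerate geometry (straight chains, zero-length chain-to-axis
  vectors) yields an indeterminate marker, not an exception; division
  guards use 1e-10 thresholds.
- Mean profile statistics exclude the two outermost defined residues at
  each end ("interior residues") to avoid residual end effects.
- PDB coordinates are written at the format's fixed 0.001 Å precision;
  round-trips are verified to that tolerance.  Coordinates outside the
  fixed-width field raise an error.
- Alternate locations: altloc 'A' or blank kept, others dropped.
- The whitespace-delimited coordinate dialect (serial, atom, residue,
  chain, residue number, x, y, z) is attempted when strict fixed-column
  parsing fails, since plain-text depositions of final structures use it.

## Shipped defaults that users may need to edit

- `data/subdomains_k1k10.tsv`: K1/K10 subdomain boundaries.  A best
  reconstruction from published residue landmarks (1A start K1:181, 1B
  C-termini K1:328/K10:296, V1 K1:61–153/K10:31–137, H2 K1:487–497/
  K10:453–460, V2 K1:497–607/K10:461–558, chain lengths 644/584) combined
  with canonical IF rod subdomain lengths; the published figure defining
  them is graphical only.  Every analysis accepts a user table.
- `data/model_allocation.tsv`: the full/truncated split of the 25 models.

## Problem sizes

The validation suite and the acceptance script run on desk-scale
problems chosen to exercise every code path precisely: 100-residue
coiled-coils (interior statistics over ~90 residues), 20–60-residue
helices and globules, ensembles of 3–400 jittered frames where a binomial
error bound is wanted.  These sizes make every check closed-form or
generator-exact; they are not simulations of the 600-residue dimer, whose
analysis runs through the identical code paths via the CLI.

## Known limitations

- Head/tail boundary residues for K1/K10 are reconstructions (see above).
- The typed-contact cutoff table is a declared default, not a published
  reconstruction; censuses on real structures should state the table
  used.
- The knobs-into-holes ideal count depends on the frozen pairing rule.
- The hinge-angle and θr sign conventions are package conventions chosen
  to match reported magnitudes; both underlying unsigned quantities are
  recoverable.
- mmCIF input, hydrogen placement and missing-side-chain reconstruction
  are not supported.
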