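"""Synthetic structures with known ground-truth geometry.

Every analysis stage in this package is validated against structures whose
true parameters are known by construction:

* two-stranded Crick coiled-coils with prescribed superhelical radius,
  pitch and handedness (oracle for the coiled-coil profile);
* isolated ideal α-helices (oracle for the helix-axis estimator);
* compact self-avoiding-walk globules with prescribed radius of gyration
  (stand-ins for the disordered head/tail globules);
* Gaussian-jittered frame ensembles with predictable per-pair contact
  frequencies (fixtures for contact-probability aggregation);
* assembled rod+globule dimers whose head placement (axial displacement d,
  radial orientation θr) is requested exactly (round-trip fixture for the
  globule-positioning analysis).

All generators are pure functions of their parameters and an explicit seed;
there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import ChainStructure, DimerStructure, Ensemble, Residue

__all__ = [
    "CrickParams",
    "NoiseSpec",
    "generate_crick_coil",
    "generate_alpha_helix",
    "generate_globular_chain",
    "perturb_ensemble",
    "assemble_synthetic_dimer",
]

# canonical α-helix geometry: these reproduce the 3.8 Å Cα-Cα spacing
ALPHA_HELIX_RADIUS = 2.26        # Å, Cα distance from the helix axis
ALPHA_RISE_PER_RESIDUE = 1.51    # Å along the helix axis per residue
ALPHA_RESIDUES_PER_TURN = 3.6    # 100° twist per residue


@dataclass(frozen=True)
class CrickParams:
    """Parameters of an ideal two-stranded coiled-coil.

    The superhelical (major) helix has radius ``r0`` and pitch
    ``superhelical_pitch`` (axial distance per full superhelical turn, Å);
    ``handedness`` sets its chirality.  Each chain is a minor α-helix of
    radius ``r1`` wound about the superhelical path with an arc step of
    ``rise_per_residue`` per residue.  The second chain is phase-offset by
    180° about the superhelical axis unless ``chain_phase_offsets`` says
    otherwise.
    """

    r0: float
    superhelical_pitch: float
    handedness: str = "left"
    r1: float = ALPHA_HELIX_RADIUS
    rise_per_residue: float = ALPHA_RISE_PER_RESIDUE
    residues_per_helix_turn: float = ALPHA_RESIDUES_PER_TURN
    n_residues: int = 100
    chain_phase_offsets: tuple = (0.0, 180.0)  # degrees
    chain_labels: tuple = ("K1", "K10")

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("superhelical radius r0 must be positive")
        if self.superhelical_pitch <= 0:
            raise ValueError("superhelical pitch must be positive")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues per chain")


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _chain_from_ca(label: str, coords: np.ndarray, resname: str = "ALA",
                   start_number: int = 1) -> ChainStructure:
    residues = [
        Residue(resname, start_number + i, {"CA": np.asarray(c, float)})
        for i, c in enumerate(coords)
    ]
    return ChainStructure(label, residues)


def generate_crick_coil(params: CrickParams) -> DimerStructure:
    """Build Cα coordinates of an ideal two-stranded coiled-coil.

    The superhelical axis is +z.  For each residue the superhelical path
    point advances by ``rise_per_residue`` of arc length; the Cα sits at
    distance ``r1`` from that point in the plane spanned by the local
    radial direction and the local binormal, rotating by 360°/residues_per_
    helix_turn per residue.  A left-handed superhelix has its phase angle
    decreasing with increasing z.
    """
    p = params
    chirality = -1.0 if p.handedness == "left" else 1.0
    # arc length of one superhelical turn and per-residue increments
    turn_len = math.hypot(p.superhelical_pitch, 2.0 * math.pi * p.r0)
    dphi = chirality * 2.0 * math.pi * p.rise_per_residue / turn_len
    dz = p.superhelical_pitch * p.rise_per_residue / turn_len
    omega1 = 2.0 * math.pi / p.residues_per_helix_turn  # minor-helix twist

    chains = []
    for label, phase_deg in zip(p.chain_labels, p.chain_phase_offsets):
        phase = math.radians(phase_deg)
        coords = np.empty((p.n_residues, 3))
        for i in range(p.n_residues):
            phi = phase + i * dphi
            z = i * dz
            center = np.array([p.r0 * math.cos(phi), p.r0 * math.sin(phi), z])
            # local frame of the superhelical curve
            u_rad = np.array([math.cos(phi), math.sin(phi), 0.0])      # outward radial
            u_tan = np.array([-p.r0 * math.sin(phi) * dphi,
                              p.r0 * math.cos(phi) * dphi, dz])        # dC/di
            u_tan /= np.linalg.norm(u_tan)
            u_bin = np.cross(u_tan, u_rad)
            theta = i * omega1
            coords[i] = center + p.r1 * (math.cos(theta) * u_rad + math.sin(theta) * u_bin)
        chains.append(_chain_from_ca(label, coords))
    return DimerStructure(chains, source="crick")


def generate_alpha_helix(n_residues: int, axis=(0.0, 0.0, 1.0),
                         origin=(0.0, 0.0, 0.0), label: str = "H",
                         handedness: str = "right") -> ChainStructure:
    """Ideal isolated α-helix: radius 2.26 Å, rise 1.51 Å, 100°/residue."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    axis = np.asarray(axis, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis vector must be nonzero")
    axis = axis / norm
    # orthonormal frame perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    sign = 1.0 if handedness == "right" else -1.0
    omega = sign * 2.0 * math.pi / ALPHA_RESIDUES_PER_TURN
    origin = np.asarray(origin, float)
    coords = np.array([
        origin
        + ALPHA_RISE_PER_RESIDUE * i * axis
        + ALPHA_HELIX_RADIUS * (math.cos(i * omega) * e1 + math.sin(i * omega) * e2)
        for i in range(n_residues)
    ])
    return _chain_from_ca(label, coords)


def generate_globular_chain(n_residues: int, target_rg: float, seed: int,
                            label: str = "G", step: float = 3.8,
                            exclusion: float = 4.0,
                            min_pair_distance: float = 2.0) -> ChainStructure:
    """Compact self-avoiding random walk rescaled to a target Rg.

    The walk takes 3.8 Å steps with a 4.0 Å excluded-volume radius and a
    centering bias that keeps the chain compact; coordinates are then
    rescaled about the centroid so the realized radius of gyration equals
    ``target_rg`` exactly.  If rescaling would push any pair of residues
    below ``min_pair_distance`` the target is physically unattainable and a
    ValueError is raised.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if target_rg <= 0:
        raise ValueError("target_rg must be positive")
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    max_tries = 200
    for _ in range(n_residues - 1):
        placed = False
        for _try in range(max_tries):
            direction = rng.normal(size=3)
            # bias toward the centroid keeps the walk globular
            centroid = np.mean(coords, axis=0)
            direction = direction + 0.3 * (centroid - coords[-1]) / step
            direction /= np.linalg.norm(direction)
            cand = coords[-1] + step * direction
            if len(coords) < 2:
                ok = True
            else:
                d = np.linalg.norm(np.asarray(coords[:-1]) - cand, axis=1)
                ok = bool(np.all(d >= exclusion))
            if ok:
                coords.append(cand)
                placed = True
                break
        if not placed:  # restart-free fallback: accept closest legal try
            coords.append(cand)
    coords = np.asarray(coords)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    rg = math.sqrt(np.mean(np.sum(centered**2, axis=1)))
    scale = target_rg / rg
    scaled = centered * scale
    if n_residues > 2:
        from scipy.spatial.distance import pdist
        if float(pdist(scaled).min()) < min_pair_distance:
            raise ValueError(
                f"target_rg={target_rg} Å is unattainably small for "
                f"{n_residues} residues (residues would overlap)"
            )
    return _chain_from_ca(label, scaled, resname="GLY")


def perturb_ensemble(structure: DimerStructure, n_frames: int,
                     noise: NoiseSpec) -> Ensemble:
    """Independent Gaussian-jittered copies of a structure.

    Each atom coordinate receives i.i.d. N(0, sigma²) noise per frame;
    reproducible through the NoiseSpec seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(noise.seed)
    frames = []
    for k in range(n_frames):
        chains = []
        for c in structure.chains:
            residues = [
                Residue(r.name, r.number,
                        {a: p + rng.normal(scale=noise.sigma, size=3) if noise.sigma > 0
                         else p.copy()
                         for a, p in r.atoms.items()})
                for r in c.residues
            ]
            chains.append(ChainStructure(c.label, residues))
        frames.append(DimerStructure(chains, frame_id=k, source="jitter"))
    return Ensemble(frames, source="jitter")


def assemble_synthetic_dimer(rod: DimerStructure, annotation,
                             head_globules: dict | None = None,
                             tail_globules: dict | None = None,
                             placements: dict | None = None,
                             radial_offset: float = 15.0,
                             clash_distance: float = 2.0):
    """Attach globules to a coiled-coil rod at requested (d, θr) placements.

    ``head_globules``/``tail_globules`` map chain labels to ChainStructure
    globules; ``placements`` maps (chain_label, "head"|"tail") to a
    (d, theta_r) pair in Å/degrees.  The globule is rigidly translated so
    that its Cα centroid lands at

        anchor + d·M + ρ·(cosθr·O + sinθr·(M×O))

    where M is the outward-pointing anchor axis, O the K1-pointing radial
    reference and ρ = ``radial_offset`` (θr is undefined on the axis, so a
    nonzero default radial offset is used whenever θr is prescribed).
    Head residues are renumbered to sit before the rod residues of their
    chain (renumbering the rod upward when needed), tail residues after.
    Steric clashes below ``clash_distance`` trigger a warning, not an error.

    Returns ``(dimer, annotation_out)`` where ``annotation_out`` carries the
    caller's rod intervals (shifted if the rod was renumbered) plus V1/V2
    entries covering the attached globules.
    """
    import warnings

    from .domain_geometry import rod_anchor_frame
    from .structure_io import SubdomainAnnotation

    head_globules = head_globules or {}
    tail_globules = tail_globules or {}
    placements = placements or {}

    new_chains = {c.label: list(c.residues) for c in rod.chains}
    rod_offsets = {c.label: 0 for c in rod.chains}
    globule_ranges = {}  # (label, "V1"|"V2") -> (start, end)
    rod_ca = rod.all_ca()

    for domain, globs, anchor_end in (
        ("head", head_globules, "N-term-1A"),
        ("tail", tail_globules, "C-term-2B"),
    ):
        if not globs:
            continue
        frame = rod_anchor_frame(rod, annotation, anchor_end)
        for label, globule in globs.items():
            d, theta_r = placements.get((label, domain), (10.0, 0.0))
            theta = math.radians(theta_r)
            side = np.cross(frame.m_vec, frame.o_vec)
            target = (frame.anchor + d * frame.m_vec
                      + radial_offset * (math.cos(theta) * frame.o_vec
                                         + math.sin(theta) * side))
            ca = globule.ca_coords
            shift = target - ca.mean(axis=0)
            moved = ca + shift
            dmin = np.min(np.linalg.norm(
                rod_ca[:, None, :] - moved[None, :, :], axis=-1))
            if dmin < clash_distance:
                warnings.warn(
                    f"{label} {domain} globule clashes with the rod "
                    f"(min distance {dmin:.2f} Å)", stacklevel=2)
            rod_res = new_chains[label]
            if domain == "head":
                n = len(moved)
                start = rod_res[0].number - n
                if start < 1:  # renumber rod upward to make room
                    offset = 1 - start
                    rod_res = [Residue(r.name, r.number + offset, r.atoms)
                               for r in rod_res]
                    rod_offsets[label] += offset
                    start = 1
                head_res = [
                    Residue(g.name, start + i, {"CA": moved[i]})
                    for i, g in enumerate(globule.residues)
                ]
                new_chains[label] = head_res + rod_res
                globule_ranges[(label, "V1")] = (start, start + n - 1)
            else:
                last = rod_res[-1].number
                tail_res = [
                    Residue(g.name, last + 1 + i, {"CA": moved[i]})
                    for i, g in enumerate(globule.residues)
                ]
                new_chains[label] = rod_res + tail_res
                globule_ranges[(label, "V2")] = (last + 1, last + len(moved))

    chains = [ChainStructure(lab, res) for lab, res in new_chains.items()]
    dimer = DimerStructure(chains, source="assembled")
    entries = [
        (c, name, s + rod_offsets.get(c, 0), e + rod_offsets.get(c, 0))
        for c, name, s, e in annotation.entries
    ]
    entries += [
        (label, name, s, e) for (label, name), (s, e) in globule_ranges.items()
    ]
    return dimer, SubdomainAnnotation(entries)
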