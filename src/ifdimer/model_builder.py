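"""Initial-configuration machinery for head/tail folding models.

The dimer's disordered head and tail domains are initialised as extended
β-like strands folded back onto the rod through a nine-residue hairpin
turn built from fixed dihedrals (φ = −162.5°, ψ = 162.5°, ω = 180°).  Two
degrees of freedom span the configuration space: the fold direction
relative to the rod (orientations A–E) and the position of the turn along
the chain (n-shift ∈ {−5, 0, 3, 5, 10} residues toward the rod).  The 25
distinct (orientation, n-shift) combinations split into 10 full-dimer and
15 truncated (head-1A-L1-1B) models; truncated chains end at K1:328 /
K10:296 with a harmonic Cα-Cα restraint holding the cut 1B end together.

Backbone coordinates are built from dihedral specifications by natural
extension (NeRF) with canonical bond geometry, and re-measured dihedrals
round-trip to the specification within 1e-4 degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pathlib import Path

from .structure_io import AA1_TO_3, ChainStructure, Residue

__all__ = [
    "DihedralSpec",
    "ModelConfig",
    "RestraintSpec",
    "BACKBONE_GEOMETRY",
    "HAIRPIN_PHI", "HAIRPIN_PSI", "HAIRPIN_OMEGA", "HAIRPIN_LENGTH",
    "HEAD_TURN_BASE", "TAIL_TURN_BASE",
    "ORIENTATIONS", "N_SHIFTS",
    "chain_from_dihedrals",
    "measure_dihedrals",
    "make_hairpin_config",
    "enumerate_models",
    "truncation_spec",
]

# hairpin-turn dihedrals and length
HAIRPIN_PHI = -162.5
HAIRPIN_PSI = 162.5
HAIRPIN_OMEGA = 180.0
HAIRPIN_LENGTH = 9

# base hairpin-turn windows (1-based inclusive residue ranges)
HEAD_TURN_BASE = {"K1": (103, 111), "K10": (86, 94)}
TAIL_TURN_BASE = {"K1": (534, 542), "K10": (498, 506)}

# head/tail domain extents the shifted windows must stay inside
HEAD_DOMAIN = {"K1": (1, 180), "K10": (1, 148)}
TAIL_DOMAIN = {"K1": (487, 644), "K10": (453, 584)}

ORIENTATIONS = ("A", "B", "C", "D", "E")
N_SHIFTS = (-5, 0, 3, 5, 10)

ORIENTATION_MEANING = {
    "A": "both chains folded towards the K1 face of the rod",
    "B": "both chains folded towards the K10 face of the rod",
    "C": "each chain folded onto the opposite chain face",
    "D": "each chain folded onto its own chain face",
    "E": "fully extended away from the rod (not folded)",
}

# canonical backbone geometry (Å, degrees)
BACKBONE_GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "bond_C_O": 1.231,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.8,
}


@dataclass
class DihedralSpec:
    """Per-residue backbone dihedrals in degrees, in (−180, 180].

    ``phi[0]`` and the last ``psi``/first ``omega`` entries are
    geometrically undefined at the termini and are ignored by the builder;
    ``omega[i]`` is the peptide dihedral between residues i−1 and i.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, float)
        self.psi = np.asarray(self.psi, float)
        self.omega = np.asarray(self.omega, float)
        n = len(self.phi)
        if not (len(self.psi) == len(self.omega) == n):
            raise ValueError("phi, psi, omega must have equal length")
        for name, arr in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            if np.any((arr <= -180.0) | (arr > 180.0)):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    def __len__(self):
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0):
        return cls(np.full(n, phi), np.full(n, psi), np.full(n, omega))


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF: position of atom D with given internal coordinates to A-B-C."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four points, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    return math.degrees(math.atan2(float(np.cross(v, w) @ b1n), float(v @ w)))


def chain_from_dihedrals(sequence, spec: DihedralSpec, label: str = "X",
                         clash_distance: float = 1.8) -> ChainStructure:
    """Build a full-backbone chain (N, Cα, C, O) from a dihedral spec.

    ``sequence`` is a one-letter string or a list of 3-letter residue
    names.  Re-measuring dihedrals from the coordinates reproduces the
    spec within 1e-4°.  Steric self-intersections (non-bonded backbone
    atoms closer than ``clash_distance``) raise a warning listing the
    clashing residue pairs, not an error.
    """
    if isinstance(sequence, str):
        names = [AA1_TO_3.get(c.upper(), "UNK") for c in sequence]
    else:
        names = [str(s).upper() for s in sequence]
    n = len(names)
    if len(spec) != n:
        raise ValueError(f"spec length {len(spec)} != sequence length {n}")
    g = BACKBONE_GEOMETRY
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    # first residue in a canonical local frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["bond_N_CA"], 0.0, 0.0)
    ang = math.radians(g["angle_N_CA_C"])
    C[0] = CA[0] + g["bond_CA_C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], g["bond_C_N"],
                               g["angle_CA_C_N"], spec.psi[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], g["bond_N_CA"],
                                g["angle_C_N_CA"], spec.omega[i + 1])
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], g["bond_CA_C"],
                               g["angle_N_CA_C"], spec.phi[i + 1])
        # carbonyl O anti to the next amide N
        O[i] = _place_atom(N[i], CA[i], C[i], g["bond_C_O"],
                           g["angle_CA_C_O"], spec.psi[i] - 180.0)
    O[n - 1] = _place_atom(N[n - 1], CA[n - 1], C[n - 1], g["bond_C_O"],
                           g["angle_CA_C_O"], 0.0)
    residues = [
        Residue(names[i], i + 1,
                {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]})
        for i in range(n)
    ]
    chain = ChainStructure(label, residues)
    clashes = _self_clashes(chain, clash_distance)
    if clashes:
        warnings.warn(
            f"built chain has {len(clashes)} backbone clashes < "
            f"{clash_distance} Å: {clashes[:5]}...", stacklevel=2)
    return chain


def _self_clashes(chain: ChainStructure, cutoff: float):
    from scipy.spatial import cKDTree
    atoms = []
    for res in chain.residues:
        for a, p in res.atoms.items():
            atoms.append((res.number, a, p))
    tree = cKDTree([a[2] for a in atoms])
    out = []
    for i, j in tree.query_pairs(r=cutoff):
        ri, rj = atoms[i][0], atoms[j][0]
        if abs(ri - rj) <= 1:  # bonded/adjacent geometry is not a clash
            continue
        out.append((ri, rj))
    return sorted(set(out))


def measure_dihedrals(chain: ChainStructure) -> DihedralSpec:
    """Backbone φ/ψ/ω re-measured from coordinates; undefined terminal
    entries are NaN-free placeholders copied from the nearest defined
    residue so the result stays a valid DihedralSpec."""
    res = chain.residues
    n = len(res)
    phi = np.zeros(n)
    psi = np.zeros(n)
    omega = np.full(n, 180.0)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral_angle(res[i - 1].atoms["C"], res[i].atoms["N"],
                                    res[i].atoms["CA"], res[i].atoms["C"])
            omega[i] = dihedral_angle(res[i - 1].atoms["CA"], res[i - 1].atoms["C"],
                                      res[i].atoms["N"], res[i].atoms["CA"])
        if i < n - 1:
            psi[i] = dihedral_angle(res[i].atoms["N"], res[i].atoms["CA"],
                                    res[i].atoms["C"], res[i + 1].atoms["N"])
    phi[0] = phi[1] if n > 1 else 0.0
    psi[-1] = psi[-2] if n > 1 else 0.0
    def _wrap(a):
        a = np.where(a <= -180.0, a + 360.0, a)
        return np.where(a > 180.0, a - 360.0, a)
    return DihedralSpec(_wrap(phi), _wrap(psi), _wrap(omega))


# ---------------------------------------------------------------------------
# model configurations

@dataclass(frozen=True)
class ModelConfig:
    """One of the 25 initial head/tail folding configurations."""

    orientation: str
    n_shift: int
    scope: str                       # "full" | "truncated"
    head_turn_window: dict           # chain -> (start, end), 9 residues
    tail_turn_window: dict | None    # None for truncated models

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.n_shift not in N_SHIFTS:
            raise ValueError(f"n_shift must be one of {N_SHIFTS}")
        if self.scope not in ("full", "truncated"):
            raise ValueError("scope must be 'full' or 'truncated'")
        for windows, domain in ((self.head_turn_window, HEAD_DOMAIN),
                                (self.tail_turn_window, TAIL_DOMAIN)):
            if windows is None:
                continue
            for chain, (s, e) in windows.items():
                if e - s + 1 != HAIRPIN_LENGTH:
                    raise ValueError(
                        f"{chain} turn window {s}-{e} is not "
                        f"{HAIRPIN_LENGTH} residues long")
                lo, hi = domain[chain]
                if s < lo or e > hi:
                    raise ValueError(
                        f"{chain} turn window {s}-{e} leaves the domain "
                        f"{lo}-{hi}")


def _shift_windows(base: dict, n_shift: int, toward_rod_sign: int) -> dict:
    return {
        chain: (s + toward_rod_sign * n_shift, e + toward_rod_sign * n_shift)
        for chain, (s, e) in base.items()
    }


def make_hairpin_config(domain: str, orientation: str, n_shift: int,
                        scope: str = "truncated") -> ModelConfig:
    """Turn windows for one domain, shifted ``n_shift`` residues toward
    the rod.

    The rod lies C-terminal to the head, so the head windows shift to
    higher residue numbers; the tail windows shift to lower numbers.
    """
    if domain == "head":
        head = _shift_windows(HEAD_TURN_BASE, n_shift, +1)
        tail = _shift_windows(TAIL_TURN_BASE, n_shift, -1) if scope == "full" else None
    elif domain == "tail":
        head = _shift_windows(HEAD_TURN_BASE, n_shift, +1)
        tail = _shift_windows(TAIL_TURN_BASE, n_shift, -1)
        scope = "full"
    else:
        raise ValueError("domain must be 'head' or 'tail'")
    return ModelConfig(orientation, n_shift, scope, head, tail)


def _allocation_table() -> pd.DataFrame:
    path = Path(__file__).parent / "data" / "model_allocation.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    return df


def enumerate_models() -> list:
    """The 25 model configurations: each (orientation, n-shift) cell once,
    10 full + 15 truncated per the shipped allocation table.

    Full models fold head and tail in the same direction (one orientation
    for both); deterministic, order-stable (table row order).
    """
    df = _allocation_table()
    configs = []
    for row in df.itertuples():
        scope = str(row.scope)
        domain = "tail" if scope == "full" else "head"
        cfg = make_hairpin_config(domain if scope == "full" else "head",
                                  str(row.orientation), int(row.n_shift),
                                  scope=scope)
        configs.append(cfg)
    seen = {(c.orientation, c.n_shift) for c in configs}
    if len(seen) != len(configs):
        raise ValueError("allocation table repeats an (orientation, n_shift) cell")
    return configs


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic Cα-Cα restraint holding the truncated 1B C-terminus.

    The force-constant unit is recorded as printed in the source protocol,
    "kcal (Å mol)⁻¹"; note a harmonic spring constant is conventionally
    kcal mol⁻¹ Å⁻², so the printed unit is flagged when emitted.
    """

    chain_a: str = "K1"
    residue_a: int = 328
    chain_b: str = "K10"
    residue_b: int = 296
    atom: str = "CA"
    force_constant: float = 1000.0
    force_constant_unit: str = "kcal (A mol)^-1 (as printed; see note)"
    equilibrium_distance: float = 14.37

    def __post_init__(self):
        if self.equilibrium_distance <= 0:
            raise ValueError("equilibrium distance must be positive")

    @property
    def cleavage_residues(self) -> dict:
        return {self.chain_a: self.residue_a, self.chain_b: self.residue_b}

    def to_text(self) -> str:
        return "\n".join([
            "# harmonic restraint for the truncated-dimer 1B C-terminus",
            f"atom_a: {self.chain_a}:{self.residue_a}:{self.atom}",
            f"atom_b: {self.chain_b}:{self.residue_b}:{self.atom}",
            f"force_constant: {self.force_constant}",
            f"force_constant_unit: {self.force_constant_unit}",
            "# unit recorded verbatim; the conventional harmonic unit would be",
            "# kcal mol^-1 A^-2",
            f"equilibrium_distance_angstrom: {self.equilibrium_distance}",
        ]) + "\n"


def truncation_spec() -> RestraintSpec:
    """The fixed truncation restraint (cleavage at K1:328 / K10:296)."""
    return RestraintSpec()
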