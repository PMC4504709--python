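"""Per-residue coiled-coil geometry of the IF rod domain.

For a two-stranded coiled-coil the analysis proceeds residue by residue:

1. the path p_N(i) of each chain's α-helix axis is estimated from the Cα
   positions of the four consecutive residues i−1 … i+2 (second-difference
   bisector construction, exact on an ideal helix);
2. the coiled-coil central axis is the chain-wise midpoint
   P(i) = (p_K1(i) + p_K10(i)) / 2;
3. the local superhelical radius is
   R(i) = (|p_K1(i) − P(i)| + |p_K10(i) − P(i)|) / 2;
4. the local rotation Ψ(i) is the mean of four signed dihedral estimates
   (chain-to-axis vectors at consecutive residues, about the local central
   axis direction; two estimates per chain) — its sign encodes handedness:
   Ψ < 0 for a left-handed supercoil;
5. the local pitch is the local rise per residue divided by the fractional
   turn per residue, λ(i) = ½(|P(i+1)−P(i)| + |P(i)−P(i−1)|) · 360/|Ψ(i)°|,
   reported as indeterminate where |Ψ| falls below a threshold (parallel
   strands).

Subdomain major axes (axis point at the 2nd residue to the 3rd-to-last
residue) and inter-subdomain hinge angles are derived from the same
central-axis path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import ChainStructure, DimerStructure, SubdomainAnnotation

__all__ = [
    "AxisPath",
    "CoiledCoilProfile",
    "MajorAxis",
    "compute_helix_axis",
    "compute_central_axis",
    "compute_local_radius",
    "compute_rotation_angle",
    "compute_local_pitch",
    "compute_profile",
    "subdomain_profile",
    "compute_major_axis",
    "compute_hinge_angle",
]

#: |Ψ| below this (degrees per residue) counts as parallel strands; the
#: corresponding pitch would exceed ~1100 Å and is reported indeterminate.
PSI_MIN_DEG = 0.5


@dataclass
class AxisPath:
    """α-helix axis points keyed by relative residue index.

    Index 0 is the first residue of the analysed range; axis points exist
    for indices 1 … n−3 (the estimator needs residues i−1 … i+2).
    ``residue_numbers`` maps each relative index back to the chain's own
    residue numbering.
    """

    chain_label: str
    points: dict  # relative index -> (3,) ndarray
    residue_numbers: dict = field(default_factory=dict)

    def indices(self):
        return sorted(self.points)

    def __getitem__(self, idx):
        return self.points[idx]

    def __contains__(self, idx):
        return idx in self.points


@dataclass
class MajorAxis:
    vector: np.ndarray
    start_anchor: np.ndarray
    end_anchor: np.ndarray
    subdomain_name: str = ""

    def __post_init__(self):
        v = np.asarray(self.vector, float)
        n = np.linalg.norm(v)
        if abs(n - 1.0) > 1e-9:
            v = v / n
        self.vector = v


@dataclass
class CoiledCoilProfile:
    """Per-residue coiled-coil profile over one analysed range."""

    central_axis: dict            # idx -> (3,) ndarray
    radius: dict                  # idx -> Å
    psi: dict                     # idx -> signed degrees (may be missing at ends)
    pitch: dict                   # idx -> Å or None (indeterminate)
    handedness: dict              # idx -> "left" | "right" | "indeterminate"
    residue_numbers: dict = field(default_factory=dict)  # chain_label -> {idx: resnum}
    chain_labels: tuple = ()

    def indices(self):
        return sorted(self.central_axis)

    def mean_radius(self, interior_only: bool = True) -> float:
        return float(np.mean([self.radius[i] for i in self._sel(interior_only)]))

    def mean_pitch(self, interior_only: bool = True) -> float:
        vals = [self.pitch[i] for i in self._sel(interior_only)
                if i in self.pitch and self.pitch[i] is not None]
        if not vals:
            raise ValueError("pitch indeterminate everywhere (parallel strands?)")
        return float(np.mean(vals))

    def _sel(self, interior_only):
        idx = self.indices()
        if interior_only and len(idx) > 8:
            idx = idx[2:-2]
        return idx


def _axis_point(r: np.ndarray, k: int):
    """Axis point next to residue k from Cα at k−1 … k+2.

    The second difference of three consecutive points on a helix points at
    the axis with magnitude 2·r_helix·(1 − cos θ), θ being the twist per
    residue; θ is read off the angle between consecutive second differences
    projected perpendicular to the local axis direction.
    """
    v1 = r[k - 1] - 2.0 * r[k] + r[k + 1]
    v2 = r[k] - 2.0 * r[k + 1] + r[k + 2]
    axis = np.cross(v1, v2)
    norm = np.linalg.norm(axis)
    if norm < 1e-10:  # straight or degenerate: no axis information
        return None
    axis /= norm
    if axis @ (r[k + 2] - r[k - 1]) < 0:
        axis = -axis
    v1p = v1 - (v1 @ axis) * axis
    v2p = v2 - (v2 @ axis) * axis
    n1, n2 = np.linalg.norm(v1p), np.linalg.norm(v2p)
    if n1 < 1e-10 or n2 < 1e-10:
        return None
    cos_t = float(np.clip((v1p @ v2p) / (n1 * n2), -1.0, 1.0))
    if cos_t >= 1.0 - 1e-12:
        return None
    return r[k] + v1p / (2.0 * (1.0 - cos_t))


def compute_helix_axis(chain: ChainStructure, start: int | None = None,
                       end: int | None = None) -> AxisPath:
    """Estimate the α-helix axis path over ``start``–``end`` (inclusive,
    residue numbers; full chain by default)."""
    if start is None:
        start = int(chain.numbers[0])
    if end is None:
        end = int(chain.numbers[-1])
    sub = chain.subset(start, end)
    if len(sub) < 4:
        raise ValueError(
            f"chain {chain.label}: need at least 4 residues for an axis fit, "
            f"got {len(sub)} in {start}-{end}"
        )
    r = sub.ca_coords
    numbers = sub.numbers
    points, resnums = {}, {}
    for k in range(1, len(sub) - 2):
        # average the two four-residue-window estimates that centre on k
        # (windows k-1…k+2 and k-2…k+1); exact on an ideal helix, and the
        # averaging halves the variance under coordinate noise
        estimates = [_axis_point(r, k)]
        if k >= 2:
            estimates.append(_axis_point(r[::-1], len(sub) - 1 - k))
        estimates = [e for e in estimates if e is not None]
        if estimates:
            points[k] = np.mean(estimates, axis=0)
            resnums[k] = int(numbers[k])
    return AxisPath(chain.label, points, resnums)


def compute_central_axis(a: AxisPath, b: AxisPath) -> dict:
    """Pointwise midpoint of the two chain axis paths over their common
    relative-index range."""
    common = sorted(set(a.points) & set(b.points))
    if not common:
        raise ValueError("axis paths have no overlapping residue indices")
    return {i: 0.5 * (a[i] + b[i]) for i in common}


def compute_local_radius(a: AxisPath, b: AxisPath, central: dict) -> dict:
    return {
        i: 0.5 * (np.linalg.norm(a[i] - central[i]) + np.linalg.norm(b[i] - central[i]))
        for i in central if i in a and i in b
    }


def _dihedral_step(chain_pt0, chain_pt1, p0, p1):
    """Signed angle swept by the chain-to-axis vector from residue j to j+1,
    about the local central-axis direction."""
    axis = p1 - p0
    n = np.linalg.norm(axis)
    if n < 1e-10:
        return None
    axis = axis / n
    va = chain_pt0 - p0
    vb = chain_pt1 - p1
    vap = va - (va @ axis) * axis
    vbp = vb - (vb @ axis) * axis
    na, nb = np.linalg.norm(vap), np.linalg.norm(vbp)
    if na < 1e-10 or nb < 1e-10:
        return None
    return math.degrees(math.atan2(axis @ np.cross(vap, vbp), float(vap @ vbp)))


def compute_rotation_angle(a: AxisPath, b: AxisPath, central: dict, i: int):
    """Mean of the four dihedral estimates of the local rotation Ψ(i).

    Two estimates per chain: the step i−1→i and the step i→i+1.  Returns
    signed degrees (negative = left-handed supercoil) or None where the
    geometry is degenerate.
    """
    if not (i - 1 in central and i in central and i + 1 in central):
        raise ValueError(f"rotation at index {i} needs central axis at i-1, i, i+1")
    estimates = []
    for path in (a, b):
        for j in (i - 1, i):
            if j in path and j + 1 in path:
                est = _dihedral_step(path[j], path[j + 1], central[j], central[j + 1])
                if est is not None:
                    estimates.append(est)
    if not estimates:
        return None
    return float(np.mean(estimates))


def compute_local_pitch(central: dict, psi_deg: float, i: int,
                        psi_min: float = PSI_MIN_DEG):
    """Local pitch λ(i) = local rise per residue ÷ fractional turn per
    residue; None (indeterminate) when |Ψ| < psi_min."""
    if psi_deg is None or abs(psi_deg) < psi_min:
        return None
    rise = 0.5 * (np.linalg.norm(central[i + 1] - central[i])
                  + np.linalg.norm(central[i] - central[i - 1]))
    return float(rise * 360.0 / abs(psi_deg))


def compute_profile(chain_a: ChainStructure, chain_b: ChainStructure,
                    range_a=None, range_b=None,
                    psi_min: float = PSI_MIN_DEG) -> CoiledCoilProfile:
    """Full per-residue profile of a two-chain coiled-coil segment.

    ``range_a``/``range_b`` are (start, end) residue-number pairs per chain;
    the two ranges are aligned by relative index (in-register dimer).
    """
    ra = range_a or (int(chain_a.numbers[0]), int(chain_a.numbers[-1]))
    rb = range_b or (int(chain_b.numbers[0]), int(chain_b.numbers[-1]))
    pa = compute_helix_axis(chain_a, *ra)
    pb = compute_helix_axis(chain_b, *rb)
    central = compute_central_axis(pa, pb)
    radius = compute_local_radius(pa, pb, central)
    psi, pitch, hand = {}, {}, {}
    for i in sorted(central):
        if i - 1 in central and i + 1 in central:
            p = compute_rotation_angle(pa, pb, central, i)
            psi[i] = p
            lam = compute_local_pitch(central, p, i, psi_min)
            pitch[i] = lam
            if p is None or abs(p) < psi_min:
                hand[i] = "indeterminate"
            else:
                hand[i] = "left" if p < 0 else "right"
    return CoiledCoilProfile(
        central_axis=central, radius=radius, psi=psi, pitch=pitch,
        handedness=hand,
        residue_numbers={chain_a.label: pa.residue_numbers,
                         chain_b.label: pb.residue_numbers},
        chain_labels=(chain_a.label, chain_b.label),
    )


def subdomain_profile(dimer: DimerStructure, annotation: SubdomainAnnotation,
                      subdomain: str, psi_min: float = PSI_MIN_DEG) -> CoiledCoilProfile:
    """Profile of one annotated coiled-coil subdomain of a dimer."""
    la, lb = dimer.labels[:2]
    return compute_profile(
        dimer.chain(la), dimer.chain(lb),
        annotation.interval(la, subdomain), annotation.interval(lb, subdomain),
        psi_min=psi_min,
    )


def compute_major_axis(central: dict, subdomain_name: str = "",
                       n_range: int | None = None) -> MajorAxis:
    """Unit vector between the axis points at the 2nd residue and the
    3rd-to-last residue of the subdomain range.

    ``central`` is the central-axis path of the subdomain (relative indices
    0-based over a range of ``n_range`` residues; defaults to the covered
    span).  With the axis estimator those anchors are exactly the first and
    last defined axis points (indices 1 and n−3).
    """
    idx = sorted(central)
    if len(idx) < 3:
        raise ValueError(
            f"subdomain {subdomain_name or '?'}: central axis covers only "
            f"{len(idx)} residues; need >= 5 residues in the subdomain"
        )
    if n_range is not None:
        start_i, end_i = 1, n_range - 3
        if start_i not in central or end_i not in central:
            raise ValueError(
                f"subdomain {subdomain_name or '?'}: axis missing at anchor "
                f"residues (indices {start_i}, {end_i})"
            )
    else:
        start_i, end_i = idx[0], idx[-1]
    start, end = central[start_i], central[end_i]
    vec = end - start
    n = np.linalg.norm(vec)
    if n < 1e-10:
        raise ValueError("degenerate major axis (coincident anchors)")
    return MajorAxis(vec / n, start, end, subdomain_name)


def compute_hinge_angle(u: MajorAxis, v: MajorAxis,
                        convention: str = "interior") -> float:
    """Angle between two subdomain major axes (both N→C oriented).

    ``interior`` returns cos⁻¹(u·v) in [0°, 180°]; ``paper`` returns
    360° minus that (the printed-formula convention, range [180°, 360°]).
    """
    c = float(np.clip(u.vector @ v.vector, -1.0, 1.0))
    interior = math.degrees(math.acos(c))
    if convention == "interior":
        return interior
    if convention == "paper":
        return 360.0 - interior
    raise ValueError("convention must be 'interior' or 'paper'")
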