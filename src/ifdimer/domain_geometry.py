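"""Shape and placement of the disordered head/tail domains.

The head (E1-V1-H1) and tail (H2-V2-E2) domains of the keratin dimer are
quantified by:

* radius of gyration (RMS distance of backbone atoms from their centroid);
* end-to-end distance (chain terminus to the rod anchor);
* principal extents (max-minus-min spread along each principal axis);
* globule placement relative to the rod: the axial displacement ``d``
  (projection of the anchor→globule-centroid vector onto the outward
  anchor axis M) and the radial orientation ``θr`` (signed angle, in the
  plane perpendicular to M, between the projected centroid direction and
  the K1-pointing reference O).

``d`` > 0 means the globule sits beyond the rod terminus (Category I),
``d`` < 0 that it is folded back down onto the rod (Category III), with a
configurable |d| band in between (Category II).  θr = 0° is the K1 side,
θr = 180° the K10 side, ±90° between the chains; the sign follows the
right-hand rule about M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coil_geometry import compute_helix_axis, compute_central_axis, compute_major_axis
from .structure_io import ChainStructure, DimerStructure, SubdomainAnnotation

__all__ = [
    "GlobulePosition",
    "ShapeMetrics",
    "RodAnchorFrame",
    "radius_of_gyration",
    "end_to_end",
    "principal_extents",
    "shape_metrics",
    "rod_anchor_frame",
    "globule_position",
    "classify_category",
    "position_histogram",
]

#: |d| half-width (Å) of the Category II band; the band is a free
#: classification parameter, not a measured quantity.
CATEGORY_BAND = 10.0

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class GlobulePosition:
    chain_label: str
    subdomain_name: str
    d: float                 # signed Å along the outward anchor axis
    theta_r: float | None    # signed degrees in (-180, 180]; None if on-axis
    v_vec: np.ndarray        # anchor -> globule centroid (Å)
    m_vec: np.ndarray        # outward unit anchor axis
    o_vec: np.ndarray        # K1-pointing unit radial reference
    p_vec: np.ndarray | None  # unit in-plane projection of v_vec

    @property
    def theta_r_unsigned(self):
        return None if self.theta_r is None else abs(self.theta_r)


@dataclass
class ShapeMetrics:
    rg: float
    end_to_end: float
    principal_extents: tuple  # 3 descending Å values


@dataclass
class RodAnchorFrame:
    """Anchor geometry of one rod end.

    ``anchor``: axis point at the 2nd residue of 1A (head end) or the
    3rd-to-last residue of 2B (tail end).  ``m_vec`` points outward, away
    from the rod.  ``o_vec`` points from the inter-chain midpoint toward
    the K1 (first) chain, perpendicular to ``m_vec``.
    """

    anchor: np.ndarray
    m_vec: np.ndarray
    o_vec: np.ndarray
    anchor_end: str


def _points(atoms) -> np.ndarray:
    pts = np.asarray(atoms, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.size == 0:
        raise ValueError("empty point set")
    return pts


def radius_of_gyration(atoms) -> float:
    """RMS distance of the points from their centroid."""
    pts = _points(atoms)
    centered = pts - pts.mean(axis=0)
    return float(math.sqrt(np.mean(np.sum(centered**2, axis=1))))


def backbone_points(chain: ChainStructure, start: int | None = None,
                    end: int | None = None) -> np.ndarray:
    """Backbone (N, Cα, C, O) coordinates where present, else Cα only."""
    sub = chain if start is None else chain.subset(start, end)
    pts = []
    for res in sub.residues:
        named = [res.atoms[a] for a in BACKBONE_ATOMS if a in res.atoms]
        pts.extend(named if len(named) > 1 else [res.ca])
    return np.asarray(pts)


def end_to_end(chain: ChainStructure, domain: str, rod_anchor) -> float:
    """Distance from the chain's terminal residue Cα to the rod anchor.

    ``domain`` selects which terminus: "head" uses the first residue,
    "tail" the last.
    """
    if rod_anchor is None:
        raise ValueError("rod anchor position is required")
    if domain not in ("head", "tail"):
        raise ValueError("domain must be 'head' or 'tail'")
    res = chain.residues[0] if domain == "head" else chain.residues[-1]
    return float(np.linalg.norm(res.ca - np.asarray(rod_anchor, float)))


def principal_extents(atoms) -> tuple:
    """Max-minus-min spread along each principal axis, descending (Å)."""
    pts = _points(atoms)
    centered = pts - pts.mean(axis=0)
    if len(pts) == 1:
        return (0.0, 0.0, 0.0)
    cov = centered.T @ centered / len(pts)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs  # columns: ascending eigenvalue order
    spans = proj.max(axis=0) - proj.min(axis=0)
    return tuple(sorted((float(s) for s in spans), reverse=True))


def shape_metrics(chain: ChainStructure, domain: str, rod_anchor,
                  start: int | None = None, end: int | None = None) -> ShapeMetrics:
    pts = backbone_points(chain, start, end)
    sub = chain if start is None else chain.subset(start, end)
    return ShapeMetrics(
        rg=radius_of_gyration(pts),
        end_to_end=end_to_end(sub, domain, rod_anchor),
        principal_extents=principal_extents(pts),
    )


def rod_anchor_frame(dimer: DimerStructure, annotation: SubdomainAnnotation,
                     anchor_end: str) -> RodAnchorFrame:
    """Anchor point, outward axis M and K1-reference O for one rod end.

    ``anchor_end`` is "N-term-1A" (head side) or "C-term-2B" (tail side).
    """
    la, lb = dimer.labels[:2]
    if anchor_end == "N-term-1A":
        sub = "1A"
    elif anchor_end == "C-term-2B":
        sub = "2B"
    else:
        raise ValueError("anchor_end must be 'N-term-1A' or 'C-term-2B'")
    sa, ea = annotation.interval(la, sub)
    sb, eb = annotation.interval(lb, sub)
    pa = compute_helix_axis(dimer.chain(la), sa, ea)
    pb = compute_helix_axis(dimer.chain(lb), sb, eb)
    central = compute_central_axis(pa, pb)
    n_range = min(ea - sa, eb - sb) + 1
    major = compute_major_axis(central, sub, n_range=n_range)
    if anchor_end == "N-term-1A":
        anchor = major.start_anchor
        m_vec = -major.vector           # outward: beyond the 1A N-terminus
        ref_a = dimer.chain(la).residue(sa).ca
        ref_b = dimer.chain(lb).residue(sb).ca
    else:
        anchor = major.end_anchor
        m_vec = major.vector            # outward: beyond the 2B C-terminus
        ref_a = dimer.chain(la).residue(ea - 2).ca  # 3rd-to-last of 2B
        ref_b = dimer.chain(lb).residue(eb - 2).ca
    mid = 0.5 * (ref_a + ref_b)
    o = ref_a - mid
    o = o - (o @ m_vec) * m_vec         # constrain to plane C
    n = np.linalg.norm(o)
    if n < 1e-10:
        raise ValueError("degenerate K1 radial reference (chains coincide?)")
    return RodAnchorFrame(anchor, m_vec, o / n, anchor_end)


def globule_position(globule_atoms, frame: RodAnchorFrame,
                     chain_label: str = "", subdomain_name: str = "",
                     on_axis_tol: float = 1e-6) -> GlobulePosition:
    """Axial displacement and radial orientation of a globule's centroid
    relative to a rod anchor frame."""
    pts = _points(globule_atoms)
    com = pts.mean(axis=0)
    v = com - frame.anchor
    d = float(v @ frame.m_vec)
    v_perp = v - d * frame.m_vec
    n = np.linalg.norm(v_perp)
    if n < on_axis_tol:
        theta = None
        p_vec = None
    else:
        p_vec = v_perp / n
        cross = np.cross(frame.o_vec, p_vec)
        theta = math.degrees(math.atan2(float(cross @ frame.m_vec),
                                        float(p_vec @ frame.o_vec)))
        if theta <= -180.0:
            theta += 360.0
    return GlobulePosition(chain_label, subdomain_name, d, theta,
                           v, frame.m_vec, frame.o_vec, p_vec)


def classify_category(pos: GlobulePosition, band: float = CATEGORY_BAND) -> str:
    """Category I (projected out, d > band), II (|d| ≤ band, at right
    angles to the rod end), III (folded down, d < −band)."""
    if pos.d > band:
        return "I"
    if pos.d < -band:
        return "III"
    return "II"


def position_histogram(positions, d_bin: float = 5.0,
                       theta_bin: float = 15.0) -> pd.DataFrame:
    """2-D occurrence table of (d, θr) over a list of GlobulePositions.

    Positions with indeterminate θr are dropped (logged by callers).  The
    returned frame has one row per occupied bin: d_lo, d_hi, theta_lo,
    theta_hi, count; counts sum to the number of determinate positions.
    """
    if not positions:
        raise ValueError("no positions to histogram")
    ds = np.array([p.d for p in positions if p.theta_r is not None])
    ts = np.array([p.theta_r for p in positions if p.theta_r is not None])
    if ds.size == 0:
        return pd.DataFrame(columns=["d_lo", "d_hi", "theta_lo", "theta_hi", "count"])
    d_edges = np.arange(math.floor(ds.min() / d_bin) * d_bin,
                        ds.max() + d_bin, d_bin)
    if len(d_edges) < 2:
        d_edges = np.array([d_edges[0], d_edges[0] + d_bin])
    t_edges = np.arange(-180.0, 180.0 + theta_bin, theta_bin)
    counts, d_edges, t_edges = np.histogram2d(ds, ts, bins=[d_edges, t_edges])
    rows = []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] > 0:
                rows.append({
                    "d_lo": d_edges[i], "d_hi": d_edges[i + 1],
                    "theta_lo": t_edges[j], "theta_hi": t_edges[j + 1],
                    "count": int(counts[i, j]),
                })
    return pd.DataFrame(rows)
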