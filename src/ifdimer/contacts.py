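"""Residue contact maps, typed side-chain contact censuses and H-bonds.

Cα contact maps follow the 12 Å criterion: a residue pair is in contact in
a frame when its Cα–Cα distance is strictly below the cutoff, excluding
near-diagonal intra-chain pairs (|i−j| ≤ 2), and is classed by chain
pairing (K1-K1, K10-K10, K1-K10).  Contact probabilities are aggregated
over frames and models, with per-pair denominators restricted to the
models that actually contain both residues, so truncated (head-1A-L1-1B
only) and full dimer models mix correctly.

Side-chain contacts are typed by the residue pair: acid-base, hydrogen
bond, aromatic (ring centroids) or hydrophobic (closest side-chain
carbons), with a fixed precedence so each residue pair contributes at most
one contact type.  For the four neutral polar residues (Ser, Thr, Gln,
Asn) every candidate hydrogen-bonding site is checked and the pair counts
if any site satisfies the cutoff.

A heptad register supports the ideal knobs-into-holes count (each a-knob
packs against the same heptad's d-hole on the partner chain and each
d-knob against the same heptad's a-hole; one interaction per knob) and the
a/d-restricted inter-chain subtotal of the census.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import DimerStructure, Ensemble, global_index

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "ContactProbabilityMatrix",
    "ContactTypeTable",
    "SidechainContactSummary",
    "HeptadRegister",
    "ca_contact_map",
    "aggregate_contact_probability",
    "detect_sidechain_contacts",
    "summarize_contacts",
    "ideal_ad_contacts",
    "count_hbonds",
    "DEFAULT_CONTACT_TABLE",
]

CA_CUTOFF = 12.0          # Å, strict upper bound on Cα separation
SEQUENCE_EXCLUSION = 2    # intra-chain |i-j| <= this is never a contact


# ---------------------------------------------------------------------------
# residue chemistry

ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
# neutral polar side-chain hydrogen-bonding sites; Ser/Thr/Gln/Asn carry the
# double-site rule (every listed site is tested)
POLAR_SITES = {
    "SER": ("OG",), "THR": ("OG1",),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "TYR": ("OH",), "TRP": ("NE1",), "HIS": ("ND1", "NE2"), "CYS": ("SG",),
}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
BACKBONE_SET = {"N", "CA", "C", "O", "OXT"}

CLASS_PRECEDENCE = ("acid-base", "hydrogen-bond", "aromatic", "hydrophobic")


@dataclass(frozen=True)
class ContactTypeTable:
    """Interaction classes, cutoffs (Å) and the residue-pair → class rule."""

    cutoffs: dict = field(default_factory=lambda: {
        "acid-base": 4.0,
        "hydrogen-bond": 3.5,
        "aromatic": 7.0,
        "hydrophobic": 5.4,
    })

    def classify_pair(self, resname_a: str, resname_b: str):
        """Single interaction class for a residue-type pair (precedence
        acid-base > hydrogen-bond > aromatic > hydrophobic), or None."""
        a, b = resname_a.upper(), resname_b.upper()
        if (a in ACIDIC and b in BASIC) or (a in BASIC and b in ACIDIC):
            return "acid-base"
        hb = (POLAR_SITES, {**ACIDIC, **BASIC, **POLAR_SITES})
        if (a in hb[0] and b in hb[1]) or (b in hb[0] and a in hb[1]):
            return "hydrogen-bond"
        if a in AROMATIC_RINGS and b in AROMATIC_RINGS:
            return "aromatic"
        if a != "GLY" and b != "GLY":
            return "hydrophobic"
        return None

    def reference_points(self, res, cls: str):
        """Coordinates the class's distance criterion is measured between,
        or None when the residue lacks the needed atoms."""
        name = res.name.upper()
        if cls == "acid-base":
            atoms = ACIDIC.get(name) or BASIC.get(name) or ()
            pts = [res.atoms[a] for a in atoms if a in res.atoms]
            return np.asarray(pts) if pts else None
        if cls == "hydrogen-bond":
            atoms = (POLAR_SITES.get(name) or ACIDIC.get(name)
                     or BASIC.get(name) or ())
            pts = [res.atoms[a] for a in atoms if a in res.atoms]
            return np.asarray(pts) if pts else None
        if cls == "aromatic":
            atoms = AROMATIC_RINGS.get(name, ())
            pts = [res.atoms[a] for a in atoms if a in res.atoms]
            if len(pts) < 3:
                return None
            return np.mean(pts, axis=0).reshape(1, 3)  # ring centroid
        if cls == "hydrophobic":
            pts = [p for a, p in res.atoms.items()
                   if a not in BACKBONE_SET and a.startswith("C")]
            return np.asarray(pts) if pts else None
        raise KeyError(cls)

    @classmethod
    def from_tsv(cls, path) -> "ContactTypeTable":
        """Override cutoffs from a two-column TSV (class, cutoff_angstrom)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        cutoffs = dict(cls().cutoffs)
        for row in df.itertuples():
            name = str(row.interaction_class)
            if name not in cutoffs:
                raise ValueError(f"unknown interaction class {name!r}")
            cutoffs[name] = float(row.cutoff_angstrom)
        return cls(cutoffs=cutoffs)


DEFAULT_CONTACT_TABLE = ContactTypeTable()


# ---------------------------------------------------------------------------
# Cα contact maps

@dataclass
class ContactMap:
    """Cα contacts of one frame: canonical (i<j by global index) pairs with
    chain-pair class labels."""

    pairs: dict     # ((label_i, num_i), (label_j, num_j)) -> class string
    cutoff: float
    frame_id: int = 0

    def __len__(self):
        return len(self.pairs)

    def __contains__(self, key):
        return key in self.pairs


def _pair_class(label_i: str, label_j: str, chain_order=None) -> str:
    """Chain-pair class label, canonical regardless of chain order in the
    structure ("K1" sorts before "K10")."""
    if label_i == label_j:
        return f"{label_i}-{label_i}"
    a, b = sorted((label_i, label_j))
    return f"{a}-{b}"


def ca_contact_map(frame: DimerStructure, cutoff: float = CA_CUTOFF,
                   sequence_exclusion: int = SEQUENCE_EXCLUSION) -> ContactMap:
    """All residue pairs with Cα distance strictly below ``cutoff``.

    Spatially indexed (k-d tree); the test suite checks equality with a
    naive all-pairs enumeration.
    """
    coords = frame.all_ca()
    keys = []
    for chain in frame.chains:
        keys.extend((chain.label, int(n)) for n in chain.numbers)
    order = frame.labels
    tree = cKDTree(coords)
    pairs = {}
    for i, j in tree.query_pairs(r=cutoff):
        (li, ni), (lj, nj) = keys[i], keys[j]
        if li == lj and abs(ni - nj) <= sequence_exclusion:
            continue
        if np.linalg.norm(coords[i] - coords[j]) >= cutoff:  # strict bound
            continue
        key = (keys[i], keys[j]) if i < j else (keys[j], keys[i])
        pairs[key] = _pair_class(li, lj, order)
    return ContactMap(pairs, cutoff, frame.frame_id)


@dataclass
class ContactProbabilityMatrix:
    """Per-pair contact probability with chain-pair class and the
    normalization actually applied."""

    probabilities: dict   # pair key -> float in [0, 1]
    classes: dict         # pair key -> class string
    weighting: str
    cutoff: float
    n_models: int
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chain_i": k[0][0], "res_i": k[0][1],
                "chain_j": k[1][0], "res_j": k[1][1],
                "class": self.classes[k], "probability": p,
            }
            for k, p in sorted(self.probabilities.items())
        ]
        return pd.DataFrame(rows)

    def dense(self, structure: DimerStructure) -> np.ndarray:
        gidx = global_index(structure)
        n = len(gidx)
        mat = np.zeros((n, n))
        for (ki, kj), p in self.probabilities.items():
            if ki in gidx and kj in gidx:
                mat[gidx[ki], gidx[kj]] = p
                mat[gidx[kj], gidx[ki]] = p
        return mat


def aggregate_contact_probability(maps, ensemble: Ensemble,
                                  weighting: str = "per-model") -> ContactProbabilityMatrix:
    """Contact probability per residue pair over an ensemble.

    ``per-model``: each model contributes its within-model frame fraction,
    and models are averaged with equal weight — the default, which
    normalizes away unequal frame counts.  ``per-frame``: plain fraction
    over all frames.  Either way the denominator for a pair only includes
    models/frames whose structure contains both residues (truncated models
    lack the tail region entirely).
    """
    if weighting not in ("per-model", "per-frame"):
        raise ValueError("weighting must be 'per-model' or 'per-frame'")
    if len(maps) != len(ensemble):
        raise ValueError("one contact map per ensemble frame required")
    cutoffs = {m.cutoff for m in maps}
    if len(cutoffs) > 1:
        raise ValueError(f"inconsistent cutoffs in maps: {sorted(cutoffs)}")
    cutoff = cutoffs.pop() if cutoffs else CA_CUTOFF

    # which residues exist in each model
    model_residues: dict = {}
    model_frames: dict = {}
    for frame, mid in zip(ensemble.frames, ensemble.model_ids):
        model_frames[mid] = model_frames.get(mid, 0) + 1
        if mid not in model_residues:
            model_residues[mid] = {
                (c.label, int(n)) for c in frame.chains for n in c.numbers
            }

    # presence counts
    per_model_counts: dict = {}
    classes: dict = {}
    for cmap, mid in zip(maps, ensemble.model_ids):
        for key, cls in cmap.pairs.items():
            per_model_counts.setdefault(key, {}).setdefault(mid, 0)
            per_model_counts[key][mid] += 1
            classes[key] = cls

    probs = {}
    for key, counts in per_model_counts.items():
        ki, kj = key
        eligible = [mid for mid, res in model_residues.items()
                    if ki in res and kj in res]
        if not eligible:
            continue
        if weighting == "per-model":
            fracs = [counts.get(mid, 0) / model_frames[mid] for mid in eligible]
            probs[key] = float(np.mean(fracs))
        else:
            total = sum(model_frames[mid] for mid in eligible)
            probs[key] = sum(counts.values()) / total
    return ContactProbabilityMatrix(
        probs, classes, weighting, cutoff,
        n_models=len(model_residues), n_frames=len(ensemble),
    )


# ---------------------------------------------------------------------------
# typed side-chain contacts

@dataclass(frozen=True)
class SidechainContact:
    chain_i: str
    res_i: int
    chain_j: str
    res_j: int
    interaction_class: str
    distance: float
    chain_class: str


def detect_sidechain_contacts(frame: DimerStructure,
                              table: ContactTypeTable = DEFAULT_CONTACT_TABLE,
                              sequence_exclusion: int = SEQUENCE_EXCLUSION,
                              prefilter_margin: float = 14.0):
    """Typed side-chain contacts of one frame, at most one per residue pair.

    The pair's class is fixed by the residue types (precedence rule); the
    contact exists when the minimum distance between that class's reference
    points is below the class cutoff.  Pairs whose residues lack the
    reference atoms are skipped with a debug log entry.
    """
    residues = []
    for chain in frame.chains:
        for res in chain.residues:
            residues.append((chain.label, res))
    coords = np.array([r.ca for _, r in residues])
    order = frame.labels
    max_cut = max(table.cutoffs.values())
    tree = cKDTree(coords)
    contacts = []
    for i, j in sorted(tree.query_pairs(r=max_cut + prefilter_margin)):
        (li, ri), (lj, rj) = residues[i], residues[j]
        if li == lj and abs(ri.number - rj.number) <= sequence_exclusion:
            continue
        cls = table.classify_pair(ri.name, rj.name)
        if cls is None:
            continue
        pts_i = table.reference_points(ri, cls)
        pts_j = table.reference_points(rj, cls)
        if pts_i is None or pts_j is None:
            logger.debug(
                "skipping %s:%d-%s:%d (%s): missing %s reference atoms",
                li, ri.number, lj, rj.number, cls, cls)
            continue
        dmin = float(np.min(np.linalg.norm(
            pts_i[:, None, :] - pts_j[None, :, :], axis=-1)))
        if dmin < table.cutoffs[cls]:
            contacts.append(SidechainContact(
                li, ri.number, lj, rj.number, cls, dmin,
                _pair_class(li, lj, order)))
    return contacts


# ---------------------------------------------------------------------------
# heptad register and ideal knobs-into-holes counts

@dataclass
class HeptadRegister:
    """Per-residue heptad letters, possibly with stutter discontinuities."""

    letters: dict  # (chain_label, residue_number) -> letter a-g

    HEPTAD = "abcdefg"

    @classmethod
    def from_segments(cls, segments) -> "HeptadRegister":
        """Build from (chain_label, start, end, start_letter) segments,
        cycling a→g within each segment; segment breaks model stutters."""
        letters = {}
        for chain, start, end, first in segments:
            k0 = cls.HEPTAD.index(first)
            for off, num in enumerate(range(start, end + 1)):
                letters[(chain, num)] = cls.HEPTAD[(k0 + off) % 7]
        return cls(letters)

    def letter(self, chain: str, num: int):
        return self.letters.get((chain, num))

    def positions(self, chain: str, letter: str):
        return sorted(n for (c, n), l in self.letters.items()
                      if c == chain and l == letter)


def ideal_ad_contacts(register: HeptadRegister, chain_a: str, range_a,
                      chain_b: str, range_b) -> int:
    """Ideal inter-chain a/d knobs-into-holes interaction count.

    The two ranges are aligned by relative index (in-register dimer).  Each
    a-position knob of one chain packs against the partner chain's
    d-position of the same heptad (relative offset +3) and each d-knob
    against the partner's a-position (offset −3); every knob contributes
    one interaction when its partner site exists in range and carries the
    expected letter.  Stutters (register discontinuities) drop the broken
    pairings automatically.
    """
    sa, ea = range_a
    sb, eb = range_b
    for chain, lo, hi in ((chain_a, sa, ea), (chain_b, sb, eb)):
        missing = [n for n in range(lo, hi + 1)
                   if register.letter(chain, n) is None]
        if missing:
            raise ValueError(
                f"register unassigned for chain {chain} residues "
                f"{missing[0]}..{missing[-1]}"
            )
    count = 0
    span = min(ea - sa, eb - sb) + 1
    for (cx, sx), (cy, sy) in (((chain_a, sa), (chain_b, sb)),
                               ((chain_b, sb), (chain_a, sa))):
        for rel in range(span):
            lx = register.letter(cx, sx + rel)
            if lx == "a" and rel + 3 < span and \
                    register.letter(cy, sy + rel + 3) == "d":
                count += 1
            elif lx == "d" and rel - 3 >= 0 and \
                    register.letter(cy, sy + rel - 3) == "a":
                count += 1
    return count


# ---------------------------------------------------------------------------
# census

@dataclass
class SidechainContactSummary:
    """Ensemble-mean typed contact counts.

    ``mean_counts`` is indexed by (chain_class, interaction_class) and is
    the summed per-pair occurrence probability — i.e. the expected number
    of simultaneous contacts of that kind in one frame.
    """

    mean_counts: pd.Series
    pair_probabilities: pd.DataFrame
    ad_interchain_total: float | None = None

    @property
    def total(self) -> float:
        return float(self.mean_counts.sum())

    def by_interaction(self) -> pd.Series:
        return self.mean_counts.groupby(level="interaction_class").sum()

    def by_chain_class(self) -> pd.Series:
        return self.mean_counts.groupby(level="chain_class").sum()


def summarize_contacts(ensemble: Ensemble,
                       table: ContactTypeTable = DEFAULT_CONTACT_TABLE,
                       register: HeptadRegister | None = None) -> SidechainContactSummary:
    """Typed-contact census over an ensemble.

    Per-pair occurrence probability = frames containing the contact ÷
    total frames; class totals are summed probabilities.  With a heptad
    register, the inter-chain subtotal restricted to a/d positions is
    reported separately.
    """
    counts: dict = {}
    meta: dict = {}
    n = len(ensemble)
    for frame in ensemble:
        for c in detect_sidechain_contacts(frame, table):
            key = (c.chain_i, c.res_i, c.chain_j, c.res_j)
            counts[key] = counts.get(key, 0) + 1
            meta[key] = (c.interaction_class, c.chain_class)
    rows = [
        {
            "chain_i": k[0], "res_i": k[1], "chain_j": k[2], "res_j": k[3],
            "interaction_class": meta[k][0], "chain_class": meta[k][1],
            "probability": counts[k] / n,
        }
        for k in sorted(counts)
    ]
    df = pd.DataFrame(rows, columns=[
        "chain_i", "res_i", "chain_j", "res_j",
        "interaction_class", "chain_class", "probability",
    ])
    if df.empty:
        mean_counts = pd.Series(
            dtype=float,
            index=pd.MultiIndex.from_arrays([[], []],
                                            names=["chain_class", "interaction_class"]))
    else:
        mean_counts = df.groupby(["chain_class", "interaction_class"])["probability"].sum()
    ad_total = None
    if register is not None and not df.empty:
        sel = df[df.apply(
            lambda r: r.chain_i != r.chain_j
            and register.letter(r.chain_i, r.res_i) in ("a", "d")
            and register.letter(r.chain_j, r.res_j) in ("a", "d"), axis=1)]
        ad_total = float(sel["probability"].sum())
    return SidechainContactSummary(mean_counts, df, ad_total)


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.5         # donor/acceptor heavy-atom distance, Å
    min_acceptor_angle: float = 120.0  # antecedent-acceptor···partner angle
    backbone_min_separation: int = 3   # |i-j| below this: no backbone-backbone bond


def _polar_atoms(frame: DimerStructure):
    out = []
    for chain in frame.chains:
        for res in chain.residues:
            for name, pos in res.atoms.items():
                if name.startswith(("N", "O")):
                    is_backbone = name in ("N", "O", "OXT")
                    # antecedent of a carbonyl-type acceptor, for the
                    # heavy-atom linearity proxy
                    antecedent = res.atoms.get("C") if name in ("O", "OXT") else None
                    out.append((chain.label, res.number, name, is_backbone,
                                pos, antecedent))
    return out


def _acceptor_angle_ok(pos_o, antecedent, pos_partner, min_angle) -> bool:
    if antecedent is None:
        return True
    u = antecedent - pos_o
    v = pos_partner - pos_o
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0))) >= min_angle


def count_hbonds(frame: DimerStructure,
                 criteria: HBondCriteria = HBondCriteria()) -> dict:
    """Geometric hydrogen-bond counts by donor/acceptor location.

    Heavy-atom criteria (structures here typically lack hydrogens):
    an N/O pair from different residues within ``max_distance``, an
    antecedent-carbonyl angle C–O···X ≥ ``min_acceptor_angle`` whenever the
    acceptor's bonded carbon is known (the standard linearity proxy — it
    rejects the short but badly-aligned i→i+3 backbone pairs of an
    α-helix while keeping the i→i+4 bonds), and |i−j| ≥
    ``backbone_min_separation`` for intra-chain backbone-backbone pairs.

    Returns counts keyed by "backbone-backbone", "backbone-sidechain" and
    "sidechain-sidechain".
    """
    atoms = _polar_atoms(frame)
    coords = np.array([a[4] for a in atoms])
    counts = {"backbone-backbone": 0, "backbone-sidechain": 0,
              "sidechain-sidechain": 0}
    if len(atoms) < 2:
        return counts
    tree = cKDTree(coords)
    seen = set()
    for i, j in tree.query_pairs(r=criteria.max_distance):
        (li, ni, ai, bi, pi, anti), (lj, nj, aj, bj, pj, antj) = atoms[i], atoms[j]
        if (li, ni) == (lj, nj):
            continue
        if bi and bj and li == lj and \
                abs(ni - nj) < criteria.backbone_min_separation:
            continue
        if not _acceptor_angle_ok(pi, anti, pj, criteria.min_acceptor_angle):
            continue
        if not _acceptor_angle_ok(pj, antj, pi, criteria.min_acceptor_angle):
            continue
        # at most one bond per donor/acceptor residue-atom pair
        key = ((li, ni, ai), (lj, nj, aj)) if (li, ni, ai) < (lj, nj, aj) \
            else ((lj, nj, aj), (li, ni, ai))
        if key in seen:
            continue
        seen.add(key)
        if bi and bj:
            counts["backbone-backbone"] += 1
        elif bi or bj:
            counts["backbone-sidechain"] += 1
        else:
            counts["sidechain-sidechain"] += 1
    return counts
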