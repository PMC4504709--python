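"""Structure and sequence I/O plus the annotated dimer data model.

The intermediate-filament (IF) dimer analysed throughout this package is a
pair of chains — a type-II keratin ("K1") and a type-I keratin ("K10") —
each a sequence of residues with a mandatory Cα position and optional
further atoms.  Structures arrive as standard PDB files (single- or
multi-model) or as the whitespace-delimited coordinate dialect used by some
plain-text depositions; subdomain boundaries arrive as an editable TSV
table.

Residue numbering is per-chain and 1-based.  A single global residue index
(first chain's residues first, then the second chain's) is defined here and
used for contact-matrix row/column addressing everywhere else.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainStructure",
    "DimerStructure",
    "SubdomainAnnotation",
    "Ensemble",
    "PDBFormatError",
    "MissingAtomError",
    "AnnotationError",
    "read_pdb",
    "write_pdb",
    "load_annotation",
    "read_fasta",
    "default_annotation",
    "global_index",
]

SUBDOMAIN_NAMES = (
    "E1", "V1", "H1",
    "1A", "L1", "1B", "L12", "2A", "L2", "2B",
    "H2", "V2", "E2",
)

ROD_SUBDOMAINS = ("1A", "L1", "1B", "L12", "2A", "L2", "2B")
COIL_SUBDOMAINS = ("1A", "1B", "2A", "2B")
HEAD_SUBDOMAINS = ("E1", "V1", "H1")
TAIL_SUBDOMAINS = ("H2", "V2", "E2")

# one-letter <-> three-letter residue codes (standard amino acids)
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class MissingAtomError(ValueError):
    """Raised when a residue lacks a required atom (usually Cα)."""


class AnnotationError(ValueError):
    """Raised for invalid subdomain annotation tables."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    element: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.residue_number < 1:
            raise ValueError(f"atom {self.serial}: residue_number must be >= 1")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """One residue: name, per-chain 1-based number, named atom coordinates."""

    name: str
    number: int
    atoms: dict = field(default_factory=dict)  # atom_name -> (3,) ndarray

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def has(self, atom_name: str) -> bool:
        return atom_name in self.atoms


@dataclass
class ChainStructure:
    """An ordered chain of residues, each with a Cα position.

    ``label`` is conventionally "K1" (type II) or "K10" (type I) for the
    keratin dimer but may be arbitrary for synthetic fixtures.
    """

    label: str
    residues: list = field(default_factory=list)

    def __post_init__(self):
        last = 0
        for res in self.residues:
            if res.number <= last:
                raise ValueError(
                    f"chain {self.label}: residue numbers must be strictly "
                    f"increasing (saw {res.number} after {last})"
                )
            last = res.number
            if "CA" not in res.atoms:
                raise MissingAtomError(
                    f"chain {self.label} residue {res.number} ({res.name}) has no CA atom"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def numbers(self) -> np.ndarray:
        return np.array([r.number for r in self.residues], dtype=int)

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"chain {self.label} has no residue {number}")

    def subset(self, start: int, end: int) -> "ChainStructure":
        """Residues with start <= number <= end (inclusive)."""
        sel = [r for r in self.residues if start <= r.number <= end]
        return ChainStructure(self.label, sel)

    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.name, "X") for r in self.residues)


@dataclass
class DimerStructure:
    """One structural frame: the two chains of a dimer (or a single chain
    for isolated-fixture work).  Chain labels must be distinct."""

    chains: list
    frame_id: int = 0
    source: str = ""

    def __post_init__(self):
        labels = [c.label for c in self.chains]
        if len(set(labels)) != len(labels):
            raise ValueError(f"chain labels must be distinct, got {labels}")
        if not self.chains:
            raise ValueError("a structure needs at least one chain")

    def chain(self, label: str) -> ChainStructure:
        for c in self.chains:
            if c.label == label:
                return c
        raise KeyError(f"no chain labelled {label!r}")

    @property
    def labels(self) -> list:
        return [c.label for c in self.chains]

    def all_ca(self) -> np.ndarray:
        return np.vstack([c.ca_coords for c in self.chains])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DimerStructure":
        """Rigid-body copy: x -> R x + t for every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = []
        for c in self.chains:
            residues = [
                Residue(r.name, r.number, {a: R @ p + t for a, p in r.atoms.items()})
                for r in c.residues
            ]
            chains.append(ChainStructure(c.label, residues))
        return DimerStructure(chains, frame_id=self.frame_id, source=self.source)


@dataclass
class Ensemble:
    """Ordered frames with per-frame model bookkeeping.

    ``model_ids[k]`` groups frames into models; ``model_scopes[k]`` is
    "full" or "truncated" and drives contact-probability normalization.
    """

    frames: list
    model_ids: list = None
    model_scopes: list = None
    source: str = ""

    def __post_init__(self):
        if self.model_ids is None:
            self.model_ids = [0] * len(self.frames)
        if self.model_scopes is None:
            self.model_scopes = ["full"] * len(self.frames)
        if not (len(self.frames) == len(self.model_ids) == len(self.model_scopes)):
            raise ValueError("frames, model_ids, model_scopes must align")
        lengths = {}
        for fr, mid in zip(self.frames, self.model_ids):
            key = tuple((c.label, len(c)) for c in fr.chains)
            if mid in lengths and lengths[mid] != key:
                raise ValueError(f"frames of model {mid} disagree in chain lengths")
            lengths[mid] = key

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# subdomain annotation

@dataclass
class SubdomainAnnotation:
    """Per-chain subdomain intervals, 1-based inclusive."""

    entries: list  # (chain_label, subdomain, start, end)

    def __post_init__(self):
        per_chain = {}
        for chain, name, start, end in self.entries:
            if name not in SUBDOMAIN_NAMES:
                raise AnnotationError(f"unknown subdomain name {name!r}")
            if not (1 <= start <= end):
                raise AnnotationError(f"{chain} {name}: bad interval {start}-{end}")
            per_chain.setdefault(chain, []).append((start, end, name))
        for chain, ivals in per_chain.items():
            ivals.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise AnnotationError(
                        f"chain {chain}: subdomains {n1} and {n2} overlap "
                        f"({s1}-{e1} vs {s2}-{e2})"
                    )
        self.entries = [
            (chain, name, start, end)
            for chain in sorted(per_chain)
            for start, end, name in per_chain[chain]
        ]

    def interval(self, chain: str, subdomain: str):
        for c, name, s, e in self.entries:
            if c == chain and name == subdomain:
                return (s, e)
        raise KeyError(f"no {subdomain} annotated for chain {chain}")

    def has(self, chain: str, subdomain: str) -> bool:
        try:
            self.interval(chain, subdomain)
            return True
        except KeyError:
            return False

    def subdomain_of(self, chain: str, residue_number: int):
        for c, name, s, e in self.entries:
            if c == chain and s <= residue_number <= e:
                return name
        return None

    def chains(self):
        return sorted({c for c, *_ in self.entries})

    def validate_against(self, structure: DimerStructure) -> None:
        for c, name, s, e in self.entries:
            try:
                chain = structure.chain(c)
            except KeyError:
                continue
            lo, hi = chain.numbers[0], chain.numbers[-1]
            if s < lo or e > hi:
                raise AnnotationError(
                    f"chain {c} {name} {s}-{e} outside residue range {lo}-{hi}"
                )


def load_annotation(path) -> SubdomainAnnotation:
    """Read a TSV with header ``chain  subdomain  start  end``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chain", "subdomain", "start", "end"}
    if not required.issubset(df.columns):
        raise AnnotationError(
            f"annotation table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    entries = [
        (str(row.chain), str(row.subdomain), int(row.start), int(row.end))
        for row in df.itertuples()
    ]
    return SubdomainAnnotation(entries)


def default_annotation() -> SubdomainAnnotation:
    """The shipped K1/K10 subdomain table (editable file in package data).

    Boundaries are a documented best reconstruction; see the methods note.
    """
    path = Path(__file__).parent / "data" / "subdomains_k1k10.tsv"
    return load_annotation(path)


# ---------------------------------------------------------------------------
# FASTA

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


def read_fasta(path) -> dict:
    """FASTA records as uppercase one-letter sequences keyed by record id."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - _VALID_AA)
        if bad:
            raise ValueError(f"record {rec.id}: illegal sequence characters {bad}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


# ---------------------------------------------------------------------------
# PDB reading

_ALTLOC_KEEP = {" ", "", "A"}


def _parse_strict(lines) -> list:
    """Parse fixed-column PDB ATOM records; returns list of per-frame atom lists."""
    frames = [[]]
    saw_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if saw_model:
                frames.append([])
            saw_model = True
            if frames[-1]:
                frames.append([])
        elif rec == "ENDMDL":
            continue
        elif rec == "ATOM":
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16:17]
                resname = line[17:20].strip()
                chain_id = line[21:22].strip() or "A"
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 78 else ""
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"unparseable ATOM line {lineno}: {line.rstrip()!r}") from exc
            if altloc not in _ALTLOC_KEEP:
                continue
            frames[-1].append(AtomRecord(serial, name, resname, chain_id, resnum, (x, y, z), element))
    return [f for f in frames if f]


def _parse_loose(lines) -> list:
    """Whitespace-delimited dialect: serial name resname chain resnum x y z."""
    frames = [[]]
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "MODEL":
            if frames[-1]:
                frames.append([])
            continue
        if tokens[0] in ("ENDMDL", "TER", "END", "REMARK", "HEADER", "TITLE"):
            continue
        if tokens[0] == "ATOM":
            tokens = tokens[1:]
        if len(tokens) < 7:
            raise PDBFormatError(f"unparseable line {lineno}: {line.rstrip()!r}")
        try:
            serial = int(tokens[0])
            name = tokens[1]
            resname = tokens[2]
            chain_id = tokens[3]
            resnum = int(tokens[4])
            x, y, z = (float(t) for t in tokens[5:8])
        except ValueError as exc:
            raise PDBFormatError(f"unparseable line {lineno}: {line.rstrip()!r}") from exc
        frames[-1].append(AtomRecord(serial, name, resname, chain_id, resnum, (x, y, z)))
    return [f for f in frames if f]


def _frame_from_atoms(atoms, frame_id, source) -> DimerStructure:
    chains: dict = {}
    for atom in atoms:
        chain = chains.setdefault(atom.chain_id, {})
        res = chain.setdefault(atom.residue_number, Residue(atom.residue_name, atom.residue_number))
        if atom.atom_name not in res.atoms:  # first occurrence wins (altloc rule)
            res.atoms[atom.atom_name] = atom.position
    chain_objs = []
    for chain_id, residues in chains.items():
        ordered = [residues[n] for n in sorted(residues)]
        for res in ordered:
            if "CA" not in res.atoms:
                raise MissingAtomError(
                    f"{source}: chain {chain_id} residue {res.number} ({res.name}) has no CA atom"
                )
        chain_objs.append(ChainStructure(chain_id, ordered))
    return DimerStructure(chain_objs, frame_id=frame_id, source=source)


def read_pdb(path, labels=None) -> Ensemble:
    """Read a (multi-)model PDB file into an Ensemble, one frame per MODEL.

    Strict fixed-column PDB is attempted first; if that fails the
    whitespace-delimited deposition dialect (serial name resname chain
    resnum x y z) is tried before the original error is re-raised.

    ``labels`` optionally renames chains in file order (e.g. ["K1", "K10"]),
    since the one-character PDB chain field cannot hold keratin chain names.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    try:
        atom_frames = _parse_strict(lines)
        if not atom_frames:  # no ATOM records: maybe the loose dialect
            atom_frames = _parse_loose(lines)
    except PDBFormatError as strict_err:
        try:
            atom_frames = _parse_loose(lines)
        except PDBFormatError:
            raise strict_err
    if not atom_frames:
        raise PDBFormatError(f"{path}: no ATOM records found")
    frames = [
        _frame_from_atoms(atoms, frame_id=k, source=str(path))
        for k, atoms in enumerate(atom_frames)
    ]
    if labels is not None:
        for frame in frames:
            if len(labels) != len(frame.chains):
                raise ValueError(
                    f"{len(labels)} labels given for {len(frame.chains)} chains"
                )
            frame.chains = [
                ChainStructure(lab, c.residues) for lab, c in zip(labels, frame.chains)
            ]
    return Ensemble(frames, source=str(path))


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom(serial, res, atom_name, pos, chain_id) -> str:
    x, y, z = pos
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise ValueError(
                f"coordinate {v:.3f} exceeds the fixed-width PDB coordinate field"
            )
    name_field = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
    element = atom_name[0] if atom_name else ""
    return (
        f"ATOM  {serial:5d} {name_field:<4s} {res.name:<3s} {chain_id[:1]:1s}"
        f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


_BACKBONE_ORDER = ("N", "CA", "C", "O")


def _atom_order(res: Residue):
    names = list(res.atoms)
    ordered = [n for n in _BACKBONE_ORDER if n in res.atoms]
    ordered += sorted(n for n in names if n not in _BACKBONE_ORDER)
    return ordered


def write_pdb(ensemble, path) -> None:
    """Write an Ensemble (or a single DimerStructure) as standard PDB text."""
    if isinstance(ensemble, DimerStructure):
        ensemble = Ensemble([ensemble])
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    buf = io.StringIO()
    multi = len(ensemble) > 1
    for k, frame in enumerate(ensemble, start=1):
        if multi:
            buf.write(f"MODEL {k:>8d}\n")
        serial = 1
        labels = [c.label for c in frame.chains]
        if all(len(l) == 1 for l in labels) and len(set(labels)) == len(labels):
            chain_ids = labels
        else:  # keratin labels like K1/K10 do not fit the 1-char field
            chain_ids = [chr(ord("A") + i) for i in range(len(labels))]
        for chain, cid in zip(frame.chains, chain_ids):
            for res in chain.residues:
                for atom_name in _atom_order(res):
                    buf.write(_format_atom(serial, res, atom_name, res.atoms[atom_name], cid) + "\n")
                    serial += 1
            buf.write(f"TER   {serial:5d}      {chain.residues[-1].name:<3s} "
                      f"{cid}{chain.residues[-1].number:4d}\n")
            serial += 1
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# global residue indexing

def global_index(structure: DimerStructure) -> dict:
    """Map (chain_label, residue_number) -> dense global index.

    First chain's residues first (K1 by file convention), then the second's.
    """
    mapping = {}
    idx = 0
    for chain in structure.chains:
        for res in chain.residues:
            mapping[(chain.label, res.number)] = idx
            idx += 1
    return mapping
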