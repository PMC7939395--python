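"""Protein structure handling for head-domain comparison and interface analysis.

The SAS-6 head domain dimerizes through a loop (β6-β7) that inserts into a
hydrophobic pocket of the partner domain.  This module supplies the structural
primitives the rest of the pipeline builds on: a fixed-column PDB reader/writer
that preserves author residue numbering exactly, least-squares rigid
superposition, Cα RMSD between (possibly cross-species) head domains via
sequence-aligned residue pairing, and enumeration of cross-chain interface
contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AtomRecord",
    "Structure",
    "ResiduePairing",
    "PDBParseError",
    "read_structures",
    "write_structure",
    "superpose",
    "ca_rmsd",
    "interface_residues",
    "align_ca_residues",
]


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB records; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


# Three-letter -> one-letter amino acid codes (standard residues only).
_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass
class AtomRecord:
    """One ATOM/HETATM record with author numbering preserved exactly."""

    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    altloc: str = ""
    icode: str = ""
    hetatm: bool = False

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} {self.name}: xyz must be a finite 3-vector")
        if not self.element:
            # Fall back on the convention that the atom name starts with the element.
            self.element = self.name.strip(" 0123456789")[:1].upper()

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, author res_seq, insertion code) — insertion codes fold into identity."""
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms (one PDB MODEL); iteration order is file order."""

    atoms: list[AtomRecord] = field(default_factory=list)
    model_id: int = 1

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)

    def chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residues(self, chain_id: str | None = None) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Group atoms by residue identity, preserving file order of residues."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.setdefault(a.residue_id, []).append(a)
        return out

    def ca_atoms(self, chain_id: str | None = None) -> list[AtomRecord]:
        return [
            a for a in self.atoms
            if a.name.strip() == "CA" and not a.hetatm
            and (chain_id is None or a.chain_id == chain_id)
        ]

    def coords(self, atoms: Iterable[AtomRecord] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else list(atoms)
        if not src:
            return np.zeros((0, 3))
        return np.stack([a.xyz for a in src])

    def with_bfactors(self, values: dict[tuple[str, int, str], float], default: float = 0.0) -> "Structure":
        """Copy of the structure with per-residue B-factors replaced (CSP annotation)."""
        atoms = [replace(a, bfactor=values.get(a.residue_id, default), xyz=a.xyz.copy())
                 for a in self.atoms]
        return Structure(atoms=atoms, model_id=self.model_id)


@dataclass
class ResiduePairing:
    """Matched residue positions (author numbering) between two chains/structures."""

    pairs: list[tuple[int, int]]

    def __post_init__(self):
        left = [p[0] for p in self.pairs]
        right = [p[1] for p in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("a residue appears twice on one side of the pairing")

    def reversed(self) -> "ResiduePairing":
        return ResiduePairing([(b, a) for a, b in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


def _parse_float(text: str, what: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", line_no) from None


def _parse_int(text: str, what: str, line_no: int) -> int:
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text!r}", line_no) from None


def _parse_atom_line(line: str, line_no: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than coordinate columns", line_no)
    line = line.ljust(80)
    occ = line[54:60].strip()
    bfac = line[60:66].strip()
    return AtomRecord(
        serial=_parse_int(line[6:11], "serial", line_no),
        name=line[12:16].strip(),
        altloc=line[16].strip(),
        res_name=line[17:20].strip(),
        chain_id=line[21],
        res_seq=_parse_int(line[22:26], "residue number", line_no),
        icode=line[26].strip(),
        xyz=np.array([
            _parse_float(line[30:38], "x coordinate", line_no),
            _parse_float(line[38:46], "y coordinate", line_no),
            _parse_float(line[46:54], "z coordinate", line_no),
        ]),
        occupancy=_parse_float(occ, "occupancy", line_no) if occ else 1.0,
        bfactor=_parse_float(bfac, "B-factor", line_no) if bfac else 0.0,
        element=line[76:78].strip(),
        hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per (residue, name): highest occupancy, ties to first in file."""
    best: dict[tuple, int] = {}
    for idx, a in enumerate(atoms):
        key = (a.residue_id, a.name)
        if key not in best or a.occupancy > atoms[best[key]].occupancy:
            best[key] = idx
    keep = set(best.values())
    return [a for i, a in enumerate(atoms) if i in keep]


def read_structures(pdb_text: str) -> list[Structure]:
    """Parse fixed-column PDB text into one Structure per MODEL (one if no MODEL).

    Raises :class:`PDBParseError` naming the offending line for malformed
    coordinate or numeric fields, and :class:`ValueError` on empty input.
    """
    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    models: list[Structure] = []
    current = Structure(model_id=1)
    in_model = False
    for line_no, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if in_model and current.atoms:
                models.append(current)
            current = Structure(model_id=_parse_int(line[10:14], "model id", line_no))
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = Structure(model_id=current.model_id + 1)
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            current.atoms.append(_parse_atom_line(line, line_no))
    if current.atoms:
        models.append(current)
    if not models:
        raise ValueError("no ATOM/HETATM records found")
    for m in models:
        m.atoms = _resolve_altlocs(m.atoms)
    return models


def _format_atom(a: AtomRecord) -> str:
    rec = "HETATM" if a.hetatm else "ATOM  "
    # PDB convention: 1-3 char names right-padded in cols 14-16 unless 4 chars.
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{rec}{a.serial:5d} {name:<4s}{a.altloc or ' ':1s}{a.res_name:>3s} "
        f"{a.chain_id:1s}{a.res_seq:4d}{a.icode or ' ':1s}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_structure(structures: Structure | Sequence[Structure]) -> str:
    """Serialize one or more models back to fixed-column PDB text."""
    if isinstance(structures, Structure):
        structures = [structures]
    lines: list[str] = []
    multi = len(structures) > 1
    for s in structures:
        if multi:
            lines.append(f"MODEL     {s.model_id:4d}")
        lines.extend(_format_atom(a) for a in s.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def superpose(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of ``mov`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mov @ rotation.T + translation`` minimizes the RMSD to ``ref`` over all
    proper rotations (det = +1).  Point sets are paired by index; N >= 3 points
    are required.  Collinear/degenerate sets still return the optimal transform
    about the well-determined axes (the SVD sign correction keeps det = +1).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be matching N x 3 arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired points are required")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def ca_rmsd(a: Structure, b: Structure, pairing: ResiduePairing,
            chain_a: str | None = None, chain_b: str | None = None) -> float:
    """Cα RMSD between paired residues after optimal superposition.

    ``pairing`` holds author residue numbers; chain selection defaults to the
    first chain of each structure (head-domain monomers).
    """
    ca_a = {r.res_seq: r for r in a.ca_atoms(chain_a or sorted(a.chains)[0])}
    ca_b = {r.res_seq: r for r in b.ca_atoms(chain_b or sorted(b.chains)[0])}
    missing = [(ra, rb) for ra, rb in pairing.pairs if ra not in ca_a or rb not in ca_b]
    if missing:
        raise ValueError(f"paired residues missing a CA atom: {missing}")
    ref = np.stack([ca_a[ra].xyz for ra, _ in pairing.pairs])
    mov = np.stack([ca_b[rb].xyz for _, rb in pairing.pairs])
    return superpose(ref, mov)[2]


def align_ca_residues(a: Structure, b: Structure,
                      chain_a: str | None = None, chain_b: str | None = None) -> ResiduePairing:
    """Sequence-align CA-bearing residues of two structures (global, free end gaps).

    Uses BLOSUM62; unknown three-letter codes align as 'X'.  The returned
    pairing maps author residue numbers and feeds :func:`ca_rmsd` for
    cross-species head-domain comparison.
    """
    ca_a = a.ca_atoms(chain_a or sorted(a.chains)[0])
    ca_b = b.ca_atoms(chain_b or sorted(b.chains)[0])
    if not ca_a or not ca_b:
        raise ValueError("both structures need CA atoms on the selected chains")
    seq_a = "".join(_AA3TO1.get(r.res_name, "X") for r in ca_a)
    seq_b = "".join(_AA3TO1.get(r.res_name, "X") for r in ca_b)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.target_end_gap_score = 0.0
    aligner.query_end_gap_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            pairs.append((ca_a[i].res_seq, ca_b[j].res_seq))
    return ResiduePairing(pairs)


def interface_residues(s: Structure, chain_a: str, chain_b: str,
                       cutoff: float) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Cross-chain residue pairs with any heavy-atom distance <= cutoff, sorted by distance.

    Heavy atom means element other than H/D.  Returns
    ``(residue_id_a, residue_id_b, min_distance)`` triples.
    """
    from scipy.spatial.distance import cdist

    for c in (chain_a, chain_b):
        if c not in s.chains:
            raise ValueError(f"chain {c!r} not present in structure (has {sorted(s.chains)})")
    res_a = {k: [x for x in v if x.is_heavy] for k, v in s.residues(chain_a).items()}
    res_b = {k: [x for x in v if x.is_heavy] for k, v in s.residues(chain_b).items()}
    out = []
    for ka, aa in res_a.items():
        if not aa:
            continue
        ca = np.stack([x.xyz for x in aa])
        for kb, bb in res_b.items():
            if not bb:
                continue
            d = float(cdist(ca, np.stack([x.xyz for x in bb])).min())
            if d <= cutoff:
                out.append((ka, kb, d))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out
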