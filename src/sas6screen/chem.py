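"""Small-molecule library preparation: property filters, fingerprints, diversity.

Mirrors the library-preparation stage of the screening workflow: a drug-like
compound collection is filtered on molecular mass (300-500 Da), hydrogen-bond
donors (>=1) and aromatic rings (>=1), and screening hits are thinned by
Tanimoto similarity with a greedy leader walk so that only chemically diverse
representatives survive.  Molecules are RDKit ``Mol`` objects throughout; SD
files (V2000) are the interchange format, with conformers of one compound
grouped by a shared title/ID.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "MolProperties",
    "Fingerprint",
    "compute_properties",
    "filter_library",
    "fingerprint",
    "tanimoto",
    "diversity_pick",
    "read_sdf",
    "write_sdf",
    "mol_id",
]

# Standard atomic masses (most common isotope-weighted), via RDKit's periodic table.
_PT = Chem.GetPeriodicTable()


def mol_id(mol: Chem.Mol) -> str:
    """Compound identifier: the SD title (``_Name``), falling back to the SMILES."""
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return name or Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MolProperties:
    """Filterable properties: mass, H-bond donor count, aromatic ring count."""

    mw: float
    hbd_count: int
    aromatic_ring_count: int

    def __post_init__(self):
        if self.mw <= 0 or self.hbd_count < 0 or self.aromatic_ring_count < 0:
            raise ValueError("invalid molecular properties")


@dataclass(frozen=True)
class Fingerprint:
    """Sparse circular-substructure fingerprint: set of on-bit indices."""

    bits: frozenset[int]
    nbits: int = 2048

    def __post_init__(self):
        if any(b >= self.nbits or b < 0 for b in self.bits):
            raise ValueError("bit index outside fingerprint space")


def compute_properties(mol: Chem.Mol) -> MolProperties:
    """Mass with implicit hydrogens, OpenBabel-style donor count, aromatic rings.

    A hydrogen-bond donor is any N/O/S atom carrying at least one (implicit or
    explicit) hydrogen.  An aromatic ring is a smallest-set ring whose bonds
    are all aromatic.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    mw = 0.0
    hbd = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise ValueError(f"unknown element for atom index {atom.GetIdx()}")
        mw += _PT.GetAtomicWeight(atom.GetAtomicNum())
        mw += atom.GetTotalNumHs() * _PT.GetAtomicWeight(1)
        if atom.GetSymbol() in ("N", "O", "S") and atom.GetTotalNumHs() > 0:
            hbd += 1
    ring_info = mol.GetRingInfo()
    aromatic_rings = sum(
        1 for ring in ring_info.BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )
    return MolProperties(mw=mw, hbd_count=hbd, aromatic_ring_count=aromatic_rings)


def filter_library(mols: Sequence[Chem.Mol], mw_min: float = 300.0, mw_max: float = 500.0,
                   hbd_min: int = 1, aromatic_min: int = 1) -> list[Chem.Mol]:
    """Keep molecules inside all (inclusive) property bounds, preserving order."""
    if mw_min > mw_max:
        raise ValueError(f"mw_min ({mw_min}) exceeds mw_max ({mw_max})")
    kept = []
    for m in mols:
        p = compute_properties(m)
        if (mw_min <= p.mw <= mw_max and p.hbd_count >= hbd_min
                and p.aromatic_ring_count >= aromatic_min):
            kept.append(m)
    return kept


def fingerprint(mol: Chem.Mol, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Morgan (circular) fingerprint as a sparse bit set; deterministic per graph."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 when both bit sets are empty."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint sizes differ ({a.nbits} vs {b.nbits})")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def diversity_pick(mols: Sequence[Chem.Mol], scores: Sequence[float],
                   sim_threshold: float = 0.6, radius: int = 2,
                   nbits: int = 2048) -> list[Chem.Mol]:
    """Greedy leader picking over a score-ranked list.

    Walks molecules in descending score order (ties by compound id) and keeps a
    molecule iff its Tanimoto similarity to every already-kept molecule is
    strictly below ``sim_threshold``.
    """
    if not 0.0 < sim_threshold <= 1.0:
        raise ValueError("sim_threshold must lie in (0, 1]")
    if len(mols) != len(scores):
        raise ValueError("one score per molecule required")
    order = sorted(range(len(mols)), key=lambda i: (-scores[i], mol_id(mols[i])))
    kept_idx: list[int] = []
    fps = {}
    for i in order:
        fps[i] = fingerprint(mols[i], radius=radius, nbits=nbits)
        if all(tanimoto(fps[i], fps[j]) < sim_threshold for j in kept_idx):
            kept_idx.append(i)
    kept_idx.sort()  # report in input order
    return [mols[i] for i in kept_idx]


def read_sdf(sdf_text: str, sanitize: bool = True) -> list[Chem.Mol]:
    """Read a V2000 SD file from text, one Mol per record (3-D coords kept)."""
    supplier = Chem.SDMolSupplier()
    supplier.SetData(sdf_text, sanitize=sanitize, removeHs=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError("no molecules parsed from SD input")
    return mols


def write_sdf(mols: Iterable[Chem.Mol]) -> str:
    """Serialize molecules (with any conformers' first coordinates) to SD text."""
    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(True)
    for m in mols:
        writer.write(m)
    writer.close()
    return buf.getvalue()


def group_conformers(mols: Sequence[Chem.Mol]) -> dict[str, list[Chem.Mol]]:
    """Group SD records of the same compound (shared title/ID), preserving order."""
    groups: dict[str, list[Chem.Mol]] = {}
    for m in mols:
        groups.setdefault(mol_id(m), []).append(m)
    return groups
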