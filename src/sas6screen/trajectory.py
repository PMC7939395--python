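"""Trajectory-frame analysis of a protein–ligand complex.

Works on engine-agnostic frame series (multi-model PDB): per-frame ligand RMSD
after protein-Cα superposition, qualitative pose-stability classification
(stable / semi-stable / unstable), hydrogen-bond occupancies under a standard
distance/angle criterion, and ligand-atom × protein-residue close-contact maps
normalized so the most frequent contact equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import Structure, read_structures, superpose

__all__ = [
    "FrameSeries",
    "ContactMap",
    "HBondSpec",
    "ligand_rmsd_series",
    "contact_map",
    "hbond_occupancy",
    "pose_stability",
]


@dataclass
class FrameSeries:
    """A topology plus per-frame coordinates (one coordinate row per topology atom)."""

    topology: Structure
    frames: list[np.ndarray]
    ligand_resname: str = "LIG"
    frame_spacing: float = 1.0          # metadata only (e.g. ns between frames)

    def __post_init__(self):
        n = len(self.topology.atoms)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: expected {(n, 3)} coordinates, got {f.shape}")

    @classmethod
    def from_pdb(cls, pdb_text: str, ligand_resname: str = "LIG") -> "FrameSeries":
        models = read_structures(pdb_text)
        topo = models[0]
        key = [(a.chain_id, a.res_seq, a.icode, a.name) for a in topo.atoms]
        frames = []
        for m in models:
            mkey = [(a.chain_id, a.res_seq, a.icode, a.name) for a in m.atoms]
            if mkey != key:
                raise ValueError(f"model {m.model_id}: atom list differs from first model")
            frames.append(m.coords())
        return cls(topology=topo, frames=frames, ligand_resname=ligand_resname)

    def ligand_indices(self, heavy_only: bool = True) -> list[int]:
        idx = [i for i, a in enumerate(self.topology.atoms)
               if a.res_name == self.ligand_resname and (a.is_heavy or not heavy_only)]
        if not idx:
            raise ValueError(f"no ligand atoms with residue name {self.ligand_resname!r}")
        return idx

    def protein_ca_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.topology.atoms)
                if a.name == "CA" and a.res_name != self.ligand_resname]

    def atom_index(self, name: str, resname: str | None = None) -> int:
        for i, a in enumerate(self.topology.atoms):
            if a.name == name and (resname is None or a.res_name == resname):
                return i
        raise ValueError(f"unknown atom name {name!r}" + (f" in {resname}" if resname else ""))


def ligand_rmsd_series(fs: FrameSeries, ref_frame: int = 0) -> np.ndarray:
    """Ligand heavy-atom RMSD per frame after protein-Cα superposition on a reference.

    Each frame is rigidly superposed on the reference frame using protein CA
    atoms only; the RMSD is then computed over ligand heavy atoms with no
    further fitting, so genuine ligand excursions from the pose survive.
    """
    if len(fs.frames) < 2:
        raise ValueError("at least 2 frames required")
    ca = fs.protein_ca_indices()
    if len(ca) < 3:
        raise ValueError("need at least 3 protein CA atoms for superposition")
    lig = fs.ligand_indices()
    ref = fs.frames[ref_frame]
    out = np.empty(len(fs.frames))
    for i, frame in enumerate(fs.frames):
        rot, trans, _ = superpose(ref[ca], frame[ca])
        moved = frame[lig] @ rot.T + trans
        out[i] = np.sqrt(np.mean(np.sum((moved - ref[lig]) ** 2, axis=1)))
    return out


@dataclass
class ContactMap:
    """Residue × ligand-heavy-atom contact frequencies, max-normalized to 1."""

    residues: list[tuple[str, int, str]]      # protein residue ids (chain, seq, icode)
    residue_labels: list[str]
    ligand_atoms: list[str]                   # ligand heavy-atom names
    density: np.ndarray                       # shape (len(residues), len(ligand_atoms))
    raw_counts: np.ndarray = field(default=None, repr=False)

    def to_tsv(self) -> str:
        lines = ["residue\t" + "\t".join(self.ligand_atoms)]
        for lab, row in zip(self.residue_labels, self.density):
            lines.append(lab + "\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


def contact_map(fs: FrameSeries, cutoff: float = 4.0) -> ContactMap:
    """Close-contact frequency of every (protein residue, ligand heavy atom) pair.

    A contact is counted in a frame when the minimum distance from the ligand
    atom to any heavy atom of the residue is <= ``cutoff``.  Counts are divided
    by the maximum count, so the most frequently observed contact is 1 (an
    all-zero map is returned unchanged when nothing is ever in contact).
    """
    if not fs.frames:
        raise ValueError("no frames")
    lig_idx = fs.ligand_indices()
    lig_names = [fs.topology.atoms[i].name for i in lig_idx]
    res_atoms: dict[tuple, list[int]] = {}
    for i, a in enumerate(fs.topology.atoms):
        if a.res_name == fs.ligand_resname or not a.is_heavy:
            continue
        res_atoms.setdefault(a.residue_id, []).append(i)
    residues = list(res_atoms)
    counts = np.zeros((len(residues), len(lig_idx)))
    for frame in fs.frames:
        lig_xyz = frame[lig_idx]
        for ri, rid in enumerate(residues):
            rx = frame[res_atoms[rid]]
            d = np.linalg.norm(rx[:, None, :] - lig_xyz[None, :, :], axis=2).min(axis=0)
            counts[ri] += d <= cutoff
    peak = counts.max()
    density = counts / peak if peak > 0 else counts.copy()
    labels = [f"{fs.topology.atoms[res_atoms[rid][0]].res_name}{rid[1]}" for rid in residues]
    return ContactMap(residues=residues, residue_labels=labels,
                      ligand_atoms=lig_names, density=density, raw_counts=counts)


@dataclass(frozen=True)
class HBondSpec:
    """Named donor-heavy/hydrogen/acceptor triple with geometric criteria."""

    donor: str
    hydrogen: str
    acceptor: str
    distance_cutoff: float = 3.5      # donor-acceptor heavy-atom distance, Å
    angle_cutoff: float = 30.0        # deviation from linear D-H...A, degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def hbond_occupancy(fs: FrameSeries, bonds: Sequence[HBondSpec]) -> dict[HBondSpec, float]:
    """Fraction of frames in which each hydrogen bond is formed.

    Formed means donor–acceptor distance <= ``distance_cutoff`` and the
    D-H···A angle within ``angle_cutoff`` of linear (180°).
    """
    out = {}
    for b in bonds:
        di = fs.atom_index(b.donor)
        hi = fs.atom_index(b.hydrogen)
        ai = fs.atom_index(b.acceptor)
        formed = 0
        for frame in fs.frames:
            d_xyz, h_xyz, a_xyz = frame[di], frame[hi], frame[ai]
            if np.linalg.norm(d_xyz - a_xyz) > b.distance_cutoff:
                continue
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cos_a = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0)))
            if angle >= 180.0 - b.angle_cutoff:
                formed += 1
        out[b] = formed / len(fs.frames)
    return out


def pose_stability(rmsd: np.ndarray, stable_thresh: float = 2.0,
                   fraction: float = 0.8) -> str:
    """Classify a ligand RMSD series as stable / semi-stable / unstable.

    Stable when at least ``fraction`` of frames lie below ``stable_thresh``;
    unstable when fewer than ``fraction/2`` do; semi-stable in between —
    a coarse classification mirroring the qualitative language used for
    persistent, intermittent, and lost binding poses.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if rmsd.size == 0:
        raise ValueError("empty RMSD series")
    below = float(np.mean(rmsd < stable_thresh))
    if below >= fraction:
        return "stable"
    if below < fraction / 2.0:
        return "unstable"
    return "semi-stable"
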