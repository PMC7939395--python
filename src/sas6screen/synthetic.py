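"""Seeded generators emulating the study's inputs: interface, library, spectra, frames.

Each generator is a pure function of a :class:`SyntheticSpec` — identical specs
produce bit-identical outputs — and returns ground-truth metadata sufficient to
score downstream recovery.  The geometry emulates a loop-into-pocket dimer
interface (a buried apolar loop tip plus backbone hydrogen bonds along the
pocket rim), libraries with planted pharmacophore-matching binders among
decoys, fast-exchange 1:1 titration peak lists, and frame series with planted
stable / semi-stable / unstable ligand poses.  Idealized pseudo-residue
geometry is used throughout: the planted distances are exactly what the
analysis operators measure, with no attempt at force-field realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .nmr import PeakList, TitrationSeries, binding_isotherm
from .pharmacophore import ConformerSet, Feature, FeaturePoint, PharmacophoreModel
from .structures import AtomRecord, Structure
from .trajectory import FrameSeries

__all__ = [
    "SyntheticSpec",
    "make_toy_interface",
    "make_ligand_library",
    "make_titration_peaks",
    "make_trajectory",
    "make_toy_complex",
    "make_peaklist_pair",
    "make_chain_structure",
    "make_hbond_frames",
    "make_contact_frames",
]

# Combined-CSP value of a (1, 2) ppm ¹H/¹⁵N split of unit amplitude:
# sqrt((1 + 0.14*4)/2).  Planted effects use this fixed split.
_SPLIT_NORM = float(np.sqrt((1.0 + 0.14 * 4.0) / 2.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters controlling every generator (the planted study conditions)."""

    seed: int = 0
    # counts
    n_residues: int = 50
    n_binders: int = 1
    n_decoys: int = 20
    n_frames: int = 100
    n_conformers: int = 2
    # binding / titration (fast-exchange 1:1)
    kd: float = 2e-3                   # molar — millimolar-range binder
    dmax: float = 0.15                 # ppm, saturating combined shift
    protein_conc: float = 1e-4         # molar (0.1 mM NMR samples)
    concentrations: tuple[float, ...] = (1.25e-4, 2.5e-4, 5e-4, 1e-3, 2e-3)
    titration_noise_frac: float = 0.02  # Δδ noise as fraction of dmax
    csp_noise: float = 0.005           # ppm, off-site combined-shift noise
    site_residues: tuple[int, ...] = (10, 11, 12, 20, 21, 22, 30, 31)
    # screening library
    feature_jitter: float = 0.25       # Å, binder feature-point placement error
    # trajectory
    coord_jitter: float = 0.5          # Å, stable-pose ligand jitter
    protein_jitter: float = 0.1        # Å, protein jitter in frames
    planted_displacement: float = 4.0  # Å, semi-stable second state offset
    semi_occupancy: float = 0.6        # fraction of frames in the bound state
    contact_occupancy: float = 0.7     # planted H-bond / contact frame fraction

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _atom(serial, name, res_name, chain, res_seq, xyz, element=None) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, res_name=res_name, chain_id=chain,
                      res_seq=res_seq, xyz=np.array(xyz, dtype=float),
                      element=element or name[0])


# ---------------------------------------------------------------------------
# Toy dimer interface
# ---------------------------------------------------------------------------

def make_toy_interface(spec: SyntheticSpec, minimal: bool = False) -> tuple[Structure, dict]:
    """Two-chain loop-into-pocket interface with planted contacts.

    Chain A (receptor): four apolar pocket-wall pseudo-residues around a
    cavity, a rim backbone carbonyl (C=O) and a rim backbone amide (N-H).
    Chain B ('ligand' loop, residues 101-104): a proline-like apolar residue,
    an isoleucine-like tip whose side chain sits in the pocket, a serine-like
    residue whose amide H donates to the rim carbonyl, and a lysine-like
    residue whose carbonyl accepts from the rim amide, plus one more apolar
    side chain on the pocket edge.

    With ``minimal=True`` only the tip apolar contact and the N-H···O=C pair
    are present (one hydrophobic + one donor feature).  Coordinates are exact
    (no noise); planted distances are returned in the metadata.
    """
    atoms: list[AtomRecord] = []
    serial = iter(range(1, 1000))

    # --- chain A: pocket walls (residues 1-4, LEU-like, carbons only)
    for k, theta in enumerate(np.deg2rad([0.0, 90.0, 180.0, 270.0])):
        c, s = np.cos(theta), np.sin(theta)
        atoms.append(_atom(next(serial), "CA", "LEU", "A", k + 1, [6.0 * c, 6.0 * s, -1.0], "C"))
        atoms.append(_atom(next(serial), "CB", "LEU", "A", k + 1, [4.0 * c, 4.0 * s, -1.0], "C"))
        atoms.append(_atom(next(serial), "CG", "LEU", "A", k + 1, [4.3 * c, 4.3 * s, -2.3], "C"))

    # --- chain A: rim carbonyl (residue 5) — acceptor for the ligand donor
    rim_c = np.array([3.2, -3.2, 1.2])
    co_dir = np.array([-0.276, 0.276, 0.920])
    co_dir /= np.linalg.norm(co_dir)
    rim_o = rim_c + 1.23 * co_dir
    atoms.append(_atom(next(serial), "C", "GLY", "A", 5, rim_c, "C"))
    atoms.append(_atom(next(serial), "O", "GLY", "A", 5, rim_o, "O"))

    # --- chain A: rim amide (residue 6) — donor toward the ligand acceptor
    rim_n = np.array([-3.0, -2.0, 2.0])
    nh_dir = np.array([1.0, 0.6, 1.0])
    nh_dir /= np.linalg.norm(nh_dir)
    if not minimal:
        atoms.append(_atom(next(serial), "N", "THR", "A", 6, rim_n, "N"))
        atoms.append(_atom(next(serial), "H", "THR", "A", 6, rim_n + 1.0 * nh_dir, "H"))

    # --- chain B residue 102: ILE-like tip buried in the pocket
    atoms.append(_atom(next(serial), "N", "ILE", "B", 102, [0.6, -2.0, 4.2], "N"))
    atoms.append(_atom(next(serial), "CA", "ILE", "B", 102, [0.0, -1.2, 3.4], "C"))
    atoms.append(_atom(next(serial), "CB", "ILE", "B", 102, [0.0, 0.0, 0.8], "C"))
    atoms.append(_atom(next(serial), "CG1", "ILE", "B", 102, [0.0, 0.0, -0.6], "C"))
    atoms.append(_atom(next(serial), "CD1", "ILE", "B", 102, [0.8, 0.4, -1.8], "C"))

    # --- chain B residue 103: SER-like, backbone N-H donating to the rim carbonyl
    ser_n = rim_o + 2.9 * co_dir
    ser_h = ser_n - 1.0 * co_dir
    atoms.append(_atom(next(serial), "CA", "SER", "B", 103, ser_n + [-0.8, 0.6, 1.1], "C"))
    atoms.append(_atom(next(serial), "N", "SER", "B", 103, ser_n, "N"))
    atoms.append(_atom(next(serial), "H", "SER", "B", 103, ser_h, "H"))

    if not minimal:
        # --- chain B residue 101: PRO-like apolar contact at the pocket mouth
        atoms.append(_atom(next(serial), "CA", "PRO", "B", 101, [2.5, 2.0, 3.0], "C"))
        atoms.append(_atom(next(serial), "N", "PRO", "B", 101, [3.0, 1.2, 3.8], "N"))
        atoms.append(_atom(next(serial), "CB", "PRO", "B", 101, [2.8, 2.0, 1.0], "C"))
        atoms.append(_atom(next(serial), "CG", "PRO", "B", 101, [3.4, 2.6, 0.2], "C"))

        # --- chain B residue 104: LYS-like; carbonyl accepts from the rim amide,
        #     apolar CB/CG contact the opposite pocket wall
        lys_o = rim_n + 2.9 * nh_dir
        atoms.append(_atom(next(serial), "CA", "LYS", "B", 104, [-2.5, -0.5, 5.5], "C"))
        atoms.append(_atom(next(serial), "C", "LYS", "B", 104, lys_o + [-0.79, -0.33, 0.51], "C"))
        atoms.append(_atom(next(serial), "O", "LYS", "B", 104, lys_o, "O"))
        atoms.append(_atom(next(serial), "CB", "LYS", "B", 104, [-3.2, 0.5, 1.8], "C"))
        atoms.append(_atom(next(serial), "CG", "LYS", "B", 104, [-3.0, 0.2, 1.2], "C"))

    s = Structure(atoms=atoms)
    tip = [a.xyz for a in atoms if a.chain_id == "B" and a.res_seq == 102]
    walls = [a.xyz for a in atoms if a.chain_id == "A" and a.name in ("CB", "CG")]
    meta = {
        "tip_residue": ("B", 102, ""),
        "tip_pocket_distance": float(min(np.linalg.norm(t - w) for t in tip for w in walls)),
        "donor_h": ser_h.tolist(),
        "donor_vector": (-co_dir).tolist(),       # planted H -> acceptor direction
        "rim_acceptor": rim_o.tolist(),
        "rim_donor": rim_n.tolist(),
        "minimal": minimal,
    }
    return s, meta


# ---------------------------------------------------------------------------
# Screening library with planted binders
# ---------------------------------------------------------------------------

_KIND_ELEMENT = {"hydrophobic": "C", "aromatic": "C", "donor": "N", "acceptor": "O"}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _chain_mol(elements: list[str]) -> Chem.Mol:
    """A simple connected graph (single-bond chain) carrying one atom per feature."""
    em = Chem.RWMol()
    for e in elements:
        em.AddAtom(Chem.Atom(e))
    for i in range(len(elements) - 1):
        em.AddBond(i, i + 1, Chem.BondType.SINGLE)
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _with_conformer(mol: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol = Chem.Mol(mol)
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    return mol


def make_ligand_library(model: PharmacophoreModel, n_binders: int, n_decoys: int,
                        spec: SyntheticSpec) -> list[ConformerSet]:
    """Planted binders plus decoys for a given pharmacophore model.

    Binders carry feature points on every model feature center (jittered by at
    most ``feature_jitter``, capped at half the feature radius, and rigidly
    re-oriented so the fit is non-trivial) and a consistent chain-graph
    molecule whose atoms sit at those points.  Decoys are random graphs and
    coordinates lacking any donor point, so they can never satisfy a mandatory
    core that includes a donor.  Ground truth is in ``meta['is_binder']``.
    """
    if n_binders + n_decoys == 0:
        raise ValueError("empty library requested")
    if not model.features:
        raise ValueError("empty pharmacophore model")
    rng = spec.rng()
    library: list[ConformerSet] = []

    for b in range(n_binders):
        confs, points = [], []
        for _ in range(spec.n_conformers):
            rot = _random_rotation(rng)
            shift = rng.uniform(-10.0, 10.0, size=3)
            pts, kinds = [], []
            for f in model.features:
                jit = rng.normal(size=3)
                jit *= min(spec.feature_jitter, f.radius / 2.0) / max(np.linalg.norm(jit), 1e-12)
                jit *= rng.uniform(0.0, 1.0)
                center = (f.center + jit) @ rot.T + shift
                direction = None if f.direction is None else f.direction @ rot.T
                kind = "aromatic" if f.kind == "aromatic" else f.kind
                pts.append(FeaturePoint(kind, center, direction))
                kinds.append(kind)
            coords = np.stack([p.point for p in pts])
            confs.append(coords)
            points.append(pts)
        mol = _chain_mol([_KIND_ELEMENT[k] for k in kinds])
        mol.SetProp("_Name", f"binder-{b:02d}")
        library.append(ConformerSet(compound_id=f"binder-{b:02d}", molecule=_with_conformer(mol, confs[0]),
                                    conformers=confs, feature_points=points,
                                    meta={"is_binder": True}))

    decoy_kinds = ["hydrophobic", "aromatic", "acceptor"]
    for d in range(n_decoys):
        n_points = int(rng.integers(4, 8))
        confs, points = [], []
        kinds = [decoy_kinds[int(rng.integers(0, len(decoy_kinds)))] for _ in range(n_points)]
        for _ in range(spec.n_conformers):
            coords = rng.uniform(-4.0, 4.0, size=(n_points, 3))
            confs.append(coords)
            points.append([FeaturePoint(k, xyz) for k, xyz in zip(kinds, coords)])
        mol = _chain_mol([_KIND_ELEMENT[k] for k in kinds])
        mol.SetProp("_Name", f"decoy-{d:02d}")
        library.append(ConformerSet(compound_id=f"decoy-{d:02d}", molecule=_with_conformer(mol, confs[0]),
                                    conformers=confs, feature_points=points,
                                    meta={"is_binder": False}))
    return library


# ---------------------------------------------------------------------------
# Titration peak lists
# ---------------------------------------------------------------------------

def _apo_peaks(rng: np.random.Generator, n_residues: int) -> dict[int, tuple[float, float]]:
    return {r: (float(rng.uniform(7.0, 9.5)), float(rng.uniform(105.0, 130.0)))
            for r in range(1, n_residues + 1)}


def _split(delta: float) -> tuple[float, float]:
    """Split a combined Δδ into (ΔδH, ΔδN) with the fixed 1:2 ppm ratio."""
    a = delta / _SPLIT_NORM
    return a, 2.0 * a


def make_titration_peaks(spec: SyntheticSpec,
                         site_residues: tuple[int, ...] | None = None,
                         dmax_map: dict[int, float] | None = None) -> tuple[list[PeakList], dict]:
    """Apo peak list plus one list per ligand concentration (fast-exchange 1:1).

    Site residues move along the binding isotherm (Δδmax from ``dmax_map`` or
    the spec default), split into ¹H/¹⁵N components at a fixed 1:2 ppm ratio;
    every residue additionally receives Gaussian measurement noise
    (σ = ``titration_noise_frac·dmax`` on the combined scale for site residues,
    ``csp_noise`` for off-site residues).  Returns the peak lists (apo first)
    and ground-truth metadata.
    """
    rng = spec.rng()
    site = tuple(site_residues if site_residues is not None else spec.site_residues)
    apo = _apo_peaks(rng, spec.n_residues)
    dmax = {r: (dmax_map.get(r, spec.dmax) if dmax_map else spec.dmax) for r in site}
    lists = [PeakList(entries=dict(apo), condition="apo")]
    for L in spec.concentrations:
        entries = {}
        for r, (h0, n0) in apo.items():
            if r in site:
                delta = float(binding_isotherm(L, spec.protein_conc, spec.kd, dmax[r]))
                delta += float(rng.normal(0.0, spec.titration_noise_frac * dmax[r]))
                dh, dn = _split(max(delta, 0.0))
            else:
                dh = float(rng.normal(0.0, spec.csp_noise))
                dn = float(rng.normal(0.0, 2.0 * spec.csp_noise))
            entries[r] = (h0 + dh, n0 + dn)
        lists.append(PeakList(entries=entries, condition=f"L={L:g}M"))
    meta = {"kd": spec.kd, "dmax": dmax, "site": site,
            "concentrations": list(spec.concentrations), "protein_conc": spec.protein_conc}
    return lists, meta


def titration_series_from_peaks(lists: list[PeakList], spec: SyntheticSpec,
                                concentrations: tuple[float, ...] | None = None) -> TitrationSeries:
    """Assemble a TitrationSeries (per-residue Δδ vs apo) from generated peak lists."""
    from .nmr import combined_csp
    apo = lists[0]
    conc = np.asarray(concentrations if concentrations is not None else spec.concentrations)
    deltas: dict[int, np.ndarray] = {}
    for r in apo.entries:
        row = []
        for pl in lists[1:]:
            h0, n0 = apo.entries[r]
            h1, n1 = pl.entries[r]
            row.append(combined_csp(h1 - h0, n1 - n0))
        deltas[r] = np.array(row)
    return TitrationSeries(concentrations=conc, deltas=deltas,
                           protein_conc=spec.protein_conc)


def make_peaklist_pair(spec: SyntheticSpec,
                       shifts: dict[int, tuple[float, float]]) -> tuple[PeakList, PeakList]:
    """Apo/holo pair: planted (ΔδH, ΔδN) shifts on selected residues, noise elsewhere."""
    rng = spec.rng()
    apo_entries = _apo_peaks(rng, spec.n_residues)
    holo_entries = {}
    for r, (h0, n0) in apo_entries.items():
        if r in shifts:
            dh, dn = shifts[r]
        else:
            dh = float(rng.normal(0.0, spec.csp_noise))
            dn = float(rng.normal(0.0, 2.0 * spec.csp_noise))
        holo_entries[r] = (h0 + dh, n0 + dn)
    return (PeakList(entries=apo_entries, condition="apo"),
            PeakList(entries=holo_entries, condition="holo"))


def make_chain_structure(spec: SyntheticSpec, n_residues: int | None = None,
                         chain: str = "A") -> Structure:
    """CA-only chain with 3.8 Å spacing along a gentle helix (for site mapping)."""
    n = n_residues or spec.n_residues
    atoms = []
    for r in range(1, n + 1):
        t = r * 0.6
        xyz = [8.0 * np.cos(t), 8.0 * np.sin(t), 2.4 * t]
        atoms.append(_atom(r, "CA", "GLY", chain, r, xyz, "C"))
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_toy_complex(spec: SyntheticSpec) -> Structure:
    """Minimal protein-ligand complex: CA scaffold, pocket atoms, 4-atom ligand.

    The ligand C1 atom is the planted deepest contact (2.2 Å from the pocket
    CB of residue 3); other ligand atoms sit 3.6+ Å from protein heavy atoms.
    """
    atoms = []
    serial = iter(range(1, 100))
    ca_positions = [(-8, -8, 0), (8, -8, 0), (-8, 8, 0), (8, 8, 0), (0, -9, 5), (0, 9, 5)]
    for r, xyz in enumerate(ca_positions, start=1):
        atoms.append(_atom(next(serial), "CA", "GLY", "A", r, xyz, "C"))
    # pocket side chain of residue 3 and an acceptor carbonyl on residue 5
    atoms.append(_atom(next(serial), "CB", "LEU", "A", 7, [0.0, 0.0, -2.2], "C"))
    atoms.append(_atom(next(serial), "CG", "LEU", "A", 7, [1.2, 0.4, -3.2], "C"))
    atoms.append(_atom(next(serial), "O", "GLY", "A", 8, [0.0, 2.9, 1.9], "O"))
    # ligand (residue LIG 900): C1 deep contact, C2/N1/O1 peripheral, H1 on N1
    atoms.append(_atom(next(serial), "C1", "LIG", "L", 900, [0.0, 0.0, 0.0], "C"))
    atoms.append(_atom(next(serial), "C2", "LIG", "L", 900, [1.4, 0.0, 0.6], "C"))
    atoms.append(_atom(next(serial), "N1", "LIG", "L", 900, [0.0, 0.9, 1.9], "N"))
    atoms.append(_atom(next(serial), "H1", "LIG", "L", 900, [0.0, 1.9, 1.9], "H"))
    atoms.append(_atom(next(serial), "O1", "LIG", "L", 900, [-1.2, -0.6, 0.8], "O"))
    return Structure(atoms=atoms)


def make_trajectory(complex_structure: Structure, mode: str, n_frames: int | None,
                    spec: SyntheticSpec, ligand_resname: str = "LIG") -> FrameSeries:
    """Frame series with a planted stable, semi-stable, or unstable ligand pose.

    stable — ligand jitter σ = ``coord_jitter`` about the pose;
    semi — two-state hopping between the pose and a state displaced by
    ``planted_displacement``, bound-state occupancy ``semi_occupancy``;
    unstable — steady drift out of the pocket (0.15·displacement per frame)
    plus jitter.  The protein receives σ = ``protein_jitter`` everywhere.
    """
    if mode not in ("stable", "semi", "unstable"):
        raise ValueError(f"unknown mode {mode!r}")
    n = n_frames or spec.n_frames
    rng = spec.rng()
    lig_mask = np.array([a.res_name == ligand_resname for a in complex_structure.atoms])
    if not lig_mask.any():
        raise ValueError(f"complex has no {ligand_resname!r} residue")
    base = complex_structure.coords()
    escape = np.array([0.3, 0.5, 0.8])
    escape /= np.linalg.norm(escape)
    frames = []
    for t in range(n):
        coords = base + rng.normal(0.0, spec.protein_jitter, size=base.shape)
        lig_jitter = rng.normal(0.0, spec.coord_jitter, size=(int(lig_mask.sum()), 3))
        offset = np.zeros(3)
        if t > 0:
            if mode == "semi" and rng.uniform() > spec.semi_occupancy:
                offset = spec.planted_displacement * escape
            elif mode == "unstable":
                offset = 0.15 * spec.planted_displacement * t * escape
        coords[lig_mask] = base[lig_mask] + offset + lig_jitter
        frames.append(coords)
    return FrameSeries(topology=complex_structure, frames=frames,
                       ligand_resname=ligand_resname)


def make_hbond_frames(spec: SyntheticSpec, occupancy: float | None = None,
                      n_frames: int | None = None) -> tuple[FrameSeries, dict]:
    """Frames in which a single N1-H1···OAC hydrogen bond is formed per-frame
    with the planted Bernoulli probability (ideal linear geometry when formed,
    acceptor displaced to 6 Å otherwise)."""
    occ = spec.contact_occupancy if occupancy is None else occupancy
    n = n_frames or spec.n_frames
    rng = spec.rng()
    atoms = [
        _atom(1, "CA", "GLY", "A", 1, [-6, 0, 0], "C"),
        _atom(2, "CA", "GLY", "A", 2, [6, 0, 0], "C"),
        _atom(3, "CA", "GLY", "A", 3, [0, 6, 0], "C"),
        _atom(4, "OAC", "GLY", "A", 4, [0, 0, 2.9], "O"),
        _atom(5, "N1", "LIG", "L", 900, [0, 0, 0], "N"),
        _atom(6, "H1", "LIG", "L", 900, [0, 0, 1], "H"),
        _atom(7, "C9", "LIG", "L", 900, [1.4, 0, -0.5], "C"),
    ]
    topo = Structure(atoms=atoms)
    base = topo.coords()
    formed = rng.uniform(size=n) < occ
    frames = []
    for t in range(n):
        coords = base.copy()
        if not formed[t]:
            coords[3] = [0.0, 0.0, 6.0]
        frames.append(coords)
    return (FrameSeries(topology=topo, frames=frames, ligand_resname="LIG"),
            {"occupancy": occ, "formed_fraction": float(formed.mean())})


def make_contact_frames(spec: SyntheticSpec, occupancy_a: float = 0.5,
                        occupancy_b: float = 1.0,
                        n_frames: int | None = None) -> tuple[FrameSeries, dict]:
    """Frames with exact planted contact counts for two (residue, ligand atom) pairs.

    Ligand atom L1 contacts residue 1 in exactly ``round(occupancy_a·n)``
    frames (a seeded random subset) and L2 contacts residue 2 in exactly
    ``round(occupancy_b·n)`` frames, so the normalized contact map is known in
    closed form.
    """
    n = n_frames or spec.n_frames
    rng = spec.rng()
    atoms = [
        _atom(1, "CB", "LEU", "A", 1, [0, 0, 0], "C"),
        _atom(2, "CB", "VAL", "A", 2, [12, 0, 0], "C"),
        _atom(3, "L1", "LIG", "L", 900, [0, 0, 3.0], "C"),
        _atom(4, "L2", "LIG", "L", 900, [12, 0, 3.0], "C"),
    ]
    topo = Structure(atoms=atoms)
    base = topo.coords()
    k_a = round(occupancy_a * n)
    k_b = round(occupancy_b * n)
    in_a = np.zeros(n, dtype=bool)
    in_a[rng.permutation(n)[:k_a]] = True
    in_b = np.zeros(n, dtype=bool)
    in_b[rng.permutation(n)[:k_b]] = True
    frames = []
    for t in range(n):
        coords = base.copy()
        if not in_a[t]:
            coords[2] = [0.0, 0.0, 9.0]
        if not in_b[t]:
            coords[3] = [12.0, 0.0, 9.0]
        frames.append(coords)
    return (FrameSeries(topology=topo, frames=frames, ligand_resname="LIG"),
            {"count_a": int(k_a), "count_b": int(k_b), "n_frames": n})
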