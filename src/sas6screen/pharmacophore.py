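"""Interface-derived pharmacophore modelling and rigid-body virtual screening.

The dimerization interface of the SAS-6 head domain — a loop residue buried in
a hydrophobic pocket plus backbone hydrogen bonds along the pocket rim — is
abstracted into a small set of typed, located interaction features
(hydrophobic, aromatic, hydrogen-bond donor/acceptor) complemented by
exclusion spheres on the receptor van der Waals surface.  Ligand conformers
are reduced to typed feature points, rigid-body fitted onto every sub-model of
at least ``min_match`` features that contains a mandatory core, and ranked by
a Gaussian-overlap goodness of fit.

The fit is exact on desk-scale inputs: the correspondence search enumerates
all type-compatible injective mappings (with pairwise-distance pruning that
never discards a feasible mapping), and each mapping is scored after a
closed-form least-squares superposition.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .structures import AtomRecord, Structure, superpose

__all__ = [
    "Feature",
    "PharmacophoreModel",
    "SubModel",
    "FeaturePoint",
    "ConformerSet",
    "FitResult",
    "derive_model",
    "enumerate_submodels",
    "extract_ligand_features",
    "fit_conformer",
    "screen",
]

FEATURE_KINDS = ("hydrophobic", "aromatic", "donor", "acceptor", "exclusion")

# Which ligand point kinds may satisfy which model feature kinds.  Aromatic
# ligand groups may satisfy hydrophobic features (mixed aromatic/hydrophobic
# features at the pocket mouth), but a plain aliphatic group cannot satisfy an
# aromatic feature.
_COMPATIBLE = {
    "hydrophobic": ("hydrophobic", "aromatic"),
    "aromatic": ("aromatic",),
    "donor": ("donor",),
    "acceptor": ("acceptor",),
}

_VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
              "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}

DEFAULT_RADII = {"hydrophobic": 1.5, "aromatic": 1.5, "donor": 1.0, "acceptor": 1.0}
DEFAULT_ANGLE_TOL = 45.0  # degrees, between ligand and model H-bond vectors


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass
class Feature:
    """A typed interaction feature: center, tolerance radius, optional direction."""

    kind: str
    center: np.ndarray
    radius: float
    direction: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")
        self.center = np.asarray(self.center, dtype=float)
        if self.direction is not None:
            if self.kind == "exclusion":
                raise ValueError("exclusion features carry no direction")
            self.direction = _unit(np.asarray(self.direction, dtype=float))

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "center": [round(float(x), 6) for x in self.center],
             "radius": float(self.radius), "label": self.label}
        if self.direction is not None:
            d["direction"] = [round(float(x), 6) for x in self.direction]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Feature":
        return cls(kind=d["kind"], center=np.array(d["center"]), radius=d["radius"],
                   direction=np.array(d["direction"]) if "direction" in d else None,
                   label=d.get("label", ""))


@dataclass
class PharmacophoreModel:
    """Positive features plus exclusion spheres, with a mandatory feature core."""

    features: list[Feature]
    exclusions: list[Feature] = field(default_factory=list)
    mandatory: frozenset[int] = frozenset()
    min_match: int = 5

    def __post_init__(self):
        self.mandatory = frozenset(self.mandatory)
        if any(f.kind == "exclusion" for f in self.features):
            raise ValueError("exclusion features belong in .exclusions")
        if any(f.kind != "exclusion" for f in self.exclusions):
            raise ValueError("only exclusion features belong in .exclusions")
        if not self.mandatory <= set(range(len(self.features))):
            raise ValueError("mandatory indices outside feature list")

    def to_json(self) -> str:
        return json.dumps({
            "features": [f.to_dict() for f in self.features],
            "exclusions": [f.to_dict() for f in self.exclusions],
            "mandatory": sorted(self.mandatory),
            "min_match": self.min_match,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        d = json.loads(text)
        return cls(features=[Feature.from_dict(f) for f in d["features"]],
                   exclusions=[Feature.from_dict(f) for f in d["exclusions"]],
                   mandatory=frozenset(d["mandatory"]), min_match=d["min_match"])


@dataclass(frozen=True)
class SubModel:
    """A feature-index subset of a model (>= min_match, contains the mandatory core)."""

    model: PharmacophoreModel
    indices: tuple[int, ...]

    @property
    def features(self) -> list[Feature]:
        return [self.model.features[i] for i in self.indices]

    @property
    def exclusions(self) -> list[Feature]:
        return self.model.exclusions


@dataclass
class FeaturePoint:
    """A typed feature point extracted from one ligand conformer."""

    kind: str
    point: np.ndarray
    direction: np.ndarray | None = None

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        if self.direction is not None:
            self.direction = _unit(np.asarray(self.direction, dtype=float))


@dataclass
class ConformerSet:
    """One compound: topology, 3-D conformers, and per-conformer feature points."""

    compound_id: str
    molecule: Chem.Mol | None
    conformers: list[np.ndarray]
    feature_points: list[list[FeaturePoint]] | None = None
    meta: dict = field(default_factory=dict)
    max_conformers: int = 250

    def __post_init__(self):
        if len(self.conformers) > self.max_conformers:
            raise ValueError(f"more than {self.max_conformers} conformers")
        if self.feature_points is not None and len(self.feature_points) != len(self.conformers):
            raise ValueError("feature_points must align with conformers")

    @classmethod
    def from_mol(cls, mol: Chem.Mol, compound_id: str | None = None) -> "ConformerSet":
        from .chem import mol_id
        coords = [np.array(c.GetPositions(), dtype=float) for c in mol.GetConformers()]
        if not coords:
            raise ValueError("molecule has no 3-D conformers")
        return cls(compound_id=compound_id or mol_id(mol), molecule=mol, conformers=coords)

    def points(self, i: int) -> list[FeaturePoint]:
        if self.feature_points is not None:
            return self.feature_points[i]
        return extract_ligand_features(self.molecule, self.conformers[i])


@dataclass
class FitResult:
    """Best rigid-body placement of one conformer onto one sub-model."""

    submodel: tuple[int, ...]
    conformer: int
    correspondence: list[tuple[int, int]]  # (ligand point index, model feature index)
    rotation: np.ndarray
    translation: np.ndarray
    score: float
    clash: bool = False

    @property
    def matched(self) -> int:
        return len(self.correspondence)


# ---------------------------------------------------------------------------
# Model derivation from a protein-protein complex
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _is_apolar(a: AtomRecord) -> bool:
    return a.element.upper() in ("C", "S") and a.is_heavy


def _vdw(a: AtomRecord) -> float:
    return _VDW_RADII.get(a.element.upper(), 1.7)


def _merge_features(feats: list[Feature], min_dist: float) -> list[Feature]:
    """Union same-kind features closer than min_dist (centroid center, max radius)."""
    out = list(feats)
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(out)), 2):
            a, b = out[i], out[j]
            if a.kind == b.kind and np.linalg.norm(a.center - b.center) < min_dist:
                direction = None
                if a.direction is not None and b.direction is not None:
                    direction = _unit(a.direction + b.direction)
                new = Feature(kind=a.kind, center=(a.center + b.center) / 2,
                              radius=max(a.radius, b.radius), direction=direction,
                              label=f"{a.label}+{b.label}")
                out = [f for k, f in enumerate(out) if k not in (i, j)] + [new]
                merged = True
                break
    return out


def derive_model(complex_structure: Structure, ligand_chain: str, receptor_chain: str,
                 ligand_residues: Iterable[int] | None = None,
                 min_feature_distance: float = 1.5,
                 hydrophobic_range: float = 4.5, hbond_range: float = 3.5,
                 exclusion_range: float = 5.0, min_match: int = 5,
                 radii: dict[str, float] = DEFAULT_RADII) -> PharmacophoreModel:
    """Derive a pharmacophore model from a two-chain interface.

    The 'ligand' selection is a peptide segment (the loop that inserts into the
    pocket); the receptor chain provides the complementary surface.  Features:

    * hydrophobic — centroid of each ligand residue's apolar side-chain heavy
      atoms that touch (<= ``hydrophobic_range``) receptor apolar atoms;
    * donor — ligand N-H/O-H hydrogens whose heavy donor lies within
      ``hbond_range`` of a receptor acceptor (O, or N with no hydrogens);
      direction points at the acceptor;
    * acceptor — ligand O (or H-less N) atoms within ``hbond_range`` of a
      receptor donor nitrogen/hydroxyl; direction points at the donor;
    * exclusion — receptor heavy atoms within ``exclusion_range`` of any ligand
      atom, with element van der Waals radii.

    Same-kind features closer than ``min_feature_distance`` are merged
    (centroid, max radius).  The mandatory core is up to two
    hydrophobic/aromatic features plus the first donor, mirroring a
    pocket-insertion interaction that always requires the buried apolar group
    and one rim hydrogen bond.
    """
    lig_atoms = [a for a in complex_structure.chain(ligand_chain)
                 if ligand_residues is None or a.res_seq in ligand_residues]
    rec_atoms = complex_structure.chain(receptor_chain)
    if not lig_atoms or not rec_atoms:
        raise ValueError("empty ligand or receptor selection")

    rec_heavy = [a for a in rec_atoms if a.is_heavy]
    rec_apolar = np.array([a.xyz for a in rec_heavy if _is_apolar(a)]).reshape(-1, 3)

    def _near(xyz: np.ndarray, pool: np.ndarray, cutoff: float) -> bool:
        return pool.size > 0 and bool(np.min(np.linalg.norm(pool - xyz, axis=1)) <= cutoff)

    feats: list[Feature] = []

    # Hydrophobic: per ligand residue, apolar side-chain atoms in receptor contact.
    for res_id, atoms in _group_by_residue(lig_atoms).items():
        side = [a for a in atoms if _is_apolar(a) and a.name not in _BACKBONE]
        contact = [a for a in side if _near(a.xyz, rec_apolar, hydrophobic_range)]
        if contact:
            centroid = np.mean([a.xyz for a in contact], axis=0)
            feats.append(Feature("hydrophobic", centroid, radii["hydrophobic"],
                                 label=f"{atoms[0].res_name}{res_id[1]}"))

    # Hydrogen bond partners on the receptor side.
    rec_by_name = {(a.residue_id, a.name): a for a in rec_atoms}
    rec_acceptors = [a for a in rec_heavy if a.element.upper() == "O"
                     or (a.element.upper() == "N" and not _has_attached_h(a, rec_atoms))]
    rec_donors = [a for a in rec_heavy if a.element.upper() in ("N", "O")
                  and (_has_attached_h(a, rec_atoms) or a.name == "N")]

    lig_heavy = [a for a in lig_atoms if a.is_heavy]
    lig_hydrogens = [a for a in lig_atoms if not a.is_heavy]

    # Donors: ligand hydrogens on N/O whose parent lies in H-bond range of an acceptor.
    for h in lig_hydrogens:
        parent = _nearest(h, [a for a in lig_heavy if a.element.upper() in ("N", "O")], 1.3)
        if parent is None:
            continue
        for acc in rec_acceptors:
            if np.linalg.norm(parent.xyz - acc.xyz) <= hbond_range:
                feats.append(Feature("donor", h.xyz, radii["donor"],
                                     direction=acc.xyz - h.xyz,
                                     label=f"{parent.res_name}{parent.res_seq}-H..{acc.res_name}{acc.res_seq}"))
                break
    if not lig_hydrogens:
        # Crystal structures usually lack hydrogens: fall back on donor heavy atoms.
        for d in lig_heavy:
            if d.element.upper() != "N" and not (d.element.upper() == "O" and d.name not in _BACKBONE):
                continue
            for acc in rec_acceptors:
                if np.linalg.norm(d.xyz - acc.xyz) <= hbond_range:
                    feats.append(Feature("donor", d.xyz, radii["donor"],
                                         direction=acc.xyz - d.xyz,
                                         label=f"{d.res_name}{d.res_seq}..{acc.res_name}{acc.res_seq}"))
                    break

    # Acceptors: ligand O / H-less N near a receptor donor; direction toward the donor.
    for a in lig_heavy:
        is_acc = a.element.upper() == "O" or (
            a.element.upper() == "N" and not _has_attached_h(a, lig_atoms))
        if not is_acc:
            continue
        for don in rec_donors:
            if np.linalg.norm(a.xyz - don.xyz) <= hbond_range:
                feats.append(Feature("acceptor", a.xyz, radii["acceptor"],
                                     direction=don.xyz - a.xyz,
                                     label=f"{a.res_name}{a.res_seq}..{don.res_name}{don.res_seq}"))
                break

    feats = _merge_features(feats, min_feature_distance)
    # Deterministic order: kind then coordinates.
    feats.sort(key=lambda f: (f.kind, tuple(np.round(f.center, 4))))

    lig_xyz = np.array([a.xyz for a in lig_atoms]).reshape(-1, 3)
    exclusions = [Feature("exclusion", a.xyz, _vdw(a), label=f"{a.res_name}{a.res_seq}:{a.name}")
                  for a in rec_heavy if _near(a.xyz, lig_xyz, exclusion_range)]

    hydro_idx = [i for i, f in enumerate(feats) if f.kind in ("hydrophobic", "aromatic")]
    donor_idx = [i for i, f in enumerate(feats) if f.kind == "donor"]
    mandatory = frozenset(hydro_idx[:2] + donor_idx[:1])
    return PharmacophoreModel(features=feats, exclusions=exclusions, mandatory=mandatory,
                              min_match=min(min_match, max(len(feats), 1)))


def _group_by_residue(atoms: Sequence[AtomRecord]) -> dict:
    out: dict = {}
    for a in atoms:
        out.setdefault(a.residue_id, []).append(a)
    return out


def _nearest(h: AtomRecord, pool: Sequence[AtomRecord], cutoff: float) -> AtomRecord | None:
    best, best_d = None, cutoff
    for a in pool:
        d = float(np.linalg.norm(h.xyz - a.xyz))
        if d <= best_d:
            best, best_d = a, d
    return best


def _has_attached_h(a: AtomRecord, atoms: Sequence[AtomRecord]) -> bool:
    return any(not x.is_heavy and np.linalg.norm(x.xyz - a.xyz) <= 1.3 for x in atoms)


# ---------------------------------------------------------------------------
# Sub-model enumeration
# ---------------------------------------------------------------------------

def enumerate_submodels(model: PharmacophoreModel, min_match: int = 5,
                        cap: int | None = None) -> list[SubModel]:
    """All feature subsets of size >= min_match containing the mandatory core.

    Deterministic order: by subset size, then lexicographic on indices;
    truncated to ``cap`` when given.  Exclusion spheres ride along with every
    sub-model.
    """
    n = len(model.features)
    if min_match > n:
        raise ValueError(f"min_match ({min_match}) exceeds feature count ({n})")
    if len(model.mandatory) > n:
        raise ValueError("mandatory core larger than feature set")
    core = tuple(sorted(model.mandatory))
    rest = [i for i in range(n) if i not in model.mandatory]
    subs: list[SubModel] = []
    for size in range(min_match, n + 1):
        k = size - len(core)
        if k < 0:
            continue
        for extra in itertools.combinations(rest, k):
            subs.append(SubModel(model, tuple(sorted(core + extra))))
    subs.sort(key=lambda s: (len(s.indices), s.indices))
    if cap is not None:
        subs = subs[:cap]
    return subs


# ---------------------------------------------------------------------------
# Ligand feature extraction
# ---------------------------------------------------------------------------

def extract_ligand_features(mol: Chem.Mol, coords: np.ndarray) -> list[FeaturePoint]:
    """Type a small-molecule conformer into pharmacophore feature points.

    * donor — N/O/S bearing >= 1 H; point at the heavy atom, direction along
      the heavy-atom -> H bond when an explicit hydrogen is present;
    * acceptor — any non-cationic O, and N with a free lone pair (no attached
      H, charge <= 0, fewer than four connections);
    * hydrophobic — centroid of each connected group of >= 2 contiguous apolar
      heavy atoms (C/S/halogens with no bonded N/O);
    * aromatic — centroid + plane normal of each fully aromatic SSSR ring.
    """
    if mol is None:
        raise ValueError("molecule required for feature extraction")
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ValueError("coordinates do not match molecule atoms")
    points: list[FeaturePoint] = []

    h_neighbors = {a.GetIdx(): [n.GetIdx() for n in a.GetNeighbors() if n.GetAtomicNum() == 1]
                   for a in mol.GetAtoms()}

    for atom in mol.GetAtoms():
        idx, sym = atom.GetIdx(), atom.GetSymbol()
        if sym in ("N", "O", "S") and atom.GetTotalNumHs(includeNeighbors=True) > 0:
            direction = None
            if h_neighbors[idx]:
                direction = coords[h_neighbors[idx][0]] - coords[idx]
            points.append(FeaturePoint("donor", coords[idx], direction))
        if sym == "O" and atom.GetFormalCharge() <= 0:
            points.append(FeaturePoint("acceptor", coords[idx]))
        elif (sym == "N" and atom.GetFormalCharge() <= 0
              and atom.GetTotalNumHs(includeNeighbors=True) == 0
              and atom.GetTotalDegree() < 4):
            points.append(FeaturePoint("acceptor", coords[idx]))

    # Aromatic rings: fully aromatic SSSR rings.
    ring_atoms_in_aromatic: set[int] = set()
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            pts = coords[list(ring)]
            centroid = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - centroid)
            points.append(FeaturePoint("aromatic", centroid, vt[2]))
            ring_atoms_in_aromatic.update(ring)

    # Hydrophobic groups: connected apolar heavy atoms not in aromatic rings.
    apolar = set()
    for atom in mol.GetAtoms():
        if atom.GetIdx() in ring_atoms_in_aromatic:
            continue
        if atom.GetSymbol() in ("C", "S", "F", "Cl", "Br", "I"):
            if not any(n.GetSymbol() in ("N", "O") for n in atom.GetNeighbors()):
                apolar.add(atom.GetIdx())
    seen: set[int] = set()
    for start in sorted(apolar):
        if start in seen:
            continue
        group, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen or i not in apolar:
                continue
            seen.add(i)
            group.append(i)
            stack.extend(n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors())
        if len(group) >= 2:
            points.append(FeaturePoint("hydrophobic", coords[group].mean(axis=0)))
    return points


# ---------------------------------------------------------------------------
# Rigid-body fitting
# ---------------------------------------------------------------------------

def _pair_score(d: float, radius: float) -> float:
    return math.exp(-d * d / (2.0 * (radius / 2.0) ** 2))


def _evaluate_mapping(points: Sequence[FeaturePoint], sub_features: Sequence[Feature],
                      mapping: Sequence[int], atom_coords: np.ndarray | None,
                      exclusions: Sequence[Feature], angle_tol: float):
    """Score one injective ligand-point -> sub-model-feature mapping; None if invalid."""
    lig = np.stack([points[i].point for i in mapping])
    mod = np.stack([f.center for f in sub_features])
    try:
        rot, trans, _ = superpose(mod, lig)
    except ValueError:
        return None
    placed = lig @ rot.T + trans
    score = 0.0
    cos_tol = math.cos(math.radians(angle_tol))
    for k, f in enumerate(sub_features):
        d = float(np.linalg.norm(placed[k] - f.center))
        if d > f.radius:
            return None
        p = points[mapping[k]]
        if f.direction is not None and p.direction is not None:
            if float(np.dot(rot @ p.direction, f.direction)) < cos_tol:
                return None
        score += _pair_score(d, f.radius)
    clash = False
    if atom_coords is not None and len(exclusions):
        placed_atoms = atom_coords @ rot.T + trans
        centers = np.stack([e.center for e in exclusions])
        radii = np.array([e.radius for e in exclusions])
        dists = np.linalg.norm(placed_atoms[:, None, :] - centers[None, :, :], axis=2)
        clash = bool(np.any(dists < radii[None, :]))
    return rot, trans, score, clash


def fit_conformer(points: Sequence[FeaturePoint], sub: SubModel,
                  atom_coords: np.ndarray | None = None,
                  angle_tol: float = DEFAULT_ANGLE_TOL) -> FitResult | None:
    """Best rigid-body fit of one conformer's feature points onto a sub-model.

    Every feature of the sub-model must be satisfied by a distinct,
    type-compatible ligand point lying within the feature radius after the
    least-squares transform; directional features must agree within
    ``angle_tol`` degrees.  A placement whose heavy atoms enter any exclusion
    sphere is marked ``clash`` and never returned as the best fit if a
    clash-free placement exists.  Returns ``None`` when no valid placement
    exists (not an error).
    """
    sub_features = sub.features
    m = len(sub_features)
    if len(points) < m:
        return None
    candidates: list[list[int]] = []
    for f in sub_features:
        ok = [i for i, p in enumerate(points) if p.kind in _COMPATIBLE[f.kind]]
        if not ok:
            return None
        candidates.append(ok)

    mod_centers = np.stack([f.center for f in sub_features])
    mod_dist = np.linalg.norm(mod_centers[:, None] - mod_centers[None, :], axis=2)
    pts = np.stack([p.point for p in points])
    pts_dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    radii = np.array([f.radius for f in sub_features])

    best: FitResult | None = None

    def backtrack(k: int, mapping: list[int], used: set[int]):
        nonlocal best
        if k == m:
            res = _evaluate_mapping(points, sub_features, mapping, atom_coords,
                                    sub.exclusions, angle_tol)
            if res is None:
                return
            rot, trans, score, clash = res
            cand = FitResult(submodel=sub.indices, conformer=-1,
                             correspondence=[(mapping[i], sub.indices[i]) for i in range(m)],
                             rotation=rot, translation=trans, score=score, clash=clash)
            if _better(cand, best):
                best = cand
            return
        for i in candidates[k]:
            if i in used:
                continue
            # A feasible rigid placement keeps every pairwise residual within
            # the two feature radii, so this pruning is lossless.
            if any(abs(pts_dist[i, mapping[j]] - mod_dist[k, j]) > radii[k] + radii[j]
                   for j in range(k)):
                continue
            mapping.append(i)
            used.add(i)
            backtrack(k + 1, mapping, used)
            mapping.pop()
            used.remove(i)

    backtrack(0, [], set())
    return best


def _better(a: FitResult, b: FitResult | None) -> bool:
    if b is None:
        return True
    if a.clash != b.clash:
        return not a.clash
    return a.score > b.score


def screen(library: Sequence[ConformerSet], model: PharmacophoreModel,
           min_match: int = 5, cap: int | None = None,
           angle_tol: float = DEFAULT_ANGLE_TOL):
    """Rank a conformer library against a pharmacophore model.

    For each compound the best clash-free fit over all conformers x sub-models
    is retained.  Returns a pandas DataFrame sorted by score (descending, ties
    by compound id) with columns compound_id, score, matched, submodel,
    conformer, plus rank.
    """
    import pandas as pd

    if model is None or not model.features:
        raise ValueError("empty pharmacophore model")
    subs = enumerate_submodels(model, min_match=min_match, cap=cap)
    rows = []
    for cs in library:
        best: FitResult | None = None
        for ci in range(len(cs.conformers)):
            points = cs.points(ci)
            coords = cs.conformers[ci]
            for sub in subs:
                res = fit_conformer(points, sub, atom_coords=coords, angle_tol=angle_tol)
                if res is not None and not res.clash:
                    res.conformer = ci
                    if _better(res, best):
                        best = res
        if best is not None:
            rows.append({"compound_id": cs.compound_id, "score": best.score,
                         "matched": best.matched,
                         "submodel": ",".join(map(str, best.submodel)),
                         "conformer": best.conformer})
    df = pd.DataFrame(rows, columns=["compound_id", "score", "matched", "submodel", "conformer"])
    if not df.empty:
        df = df.sort_values(["score", "compound_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
    else:
        df.insert(0, "rank", np.array([], dtype=int))
    return df
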