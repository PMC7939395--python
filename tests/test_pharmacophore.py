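"""Pharmacophore derivation, sub-model enumeration, ligand typing, rigid fitting."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from sas6screen import pharmacophore as ph
from sas6screen import synthetic
from sas6screen.structures import Structure

from conftest import random_rigid


# ---------------------------------------------------------------------------
# Independent exhaustive fit oracle (no pruning, scipy-based superposition)
# ---------------------------------------------------------------------------

def _oracle_superpose(ref, mov):
    from scipy.spatial.transform import Rotation
    ref_c, mov_c = ref.mean(axis=0), mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    mat = rot.as_matrix()
    return mat, ref_c - mat @ mov_c


def oracle_best_fit(points, sub, angle_tol=45.0):
    """Brute-force maximum score over every type-compatible injective mapping."""
    feats = sub.features
    m = len(feats)
    compat = {"hydrophobic": ("hydrophobic", "aromatic"), "aromatic": ("aromatic",),
              "donor": ("donor",), "acceptor": ("acceptor",)}
    best = None
    for mapping in itertools.permutations(range(len(points)), m):
        if any(points[i].kind not in compat[f.kind] for i, f in zip(mapping, feats)):
            continue
        lig = np.stack([points[i].point for i in mapping])
        mod = np.stack([f.center for f in feats])
        rot, trans = _oracle_superpose(mod, lig)
        placed = lig @ rot.T + trans
        ok, score = True, 0.0
        for k, f in enumerate(feats):
            d = float(np.linalg.norm(placed[k] - f.center))
            if d > f.radius:
                ok = False
                break
            p = points[mapping[k]]
            if f.direction is not None and p.direction is not None:
                cosang = float(np.dot(rot @ p.direction, f.direction))
                if cosang < math.cos(math.radians(angle_tol)):
                    ok = False
                    break
            score += math.exp(-d * d / (2 * (f.radius / 2) ** 2))
        if ok and (best is None or score > best):
            best = score
    return best


def _random_case(rng, n_features=None, n_points=None):
    """A random small model plus ligand points (some matched, some extra)."""
    kinds = ["hydrophobic", "aromatic", "donor", "acceptor"]
    nf = n_features or int(rng.integers(3, 6))
    feats = []
    centers = rng.uniform(-4, 4, size=(nf, 3))
    # keep features separated so radii do not fully overlap
    centers *= 1.5
    for i in range(nf):
        kind = kinds[int(rng.integers(0, 4))]
        direction = rng.normal(size=3) if kind in ("donor", "acceptor") else None
        feats.append(ph.Feature(kind, centers[i], float(rng.uniform(0.8, 1.6)),
                                direction=direction))
    model = ph.PharmacophoreModel(features=feats, mandatory=frozenset(), min_match=nf)
    sub = ph.SubModel(model, tuple(range(nf)))
    rot, trans = random_rigid(rng)
    pts = []
    for f in feats:
        jitter = rng.normal(scale=0.2, size=3)
        direction = None if f.direction is None else f.direction @ rot.T
        pts.append(ph.FeaturePoint(f.kind, (f.center + jitter) @ rot.T + trans, direction))
    n_extra = (n_points or int(rng.integers(nf, 9))) - nf
    for _ in range(max(n_extra, 0)):
        pts.append(ph.FeaturePoint(kinds[int(rng.integers(0, 4))],
                                   rng.uniform(-8, 8, size=3) @ rot.T + trans))
    order = rng.permutation(len(pts))
    return [pts[i] for i in order], sub


class TestDeriveModel:
    def test_minimal_interface_one_hydrophobic_one_donor(self, spec):
        s, meta = synthetic.make_toy_interface(spec, minimal=True)
        model = ph.derive_model(s, "B", "A")
        kinds = sorted(f.kind for f in model.features)
        assert kinds == ["donor", "hydrophobic"]
        donor = next(f for f in model.features if f.kind == "donor")
        planted = np.array(meta["donor_vector"])
        angle = np.degrees(np.arccos(np.clip(np.dot(donor.direction, planted), -1, 1)))
        assert angle < 15.0

    def test_full_interface_feature_set(self, interface_model):
        kinds = [f.kind for f in interface_model.features]
        assert kinds.count("hydrophobic") >= 1 and kinds.count("donor") >= 1
        assert len(interface_model.exclusions) > 0
        assert len(interface_model.mandatory) == 3

    def test_translated_ligand_gives_empty_model(self, spec):
        s, _ = synthetic.make_toy_interface(spec)
        moved = Structure(atoms=[
            a if a.chain_id == "A" else _shift(a, 20.0) for a in s.atoms])
        model = ph.derive_model(moved, "B", "A")
        assert model.features == []

    def test_close_features_merged(self, spec):
        s, _ = synthetic.make_toy_interface(spec)
        # huge merge distance forces all three hydrophobic features into one
        model = ph.derive_model(s, "B", "A", min_feature_distance=20.0)
        assert sum(1 for f in model.features if f.kind == "hydrophobic") == 1

    def test_empty_selection_rejected(self, spec):
        s, _ = synthetic.make_toy_interface(spec)
        with pytest.raises(ValueError):
            ph.derive_model(s, "Z", "A")


def _shift(a, dx):
    from dataclasses import replace
    return replace(a, xyz=a.xyz + dx)


class TestEnumerateSubmodels:
    def _model(self, n, mandatory):
        feats = [ph.Feature("hydrophobic", [3.0 * i, 0, 0], 1.0) for i in range(n)]
        return ph.PharmacophoreModel(features=feats, mandatory=frozenset(mandatory))

    def test_counts_match_brute_force(self):
        model = self._model(10, {0, 1, 2})
        subs = ph.enumerate_submodels(model, min_match=5)
        # independent brute force over all subsets
        brute = [frozenset(c) for size in range(5, 11)
                 for c in itertools.combinations(range(10), size)
                 if {0, 1, 2} <= set(c)]
        assert len(subs) == len(brute) == 120
        assert {frozenset(s.indices) for s in subs} == set(brute)
        sizes = [len(s.indices) for s in subs]
        assert sizes == sorted(sizes)

    def test_min_match_equals_feature_count(self):
        model = self._model(6, {0})
        subs = ph.enumerate_submodels(model, min_match=6)
        assert len(subs) == 1 and subs[0].indices == tuple(range(6))

    def test_min_match_too_large_rejected(self):
        with pytest.raises(ValueError):
            ph.enumerate_submodels(self._model(4, set()), min_match=5)

    def test_cap_truncates_deterministic_order(self):
        model = self._model(8, {0})
        full = ph.enumerate_submodels(model, min_match=5)
        capped = ph.enumerate_submodels(model, min_match=5, cap=10)
        assert capped == full[:10]


class TestExtractLigandFeatures:
    def _embedded(self, smiles):
        m = Chem.AddHs(Chem.MolFromSmiles(smiles))
        AllChem.EmbedMolecule(m, randomSeed=4)
        return m, np.array(m.GetConformer().GetPositions())

    def test_benzene_single_aromatic_point_at_centroid(self):
        mol, coords = self._embedded("c1ccccc1")
        pts = ph.extract_ligand_features(mol, coords)
        aromatic = [p for p in pts if p.kind == "aromatic"]
        assert len(aromatic) == 1
        ring = [a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()]
        np.testing.assert_allclose(aromatic[0].point, coords[ring].mean(axis=0), atol=1e-8)

    def test_ethanol_donor_and_acceptor_on_oxygen(self):
        mol, coords = self._embedded("CCO")
        pts = ph.extract_ligand_features(mol, coords)
        o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        donors = [p for p in pts if p.kind == "donor"]
        acceptors = [p for p in pts if p.kind == "acceptor"]
        assert len(donors) == 1 and len(acceptors) == 1
        np.testing.assert_allclose(donors[0].point, coords[o_idx], atol=1e-8)
        np.testing.assert_allclose(acceptors[0].point, coords[o_idx], atol=1e-8)

    def test_sulfonyl_hydroxyl_aromatic_fixture(self):
        # aromatic ring + sulfonamide + terminal hydroxyl, A11-like topology
        mol, coords = self._embedded("OCCCNS(=O)(=O)c1ccc(Cl)cc1")
        pts = ph.extract_ligand_features(mol, coords)
        kinds = [p.kind for p in pts]
        assert kinds.count("aromatic") >= 1
        assert kinds.count("acceptor") >= 2     # the two sulfonyl oxygens
        assert kinds.count("donor") >= 1        # the hydroxyl (and the N-H)

    def test_no_coordinates_rejected(self):
        mol = Chem.MolFromSmiles("CCO")
        with pytest.raises(ValueError):
            ph.extract_ligand_features(mol, np.zeros((1, 3)))


class TestFitConformer:
    def _perfect_sub(self):
        feats = [
            ph.Feature("hydrophobic", [0, 0, 0], 1.5),
            ph.Feature("hydrophobic", [3, 0, 0], 1.5),
            ph.Feature("aromatic", [0, 3, 0], 1.5),
            ph.Feature("donor", [0, 0, 3], 1.0, direction=[0, 0, 1]),
            ph.Feature("acceptor", [3, 3, 0], 1.0, direction=[1, 0, 0]),
        ]
        model = ph.PharmacophoreModel(features=feats, mandatory=frozenset({3}))
        return ph.SubModel(model, tuple(range(5)))

    def _perfect_points(self, sub):
        return [ph.FeaturePoint(f.kind, f.center.copy(),
                                None if f.direction is None else f.direction.copy())
                for f in sub.features]

    def test_exact_placement_scores_matched_count(self):
        sub = self._perfect_sub()
        res = ph.fit_conformer(self._perfect_points(sub), sub)
        assert res is not None and not res.clash
        assert res.score == pytest.approx(5.0, abs=1e-9)
        assert res.matched == 5

    def test_missing_donor_point_means_no_fit(self):
        sub = self._perfect_sub()
        pts = [p for p in self._perfect_points(sub) if p.kind != "donor"]
        assert ph.fit_conformer(pts, sub) is None

    def test_score_decreases_with_residual_distance(self):
        sub = self._perfect_sub()
        scores = []
        for off in (0.0, 0.3, 0.6, 0.9):
            pts = self._perfect_points(sub)
            pts[0] = ph.FeaturePoint("hydrophobic", pts[0].point + [0, 0, off])
            scores.append(ph.fit_conformer(pts, sub).score)
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_rigid_invariance_of_score(self):
        sub = self._perfect_sub()
        rng = np.random.default_rng(2)
        base_pts = self._perfect_points(sub)
        base_pts[1] = ph.FeaturePoint("hydrophobic", base_pts[1].point + [0.4, 0.2, 0])
        base = ph.fit_conformer(base_pts, sub).score
        for seed in range(5):
            rot, trans = random_rigid(np.random.default_rng(seed))
            pts = [ph.FeaturePoint(p.kind, p.point @ rot.T + trans,
                                   None if p.direction is None else p.direction @ rot.T)
                   for p in base_pts]
            assert ph.fit_conformer(pts, sub).score == pytest.approx(base, abs=1e-6)

    def test_clash_flagged_inside_exclusion(self):
        sub = self._perfect_sub()
        sub.model.exclusions.append(ph.Feature("exclusion", [0, 0, 0], 1.7))
        pts = self._perfect_points(sub)
        res = ph.fit_conformer(pts, sub, atom_coords=np.stack([p.point for p in pts]))
        assert res is not None and res.clash
        sub.model.exclusions.clear()

    def test_direction_mismatch_rejected(self):
        sub = self._perfect_sub()
        pts = self._perfect_points(sub)
        pts[3] = ph.FeaturePoint("donor", pts[3].point, direction=[0, 0, -1])
        res = ph.fit_conformer(pts, sub)
        assert res is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        points, sub = _random_case(rng)
        mine = ph.fit_conformer(points, sub)
        oracle = oracle_best_fit(points, sub)
        if oracle is None:
            assert mine is None
        else:
            assert mine is not None
            assert mine.score == pytest.approx(oracle, abs=1e-6)


class TestScreen:
    def test_perfect_match_ranks_first(self, interface_model, spec):
        lib = synthetic.make_ligand_library(interface_model, 1, 5, spec)
        hits = ph.screen(lib, interface_model, min_match=len(interface_model.features))
        assert hits.iloc[0]["compound_id"] == "binder-00"
        assert hits.iloc[0]["matched"] >= 5

    def test_empty_library_empty_table(self, interface_model):
        hits = ph.screen([], interface_model)
        assert len(hits) == 0
        assert list(hits.columns) == ["rank", "compound_id", "score", "matched",
                                      "submodel", "conformer"]

    def test_reported_fits_satisfy_contract(self, interface_model, spec):
        lib = synthetic.make_ligand_library(interface_model, 2, 10, spec)
        hits = ph.screen(lib, interface_model, min_match=5)
        assert (hits["matched"] >= 5).all()
        mandatory = set(interface_model.mandatory)
        for sub_str in hits["submodel"]:
            assert mandatory <= {int(x) for x in sub_str.split(",")}


class TestModelSerialization:
    def test_json_round_trip(self, interface_model):
        text = interface_model.to_json()
        back = ph.PharmacophoreModel.from_json(text)
        assert back.to_json() == text
        assert len(back.features) == len(interface_model.features)
        assert back.mandatory == interface_model.mandatory
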