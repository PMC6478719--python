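"""Feature perception, the six-site model, rigid matching and the selection filters."""

import itertools
import json

import numpy as np
import pytest

from olfscreen.chemlib import Compound, lowest_energy_conformer
from olfscreen.errors import ConfigurationError, MissingGeometryError
from olfscreen.pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
    Site,
    build_olfr73_ph4,
    build_shape_counter,
    ionization_penalty,
    kabsch,
    match_features,
    match_ph4,
    perceive_features,
    polarity_filter,
    shape_volume_filter,
)


def _features(smiles):
    return perceive_features(lowest_energy_conformer(Compound.from_smiles(smiles, id="x")))


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

def test_phenol_hydroxyl_is_ambivalent_hbond_feature():
    kinds = [f.kind for f in _features("c1ccccc1O")]
    assert kinds.count("donor_or_acceptor") == 1
    assert "acceptor" not in kinds


def test_methane_has_no_polar_features():
    kinds = [f.kind for f in _features("C")]
    assert "donor" not in kinds and "acceptor" not in kinds and "donor_or_acceptor" not in kinds


def test_isoeugenol_feature_inventory():
    kinds = [f.kind for f in _features("C/C=C/c1ccc(O)c(OC)c1")]
    assert kinds.count("donor_or_acceptor") == 1  # phenolic OH
    assert kinds.count("acceptor") == 1           # methoxy oxygen
    assert kinds.count("aromatic") == 1
    assert kinds.count("hydrophobic") >= 1        # propenyl chain


def test_feature_center_is_source_centroid():
    mol = lowest_energy_conformer(Compound.from_smiles("c1ccccc1O", id="x"))
    pos = mol.GetConformer().GetPositions()
    for f in perceive_features(mol):
        np.testing.assert_allclose(f.center, pos[list(f.source_atoms)].mean(axis=0), atol=1e-9)


def test_perceive_requires_conformer():
    from rdkit import Chem

    with pytest.raises(MissingGeometryError):
        perceive_features(Chem.MolFromSmiles("CCO"))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

ANCHORS = [(0, 0, 0), (2.8, 0, 0), (0, 4, 0), (3, 4, 1), (5, 2, -1), (4, -2, 2)]


def test_six_site_model_kinds():
    m = build_olfr73_ph4(ANCHORS)
    assert [s.kind for s in m.sites] == [
        "donor_or_acceptor", "acceptor", "hydrophobic", "hydrophobic",
        "hydrophobic", "hydrophobic",
    ]
    assert m.required_matches == 6


def test_wrong_anchor_count_rejected():
    with pytest.raises(ConfigurationError):
        build_olfr73_ph4(ANCHORS[:5])


def test_zero_tolerance_radius_rejected():
    with pytest.raises(ConfigurationError):
        build_olfr73_ph4(ANCHORS, radius=0.0)


def test_model_json_roundtrip_is_exact():
    m = build_olfr73_ph4(ANCHORS, radius=1.25)
    m2 = PharmacophoreModel.from_json(m.to_json())
    assert m2.to_json() == m.to_json()
    assert json.loads(m.to_json())["required_matches"] == 6


# ---------------------------------------------------------------------------
# rigid matching
# ---------------------------------------------------------------------------

def _ideal_features(model):
    return [
        PharmacophoreFeature(kind=s.kind if s.kind != "hydrophobic" else "hydrophobic",
                             center=s.center)
        for s in model.sites
    ]


def test_identity_placement_matches_with_zero_rmsd():
    m = build_olfr73_ph4(ANCHORS)
    res = match_features(_ideal_features(m), m)
    assert res.matched
    assert res.rmsd_of_assignment == pytest.approx(0.0, abs=1e-9)


def test_match_recovers_translated_ligand():
    m = build_olfr73_ph4(ANCHORS)
    feats = [
        PharmacophoreFeature(f.kind, tuple(np.array(f.center) + 50.0))
        for f in _ideal_features(m)
    ]
    res = match_features(feats, m)
    assert res.matched
    assert res.rmsd_of_assignment == pytest.approx(0.0, abs=1e-6)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def test_match_invariant_under_rigid_motion(rng):
    m = build_olfr73_ph4(ANCHORS)
    base = _ideal_features(m)
    for _ in range(10):
        R = _random_rotation(rng)
        t = rng.normal(scale=20.0, size=3)
        feats = [PharmacophoreFeature(f.kind, tuple(R @ np.array(f.center) + t)) for f in base]
        res = match_features(feats, m)
        assert res.matched
        assert res.rmsd_of_assignment < 1e-3


def _oracle_match(features, model):
    """Exhaustive assignment enumeration with full Kabsch verification."""
    from olfscreen.pharmacophore import SITE_COMPATIBILITY

    best = (False, np.inf)
    sites = model.sites
    for perm in itertools.permutations(range(len(features)), len(sites)):
        if any(features[j].kind not in SITE_COMPATIBILITY[s.kind]
               for s, j in zip(sites, perm)):
            continue
        P = np.array([features[j].center for j in perm])
        Q = np.array([s.center for s in sites])
        R, t = kabsch(P, Q)
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        if np.all(d <= np.array([s.radius for s in sites]) + 1e-9):
            rmsd = float(np.sqrt((d**2).mean()))
            if rmsd < best[1]:
                best = (True, rmsd)
    return best


def test_match_equals_exhaustive_oracle_on_random_instances(rng):
    kinds = ["donor", "acceptor", "donor_or_acceptor", "hydrophobic", "aromatic"]
    agree_matched = 0
    for _ in range(100):
        n_sites = int(rng.integers(2, 5))
        n_feats = int(rng.integers(n_sites, 7))
        sites = [
            Site(kinds[int(rng.integers(len(kinds)))],
                 tuple(rng.uniform(-4, 4, 3)), radius=float(rng.uniform(0.5, 1.5)))
            for _ in range(n_sites)
        ]
        model = PharmacophoreModel(sites=sites)
        feats = [
            PharmacophoreFeature(kinds[int(rng.integers(len(kinds)))],
                                 tuple(rng.uniform(-4, 4, 3)))
            for _ in range(n_feats)
        ]
        got = match_features(feats, model)
        want_matched, want_rmsd = _oracle_match(feats, model)
        assert got.matched == want_matched
        if want_matched:
            assert got.rmsd_of_assignment == pytest.approx(want_rmsd, abs=1e-6)
            agree_matched += 1
    assert agree_matched > 0  # some instances must actually match


def test_match_ph4_on_real_compound():
    iso = Compound.from_smiles("C/C=C/c1ccc(O)c(OC)c1", id="isoeugenol")
    mol = lowest_energy_conformer(iso)
    feats = perceive_features(mol)
    by_kind = {}
    for f in feats:
        by_kind.setdefault(f.kind, []).append(f)
    sites = [
        Site("donor_or_acceptor", by_kind["donor_or_acceptor"][0].center),
        Site("acceptor", by_kind["acceptor"][0].center),
        Site("hydrophobic", by_kind["aromatic"][0].center),
        Site("hydrophobic", by_kind["hydrophobic"][0].center),
    ]
    model = PharmacophoreModel(sites=sites)
    res = match_ph4(iso, model)
    assert res.matched
    assert res.rmsd_of_assignment < 0.5


# ---------------------------------------------------------------------------
# shape counter
# ---------------------------------------------------------------------------

def _single_sphere(center, r):
    return (np.array([center], float), np.array([r], float))


def test_counter_volume_of_disjoint_spheres_is_additive():
    r = 1.52
    counter = build_shape_counter(
        [_single_sphere((0, 0, 0), r), _single_sphere((10, 0, 0), r)], spacing=0.5
    )
    sphere = 4.0 / 3.0 * np.pi * r**3
    shell = 4.0 * np.pi * r**2 * counter.spacing  # one voxel-shell tolerance
    assert counter.total_volume == pytest.approx(2 * sphere, abs=2 * shell)


def test_reference_ligand_passes_its_own_counter():
    iso = Compound.from_smiles("C/C=C/c1ccc(O)c(OC)c1", id="iso")
    from olfscreen.pharmacophore import conformer_spheres

    coords, radii = conformer_spheres(iso)
    counter = build_shape_counter([(coords, radii)])
    res = shape_volume_filter(coords, radii, counter)
    assert res.passed
    assert res.outside_fraction == 0.0


def test_oversized_sphere_decoy_fails():
    coords, radii = _single_sphere((0, 0, 0), 5.0)  # 4/3 pi 125 = 523.6 A^3
    small = _single_sphere((0, 0, 0), 1.7)
    counter = build_shape_counter([small], max_volume=230.0)
    res = shape_volume_filter(coords, radii, counter)
    assert not res.passed
    assert res.conformer_volume > 230.0


def test_counter_serialization_roundtrip(tmp_path):
    from olfscreen.pharmacophore import ShapeCounter

    counter = build_shape_counter([_single_sphere((0, 0, 0), 1.7)], max_volume=230.0)
    p = tmp_path / "counter.vox.gz"
    counter.save(p)
    back = ShapeCounter.load(p)
    assert back.spacing == counter.spacing
    assert back.max_volume == counter.max_volume
    assert np.array_equal(back.occupancy, counter.occupancy)
    np.testing.assert_allclose(back.origin, counter.origin)


def test_shape_pass_set_shrinks_with_max_volume():
    iso = Compound.from_smiles("C/C=C/c1ccc(O)c(OC)c1", id="iso")
    from olfscreen.pharmacophore import conformer_spheres

    coords, radii = conformer_spheres(iso)
    counter = build_shape_counter([(coords, radii)])
    passed = []
    for vmax in (300.0, 200.0, 100.0, 50.0):
        counter.max_volume = vmax
        passed.append(shape_volume_filter(coords, radii, counter).passed)
    assert passed == sorted(passed, reverse=True)  # once failing, stays failing


# ---------------------------------------------------------------------------
# ionization and polarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles,charge,penalized",
    [
        ("OC(=O)c1ccccc1", -1, True),   # benzoic acid, pKa 4.2 < 7
        ("Oc1ccccc1", 0, False),        # phenol, pKa 10 > 7
        ("CCCCCC", 0, False),           # hexane
        ("NCCc1ccccc1", 1, True),       # phenethylamine
        ("Nc1ccccc1", 0, False),        # aniline, pKa 4.6 < 7
    ],
)
def test_ionization_rules(smiles, charge, penalized):
    got = ionization_penalty(Compound.from_smiles(smiles, id="x"))
    assert got == (charge, penalized)


@pytest.mark.parametrize(
    "smiles", ["OC(=O)CCC", "OC(=O)c1ccc(C)cc1", "OC(=O)C(C)c1ccccc1"]
)
def test_free_carboxylic_acids_always_flagged(smiles):
    charge, penalized = ionization_penalty(Compound.from_smiles(smiles, id="x"))
    assert charge == -1 and penalized


def test_polarity_filter_thresholds():
    assert polarity_filter(Compound.from_smiles("CCCCCC", id="x"), max_psa=1.0)
    # phloroglucinol: three phenolic OH, TPSA 60.7 > 55
    assert not polarity_filter(Compound.from_smiles("Oc1cc(O)cc(O)c1", id="y"))
    assert polarity_filter(Compound.from_smiles("Oc1ccccc1", id="z"))  # 20.2
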