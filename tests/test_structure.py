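"""Interaction fingerprints, contact frequencies, pocket volume, volume change."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from olfscreen.errors import ConfigurationError, GeometryError, InsufficientDataError
from olfscreen.structure import (
    INTERACTION_TYPES,
    IFPParams,
    InteractionFingerprint,
    PocketAtom,
    PocketModel,
    PocketResidue,
    compute_ifp,
    contact_frequency,
    percent_volume_change,
    pocket_volume,
)
from olfscreen.synthetic_data import (
    ToyPocketSpec,
    add_hbond_partner,
    gen_pocket,
    place_hbond_pose,
)


def _embedded(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(mol, params)
    return mol


# ---------------------------------------------------------------------------
# interaction fingerprints
# ---------------------------------------------------------------------------

def test_constructed_hbond_to_conserved_tyrosine():
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=5.0))
    acceptor = add_hbond_partner(pocket, "Y260^6.52")
    pose = place_hbond_pose(pocket, acceptor, smiles="C/C=C/c1ccc(O)c(OC)c1",
                            distance=2.8, angle=150.0)
    fp = compute_ifp(pocket, pose)
    assert fp.get("Y260^6.52", "hbond") == 1


def test_minimal_probe_sets_exactly_one_hbond_bit():
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=5.0))
    acceptor = add_hbond_partner(pocket, "Y260^6.52")
    pose = place_hbond_pose(pocket, acceptor, smiles="CO")
    fp = compute_ifp(pocket, pose)
    on = [k for k, v in fp.bits.items() if v]
    assert on == [("Y260^6.52", "hbond")]


def test_far_translated_ligand_gives_zero_fingerprint(caplog):
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=5.0))
    acceptor = add_hbond_partner(pocket, "Y260^6.52")
    pose = place_hbond_pose(pocket, acceptor, smiles="CO")
    conf = pose.GetConformer()
    for i in range(pose.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, (p.x + 50.0, p.y + 50.0, p.z + 50.0))
    with caplog.at_level("WARNING"):
        fp = compute_ifp(pocket, pose)
    assert not any(fp.bits.values())
    assert any("outside" in r.message for r in caplog.records)


def _random_toy_pocket(rng, n_res=4):
    residues = []
    for i in range(n_res):
        n_atoms = int(rng.integers(2, 5))
        atoms = []
        for j in range(n_atoms):
            element = ["C", "O", "N"][int(rng.integers(3))]
            xyz = tuple(rng.uniform(-6, 6, 3))
            atoms.append(
                PocketAtom(
                    name=f"X{j}", element=element, xyz=xyz,
                    is_donor=element in ("O", "N") and rng.random() < 0.5,
                    is_acceptor=element in ("O", "N") and rng.random() < 0.7,
                    is_apolar_carbon=element == "C",
                    charge=int(rng.choice([-1, 0, 0, 0, 1])) if element != "C" else 0,
                )
            )
        residues.append(PocketResidue(label=f"R{i}", resname="ALA", atoms=atoms))
    return PocketModel(
        residues=residues, pocket_center=np.zeros(3),
        bbox=(np.full(3, -30.0), np.full(3, 30.0)),
    )


def _oracle_ifp(pocket, pose, params=IFPParams()):
    """Independent per-pair scan over the same geometric rules."""
    fp = InteractionFingerprint(residue_labels=tuple(pocket.labels))
    pos = pose.GetConformer().GetPositions()
    atoms = list(pose.GetAtoms())

    def angle(a, b, c):
        u, v = pos[a] - pos[b], np.asarray(c) - pos[b]
        cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
        return math.degrees(math.acos(max(-1, min(1, cosv))))

    from olfscreen._ionization import ionizable_sites

    lig_charges = [(a.GetIdx(), a.GetFormalCharge()) for a in atoms if a.GetFormalCharge()]
    lig_charges += [(at[0], q) for _n, at, q in ionizable_sites(pose) if q]

    for res in pocket.residues:
        for pa in res.atoms:
            for a in atoms:
                i = a.GetIdx()
                d = float(np.linalg.norm(pos[i] - np.array(pa.xyz)))
                if pa.is_apolar_carbon and a.GetSymbol() == "C" and all(
                    n.GetSymbol() in ("C", "H") for n in a.GetNeighbors()
                ) and d <= params.hydrophobic_distance:
                    fp.set(res.label, "hydrophobic")
                if a.GetSymbol() in ("O", "N"):
                    hs = [n.GetIdx() for n in a.GetNeighbors() if n.GetSymbol() == "H"]
                    if pa.is_acceptor and hs and d <= params.hbond_distance and any(
                        angle(i, h, pa.xyz) >= params.hbond_angle for h in hs
                    ):
                        fp.set(res.label, "hbond")
                    if pa.is_donor and d <= params.hbond_distance:
                        if pa.base_xyz is None:
                            fp.set(res.label, "hbond")
                        else:
                            u = np.array(pa.base_xyz) - np.array(pa.xyz)
                            v = pos[i] - np.array(pa.xyz)
                            cosv = np.dot(u, v) / (
                                np.linalg.norm(u) * np.linalg.norm(v) + 1e-12
                            )
                            if math.degrees(math.acos(max(-1, min(1, cosv)))) >= 90.0:
                                fp.set(res.label, "hbond")
            for li, lq in lig_charges:
                if pa.charge and lq * pa.charge < 0:
                    if np.linalg.norm(pos[li] - np.array(pa.xyz)) <= params.ionic_distance:
                        fp.set(res.label, "ionic")
        cen = res.ring_centroid()
        if cen is not None:
            ri = pose.GetRingInfo()
            for ring in ri.AtomRings():
                if all(pose.GetAtomWithIdx(k).GetIsAromatic() for k in ring):
                    c = pos[list(ring)].mean(axis=0)
                    if np.linalg.norm(c - cen) <= params.aromatic_distance:
                        fp.set(res.label, "aromatic")
    return fp


@pytest.mark.parametrize("smiles", ["CCO", "OC(=O)C", "c1ccccc1O", "NCCO"])
def test_fingerprint_equals_bruteforce_scan(smiles, rng):
    pose = _embedded(smiles)
    for trial in range(10):
        pocket = _random_toy_pocket(rng)
        shift = rng.uniform(-3, 3, 3)
        conf = pose.GetConformer()
        base = conf.GetPositions()
        for i in range(pose.GetNumAtoms()):
            conf.SetAtomPosition(i, tuple(base[i] + shift))
        got = compute_ifp(pocket, pose)
        want = _oracle_ifp(pocket, pose)
        assert got.bits == want.bits
        for i in range(pose.GetNumAtoms()):
            conf.SetAtomPosition(i, tuple(base[i]))


def test_fingerprint_invariant_under_joint_rigid_motion(rng):
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=5.0))
    acceptor = add_hbond_partner(pocket, "Y260^6.52")
    pose = place_hbond_pose(pocket, acceptor, smiles="C/C=C/c1ccc(O)c(OC)c1")
    before = compute_ifp(pocket, pose).bits

    theta = 0.7
    R = np.array([[math.cos(theta), -math.sin(theta), 0],
                  [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
    t = np.array([5.0, -3.0, 2.0])

    def mv(p):
        return tuple(R @ np.asarray(p) + t)

    for res in pocket.residues:
        res.atoms = [
            PocketAtom(a.name, a.element, mv(a.xyz), a.is_donor, a.is_acceptor,
                       a.is_apolar_carbon, a.charge,
                       mv(a.base_xyz) if a.base_xyz else None)
            for a in res.atoms
        ]
    pocket.pocket_center = R @ pocket.pocket_center + t
    corners = np.array([R @ c + t for c in np.array(np.meshgrid(*zip(*pocket.bbox))).T.reshape(-1, 3)])
    pocket.bbox = (corners.min(axis=0), corners.max(axis=0))
    conf = pose.GetConformer()
    for i in range(pose.GetNumAtoms()):
        conf.SetAtomPosition(i, mv(conf.GetAtomPosition(i)))
    after = compute_ifp(pocket, pose).bits
    assert after == before


def _pdb_line(serial, name, resname, resseq, xyz, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:>3s} A{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element:>2s}"
    )


def test_pocket_pdb_reading_classifies_side_chains(tmp_path):
    from olfscreen.structure import read_pocket_pdb

    lines = [
        _pdb_line(1, "CB", "TYR", 260, (0.0, 0.0, 0.0), "C"),
        _pdb_line(2, "OH", "TYR", 260, (2.0, 0.0, 0.0), "O"),
        _pdb_line(3, "CB", "GLU", 208, (0.0, 5.0, 0.0), "C"),
        _pdb_line(4, "OE1", "GLU", 208, (1.5, 5.0, 0.0), "O"),
        _pdb_line(5, "CG", "PHE", 105, (0.0, 0.0, 5.0), "C"),
    ]
    p = tmp_path / "pocket.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    pocket = read_pocket_pdb(
        p, {"260": "Y260^6.52", "208": "E208^5.47", "105": "F105^3.33"}
    )
    assert set(pocket.labels) == {"Y260^6.52", "E208^5.47", "F105^3.33"}
    tyr = next(r for r in pocket.residues if r.label == "Y260^6.52")
    oh = next(a for a in tyr.atoms if a.name == "OH")
    assert oh.is_donor and oh.is_acceptor
    glu = next(r for r in pocket.residues if r.label == "E208^5.47")
    oe1 = next(a for a in glu.atoms if a.name == "OE1")
    assert oe1.charge == -1 and oe1.is_acceptor
    # a hydroxyl ligand next to the tyrosine OH registers an H-bond
    pose = _embedded("CO")
    conf = pose.GetConformer()
    o_idx = next(a.GetIdx() for a in pose.GetAtoms() if a.GetSymbol() == "O")
    shift = np.array([4.8, 0.0, 0.0]) - conf.GetPositions()[o_idx]
    for i in range(pose.GetNumAtoms()):
        conf.SetAtomPosition(i, tuple(conf.GetPositions()[i] + shift))
    fp = compute_ifp(pocket, pose)
    assert fp.get("Y260^6.52", "hbond") == 1


# ---------------------------------------------------------------------------
# contact frequency
# ---------------------------------------------------------------------------

def _fp_with(labels, contacts):
    fp = InteractionFingerprint(residue_labels=tuple(labels))
    for lab, typ in contacts:
        fp.set(lab, typ)
    return fp


def test_contact_frequency_all_and_one_of_25():
    labels = ("F105^3.33", "V109^3.37")
    fps = [_fp_with(labels, [("F105^3.33", "hydrophobic")]) for _ in range(25)]
    fps[0].set("V109^3.37", "hbond")
    freq = contact_frequency(fps)
    assert freq["F105^3.33"] == 100.0
    assert freq["V109^3.37"] == pytest.approx(4.0)


def test_contact_frequency_equals_bruteforce_and_is_permutation_invariant(rng):
    labels = tuple(f"R{i}" for i in range(5))
    fps = []
    for _ in range(20):
        contacts = [
            (lab, typ)
            for lab in labels
            for typ in INTERACTION_TYPES
            if rng.random() < 0.2
        ]
        fps.append(_fp_with(labels, contacts))
    freq = contact_frequency(fps)
    for lab in labels:
        manual = 100.0 * sum(
            any(fp.get(lab, t) for t in INTERACTION_TYPES) for fp in fps
        ) / len(fps)
        assert freq[lab] == pytest.approx(manual)
        assert 0.0 <= freq[lab] <= 100.0
    perm = [fps[i] for i in rng.permutation(len(fps))]
    assert contact_frequency(perm) == freq


def test_contact_frequency_empty_input():
    with pytest.raises(InsufficientDataError):
        contact_frequency([])


def test_contact_frequency_mixed_residue_sets_rejected():
    with pytest.raises(ConfigurationError):
        contact_frequency([_fp_with(("A",), []), _fp_with(("B",), [])])


# ---------------------------------------------------------------------------
# pocket volume
# ---------------------------------------------------------------------------

def test_cubic_cavity_volume():
    pocket = gen_pocket(ToyPocketSpec(shape="cube", size=6.0))
    pv = pocket_volume(pocket, spacing=0.5)
    shell = 6 * 6.0**2 * 0.5
    assert pv.volume == pytest.approx(216.0, abs=shell)
    assert pv.volume == pv.voxel_count * pv.grid_spacing**3


def test_spherical_cavity_volume():
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=3.6))
    pv = pocket_volume(pocket, spacing=0.5)
    analytic = 4.0 / 3.0 * math.pi * 3.6**3  # 195.4
    shell = 4 * math.pi * 3.6**2 * 0.5
    assert pv.volume == pytest.approx(analytic, abs=shell)


def test_volume_converges_under_grid_refinement():
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=3.6))
    coarse = pocket_volume(pocket, spacing=0.5).volume
    fine = pocket_volume(pocket, spacing=0.25).volume
    assert abs(fine - coarse) / fine <= 0.02


def test_occluded_center_raises():
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=3.6))
    pocket.pocket_center = np.array([0.0, 0.0, 3.6 + 1.7 + 1.4])  # inside shell atoms
    with pytest.raises(GeometryError):
        pocket_volume(pocket)


def test_atom_center_mode_gives_larger_cavity():
    pocket = gen_pocket(ToyPocketSpec(shape="sphere", size=3.6))
    probe = pocket_volume(pocket, mode="probe").volume
    bare = pocket_volume(pocket, mode="atom-center").volume
    assert bare > probe


# ---------------------------------------------------------------------------
# percent volume change
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "apo,holo,expected",
    [(230, 280, 22), (360, 425, 18), (270, 315, 17), (510, 575, 13), (190, 220, 16)],
)
def test_reported_pocket_expansions(apo, holo, expected):
    assert percent_volume_change(apo, holo) == expected


def test_no_change_is_zero_and_sign_follows_direction(rng):
    assert percent_volume_change(200.0, 200.0) == 0
    for _ in range(50):
        a = float(rng.uniform(50, 600))
        b = float(rng.uniform(50, 600))
        pct = percent_volume_change(a, b)
        if abs(100 * (b - a) / a) >= 0.5:
            assert np.sign(pct) == np.sign(b - a)


def test_nonpositive_apo_volume_rejected():
    with pytest.raises(ValueError):
        percent_volume_change(0.0, 100.0)
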