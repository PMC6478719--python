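"""Generators and packaged fixtures for testing every pipeline stage offline.

The packaged 42-agonist fixture is a synthetic reconstruction of the mouse
eugenol-receptor (Olfr73) agonist panel: 17 newly-found (A1-A17) and 25
previously-reported (B1-B25) agonists in six structural classes (para-alkyl
phenols; guaiacols with a hydrophobic substituent; alkoxybenzaldehydes; polar
oxygenated phenols; 4-alkylcyclohexanones; a disubstituted tetrahydropyran),
with per-class micromolar EC50 ranges taken from the published panel
(class 1: 13-64, class 2: 7-240, class 3: 26-270, class 4: 4-660,
class 5: 36-63, class 6: 630).  Structures whose identity the published class
descriptions do not pin down are flagged in the fixture metadata.

The library generator emulates a drug-like screening deck: planted hits are
guaiacol-family agonist analogs that satisfy the default funnel end to end;
decoys are built to violate a named stage (mass window, ionization state,
polarity ceiling, or pharmacophore feature count).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .activity import DoseResponse, hill
from .chemlib import Compound, embed_conformers
from .errors import ConfigurationError, DataIntegrityError, GeometryError
from .structure import OLFR73_POCKET_RESIDUES, PocketAtom, PocketModel, PocketResidue

_CHECKSUMS = {
    "agonists.smi": "717a01233417290dda0bb92de3c093da2713b189fcee3903a8a741e8956ec461",
    "agonists.csv": "01b86cfeb9ee590f603dccfdfe661b19ed88057f8d5f233f80ad3fa3ced33406",
}


# ---------------------------------------------------------------------------
# packaged agonist fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgonistRecord:
    id: str
    name: str
    smiles: str
    ec50_uM: float
    class_label: int
    encoding: str
    flag: str

    def compound(self) -> Compound:
        return Compound.from_smiles(self.smiles, id=self.id, name=self.name,
                                    ec50_uM=self.ec50_uM, class_label=self.class_label)


@dataclass
class AgonistFixture:
    records: list[AgonistRecord]

    def compounds(self) -> list[Compound]:
        return [r.compound() for r in self.records]

    def by_id(self, rid: str) -> AgonistRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def class_labels(self) -> dict[str, int]:
        return {r.id: r.class_label for r in self.records}


def _read_data(name: str) -> str:
    data = resources.files("olfscreen.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise DataIntegrityError(f"{name}: checksum mismatch ({digest})")
    return data.decode()


def load_agonist_fixture() -> AgonistFixture:
    """The packaged, validated 42-agonist panel (17 A-records, 25 B-records)."""
    smiles = {}
    for line in _read_data("agonists.smi").splitlines():
        if line.strip():
            smi, rid = line.split()
            smiles[rid] = smi
    import csv
    import io

    records = []
    reader = csv.DictReader(io.StringIO(_read_data("agonists.csv")))
    for row in reader:
        records.append(
            AgonistRecord(id=row["id"], name=row["name"], smiles=smiles[row["id"]],
                          ec50_uM=float(row["ec50_uM"]), class_label=int(row["class"]),
                          encoding=row["encoding"], flag=row["flag"])
        )
    fx = AgonistFixture(records=records)
    n_a = sum(1 for r in fx.records if r.id.startswith("A"))
    n_b = sum(1 for r in fx.records if r.id.startswith("B"))
    if (n_a, n_b) != (17, 25):
        raise DataIntegrityError(f"expected 17 A + 25 B records, got {n_a}+{n_b}")
    if set(r.class_label for r in fx.records) != set(range(1, 7)):
        raise DataIntegrityError("class labels 1..6 must all be present")
    if any(r.ec50_uM <= 0 for r in fx.records):
        raise DataIntegrityError("EC50 values must be positive")
    return fx


# ---------------------------------------------------------------------------
# compound-library generator
# ---------------------------------------------------------------------------

#: guaiacol-family agonist analogs used as planted hits; each carries the
#: donor-or-acceptor hydroxyl, the methoxy acceptor, the aromatic ring and an
#: aliphatic hydrophobic group the default pharmacophore model asks for
HIT_TEMPLATES = [
    ("eugenol", "C=CCc1ccc(O)c(OC)c1"),
    ("isoeugenol", "C/C=C/c1ccc(O)c(OC)c1"),
    ("4-propylguaiacol", "CCCc1ccc(O)c(OC)c1"),
    ("4-butylguaiacol", "CCCCc1ccc(O)c(OC)c1"),
    ("4-isobutylguaiacol", "CC(C)Cc1ccc(O)c(OC)c1"),
    ("4-pentylguaiacol", "CCCCCc1ccc(O)c(OC)c1"),
    ("4-prenylguaiacol", "CC(C)=CCc1ccc(O)c(OC)c1"),
    ("4-cyclopentylguaiacol", "COc1cc(ccc1O)C1CCCC1"),
]

_ALKYLS = ["CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CC(C)CC", "C2CCCCC2", "C2CCCC2"]
_ALKOXYS = ["OC", "OCC", "OCCC"]

#: decoy builders per violated stage
def _decoy_mass_high(rng) -> str:
    n = rng.integers(18, 24)
    return "Oc1ccc(" + "C" * int(n) + ")cc1"  # long-chain alkylphenol, M > 320


def _decoy_mass_low(rng) -> str:
    return rng.choice(["CCO", "CCC", "CC=O", "CCN", "OCC=C"])  # M < 110


def _decoy_charge(rng) -> str:
    r = rng.choice(_ALKYLS)
    if rng.random() < 0.5:
        return f"OC(=O)c1ccc({r})cc1"  # benzoic acid, anionic at pH 7
    return f"NCCc1ccc({r})cc1"  # aliphatic amine, cationic at pH 7


def _decoy_polarity(rng) -> str:
    return rng.choice([
        "Oc1cc(O)cc(O)c1", "Oc1ccc(O)c(O)c1", "OCC(O)C(O)CO",
        "OCC(O)C(O)C(O)CO", "Oc1cc(O)c(O)cc1O",
    ])  # neutral polyols/polyphenols, PSA > 55


def _decoy_ph4(rng) -> str:
    r = rng.choice(_ALKYLS)
    return rng.choice([
        f"O=Cc1ccc({r})cc1",      # alkylbenzaldehyde: one acceptor only
        f"O=C1CCC({r})CC1",       # alkylcyclohexanone: no aromatic ring
        f"c1ccccc1{r}",           # alkylbenzene: no polar feature
    ])


_DECOY_BUILDERS = {
    "physchem": lambda rng: _decoy_mass_high(rng) if rng.random() < 0.5 else _decoy_mass_low(rng),
    "ionization": _decoy_charge,
    "polarity": _decoy_polarity,
    "ph4": _decoy_ph4,
}


@dataclass
class LibrarySpec:
    """Parameters of a synthetic screening library."""

    n: int = 500
    n_hits: int = 10
    seed: int = 0
    decoy_weights: dict = field(
        default_factory=lambda: {"physchem": 0.3, "ionization": 0.25,
                                 "polarity": 0.15, "ph4": 0.3}
    )
    mass_range: tuple[float, float] = (110.0, 320.0)

    def __post_init__(self):
        if self.n_hits > self.n:
            raise ConfigurationError("more planted hits than library size")
        total = sum(self.decoy_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigurationError("decoy weights must sum to 1")


def gen_library(spec: LibrarySpec) -> list[Compound]:
    """Deterministic synthetic library with planted hits and stage-violating decoys.

    Hits cycle through the guaiacol template panel; each decoy's metadata names
    the funnel stage it is designed to violate.
    """
    rng = np.random.default_rng(spec.seed)
    compounds: list[Compound] = []
    for i in range(spec.n_hits):
        name, smi = HIT_TEMPLATES[i % len(HIT_TEMPLATES)]
        compounds.append(
            Compound.from_smiles(smi, id=f"HIT{i+1:03d}", name=name, planted_hit=True)
        )
    kinds = list(spec.decoy_weights)
    probs = np.array([spec.decoy_weights[k] for k in kinds])
    for i in range(spec.n - spec.n_hits):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        smi = _DECOY_BUILDERS[kind](rng)
        compounds.append(
            Compound.from_smiles(smi, id=f"DEC{i+1:04d}", planted_hit=False,
                                 decoy_violates=kind)
        )
    order = rng.permutation(len(compounds))
    return [compounds[i] for i in order]


def gen_scaffold_families(
    n_families: int, per_family: int, seed: int = 0
) -> tuple[list[Compound], np.ndarray]:
    """Compounds drawn from well-separated scaffold families, with family labels."""
    if not 2 <= n_families <= 6:
        raise ConfigurationError("supported family counts: 2..6")
    rng = np.random.default_rng(seed)
    families = [
        ("phenol", ["Oc1ccc(%s)cc1" % a for a in ("CC(C)C", "C(C)(C)C", "CCC(C)C",
                                                  "C2CCCCC2", "CC(C)CC", "CCCC")]),
        ("guaiacol", ["COc1cc(%s)ccc1O" % a for a in ("CC=C", "CCC", "CCCC", "CC(C)C",
                                                      "C2CCCC2", "CCCCC")]),
        ("benzaldehyde", ["O=Cc1ccc(%s)cc1" % a for a in ("OC", "OCC", "OCCC")]
         + ["Cc1cc(C=O)ccc1OC", "COc1ccc(C=O)cc1C", "CCOc1ccc(C=O)cc1C"]),
        ("cyclohexanone", ["O=C1CCC(%s)CC1" % a for a in ("CCC", "CC(C)C", "C(C)(C)C",
                                                          "C(C)CC", "CCCC", "CCC(C)C")]),
        ("tetrahydropyran", ["CC1CCOC(%s)C1" % a for a in ("C=C(C)C", "CCC", "CC(C)C",
                                                           "CCCC", "C(C)CC", "CCCCC")]),
        ("alkylbenzene", ["c1ccccc1%s" % a for a in ("CCCC", "CC(C)C", "CCCCC",
                                                     "C2CCCCC2", "CCC(C)C", "CCCCCC")]),
    ]
    chosen = [families[i] for i in rng.choice(len(families), size=n_families, replace=False)]
    compounds, labels = [], []
    for fi, (fname, pool) in enumerate(chosen):
        picks = rng.choice(len(pool), size=per_family, replace=per_family > len(pool))
        for j, pi in enumerate(picks):
            compounds.append(
                Compound.from_smiles(pool[int(pi)], id=f"{fname}_{j}", name=fname)
            )
            labels.append(fi)
    return compounds, np.array(labels)


# ---------------------------------------------------------------------------
# toy binding pocket
# ---------------------------------------------------------------------------

@dataclass
class ToyPocketSpec:
    """A cavity of known analytic volume lined by labelled residue shells."""

    shape: str = "sphere"        # "sphere" or "cube"
    size: float = 3.6            # radius (sphere) or edge length (cube), A
    seed: int = 0
    probe_radius: float = 1.4
    shell_element: str = "C"
    shell_point_spacing: float = 0.8
    residue_labels: tuple[str, ...] = OLFR73_POCKET_RESIDUES


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def gen_pocket(spec: ToyPocketSpec) -> PocketModel:
    """Toy pocket whose probe-accessible cavity matches the requested shape.

    Shell atom centers are offset outward by (vdW radius + probe radius) so the
    probe-accessible boundary coincides with the nominal cavity surface.
    """
    from .pharmacophore import VDW_RADII, DEFAULT_VDW

    offset = VDW_RADII.get(spec.shell_element, DEFAULT_VDW) + spec.probe_radius
    if spec.shape == "sphere":
        shell_r = spec.size + offset
        n_pts = max(200, int(4 * math.pi * shell_r**2 / spec.shell_point_spacing**2))
        pts = _fibonacci_sphere(n_pts) * shell_r
    elif spec.shape == "cube":
        half = spec.size / 2 + offset
        axes = np.arange(-half, half + 1e-9, spec.shell_point_spacing)
        faces = []
        for d in range(3):
            for sgn in (-half, half):
                a, b = np.meshgrid(axes, axes, indexing="ij")
                face = np.zeros((a.size, 3))
                face[:, d] = sgn
                face[:, (d + 1) % 3] = a.ravel()
                face[:, (d + 2) % 3] = b.ravel()
                faces.append(face)
        pts = np.vstack(faces)
    else:
        raise ConfigurationError(f"unknown pocket shape {spec.shape!r}")

    labels = spec.residue_labels
    residues = []
    per = max(1, len(pts) // len(labels))
    for li, label in enumerate(labels):
        chunk = pts[li * per : (li + 1) * per] if li < len(labels) - 1 else pts[li * per :]
        atoms = [
            PocketAtom(name=f"C{j}", element=spec.shell_element,
                       xyz=tuple(map(float, p)), is_apolar_carbon=True)
            for j, p in enumerate(chunk)
        ]
        resname = {"Y": "TYR", "F": "PHE", "E": "GLU", "K": "LYS", "L": "LEU",
                   "V": "VAL", "C": "CYS", "T": "THR"}.get(label[0], "ALA")
        residues.append(PocketResidue(label=label, resname=resname, atoms=atoms))
    margin = 2.0
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    return PocketModel(residues=residues, pocket_center=np.zeros(3), bbox=(lo, hi))


def add_hbond_partner(
    pocket: PocketModel, label: str = "Y260^6.52", depth: float = 1.0
) -> np.ndarray:
    """Give one residue an inward-pointing hydroxyl oxygen (donor/acceptor).

    The oxygen sits ``depth`` A inside the cavity boundary along the residue's
    mean direction; returns its position.
    """
    for res in pocket.residues:
        if res.label != label:
            continue
        direction = np.array([a.xyz for a in res.atoms]).mean(axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            raise GeometryError("cannot orient residue toward the cavity")
        u = direction / norm
        # cavity boundary along u: estimated from nearest shell atom distance
        shell_r = min(np.linalg.norm(np.array(a.xyz)) for a in res.atoms)
        pos = u * (shell_r - 3.0 - depth)
        base = pos + u * 1.4
        res.atoms.append(
            PocketAtom(name="OH", element="O", xyz=tuple(map(float, pos)),
                       is_donor=True, is_acceptor=True,
                       base_xyz=tuple(map(float, base)))
        )
        return pos
    raise ConfigurationError(f"no residue labelled {label!r}")


def place_hbond_pose(
    pocket: PocketModel,
    acceptor_xyz: Sequence[float],
    smiles: str = "CO",
    distance: float = 2.8,
    angle: float = 150.0,
    seed: int = 2019,
) -> Chem.Mol:
    """Pose a hydroxyl-bearing ligand so its OH donates an H-bond to ``acceptor_xyz``.

    The ligand hydroxyl oxygen is placed ``distance`` A from the acceptor along
    the direction toward the pocket center, and its hydrogen is oriented to
    realize the requested donor angle (the D-H...A angle at the hydrogen).
    """
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(mol, params)
    conf = mol.GetConformer()
    o_idx = h_idx = None
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "O":
            hs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetSymbol() == "H"]
            if hs:
                o_idx, h_idx = atom.GetIdx(), hs[0]
                break
    if o_idx is None:
        raise ConfigurationError("ligand has no hydroxyl group")

    pos = conf.GetPositions()
    A = np.asarray(acceptor_xyz, float)
    center = np.asarray(pocket.pocket_center, float)
    u = center - A
    u = u / (np.linalg.norm(u) + 1e-12)
    D = A + u * distance  # target donor-oxygen position

    # target H position: on the D-A plane, 1.0 A from D, making the requested
    # angle at H between H->D and H->A
    d_oh = float(np.linalg.norm(pos[h_idx] - pos[o_idx]))
    theta = math.radians(angle)
    # law of cosines on triangle D-H-A with |DH| = d_oh, angle at H = theta
    # place H at angle alpha off the D->A axis seen from D
    dDA = distance
    # |HA|^2 = |DH|^2 + |DA|^2 - 2 |DH||DA| cos(alpha); angle at H from those
    best_alpha, best_err = 0.0, float("inf")
    for alpha_deg in np.linspace(0.0, 90.0, 901):
        alpha = math.radians(alpha_deg)
        H = D + _rotate_towards(u * -1.0, alpha) * d_oh
        ang = _angle_at(H, D, A)
        err = abs(ang - angle)
        if err < best_err:
            best_err, best_alpha = err, alpha
    H_target = D + _rotate_towards(u * -1.0, best_alpha) * d_oh

    # rigid transform: move O to D, rotate O->H onto O->H_target
    shift = D - pos[o_idx]
    pos = pos + shift
    v_from = pos[h_idx] - pos[o_idx]
    v_to = H_target - D
    R = _rotation_between(v_from, v_to)
    pos = (pos - D) @ R.T + D
    for i, p in enumerate(pos):
        conf.SetAtomPosition(i, tuple(map(float, p)))
    return mol


def _rotate_towards(axis_dir: np.ndarray, alpha: float) -> np.ndarray:
    """Unit vector at angle alpha from ``axis_dir`` (in a fixed perpendicular plane)."""
    a = axis_dir / np.linalg.norm(axis_dir)
    perp = np.cross(a, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(a, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    return a * math.cos(alpha) + perp * math.sin(alpha)


def _angle_at(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u, v = a - p, b - p
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _rotation_between(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping direction v1 onto v2 (Rodrigues)."""
    a = v1 / (np.linalg.norm(v1) + 1e-12)
    b = v2 / (np.linalg.norm(v2) + 1e-12)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-9:
        if c > 0:
            return np.eye(3)
        # opposite directions: rotate pi about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1 / (1 + c))


# ---------------------------------------------------------------------------
# dose-response generator
# ---------------------------------------------------------------------------

def gen_dose_response(
    fmax: float,
    ec50_uM: float,
    n: float,
    concentrations_uM: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Hill-model responses with seeded additive Gaussian noise."""
    if fmax <= 0 or ec50_uM <= 0 or n <= 0:
        raise ConfigurationError("fmax, EC50 and n must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise sd must be non-negative")
    x = np.asarray(concentrations_uM, float)
    y = hill(x, fmax, ec50_uM, n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return DoseResponse(concentrations_uM=x, responses=y)
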