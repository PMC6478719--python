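"""Receptor-pocket model, interaction fingerprints, contact frequencies,
grid-based pocket volume, and apo-to-holo volume-change arithmetic.

An interaction fingerprint records, per pocket residue, the presence of four
contact types between a docked ligand pose and the residue: hydrophobic
contact, H-bond, ionic (salt-bridge / "ion-lock") contact, and aromatic
(ring-stacking) contact.  Geometric cutoffs follow common fingerprinting
practice and are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy import ndimage

from ._ionization import ionizable_sites
from .errors import ConfigurationError, GeometryError, InsufficientDataError
from .pharmacophore import DEFAULT_VDW, VDW_RADII, _mark_spheres

log = logging.getLogger(__name__)

INTERACTION_TYPES = ("hydrophobic", "hbond", "ionic", "aromatic")

#: pocket-lining residues of the mouse eugenol receptor, Ballesteros-Weinstein labelled
OLFR73_POCKET_RESIDUES = (
    "F102^3.30", "F105^3.33", "C106^3.34", "V109^3.37", "V110^3.38",
    "F179^ECL2", "E181^ECL2", "F182^ECL2", "L199^5.38", "F203^5.42",
    "E208^5.47", "L259^6.51", "Y260^6.52", "K273^7.35", "V277^7.39",
    "T280^7.42",
)


@dataclass(frozen=True)
class PocketAtom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    is_donor: bool = False      # can donate an H-bond (heavy atom carrying H)
    is_acceptor: bool = False
    is_apolar_carbon: bool = False
    charge: int = 0
    base_xyz: tuple[float, float, float] | None = None  # bonded heavy atom, for donor geometry


@dataclass
class PocketResidue:
    label: str        # e.g. "Y260^6.52"
    resname: str
    atoms: list[PocketAtom]
    ring_atom_names: tuple[str, ...] = ()

    def ring_centroid(self) -> np.ndarray | None:
        ring = [a for a in self.atoms if a.name in self.ring_atom_names]
        if len(ring) < 3:
            return None
        return np.array([a.xyz for a in ring]).mean(axis=0)


@dataclass
class PocketModel:
    residues: list[PocketResidue]
    pocket_center: np.ndarray
    bbox: tuple[np.ndarray, np.ndarray]  # (min corner, max corner)

    def __post_init__(self):
        labels = [r.label for r in self.residues]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("pocket residue labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def all_atoms(self) -> list[PocketAtom]:
        return [a for r in self.residues for a in r.atoms]


# per-residue side-chain classification used when reading PDB coordinates:
# donors / acceptors / formal charges / aromatic ring atoms
_SIDECHAIN = {
    "TYR": {"donor": {"OH"}, "acceptor": {"OH"}, "ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "PHE": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TRP": {"donor": {"NE1"}, "ring": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")},
    "HIS": {"donor": {"ND1", "NE2"}, "acceptor": {"ND1", "NE2"},
            "ring": ("CG", "ND1", "CD2", "CE1", "NE2")},
    "SER": {"donor": {"OG"}, "acceptor": {"OG"}},
    "THR": {"donor": {"OG1"}, "acceptor": {"OG1"}},
    "CYS": {"donor": {"SG"}},
    "ASN": {"donor": {"ND2"}, "acceptor": {"OD1"}},
    "GLN": {"donor": {"NE2"}, "acceptor": {"OE1"}},
    "ASP": {"acceptor": {"OD1", "OD2"}, "charged": {"OD1": -1}},
    "GLU": {"acceptor": {"OE1", "OE2"}, "charged": {"OE1": -1}},
    "LYS": {"donor": {"NZ"}, "charged": {"NZ": 1}},
    "ARG": {"donor": {"NE", "NH1", "NH2"}, "charged": {"NH1": 1}},
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def classify_residue_atoms(
    resname: str, atoms: Sequence[tuple[str, str, tuple[float, float, float]]]
) -> tuple[list[PocketAtom], tuple[str, ...]]:
    """Classify (name, element, xyz) records of one residue for fingerprinting."""
    rules = _SIDECHAIN.get(resname, {})
    donors = rules.get("donor", set())
    acceptors = rules.get("acceptor", set())
    charged = rules.get("charged", {})
    ring = tuple(rules.get("ring", ()))
    coords = {name: np.array(xyz) for name, _, xyz in atoms}
    out = []
    for name, element, xyz in atoms:
        # side-chain carbons (aromatic included) count as apolar contact atoms;
        # the backbone carbonyl carbon does not
        apolar = element == "C" and name not in {"C", "CA"}
        base = None
        if name in donors:
            # nearest other heavy atom of the residue approximates the bonded base
            others = [(np.linalg.norm(coords[n] - coords[name]), n) for n in coords if n != name]
            if others:
                base = tuple(map(float, coords[min(others)[1]]))
        out.append(
            PocketAtom(
                name=name,
                element=element,
                xyz=tuple(map(float, xyz)),
                is_donor=name in donors,
                is_acceptor=name in acceptors,
                is_apolar_carbon=apolar,
                charge=charged.get(name, 0),
                base_xyz=base,
            )
        )
    return out, ring


def read_pocket_pdb(
    path: str | Path,
    label_map: Mapping[str, str],
    pocket_center: Sequence[float] | None = None,
    bbox_margin: float = 3.0,
) -> PocketModel:
    """Pocket model from PDB coordinates (first model, altloc 'A').

    ``label_map`` maps residue sequence numbers (as strings) to
    Ballesteros-Weinstein labels, e.g. ``{"260": "Y260^6.52"}``; unmapped
    residues get ``<aa1><resseq>``.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pocket", str(path))
    model = next(structure.get_models())
    residues: list[PocketResidue] = []
    for chain in model:
        for res in chain:
            if res.id[0] != " ":
                continue
            resname = res.get_resname()
            atoms = []
            for atom in res:
                if atom.get_altloc() not in (" ", "A"):
                    continue
                el = atom.element.strip().capitalize() or atom.get_name()[0]
                atoms.append((atom.get_name(), el, tuple(map(float, atom.get_coord()))))
            if not atoms:
                continue
            classified, ring = classify_residue_atoms(resname, atoms)
            resseq = str(res.id[1])
            label = label_map.get(resseq, f"{_AA3TO1.get(resname, 'X')}{resseq}")
            residues.append(PocketResidue(label=label, resname=resname, atoms=classified,
                                          ring_atom_names=ring))
    coords = np.array([a.xyz for r in residues for a in r.atoms])
    lo, hi = coords.min(axis=0) - bbox_margin, coords.max(axis=0) + bbox_margin
    center = np.array(pocket_center, float) if pocket_center is not None else coords.mean(axis=0)
    return PocketModel(residues=residues, pocket_center=center, bbox=(lo, hi))


# ---------------------------------------------------------------------------
# interaction fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IFPParams:
    """Geometric cutoffs for the four interaction types."""

    hbond_distance: float = 3.5   # donor-acceptor heavy-atom distance, A
    hbond_angle: float = 120.0    # D-H...A angle, degrees (>=)
    hydrophobic_distance: float = 4.5
    ionic_distance: float = 4.0
    aromatic_distance: float = 5.0


@dataclass
class InteractionFingerprint:
    """Per-residue x interaction-type presence bits for one pose."""

    residue_labels: tuple[str, ...]
    bits: dict[tuple[str, str], int] = field(default_factory=dict)

    def set(self, label: str, itype: str) -> None:
        if itype not in INTERACTION_TYPES:
            raise ConfigurationError(f"unknown interaction type {itype!r}")
        if label not in self.residue_labels:
            raise ConfigurationError(f"unknown residue label {label!r}")
        self.bits[(label, itype)] = 1

    def get(self, label: str, itype: str) -> int:
        return self.bits.get((label, itype), 0)

    def any_contact(self, label: str) -> bool:
        return any(self.get(label, t) for t in INTERACTION_TYPES)

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.get(l, t) for l in self.residue_labels for t in INTERACTION_TYPES], int
        )


class _LigandView:
    """Interaction-relevant atom sets of a posed ligand conformer."""

    def __init__(self, mol: Chem.Mol, conf_id: int = 0, pH: float = 7.0):
        if mol.GetNumConformers() == 0:
            raise GeometryError("ligand pose needs a conformer")
        self.pos = mol.GetConformer(conf_id).GetPositions()
        self.donors: list[tuple[int, list[int]]] = []   # heavy atom, its H indices
        self.acceptors: list[int] = []
        self.apolar: list[int] = []
        for atom in mol.GetAtoms():
            i, sym = atom.GetIdx(), atom.GetSymbol()
            hs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetSymbol() == "H"]
            if sym in ("O", "N"):
                if hs or atom.GetTotalNumHs() > 0:
                    self.donors.append((i, hs))
                self.acceptors.append(i)
            elif sym == "C":
                if all(n.GetSymbol() in ("C", "H") for n in atom.GetNeighbors()):
                    self.apolar.append(i)
        self.rings = [
            np.array([self.pos[i] for i in ring]).mean(axis=0)
            for ring in mol.GetRingInfo().AtomRings()
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
        ]
        self.charges: list[tuple[int, int]] = []  # (atom, charge)
        for a in mol.GetAtoms():
            if a.GetFormalCharge():
                self.charges.append((a.GetIdx(), a.GetFormalCharge()))
        for _name, atoms, q in ionizable_sites(mol, pH=pH):
            if q:
                self.charges.append((atoms[0], q))
        self.heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees)."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def compute_ifp(
    pocket: PocketModel,
    pose: Chem.Mol,
    conf_id: int = 0,
    params: IFPParams = IFPParams(),
    pH: float = 7.0,
) -> InteractionFingerprint:
    """Interaction fingerprint of one posed ligand conformer in the pocket frame.

    A pose entirely outside the pocket bounding box yields an all-zero
    fingerprint with a logged warning.
    """
    lig = _LigandView(pose, conf_id, pH=pH)
    fp = InteractionFingerprint(residue_labels=tuple(pocket.labels))
    lo, hi = pocket.bbox
    heavy = lig.pos[lig.heavy]
    if np.all(np.any((heavy < lo) | (heavy > hi), axis=1)):
        log.warning("pose lies entirely outside the pocket bounding box; zero fingerprint")
        return fp

    for res in pocket.residues:
        # hydrophobic: any apolar carbon pair within cutoff
        res_apolar = np.array([a.xyz for a in res.atoms if a.is_apolar_carbon])
        if len(res_apolar) and lig.apolar:
            d = np.linalg.norm(lig.pos[lig.apolar][:, None, :] - res_apolar[None], axis=-1)
            if d.min() <= params.hydrophobic_distance:
                fp.set(res.label, "hydrophobic")

        # H-bond, both directions
        for a in res.atoms:
            axyz = np.array(a.xyz)
            if a.is_acceptor:
                for d_idx, hs in lig.donors:
                    if np.linalg.norm(lig.pos[d_idx] - axyz) <= params.hbond_distance:
                        if not hs:
                            fp.set(res.label, "hbond")
                        elif any(_angle(lig.pos[d_idx], lig.pos[h], axyz) >= params.hbond_angle
                                 for h in hs):
                            fp.set(res.label, "hbond")
            if a.is_donor:
                for acc in lig.acceptors:
                    if np.linalg.norm(lig.pos[acc] - axyz) <= params.hbond_distance:
                        # pocket hydrogens are usually absent; require the
                        # acceptor to sit on the outward side of the donor
                        if a.base_xyz is None or _angle(
                            np.array(a.base_xyz), axyz, lig.pos[acc]
                        ) >= 90.0:
                            fp.set(res.label, "hbond")

        # ionic ("ion-lock"): opposite formal charges within cutoff
        for a in res.atoms:
            if a.charge == 0:
                continue
            for li, lq in lig.charges:
                if lq * a.charge < 0 and np.linalg.norm(
                    lig.pos[li] - np.array(a.xyz)
                ) <= params.ionic_distance:
                    fp.set(res.label, "ionic")

        # aromatic: ring-centroid proximity
        cen = res.ring_centroid()
        if cen is not None:
            for lring in lig.rings:
                if np.linalg.norm(lring - cen) <= params.aromatic_distance:
                    fp.set(res.label, "aromatic")
    return fp


def contact_frequency(fps: Sequence[InteractionFingerprint]) -> dict[str, float]:
    """Per-residue percentage of fingerprints with any contact bit set."""
    if not fps:
        raise InsufficientDataError("contact_frequency needs at least one fingerprint")
    labels = fps[0].residue_labels
    for fp in fps:
        if fp.residue_labels != labels:
            raise ConfigurationError("fingerprints computed over different residue sets")
    return {
        label: 100.0 * sum(fp.any_contact(label) for fp in fps) / len(fps)
        for label in labels
    }


# ---------------------------------------------------------------------------
# pocket volume
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketVolume:
    volume: float
    grid_spacing: float
    probe_radius: float
    voxel_count: int


def pocket_volume(
    pocket: PocketModel,
    spacing: float = 0.5,
    probe_radius: float = 1.4,
    mode: str = "probe",
) -> PocketVolume:
    """Cavity volume by flood fill from the pocket center.

    A voxel is accessible when its center lies at least ``r_vdw [+ probe]``
    from every protein atom center ("probe" vs "atom-center" mode).  The
    connected accessible component containing the seed (6-connectivity,
    clipped to the bounding box) is the pocket.
    """
    if mode not in ("probe", "atom-center"):
        raise ConfigurationError(f"unknown pocket-volume mode {mode!r}")
    pad = probe_radius if mode == "probe" else 0.0
    atoms = pocket.all_atoms()
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) + pad for a in atoms])
    lo, hi = pocket.bbox
    origin = np.asarray(lo, float)
    shape = tuple(np.ceil((np.asarray(hi) - origin) / spacing).astype(int))
    blocked = np.zeros(shape, bool)
    _mark_spheres(blocked, origin, spacing, coords, radii)

    seed = tuple(((np.asarray(pocket.pocket_center) - origin) / spacing).astype(int))
    if any(s < 0 or s >= dim for s, dim in zip(seed, shape)):
        raise GeometryError("pocket center outside the bounding box")
    if blocked[seed]:
        raise GeometryError("pocket center is occluded by protein atoms")

    structure6 = ndimage.generate_binary_structure(3, 1)
    labels, _n = ndimage.label(~blocked, structure=structure6)
    count = int((labels == labels[seed]).sum())
    return PocketVolume(
        volume=count * spacing**3,
        grid_spacing=spacing,
        probe_radius=probe_radius if mode == "probe" else 0.0,
        voxel_count=count,
    )


def percent_volume_change(v_apo: float, v_holo: float) -> int:
    """Relative pocket-volume change in percent, rounded half away from zero."""
    if v_apo <= 0:
        raise ValueError("apo volume must be positive")
    pct = 100.0 * (v_holo - v_apo) / v_apo
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))
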