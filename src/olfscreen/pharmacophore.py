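"""Pharmacophore perception, the six-site receptor model, 3D matching and the
shape/ionization/polarity selection filters.

Feature perception is rule based: hydroxyl oxygens are ambivalent H-bond
partners (donor-or-acceptor), ether/carbonyl oxygens are acceptors, N-H groups
donors, other nitrogens acceptors, aromatic rings contribute ring centroids,
and connected groups of three or more apolar aliphatic carbons contribute
hydrophobic centroids.

Matching asks whether a rigid-body placement of the conformer's features puts
a kind-compatible feature inside every required tolerance sphere.  The search
enumerates kind-compatible injective assignments with pairwise distance
pruning (a rigid motion cannot change an inter-feature distance by more than
twice the tolerance) and verifies each candidate by Kabsch superposition.
"""

from __future__ import annotations

import gzip
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from ._ionization import net_charge
from .chemlib import Compound, compute_descriptors, embed_conformers
from .errors import ConfigurationError, GeometryError, MissingGeometryError

log = logging.getLogger(__name__)

FEATURE_KINDS = ("donor", "acceptor", "donor_or_acceptor", "hydrophobic", "aromatic")

#: features acceptable inside a site of a given kind
SITE_COMPATIBILITY = {
    "donor": {"donor", "donor_or_acceptor"},
    "acceptor": {"acceptor", "donor_or_acceptor"},
    "donor_or_acceptor": {"donor", "acceptor", "donor_or_acceptor"},
    "hydrophobic": {"hydrophobic", "aromatic"},
    "aromatic": {"aromatic"},
}

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

DEFAULT_SITE_RADIUS = 1.0  # Angstrom
COUNTER_SPACING = 0.5  # Angstrom
COUNTER_MAX_VOLUME = 230.0  # A^3, the inclusion-volume cap
DEFAULT_OUTSIDE_TOLERANCE = 0.10
DEFAULT_MAX_PSA = 55.0  # A^2, upper edge of the poor-potency PSA band


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class Site:
    kind: str
    center: tuple[float, float, float]
    radius: float = DEFAULT_SITE_RADIUS

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ConfigurationError(f"unknown site kind {self.kind!r}")
        if self.radius <= 0:
            raise ConfigurationError("site tolerance radius must be positive")


@dataclass
class PharmacophoreModel:
    """Ordered tolerance spheres a candidate must occupy."""

    sites: list[Site]
    required_matches: int | None = None  # None -> all sites

    def __post_init__(self):
        if not self.sites:
            raise ConfigurationError("a pharmacophore model needs at least one site")
        if self.required_matches is None:
            self.required_matches = len(self.sites)
        if not 1 <= self.required_matches <= len(self.sites):
            raise ConfigurationError("required_matches out of range")

    def to_json(self) -> str:
        return json.dumps(
            {
                "required_matches": self.required_matches,
                "sites": [
                    {"kind": s.kind, "center": list(s.center), "radius": s.radius}
                    for s in self.sites
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        obj = json.loads(text)
        sites = [Site(s["kind"], tuple(s["center"]), s["radius"]) for s in obj["sites"]]
        return cls(sites=sites, required_matches=obj.get("required_matches"))


#: site kinds of the six-site eugenol-receptor model: an ambivalent H-bond
#: sphere next to the conserved tyrosine hydroxyl (I), an acceptor sphere next
#: to it (II), and four hydrophobic spheres (III-VI)
OLFR73_SITE_KINDS = (
    "donor_or_acceptor",
    "acceptor",
    "hydrophobic",
    "hydrophobic",
    "hydrophobic",
    "hydrophobic",
)


def build_olfr73_ph4(
    anchors: Sequence[Sequence[float]],
    radius: float = DEFAULT_SITE_RADIUS,
    required_matches: int | None = None,
) -> PharmacophoreModel:
    """Six-site receptor pharmacophore from anchor coordinates (sites I..VI)."""
    if len(anchors) != 6:
        raise ConfigurationError(f"expected 6 anchor points, got {len(anchors)}")
    if radius <= 0:
        raise ConfigurationError("site tolerance radius must be positive")
    sites = [Site(kind, tuple(map(float, a)), radius) for kind, a in zip(OLFR73_SITE_KINDS, anchors)]
    return PharmacophoreModel(sites=sites, required_matches=required_matches)


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def perceive_features(mol: Chem.Mol, conf_id: int = 0) -> list[PharmacophoreFeature]:
    """Rule-based pharmacophore features of one conformer.

    ``mol`` must carry at least one conformer (explicit hydrogens are used to
    tell hydroxyls from ethers but feature centers are heavy-atom centroids).
    """
    if mol.GetNumConformers() == 0:
        raise MissingGeometryError("feature perception needs a conformer")
    pos = mol.GetConformer(conf_id).GetPositions()
    feats: list[PharmacophoreFeature] = []

    def _add(kind: str, atoms: Sequence[int]):
        center = pos[list(atoms)].mean(axis=0)
        feats.append(PharmacophoreFeature(kind, tuple(map(float, center)), tuple(atoms)))

    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        i = atom.GetIdx()
        if sym == "O":
            has_h = atom.GetTotalNumHs() > 0 or any(n.GetSymbol() == "H" for n in atom.GetNeighbors())
            _add("donor_or_acceptor" if has_h else "acceptor", [i])
        elif sym == "N":
            has_h = atom.GetTotalNumHs() > 0 or any(n.GetSymbol() == "H" for n in atom.GetNeighbors())
            _add("donor" if has_h else "acceptor", [i])

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            _add("aromatic", list(ring))

    apolar = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C"
        and not a.GetIsAromatic()
        and all(n.GetSymbol() in ("C", "H") for n in a.GetNeighbors())
    }
    seen: set[int] = set()
    for i in sorted(apolar):
        if i in seen:
            continue
        comp, stack = {i}, [i]
        while stack:
            j = stack.pop()
            for n in mol.GetAtomWithIdx(j).GetNeighbors():
                k = n.GetIdx()
                if k in apolar and k not in comp:
                    comp.add(k)
                    stack.append(k)
        seen |= comp
        if len(comp) >= 3:
            _add("hydrophobic", sorted(comp))
    return feats


# ---------------------------------------------------------------------------
# rigid-body matching
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with ``R @ P.T + t ~ Q`` (least squares)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


@dataclass
class MatchResult:
    matched: bool
    site_assignments: dict[int, PharmacophoreFeature] = field(default_factory=dict)
    rmsd_of_assignment: float = float("inf")
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    conformer_id: int = -1

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Map conformer-frame coordinates into the model frame."""
        if self.rotation is None:
            raise GeometryError("no alignment available")
        return coords @ self.rotation.T + self.translation


def _assignment_result(
    sites: Sequence[Site], feats: Sequence[PharmacophoreFeature], assign: Sequence[int]
) -> tuple[bool, float, np.ndarray, np.ndarray]:
    P = np.array([feats[j].center for j in assign], float)
    Q = np.array([s.center for s in sites], float)
    if len(assign) == 1:
        R = np.eye(3)
        t = Q[0] - P[0]
    else:
        R, t = kabsch(P, Q)
    placed = P @ R.T + t
    dists = np.linalg.norm(placed - Q, axis=1)
    ok = bool(np.all(dists <= np.array([s.radius for s in sites]) + 1e-9))
    rmsd = float(np.sqrt(np.mean(dists**2)))
    return ok, rmsd, R, t


def match_features(
    features: Sequence[PharmacophoreFeature], model: PharmacophoreModel
) -> MatchResult:
    """Best rigid-body assignment of perceived features to the model's sites.

    Enumerates kind-compatible injective assignments (with pairwise-distance
    pruning), superposes each by Kabsch, and accepts assignments placing every
    required site's feature inside its tolerance sphere.  Ties are broken by
    lower RMSD, then by lexicographic assignment order.
    """
    feats = list(features)
    best = MatchResult(matched=False)

    site_subsets: Iterable[tuple[int, ...]]
    if model.required_matches == len(model.sites):
        site_subsets = [tuple(range(len(model.sites)))]
    else:
        site_subsets = itertools.combinations(range(len(model.sites)), model.required_matches)

    fpos = np.array([f.center for f in feats], float) if feats else np.zeros((0, 3))
    fdist = np.linalg.norm(fpos[:, None, :] - fpos[None, :, :], axis=-1) if feats else None

    for subset in site_subsets:
        sites = [model.sites[i] for i in subset]
        spos = np.array([s.center for s in sites], float)
        sdist = np.linalg.norm(spos[:, None, :] - spos[None, :, :], axis=-1)
        compat = [
            [j for j, f in enumerate(feats) if f.kind in SITE_COMPATIBILITY[s.kind]]
            for s in sites
        ]
        if any(not c for c in compat):
            continue

        def _search(k: int, assign: list[int]):
            nonlocal best
            if k == len(sites):
                ok, rmsd, R, t = _assignment_result(sites, feats, assign)
                if ok and (not best.matched or rmsd < best.rmsd_of_assignment - 1e-12):
                    best = MatchResult(
                        matched=True,
                        site_assignments={si: feats[j] for si, j in zip(subset, assign)},
                        rmsd_of_assignment=rmsd,
                        rotation=R,
                        translation=t,
                    )
                return
            for j in compat[k]:
                if j in assign:
                    continue
                tol_slack = 2.0 * max(s.radius for s in sites)
                if any(abs(fdist[j, assign[m]] - sdist[k, m]) > tol_slack for m in range(k)):
                    continue
                assign.append(j)
                _search(k + 1, assign)
                assign.pop()

        _search(0, [])
    return best


def match_ph4(
    compound: Compound,
    model: PharmacophoreModel,
    n_conformers: int = 10,
    seed: int = 2019,
) -> MatchResult:
    """Match a compound against the model over a seeded conformer ensemble."""
    mol = embed_conformers(compound, n_conformers=n_conformers, seed=seed)
    best = MatchResult(matched=False)
    for conf in mol.GetConformers():
        res = match_features(perceive_features(mol, conf.GetId()), model)
        res.conformer_id = conf.GetId()
        if res.matched and res.rmsd_of_assignment < best.rmsd_of_assignment:
            best = res
    if best.matched:
        compound.meta["_ph4_alignment"] = (mol, best)
    return best


# ---------------------------------------------------------------------------
# shape-volume counter
# ---------------------------------------------------------------------------

@dataclass
class ShapeCounter:
    """Inclusion volume built from superimposed known actives.

    ``occupancy`` is a boolean voxel grid in the model frame; candidates whose
    van-der-Waals volume exceeds ``max_volume`` or that protrude from the
    occupancy grid are rejected.
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray  # 3D bool
    max_volume: float = COUNTER_MAX_VOLUME

    def __post_init__(self):
        if self.max_volume <= 0:
            raise ConfigurationError("max_volume must be positive")

    @property
    def total_volume(self) -> float:
        return float(self.occupancy.sum()) * self.spacing**3

    def save(self, path: str | Path) -> None:
        idx = np.argwhere(self.occupancy)
        payload = {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "shape": list(self.occupancy.shape),
            "max_volume": self.max_volume,
            "voxels": idx.tolist(),
        }
        with gzip.open(path, "wt") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ShapeCounter":
        with gzip.open(path, "rt") as fh:
            payload = json.load(fh)
        occ = np.zeros(tuple(payload["shape"]), bool)
        idx = np.array(payload["voxels"], int)
        if len(idx):
            occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return cls(
            origin=np.array(payload["origin"]),
            spacing=payload["spacing"],
            occupancy=occ,
            max_volume=payload["max_volume"],
        )


def _mark_spheres(
    occupancy: np.ndarray, origin: np.ndarray, spacing: float,
    coords: np.ndarray, radii: np.ndarray,
) -> None:
    """Mark voxels whose centers fall inside any sphere (in place)."""
    shape = occupancy.shape
    for (x, y, z), r in zip(coords, radii):
        lo = np.maximum(np.floor((np.array([x, y, z]) - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((np.array([x, y, z]) + r - origin) / spacing).astype(int) + 1,
                        shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[d] + (np.arange(lo[d], hi[d]) + 0.5) * spacing for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        mask = (gx - x) ** 2 + (gy - y) ** 2 + (gz - z) ** 2 <= r**2
        occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= mask


def _atom_spheres(mol: Chem.Mol, conf_id: int = -1) -> tuple[np.ndarray, np.ndarray]:
    conf = mol.GetConformer(conf_id)
    coords, radii = [], []
    for atom in mol.GetAtoms():
        coords.append(conf.GetAtomPosition(atom.GetIdx()))
        radii.append(VDW_RADII.get(atom.GetSymbol(), DEFAULT_VDW))
    return np.array([[p.x, p.y, p.z] for p in coords]), np.array(radii)


def build_shape_counter(
    aligned: Sequence[tuple[np.ndarray, np.ndarray]],
    spacing: float = COUNTER_SPACING,
    max_volume: float = COUNTER_MAX_VOLUME,
) -> ShapeCounter:
    """Voxel union of aligned ligand conformers.

    ``aligned`` is a sequence of ``(coords, radii)`` pairs already expressed in
    the common model frame.
    """
    if not aligned:
        raise ConfigurationError("need at least one aligned ligand")
    all_c = np.vstack([c for c, _ in aligned])
    rmax = max(float(r.max()) for _, r in aligned)
    origin = all_c.min(axis=0) - rmax - spacing
    top = all_c.max(axis=0) + rmax + spacing
    shape = tuple(np.ceil((top - origin) / spacing).astype(int) + 1)
    occ = np.zeros(shape, bool)
    for coords, radii in aligned:
        _mark_spheres(occ, origin, spacing, coords, radii)
    return ShapeCounter(origin=origin, spacing=spacing, occupancy=occ, max_volume=max_volume)


@dataclass(frozen=True)
class ShapeFilterResult:
    passed: bool
    conformer_volume: float
    outside_fraction: float


def shape_volume_filter(
    coords: np.ndarray,
    radii: np.ndarray,
    counter: ShapeCounter,
    outside_tolerance: float = DEFAULT_OUTSIDE_TOLERANCE,
) -> ShapeFilterResult:
    """Volume and protrusion check of an aligned conformer against the counter.

    The conformer volume is integrated on the counter lattice; a voxel of the
    conformer counts as *outside* when it is not part of the counter occupancy
    (including voxels beyond the grid bounds).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    spacing = counter.spacing
    rmax = float(radii.max())
    origin = np.minimum(counter.origin, coords.min(axis=0) - rmax - spacing)
    # snap to counter lattice so voxel centers coincide
    origin = counter.origin - np.ceil((counter.origin - origin) / spacing) * spacing
    top = np.maximum(
        counter.origin + np.array(counter.occupancy.shape) * spacing,
        coords.max(axis=0) + rmax + spacing,
    )
    shape = tuple(np.ceil((top - origin) / spacing).astype(int) + 1)
    occ = np.zeros(shape, bool)
    _mark_spheres(occ, origin, spacing, coords, radii)
    vol = float(occ.sum()) * spacing**3

    offset = np.round((counter.origin - origin) / spacing).astype(int)
    inside = np.zeros_like(occ)
    cshape = counter.occupancy.shape
    sl = tuple(slice(offset[d], offset[d] + cshape[d]) for d in range(3))
    inside[sl] = counter.occupancy
    n_occ = occ.sum()
    outside_fraction = float((occ & ~inside).sum() / n_occ) if n_occ else 0.0
    passed = vol <= counter.max_volume + 1e-9 and outside_fraction <= outside_tolerance + 1e-12
    return ShapeFilterResult(passed=passed, conformer_volume=vol, outside_fraction=outside_fraction)


def conformer_spheres(compound: Compound, conf_id: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """(coords, vdW radii) of a compound's embedded conformer."""
    mol = embed_conformers(compound)
    return _atom_spheres(mol, conf_id)


# ---------------------------------------------------------------------------
# ionization and polarity filters
# ---------------------------------------------------------------------------

def ionization_penalty(compound: Compound, pH: float = 7.0) -> tuple[int, bool]:
    """Net charge of the dominant species at ``pH`` and whether it is penalized.

    Penalized means the dominant species is not neutral; used as a hard filter
    in the funnel (a score-offset mode is available there).
    """
    charge, groups = net_charge(compound.mol, pH=pH)
    compound.meta["_ionizable_groups"] = groups
    return charge, charge != 0


def polarity_filter(compound: Compound, max_psa: float = DEFAULT_MAX_PSA) -> bool:
    """Pass iff topological polar surface area does not exceed ``max_psa``."""
    return compute_descriptors(compound).PSA <= max_psa
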