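"""Compound data model, structure I/O, descriptors, and the first funnel stage.

A :class:`Compound` wraps an RDKit molecule together with a stable identifier.
Descriptors follow the conventions used when property-filtering screening
libraries: molecular mass, Crippen clogP, rotatable-bond count, topological
polar surface area, grid-based van-der-Waals molecular volume, and the net
formal charge of the dominant species at pH 7.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

from ._ionization import net_charge
from .errors import ConfigurationError, EmptyLibraryError, InvalidStructureError, MissingGeometryError

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("M", "clogP", "nRot", "PSA", "mol_volume", "net_charge_pH7")

#: conformer-embedding seed used everywhere a single reference conformer is needed
DEFAULT_CONFORMER_SEED = 2019

#: grid spacing (Angstrom) for molecular-volume integration; matches the
#: pocket-volume grid engine so ligand and pocket volumes are comparable
VOLUME_GRID_SPACING = 0.4


@dataclass
class Compound:
    """A library member: identifier, optional name, RDKit molecule.

    The molecule may or may not carry conformers; operations that need 3D
    coordinates call :func:`ensure_conformer` / :func:`embed_conformers`.
    """

    id: str
    mol: Chem.Mol
    name: str = ""
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_smiles(cls, smiles: str, id: str, name: str = "", **meta) -> "Compound":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise InvalidStructureError(f"unparseable SMILES for {id!r}: {smiles!r}")
        return cls(id=id, mol=mol, name=name, meta=dict(meta))

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def has_conformer(self) -> bool:
        return self.mol.GetNumConformers() > 0


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors of one compound."""

    M: float
    clogP: float
    nRot: int
    PSA: float
    mol_volume: float
    net_charge_pH7: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


@dataclass(frozen=True)
class PropertyFilterSpec:
    """Closed intervals per descriptor name, e.g. ``{"M": (110, 320)}``."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if name not in DESCRIPTOR_NAMES:
                raise ConfigurationError(f"unknown descriptor {name!r}")
            if lo > hi:
                raise ConfigurationError(f"empty interval for {name!r}: [{lo}, {hi}]")

    def accepts(self, d: DescriptorSet) -> bool:
        vals = d.as_dict()
        return all(lo <= vals[n] <= hi for n, (lo, hi) in self.ranges.items())


#: mass window used in the original screen ("M of 110-320 Da")
DEFAULT_MASS_FILTER = PropertyFilterSpec({"M": (110.0, 320.0)})


def read_library(path: str | Path, fmt: str | None = None) -> list[Compound]:
    """Read a SMILES (.smi, one record per line, optional name) or SDF library.

    Invalid records are skipped with a logged warning and counted in the
    returned compounds' shared metadata is not touched; the skip count is
    logged.  Raises :class:`EmptyLibraryError` if no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".sd", ".mol") else "smi"

    compounds: list[Compound] = []
    skipped = 0
    if fmt == "smi":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                skipped += 1
                log.warning("%s:%d: skipping unparseable record %r", path.name, ln, parts[0])
                continue
            name = parts[1].strip() if len(parts) > 1 else ""
            compounds.append(Compound(id=name or f"{path.stem}_{ln}", mol=mol, name=name))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                log.warning("%s: skipping unparseable SDF record %d", path.name, i)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            compounds.append(Compound(id=name or f"{path.stem}_{i}", mol=mol, name=name))
    else:
        raise ConfigurationError(f"unknown library format {fmt!r}")

    if not compounds:
        raise EmptyLibraryError(f"{path}: no valid records (skipped {skipped})")
    if skipped:
        log.warning("%s: skipped %d invalid records", path.name, skipped)
    return compounds


def embed_conformers(
    compound: Compound,
    n_conformers: int = 1,
    seed: int = DEFAULT_CONFORMER_SEED,
    optimize: bool = True,
) -> Chem.Mol:
    """Return a molecule with explicit hydrogens and embedded 3D conformers.

    Distance-geometry (ETKDG) embedding with a fixed random seed; conformers
    are MMFF-optimized when possible.  The embedded molecule is cached on the
    compound (keyed by seed and count) so repeat calls are cheap.
    """
    key = ("_embedded", n_conformers, seed, optimize)
    if key in compound.meta:
        return compound.meta[key]
    mol = Chem.AddHs(Chem.Mol(compound.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if len(ids) == 0:
        # fall back to random coordinates for pathological inputs
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if len(ids) == 0:
        raise MissingGeometryError(f"could not embed a conformer for {compound.id}")
    if optimize:
        try:
            AllChem.MMFFOptimizeMoleculeConfs(mol)
        except Exception:  # MMFF typing can fail for exotic atoms; keep raw geometry
            pass
    compound.meta[key] = mol
    return mol


def lowest_energy_conformer(compound: Compound, seed: int = DEFAULT_CONFORMER_SEED) -> Chem.Mol:
    """Single MMFF-optimized conformer used for 3D feature perception."""
    return embed_conformers(compound, n_conformers=1, seed=seed)


def _vdw_volume(mol: Chem.Mol, conf_id: int = -1, spacing: float = VOLUME_GRID_SPACING) -> float:
    """Grid volume (A^3) of the union of van-der-Waals spheres of one conformer."""
    return float(AllChem.ComputeMolVolume(mol, confId=conf_id, gridSpacing=spacing))


def compute_descriptors(compound: Compound, pH: float = 7.0) -> DescriptorSet:
    """All six descriptors; deterministic for a fixed structure.

    The molecular volume is integrated on a 0.4 A grid over one seeded
    low-energy conformer.  Results are cached on the compound.
    """
    cache_key = ("_descriptors", pH)
    if cache_key in compound.meta:
        return compound.meta[cache_key]
    mol = compound.mol
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise InvalidStructureError(f"{compound.id}: {exc}") from exc
    mol3d = lowest_energy_conformer(compound)
    charge, _groups = net_charge(mol, pH=pH)
    d = DescriptorSet(
        M=float(Descriptors.MolWt(mol)),
        clogP=float(Crippen.MolLogP(mol)),
        nRot=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        PSA=float(rdMolDescriptors.CalcTPSA(mol)),
        mol_volume=_vdw_volume(mol3d),
        net_charge_pH7=charge,
    )
    compound.meta[cache_key] = d
    return d


@dataclass
class FilterReport:
    """Input/output counts of one property-filter application."""

    n_in: int
    n_out: int
    spec: PropertyFilterSpec


def physchem_filter(
    library: Sequence[Compound], spec: PropertyFilterSpec = DEFAULT_MASS_FILTER
) -> tuple[list[Compound], FilterReport]:
    """Keep compounds whose every filtered descriptor lies in its closed interval.

    Order is preserved; the report records input and output counts.
    """
    survivors = [c for c in library if spec.accepts(compute_descriptors(c))]
    return survivors, FilterReport(n_in=len(library), n_out=len(survivors), spec=spec)


def mass_distribution(library: Sequence[Compound], bin_width: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of molecular masses with half-open bins ``[lo, hi)``.

    Returns ``(counts, bin_edges)``; counts sum to the library size.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin width must be positive")
    if not library:
        raise EmptyLibraryError("mass_distribution needs a non-empty library")
    masses = np.array([compute_descriptors(c).M for c in library])
    lo = math.floor(masses.min() / bin_width) * bin_width
    hi = math.floor(masses.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(masses, bins=edges)
    return counts, edges


def descriptor_table(library: Iterable[Compound]):
    """Descriptor table (one row per compound) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in library:
        d = compute_descriptors(c)
        rows.append({"id": c.id, "name": c.name, **d.as_dict()})
    return pd.DataFrame(rows, columns=["id", "name", *DESCRIPTOR_NAMES])
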