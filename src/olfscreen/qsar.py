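"""Molecular-field QSAR: steric and electrostatic probe fields on a lattice
around aligned ligands, partial-least-squares regression against potency, and
ranking of screening candidates.

The probe is an sp3 carbon with unit positive charge.  Steric energies are
Lennard-Jones 6-12 with Lorentz-Berthelot combination, capped at +30 kcal/mol;
electrostatic energies are Coulombic with a distance-dependent dielectric
(eps = r), capped at +/-30 kcal/mol.  Partial charges are Gasteiger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression


def _fit_pls(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLSRegression:
    pls = PLSRegression(n_components=ncomp, scale=False)
    with warnings.catch_warnings():
        # an exact fit before the last component triggers a benign warning
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(X, y)
    return pls

from .errors import ConfigurationError, InsufficientDataError

COULOMB_CONSTANT = 332.0636  # kcal mol^-1 A e^-2
STERIC_CAP = 30.0
ELECTROSTATIC_CAP = 30.0
PROBE_RADIUS = 1.7   # sp3 carbon Rmin/2, A
PROBE_EPSILON = 0.1  # kcal/mol
PROBE_CHARGE = 1.0

# per-element LJ parameters (Rmin/2 in A, epsilon in kcal/mol)
LJ_PARAMS = {
    "H": (1.20, 0.02), "C": (1.70, 0.10), "N": (1.55, 0.12), "O": (1.52, 0.15),
    "S": (1.80, 0.20), "P": (1.80, 0.20), "F": (1.47, 0.08), "Cl": (1.75, 0.24),
    "Br": (1.85, 0.30), "I": (1.98, 0.40),
}
DEFAULT_LJ = (1.70, 0.10)

DEFAULT_SPACING = 2.0  # A
DEFAULT_MARGIN = 4.0   # A beyond the union bounding box
MIN_COLUMN_SD = 0.05   # kcal/mol; near-constant lattice cells are dropped
MAX_COMPONENTS = 5


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    ec50_uM: float

    def __post_init__(self):
        if self.ec50_uM <= 0:
            raise ConfigurationError("EC50 must be positive")

    @property
    def pEC50(self) -> float:
        return float(-np.log10(self.ec50_uM * 1e-6))


@dataclass
class FieldGrid:
    """Per-ligand steric/electrostatic probe energies on a shared lattice."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    ligand_ids: list[str]
    steric: np.ndarray        # (n_ligands, n_cells)
    electrostatic: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.dims))

    def design_matrix(self) -> np.ndarray:
        return np.hstack([self.steric, self.electrostatic])

    def lattice_points(self) -> np.ndarray:
        ax = [self.origin[d] + np.arange(self.dims[d]) * self.spacing for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def same_lattice(self, other: "FieldGrid") -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


def probe_energies(
    coords: np.ndarray,
    elements: Sequence[str],
    charges: np.ndarray,
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Capped steric and electrostatic probe energies at lattice points."""
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    rmin_half = np.array([LJ_PARAMS.get(e, DEFAULT_LJ)[0] for e in elements])
    eps = np.array([LJ_PARAMS.get(e, DEFAULT_LJ)[1] for e in elements])
    r = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=-1)
    r = np.maximum(r, 1e-6)
    rm = rmin_half + PROBE_RADIUS
    eij = np.sqrt(eps * PROBE_EPSILON)
    frac = (rm / r) ** 6
    steric = np.minimum((eij * (frac**2 - 2 * frac)).sum(axis=1), STERIC_CAP)
    elec = (COULOMB_CONSTANT * PROBE_CHARGE * charges / r**2).sum(axis=1)
    elec = np.clip(elec, -ELECTROSTATIC_CAP, ELECTROSTATIC_CAP)
    return steric, elec


def gasteiger_charges(mol) -> np.ndarray:
    from rdkit.Chem import AllChem

    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()])
    return np.nan_to_num(q)


def compute_fields(
    ligands: Sequence[tuple[str, np.ndarray, Sequence[str], np.ndarray]],
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
) -> FieldGrid:
    """Fields for aligned ligands given as ``(id, coords, elements, charges)``.

    The lattice spans the union bounding box plus ``margin`` unless an explicit
    ``origin``/``dims`` (a training lattice) is provided.
    """
    if not ligands:
        raise ConfigurationError("no ligands")
    if origin is None or dims is None:
        all_c = np.vstack([c for _, c, _, _ in ligands])
        origin = all_c.min(axis=0) - margin
        top = all_c.max(axis=0) + margin
        dims = tuple(np.ceil((top - origin) / spacing).astype(int) + 1)
    if int(np.prod(dims)) == 0:
        raise ConfigurationError("empty lattice")
    grid = FieldGrid(
        origin=np.asarray(origin, float),
        spacing=spacing,
        dims=tuple(dims),
        ligand_ids=[lid for lid, *_ in ligands],
        steric=np.zeros((len(ligands), int(np.prod(dims)))),
        electrostatic=np.zeros((len(ligands), int(np.prod(dims)))),
    )
    points = grid.lattice_points()
    for i, (_lid, coords, elements, charges) in enumerate(ligands):
        s, e = probe_energies(coords, elements, charges, points)
        grid.steric[i] = s
        grid.electrostatic[i] = e
    return grid


@dataclass
class QSARModel:
    n_components: int
    kept_columns: np.ndarray
    column_mean: np.ndarray
    pls: PLSRegression
    r2: float
    q2: float
    training_ids: list[str]
    lattice: tuple  # (origin tuple, spacing, dims) for compatibility checks

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.ravel(self.pls.predict(X[:, self.kept_columns]))


def _loo_q2(X: np.ndarray, y: np.ndarray, ncomp: int) -> float:
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        pls = _fit_pls(X[mask], y[mask], ncomp)
        preds[i] = float(np.ravel(pls.predict(X[i : i + 1]))[0])
    ss_res = float(((y - preds) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def pls_fit(
    grid: FieldGrid,
    activities: Sequence[ActivityRecord],
    n_components: int | None = None,
) -> QSARModel:
    """PLS regression of pEC50 on the field columns.

    Columns with standard deviation below ``MIN_COLUMN_SD`` are dropped.  By
    default the number of latent components (up to 5) maximizes leave-one-out
    q2; pass ``n_components`` to fix it explicitly.
    """
    by_id = {a.compound_id: a for a in activities}
    missing = [lid for lid in grid.ligand_ids if lid not in by_id]
    if missing:
        raise ConfigurationError(f"activities missing for {missing[:3]}...")
    y = np.array([by_id[lid].pEC50 for lid in grid.ligand_ids])
    if len(y) < 5:
        raise InsufficientDataError("PLS fit needs at least five records")
    X_full = grid.design_matrix()
    kept = np.where(X_full.std(axis=0) >= MIN_COLUMN_SD)[0]
    if len(kept) == 0:
        raise InsufficientDataError("no informative field columns")
    X = X_full[:, kept]
    max_comp = min(MAX_COMPONENTS, len(y) - 1, X.shape[1])
    if n_components is not None:
        if not 1 <= n_components <= max_comp:
            raise ConfigurationError(f"n_components must be in 1..{max_comp}")
        ncomp = n_components
        q2s = {ncomp: _loo_q2(X, y, ncomp)}
    else:
        q2s = {nc: _loo_q2(X, y, nc) for nc in range(1, max_comp + 1)}
        ncomp = max(q2s, key=lambda nc: (q2s[nc], -nc))
    pls = _fit_pls(X, y, ncomp)
    y_hat = np.ravel(pls.predict(X))
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return QSARModel(
        n_components=ncomp,
        kept_columns=kept,
        column_mean=X.mean(axis=0),
        pls=pls,
        r2=r2,
        q2=q2s[ncomp],
        training_ids=list(grid.ligand_ids),
        lattice=(tuple(grid.origin), grid.spacing, grid.dims),
    )


def qsar_rank(model: QSARModel, candidates: FieldGrid) -> list[tuple[str, float]]:
    """Candidates sorted by predicted pEC50, descending; ties by compound id."""
    lattice = (tuple(candidates.origin), candidates.spacing, candidates.dims)
    if not (
        lattice[1] == model.lattice[1]
        and lattice[2] == tuple(model.lattice[2])
        and np.allclose(lattice[0], model.lattice[0], atol=1e-9)
    ):
        raise ConfigurationError("candidate fields are not on the training lattice")
    preds = model.predict(candidates.design_matrix())
    order = sorted(zip(candidates.ligand_ids, preds), key=lambda t: (-t[1], t[0]))
    return [(lid, float(p)) for lid, p in order]
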