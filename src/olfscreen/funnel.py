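"""Orchestration of the multi-stage virtual-screening cascade.

Stage order is fixed: physicochemical property filter, pharmacophore match,
shape-volume counter, ionization penalty, polarity ceiling, QSAR ranking.
Individual stages can be disabled.  Every compound's elimination stage is
recorded, and the report carries the original campaign's survivor counts
(1.58 M ZINC compounds down to 64 candidates) as non-reproducible reference
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemlib import (
    Compound,
    DEFAULT_MASS_FILTER,
    PropertyFilterSpec,
    compute_descriptors,
    embed_conformers,
)
from .errors import ConfigurationError
from .pharmacophore import (
    DEFAULT_MAX_PSA,
    PharmacophoreModel,
    ShapeCounter,
    Site,
    _atom_spheres,
    build_shape_counter,
    ionization_penalty,
    match_ph4,
    perceive_features,
    polarity_filter,
    shape_volume_filter,
)

#: survivor counts of the original ZINC campaign (reference metadata only):
#: library, property filter, PH4, shape volume, ionization, polarity,
#: QSAR top ranks, docking-verified
REFERENCE_FUNNEL_COUNTS = (1_580_000, 312_800, 266_000, 493, 371, 204, 100, 64)

STAGE_ORDER = ("physchem", "ph4", "shape_volume", "ionization", "polarity", "qsar_rank")


@dataclass
class FunnelConfig:
    property_spec: PropertyFilterSpec = DEFAULT_MASS_FILTER
    ph4_model: PharmacophoreModel | None = None
    shape_counter: ShapeCounter | None = None
    outside_tolerance: float = 0.10
    ionization_pH: float = 7.0
    ionization_mode: str = "filter"  # "filter" or "offset"
    max_psa: float = DEFAULT_MAX_PSA
    qsar_model: object | None = None
    qsar_top_k: int = 64
    n_conformers: int = 10
    seed: int = 0
    enabled: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})

    def stage_seed(self, stage: str) -> int:
        return self.seed + 100 * STAGE_ORDER.index(stage)


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    params: dict
    seed: int | None = None


@dataclass
class FunnelReport:
    stages: list[StageReport] = field(default_factory=list)
    eliminated: dict = field(default_factory=dict)  # compound id -> stage name
    notes: list[str] = field(default_factory=list)
    reference_counts: tuple = REFERENCE_FUNNEL_COUNTS

    def survivors_per_stage(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]


def build_reference_model(
    reference: Sequence[Compound],
    radius: float = 1.0,
    seed: int = 2019,
) -> tuple[PharmacophoreModel, ShapeCounter]:
    """Pharmacophore model and shape counter derived from known agonists.

    The first reference compound anchors the model: its hydroxyl (site I),
    its strongest acceptor (site II), its aromatic centroid and its aliphatic
    hydrophobic centroid (hydrophobic sites).  All references are then aligned
    to the model and their van-der-Waals union forms the inclusion volume.
    """
    if not reference:
        raise ConfigurationError("need at least one reference agonist")
    anchor = reference[0]
    mol = embed_conformers(anchor, n_conformers=1, seed=seed)
    feats = perceive_features(mol)
    by_kind = {}
    for f in feats:
        by_kind.setdefault(f.kind, []).append(f)
    try:
        site_defs = [
            ("donor_or_acceptor", by_kind["donor_or_acceptor"][0].center),
            ("acceptor", by_kind["acceptor"][0].center),
            ("hydrophobic", by_kind["aromatic"][0].center),
            ("hydrophobic", by_kind["hydrophobic"][0].center),
        ]
    except (KeyError, IndexError) as exc:
        raise ConfigurationError(
            "anchor compound lacks the hydroxyl/acceptor/aromatic/hydrophobic "
            "features needed to place the model sites"
        ) from exc
    model = PharmacophoreModel(sites=[Site(k, c, radius) for k, c in site_defs])

    aligned = []
    for comp in reference:
        res = match_ph4(comp, model, n_conformers=10, seed=seed)
        if not res.matched:
            continue
        emb, _ = comp.meta["_ph4_alignment"]
        coords, radii = _atom_spheres(emb, res.conformer_id)
        aligned.append((res.transform(coords), radii))
    if not aligned:
        raise ConfigurationError("no reference compound matches its own model")
    counter = build_shape_counter(aligned)
    return model, counter


def run_funnel(
    library: Sequence[Compound], config: FunnelConfig
) -> tuple[list[Compound], FunnelReport]:
    """Apply the enabled stages in order, recording every compound's fate."""
    report = FunnelReport()
    current = list(library)

    def _stage(name: str, keep_fn, params: dict, seed: int | None = None):
        nonlocal current
        n_in = len(current)
        survivors = []
        for comp in current:
            if keep_fn(comp):
                survivors.append(comp)
            else:
                report.eliminated[comp.id] = name
        report.stages.append(StageReport(name, n_in, len(survivors), params, seed))
        current = survivors

    cfg = config
    if cfg.enabled.get("physchem", True):
        _stage(
            "physchem",
            lambda c: cfg.property_spec.accepts(compute_descriptors(c)),
            {"ranges": {k: list(v) for k, v in cfg.property_spec.ranges.items()}},
        )

    if cfg.enabled.get("ph4", True):
        if cfg.ph4_model is None:
            raise ConfigurationError("PH4 stage enabled but no model configured")
        seed = cfg.stage_seed("ph4")

        def _match(c: Compound) -> bool:
            res = match_ph4(c, cfg.ph4_model, n_conformers=cfg.n_conformers, seed=seed)
            return res.matched

        _stage("ph4", _match,
               {"sites": len(cfg.ph4_model.sites),
                "required": cfg.ph4_model.required_matches,
                "n_conformers": cfg.n_conformers},
               seed=seed)

    if cfg.enabled.get("shape_volume", True):
        if cfg.shape_counter is None:
            raise ConfigurationError("shape stage enabled but no counter configured")

        def _shape(c: Compound) -> bool:
            align = c.meta.get("_ph4_alignment")
            if align is None:
                return False
            mol, res = align
            coords, radii = _atom_spheres(mol, res.conformer_id)
            out = shape_volume_filter(
                res.transform(coords), radii, cfg.shape_counter,
                outside_tolerance=cfg.outside_tolerance,
            )
            return out.passed

        _stage("shape_volume", _shape,
               {"max_volume": cfg.shape_counter.max_volume,
                "outside_tolerance": cfg.outside_tolerance})

    if cfg.enabled.get("ionization", True):
        if cfg.ionization_mode == "filter":
            _stage("ionization",
                   lambda c: not ionization_penalty(c, pH=cfg.ionization_pH)[1],
                   {"pH": cfg.ionization_pH, "mode": "filter"})
        else:
            # score-offset mode: nothing is eliminated, penalties are recorded
            for c in current:
                charge, pen = ionization_penalty(c, pH=cfg.ionization_pH)
                c.meta["ionization_offset"] = abs(charge)
            report.stages.append(StageReport("ionization", len(current), len(current),
                                             {"pH": cfg.ionization_pH, "mode": "offset"}))

    if cfg.enabled.get("polarity", True):
        _stage("polarity", lambda c: polarity_filter(c, max_psa=cfg.max_psa),
               {"max_psa": cfg.max_psa})

    if cfg.enabled.get("qsar_rank", True) and cfg.qsar_model is not None:
        from .qsar import FieldGrid, compute_fields, gasteiger_charges, qsar_rank

        origin, spacing, dims = cfg.qsar_model.lattice
        ligands = []
        for c in current:
            align = c.meta.get("_ph4_alignment")
            if align is None:
                continue
            mol, res = align
            coords, _ = _atom_spheres(mol, res.conformer_id)
            elements = [a.GetSymbol() for a in mol.GetAtoms()]
            ligands.append((c.id, res.transform(coords), elements, gasteiger_charges(mol)))
        if ligands:
            grid = compute_fields(ligands, spacing=spacing,
                                  origin=np.array(origin), dims=dims)
            ranked = qsar_rank(cfg.qsar_model, grid)
            keep = {lid for lid, _ in ranked[: cfg.qsar_top_k]}
            _stage("qsar_rank", lambda c: c.id in keep, {"top_k": cfg.qsar_top_k})
        else:
            _stage("qsar_rank", lambda c: False, {"top_k": cfg.qsar_top_k})
        report.notes.append(
            "QSAR ranking stands in for the original rank-then-dock tail; "
            "docking verification is out of scope."
        )

    return current, report


def funnel_summary(report: FunnelReport) -> tuple[str, dict]:
    """Human-readable table and JSON-serializable dict of a funnel run."""
    rows = []
    corrupt = []
    for s in report.stages:
        rows.append(f"{s.name:<14} {s.n_in:>8} -> {s.n_out:>8}")
        if s.n_out > s.n_in:
            corrupt.append(s.name)
    text = "stage             in        out\n" + "\n".join(rows)
    if corrupt:
        text += "\nCORRUPT STAGES (output exceeds input): " + ", ".join(corrupt)
    payload = {
        "stages": [
            {"name": s.name, "n_in": s.n_in, "n_out": s.n_out, "params": s.params,
             "seed": s.seed}
            for s in report.stages
        ],
        "eliminated": dict(report.eliminated),
        "corrupt_stages": corrupt,
        "reference_counts": {
            "note": "original campaign survivor counts; not reproducible at desk scale",
            "counts": list(report.reference_counts),
        },
        "notes": list(report.notes),
    }
    json.dumps(payload)  # must round-trip
    return text, payload
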