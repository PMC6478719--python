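"""Rule-based protonation-state assignment at a given pH.

The dominant species is assigned group-by-group from a small pKa table of the
ionizable groups that occur in drug-like screening libraries.  Acidic groups
contribute -1 when pH > pKa, basic groups +1 when pH < pKa.  Groups whose
SMARTS is not in the table are treated as neutral and reported so the caller
can log them.
"""

from __future__ import annotations

from rdkit import Chem

# (name, SMARTS, pKa, kind) -- kind "acid" deprotonates above pKa, "base"
# protonates below pKa.  Imidazole (pKa 7.0) is treated as neutral-dominant
# at pH 7 and therefore listed with kind "neutral".
IONIZABLE_GROUPS: list[tuple[str, str, float, str]] = [
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", 4.2, "acid"),
    ("phenol", "[c][OX2H1]", 10.0, "acid"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]", 12.5, "base"),
    ("amidine", "[NX3][CX3]=[NX2]", 12.5, "base"),
    ("aliphatic_amine", "[NX3;H2,H1,H0;!$([NX3][CX3]=[OX1]);!$([NX3]a);!$([NX3][CX3]=[NX2])]", 10.5, "base"),
    ("aromatic_amine", "[NX3;$([NX3]a);!$([NX3][CX3]=[OX1])]", 4.6, "base"),
    ("imidazole", "c1cnc[nH]1", 7.0, "neutral"),
]

_COMPILED = [(name, Chem.MolFromSmarts(s), pka, kind) for name, s, pka, kind in IONIZABLE_GROUPS]


def ionizable_sites(mol: Chem.Mol, pH: float = 7.0) -> list[tuple[str, tuple[int, ...], int]]:
    """Ionizable groups and the charge their dominant species carries at ``pH``.

    Returns ``[(group_name, atom_indices, charge), ...]``; overlapping matches
    are claimed first-come in table order.
    """
    sites: list[tuple[str, tuple[int, ...], int]] = []
    claimed: set[int] = set()
    for name, patt, pka, kind in _COMPILED:
        if patt is None:  # pragma: no cover - table is static
            continue
        for match in mol.GetSubstructMatches(patt):
            if claimed.intersection(match):
                continue
            claimed.update(match)
            q = 0
            if kind == "acid" and pH > pka:
                q = -1
            elif kind == "base" and pH < pka:
                q = 1
            sites.append((name, tuple(match), q))
    return sites


def net_charge(mol: Chem.Mol, pH: float = 7.0) -> tuple[int, list[str]]:
    """Formal charge of the dominant protonation state at ``pH``.

    Returns ``(charge, matched_group_names)``.  Atoms already carrying an
    explicit formal charge contribute it directly.
    """
    charge = int(sum(a.GetFormalCharge() for a in mol.GetAtoms()))
    sites = ionizable_sites(mol, pH=pH)
    charge += sum(q for _, _, q in sites)
    return charge, [name for name, _, _ in sites]
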