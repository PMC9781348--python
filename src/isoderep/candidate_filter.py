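"""MS-constrained filtering of candidate structures.

Generated candidate structures (SMILES) are standardized — validity check,
stereochemistry stripped, canonicalized, deduplicated — and then filtered
against the mass-spectrometric evidence in stages: (1) the structure must
carry at least one ionizable group (-OH or -COOH) to be visible as
[M-H]-; (2) it must contain at least one of the three tag-enumerated
moieties (aromatic ring, carboxyl, carbonyl); (3) its CHO formula must
match a detected component exactly; and, in strict mode, (4) its group
counts must agree with that component's labeling-derived descriptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .chem_core import InvalidFormulaError, MolecularFormula
from .series_detect import FunctionalDescriptor

__all__ = [
    "GroupCounts",
    "CandidateStructure",
    "FilterReport",
    "StandardizationReport",
    "standardize_candidates",
    "count_groups",
    "filter_candidates",
]

RDLogger.DisableLog("rdApp.*")

_CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_HYDROXYL = Chem.MolFromSmarts("[OX2H]")
_CARBONYL = Chem.MolFromSmarts("[CX3]=[OX1]")


@dataclass(frozen=True)
class GroupCounts:
    """Functional-group counts relevant to the labeling reactions."""

    carboxyl: int
    hydroxyl: int  # non-carboxyl OH (phenolic or alcoholic)
    carbonyl: int  # ketone/aldehyde C=O, excluding carboxyls and esters
    aromatic_rings: int  # fused aromatic systems count once

    @property
    def ionizable(self) -> int:
        return self.carboxyl + self.hydroxyl


@dataclass(frozen=True)
class CandidateStructure:
    """A standardized candidate with its derived formula and groups."""

    smiles: str
    formula: MolecularFormula
    groups: GroupCounts


def _mol_groups(mol: Chem.Mol) -> GroupCounts:
    carboxyl_matches = mol.GetSubstructMatches(_CARBOXYL)
    carboxyl = len(carboxyl_matches)
    carboxyl_c = {m[0] for m in carboxyl_matches}
    carboxyl_oh = {m[2] for m in carboxyl_matches}

    hydroxyl = sum(
        1 for m in mol.GetSubstructMatches(_HYDROXYL) if m[0] not in carboxyl_oh
    )

    carbonyl = 0
    for m in mol.GetSubstructMatches(_CARBONYL):
        c = mol.GetAtomWithIdx(m[0])
        if m[0] in carboxyl_c:
            continue
        # esters/acids have a single-bonded O on the carbonyl carbon;
        # ketones and aldehydes do not
        if any(
            nb.GetAtomicNum() == 8
            and mol.GetBondBetweenAtoms(c.GetIdx(), nb.GetIdx()).GetBondTypeAsDouble() == 1.0
            for nb in c.GetNeighbors()
        ):
            continue
        carbonyl += 1

    ring_info = mol.GetRingInfo()
    aromatic_rings = [
        set(ring)
        for ring in ring_info.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]
    # merge fused rings into systems
    systems: list[set[int]] = []
    for ring in aromatic_rings:
        merged = ring
        rest = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                rest.append(sys_)
        systems = rest + [merged]
    return GroupCounts(
        carboxyl=carboxyl,
        hydroxyl=hydroxyl,
        carbonyl=carbonyl,
        aromatic_rings=len(systems),
    )


def count_groups(structure) -> GroupCounts:
    """Count carboxyl, non-carboxyl OH, ketone/aldehyde C=O and aromatic systems.

    Accepts a :class:`CandidateStructure`, a SMILES string or an RDKit Mol.
    """
    if isinstance(structure, CandidateStructure):
        return structure.groups
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(str(structure))
        if mol is None:
            raise ValueError(f"invalid structure {structure!r}")
    return _mol_groups(Chem.AddHs(mol))


def _formula_from_mol(mol: Chem.Mol) -> Optional[MolecularFormula]:
    counts = {"C": 0, "H": 0, "O": 0}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in counts:
            return None  # not a CHO structure
        counts[sym] += 1
        counts["H"] += atom.GetTotalNumHs()
    if counts["C"] < 1:
        return None
    try:
        return MolecularFormula(c=counts["C"], h=counts["H"], o=counts["O"])
    except InvalidFormulaError:
        return None


@dataclass
class StandardizationReport:
    n_input: int
    n_valid: int
    n_cho: int
    n_unique: int


def standardize_candidates(
    raw: Iterable[str],
) -> tuple[list[CandidateStructure], StandardizationReport]:
    """Validate, strip stereochemistry, canonicalize and deduplicate SMILES.

    Invalid strings and non-CHO structures are dropped (counted, not
    raised — invalidity is data for generated libraries). Duplicates by
    canonical SMILES collapse to one candidate.
    """
    raw = list(raw)
    seen: dict[str, CandidateStructure] = {}
    n_valid = 0
    n_cho = 0
    for s in raw:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        n_valid += 1
        Chem.RemoveStereochemistry(mol)
        formula = _formula_from_mol(mol)
        if formula is None:
            continue
        n_cho += 1
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen[canonical] = CandidateStructure(
            smiles=canonical, formula=formula, groups=_mol_groups(Chem.AddHs(mol))
        )
    report = StandardizationReport(
        n_input=len(raw), n_valid=n_valid, n_cho=n_cho, n_unique=len(seen)
    )
    return list(seen.values()), report


@dataclass
class FilterReport:
    """Stage counts of the candidate filter (non-increasing by design)."""

    n_input: int = 0
    n_valid: int = 0
    n_unique: int = 0
    n_ionizable_pass: int = 0
    n_moiety_pass: int = 0
    n_formula_match: int = 0
    n_descriptor_match: Optional[int] = None
    mode: str = "lenient"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def filter_candidates(
    candidates: Sequence[CandidateStructure],
    components,
    mode: str = "lenient",
    standardization: Optional[StandardizationReport] = None,
) -> tuple[list[CandidateStructure], FilterReport]:
    """Retain candidates compatible with the MS-derived component list.

    Stages: ionizable group (>= 1 OH or COOH), moiety (>= 1 of aromatic /
    carboxyl / carbonyl), exact CHO formula match against the components,
    and in ``strict`` mode agreement with the matched component's known
    descriptor fields (carboxyl count, carbonyl count, aromatic presence).
    ``components`` may be ComponentRecord-like objects (with ``formula``
    and optional ``descriptor``) or bare formulas.
    """
    if mode not in ("lenient", "strict"):
        raise ValueError(f"mode must be 'lenient' or 'strict', got {mode!r}")

    formulas: set[MolecularFormula] = set()
    descriptors: dict[MolecularFormula, FunctionalDescriptor] = {}
    for comp in components:
        if isinstance(comp, MolecularFormula):
            formulas.add(comp)
            continue
        f = comp.formula
        formulas.add(f)
        desc = getattr(comp, "descriptor", None)
        if desc is not None:
            descriptors[f] = desc

    report = FilterReport(mode=mode)
    if standardization is not None:
        report.n_input = standardization.n_input
        report.n_valid = standardization.n_valid
    else:
        report.n_input = report.n_valid = len(candidates)
    report.n_unique = len(candidates)

    ionizable = [c for c in candidates if c.groups.ionizable >= 1]
    report.n_ionizable_pass = len(ionizable)

    moiety = [
        c
        for c in ionizable
        if c.groups.aromatic_rings >= 1 or c.groups.carboxyl >= 1 or c.groups.carbonyl >= 1
    ]
    report.n_moiety_pass = len(moiety)

    matched = [c for c in moiety if c.formula in formulas]
    report.n_formula_match = len(matched)

    if mode == "lenient":
        return matched, report

    def descriptor_ok(c: CandidateStructure) -> bool:
        d = descriptors.get(c.formula)
        if d is None:
            return True
        if d.n_cooh is not None and c.groups.carboxyl != d.n_cooh:
            return False
        if d.n_carbonyl is not None and c.groups.carbonyl != d.n_carbonyl:
            return False
        if d.is_aromatic is not None and (c.groups.aromatic_rings >= 1) != d.is_aromatic:
            return False
        return True

    strict = [c for c in matched if descriptor_ok(c)]
    report.n_descriptor_match = len(strict)
    return strict, report
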