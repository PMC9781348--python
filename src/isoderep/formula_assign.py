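"""CHO molecular-formula assignment for negative-mode [M-H]- peaks.

Assignment is exhaustive enumeration over C/H/O counts under chemical
constraints (element bounds, H/C and O/C windows, non-negative integer
DBE) within a relative mass tolerance. Ultrahigh resolving power makes the
best candidate unique for almost all peaks below 800 Da; the rare
collisions are flagged, never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    MASS_C,
    MASS_H,
    MASS_O,
    MolecularFormula,
    aromaticity_index,
    compound_class,
    neutral_mass_from_mz,
)
from .spectra_io import Peak, Spectrum

__all__ = [
    "AssignmentConfig",
    "Assignment",
    "AssignmentResult",
    "enumerate_candidates",
    "assign_formulas",
    "assignment_table",
]


@dataclass(frozen=True)
class AssignmentConfig:
    """Constraints of the exhaustive CHO enumeration.

    Defaults cover the CHO polyphenol space below ~800 Da: C <= 40,
    H <= 80, O <= 40, H/C in [0.3, 2.2], O/C <= 1, integer DBE >= 0,
    0.5 ppm tolerance.
    """

    tol_ppm: float = 0.5
    c_max: int = 40
    h_max: int = 80
    o_max: int = 40
    hc_range: tuple[float, float] = (0.3, 2.2)
    oc_max: float = 1.0
    require_integer_dbe: bool = True

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if min(self.c_max, self.h_max, self.o_max) < 1:
            raise ValueError("element bounds must be positive")
        lo, hi = self.hc_range
        if not (0 <= lo <= hi <= 3):
            raise ValueError("hc_range must lie within [0, 3]")


DEFAULT_CONFIG = AssignmentConfig()


def _formula_ok(c: int, h: int, o: int, config: AssignmentConfig) -> bool:
    if h < 0 or h > config.h_max or h > 2 * c + 2:
        return False
    hc = h / c
    if not (config.hc_range[0] <= hc <= config.hc_range[1]):
        return False
    if o / c > config.oc_max:
        return False
    dbe = c - h / 2 + 1
    if dbe < 0:
        return False
    if config.require_integer_dbe and h % 2 != 0:
        return False
    return True


def enumerate_candidates(
    neutral_mass: float, config: AssignmentConfig = DEFAULT_CONFIG
) -> list[MolecularFormula]:
    """All CHO formulas within ``tol_ppm`` of a neutral mass, best first.

    Sorted by |mass error|, ties broken by fewer oxygens then fewer
    carbons. Returns an empty list when nothing qualifies.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    tol_da = neutral_mass * config.tol_ppm * 1e-6
    out: list[tuple[float, int, int, MolecularFormula]] = []
    c_hi = min(config.c_max, int((neutral_mass + tol_da) // MASS_C))
    for c in range(1, c_hi + 1):
        rem_c = neutral_mass - c * MASS_C
        o_hi = min(config.o_max, int(c * config.oc_max), int(max(0.0, rem_c + tol_da) // MASS_O))
        for o in range(0, o_hi + 1):
            rem = rem_c - o * MASS_O
            if rem < -tol_da:
                break
            h_center = rem / MASS_H
            # the tolerance window is far narrower than one H mass, but
            # check both neighbouring integers to be safe
            for h in {int(np.floor(h_center)), int(np.ceil(h_center))}:
                if not _formula_ok(c, h, o, config):
                    continue
                err = c * MASS_C + h * MASS_H + o * MASS_O - neutral_mass
                if abs(err) <= tol_da:
                    out.append((abs(err), o, c, MolecularFormula(c=c, h=h, o=o)))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return [f for _, _, _, f in out]


@dataclass(frozen=True)
class Assignment:
    """The best formula for one peak, with the signed mass error."""

    peak: Peak
    formula: MolecularFormula
    error_ppm: float
    n_candidates: int = 1

    @property
    def ambiguous(self) -> bool:
        """True when more than one formula fell inside the tolerance."""
        return self.n_candidates > 1


@dataclass
class AssignmentResult:
    """Assignments for a spectrum plus a coverage summary."""

    assignments: list[Assignment]
    n_peaks: int
    n_ambiguous: int

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    @property
    def n_unassigned(self) -> int:
        return self.n_peaks - self.n_assigned

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def by_mz(self) -> dict[float, Assignment]:
        return {a.peak.mz: a for a in self.assignments}


def assign_formulas(
    spectrum: Spectrum, config: AssignmentConfig = DEFAULT_CONFIG
) -> AssignmentResult:
    """Assign the best CHO formula to every peak of a negative-mode spectrum.

    Peaks with no candidate within tolerance are omitted (counted in the
    summary); peaks with several candidates keep the best one and carry an
    ambiguity flag.
    """
    if spectrum.polarity != "negative":
        raise ValueError(
            f"formula assignment expects a negative-mode spectrum, got {spectrum.polarity!r}"
        )
    assignments: list[Assignment] = []
    n_ambiguous = 0
    for m, inten in zip(spectrum.mz, spectrum.intensity):
        neutral = neutral_mass_from_mz(float(m))
        cands = enumerate_candidates(neutral, config)
        if not cands:
            continue
        best = cands[0]
        err_ppm = (best.mass - neutral) / neutral * 1e6
        if len(cands) > 1:
            n_ambiguous += 1
        assignments.append(
            Assignment(
                peak=Peak(float(m), float(inten)),
                formula=best,
                error_ppm=float(err_ppm),
                n_candidates=len(cands),
            )
        )
    return AssignmentResult(
        assignments=assignments, n_peaks=len(spectrum), n_ambiguous=n_ambiguous
    )


def assignment_table(result: AssignmentResult) -> pd.DataFrame:
    """Flat table of assignments: mz, intensity, formula, error and descriptors."""
    rows = []
    for a in result.assignments:
        f = a.formula
        rows.append(
            {
                "mz": a.peak.mz,
                "intensity": a.peak.intensity,
                "formula": str(f),
                "error_ppm": a.error_ppm,
                "dbe": f.dbe,
                "oc": f.oc,
                "hc": f.hc,
                "ai": aromaticity_index(f),
                "class": compound_class(f).value,
                "ambiguous": a.ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mz",
            "intensity",
            "formula",
            "error_ppm",
            "dbe",
            "oc",
            "hc",
            "ai",
            "class",
            "ambiguous",
        ],
    )
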