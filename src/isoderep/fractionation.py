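"""Molecular profiling of solvent fractions.

A Soxhlet gradient from pure methanol to 25% methanol splits a
polyphenolic mixture into fractions whose assigned-formula inventories
shift from unsaturated toward aromatic and condensed-aromatic character.
This module summarises per-fraction profiles: number-averaged metrics
((O/C)n, (H/C)n, AIn), compound-class distributions with lipid exclusion,
van Krevelen exports, and enrichment of a target component set (e.g. the
components recovered from liver) by intensity share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    CompoundClass,
    ClassThresholds,
    DEFAULT_THRESHOLDS,
    MolecularFormula,
    aromaticity_index,
    compound_class,
)
from .formula_assign import AssignmentConfig, assign_formulas
from .spectra_io import Spectrum

__all__ = [
    "FractionProfile",
    "number_average",
    "class_distribution",
    "enrichment_score",
    "rank_fractions",
    "van_krevelen_table",
    "van_krevelen_export",
    "profile_from_spectrum",
]

_METRICS = {
    "oc": lambda f: f.oc,
    "hc": lambda f: f.hc,
    "ai": aromaticity_index,
    "mass": lambda f: f.mass,
}


@dataclass
class FractionProfile:
    """Formula -> summed intensity inventory of one solvent fraction."""

    fraction_id: str
    assignments: dict[MolecularFormula, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.assignments.values()):
            raise ValueError("intensities must be non-negative")

    @property
    def n_formulas(self) -> int:
        return len(self.assignments)

    @property
    def total_intensity(self) -> float:
        return float(sum(self.assignments.values()))


def profile_from_spectrum(
    spectrum: Spectrum,
    fraction_id: Optional[str] = None,
    config: Optional[AssignmentConfig] = None,
) -> FractionProfile:
    """Assign formulas to a fraction spectrum and sum intensity per formula."""
    result = assign_formulas(spectrum, config or AssignmentConfig())
    inv: dict[MolecularFormula, float] = {}
    for a in result:
        inv[a.formula] = inv.get(a.formula, 0.0) + a.peak.intensity
    return FractionProfile(
        fraction_id=fraction_id or spectrum.metadata.get("fraction", spectrum.sample_id),
        assignments=inv,
    )


def number_average(
    profile: FractionProfile, metric: str = "oc", weighting: str = "none"
) -> float:
    """Number-averaged ((.)n, unweighted) or intensity-weighted mean metric.

    The (O/C)n convention averages over assigned formulas with equal
    weight; ``weighting="intensity"`` weights each formula by its summed
    intensity instead.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if profile.n_formulas == 0:
        raise ValueError(f"fraction {profile.fraction_id!r} has no assigned formulas")
    fn = _METRICS[metric]
    values = np.array([fn(f) for f in profile.assignments])
    if weighting == "none":
        return float(values.mean())
    if weighting == "intensity":
        w = np.array(list(profile.assignments.values()), dtype=float)
        if w.sum() == 0:
            return float(values.mean())
        return float(np.average(values, weights=w))
    raise ValueError(f"unknown weighting {weighting!r}")


def class_distribution(
    profile: FractionProfile,
    exclude: Iterable[CompoundClass] = (CompoundClass.LIPID_LIKE,),
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> dict[CompoundClass, tuple[int, float]]:
    """Compound-class tally as (formula count, intensity share).

    Excluded classes (lipid-like by default — unlikely indigenous to a
    polyphenolic material) are removed before shares are computed, so the
    shares of retained classes sum to 1.
    """
    excluded = set(exclude)
    counts: dict[CompoundClass, int] = {}
    inten: dict[CompoundClass, float] = {}
    for f, x in profile.assignments.items():
        cls = compound_class(f, thresholds)
        if cls in excluded:
            continue
        counts[cls] = counts.get(cls, 0) + 1
        inten[cls] = inten.get(cls, 0.0) + x
    total = sum(inten.values())
    out: dict[CompoundClass, tuple[int, float]] = {}
    for cls in counts:
        share = inten[cls] / total if total > 0 else 0.0
        out[cls] = (counts[cls], share)
    return out


def enrichment_score(
    profile: FractionProfile, targets: Iterable[MolecularFormula]
) -> float:
    """Intensity share of the target formulas within the fraction.

    Relative intensity inside each fraction's own spectrum makes fractions
    of different total ion current comparable. Always in [0, 1]; monotone
    in the target set.
    """
    if profile.n_formulas == 0:
        raise ValueError(f"fraction {profile.fraction_id!r} has no assigned formulas")
    tset = set(targets)
    total = profile.total_intensity
    if total == 0:
        return 0.0
    hit = sum(x for f, x in profile.assignments.items() if f in tset)
    return hit / total


def rank_fractions(
    profiles: Sequence[FractionProfile], targets: Iterable[MolecularFormula]
) -> list[tuple[FractionProfile, float]]:
    """Fractions ordered by target enrichment, best first (stable on ties)."""
    if not profiles:
        raise ValueError("need at least one fraction profile")
    tset = set(targets)
    scored = [(p, enrichment_score(p, tset)) for p in profiles]
    return sorted(scored, key=lambda t: -t[1])


def van_krevelen_table(
    profile: FractionProfile, thresholds: ClassThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Per-formula O/C, H/C, intensity and class — the van Krevelen data."""
    rows = [
        {
            "formula": str(f),
            "oc": f.oc,
            "hc": f.hc,
            "intensity": x,
            "class": compound_class(f, thresholds).value,
        }
        for f, x in sorted(profile.assignments.items(), key=lambda kv: kv[0].mass)
    ]
    return pd.DataFrame(rows, columns=["formula", "oc", "hc", "intensity", "class"])


def van_krevelen_export(
    profile: FractionProfile,
    path,
    plot_path=None,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Write the van Krevelen table to CSV, optionally with a scatter PNG."""
    df = van_krevelen_table(profile, thresholds)
    df.to_csv(Path(path), index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if len(df):
            classes = sorted(df["class"].unique())
            for cls in classes:
                sub = df[df["class"] == cls]
                size = 4 + 40 * sub["intensity"] / max(df["intensity"].max(), 1e-12)
                ax.scatter(sub["oc"], sub["hc"], s=size, label=cls, alpha=0.6)
            ax.legend(fontsize=7)
        ax.set_xlabel("O/C")
        ax.set_ylabel("H/C")
        ax.set_title(f"van Krevelen — {profile.fraction_id}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
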