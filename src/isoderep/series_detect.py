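"""Labeling-series extraction, chemistry-rule filtration and descriptors.

A labeling series is a set of peaks separated by integer multiples of one
reaction's per-event mass shift, sharing an unlabeled base compound. The
detector chains peaks at ``base + k*delta`` (anchored at the base, so
position errors do not accumulate), the filter discards series that are
chemically impossible for the base formula, and the descriptor step turns
series lengths into functional-group counts: deuteromethylation events ->
carboxyl groups, reduction events -> carbonyl groups, a bromination series
-> aromatic ring presence, H/D exchange events -> exchangeable hydrogens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem_core import MolecularFormula, ReactionKind, dbe, reaction_mass_shift
from .formula_assign import Assignment, AssignmentResult
from .spectra_io import Peak, Spectrum

__all__ = [
    "DEFAULT_TOL_MZ",
    "DEFAULT_K_MAX",
    "LabelSeries",
    "FunctionalDescriptor",
    "SeriesRules",
    "SeriesFilterResult",
    "DescriptorConsistencyError",
    "detect_series",
    "filter_series",
    "descriptors_from_series",
    "series_table",
]

#: Maximum m/z error between a series member and its ideal chain position
#: (Th), set by the mass accuracy of the FTICR instrument.
DEFAULT_TOL_MZ = 0.0003

#: Longest series searched for; exchangeable-H counts of <800 Da
#: polyphenols stay well below this.
DEFAULT_K_MAX = 12


@dataclass
class LabelSeries:
    """A base peak plus members at integer multiples of the reaction shift.

    ``members`` holds ``(k, peak)`` pairs with k strictly increasing from 0
    (the base itself). ``max_k`` is the number of labeling events of the
    most-labeled member.
    """

    reaction: ReactionKind
    base_peak: Peak
    members: list[tuple[int, Peak]]
    base_formula: Optional[MolecularFormula] = None
    source_id: Optional[str] = None

    @property
    def max_k(self) -> int:
        return self.members[-1][0] if self.members else 0

    @property
    def member_mzs(self) -> list[float]:
        return [p.mz for _, p in self.members]

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.members]
        if ks and (ks[0] != 0 or any(b <= a for a, b in zip(ks, ks[1:]))):
            raise ValueError("member k values must strictly increase from 0")


def detect_series(
    spectrum: Spectrum,
    reaction: ReactionKind,
    tol_mz: float = DEFAULT_TOL_MZ,
    k_max: int = DEFAULT_K_MAX,
) -> list[LabelSeries]:
    """Extract all labeling series of one reaction from a spectrum.

    For every candidate base peak the maximal chain of peaks at
    ``base + k*delta`` (k = 1..k_max, each within ``tol_mz`` of the ideal
    position, nearest peak wins, lower m/z on ties) is built; the chain
    stops at the first missing k. A peak that is itself preceded by a peak
    at ``mz - delta`` is not a base, so each chain is reported exactly once
    under its lowest-m/z base. Chains with no labeled member are dropped.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be positive")
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    mz = spectrum.mz
    n = mz.size
    if n == 0:
        return []
    delta = reaction_mass_shift(reaction)

    def nearest_within(targets: np.ndarray) -> np.ndarray:
        """Index of the nearest peak within tol of each target, else -1."""
        pos = np.searchsorted(mz, targets)
        left = np.clip(pos - 1, 0, n - 1)
        right = np.clip(pos, 0, n - 1)
        dl = np.abs(mz[left] - targets)
        dr = np.abs(mz[right] - targets)
        take_left = dl <= dr  # prefers the lower index on exact ties
        idx = np.where(take_left, left, right)
        dist = np.where(take_left, dl, dr)
        return np.where(dist <= tol_mz, idx, -1)

    # A peak with a predecessor at mz - delta (within tol) belongs to a
    # chain reported under a lower base.
    has_pred = nearest_within(mz - delta) >= 0

    base_idx = np.flatnonzero(~has_pred)
    chains: dict[int, list[tuple[int, int]]] = {int(i): [(0, int(i))] for i in base_idx}
    active = base_idx
    for k in range(1, k_max + 1):
        if active.size == 0:
            break
        hit = nearest_within(mz[active] + k * delta)
        found = hit >= 0
        for b, j in zip(active[found], hit[found]):
            chains[int(b)].append((k, int(j)))
        active = active[found]

    out: list[LabelSeries] = []
    for b in sorted(chains):
        members = chains[b]
        if len(members) < 2:
            continue
        out.append(
            LabelSeries(
                reaction=reaction,
                base_peak=Peak(float(mz[b]), float(spectrum.intensity[b])),
                members=[
                    (k, Peak(float(mz[j]), float(spectrum.intensity[j]))) for k, j in members
                ],
                source_id=spectrum.sample_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# chemistry-rule filtration


def _hd_feasible(f: MolecularFormula, k: int) -> bool:
    return k <= f.h


def _dm_feasible(f: MolecularFormula, k: int) -> bool:
    return k <= f.o // 2


def _red_feasible(f: MolecularFormula, k: int, n_cooh: Optional[int] = None) -> bool:
    return k <= f.o - (n_cooh if n_cooh is not None else 0)


def _br_feasible(f: MolecularFormula, k: int) -> bool:
    return k <= max(0, round(dbe(f)) - 3)


@dataclass
class SeriesRules:
    """Per-reaction feasibility rules applied to a series' base formula.

    Defaults encode the group semantics of each reaction: H/D events
    cannot exceed the hydrogen count, deuteromethylation events the number
    of possible carboxyls (floor(O/2)), reduction events the oxygens not
    already committed to known carboxyls, and bromination events the
    aromatic capacity implied by DBE. ``overrides`` replaces the rule for
    a reaction with any ``(formula, k) -> bool`` callable.
    """

    require_assignment: bool = True
    require_unlabeled_base: bool = True
    cooh_counts: Optional[Mapping[MolecularFormula, int]] = None
    overrides: dict[ReactionKind, Callable[[MolecularFormula, int], bool]] = field(
        default_factory=dict
    )

    def feasible(self, reaction: ReactionKind, formula: MolecularFormula, k: int) -> bool:
        if reaction in self.overrides:
            return self.overrides[reaction](formula, k)
        if reaction is ReactionKind.HD_EXCHANGE:
            return _hd_feasible(formula, k)
        if reaction is ReactionKind.DEUTEROMETHYLATION:
            return _dm_feasible(formula, k)
        if reaction is ReactionKind.REDUCTION:
            n_cooh = None
            if self.cooh_counts is not None:
                n_cooh = self.cooh_counts.get(formula)
            return _red_feasible(formula, k, n_cooh)
        if reaction is ReactionKind.BROMINATION:
            return _br_feasible(formula, k)
        raise ValueError(f"unknown reaction {reaction!r}")


DEFAULT_RULES = SeriesRules()


@dataclass
class SeriesFilterResult:
    """Retained series plus the rejection log (series, violated rule)."""

    retained: list[LabelSeries]
    rejected: list[tuple[LabelSeries, str]]


AssignmentsLike = Union[AssignmentResult, Sequence[Assignment], Mapping[float, Assignment]]


def _assignment_lookup(assignments: AssignmentsLike) -> Mapping[float, Assignment]:
    if isinstance(assignments, AssignmentResult):
        return assignments.by_mz()
    if isinstance(assignments, Mapping):
        return assignments
    return {a.peak.mz: a for a in assignments}


def filter_series(
    series: Iterable[LabelSeries],
    assignments: AssignmentsLike,
    rules: SeriesRules = DEFAULT_RULES,
) -> SeriesFilterResult:
    """Keep series whose base is an assigned, unlabeled, feasible formula.

    A retained series gains its ``base_formula``. Rejections are logged
    with the violated rule name.
    """
    lookup = _assignment_lookup(assignments)
    retained: list[LabelSeries] = []
    rejected: list[tuple[LabelSeries, str]] = []
    for s in series:
        a = lookup.get(s.base_peak.mz)
        if a is None:
            if rules.require_assignment:
                rejected.append((s, "unassigned-base"))
                continue
            retained.append(s)
            continue
        f = a.formula
        if rules.require_unlabeled_base and f.d != 0:
            rejected.append((s, "labeled-base"))
            continue
        if not rules.feasible(s.reaction, f, s.max_k):
            rejected.append((s, f"infeasible-{s.reaction.value}-k{s.max_k}"))
            continue
        retained.append(
            LabelSeries(
                reaction=s.reaction,
                base_peak=s.base_peak,
                members=list(s.members),
                base_formula=f,
                source_id=s.source_id,
            )
        )
    return SeriesFilterResult(retained=retained, rejected=rejected)


# ---------------------------------------------------------------------------
# descriptors


class DescriptorConsistencyError(ValueError):
    """Series handed to the descriptor step disagree on the base formula."""


@dataclass(frozen=True)
class FunctionalDescriptor:
    """Functional-group counts of one formula, as reported by labeling.

    ``None`` means unknown (the experiment was not run, or the compound
    was not observed in it). A reduction experiment that was run but shows
    no series legitimately reports zero carbonyls, and a bromination
    experiment with no series reports a non-aromatic compound.
    """

    formula: MolecularFormula
    n_cooh: Optional[int] = None
    n_carbonyl: Optional[int] = None
    is_aromatic: Optional[bool] = None
    n_exchangeable: Optional[int] = None

    def __post_init__(self) -> None:
        f = self.formula
        if self.n_cooh is not None:
            if self.n_cooh < 0 or self.n_cooh > f.o // 2:
                raise DescriptorConsistencyError(
                    f"{self.n_cooh} carboxyls impossible for {f}"
                )
        if self.n_carbonyl is not None:
            if self.n_carbonyl < 0:
                raise DescriptorConsistencyError("negative carbonyl count")
            if self.n_cooh is not None and self.n_carbonyl > f.o - 2 * self.n_cooh:
                raise DescriptorConsistencyError(
                    f"{self.n_carbonyl} carbonyls + {self.n_cooh} carboxyls "
                    f"exceed {f.o} oxygens of {f}"
                )
        if self.n_exchangeable is not None and not (
            0 <= self.n_exchangeable <= f.h_total
        ):
            raise DescriptorConsistencyError(
                f"{self.n_exchangeable} exchangeable H impossible for {f}"
            )

    @property
    def complete(self) -> bool:
        """All three structural descriptors (COOH, C=O, aromaticity) known."""
        return (
            self.n_cooh is not None
            and self.n_carbonyl is not None
            and self.is_aromatic is not None
        )


def descriptors_from_series(
    formula: MolecularFormula,
    series_by_reaction: Mapping[ReactionKind, Optional[LabelSeries]],
    experiments_run: Optional[Iterable[ReactionKind]] = None,
) -> FunctionalDescriptor:
    """Fold per-reaction series into a functional-group descriptor.

    ``experiments_run`` separates "not measured" from "measured, none
    found"; it defaults to the reactions present in ``series_by_reaction``.
    """
    run = set(experiments_run) if experiments_run is not None else set(series_by_reaction)
    for rxn, s in series_by_reaction.items():
        if s is None:
            continue
        base = s.base_formula
        if base is not None and (base.c, base.h_total, base.o) != (
            formula.c,
            formula.h_total,
            formula.o,
        ):
            raise DescriptorConsistencyError(
                f"{rxn.name} series base {base} does not match {formula}"
            )

    def series_k(rxn: ReactionKind) -> Optional[int]:
        s = series_by_reaction.get(rxn)
        return s.max_k if s is not None else None

    n_cooh = series_k(ReactionKind.DEUTEROMETHYLATION)
    n_exch = series_k(ReactionKind.HD_EXCHANGE)
    red_k = series_k(ReactionKind.REDUCTION)
    if red_k is not None:
        n_carbonyl: Optional[int] = red_k
    elif ReactionKind.REDUCTION in run:
        n_carbonyl = 0
    else:
        n_carbonyl = None
    if ReactionKind.BROMINATION in run:
        is_aromatic: Optional[bool] = series_by_reaction.get(ReactionKind.BROMINATION) is not None
    else:
        is_aromatic = None
    return FunctionalDescriptor(
        formula=formula,
        n_cooh=n_cooh,
        n_carbonyl=n_carbonyl,
        is_aromatic=is_aromatic,
        n_exchangeable=n_exch,
    )


def series_table(series: Iterable[LabelSeries]) -> pd.DataFrame:
    """Flat export of series: base m/z, formula, reaction, length, members."""
    rows = [
        {
            "base_mz": s.base_peak.mz,
            "formula": str(s.base_formula) if s.base_formula else "",
            "reaction": s.reaction.value,
            "max_k": s.max_k,
            "member_mzs": ";".join(f"{m:.6f}" for m in s.member_mzs),
        }
        for s in series
    ]
    return pd.DataFrame(rows, columns=["base_mz", "formula", "reaction", "max_k", "member_mzs"])
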