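"""Detection of D-labeled exogenous components in tissue-extract spectra.

An administered, deeply D-labeled mixture leaves a signature that
endogenous metabolites cannot fake: H/D-exchange series (peaks spaced by
m(D)-m(H)) whose base is an unlabeled CHO formula. A component is called
exogenous when such a series is found in a labeled-administration extract,
its base formula is assigned, and no series at that base m/z occurs in any
control extract. Records from the administration routes are merged by
formula, filtered (replicate support, presence in the labeled reference
material, CHO plausibility windows), and annotated with functional-group
descriptors from the chemical-tagging experiments on the parent material.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import MolecularFormula, ReactionKind
from .formula_assign import AssignmentConfig, AssignmentResult, assign_formulas
from .series_detect import (
    DEFAULT_K_MAX,
    DEFAULT_TOL_MZ,
    DescriptorConsistencyError,
    FunctionalDescriptor,
    LabelSeries,
    SeriesRules,
    descriptors_from_series,
    detect_series,
    filter_series,
)
from .spectra_io import Spectrum, read_manifest, read_peaklist

__all__ = [
    "ROUTES",
    "SampleSet",
    "ComponentRecord",
    "DetectionConfig",
    "FilterCriteria",
    "FinalFilterResult",
    "detect_exogenous",
    "extract_series",
    "merge_routes",
    "final_filter",
    "aggregate_descriptors",
    "component_table",
    "load_sample_set",
]

ROUTES = ("parenteral", "oral")


@dataclass
class SampleSet:
    """Spectra of one labeling study, grouped by experimental role."""

    control: list[Spectrum]
    labeled_admin: dict[str, list[Spectrum]]
    labeled_ref: list[Spectrum]
    parent_ref: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.control:
            raise ValueError("a sample set needs at least one control spectrum")
        if not self.labeled_ref:
            raise ValueError("a sample set needs labeled reference spectra")
        for route in self.labeled_admin:
            if route not in ROUTES:
                raise ValueError(f"unknown administration route {route!r}; allowed: {ROUTES}")


@dataclass
class ComponentRecord:
    """One exogenous molecular component with its detection evidence."""

    formula: MolecularFormula
    routes: frozenset[str]
    in_labeled_ref: bool
    support: dict[str, int] = field(default_factory=dict)  # route -> replicate count
    descriptor: Optional[FunctionalDescriptor] = None
    descriptor_conflict: bool = False
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.routes = frozenset(self.routes)
        if not self.routes:
            raise ValueError("a component record needs at least one route")
        if self.formula.d != 0:
            raise ValueError("component records are keyed by the unlabeled base formula")

    @property
    def max_support(self) -> int:
        return max(self.support.values(), default=1)

    @property
    def complete(self) -> bool:
        return self.descriptor is not None and self.descriptor.complete


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the exogenous-component detection."""

    tol_mz: float = DEFAULT_TOL_MZ
    k_max: int = DEFAULT_K_MAX
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    rules: SeriesRules = field(default_factory=SeriesRules)


DEFAULT_DETECTION = DetectionConfig()


def _assign_bases(
    spectrum: Spectrum, series: Sequence[LabelSeries], config: DetectionConfig
) -> AssignmentResult:
    """Assign formulas only to series base peaks (the rest is never needed)."""
    if not series:
        return AssignmentResult(assignments=[], n_peaks=0, n_ambiguous=0)
    base = Spectrum.from_peaks(
        spectrum.sample_id,
        [(s.base_peak.mz, s.base_peak.intensity) for s in series],
        polarity=spectrum.polarity,
    )
    return assign_formulas(base, config.assignment)


def extract_series(
    spectrum: Spectrum, reaction: ReactionKind, config: DetectionConfig = DEFAULT_DETECTION
) -> list[LabelSeries]:
    """Detect, assign and chemistry-filter one reaction's series in a spectrum."""
    raw = detect_series(spectrum, reaction, config.tol_mz, config.k_max)
    assignments = _assign_bases(spectrum, raw, config)
    return filter_series(raw, assignments, config.rules).retained


_filtered_series = extract_series


def detect_exogenous(
    sample_set: SampleSet,
    route: str,
    config: DetectionConfig = DEFAULT_DETECTION,
) -> list[ComponentRecord]:
    """Exogenous components of one administration route.

    A record is emitted when a chemically feasible H/D series with an
    assigned, unlabeled base formula occurs in a labeled-administration
    spectrum and no H/D series sits at that base m/z (within tolerance) in
    any control spectrum. Components missing from the labeled reference
    spectra are kept but flagged ``in_labeled_ref=False`` — direct-ESI
    spectra of a complex mixture do not reproducibly ionize everything.
    """
    if route not in sample_set.labeled_admin or not sample_set.labeled_admin[route]:
        raise ValueError(f"no labeled-administration spectra for route {route!r}")

    control_bases: list[float] = []
    for spec in sample_set.control:
        for s in detect_series(spec, ReactionKind.HD_EXCHANGE, config.tol_mz, config.k_max):
            control_bases.append(s.base_peak.mz)
    control_bases_arr = np.sort(np.asarray(control_bases))

    def in_control(mz: float) -> bool:
        if control_bases_arr.size == 0:
            return False
        i = int(np.searchsorted(control_bases_arr, mz))
        for j in (i - 1, i):
            if 0 <= j < control_bases_arr.size and abs(control_bases_arr[j] - mz) <= config.tol_mz:
                return True
        return False

    ref_formulas: set[MolecularFormula] = set()
    for spec in sample_set.labeled_ref:
        for s in _filtered_series(spec, ReactionKind.HD_EXCHANGE, config):
            if s.base_formula is not None:
                ref_formulas.add(s.base_formula)

    by_formula: dict[MolecularFormula, dict] = {}
    for spec in sample_set.labeled_admin[route]:
        seen_here: set[MolecularFormula] = set()
        for s in _filtered_series(spec, ReactionKind.HD_EXCHANGE, config):
            f = s.base_formula
            assert f is not None
            if in_control(s.base_peak.mz):
                continue
            rec = by_formula.setdefault(f, {"n": 0, "evidence": []})
            rec["evidence"].append(f"{route}/{spec.sample_id}@{s.base_peak.mz:.5f}:k{s.max_k}")
            if f not in seen_here:
                rec["n"] += 1
                seen_here.add(f)

    records = [
        ComponentRecord(
            formula=f,
            routes=frozenset({route}),
            in_labeled_ref=f in ref_formulas,
            support={route: info["n"]},
            evidence=info["evidence"],
        )
        for f, info in by_formula.items()
    ]
    records.sort(key=lambda r: r.formula.mass)
    return records


def merge_routes(per_route: Mapping[str, Sequence[ComponentRecord]]) -> list[ComponentRecord]:
    """Union records across administration routes, keyed by formula.

    Routes and evidence are unioned, replicate support kept per route, and
    descriptors merged field-wise; a disagreement between routes keeps the
    first value and sets ``descriptor_conflict``. The operation is
    idempotent and commutative in route order (output sorted by mass).
    """
    merged: dict[MolecularFormula, ComponentRecord] = {}
    for route in sorted(per_route):
        for rec in per_route[route]:
            cur = merged.get(rec.formula)
            if cur is None:
                merged[rec.formula] = ComponentRecord(
                    formula=rec.formula,
                    routes=rec.routes,
                    in_labeled_ref=rec.in_labeled_ref,
                    support=dict(rec.support),
                    descriptor=rec.descriptor,
                    descriptor_conflict=rec.descriptor_conflict,
                    evidence=list(rec.evidence),
                )
                continue
            support = dict(cur.support)
            for r, n in rec.support.items():
                support[r] = max(support.get(r, 0), n)
            desc, conflict = _merge_descriptors(cur.descriptor, rec.descriptor)
            merged[rec.formula] = ComponentRecord(
                formula=cur.formula,
                routes=cur.routes | rec.routes,
                in_labeled_ref=cur.in_labeled_ref or rec.in_labeled_ref,
                support=support,
                descriptor=desc,
                descriptor_conflict=cur.descriptor_conflict or rec.descriptor_conflict or conflict,
                evidence=cur.evidence + [e for e in rec.evidence if e not in cur.evidence],
            )
    return sorted(merged.values(), key=lambda r: r.formula.mass)


def _merge_descriptors(
    a: Optional[FunctionalDescriptor], b: Optional[FunctionalDescriptor]
) -> tuple[Optional[FunctionalDescriptor], bool]:
    if a is None:
        return b, False
    if b is None:
        return a, False
    conflict = False
    merged = {}
    for name in ("n_cooh", "n_carbonyl", "is_aromatic", "n_exchangeable"):
        va, vb = getattr(a, name), getattr(b, name)
        if va is None:
            merged[name] = vb
        elif vb is None or va == vb:
            merged[name] = va
        else:
            merged[name] = va
            conflict = True
    return FunctionalDescriptor(formula=a.formula, **merged), conflict


@dataclass(frozen=True)
class FilterCriteria:
    """Conjunctive criteria of the final component filtration.

    Each criterion can be disabled; the attrition log reports how many
    records each enabled criterion removed (first violated rule wins).
    """

    min_support: Optional[int] = 2
    require_labeled_ref: bool = True
    hc_range: Optional[tuple[float, float]] = (0.3, 2.2)
    oc_range: Optional[tuple[float, float]] = (0.0, 1.0)


DEFAULT_CRITERIA = FilterCriteria()


@dataclass
class FinalFilterResult:
    retained: list[ComponentRecord]
    attrition: dict[str, int]
    rejections: list[tuple[ComponentRecord, str]]


def final_filter(
    records: Sequence[ComponentRecord], criteria: FilterCriteria = DEFAULT_CRITERIA
) -> FinalFilterResult:
    """Apply the final filtration, logging per-criterion attrition."""
    attrition = {"min_support": 0, "labeled_ref": 0, "hc_range": 0, "oc_range": 0}
    retained: list[ComponentRecord] = []
    rejections: list[tuple[ComponentRecord, str]] = []

    def violated(rec: ComponentRecord) -> Optional[str]:
        if criteria.min_support is not None and rec.max_support < criteria.min_support:
            return "min_support"
        if criteria.require_labeled_ref and not rec.in_labeled_ref:
            return "labeled_ref"
        if criteria.hc_range is not None and not (
            criteria.hc_range[0] <= rec.formula.hc <= criteria.hc_range[1]
        ):
            return "hc_range"
        if criteria.oc_range is not None and not (
            criteria.oc_range[0] <= rec.formula.oc <= criteria.oc_range[1]
        ):
            return "oc_range"
        return None

    for rec in records:
        rule = violated(rec)
        if rule is None:
            retained.append(rec)
        else:
            attrition[rule] += 1
            rejections.append((rec, rule))
    return FinalFilterResult(retained=retained, attrition=attrition, rejections=rejections)


def aggregate_descriptors(
    records: Sequence[ComponentRecord],
    tag_experiments: Mapping[ReactionKind, Sequence[Spectrum]],
    config: DetectionConfig = DEFAULT_DETECTION,
) -> list[ComponentRecord]:
    """Annotate records with descriptors from chemical-tagging spectra.

    Tag experiments are run on the parent material itself. For every
    reaction, series are detected and filtered in its spectra; a record's
    descriptor folds the longest series found for its formula in each
    experiment. Records found in all three structural experiments
    (deuteromethylation, reduction, bromination) become ``complete``.
    """
    per_reaction: dict[ReactionKind, dict[MolecularFormula, LabelSeries]] = {}
    for rxn, spectra in tag_experiments.items():
        best: dict[MolecularFormula, LabelSeries] = {}
        for spec in spectra:
            for s in _filtered_series(spec, rxn, config):
                f = s.base_formula
                assert f is not None
                if f not in best or s.max_k > best[f].max_k:
                    best[f] = s
        per_reaction[rxn] = best

    run = set(tag_experiments)
    out: list[ComponentRecord] = []
    for rec in records:
        series_by_rxn = {
            rxn: per_reaction.get(rxn, {}).get(rec.formula) for rxn in run
        }
        conflict = rec.descriptor_conflict
        try:
            desc = descriptors_from_series(rec.formula, series_by_rxn, experiments_run=run)
        except DescriptorConsistencyError:
            # e.g. reduction + deuteromethylation series jointly overrun the
            # oxygen budget: keep the carboxyl count, drop the carbonyl one
            series_by_rxn = dict(series_by_rxn)
            series_by_rxn[ReactionKind.REDUCTION] = None
            desc = descriptors_from_series(
                rec.formula,
                series_by_rxn,
                experiments_run=run - {ReactionKind.REDUCTION},
            )
            conflict = True
        merged, merge_conflict = _merge_descriptors(desc, rec.descriptor)
        out.append(replace(rec, descriptor=merged, descriptor_conflict=conflict or merge_conflict))
    return out


def component_table(records: Sequence[ComponentRecord]) -> pd.DataFrame:
    """Flat export: formula, routes, descriptors, support, completeness."""
    rows = []
    for r in records:
        d = r.descriptor
        rows.append(
            {
                "formula": str(r.formula),
                "mass": r.formula.mass,
                "routes": "+".join(sorted(r.routes)),
                "in_labeled_ref": r.in_labeled_ref,
                "support": r.max_support,
                "n_cooh": None if d is None else d.n_cooh,
                "n_carbonyl": None if d is None else d.n_carbonyl,
                "aromatic": None if d is None else d.is_aromatic,
                "n_exchangeable": None if d is None else d.n_exchangeable,
                "complete": r.complete,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "formula",
            "mass",
            "routes",
            "in_labeled_ref",
            "support",
            "n_cooh",
            "n_carbonyl",
            "aromatic",
            "n_exchangeable",
            "complete",
        ],
    )


def load_sample_set(manifest_path) -> SampleSet:
    """Build a :class:`SampleSet` from a YAML manifest of peak-list paths."""
    manifest = read_manifest(manifest_path)

    def _spectra(paths) -> list[Spectrum]:
        if isinstance(paths, str):
            paths = [paths]
        return [read_peaklist(p) for p in paths]

    admin = {
        route: _spectra(paths)
        for route, paths in manifest.get("labeled_admin", {}).items()
    }
    return SampleSet(
        control=_spectra(manifest.get("control", [])),
        labeled_admin=admin,
        labeled_ref=_spectra(manifest.get("labeled_ref", [])),
        parent_ref=_spectra(manifest.get("parent_ref", [])),
    )
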