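"""Seeded ground-truth generators for every stage of the workflow.

The generators emulate negative-mode [M-H]- FTICR peak lists of a CHO
polyphenolic mixture and its D-labeled analogs: planted compounds with
known functional-group counts, endogenous tissue background, uniform noise
peaks, Gaussian m/z error, log-normal intensities, solvent-fraction
profiles with a polarity gradient, and a toy structure library sharing the
planted chemotypes. Everything is bit-reproducible given a seed.

Default study design follows the labeling experiment it emulates: 3
control animals and 10 labeled-administered animals per route, with
labeling-series tolerance-scale m/z jitter (5e-5 Th) and 90% per-member
labeling efficiency in vivo (back-exchange); chemical-tagging spectra of
the parent material are generated at full efficiency, as derivatization
reactions driven to completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .chem_core import (
    CompoundClass,
    MolecularFormula,
    ReactionKind,
    compound_class,
    dbe,
    mz_from_formula,
    reaction_mass_shift,
)
from .dereplication import ROUTES, SampleSet
from .fractionation import FractionProfile
from .spectra_io import Spectrum

__all__ = [
    "GroundTruthCompound",
    "GroundTruth",
    "SimulatedStudy",
    "generate_mixture",
    "simulate_label_spectrum",
    "simulate_sample_set",
    "simulate_tag_experiments",
    "simulate_fractions",
    "generate_structure_library",
    "FRACTION_IDS",
]

FRACTION_IDS = ("100% CH3OH", "75% CH3OH", "50% CH3OH", "25% CH3OH")


@dataclass(frozen=True)
class GroundTruthCompound:
    """One planted mixture component with its true structural descriptors."""

    formula: MolecularFormula
    n_cooh: int
    n_carbonyl: int
    is_aromatic: bool
    n_exchangeable: int
    smiles: Optional[str] = None

    def true_events(self, reaction: ReactionKind) -> int:
        """How many labeling events this compound undergoes in a reaction."""
        if reaction is ReactionKind.HD_EXCHANGE:
            return self.n_exchangeable
        if reaction is ReactionKind.DEUTEROMETHYLATION:
            return self.n_cooh
        if reaction is ReactionKind.REDUCTION:
            return self.n_carbonyl
        if reaction is ReactionKind.BROMINATION:
            return 1 if self.is_aromatic else 0
        raise ValueError(reaction)


@dataclass
class GroundTruth:
    """A planted mixture: compounds, the seed and the generation settings."""

    compounds: list[GroundTruthCompound]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def formulas(self) -> list[MolecularFormula]:
        return [c.formula for c in self.compounds]

    def by_formula(self) -> dict[MolecularFormula, GroundTruthCompound]:
        return {c.formula: c for c in self.compounds}


def _sample_formula(
    rng: np.random.Generator,
    mass_range: tuple[float, float],
    oc_mean: float = 0.28,
    max_tries: int = 10000,
) -> MolecularFormula:
    """Rejection-sample one valid CHO formula in the mass window.

    Oxygen is drawn binomially around ``oc_mean`` (oxidized-lignin
    polyphenols sit at modest O/C), hydrogen even (integer DBE) within the
    H/C window [0.3, 2.2].
    """
    lo, hi = mass_range
    for _ in range(max_tries):
        c = int(rng.integers(max(6, int(lo // 22)), min(40, int(hi // 12)) + 1))
        o = int(np.clip(rng.binomial(c, oc_mean), 2, min(c, 40)))
        h_lo = int(np.ceil(0.3 * c))
        h_hi = int(min(2.2 * c, 2 * c + 2, 80))
        h_lo += h_lo % 2  # even hydrogen -> integer DBE
        if h_lo > h_hi:
            continue
        h = int(rng.integers(h_lo // 2, h_hi // 2 + 1)) * 2
        if h < 2 or c - h / 2 + 1 < 0:
            continue
        f = MolecularFormula(c=c, h=h, o=o)
        if lo <= f.mass <= hi:
            return f
    raise RuntimeError("could not sample a formula under the given constraints")


def _sample_groups(
    rng: np.random.Generator, f: MolecularFormula
) -> tuple[int, int, bool, int]:
    """Draw group counts consistent with the formula's element budget."""
    cooh_cap = f.o // 2
    n_cooh = min(int(rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2])), cooh_cap)
    carbonyl_cap = max(0, min(3, f.o - 2 * n_cooh))
    n_carbonyl = int(rng.integers(0, carbonyl_cap + 1))
    is_aromatic = dbe(f) >= 4
    exch_hi = min(f.h, 6)
    n_exchangeable = int(rng.integers(min(2, exch_hi), exch_hi + 1))
    return n_cooh, n_carbonyl, is_aromatic, n_exchangeable


def generate_mixture(
    n: int,
    seed: int = 0,
    mass_range: tuple[float, float] = (150.0, 800.0),
    class_mix: Optional[Mapping[CompoundClass, float]] = None,
    with_structures: bool = False,
) -> GroundTruth:
    """Sample ``n`` distinct planted compounds.

    ``class_mix`` fixes the compound-class composition (fractions summing
    to 1); ``with_structures=True`` builds every compound from the toy
    structure grammar instead, so formulas and group counts derive from an
    actual RDKit molecule.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    compounds: list[GroundTruthCompound] = []
    used: set[MolecularFormula] = set()

    if with_structures:
        for smiles, comp in _structures_from_grammar(rng, n, mass_range, used):
            compounds.append(comp)
            used.add(comp.formula)
        return GroundTruth(
            compounds=compounds,
            seed=seed,
            params={"n": n, "mass_range": mass_range, "with_structures": True},
        )

    quotas: Optional[dict[CompoundClass, int]] = None
    if class_mix is not None:
        total = sum(class_mix.values())
        quotas = {cls: int(round(n * w / total)) for cls, w in class_mix.items()}
        short = n - sum(quotas.values())
        if short:
            top = max(class_mix, key=lambda k: class_mix[k])
            quotas[top] += short

    tries = 0
    while len(compounds) < n:
        tries += 1
        if tries > 200000:
            raise RuntimeError("mixture constraints are infeasible")
        f = _sample_formula(rng, mass_range)
        if f in used:
            continue
        if quotas is not None:
            cls = compound_class(f)
            if quotas.get(cls, 0) <= 0:
                continue
            quotas[cls] -= 1
        used.add(f)
        n_cooh, n_carbonyl, is_aromatic, n_exch = _sample_groups(rng, f)
        compounds.append(
            GroundTruthCompound(f, n_cooh, n_carbonyl, is_aromatic, n_exch)
        )
    return GroundTruth(
        compounds=compounds,
        seed=seed,
        params={"n": n, "mass_range": mass_range, "class_mix": dict(class_mix or {})},
    )


# ---------------------------------------------------------------------------
# spectra


def _lognormal_intensity(rng: np.random.Generator, size: int) -> np.ndarray:
    # arbitrary-unit abundances; only relative values matter downstream
    return rng.lognormal(mean=10.0, sigma=1.0, size=size)


def simulate_label_spectrum(
    truth: GroundTruth,
    reaction: ReactionKind,
    efficiency: float = 1.0,
    noise: tuple[int, float] = (0, 0.0),
    seed: int = 0,
    sample_id: str = "labeled",
    extra_formulas: Sequence[MolecularFormula] = (),
    mz_range: Optional[tuple[float, float]] = None,
) -> Spectrum:
    """One spectrum of the labeled mixture.

    Every compound contributes its base [M-H]- peak plus series members at
    ``k = 1..true_events``, each retained independently with probability
    ``efficiency`` (back-exchange / incomplete derivatization thinning).
    ``noise = (n_decoys, mz_jitter_sd)`` adds uniform random peaks and
    Gaussian m/z error on every peak. ``extra_formulas`` appear as
    unlabeled base peaks (endogenous background).
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be within [0, 1]")
    n_decoys, jitter_sd = noise
    if jitter_sd < 0:
        raise ValueError("mz_jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    delta = reaction_mass_shift(reaction)
    mzs: list[float] = []
    for comp in truth.compounds:
        base = mz_from_formula(comp.formula)
        mzs.append(base)
        for k in range(1, comp.true_events(reaction) + 1):
            if efficiency == 1.0 or rng.random() < efficiency:
                mzs.append(base + k * delta)
    for f in extra_formulas:
        mzs.append(mz_from_formula(f))
    if n_decoys:
        if mz_range is None:
            lo = min(mzs) - 10.0 if mzs else 100.0
            hi = max(mzs) + 10.0 if mzs else 800.0
        else:
            lo, hi = mz_range
        mzs.extend(rng.uniform(lo, hi, size=n_decoys).tolist())
    mz = np.asarray(mzs, dtype=float)
    if jitter_sd > 0:
        mz = mz + rng.normal(0.0, jitter_sd, size=mz.size)
    intensity = _lognormal_intensity(rng, mz.size)
    return Spectrum(
        sample_id=sample_id,
        mz=mz,
        intensity=intensity,
        polarity="negative",
        metadata={"reaction": reaction.value, "seed": seed},
    )


@dataclass
class SimulatedStudy:
    """A simulated tissue study plus its planted ground truth."""

    sample_set: SampleSet
    route_assignment: dict[str, set[MolecularFormula]]
    truth: GroundTruth


def _route_subsets(
    rng: np.random.Generator, truth: GroundTruth, route_overlap: float
) -> dict[str, set[MolecularFormula]]:
    """Split the truth into two route subsets whose union covers everything."""
    if not 0.0 <= route_overlap <= 1.0:
        raise ValueError("route_overlap must be within [0, 1]")
    formulas = list(truth.formulas)
    n = len(formulas)
    idx = rng.permutation(n)
    n_shared = int(round(route_overlap * n))
    shared = [formulas[i] for i in idx[:n_shared]]
    rest = [formulas[i] for i in idx[n_shared:]]
    half = (len(rest) + 1) // 2
    a = set(shared) | set(rest[:half])
    b = set(shared) | set(rest[half:])
    return {ROUTES[0]: a, ROUTES[1]: b}


def simulate_sample_set(
    truth: GroundTruth,
    background_n: int = 500,
    route_overlap: float = 0.18,
    seed: int = 0,
    n_control: int = 3,
    n_labeled: int = 10,
    n_ref: int = 3,
    n_decoys: int = 5000,
    mz_jitter_sd: float = 5e-5,
    efficiency: float = 0.9,
    mass_range: tuple[float, float] = (150.0, 800.0),
) -> SimulatedStudy:
    """Simulate a full labeling study around a planted mixture.

    Control extracts carry the endogenous background (shared formulas,
    per-spectrum intensities and m/z error) plus noise; each route's
    labeled-administration extracts add H/D series for that route's subset
    of planted compounds; labeled-reference spectra show all compounds
    with series; parent-reference spectra show them unlabeled.
    """
    rng = np.random.default_rng(seed)
    truth_set = set(truth.formulas)
    background: list[MolecularFormula] = []
    bg_used: set[MolecularFormula] = set(truth_set)
    while len(background) < background_n:
        f = _sample_formula(rng, mass_range)
        if f in bg_used:
            continue
        bg_used.add(f)
        background.append(f)

    routes = _route_subsets(rng, truth, route_overlap)
    empty = GroundTruth(compounds=[], seed=seed, params={})

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def background_spectrum(sample_id: str) -> Spectrum:
        return simulate_label_spectrum(
            empty,
            ReactionKind.HD_EXCHANGE,
            noise=(n_decoys, mz_jitter_sd),
            seed=child_seed(),
            sample_id=sample_id,
            extra_formulas=background,
            mz_range=(mass_range[0] - 1.0, mass_range[1] + 1.0),
        )

    control = [background_spectrum(f"control_{i + 1}") for i in range(n_control)]

    labeled_admin: dict[str, list[Spectrum]] = {}
    for route in ROUTES:
        subset = GroundTruth(
            compounds=[c for c in truth.compounds if c.formula in routes[route]],
            seed=seed,
            params={},
        )
        labeled_admin[route] = [
            simulate_label_spectrum(
                subset,
                ReactionKind.HD_EXCHANGE,
                efficiency=efficiency,
                noise=(n_decoys, mz_jitter_sd),
                seed=child_seed(),
                sample_id=f"{route}_{i + 1}",
                extra_formulas=background,
                mz_range=(mass_range[0] - 1.0, mass_range[1] + 1.0),
            )
            for i in range(n_labeled)
        ]

    labeled_ref = [
        simulate_label_spectrum(
            truth,
            ReactionKind.HD_EXCHANGE,
            efficiency=efficiency,
            noise=(n_decoys // 10, mz_jitter_sd),
            seed=child_seed(),
            sample_id=f"labeled_ref_{i + 1}",
        )
        for i in range(n_ref)
    ]
    parent_ref = [
        simulate_label_spectrum(
            truth,
            ReactionKind.HD_EXCHANGE,
            efficiency=0.0,
            noise=(n_decoys // 10, mz_jitter_sd),
            seed=child_seed(),
            sample_id="parent_ref_1",
        )
    ]
    return SimulatedStudy(
        sample_set=SampleSet(
            control=control,
            labeled_admin=labeled_admin,
            labeled_ref=labeled_ref,
            parent_ref=parent_ref,
        ),
        route_assignment=routes,
        truth=truth,
    )


def simulate_tag_experiments(
    truth: GroundTruth,
    seed: int = 0,
    reactions: Sequence[ReactionKind] = (
        ReactionKind.DEUTEROMETHYLATION,
        ReactionKind.REDUCTION,
        ReactionKind.BROMINATION,
        ReactionKind.HD_EXCHANGE,
    ),
    efficiency: float = 1.0,
    n_decoys: int = 500,
    mz_jitter_sd: float = 5e-5,
) -> dict[ReactionKind, list[Spectrum]]:
    """Chemical-tagging spectra of the parent material, one per reaction."""
    rng = np.random.default_rng(seed)
    out: dict[ReactionKind, list[Spectrum]] = {}
    for rxn in reactions:
        out[rxn] = [
            simulate_label_spectrum(
                truth,
                rxn,
                efficiency=efficiency,
                noise=(n_decoys, mz_jitter_sd),
                seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=f"tag_{rxn.value}",
            )
        ]
    return out


# ---------------------------------------------------------------------------
# fractions

# inclusion probability / intensity weight per (class, fraction) pair; the
# polarity gradient shifts unsaturated -> aromatic -> condensed aromatic
# character from 100% down to 25% methanol
_CLASS_INCLUSION = {
    CompoundClass.UNSATURATED: (0.95, 0.85, 0.60, 0.40),
    CompoundClass.AROMATIC: (0.70, 0.80, 0.85, 0.70),
    CompoundClass.CONDENSED_AROMATIC: (0.40, 0.55, 0.80, 0.90),
    CompoundClass.ALIPHATIC: (0.90, 0.75, 0.50, 0.30),
    CompoundClass.LIPID_LIKE: (0.70, 0.40, 0.20, 0.10),
}
_CLASS_WEIGHT = {
    CompoundClass.UNSATURATED: (1.5, 1.0, 0.6, 0.4),
    CompoundClass.AROMATIC: (0.8, 1.0, 1.2, 1.0),
    CompoundClass.CONDENSED_AROMATIC: (0.4, 0.7, 1.3, 1.6),
    CompoundClass.ALIPHATIC: (1.3, 1.0, 0.6, 0.4),
    CompoundClass.LIPID_LIKE: (1.5, 0.8, 0.4, 0.2),
}
# overall inclusion scale: formula counts peak in 100% MeOH, bottom in 25%
_FRACTION_SCALE = (1.0, 0.95, 0.9, 0.8)
# planted (liver-detected) compounds concentrate in the methanol fraction
_TARGET_WEIGHT = (6.0, 2.0, 1.0, 0.6)


def simulate_fractions(
    truth: GroundTruth,
    seed: int = 0,
    background_n: int = 1200,
    mass_range: tuple[float, float] = (150.0, 800.0),
    fraction_ids: Sequence[str] = FRACTION_IDS,
) -> list[FractionProfile]:
    """Solvent-fraction profiles with a polarity gradient.

    Background formulas distribute across fractions by compound class
    (emulating the unsaturated -> aromatic -> condensed shift down the
    methanol gradient); the planted compounds are boosted in the 100%
    methanol fraction.
    """
    rng = np.random.default_rng(seed)
    truth_set = set(truth.formulas)
    pool: list[MolecularFormula] = list(truth.formulas)
    used = set(truth_set)
    while len(pool) < background_n + len(truth_set):
        f = _sample_formula(rng, mass_range, oc_mean=0.24)
        if f in used:
            continue
        used.add(f)
        pool.append(f)

    profiles = []
    nf = len(fraction_ids)
    for j, fid in enumerate(fraction_ids):
        inv: dict[MolecularFormula, float] = {}
        for f in pool:
            cls = compound_class(f)
            jj = min(j, 3) if nf == 4 else min(int(round(j * 3 / max(nf - 1, 1))), 3)
            p_inc = _CLASS_INCLUSION[cls][jj] * _FRACTION_SCALE[jj]
            weight = _CLASS_WEIGHT[cls][jj]
            if f in truth_set:
                p_inc = min(1.0, p_inc + 0.25)
                weight *= _TARGET_WEIGHT[jj]
            if rng.random() < p_inc:
                inv[f] = float(rng.lognormal(10.0, 1.0) * weight)
        profiles.append(FractionProfile(fraction_id=fid, assignments=inv))
    return profiles


# ---------------------------------------------------------------------------
# toy structures

_CORE = "c1c{0}c{1}c{2}c{3}c1{4}"
_SUBSTITUENTS = [
    ("O", 4.0),  # phenolic OH
    ("C(=O)O", 3.0),  # carboxyl
    ("OC", 2.0),  # methoxy
    ("C", 1.5),  # methyl
    ("C(=O)C", 1.0),  # acetyl (ketone)
    ("C=O", 0.7),  # aldehyde
    ("CC(=O)O", 0.8),  # acetic-acid chain
    ("CCO", 0.7),  # hydroxyethyl
    ("Cc2ccc(O)cc2", 0.6),  # p-hydroxybenzyl bridge (lignin-like dimer)
    ("", 3.0),  # unsubstituted position
]


def _grammar_smiles(rng: np.random.Generator) -> str:
    frags = [s for s, _ in _SUBSTITUENTS]
    weights = np.array([w for _, w in _SUBSTITUENTS])
    weights = weights / weights.sum()
    picks = [frags[int(i)] for i in rng.choice(len(frags), size=5, p=weights)]
    if not any(p in ("O", "C(=O)O", "CC(=O)O", "CCO") for p in picks):
        picks[int(rng.integers(0, 5))] = "O" if rng.random() < 0.6 else "C(=O)O"
    slots = [f"({p})" if p else "" for p in picks[:4]]
    return _CORE.format(*slots, picks[4])


def _structures_from_grammar(
    rng: np.random.Generator,
    n: int,
    mass_range: tuple[float, float],
    used: set[MolecularFormula],
):
    """Yield (smiles, compound) pairs with RDKit-derived truth descriptors."""
    from .candidate_filter import count_groups, standardize_candidates

    out = []
    seen_smiles: set[str] = set()
    tries = 0
    local_used = set(used)
    while len(out) < n:
        tries += 1
        if tries > 100000:
            raise RuntimeError("structure grammar exhausted")
        cands, _ = standardize_candidates([_grammar_smiles(rng)])
        if not cands:
            continue
        cand = cands[0]
        if cand.smiles in seen_smiles or cand.formula in local_used:
            continue
        if not (mass_range[0] <= cand.formula.mass <= mass_range[1]):
            continue
        g = cand.groups
        n_exch = g.carboxyl + g.hydroxyl
        if n_exch < 1:
            continue
        seen_smiles.add(cand.smiles)
        local_used.add(cand.formula)
        out.append(
            (
                cand.smiles,
                GroundTruthCompound(
                    formula=cand.formula,
                    n_cooh=g.carboxyl,
                    n_carbonyl=g.carbonyl,
                    is_aromatic=g.aromatic_rings >= 1,
                    n_exchangeable=n_exch,
                    smiles=cand.smiles,
                ),
            )
        )
    return out


def generate_structure_library(
    n: int, seed: int = 0, invalid_fraction: float = 0.0
) -> list[str]:
    """Raw toy SMILES library (duplicates possible, as a generator emits).

    ``invalid_fraction`` injects syntactically broken strings to exercise
    the validity stage of the candidate filter.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if invalid_fraction and rng.random() < invalid_fraction:
            out.append("not_a_smiles_" + str(int(rng.integers(0, 10**6))))
        else:
            out.append(_grammar_smiles(rng))
    return out
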