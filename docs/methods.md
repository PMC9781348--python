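# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `isoderep`. It describes what the code computes and why the
defaults are what they are; every number quoted here is produced by the
test suite or by `scripts/acceptance.py`.

## Mass model

All arithmetic is monoisotopic: H = 1.0078250319, D = 2.0141017780,
C = 12 (exact), O = 15.9949146221, Br = 78.9183376 Da. Ionization is
negative-mode deprotonation at unit charge, m/z = M − 1.007276467 (the
proton mass; the electron stays with the anion). Polyphenols ionize
efficiently as [M−H]⁻ and the workflow assumes singly charged ions
throughout; other polarities and charge states raise
`NotImplementedError` rather than silently computing something else.

The per-event shifts of the four labeling reactions are derived, not
stored: H/D exchange is +D − H (1.0062767 Da), deuteromethylation
converts an acidic OH to OCD₃ (+C + 3D − H = 17.0344803 Da), deuteride
reduction converts C=O to CHD–OH (+H + D = 3.0219268 Da), and NBS
bromination substitutes an aromatic H by Br (+Br − H = 77.9105126 Da).
Import-time assertions pin each derived value to its conventional
5-decimal constant within 1 × 10⁻⁵ Da.

Deuterium counts as hydrogen in every formula descriptor (H/C, DBE,
aromaticity index), so labeling never moves a compound between classes.

## Formula descriptors and compound classes

- DBE = C − (H + D + Br)/2 + 1.
- Aromaticity index (CHO-restricted): AI = (1 + C − O − 0.5·H) / (C − O),
  clamped to 0 when the denominator is ≤ 0 or the numerator negative.
  This is the standard formula-level aromaticity measure for complex
  organic mixtures; the clamping convention makes AI a total function.
- Classes, evaluated in order: lipid-like (H/C ≥ 1.7 and O/C ≤ 0.25),
  aliphatic (H/C ≥ 1.5), condensed aromatic (AI ≥ 0.67), aromatic
  (AI > 0.5), otherwise unsaturated. The thresholds are the field
  conventions for van Krevelen classification and are configurable
  (`ClassThresholds`); the lipid window exists so that fraction profiles
  can exclude compounds unlikely to be indigenous to a polyphenolic
  material.

## Formula assignment

Peaks are assigned by exhaustive enumeration of CHO compositions within a
relative tolerance. For each (C, O) pair the hydrogen count is solved
directly from the residual mass, so the scan is O(C_max · O_max) per
peak. Defaults: C ≤ 40, H ≤ 80, O ≤ 40, H/C ∈ [0.3, 2.2], O/C ≤ 1,
integer DBE ≥ 0 (even hydrogen — the CHO analogue of the nitrogen rule),
0.5 ppm tolerance. These bounds cover the sub-800 Da polyphenol space
with margin. The best candidate (smallest |error|, ties broken by fewer
oxygens then fewer carbons) is kept; peaks with several candidates in
tolerance carry an `ambiguous` flag and are never silently resolved.
Below 800 Da at 0.2 ppm, recovery of planted formulas from exact masses
is complete (`formula_recovery_rate_pct` in the acceptance output).

## Series extraction

A labeling series is the maximal chain of peaks at `base + k·Δ`,
k = 1..k_max, each within an absolute tolerance of the ideal position.
Two deliberate choices:

- **Base anchoring.** Member positions are computed from the observed
  base, not from the previously found member, so position errors do not
  accumulate along the chain. The tolerance (default 0.0003 m/z) is
  absolute, matching how FTICR mass error between series members behaves.
- **Lowest-base reporting.** A peak that itself has a predecessor at
  `mz − Δ` is not a chain base; every chain is therefore reported exactly
  once, under its lowest-m/z member. Chains stop at the first missing k
  and singleton "chains" (no labeled member) are discarded.

The detector is vectorized level-by-level with binary search; a naive
O(n²·k_max) all-pairs oracle in the test suite reproduces its output
exactly on randomized spectra. `k_max` defaults to 12, above the
exchangeable-hydrogen counts of sub-800 Da polyphenols.

Chemistry-rule filtration requires the base peak to carry an assigned,
unlabeled (d = 0) formula and the series length to be feasible for it:
H/D events ≤ H; deuteromethylation events ≤ ⌊O/2⌋ (each carboxyl needs
two oxygens); reduction events ≤ O minus oxygens committed to known
carboxyls (when a carboxyl count is available); bromination events ≤
max(0, DBE − 3), used as presence/absence evidence only — whether longer
bromination series report aromatic-H counts quantitatively is not
established, so the package does not interpret them. All rules are
config-overridable (`SeriesRules`).

## Descriptors

Series lengths fold into per-formula descriptors: carboxyl count from the
deuteromethylation series, carbonyl count from the reduction series,
aromaticity from bromination presence, exchangeable-H count from the H/D
series. An experiment-coverage set distinguishes "not measured" from
"measured, none found": a reduction experiment that was run and shows no
series reports zero carbonyls, and a bromination experiment with no
series reports a non-aromatic compound, while a missing deuteromethylation
series stays unknown (absence of a series may reflect ionization failure
as well as absence of the group). A record is *complete* when all three
structural descriptors (COOH, C=O, aromaticity) are known.

## Exogenous-component detection

A component record for one administration route requires, per the
labeling logic: (i) a chemistry-feasible H/D series in a
labeled-administration spectrum, (ii) an assigned unlabeled base formula,
and (iii) no H/D series at that base m/z (within tolerance) in any
control spectrum. The control test is on *series*, not peaks — an
endogenous compound may share the base mass, but only administered,
labeled material produces the D signature. Components missing from the
labeled-reference spectra are retained but flagged, since direct-ESI
spectra of complex mixtures do not reproducibly ionize every component;
the final filter can (and by default does) require the flag.

Records merge across routes by formula (routes unioned, per-route
replicate support kept, descriptors merged field-wise with conflicts
flagged). The final filtration is conjunctive and logged per criterion:
replicate support ≥ 2, presence in the labeled reference, H/C ∈
[0.3, 2.2], O/C ∈ [0, 1]. The per-criterion attrition counts in the run
report let users audit or emulate alternative filtration schemes.

## Fraction profiling

Number-averaged metrics ((O/C)ₙ and friends) are unweighted means over
assigned formulas — the (·)ₙ convention — with intensity weighting
available as an option. Class distributions exclude lipid-like formulas
by default before computing shares, which then sum to 1 over retained
classes. Enrichment of a target set is its summed intensity share within
the fraction's own spectrum, so fractions of different total ion current
compare fairly; the score is bounded in [0, 1] and monotone in the target
set (property-tested). Fraction ranking is a stable sort by score.

## Candidate filtering

Structures are standardized with RDKit: validity check, stereochemistry
stripped, canonical SMILES deduplication, non-CHO structures dropped.
Group counting uses SMARTS with explicit exclusions: carboxyl =
C(=O)OH; hydroxyl = OH not in a carboxyl (phenolic and alcoholic OH both
count as ionizable); carbonyl = ketone/aldehyde C=O, excluding carboxyls
and esters; aromatic rings are counted as fused ring *systems*
(naphthalene is one, biphenyl two).

Filtering is staged and the report counts are non-increasing by
construction: (1) ≥ 1 ionizable group (–OH or –COOH) — a structure
invisible in negative ESI cannot be a detected component; (2) ≥ 1 of the
three tag-enumerable moieties (aromatic ring, carboxyl, carbonyl);
(3) exact C/H/O formula match against the component list; (4, strict mode
only) equality of the structure's group counts with the matched
component's known descriptor fields. The lenient/strict pair brackets the
two defensible readings of "matched at least one of three moieties":
global possession of a moiety versus per-formula count agreement; the
stage report makes the difference observable.

## The synthetic-data generators

The generators define the study conditions under which the pipeline is
validated; they are first-class, tested code.

- **Mixture**: rejection-sampled CHO formulas at 150–800 Da, H/C ∈
  [0.3, 2.2], even hydrogen, oxygen drawn binomially around O/C ≈ 0.28
  (oxidized-lignin-like). Group counts respect the element budget:
  carboxyls in {1, 2, 3} (weighted toward 2, as carboxyl-rich oxidized
  polyphenols are), capped at ⌊O/2⌋; carbonyls within the remaining
  oxygen; aromaticity tied to DBE ≥ 4; 2–6 exchangeable hydrogens
  (deep labeling exchanges more than the hydroxyl protons). An optional
  grammar mode builds each compound from an actual substituted-arene
  SMILES so that formula, groups and structure are mutually consistent.
- **Labeled spectra**: base [M−H]⁻ peak per compound plus members
  k = 1..(true event count), each retained independently with probability
  `efficiency`; Gaussian m/z jitter on every peak; uniform decoy peaks;
  log-normal intensities (only relative values matter downstream).
  Back-exchange is modeled solely by this thinning — no kinetics.
- **Study design**: 3 control and 10 labeled-administration spectra per
  route, 3 labeled-reference spectra, the replicate structure of the
  pharmacokinetic experiment the simulation emulates. In-vivo H/D spectra
  default to efficiency 0.9 (metabolic back-exchange); chemical-tagging
  spectra of the parent material default to 1.0, as derivatization
  chemistry driven to completion. Defaults: 500 endogenous background
  formulas shared across all tissue spectra, 5000 decoy peaks per
  spectrum, jitter σ = 5 × 10⁻⁵ m/z (so member-to-base error is ~4σ
  inside the 0.0003 tolerance), route overlap 0.18 of the mixture.
- **Fractions**: four solvent compositions (100/75/50/25% CH₃OH);
  per-class inclusion probabilities and intensity weights shift the
  profile from unsaturated toward condensed-aromatic down the gradient,
  total formula counts fall monotonically, and planted compounds are
  boosted in the methanol fraction.

What passing these tests shows — and does not. The simulations exercise
the complete decision logic (series chaining under jitter, control
subtraction, replicate support, reference matching, descriptor folding)
at realistic peak densities. They do not model FTICR noise physics,
space-charge effects, isotopologue fine structure, adducts other than
[M−H]⁻, intensity-dependent mass error, or partial back-exchange
kinetics; recovery rates on real spectra will be lower and
instrument-dependent.

## Numerical and degenerate-input choices

- Peak lists are deduplicated at 1 × 10⁻⁶ m/z (intensity-summed,
  intensity-weighted centroid); spectra are always sorted.
- Nearest-peak ties in series chaining resolve to the lower m/z; the
  brute-force oracle mirrors this rule, so equivalence is exact.
- Assignment ties resolve by fewer oxygens, then fewer carbons —
  deterministic, and flagged as ambiguous regardless.
- AI degenerate cases clamp to 0; empty profiles raise on averaging and
  scoring rather than returning NaN.
- Greedy one-to-one peak matching by smallest |Δm/z| partitions both
  spectra; on ≤ 10-peak inputs it agrees with brute-force optimal
  matching in the tested regimes.
- If a reduction series and a deuteromethylation series jointly overrun a
  formula's oxygen budget, the carboxyl count wins, the carbonyl count is
  dropped to unknown, and the record is flagged as conflicting.

## Problem sizes

The default validation study (50 planted compounds, 500 background
formulas, 5000 decoys per spectrum, 26 spectra of ~6000 peaks) was chosen
so the full pipeline and its oracle cross-checks run comfortably on a
laptop; all headline rates in `scripts/acceptance.py` are computed at
these sizes. Sensitivity and FDR are stable across seeds because
replicate support (≥ 2 of 10 spectra) makes both missed detections and
decoy coincidences vanishingly rare; the residual failure mode is a
low-mass compound whose jittered base peak exceeds the 0.5 ppm assignment
window in a single tag spectrum, which surfaces as an unknown descriptor,
not a wrong one.

## Known limitations

- CHO(+D, Br) only; no N/S/P heteroatoms, no adducts, no multimers.
- Single best formula per peak; isotopic fine structure is not used to
  confirm assignments.
- The final-filtration criteria and series-feasibility rules are
  reasonable defaults, explicitly configurable, and logged — not claims
  about any particular instrument's optimal settings.
- Bromination series are interpreted qualitatively only.
- The candidate filter constrains composition and group counts; it cannot
  distinguish structural isomers with identical counts.
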