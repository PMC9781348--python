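"""Assign CHO molecular formulas to negative-mode [M-H]- peaks.

Builds a tiny spectrum from three known compounds, assigns formulas by
exhaustive enumeration at 0.5 ppm, and prints the assignment table.
"""

from isoderep import MolecularFormula, Spectrum, assign_formulas, mz_from_formula
from isoderep.formula_assign import assignment_table

known = [
    MolecularFormula(c=7, h=6, o=2),   # benzoic acid
    MolecularFormula(c=9, h=8, o=4),   # coumaric-acid-like
    MolecularFormula(c=15, h=10, o=6), # flavone-like
]
spectrum = Spectrum.from_peaks(
    "demo", [(mz_from_formula(f), 100.0 * (i + 1)) for i, f in enumerate(known)]
)

result = assign_formulas(spectrum)
print(assignment_table(result).to_string(index=False))
print(
    f"\n{result.n_assigned}/{result.n_peaks} peaks assigned, "
    f"{result.n_ambiguous} ambiguous."
)
print(
    "Each row maps a peak to its unique elemental composition; error_ppm is\n"
    "the relative mass error, dbe/oc/hc/ai are the formula descriptors used\n"
    "later for compound classification."
)
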