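"""Profile solvent fractions and rank them by target enrichment.

Simulates the methanol-water fraction gradient of a polyphenolic mixture
and prints per-fraction formula counts, number-averaged O/C, compound-class
shares (lipids excluded) and the intensity share of the target components.
"""

from isoderep import class_distribution, enrichment_score, number_average, rank_fractions
from isoderep.synthetic import generate_mixture, simulate_fractions

truth = generate_mixture(50, seed=42)
profiles = simulate_fractions(truth, seed=43)
targets = set(truth.formulas)

print(f"{'fraction':>12} {'formulas':>9} {'(O/C)n':>7} {'enrichment':>11}  class shares")
for p in profiles:
    dist = class_distribution(p)
    shares = ", ".join(
        f"{cls.value[:11]}={share:.2f}" for cls, (_, share) in sorted(
            dist.items(), key=lambda kv: -kv[1][1]
        )
    )
    print(f"{p.fraction_id:>12} {p.n_formulas:>9} {number_average(p, 'oc'):>7.3f} "
          f"{enrichment_score(p, targets):>11.3f}  {shares}")

best, score = rank_fractions(profiles, targets)[0]
print(f"\nmost enriched fraction: {best.fraction_id} (target share {score:.3f})")
print(
    "Formula counts fall and condensed-aromatic character grows down the\n"
    "methanol gradient, while the pure-methanol fraction concentrates the\n"
    "components previously detected in tissue — the fraction worth isolating."
)
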