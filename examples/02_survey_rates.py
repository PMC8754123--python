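"""Recompute survey-level SAC rates and the habitat association.

Uses the per-order strain/type-strain counts of the reference
actinobacterial survey shipped with the package (7,180 strains, 1,969
type strains = species) and the printed habitat partition of the 1,923
source-classified species.
"""

from nanclust import load_reference_order_counts, rate_table
from nanclust.stats import contingency_from_counts

ref = load_reference_order_counts()
types = rate_table(
    ref.rename(columns={"order": "taxon", "n_type": "n", "n_sac_type": "n_positive"})[
        ["taxon", "n", "n_positive"]
    ]
).set_index("taxon")

print("species-level SAC positive rates (type strains), selected orders:")
for taxon in ("Actinomycetales", "Dermabacterales", "Coriobacteriales",
              "Mycobacteriales", "Ruaniales", "Total"):
    row = types.loc[taxon]
    print(f"  {taxon:<18} {row['n']:>5}  positive {row['n_positive']:>4}  rate {row['rate']}")

res = contingency_from_counts(151, 458, 103, 1211)
print(
    f"\nhabitat association: {res.rate_animal}% of animal-associated vs "
    f"{res.rate_non_animal}% of non-animal-associated species are SAC-positive"
)
print(f"two-sided Fisher exact p = {res.p_value:.3g}")
print(
    "\nRates are percentages rounded half-up to 2 decimals; taxa with fewer"
    "\nthan 5 members report ND (no data). The tiny p shows the strong"
    "\nenrichment of sialic acid catabolism among animal-associated species."
)
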