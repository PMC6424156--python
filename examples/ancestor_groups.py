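"""Ancestor-group survival curves vs period life tables from age 31.

Generates a three-group synthetic genealogy in which group differences come
entirely from the age-independent (Makeham) hazard — early/mid-life
environment — and contrasts the adult survival curves with stylised
19th-century and contemporary period life tables, both conditioned on
having reached age 31.
"""

from plateaurecord import (
    FRANCE_1875_LIKE,
    FRANCE_2014_LIKE,
    empirical_survival,
    generate_ancestor_cohorts,
    generate_life_table,
    lifetable_survival,
)

START_AGE = 31

ancestors = generate_ancestor_cohorts(seed=21)
print(f"genealogy of {len(ancestors)} ancestors in groups {ancestors.groups}")
for g in ancestors.groups:
    spans = ancestors.subset(g).lifespans()
    adults = spans[spans >= START_AGE]
    curve = empirical_survival(ancestors, START_AGE, group=g)
    print(f"  {g:20s} n={len(spans):2d}  adults={len(adults):2d}  "
          f"median adult lifespan {START_AGE + curve.median():.0f}y  "
          f"max {spans.max():.0f}y")

for model, tag in [(FRANCE_1875_LIKE, "period-1875-like"), (FRANCE_2014_LIKE, "period-2014-like")]:
    table = generate_life_table(model, 110, tag)
    curve = lifetable_survival(table, START_AGE)
    print(f"  {tag:20s} life-table median adult lifespan "
          f"{START_AGE + curve.median():.0f}y")

print("\nReading: the two low-background-mortality groups are nearly")
print("indistinguishable and resemble the modern life table, while the")
print("high-background group dies much earlier — a difference in early-adult")
print("environment, not in old-age longevity.")
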