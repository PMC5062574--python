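"""Derived-doubleton sharing between populations.

Doubletons — variants seen exactly twice — mark very recent shared ancestry:
the two carriers nearly always co-inherited the mutation from a recent
common ancestor. Simulating two African-heavy populations and one
European-heavy population shows sharing tracking shared demographic history.
"""

import admixstats as A

pops = {
    "GroupA1": {"AFR": 0.85, "EUR": 0.10, "NAM": 0.05},
    "GroupA2": {"AFR": 0.80, "EUR": 0.15, "NAM": 0.05},
    "GroupB": {"AFR": 0.25, "EUR": 0.65, "NAM": 0.10},
}
spec = A.DemographicSpec(
    n_individuals=25, populations=tuple(pops), s_f=pops, s_m=pops, seed=3
)
panel = A.simulate_panel(40_000, spec)
cohort = A.simulate_cohort(spec, panel)

dbl = A.find_doubletons(cohort.genotypes, panel.table, missingness_max=0.05)
share = A.sharing_matrix(cohort.genotypes, dbl)
print(f"{share.total_doubletons} doubletons "
      f"({share.excluded_homozygous} carried twice by one individual, "
      "excluded from the pair matrix)")
print("\nper-pair normalized sharing (higher = more recent shared ancestry):")
print(share.pop_normalized.round(3))
# The two African-heavy groups share more with each other than either does
# with the European-heavy group: rare variants are young and mostly arose on
# the African background both groups inherit from.
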