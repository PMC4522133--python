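"""Reproduce the reference cohort's genotype-frequency table.

Expands the shipped genotype composition of a 279-patient reference cohort
and tabulates diplotype and metabolizer-category frequencies.
"""

from tamoxmr import genotype_frequency_table, load_reference_cohort

dips = load_reference_cohort()
by_dip, by_cat = genotype_frequency_table(dips)

print(f"cohort size: {len(dips)}")
print()
print(by_cat.round(1).to_string(index=False))
print()
empm = by_dip[by_dip["category"] == "EM/PM"].set_index("diplotype")
wt4 = empm.loc["*1/*4", "count"] + empm.loc["*2/*4", "count"]
print(
    f"within EM/PM, {wt4} of {empm['count'].sum()} patients "
    f"({100 * wt4 / empm['count'].sum():.1f} %) carry a wild-type/*4 combination"
)
print()
print(
    "EM/PM (one functional, one null allele) is the most common category;\n"
    "percentages are fractions of the analysable cohort."
)
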