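# Default CYP2D6 star-allele definition table for the 11-SNP TaqMan panel
# (plus two copy-number assays for whole-gene deletion *5 / duplication).
#
# Each non-reference allele is keyed by the canonical variant(s) that must
# carry the alternate base for the allele to be called; *2 is keyed by its
# two-variant signature (2850C>T + 4180G>C).  1661G>C is tracked on the
# panel but defines no allele in this table: it occurs on several
# haplotypes and is uninformative for this allele set.
#
# activity: EM = fully functional, IM = reduced function, PM = null.
# *5 is the whole-gene deletion and is represented by copy number (< 2),
# not by variant states.
panel:
  - "100C>T"
  - "1023C>T"
  - "1661G>C"
  - "1707delT"
  - "1846G>A"
  - "2549delA"
  - "2613delAGA"
  - "2850C>T"
  - "2935A>C"
  - "2988G>A"
  - "4180G>C"
alleles:
  "*1":  {activity: EM, variants: []}
  "*2":  {activity: EM, variants: ["2850C>T", "4180G>C"]}
  "*3":  {activity: PM, variants: ["2549delA"]}
  "*4":  {activity: PM, variants: ["1846G>A"]}
  "*5":  {activity: PM, variants: [], deletion: true}
  "*6":  {activity: PM, variants: ["1707delT"]}
  "*7":  {activity: PM, variants: ["2935A>C"]}
  "*9":  {activity: IM, variants: ["2613delAGA"]}
  "*10": {activity: IM, variants: ["100C>T"]}
  "*17": {activity: IM, variants: ["1023C>T"]}
  "*41": {activity: IM, variants: ["2988G>A"]}
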