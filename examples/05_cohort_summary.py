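"""Summarize the bundled 18-month novel-allele cohort.

Allele-level tallies (mutation class, locus, exon category) run over the 29
unique novel alleles; sample-level tallies (patient category, ethnicity)
over all 41 samples, since related donors can carry the same novelty.
"""

from hlanovel.cohort import summarize_reference_cohort

print(summarize_reference_cohort().report())

# 1.6 unique novelties per month over 18 months of routine clinical NGS
# typing -- novel alleles are an everyday occurrence, not a curiosity; over
# half sit in the class II alpha genes (DPA1, DQA1), which older typing
# methods rarely sequenced at full length.
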