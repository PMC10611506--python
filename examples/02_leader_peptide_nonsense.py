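"""Negative codon numbering: a stop-gain inside the leader peptide.

The bundled DPA1-like model places the leader's 31 codons at the start of
the gene; a C>T at genomic position 79 turns the arginine codon CGA at
leader position -5 into the TGA stop, producing a null allele.
"""

from hlanovel import characterize, render_aa
from hlanovel.fixtures import dpa1_leader_model
from hlanovel.variants import ObservedVariant

model = dpa1_leader_model()
char = characterize(model, ObservedVariant(79, "C", "T"))
cc = char.codon_change

print(f"exon {char.region.index}, domain {char.domain.value}")
print(f"codon {cc.codon_position}: {cc.ref_codon} > {cc.alt_codon}")
print(f"protein: {render_aa(cc.ref_aa)} -> {render_aa(cc.alt_aa)} "
      f"({char.mutation_class.value})")

# codon -5 means the fifth codon before the mature protein starts; the stop
# is rendered X, the convention on HLA sequence alignments.  A truncated
# leader prevents surface expression, hence an N (null) suffix on the
# eventual allele name.
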