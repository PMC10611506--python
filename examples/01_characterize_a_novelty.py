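"""Characterize a novel allele from a reference/consensus sequence pair.

Builds the bundled HLA-B-like gene model, introduces the Thr228Ala novelty
into its sequence, detects the difference and annotates it: the exon, the
protein domain, the codon change in mature-protein numbering and the
mutation class, ending with the written sentence used when registering the
allele.
"""

from hlanovel import characterize, describe_mutation, detect_variants
from hlanovel.fixtures import b48_model
from hlanovel.gene_model import DOMAIN_DISPLAY

model = b48_model()
reference = model.sequence
consensus = reference[:1700] + "G" + reference[1701:]  # A>G at position 1701

[variant] = detect_variants(reference, consensus)
print(f"variant: position {variant.pos}, "
      f"{variant.ref_base} > {variant.alt_base}")

char = characterize(model, variant)
cc = char.codon_change
print(f"region:  exon {char.region.index} "
      f"({DOMAIN_DISPLAY[char.domain]}), key exon: {char.key_exon}")
print(f"codon:   {cc.codon_position} {cc.ref_codon} > {cc.alt_codon} "
      f"({cc.ref_aa} -> {cc.alt_aa}), class: {char.mutation_class.value}")
print(describe_mutation("VGH002", "B*48:01:01:01", char))

# The codon is numbered 228 because the raw CDS codon (252) sits 24 codons
# -- the leader peptide -- after the initiator; mature-protein numbering
# starts at +1 after the leader and never uses 0.
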