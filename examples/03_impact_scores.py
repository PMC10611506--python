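"""Score the potential protein impact of the bundled missense novelties.

Each missense novelty gets one "+" per criterion met: the amino-acid change
itself, a change of physicochemical category, location in the antigen-
binding site, and an effect on a known eplet.
"""

from hlanovel import (
    default_property_table,
    demo_eplet_registry,
    locus_group_of,
    score_impact,
)
from hlanovel.fixtures import (
    characterization_from_fixture_row,
    load_missense_table,
    load_novel_allele_table,
)

table = default_property_table()
registry = demo_eplet_registry()
rows = {r.allele: r for r in load_novel_allele_table().itertuples()}

print(f"{'allele':<14} {'codon':>6} change    score  criteria")
for r in load_missense_table().itertuples():
    char = characterization_from_fixture_row(rows[r.allele])
    s = score_impact(char, table, registry,
                     locus_group_of(r.allele.split('*')[0]))
    flags = "".join("ap bs ep".split()[i] + " "
                    for i, hit in enumerate(
                        [s.property_change, s.binding_site, s.eplet_effect])
                    if hit)
    print(f"{r.allele:<14} {r.codon_position:>6} "
          f"{r.ref_aa}->{r.alt_aa:<6} {s.rendered:<6} aa {flags}")

# 'aa' = amino-acid change (every missense), 'ap' = altered property
# category, 'bs' = antigen-binding site, 'ep' = eplet affected.  A "++++"
# allele changes residue chemistry inside the binding site at an eplet
# position -- the strongest signal for antibody-relevant change.
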