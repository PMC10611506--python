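residue	category
Gly	nonpolar_aliphatic
Ala	nonpolar_aliphatic
Val	nonpolar_aliphatic
Leu	nonpolar_aliphatic
Ile	nonpolar_aliphatic
Met	nonpolar_aliphatic
Pro	nonpolar_aliphatic
Phe	nonpolar_aromatic
Trp	nonpolar_aromatic
Tyr	nonpolar_aromatic
Ser	polar_uncharged
Thr	polar_uncharged
Cys	polar_uncharged
Asn	polar_uncharged
Gln	polar_uncharged
Lys	basic
Arg	basic
His	basic
Asp	acidic
Glu	acidic
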