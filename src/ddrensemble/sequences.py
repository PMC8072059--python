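"""Reference sequences used in examples and reference-state runs.

FUS_NTD is the intrinsically disordered N-terminal region (residues
1-267) of human fused in sarcoma (FUS, UniProt P35637), a QGSY- and
glycine-rich low-complexity sequence with no folded domains — the
standard fully disordered reference system for coil-statistics runs.
Reference-state ensemble statistics depend on the residue-class
composition (Gly/Pro/branched fractions), not on the exact residue
order.
"""

FUS_NTD = (
    "MASNDYTQQATQSYGAYPTQPGQGYSQQSSQPYGQQSYSGYSQSTDTSGY"
    "GQSSYSSYGQSQNTGYGTQSTPQGYGSTGGYGSSQSSQSSYGQQSSYPGY"
    "GQQPAPSSTSGSYGSSSQSSSYGQPQSGSYSQQPSYGGQQQSYGQQQSYN"
    "PPQGYGQQNQYNSSSGGGGGGGGGGNYGQDQSSMSSGGGSGGGYGNQDQS"
    "GGGGSGGYGQQDRGGRGRGGSGGGGGGGGGGYNRSSGGYEPRGRGGGRGG"
    "RGGMGGSDRGGFNKFGG"
)

#: first 100 residues — the section used for large reference ensembles
FUS_1_100 = FUS_NTD[:100]

#: residues 67-166 — the section flanking segment 105-128
FUS_67_166 = FUS_NTD[66:166]
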