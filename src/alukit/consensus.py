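"""Packaged Alu consensus.

A single AluY-family consensus with an intact 5' end (it begins with the
GGCCGGGCGC signature motif). It serves two roles: the homology reference
for scoring REF+ candidate spans, and the default insert backbone for
the planted-insertion simulator. Users may substitute their own
(possibly multi-record) Alu library wherever a consensus is accepted.
"""

ALU_CONSENSUS_NAME = "AluY_consensus"

ALU_CONSENSUS = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGA"
    "TCACGAGGTCAGGAGATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTAA"
    "AAATACAAAAAATTAGCCGGGCGTGGTGGCGGGCGCCTGTAGTCCCAGCTACTCGGGAGG"
    "CTGAGGCAGGAGAATGGCGTGAACCCGGGAGGCGGAGCTTGCAGTGAGCCGAGATCGCGC"
    "CACTGCACTCCAGCCTGGGCGACAGAGCGAGACTCCGTCTCAAAAAAA"
)


def alu_consensus_records() -> dict[str, str]:
    """Consensus as a {name: sequence} mapping (FASTA-record shaped)."""
    return {ALU_CONSENSUS_NAME: ALU_CONSENSUS}
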