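"""Sequence utilities and the bundled synthetic target.

The bundled target is a synthetic 120-nt fluoride-riboswitch-like RNA: a
random sequence with a fixed seed, screened so that it contains no EcoRI
recognition site, no copy of the sequencing linker, and no repeated 18-mer
(so error-free reads map uniquely).  It is a stand-in for a real target; the
folding ground truth is positional, so only coordinates matter.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


#: synthetic 120-nt target RNA (written in DNA alphabet, nontemplate sense)
SYNTHETIC_TARGET = (
    "GAGGTTCCGGAAATCGATATCGTATGAGCGCTACAGGTTGGCTAGATGCAGGTTAAGAAA"
    "TTCCTCGATGCCGACACCTTAAAATCCGATCTGGCATTCATATTCAGTTACGCGGTCCTT"
)

#: synthetic 45-nt promoter (positions -45..-1; carried by the forward primer)
SYNTHETIC_PROMOTER = "CGTGTGAGTGAATGCGCCTCGTGCAGGACCCATGCGGAGAAAACC"

#: non-native sequence transcribed by Gln111 roadblock run-through TECs:
#: the EcoRI recognition site followed by synthetic cassette filler
ECORI_SITE = "GAATTC"
CASSETTE_FILLER = "AAGATTTTGAACAGACTAGGACCACGTTTG"
CASSETTE = ECORI_SITE + CASSETTE_FILLER


def hamming(a: str, b: str) -> int:
    """Mismatch count over the common prefix of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
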