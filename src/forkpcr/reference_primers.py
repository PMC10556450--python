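"""Reference fork PCR primers bundled with the package.

Two fork primer sets sharing one universal branch primer, plus the nested
site-specific primer triples for the four loci the method was validated on
(gadA, gadR, pct in *Levilactobacillus brevis* CD0817; hyg in rice).  These
are inputs: the validator is applied to them in tests, and one of them
(gadR iNSP, which contains an AAAA run) deliberately fails the run-length
design rule — it is kept verbatim.
"""

from __future__ import annotations

from .oligos import Oligo, ForkPrimerSet, decompose_fork

__all__ = ["FORK1", "FORK2", "NSP_TRIPLES", "ALL_PRIMERS", "BP"]

BP = Oligo("BP", "CCTGACCGCCTTCTACACCT", "BP")

FORK1: ForkPrimerSet = decompose_fork(
    Oligo("PFP1", "ACGCGTAATAGCTCGGGATGATGCTGCTCGTGGATGACTCT", "PFP"),
    Oligo("SFP1", "CCTGACCGCCTTCTACACCTATGCTGCTCGTGGATGACTCT", "SFP"),
    BP,
    set_id="fork1",
)

FORK2: ForkPrimerSet = decompose_fork(
    Oligo("PFP2", "ATCCGCCCATAGCCTTCAGTGACTACGCTGCCTTGCTACTT", "PFP"),
    Oligo("SFP2", "CCTGACCGCCTTCTACACCTGACTACGCTGCCTTGCTACTT", "SFP"),
    BP,
    set_id="fork2",
)

#: locus -> (oNSP, mNSP, iNSP) used one per walking round
NSP_TRIPLES: dict[str, tuple[Oligo, Oligo, Oligo]] = {
    "gadA": (
        Oligo("gadA_oNSP", "GTTTCTGGTCACAAGTACGGCATGG", "oNSP"),
        Oligo("gadA_mNSP", "TGCTGATACGCTGCCAGAAGAAATG", "mNSP"),
        Oligo("gadA_iNSP", "ACGGTTGACTCCATTGCCATTAACT", "iNSP"),
    ),
    "gadR": (
        Oligo("gadR_oNSP", "TCCTTCGTTCTTGATTCCATACCCT", "oNSP"),
        Oligo("gadR_mNSP", "CCATTTCCATAGGTTGCTCCAAGG", "mNSP"),
        Oligo("gadR_iNSP", "GGATACTGGCTAAAATGAATTAACTCGGATAA", "iNSP"),
    ),
    "pct": (
        Oligo("pct_oNSP", "TCTTGTTCTTCAACAGTGGTGGGTA", "oNSP"),
        Oligo("pct_mNSP", "TCGTCTTTCGTGTAAGTGTTGGTGT", "mNSP"),
        Oligo("pct_iNSP", "AGGAAATATGCACTCTTGGGAAGCG", "iNSP"),
    ),
    "hyg": (
        Oligo("hyg_oNSP", "ACGGCAATTTCGATGATGCAGCTTG", "oNSP"),
        Oligo("hyg_mNSP", "GGGACTGTCGGGCGTACACAA", "mNSP"),
        Oligo("hyg_iNSP", "CTGGACCGATGGCTGTGTAGAAG", "iNSP"),
    ),
}

ALL_PRIMERS: dict[str, Oligo] = {
    o.name: o
    for o in (
        FORK1.pfp, FORK1.sfp, BP, FORK2.pfp, FORK2.sfp,
        *(o for trip in NSP_TRIPLES.values() for o in trip),
    )
}
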