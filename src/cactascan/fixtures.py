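"""Published sequence fixtures for the Chenopodium Jozin CACTA family.

These are the terminal inverted repeats (TIRs), subterminal repeat (subTIR)
unit motifs, per-end copy counts, element lengths and the satellite-DNA
consensus monomer reported for the CACTA-like element *Jozin* in
*Chenopodium album* aggregate species and in the *C. quinoa* assembly.
They anchor the synthetic element families (:mod:`cactascan.simulate`)
and the regression tests.
"""

from __future__ import annotations

#: 28-bp CACTA-anchored TIRs, one per source genome (5' orientation).
TIRS: dict[str, str] = {
    "pamiricum": "CACTAGTAGAAAAAACGTCATTTGTAAC",
    "sosnowskyi": "CACTAGTGGAAAAAAGTTCATTTGCAAC",
    "iljinii": "CACTAGTAGAAAAATGTACATTTGCGTC",
    "vulvaria": "CACTAGTACAAAAACGTACATTTACTTC",
    "quinoa_scaffold3500": "CACTAGTAGAAAAATAGAAATAGGCAAC",
}

#: 12-bp subTIR unit motifs (5' direct orientation).
SUBTIR_MOTIFS: dict[str, str] = {
    "pamiricum": "TATTTGTAACTA",
    "sosnowskyi": "TATTTGTAACGG",
    "iljinii": "TATTTGCGTCAC",
    "vulvaria": "TATTTGCGTCAC",
}

#: Reported per-end subTIR unit copy counts (n 5', n 3').
SUBTIR_COUNTS: dict[str, tuple[int, int]] = {
    "pamiricum": (9, 10),
    "sosnowskyi": (11, 8),
    "iljinii": (10, 13),
    "vulvaria": (10, 11),
    # quinoa scaffold 3500: TIRs and subTIRs present, per-end counts not
    # published; nominal symmetric layout used for the synthetic family.
    "quinoa_scaffold3500": (10, 10),
}

#: Reported total element lengths, bp (TSDs excluded; flanking).
ELEMENT_LENGTHS: dict[str, int] = {
    "sosnowskyi": 8258,
    "pamiricum": 8380,
    "iljinii": 9210,
    "vulvaria": 10109,
    "quinoa_scaffold3500": 9486,
}

#: satDNA consensus monomer exactly as printed (169 nt as transcribed; the
#: published consensus is stated to be 171 bp -- see SAT_MONOMER_171).
SAT_MONOMER_PRINTED: str = (
    "GCCATTTTGGTTGAAATTGCGTCCCAAAACCTCTTACTTGCTCTTTTCTTGTAATC"
    "TCAAGCATTAGTCACCTATAACTAAGTGATAATGACATGTTTTAACTAGTTATGAGC"
    "AATAGACATGAATTGTAGAAAATAGGCATCCTAGTAGCCAAAATGGCCTTACTTGA"
)

#: Synthetic length-restored 171-nt monomer. The transcription of the
#: published monomer available to this package dropped two bases at a line
#: wrap (169 nt survive); the published consensus length is 171 bp. Two
#: placeholder bases ("CA") are restored at the wrap seam so that
#: length-driven arithmetic (copy number = array length / monomer length)
#: reproduces the published figures. Synthetic restoration: the two inserted
#: bases are not authoritative sequence.
SAT_MONOMER_171: str = (
    SAT_MONOMER_PRINTED[:56] + "CA" + SAT_MONOMER_PRINTED[56:]
)

#: Published satellite-array arithmetic inside the scaffold-3389 element:
#: array interval 10098..15648 (length 5550 bp), 32.5 monomers of 171 bp.
SAT_ARRAY_INTERVAL: tuple[int, int] = (10098, 15648)
SAT_ARRAY_LENGTH: int = 5550
SAT_ARRAY_COPY_NUMBER: float = 32.5
SAT_MONOMER_LENGTH: int = 171

#: DANTE-style protein-domain hit filter defaults.
DOMAIN_FILTER_DEFAULTS: dict[str, float] = {
    "min_identity": 0.35,
    "min_similarity": 0.45,
    "min_aln_len": 0.8,
    "max_interruptions": 0,
    "max_len_prop": 1.2,
}

#: Nucleotide length of a complete tnp2 (Transposase_21) domain, bp.
TNP2_FULL_LENGTH: int = 630

#: Canonical ORF1 domain order shared by all complete Jozin elements.
BASIC_DOMAINS: tuple[str, ...] = ("TAD", "Transposase_21", "DUF4218", "DUF4216")

#: The four published conserved-domain-architecture types.
CDA_DOMAIN_SETS: dict[str, tuple[str, ...]] = {
    "type1": BASIC_DOMAINS,
    "type2": BASIC_DOMAINS + ("Peptidase_C48",),
    "type3": BASIC_DOMAINS + ("Transposase_24",),
    "type4": BASIC_DOMAINS + ("Transposase_24", "Peptidase_C48"),
}

#: CDA type of each named element family.
FAMILY_CDA: dict[str, str] = {
    "sosnowskyi": "type1",
    "pamiricum": "type2",
    "iljinii": "type4",
    "vulvaria": "type4",
    "quinoa_scaffold3500": "type1",
}

#: Published Neprosin-superfamily fragment coordinates inside the
#: C. vulvaria element (element-local, 1-based start, end = start + length)
#: and the reported gap to the TAD domain start.
NEPROSIN_FRAGMENTS: tuple[tuple[str, int, int], ...] = (
    ("pfam14365", 2894, 3007),
    ("pfam03080", 3254, 3457),
)
NEPROSIN_DIST_TO_TAD: int = 754

#: Reported AP2 capture: an 80-bp Apetala 2 fragment 857 bp upstream of TAD
#: (C. acerifolium; 1331 and 1342 bp in C. album / C. opulifolium).
AP2_FRAGMENT_LENGTH: int = 80
AP2_DIST_TO_TAD: dict[str, int] = {
    "acerifolium": 857,
    "album": 1331,
    "opulifolium": 1342,
}
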