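"""Published oligonucleotide catalog for the DHFR minigene editing system.

The editing PPRHs target three polypurine regions of the pD22 DHFR
minigene (promoter, exon 3, exon 6) and carry homology tails spanning
the PstI insertion junction in intron 1 of the wildtype pDCH1P minigene.
Names follow the original nomenclature and are treated as opaque labels;
``UDPst1`` is the tail-only negative control (no hairpin core).
"""

from __future__ import annotations

TABLE1_OLIGOS: dict[str, tuple[str, str]] = {
    # name: (sequence 5'->3', target region of the PPRH core)
    "LDSHpPrI1UPstI": (
        "CTGCAGCCGGCGGGCCTACCTTTTTGGGGAAGGAAAAGTGGGTGACATTTTTACAGTGGGTGAAAAGGAAGGGG",
        "Promoter",
    ),
    "LDSHpPrI1UDstI": (
        "ACCGCGGGCATGGGCAAGGGCTGCAGCCGGCGGGCCTACCTTTTT"
        "GGGGAAGGAAAAGTGGGTGACATTTTTACAGTGGGTGAAAAGGAAGGGG",
        "Promoter",
    ),
    "LDSHpE6I1DPstI": (
        "CCCTTGCCCATGCCCGCGGTTTTTTAGGAGGAAAAAGGCATCAAGTTTTTGAACTACGGAAAAAGGAGGA",
        "Exon 6",
    ),
    "LDSHpE6I1UDPstI": (
        "GGTAGGCCCGCCGGCTGCAGCCCTTGCCCATGCCCGCGGTTTTTT"
        "AGGAGGAAAAAGGCATCAAGTTTTTGAACTACGGAAAAAGGAGGA",
        "Exon 6",
    ),
    "LDSHpE3I1UDPstI": (
        "GGTAGGCCCGCCGGCTGCAGCCCTTGCCCATGCCCGCGGTTTTT"
        "TGGACCAAGAGGTAAGGATTTTTAGGAATGGAGAACCAGG",
        "Exon 3",
    ),
    "UDPst1": ("GGTAGGCCCGCCGGCTGCAGCCCTTGCCCATGCCCGCGGT", "None"),
}

#: The five editing PPRHs (core + tail); excludes the tail-only control.
EDITING_PPRH_NAMES = [n for n in TABLE1_OLIGOS if n != "UDPst1"]

#: Polypurine arms (hairpin 5' arms) of the three PPRH cores.
ARMS: dict[str, str] = {
    "promoter": "GGGGAAGGAAAAGTGGGTGACA",
    "E3": "GGACCAAGAGGTAAGGA",
    "E6": "AGGAGGAAAAAGGCATCAAG",
}

#: Homology blocks flanking the PstI junction on the restored reference:
#: 20 nt immediately upstream and 20 nt downstream (beginning with CTGCAG).
U20 = "ACCGCGGGCATGGGCAAGGG"
D20 = "CTGCAGCCGGCGGGCCTACC"

PSTI_MOTIF = "CTGCAG"

#: Published PCR primer pairs (pair label -> (forward, reverse)).
PRIMER_PAIRS: dict[str, tuple[str, str]] = {
    "exon1_exon3_gdna": ("AAGAACGGAGACCTTCCCTGGCCA", "GAACCAGGTTTTCCGGCCCA"),
    "exon1_exon3_cdna": ("AAGAACGGAGACCTTCCCTGGCCA", "GAACCAGGTTTTCCGGCCCA"),
    "intron1": ("CCGAGGCGGTTCGCTGAATC", "CCTGTCACGTGTGCTCAGGC"),
    "intron1_intron2": ("CCGAGGCGGTTCGCTGAATC", "TCCCACGGGAGACTTCGCACT"),
}

EXON1_FWD_PRIMER = PRIMER_PAIRS["exon1_exon3_gdna"][0]
EXON3_REV_PRIMER = PRIMER_PAIRS["exon1_exon3_gdna"][1]
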