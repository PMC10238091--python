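"""Published input sequences used by the worked examples.

The two custom esiRNA target sequences cover the alternatively spliced
C-terminal exons of the SA paralogs (SA1 exon 31, SA2 exon 32). Translating
both at their unique common stop-free reading offset yields the basic exon
peptides whose isoelectric points the toolkit reconstructs.
"""

#: esiRNA target sequence covering SA1 (STAG1) exon 31.
ESIRNA_SA1_EXON31 = (
    "TCCTCAGATGCAGATCTCTTGGTTAGGCC"
    "AGCCGAAGTTAGAAGACTTAAATCGGAAG"
    "GACAGAACAGGAATGAACTACATGAAAGTG"
    "AGAACTGGAGTGAGGCATGCTGT"
)

#: esiRNA target sequence covering SA2 (STAG2) exon 32.
ESIRNA_SA2_EXON32 = (
    "CACGCAGGTAACATGGATGTTAGCTCAAAG"
    "ACAACAAGAGGAAGCAAGGCAACAGCAGG"
    "AGAGAGCAGCAATGAGCTATGTTAAACTG"
    "CGAACTAATCTTCAGCATGCCAT"
)
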