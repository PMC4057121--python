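gene,forward_seq,reverse_seq,amplicon_lo,amplicon_hi,genomic_bp
18S,CGAAAGCATTTGCCAAGAAT,GGCATCGTTTATGGTCGG,98,99,98
ABL,GCTGCTCGCTGGAACTCC,GTGATGTAATTGCTGGGGACC,218,218,940
GAPDH,GTGGTGCTAAGCGTGTTATCATC,GGCAGCACCTCTGCCATC,269,270,534
GUSB,GGCAAACTCCTTCCGCAC,TCATTGGCTACTGACCACATCA,222,224,858
HMBS,CTGAAGAGAATGGGCTGGGA,TCTTGGTCTTTGGCACGAAC,113,115,1791
HPRT,GATGAACAAGGTTACGACCTGGA,TATAGCCACCCTTGAGTACACAGAG,181,181,1575
PGK1,AAAGTTCAGGATAAGATCCAGCTG,GCCATCAGGTCCTTGACAAT,167,167,450
RPL13,CCACAAGGACTGGCAGCG,ACGATGGGCCGGATGG,135,135,434
RPL19,CCAACGAGACCAACGAGATC,CATGTGCCGGCCCTTCC,152,153,629
RPS7,TAGGTGGTGGCAGGAAAGC,TTGGCTTGGGCAGAATCC,156,156,1773
SDHA,TTGGTGGACAGAGTCTTCAGTT,GTGTTCTTTGCTCTAAAACGATG,238,238,1821
TFRC,GGAACTTGCCCGTGTGATC,GTAGCACCCACAGCTCCGT,111,113,723
VIM,GGAACAATGATGCCCTGC,GCAAAATTCTCCTCCATTTCAC,145,145,761
YWHAZ,GTGGAGCAATCACAACAGGC,GCGTGCGTCTTTGTATGACTC,222,224,326
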