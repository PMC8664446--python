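LOCUS       As12a_pGAL1              251 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  synthetic Golden Gate cloning region of As12a_pGAL1 (pre-digestion).
ACCESSION   As12a_pGAL1
VERSION     As12a_pGAL1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     misc_feature    1..119
                     /label="flank_left (polII_GAL1 side)"
     misc_feature    120..123
                     /label="left overhang AGAT"
     misc_feature    124
                     /label="BsaI spacer"
     protein_bind    complement(125..130)
                     /label="BsaI recognition site (bottom strand)"
     misc_feature    131..160
                     /label="stuffer (excised)"
     protein_bind    161..166
                     /label="BsaI recognition site (top strand)"
     misc_feature    167
                     /label="BsaI spacer"
     misc_feature    168..171
                     /label="right overhang (complement AAAA)"
     misc_feature    172..251
                     /label="flank_right (scaffold/3' elements side)"
ORIGIN
        1 catatacttt aacgtcaagg agaaaaaact atagcgcaag tggtttagtg gtaaaatcca
       61 acgttgccat cgttgggccc cggttcgatt ccgggcttgc gcataatttc tactcttgta
      121 gatagagacc atacgtctta agcatcgatc ttaagtacgt ggtctcattt tattttggcc
      181 ggcatggtcc cagcctcctc gctggcgccg gctgggcaac atgcttcggc atggcgaatg
      241 ggactttttt t
//
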