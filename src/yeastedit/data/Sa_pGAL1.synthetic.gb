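LOCUS       Sa_pGAL1                 232 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  synthetic Golden Gate cloning region of Sa_pGAL1 (pre-digestion).
ACCESSION   Sa_pGAL1
VERSION     Sa_pGAL1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     misc_feature    1..33
                     /label="flank_left (polII_GAL1 side)"
     misc_feature    34..37
                     /label="left overhang TACT"
     misc_feature    38
                     /label="BsaI spacer"
     protein_bind    complement(39..44)
                     /label="BsaI recognition site (bottom strand)"
     misc_feature    45..74
                     /label="stuffer (excised)"
     protein_bind    75..80
                     /label="BsaI recognition site (top strand)"
     misc_feature    81
                     /label="BsaI spacer"
     misc_feature    82..85
                     /label="right overhang (complement AAAC)"
     misc_feature    86..232
                     /label="flank_right (scaffold/3' elements side)"
ORIGIN
        1 catatacttt aacgtcaagg agaaaaaact atatactaga gaccatacgt cttaagcatc
       61 gatcttaagt acgtggtctc agttttagta ctctggaaac agaatctact aaaacaaggc
      121 aaaatgccgt gtttatctcg tcaacttgtt ggcgagaggc cggcatggtc ccagcctcct
      181 cgctggcgcc ggctgggcaa catgcttcgg catggcgaat gggacttttt tt
//
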