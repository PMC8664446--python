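LOCUS       Sp_pSNR52                159 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  synthetic Golden Gate cloning region of Sp_pSNR52 (pre-digestion).
ACCESSION   Sp_pSNR52
VERSION     Sp_pSNR52
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     misc_feature    1..28
                     /label="flank_left (polIII_SNR52 side)"
     misc_feature    29..32
                     /label="left overhang ATCA"
     misc_feature    33
                     /label="BsaI spacer"
     protein_bind    complement(34..39)
                     /label="BsaI recognition site (bottom strand)"
     misc_feature    40..69
                     /label="stuffer (excised)"
     protein_bind    70..75
                     /label="BsaI recognition site (top strand)"
     misc_feature    76
                     /label="BsaI spacer"
     misc_feature    77..80
                     /label="right overhang (complement AAAC)"
     misc_feature    81..159
                     /label="flank_right (scaffold/3' elements side)"
ORIGIN
        1 tttataatta tttgaaagat aaatgatcat caagagacca tacgtcttaa gcatcgatct
       61 taagtacgtg gtctcagttt tagagctaga aatagcaagt taaaataagg ctagtccgtt
      121 atcaacttga aaaagtggca ccgagtcggt gcttttttt
//
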