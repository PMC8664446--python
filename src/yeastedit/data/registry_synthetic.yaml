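# Synthetic vector registry for the four genome-editing backbone vectors.
#
# SYNTHETIC STAND-IN: the authors' deposited vector sequence files are not
# bundled; this registry reproduces the backbone ARCHITECTURE (which vector
# carries a hammerhead, spacer 5' vs 3' of the scaffold, Pol II vs Pol III
# promoter, BsaI overhang layout) with representative data.  Element
# sequences that are canonical public parts (minimal hammerhead catalytic
# core, Sp/Sa sgRNA scaffolds, the Cas12a direct repeat, the HDV ribozyme
# 5' region, tRNA-Gly, the U4AU4 9-mer) are the field-standard sequences;
# the 4-nt overhangs and promoter/terminator flanks are invented but honor
# every contract (4 nt, left != right, no BsaI site anywhere).  Users
# cloning on the real vectors should regenerate this file from their
# vendor's sequence files; the schema is what the loader documents.
#
# Overhang orientation: "left" coheres with the promoter-side vector end.
# Flanks are plus-strand vector sequence immediately outside the
# BsaI-generated overhang positions.  For the Cas9 vectors the right
# overhang's complement supplies the sgRNA scaffold's first 4 nt (scarless
# junction); for the Cas12a vector the left overhang supplies the direct
# repeat's last 4 nt and the right overhang's complement the U4AU4 first
# 4 nt.

registry_version: "1-synthetic"

# Minimal hammerhead catalytic core + stems II/III; stem I (the 6-nt
# antisense arm) is prepended per target at design time.
hammerhead_core: CTGATGAGTCCGTGAGGACGAAACGAGTAAGCTCGTC

vectors:
  sp-gal1:
    name: Sp_pGAL1
    system: SpCas9
    promoter_class: polII_GAL1
    left_overhang: CATT
    right_overhang: AAAC
    needs_hammerhead: true
    insert_position: spacer_5prime_of_scaffold
    scaffold_seq: GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
    flank_left: CATATACTTTAACGTCAAGGAGAAAAAACTATA
    flank_right: TAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCGGCCGGCATGGTCCCAGCCTCCTCGCTGGCGCCGGCTGGGCAACATGCTTCGGCATGGCGAATGGGACTTTTTTT
    scaffold_elements: [pGAL1, hammerhead_site, sgRNA_scaffold, HDV_ribozyme, tCYC1]

  sp-snr52:
    name: Sp_pSNR52
    system: SpCas9
    promoter_class: polIII_SNR52
    left_overhang: ATCA
    right_overhang: AAAC
    needs_hammerhead: true
    insert_position: spacer_5prime_of_scaffold
    scaffold_seq: GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
    flank_left: TTTATAATTATTTGAAAGATAAATGATC
    flank_right: TAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTTTTT
    scaffold_elements: [pSNR52, hammerhead_site, sgRNA_scaffold, tSUP4]

  sa-gal1:
    name: Sa_pGAL1
    system: SaCas9
    promoter_class: polII_GAL1
    left_overhang: TACT
    right_overhang: AAAC
    needs_hammerhead: true
    insert_position: spacer_5prime_of_scaffold
    scaffold_seq: GTTTTAGTACTCTGGAAACAGAATCTACTAAAACAAGGCAAAATGCCGTGTTTATCTCGTCAACTTGTTGGCGAGA
    flank_left: CATATACTTTAACGTCAAGGAGAAAAAACTATA
    flank_right: TAGTACTCTGGAAACAGAATCTACTAAAACAAGGCAAAATGCCGTGTTTATCTCGTCAACTTGTTGGCGAGAGGCCGGCATGGTCCCAGCCTCCTCGCTGGCGCCGGCTGGGCAACATGCTTCGGCATGGCGAATGGGACTTTTTTT
    scaffold_elements: [pGAL1, hammerhead_site, sgRNA_scaffold_sa, HDV_ribozyme, tCYC1]

  as12a:
    name: As12a_pGAL1
    system: AsCas12a
    promoter_class: polII_GAL1
    left_overhang: AGAT
    right_overhang: AAAA
    needs_hammerhead: false
    insert_position: spacer_3prime_of_scaffold
    scaffold_seq: TAATTTCTACTCTTGTAGAT
    flank_left: CATATACTTTAACGTCAAGGAGAAAAAACTATAGCGCAAGTGGTTTAGTGGTAAAATCCAACGTTGCCATCGTTGGGCCCCGGTTCGATTCCGGGCTTGCGCATAATTTCTACTCTTGT
    flank_right: ATTTTGGCCGGCATGGTCCCAGCCTCCTCGCTGGCGCCGGCTGGGCAACATGCTTCGGCATGGCGAATGGGACTTTTTTT
    scaffold_elements: [pGAL1, tRNA_Gly, crRNA_scaffold, U4AU4, HDV_ribozyme, tCYC1]
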