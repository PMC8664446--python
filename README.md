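# yeastedit

A toolkit for CRISPR genome editing in *Saccharomyces cerevisiae* with
three Cas systems — SpCas9 (PAM NGG, 3′ of the target), SaCas9 (NNGRRT,
3′) and enAsCas12a (TTTV, 5′) — built for two audiences: people asking
*"can any of these systems edit my locus, and how much of the genome is
reachable at all?"*, and people who have picked a target and need the
actual wet-lab artifacts (Golden Gate oligos, HDR donor fragments)
computed without hand errors.

## What it computes

**Editable-genome coverage.** A genomic nucleotide is *editable* by a
system if substituting it blocks re-cleavage of the repaired allele:
either it lies in the PAM-proximal seed window of some protospacer
(positions 1–11 from the PAM for the Cas9s, 1–17 for Cas12a) or it is a
non-degenerate base of the PAM itself (the GG of NGG, the G·T of NNGRRT,
the TTT of TTTV; degenerate symbols N/R/V tolerate substitutions within
their class and are excluded). Both strands are scanned; a nucleotide
covered from either strand counts once. For a set of systems *S* the
coverage is

&nbsp;&nbsp;&nbsp;&nbsp;f(S) = | ∪<sub>s∈S</sub> E<sub>s</sub> | / G

where E<sub>s</sub> is the union of editable-position sets over all PAM
occurrences of system *s* and G the genome length. All seven non-empty
subsets of the three systems are reported.

**Golden Gate ODN design.** For each of four backbone vectors
(SpCas9+pGAL1, SpCas9+pSNR52, SaCas9+pGAL1, enAsCas12a+pGAL1) the toolkit
computes the two synthetic oligos whose annealed duplex, with its 4-nt
5′ extensions, drops into the BsaI-digested backbone. The Cas9 cassettes
include a per-target hammerhead ribozyme whose stem-I arm is the reverse
complement of the spacer's first 6 nt, so self-cleavage leaves the spacer
as the exact transcript 5′ end; the Cas12a cassette is the bare spacer
(scaffold, U₄AU₄ and HDV ribozyme are vector-resident). Designs carrying
a BsaI site (GGTCTC/GAGACC) in the duplex are rejected, and spacers with
a T₄ stretch are flagged on the RNA-Pol-III (pSNR52) backbone.

**HDR donor design.** Insertion donors (arm + insert + arm, 45-bp arms by
default, with arm-tailed amplification primers), 100-bp ORF-deletion
donors fusing the 50-bp flanks, and point-mutation donors that are
*rejected outright* if the requested edit would leave the locus cleavable
by any of the guides used.

## Worked example

```bash
# a seeded 5-kb synthetic contig at yeast GC, with one planted SpCas9 site
yeastedit synth --contig-len 5000 --gc 0.38 --seed 11 \
    --plant sp:ACACTCACACACACACACAC:AGG:0:1000:+ --out demo.fa

yeastedit coverage --genome demo.fa --out demo_coverage.tsv
```

which logs (fractions vary with the contig; these are for seed 11):

```
[yeastedit 0.1.0] AsCas12a: 2911 / 5000 = 58.2200%
[yeastedit 0.1.0] SaCas9: 1803 / 5000 = 36.0600%
[yeastedit 0.1.0] SpCas9: 2871 / 5000 = 57.4200%
...
[yeastedit 0.1.0] AsCas12a+SaCas9+SpCas9: 4421 / 5000 = 88.4200%
```

i.e. on this contig each single system reaches 36–58% of the nucleotides
and the three together 88.4% — the quantitative argument for keeping all
three systems on one unified plasmid series. Then design the cloning
oligos for the planted target on the SpCas9/pGAL1 backbone:

```bash
yeastedit design-oligos --target-name demo1 --spacer ACACTCACACACACACACAC \
    --vector sp-gal1 --out order.json --emit-insert insert.fa
```

```
demo1_Sp_pGAL1_top	CATTGAGTGTCTGATGAGTCCGTGAGGACGAAACGAGTAAGCTCGTCACACTCACACACACACACAC	67 nt
demo1_Sp_pGAL1_bottom	AAACGTGTGTGTGTGTGTGAGTGTGACGAGCTTACTCGTTTCGTCCTCACGGACTCATCAGACACTC	67 nt
```

The top strand reads 4-nt overhang (CATT) + hammerhead arm (GAGTGT =
revcomp of the spacer's first 6 nt) + hammerhead core + spacer; the
bottom strand is the complementary oligo with the other overhang. The
predicted assembled insert (in `insert.fa`) contains no residual BsaI
site, and the predicted processed sgRNA starts exactly at the spacer's
first base.

Guide pre-flight checks and donors work the same way
(`yeastedit check-guide ...`, `yeastedit design-donor insertion|deletion|pointmut ...`);
see `--help` on any subcommand.

## Layout

- `src/yeastedit/seq_core.py` — IUPAC-aware primitives, FASTA I/O
- `src/yeastedit/pam_scan.py` — both-strand PAM scanning, editable
  coverage, BED/TSV output
- `src/yeastedit/guide_design.py` — guide extraction/validation, cut-site
  prediction, re-cleavage-resistance test
- `src/yeastedit/oligo_design.py` — Golden Gate ODN + hammerhead design,
  in-silico assembly; vector registry under `src/yeastedit/data/`
- `src/yeastedit/donor_design.py` — HDR donors for the three editing modes
- `src/yeastedit/synth.py`, `cli.py` — synthetic-genome generator and CLI

Design notes and model assumptions: `docs/methods.md`.
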