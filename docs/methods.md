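# Methods and design notes

## The editable-nucleotide model

The central quantity is a per-nucleotide, strand-collapsed editability
set. For one Cas system, every PAM occurrence on either strand (all
overlapping occurrences counted) contributes:

* the PAM-proximal **seed window** of the protospacer — positions 1–11
  from the PAM for SpCas9 and SaCas9, 1–17 for AsCas12a. These lengths
  come from the mismatch-sensitivity literature for the respective
  nucleases: a single mismatch inside this window is sufficient to
  abolish re-cleavage of the repaired allele, which is the operational
  requirement for an edit to be recoverable;
* the **non-degenerate PAM bases** — GG of NGG, the G and T of NNGRRT,
  TTT of TTTV. Degenerate symbols (N, R, V) are excluded because a
  substitution within the symbol's degeneracy class does not break PAM
  recognition, so such a position cannot be *guaranteed* editable.

Full-length occurrences therefore contribute exactly 13, 13 and 20
positions for SpCas9, SaCas9 and AsCas12a. Coverage for a set of systems
is the size of the union of their position sets divided by total sequence
length; all seven non-empty subsets of the three systems are reported.
This union formulation means overlapping sites and double-strand hits
never double-count.

Assumptions worth stating explicitly: the model is binary (no graded
cleavage-efficiency score — the window either contains a mismatch or it
does not); spacer length never enters coverage (only the window length
does); chromatin state, expression and off-target burden are out of
scope, as is guide ranking (external pickers handle target choice).

## Scanning and coordinates

All coordinates are 0-based, half-open, on the plus strand, with strand
carried separately (BED convention). Minus-strand sites are found as
matches of the reverse-complemented motif on the plus strand; IUPAC
patterns compile to regular expressions inside a lookahead so overlapping
occurrences are all reported. A subject `N` matches no pattern symbol —
an unknown base cannot be asserted to satisfy a motif — and is never
counted editable (R64-2-1 contains essentially no Ns, so this choice does
not move genome-scale fractions). Input is uppercased; soft-masking is
ignored. Sites whose protospacer is clipped at a contig edge are reported
as `truncated` and still contribute their in-bounds editable positions:
the candidate definition is per-PAM-occurrence and does not require a
full protospacer (the effect on a 12-Mb genome is far below the reported
precision). Denominator policy for the reference computation: the caller
supplies the nuclear-only genome (the CLI's `--exclude-seq` drops the
mitochondrion and the 2-micron plasmid by header token).

## The re-cleavage-resistance test

`is_recut_resistant` receives the post-edit sequence over the original
protospacer+PAM span, read in the guide's orientation, and declares the
edit resistant iff (a) the PAM no longer matches its pattern, (b) a
mismatch to the original protospacer falls inside the seed window, or
(c) the span's length changed (an indel shifted the register). A window
shorter than protospacer+PAM is a contract error rather than an indel
call, so accidental mis-slicing by a caller fails loudly. The register is
evaluated only at the original position: an edit that destroys the PAM
but creates a new overlapping PAM at a shifted register still counts as
resistant, since the original guide/PAM geometry is gone; modelling
re-acquisition by shifted sites is out of scope.

This test is deliberately the same rule set that defines coverage, and
the suite verifies the link exhaustively: substituting any editable-set
base flips resistance to true, substituting any PAM-distal protospacer
base never does, and a degenerate PAM base flips it exactly when the new
base leaves the symbol's degeneracy class.

## Cut-site prediction

Cut offsets are per-system data, measured from the PAM-proximal
protospacer end: (3, 3) for both Cas9s (blunt cut between protospacer
positions 3 and 4 from the PAM) and (18, 23) for AsCas12a (staggered,
PAM-distal). They are configurable, informational, and never used by
coverage math — the editable-nucleotide definition depends on the window,
not the cut.

## Golden Gate design

The four backbones share one architecture: two BsaI sites exposing two
distinct 4-nt overhangs, directional by construction. Cassette layout is
the only system-dependent part: for the Cas9 vectors the insert is
hammerhead + spacer placed between promoter and vector-resident sgRNA
scaffold (spacer 5′ of scaffold); for the Cas12a vector the insert is the
spacer alone placed after the vector-resident crRNA scaffold (spacer 3′
of scaffold), with the U₄AU₄ 9-mer and HDV ribozyme downstream. The
hammerhead's stem-I antisense arm is `revcomp(spacer[0:6])` — the
standard minimal stem-I design; the arm length is a registry field for
vectors that want longer stems. Oligos are reported 5′→3′ for both
strands, as synthesis vendors require.

Hard design rules: a BsaI recognition sequence (GGTCTC or its complement
GAGACC) anywhere in the duplex core rejects the design with the offending
offset (never a silent emission); the same check runs again on the
predicted assembled product, where flank/overhang junctions could in
principle recreate a site. A T₄ stretch in the spacer triggers a warning
on the Pol-III (pSNR52) backbone only — T-tracts are Pol-III terminator
signals, so the sgRNA may be truncated and editing efficiency drops; the
Pol-II (pGAL1) backbones are unaffected. A terminal-T guard for spacers
ending in T on the SUP4-terminated backbone was considered and not
implemented; the effect is undocumented and the warning machinery makes
it a one-line extension. The GAL1-promoter backbones are known to lose
the Cas cassette by intramolecular recombination between their two GAL1
promoters in a minority of transformants (visible as large colonies);
that is a wet-lab phenomenon with no computable component — pick small
colonies.

### The vector registry is data

Overhang strings, flanks, scaffold and hammerhead-core sequences live in
`data/registry_synthetic.yaml` plus per-vector annotated
GenBank files (`*.synthetic.gb`, pre-digestion cloning regions), not in
code. The shipped registry is a **synthetic stand-in**: canonical public
element sequences (minimal hammerhead core, Sp/Sa sgRNA scaffolds,
Cas12a direct repeat, HDV 5′ region, tRNA-Gly, U₄AU₄) are the
field-standard ones, while overhangs and promoter/terminator flanks are
representative invented data that honor every contract (4 nt, left ≠
right, BsaI-free, scarless scaffold junctions). Anyone cloning on real
vectors regenerates the YAML from their vendor's files; every design
rule, test and invariant is registry-independent.

## HDR donors

* **Insertion**: `up_arm + insert + down_arm`, arms copied verbatim from
  the genome around the junction. Default arm length 45 bp; the
  15/25/35/45 series supports arm-length titrations (insertion efficiency
  rises with arm length and is essentially zero at 15 bp). Primers are
  arm-tailed with a 20-nt default template-annealing segment — a typical
  priming length.
* **Deletion**: the two `arm_len` flanks fused (100-bp donor at the 50-bp
  default), orderable as a duplex of two full-length ODNs.
* **Point mutation**: donor centered on the edited bases with 45-bp arms
  (matching the insertion default; exact fragment lengths are a free
  parameter). The design *fails* — error, not warning — if any guide used
  could still cleave the edited allele, unless explicitly overridden.
  Silent-mutation auto-suggestion to create resistance is deliberately
  not implemented.

Simulated HDR (`apply_donor`) replaces the genomic span between the arms
with the payload after verifying both arms match the genome exactly; the
suite round-trips all three modes against independently constructed
expected alleles. Re-cut checks against edited contigs re-anchor the
guide footprint across the edit's length change and call the resistance
test on the extracted window; a footprint that no longer fits in the
contig counts as resistant (the site is gone). Donor construction is
strand-agnostic; minus-strand ORFs are handled by the caller supplying
the interval.

## Synthetic genomes

The generator draws bases i.i.d. with P(G)=P(C)=gc/2 and
P(A)=P(T)=(1−gc)/2 from a seeded PCG64 stream, then writes planted
protospacer+PAM footprints at exact positions/strands (rejecting
overlaps). Defaults are yeast-like: GC 0.38, 5-kb contigs. The `polyA`
background contains no PAM of any of the three systems on either strand
(every pattern needs a non-A base on the strand it matches), so it
isolates planted sites exactly — the plant-and-recover and phantom-site
tests rely on this.

What the generator does *not* emulate: the real genome's non-uniform
composition — dinucleotide bias, GC heterogeneity, repeats, telomeric
and subtelomeric structure. Coverage on i.i.d. 38%-GC sequence lands
close to, but not at, the real-genome values (≈57/33/59/88% vs
59.9/31.4/61.2/89.5% on R64-2-1): passing tests demonstrate the
correctness of the scanning and set arithmetic, not the exact published
percentages, which depend on the actual S288C sequence. The
reference-genome check itself (`tests/test_acceptance.py -k reference`)
runs on the real R64-2-1 nuclear genome and requires the one-time
`yeastedit fetch-genome` download (~4 MB archive; the genome is not
bundled).

## Numerical and interface choices

* Fractions are carried at full float precision, written to 6 decimals in
  TSV; comparison with published figures uses one decimal in percent.
* Spacer lengths default to 20/21/23 nt (Sp/Sa/As) per the source
  systems; they are configurable and, by construction, never affect
  coverage.
* Problem sizes in `scripts/acceptance.py`: the coverage computation uses
  a 16-contig, 12-Mb synthetic genome — the scale of the yeast nuclear
  genome — and the remaining metrics use desk-scale fixtures (5–20 kb,
  25 spacers per vector, six donor designs); the whole script completes
  in well under a minute on one CPU.
* Outputs are deterministic byte-for-byte given identical inputs and
  seeds; every stochastic CLI entry point takes `--seed`.

## Known limitations

No off-target enumeration or scoring, no on-target efficiency models, no
thermodynamic annealing/Tm calculations for the ODNs (they are
full-duplex synthetic pairs), no NHEJ modelling for donor-free cutting,
and no modelling of shifted-register PAM re-acquisition after editing.
The bundled vector registry is representative, not the authors-of-record
sequence set; swap in real vector files before ordering oligos for real
cloning.
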