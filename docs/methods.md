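# Methods

## The problem being modelled

A recent tandem gene duplication produces two copies so similar that a
shotgun assembler merges them into one consensus copy. The resulting
reference sequence is a chimera — the body of one paralog joined, inside the
3′ UTR, to the tail of the other — and everything between the two breakpoint
homologies (part of one 3′ UTR, the intergenic region, and essentially the
whole second gene) is absent from the reference. Downstream consequences are
predictable: cDNAs from the hidden paralog mismatch the reference gene
model, PCR genotyping assays amplify a wild-type band from the intact
paralog in every individual, and insertion mutants appear to segregate
1:3:0 (selfed heterozygote) or 0:1:0 (selfed homozygote mistyped as
heterozygous). `tandemscan` implements both the diagnostics that expose such
a locus and a generator of synthetic instances with exact ground truth.

## The synthetic scenario

A scenario is built from one ancestral **repeat unit**: promoter (1161 bp) +
5′ UTR (150 bp) + 24 coding exons (CDS 2490 bp including the stop codon;
exons of 104 bp except a 98-bp last exon) + 23 introns (126 bp, `GT…AG`) +
3′ UTR (200 bp) — 6899 bp in total. The true locus is
`flank + unit_a + unit_b + flank` with 12-kb single-copy flanks; the
upstream copy is geneA, the downstream geneB. The stop-codon→start-codon
distance (3′ UTR + promoter + 5′ UTR) is exactly 1511 bp.

These sizes follow from three fixed quantities the scenario is required to
honour simultaneously: a 2490/2478-bp CDS pair, a 1511-bp stop-to-start
intergenic span, and a collapsed segment of exactly 7000 bp whose downstream
breakpoint falls inside geneB's 3′ UTR. The unit length is then forced to
~6.9 kb (gene span ≈ 5.74 kb); the package treats these as its defaults and
they are configurable through `GeneStructure`.

Divergence is applied to the **a** copy relative to the ancestor (= geneB):

* 27 coding substitutions confined to 12 exons drawn from exons 2–23
  (terminal exons stay identical so shared outward primers exist; the exon
  carrying the coding indel is excluded). 22 substitutions are forced
  synonymous and 5 non-synonymous (never creating stops), so the protein
  diff is exactly 5 tokens.
* One in-frame 12-bp deletion in exon 16 of copy a, codon-aligned, giving a
  4-residue protein indel borne by a.
* 40 non-coding indels in the promoter and introns. Lengths are truncated-
  geometric on [1, 35] bp (p = 0.25, mean ≈ 4): real indel length spectra
  are heavily short-biased, and only the observed *range* 1–35 nt is treated
  as a constraint (one indel is pinned to each end of the range so the
  configured bounds are always exercised). UTRs are kept indel-free so the
  spliced cDNA lengths differ by exactly the coding indel.
* Intron substitutions at rate 0.03 per intron base.

Two placement rules make the ground truth *exactly* recoverable rather than
statistically so: every planted event keeps ≥ 14 bp from every other event
and from splice sites/feature edges, and indel boundaries carry "anti-slide"
guards (the first/last base of an inserted or deleted segment is forced to
differ from the base the gap could slide onto). Under the alignment scoring
below, the optimal global alignment then reproduces each planted event as
one mismatch column or one gap run at its planted position, which the
round-trip tests assert seed by seed.

A **BpiI marker** is planted in the CDS (on by default): three shared
in-frame GAAGAC sites plus one geneB-only site, disabled in copy a by a
planted *synonymous* substitution that counts among the 27. Digesting the
two CDSs (2490/2478 bp) yields top-strand cut coordinates 78/392/681/1867
versus 78/392/681 — five fragments against four — so clone typing by
fragment pattern has a deterministic answer. Generation retries (seeded,
deterministic) until no spurious GAAGAC/GTCTTC occurs in either CDS.

The **collapsed reference** removes `true_locus[s : s+7000)` where `s` is
geneA's 3′ UTR start; the removal ends 101 bp into geneB's 3′ UTR, so the
reference gene is geneA's body wearing the tail of geneB's 3′ UTR — the
chimera structure described above.

The **outgroup** is the ancestral unit with independent, heavier noise (2%
coding and 8% non-coding substitutions, a few private short indels kept
≥ 14 bp away from the planted a/b indel loci). It therefore carries the
segment deleted from a (polarising that indel as a deletion) and lacks the
segments private to a.

Offspring genotypes are multinomial draws (¼, ½, ¼ for a selfed
heterozygote); reads are error-free, uniform-start, random-strand, with
read count `round(depth·L/read_len)`. A single `SeedSequence` per scenario
is forked into labelled substreams (sequence, divergence, outgroup, T-DNA,
flanks), so adding draws to one stage cannot perturb another; identical
seeds give byte-identical scenario directories.

## Alignment and identity bookkeeping

Nucleotide alignments are global with affine gaps: match +2, mismatch −3,
gap open −8, gap extend −1 (a gap of length k costs 8 + (k−1)); protein
mode uses BLOSUM62 with −11/−1. Percent identity implements the
"ignore indels longer than one nucleotide" rule: columns inside gap runs
longer than `long_indel_cutoff` (default 1) are excluded from numerator and
denominator, while 1-bp gaps count as mismatches. The diff catalog treats
each maximal gap run as one indel (gap *runs*, not gap columns) and orients
substitutions a→b.

The three-taxon verdict calls the duplication younger than the speciation
when the a↔b identity exceeds both paralog↔outgroup identities by ≥ 0.5
percentage points (configurable; identities below 55% mark the outgroup
unalignable). Indel polarity is judged on the *lacking* paralog's alignment
to the outgroup: the number of extra outgroup bases across a ±10 bp window
around the junction is compared to half the indel length. The window, not
the single junction column, is used because optimal alignments can let a
short gap drift a few bases through mismatch-noisy flanks; a fraction-of-
aligned-bases statistic on the carrier side was rejected because aligners
absorb short inserted segments as mismatch columns, which would call every
short indel "present" in the outgroup.

## PCR model

A primer anneals where every base is IUPAC-compatible, with at most
`max_mismatches` mismatches (default 0) and none within the 3-bp 3′ anchor.
Tm is the Wallace rule 2(A+T) + 4(G+C) and is used only to filter design
candidates. Products are all convergent (+,−) site pairs — including pairs
of one primer with itself — with length ≤ 6000 bp by default; the value
reflects that amplifying a whole ~6–8-kb gene routinely fails while a
~1.6-kb intergenic product succeeds. The arrangement truth table is always
derived at run time by executing the predictor on canonical toy templates,
never stored.

## Digest model

Cut offsets are defined relative to the recognition 3′ end on the strand
carrying the site (BpiI/BbsI: GAAGAC 2/6; negative offsets place the cut
inside the site for ordinary palindromic cutters). Printed cut positions are
interpreted as 1-based top-strand cleavage coordinates counted from the
start codon; internally a cut coordinate k means cleavage between bases k−1
and k (0-based gap coordinate), with the 1↔0 conversion confined to I/O.
Only top-strand cuts define fragment lengths — a few-nucleotide overhang is
below gel resolution. Sites whose cut coordinate falls outside a linear
template are skipped with a warning.

## Collapse detection

Shared unique exact k-mers (default k = 50) establish that the two
sequences are related and collinear. When the flank homology is exact end to
end (the error-free scenario), the breakpoint interval is computed directly
from the longest common prefix p and suffix q: every reference breakpoint in
`[len(ref) − q, p]` is equivalent, so the placement width p + q − len(ref)
equals the length of the repeated flank (108 in the constructed repeat
case). Otherwise the largest anchor-offset jump brackets the event and the
flanks are extended inward by exact match. The canonical placement is the
leftmost — any single reported point is a convention, which is precisely why
the full interval is part of the report.

## Segregation statistics

χ² = Σ(O−E)²/E over classes with E > 0, df = (positive classes − 1), upper
tail of the χ² distribution, no continuity correction (the uncorrected
statistic reproduces the published table to three decimals). An observed
count in a zero-expectation class is categorical evidence against the model
("incompatible", P = 0) rather than an arithmetic infinity. Competing
explanations are parameter-free apparent ratios — normal 1:2:1, hidden
paralog with het (1:3:0) or hom (0:1:0) parent, embryo-lethal 1:2:1→1:2:0,
male-gametophytic 1:1:0 — ranked by exact multinomial log-likelihood with
equal priors (no information criterion is needed when every candidate has
zero free parameters); a top-two gap under 2 log-units is flagged as a
close call.

## Coverage scanning

Reads are placed full-length at all best-scoring locations: exact matches
via a positional index, otherwise (when an edit budget is set) seed-and-
extend — several spaced 20-mers nominate candidate windows that edlib
aligns, and all placements achieving the best edit distance ≤ budget are
kept, each contributing 1/k depth. The default budget in the pipeline is 20
edits per 100-bp read: full-read edit distance is this module's crude
stand-in for a gapped mapper, so the budget must cover most of the indel
length spectrum or every read spanning a paralog-specific indel is lost.
Windows are 100 bp; a duplication call is ≥ 3 consecutive windows at
≥ 1.75× the single-copy baseline (midway between the 1× and 2×
expectations), with single cold windows bridged. The baseline is a
*masked* median: after a first pass, called windows are excluded and the
median re-estimated — with a ~7-kb duplication inside a ~31-kb reference
the naive genome median is visibly inflated by the two-copy windows, and
the two-pass baseline removes that bias (this is the standard practice in
read-depth copy-number analysis).

What passing the depth-ratio tests shows — and what it does not: on
error-free reads from a genome whose only repeat is the planted
duplication, the two-copy region sits at 1.8–2.1× and the background at
1.0×. Real data add sequencing error, GC bias, and other repeats, all of
which widen both distributions; the module demonstrates the detection
principle, not a production CNV caller. Known depression of the signal
near paralog-specific variants remains: reads spanning an indel longer
than the edit budget cannot cross-map, so windows around the largest
planted indels dip and calls can fragment across them.

## Problem sizes used by the tests and acceptance script

The default scenario (≈ 38-kb locus, ≈ 31-kb collapsed reference, 6.9-kb
units) is analysed in full. The planted-divergence sweep uses 20 seeds; the
depth-ratio property uses one scenario and 100 read-sampling replicates at
30×; oracle-equivalence checks use 1000 random instances per primitive on
templates of 120–300 bp (brute-force oracles are quadratic, so small
instances keep them honest and fast). These sizes are the package's chosen
defaults for its own validation.

## Known limitations

* The assembler is for small error-free clone sets (≤ 12 fragments, exact
  overlaps); it is not a de novo assembler, and per-base conflict
  resolution between duplicate clones is out of scope.
* The read mapper reports best-scoring placements only and has no concept
  of base quality, pairing, or soft-clipping.
* `detect_collapsed_segment` handles one collapsed segment per comparison —
  the single-event case its anchor-jump logic targets.
* Segregation hypotheses assume selfing and full viability of scored
  classes; transmission-ratio distortion beyond the listed candidates is
  not modelled.
* The generator's divergence placement is deliberately "clean" (spaced,
  slide-proof events); real paralog pairs contain clustered and ambiguous
  variants for which exact catalog recovery is not a meaningful target.
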