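# Methods

## Coordinate model

Every panel reference stores one in-vitro-transcribed pri-miRNA:
`GGG` (the prefix T7 transcription adds) + 5′ genomic flank + pre-miRNA +
3′ genomic flank, with 0-based boundaries `pre_start` and `pre_end`
(inclusive). Panels built from genomic context use 30-nt upstream and
25-nt downstream extensions, so `pre_start = 33`.

Strand-local coordinates anchor all windows:

- 5p strand: offset 0 = `pre_start` (CL0, the annotated cleavage site);
  positive toward the loop, negative into the basal flank.
- 3p strand: offset 0 = `pre_end`; positive toward the loop, negative
  downstream into the 3′ flank.

The 3p anchor is a genuine design choice: the alternative (anchoring at
the 3p scissile phosphate) shifts every 3p window by the overhang. We
anchor at the annotated pre-miRNA 3′ end, which places the mGHG window
(3p −5..−3) in the lower stem and CNNC (3p −16..−21) in the single-
stranded 3′ flank — the geometry these motifs have in the human
literature. Because the annotated 3′ end carries a 2-nt overhang, 3p
offset −k pairs across the duplex with 5p offset −(k+2), not −k; the
mGHG bulge test is therefore derived from the pair table's register
rather than from a mirrored window (see below).

## Read processing

Fixed stage order, mirroring the standard small-RNA protocol the library
layout comes from: adapter trimming → pair joining → quality filter →
duplicate collapse → barcode trimming → mapping. Collapse runs *before*
barcode trimming so the randomized 4-nt terminal barcodes distinguish
independent ligation events that captured identical fragments; the
practical consequence is that molecule counts saturate when a single
fragment species approaches the barcode diversity (4⁸ ≈ 65k for product
reads), a <1% effect at the depths used here.

- Adapter trimming (defaults: the two library adapters, min overlap 3,
  max error rate 0.1): substitutions only, full occurrences anywhere
  (removing everything downstream) or adapter prefixes at the read end;
  best occurrence maximizes matches − mismatches, ties toward the longer
  trim.
- Joining (max mismatch fraction 0.05, min overlap 6): mate 2 is
  reverse-complemented, all overlap lengths scored, lowest mismatch
  fraction wins (ties: longest); disagreeing bases take the higher
  Phred. Failure is a value, not an error.
- Quality filter: ≥90% of bases at Phred ≥20, applied to the joined read.
- Barcode trimming: 4/4 nt for product reads, 4/6 nt for control reads
  (the control protocol ligates a 6-nt randomized end).
- Mapping: plain local alignment against every panel reference, plus
  strand only — the panel is a few hundred short references, so no index
  is needed. Scoring: match +2, mismatch −6, a length-k gap costs
  5 + 3k, minimum accepted score 20 + 8·ln(read length) (the shape of
  bowtie2's `--local` defaults). A read is kept only when its best score
  *strictly* exceeds its best score on every other reference; ties are
  multimapped and discarded. Exact full-length substring hits attain the
  maximal local score, so they short-circuit the aligner; everything
  else goes through Biopython's `PairwiseAligner`.

## Quantification

A product fragment is *selected* when either end falls in CL−5..CL5, but
position attribution uses the 5′ end only: the accuracy distribution is
defined on the 5p strand, and an 11-bin distribution is only consistent
with single-end attribution. Selected fragments whose 5′ end is outside
the window count toward the selection total but to no position.

Product normalization: raw counts / spike-in count × 1000. The spike-in
count is the number of distinct product molecules mapped to the panel's
single spike-in record. Control normalization: counts per million mapped
control reads. References are retained when their raw control count is
strictly greater than 20 (threshold exposed as a flag).

Scores use pseudocount 0.1 exactly as printed in the README formulas.
mCL ties (never observed in practice at realistic depth) break toward
CL0, then toward the smaller signed offset.

**Overhangs** are computed against the predicted duplex, not the
annotated pre-miRNA ends (which would presume the answer): the
fragment's 5′ end is projected across the stem via the nearest paired
position ≤5 nt loopward, and the overhang is the distance of the
observed 3′ end past the projected partner. Fragments with no paired
anchor within 5 nt are excluded from overhang fractions.

**K-L divergence** D(test‖ref) = Σ p·log₂(p/q) over the 11 bins, after
adding 10⁻³ to every bin and renormalizing. Smoothing constant,
direction (mutant as test) and log base are package choices; the
divergence is asymmetric by construction.

## Structure annotation

Structures are consumed (designed tables or RNAfold dot-bracket output),
never computed. Multi-loop hairpins are flagged and excluded from
junction analyses.

The junction rule: "mismatch" is read as *unpaired 5p position* (the
rule describes single-stranded regions); wobbles count as paired here
but count for midBMW, which is explicitly defined over mismatches *and*
wobbles. A `wobble_as_mismatch` variant was considered and rejected as
the default because it breaks the identity between a perfect N-bp stem
and a junction at −(N+1). The ≥3 run must start inside the search
window but may extend beyond it; when two qualifying runs exist, the
first from CL0 wins. Stem lengths count paired positions only, so the
ruler distances are in base pairs and bulges are skipped — the same
skipping the simulator's rulers use.

mGHG is scored on the 3p −5..−3 triplet (read 5′→3′ in transcript order)
against an externally supplied triplet→score TSV; the motif is called at
score >38. Windows containing a bulge are excluded: the implementation
detects register shifts from the pair table (two paired window positions
whose partners are not anti-diagonal, or an unpaired window position
facing a paired 5p position). Symmetric mismatches are not bulges and
remain scoreable; a window with no paired position carries no register
evidence and is treated as mismatched, not bulged. Without a matrix the
mGHG fields are undefined, never guessed.

## Synthetic data

The generator emulates the study's conditions: hairpins with a 16-bp
lower stem and 25-bp upper stem by default (the two ruler lengths and
the organism's typical geometry), 10-nt loop, single-stranded flanks of
14/11 nt (reproducing the 30/25-nt construct extensions at the default
lower stem), planted mismatches (unpaired, non-complementary,
non-wobble) and G:U wobbles at chosen offsets, a 2-nt 3′ overhang, a
fixed 61-nt spike-in species (an arbitrary labelled internal-control
sequence, not a natural pre-miRNA), 4-nt randomized barcodes, the two
library adapters, 150-nt mates and uniform per-base substitution errors.
Error and barcode draws use separate RNG streams derived from the
library seed, so libraries differing only in error rate share barcodes;
everything is byte-deterministic in the seed.

The cleavage model draws each fragment's 5′ cut from an 11-bin accuracy
kernel (default 0.60 at the mode, 0.15 at ±1, 0.05 at ±2 — a dominant
site with minor alternative cleavages) centred on the ruler-determined
site: 16 paired positions above the basal junction, or 25 paired
positions below the apical junction, or a mixture of the two. A 41-bp
stem satisfies both rulers simultaneously and yields one product;
44-bp and 38-bp stems yield two products 3 nt apart. The 3′ cut is the
projected partner of the 5′ cut plus the overhang.

Recovery panels draw lower stems from [14, 18] so the 16-bp basal ruler
keeps all planted cleavage inside CL−5..CL5; annotation-recovery tests
span the full natural ranges (lower 11–24, upper 22–29).

What the generator does **not** model — and therefore what passing
recovery tests do not demonstrate about real libraries: PCR duplicates
and ligation bias, indel sequencing errors, position- or quality-
dependent error profiles, partially folded or misfolded substrates
(truth tables are designed, not folded), degradation products, and the
circularized control-read junction layout (control reads are emitted as
linear molecules with the 4/6-nt barcode scheme).

## Problem sizes and numerical choices

The acceptance script and heavy tests use 30-reference panels at 2000
product reads per reference with 0.001 substitution error (plus a
10-reference error-free run for overhang recovery), 5000-fragment
libraries for the K-L checks and 224 designs for junction recovery —
sizes at which the recovered quantities are stable to well within the
tested tolerances. Accuracy-recovery is tested by chi-square goodness of
fit on the planted-support bins at α = 0.01; sequencing errors on a
fragment's terminal base shift its apparent cut by ~1 nt, so an
off-support spill below 1% of reads (expected ~0.2% at the 0.001 error
rate) is attributed to the observation process rather than to recovery
failure.

Floating-point: score identities hold to 1e-12; control-CPM conservation
holds to floating tolerance; KL ≥ 0 is exact up to rounding in the
smoothed bins.

## Known limitations

- The uniqueness rule (strictly best score across references) and the
  aligner scoring are reimplementation decisions; on real data they can
  differ from a bowtie2 `-k 5` pipeline at the margin, chiefly for reads
  from near-duplicate pri-miRNA family members.
- 3′-end ("3p-strand") positions qualify fragments for selection but are
  never attributed to positions; if the original analysis also counted
  3p-only fragments into N_P by a projected 5p position, efficiencies on
  heavily 5′-degraded libraries would differ.
- The control library's circularized-cDNA structure may place the 6-nt
  barcode differently from the literal 4/6 trim applied here.
- mGHG scoring requires the published matrix as an external input; the
  package ships none.
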