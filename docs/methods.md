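# Methods

## Scope and model of the biology

`spacerseq` models the measurable outputs of type II-A CRISPR adaptation:
(i) amplicon sequencing of CRISPR arrays that have gained one
repeat-spacer unit, (ii) the selection-based screen for full-site
integration products, and (iii) exonucleolytic trimming of prespacer
substrates to the canonical ~30 bp. It does not model the biochemistry
that produces these outputs (protein assembly, integration chemistry,
Golden Gate reaction efficiency); only their sequence-level geometry.

## Array and read models

**CRISPR array.** `leader + R + (S_i + R)*` with all repeat copies
identical and spacers pairwise distinct. The reference condition is a
single-repeat array (no pre-existing spacers); arrays with `n` original
spacers exist to express the recombination defect class. Coordinates are
0-based, half-open throughout.

**Amplicon read.** `[5-nt random tag][3–5 bp sample barcode][20-nt
constant anchor][locus]`. The real primer cocktail's sequences are not
modelled; a configurable constant anchor provides the deterministic
register the demultiplexer needs. Acquisition inserts the new spacer with
a duplicated repeat at the leader-proximal edge. PCR bias is modelled as
`k` duplicate reads per event sharing one tag, `k ~ Geometric(mean 3)` by
default; sequencing errors as i.i.d. per-base substitutions.

**Integration colony.** The plasmid is assembled per event class
(full-site at a repeat edge; ectopic in backbone; full-site with loss of
an adjacent original spacer; full-site with a terminal substitution or
inserted base at a prespacer end; full-site with degraded traces), with
the selection cassette replacing the central 24 bp of the prespacer and
orientation drawn uniformly — the simulator's default expresses
integration *without* orientation preference, so annotator orientation
calls can be scored against a known 50/50. Reads start at two
cassette-internal primer positions (20-nt anchors) and extend outward up
to 500 nt, with Sanger-like qualities (~50 declining to ~30; the
low-quality class draws around Phred 10).

The end-defect class uses terminal substitutions/insertions rather than
terminal deletions deliberately: deleting the outer base of an untrimmed
end is, at the sequence level, indistinguishable from legitimate 3′→5′
trimming, so no annotator could separate them; substitution/insertion
defects (the oligo-synthesis-error scenario) leave stray bases at the
repeat junction that the annotator detects.

## Prespacer substrates and trimming

A substrate is a duplex (top/bottom strands, reverse-complement identity
over the duplex region) with 3′ single-stranded overhangs. The selection
cassette is two abutted, inverted BbsI sites: BbsI (GAAGAC) cuts 2 nt
(top) / 6 nt (bottom) downstream leaving 4-nt overhangs, so each
outward-facing half occupies 4+2+6 = 12 bp and the inverted pair spans
exactly the central 24 bp, with both cleavage overhangs inside it.

Trimming treats processing as a Bernoulli event per molecule with
probability set by the longest 3′ overhang: 0 for blunt ends, rising
linearly to 0.6 at 3 nt and 1.0 by 6 nt, flat through 12 nt, then
declining linearly to 0.2 at 25 nt. This piecewise-linear shape encodes
the qualitative substrate preference (6–12-nt overhangs fully processed,
longer ones progressively worse, duplexes barely touched); the slopes are
free model knobs, not measured constants. Processed molecules draw a
product length from `round(Normal(30, 1))` truncated to the input span —
the canonical product is 30 bp with 30–31 bp the dominant observed sizes,
hence SD 1 bp; unprocessed molecules keep their input length.

## Analysis conventions

- **Demultiplexing** is exact-prefix matching against a prefix-free
  barcode table; no 1-mismatch rescue. Reads shorter than
  tag + barcode + repeat + 20 nt are rejected as `too_short`.
- **Spacer calling** scans for repeat copies allowing ≤2 mismatches per
  copy by default (amplicons carry sequencing errors; the tolerance is
  configurable, and truth-recovery tests run it at 0). A call requires a
  full second repeat copy in-read. Only the leader-proximal new spacer is
  called; deeper expansions are flagged `multi_acquisition`.
- **Mapping** is exact substring search of the spacer and its reverse
  complement against the forward genome; multi-hit spacers stay in length
  statistics but are excluded from PAM/strand summaries; `circular`
  enables origin-wrapping matches. PAM = 3 nt immediately 3′ of the
  protospacer on the match strand; valid iff positions 2–3 are GG.
- **PCR-bias normalization** is distinct-tag counting per
  (sample, spacer). Tag collisions (two events, same spacer, same 5-mer)
  are not rescued; the birthday-bound expectation
  `n − M(1 − (1−1/M)^n)`, `M = 4^5`, is available so tests can account
  for them exactly.
- **Length distributions** count each unique spacer sequence once
  (abundance weighting is available but off by default). Percentages are
  over unique sequences per sample and sum to 100.
- **Kinetics** fits are per-replicate ordinary least squares of fraction
  processed against time (default design: 5, 10, 20, 40, 60, 120 min,
  three replicates), summarised as slope mean ± SD.

## Integration annotation

Both colony reads are anchored to the cassette (≤2 anchor mismatches)
and transformed into the *cassette-forward frame*: the left context ends
at the cassette's 5′ junction, the right context starts at its 3′
junction. Because the cassette travels with the prespacer during cloning,
the prespacer arms always read as the gap-filled top strand in this
frame, while the direction the array reads in this frame gives the
spacer's orientation.

Arm lengths are matched base-by-base from the cassette junction outward.
Because a trimmed arm's match can chance-extend into the repeat (¼ per
base), arm length and repeat edge are refined jointly: candidate arm
lengths down to 6 nt below the greedy match are tried and the candidate
placing the repeat edge at the smallest junction offset wins. A repeat
edge is the terminal 8 nt of the repeat abutting the spacer; up to 4
stray junction bases are tolerated but any nonzero offset marks the
prespacer end as not intact. Reconstructed spacer length = left arm + 24
+ right arm.

Exclusion reasons are assigned in fixed priority —
`low_quality` (mean Phred < 20 on either read, or missing anchor) >
`non_repeat_edge` (no repeat edge within slack on some side) >
`nonconsecutive_flank` (flanking original-array elements not adjacent;
leader counts as index 0, the downstream flank as n+1) >
`end_mutation_indel` — so co-occurring defects yield exactly one primary
reason. `leader_proximal` means insertion at the leader-side edge of
repeat 1.

## Problem sizes and statistical checks

Simulation-based tests use 100–2,000 events (acquisition), 200–1,000
colonies (integration) and 10,000 molecules (trimming), with stochastic
recoveries asserted within 3 binomial standard errors. The length-weight
recovery check samples protospacers without the PAM constraint from a
100-kb genome: unique-sequence percentages estimate the event-length
weights only when duplicate protospacer draws are rare, and a small
PAM-constrained site pool would add collapse bias on top of sampling
error (a property of the estimator worth remembering when interpreting
real samples from small genomes, not a defect of the pipeline).

## What passing tests do and do not show

The generators produce structurally faithful but idealised data: i.i.d.
protospacer draws (no hot spots or phage population structure), i.i.d.
substitution errors (no quality-correlated or indel errors in amplicons),
no chimeric PCR products, no polyclonal colonies, and no chromatogram
artefacts beyond a mean-quality gate. Perfect truth recovery at zero
error rate validates the bookkeeping and geometry of the pipeline;
performance on real data depends additionally on error modes the
simulator deliberately omits. Perfect-match mapping is a definition, not
a limitation: spacers with sequencing errors are *supposed* to drop out,
and the suite asserts that the mapped fraction declines as the error rate
rises.

## Known limitations

- The annotator assumes the selection cassette replaced the designed
  24-bp central region exactly; aberrant Golden Gate junctions surface as
  `end_mutation_indel`, not as their own class.
- Terminal deletions at prespacer ends are unidentifiable in principle
  (see above) and are therefore absent from the simulator's defect class.
- Multi-acquisition arrays are flagged but only the leader-proximal new
  spacer is called.
- Barcode demultiplexing has no mismatch rescue; reads with a corrupted
  barcode are dropped, which slightly biases against samples with
  error-prone barcodes at high error rates.
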