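# spacerseq

Simulation and analysis of spacer acquisition in the *Streptococcus
pyogenes* type II-A CRISPR-Cas system.

When a type II-A system acquires immunity, the Cas1-Cas2 integrase —
assisted by Csn2 and Cas9 in a "supercomplex" — captures a fragment of
invader DNA (a *prespacer*), trims it to the physiological ~30 bp, and
integrates it at the leader-proximal edge of the CRISPR repeat, duplicating
the repeat. Two sequencing assays measure this process:

1. **Amplicon deep sequencing of expanded arrays.** The CRISPR locus is
   PCR-amplified with a primer carrying five random nucleotides (a UMI) and
   a 3–5 bp sample barcode. Reads with an extra repeat-spacer unit reveal
   newly acquired spacers, which are mapped by *perfect* matching to the
   phage genome on both strands; the 3 nt immediately 3′ of the protospacer
   give the PAM (NGG for SpyCas9). Read counts are normalized for PCR bias
   by counting distinct UMIs, and spacer-length distributions are reported
   as percentages of *unique* spacer sequences per sample.
2. **Full-site integration selection.** Prespacer substrates carry two
   abutted, inverted BbsI sites occupying their central 24 bp. After in
   vitro integration, Golden Gate cloning swaps that region for a
   chloramphenicol cassette — selecting colonies with both prespacer ends
   joined (full-site products). Each colony is Sanger-sequenced with two
   cassette-internal, outward-facing primers, and the event is annotated
   for integration site, orientation and spacer length. Colonies are
   excluded if traces are low quality/uninterpretable, the spacer is not at
   a repeat edge, it is flanked by nonconsecutive original spacers, or the
   prespacer ends carry mutations/indels.

`spacerseq` implements both computational pipelines plus a synthetic-data
generator — phage genome, barcoded amplicon reads with PCR duplication
bias, colony read pairs across five event classes, prespacer substrates
with 3′ overhangs, and a stochastic trimming simulator — each with a
machine-readable ground-truth table, so every stage can be exercised and
scored without any external download.

## Worked example

Run the full acquisition workflow (simulate → demultiplex → call → map →
stats) and the integration workflow (design substrate → simulate colonies
→ annotate) with fixed seeds:

```sh
$ spacerseq run-acquisition --seed 7 --out-dir acq
{
 "n_spacers": 460,
 "percent_unique": 100.0,
 "percent_pam_valid": 100.0,
 "percent_forward_strand": 48.04347826086956,
 "n_ambiguous": 0,
 "n_unmapped": 0
}
```

All 460 unique simulated spacers map uniquely to the phage genome, every
one is PAM-adjacent (the generator samples NGG-adjacent protospacers), and
strands are drawn evenly. Intermediates (`reads.fastq`, `spacer_calls.tsv`,
`per_spacer.tsv`, `mapping.tsv`, `summary.json`, `manifest.json`) land in
`acq/`.

```sh
$ spacerseq run-integration --seed 7 --out-dir integ
{
 "n_events": 200,
 "n_kept": 146,
 "spacer_length_histogram": {"61": 146},
 "percent_forward": 48.63013698630137,
 "percent_leader_proximal": 28.08219178082192,
 "exclusions": {
  "low_quality": 10,
  "non_repeat_edge": 20,
  "nonconsecutive_flank": 13,
  "end_mutation_indel": 11
 }
}
```

Of 200 simulated colonies, 146 are kept as clean full-site integrations —
all with the unprocessed 61-bp spacer (45-bp duplex + two 8-nt overhangs
after fill-in) — and the 54 simulated defect colonies are each excluded
for the correct reason. Orientation is near 50/50, as expected for
integration without orientation preference.

```sh
$ spacerseq simulate prespacers --seed 7 --out-dir pre
{
 "total_span": 61,
 "fraction_processed": 1.0,
 "modal_product_bp": 30
}
```

An 8-nt-overhang substrate is fully processed by the trimming simulator
and the modal product is the canonical 30 bp.

## Layout

- `src/spacerseq/simulate/` — synthetic-data generators with truth tables
- `src/spacerseq/calling.py` — demultiplexing + expanded-array spacer calls
- `src/spacerseq/mapping.py` — perfect-match protospacer/PAM mapping
- `src/spacerseq/stats.py` — UMI normalization, length distributions,
  kinetics (linear-regression processing rates)
- `src/spacerseq/annotate.py` — integration-event annotation + exclusions
- `src/spacerseq/pipeline.py`, `cli.py` — orchestration and the
  `spacerseq` command

See `docs/methods.md` for the models, parameter choices and limitations.
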