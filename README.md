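# milseek

Discovery of miRNA-like small RNAs (milRNAs) from fungal small-RNA
sequencing libraries, as a self-contained, tested pipeline:

1. **preprocess** — 3' adapter trimming, quality/length filtering, and
   collapsing of reads to unique sequences with per-library (MY/FB) counts.
2. **fold** — secondary-structure prediction of transcript contigs with a
   weighted maximum-pairing dynamic program (GC=3, AU=2, GU=1, min loop 3);
   an external thermodynamic folder can be plugged in behind the same
   contract.
3. **discover** — mismatch-tolerant (default < 4 mismatches) remapping of
   grouped sRNAs onto folded contigs, duplex calling on hairpin stems
   (two distinct reads on opposite arms, read counts of milR strictly larger
   than milR\*), library-of-origin classes M/F/B, and conserved-miRNA
   annotation against a mature reference.
4. **deg** — RPKM per unigene per library, binomial test of equal read
   proportions (exact below 30 reads, normal approximation above),
   Benjamini-Hochberg FDR, and class calls (FDR < 0.05 and fold change >= 2
   or <= 0.5; library-specific genes handled separately).
5. **targets** — plant-style expectation scoring of milRNA/unigene
   complementarity (mismatch 1, G:U 0.5, gap 2, doubled at positions 2-13;
   ceiling 4.0), cleavage vs translation inhibition from central positions
   9-11, and a DEG-direction cross filter.
6. **context** — exact placement of precursors on genome scaffolds and
   classification as intergenic / intron / exon-antisense, plus a k-mer
   genome-size estimator.

A first-class synthetic-data module (`milseek.simulate`) generates a toy
study — genome, gene models, contigs with planted hairpin precursors, two
sRNA libraries with adapters/noise, a count table and a truth TSV — so every
stage has a known answer.

## CLI

All stages share one configuration (`milseek.io.RunConfig`, YAML-serializable,
every threshold overridable):

```bash
milseek --seed 7 --out-dir out run-all --simulate       # full synthetic run
milseek --out-dir out simulate                          # just the study files
milseek --out-dir out preprocess --my srna_MY.fastq --fb srna_FB.fastq --adapter ...
milseek --out-dir out fold --contigs contigs.fa
milseek --out-dir out discover --grouped out/grouped.tsv --folded out/folded.tsv
milseek --out-dir out deg --counts unigene_counts.tsv
milseek --out-dir out targets --candidates out/candidates.tsv \
    --unigenes contigs.fa --expression out/expression.tsv
milseek --out-dir out context --precursors precursors.fa --genome genome.fa --genes genes.gff3
```

Stage outputs are header-lined TSVs; the run report (`report.tsv` /
`report.txt`) summarizes per-stage counts, candidate classes, length and
5'-nucleotide profiles, DEG classes and retained target hits.

## Layout

```
src/milseek/
  io.py          formats (FASTA/FASTQ/GFF3/TSV), RunConfig, reference loaders
  preprocess.py  trimming, filtering, read grouping, length/5' summaries
  fold.py        weighted maximum-pairing folding, stems, windowing
  discover.py    read mapping, duplex calling, conserved annotation
  expression.py  RPKM, binomial DEG test, BH adjustment, classes
  targets.py     expectation scoring, target scan, cross filter
  context.py     genome placement, context classes, k-mer genome size
  simulate.py    synthetic study generator and truth evaluation
  cli.py         orchestration, run report, click commands
tests/           pytest suite (unit, property and acceptance tests;
                 brute-force oracles live in tests/_oracles.py)
scripts/acceptance.py
```
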