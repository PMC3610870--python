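# nodtx

Analysis toolkit for strand-specific bacterial transcriptomes and
comparative proteomes:

- **TSS detection** from dRNA-seq read-start pile-ups: positions where at
  least 280 reads (configurable, optionally per-million normalized) start
  within a centered 7-nt window, the position is the window's start peak,
  and the start count is at least 50% larger than the upstream read-through
  coverage.
- **TSS classification** into gTSS (≤ 200 nt upstream of a gene, same
  strand), iTSS (inside a gene body), aTSS (antisense to a gene) and nTSS
  (intergenic), with a configurable exclusive priority order so the four
  classes always partition the TSS set.
- **Spaced-dyad promoter motif scanning** (e.g. the NtcA-type GTA-N8-TAC
  dyad, with alternate left boxes such as GTG), reporting start and center
  offsets relative to the TSS (center −41 convention).
- **Orthology clustering** of all-vs-all protein hits: HSP merging with
  recomputed identity/length, coverage and dual best-hit window filtering,
  a self-contained sparse Markov clustering (inflation 2.0 by default), and
  core/shared/unique categorization of clusters by genome membership.
- **Direct-repeat element analysis**: Hamming distance, genome-wide k-mer
  counting (forward or both strands, overlapping or not), and detection of
  near-identical direct repeats flanking excision elements.
- **Synthetic data generation** with planted truth (genes, TSS of all four
  classes, promoter motifs, repeat-flanked elements, multi-genome protein
  families) so the whole pipeline is testable end to end without any
  external data.

Standard formats throughout: FASTA, GFF3, SAM/BAM, BED6, BLAST tabular
(outfmt 6), TSV.

## CLI

All subcommands hang off a single `nodtx` entry point; every output table
begins with comment lines recording the version and the effective
parameters. A YAML file passed via `nodtx --config run.yaml …` supplies
per-subcommand defaults; explicit flags win.

```sh
# synthetic data with known truth
nodtx simulate genome --n-genes 50 --length 200000 --seed 1 --out sim/
nodtx simulate reads  --truth-dir sim/ --seed 1 --out sim/reads.bed
nodtx simulate hsps   --n-families 50 --dropout 0.2 --seed 7 --out sim/

# TSS pipeline
nodtx tss-detect   --reads sim/reads.bed --genome sim/genome.fasta \
                   --min-window-reads 280 --window 7 --enrichment 0.5 --out sim/tss
nodtx tss-classify --tss sim/tss.tsv --gff sim/genes.gff3 \
                   --upstream-max 200 --priority gTSS,aTSS,iTSS,nTSS --out sim/cls

# promoter motifs
nodtx motif-scan --tss sim/cls.tsv --genome sim/genome.fasta \
                 --motif GTA-N8-TAC --alt GTG --from -60 --to -20 --out sim/motifs.tsv

# orthology
nodtx ortho-cluster --hits sim/hits.tsv --proteins sim/proteins.tsv \
                    --inflation 2.0 --out sim/ortho
nodtx venn --clusters sim/ortho.clusters.tsv --proteins sim/proteins.tsv \
           --out sim/venn.tsv

# repeats
nodtx repeats    --genome sim/genome.fasta --element chr:40650-40900 \
                 --min-len 8 --max-mismatch 1 --out sim/reps.tsv
nodtx kmer-count --genome sim/genome.fasta --kmer CCGTGAAG --both-strands
```

## Layout

```
src/nodtx/
  io_formats.py   FASTA/GFF3/SAM/BED/TSV readers and writers; strand-specific
                  start/coverage profile construction
  tss.py          TSS detection and gTSS/iTSS/aTSS/nTSS classification
  motifs.py       spaced-dyad (IUPAC-aware) upstream motif scanning
  ortho.py        HSP merge, best-hit filtering, Markov clustering, venn counts
  repeats.py      hamming / k-mer counting / flanking direct-repeat search
  synth.py        seeded synthetic genomes, reads and protein-hit tables
  cli.py          click-based command line interface
tests/            pytest suite incl. independent brute-force oracles and
                  hypothesis property tests; test_acceptance.py holds the
                  acceptance criteria
scripts/acceptance.py   offline acceptance report
```
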