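# prosplice

A proteogenomic toolkit for studying alternative splicing (AS) at the protein
level in plants. It identifies isoform-specific peptides from search-engine
output, maps peptides onto genomic coordinates, classifies proteomically
supported AS events (SUPPA-style), discovers unannotated retained introns
from RNA-seq depth ratios, translates them into an expanded protein database,
and post-processes quantitative proteomics matrices relative to retained
introns.

## Modules

| Module | What it does |
| --- | --- |
| `prosplice.genome_model` | GFF3 + FASTA ingestion, transcript models, CDS translation, intron enumeration (plus-strand numbering; minus-strand genes get descending display indices) |
| `prosplice.as_events` | SUPPA-style AS event catalog (RI, SE, A5, A3, AF, AL, MX) with genomic anchor coordinates, ioe-like TSV and BED export |
| `prosplice.peptide_filter` | Engine-table ingestion, decoy removal, sequence-level merging, N-terminal Met-loss adjustment, and the isoform-specificity disjointness rule |
| `prosplice.peptide_map` | Protein-to-genome coordinate projection (`residue p -> CDS nt 3p-2..3p`), junction flags, BED12 export |
| `prosplice.event_caller` | Peptide evidence per event: coordinate overlap for RI/A5/A3/AF/AL, junction-spanning peptides for SE/MX |
| `prosplice.ir_discovery` | Intron depth ratio (IDratio), retained-intron candidate selection (threshold 0.15, annotated-RI redundancy filter), IR protein construction and outcome classification, custom database writer |
| `prosplice.quant` | Protein-group selection, downshifted-normal imputation (width 0.3, shift 1.8 in total-matrix SD units), differential flags (p < .05, abs(log2FC) > 1), increased-IR (IIR) calls (depth >= 0.15, fold >= 1.5), peptide-vs-intron positioning |
| `prosplice.fixtures` | Deterministic toy genome/annotation/peptide/coverage bundles with ground-truth manifests; in-silico trypsin/AspN digestion |
| `prosplice.cli` | `prosplice` command with subcommands tying the pipeline together |

Internal coordinates are 0-based half-open everywhere; GFF3/ioe/BED dialects
are converted at the I/O boundary.

### Event-id dialect

Event ids follow the SUPPA v2.3 ioe layout `GENE;TYPE:chrom:coords:strand`
with 1-based coordinates:

- `RI`: `s1:e1-s2:e2` (flanking exon boundaries around the intron)
- `SE`: `e1-s2:e2-s3` (junctions into and out of the skipped exon)
- `A5`/`A3`: `e-s` of the inclusion-form junction, then the exclusion-form junction
- `AF`/`AL`: distal-exon interval, proximal-exon interval, shared anchor
- `MX`: `e1-s2:e2-s4:e1-s3:e3-s4`

Retained-intron events are generated with "variable" semantics: flanking
exon boundaries may differ between transcript pairs and events are
deduplicated by intron interval.

## Quick start (synthetic fixture)

```sh
prosplice fixtures --out-dir fx --seed 1
prosplice events   --genome fx/genome.fa --gff3 fx/annotation.gff3 --out events.ioe
prosplice peptides --genome fx/genome.fa --gff3 fx/annotation.gff3 \
    --prospector fx/peptides_prospector.tsv --fragger fx/peptides_fragger.tsv \
    --out peptides.tsv
prosplice map      --genome fx/genome.fa --gff3 fx/annotation.gff3 \
    --peptides peptides.tsv --out maps.tsv --bed12 maps.bed
prosplice call     --genome fx/genome.fa --gff3 fx/annotation.gff3 \
    --peptides peptides.tsv --out supports.tsv --summary summary.tsv
prosplice idratio  --genome fx/genome.fa --gff3 fx/annotation.gff3 \
    --depths fx/coverage.tsv --out idratio.tsv
prosplice build-db --genome fx/genome.fa --gff3 fx/annotation.gff3 \
    --depths fx/coverage.tsv --base-fasta fx/proteins.fa --out custom.fa
```

The fixture bundle ships a `manifest.json` with the ground truth (expected
events, peptide categories, event support, IR outcomes, IIR calls); the test
suite asserts the whole pipeline reproduces it exactly.

## Input formats

- **Genome**: FASTA (uppercase A/C/G/T/N).
- **Annotation**: GFF3 with gene/mRNA/exon/CDS and `ID`/`Parent` links.
- **Peptide tables**: TSV per engine; Protein Prospector-style
  (`DB Peptide`, `Acc #`, `;`-separated accessions) and
  MSFragger/philosopher-style (`Peptide`, `Protein`, `,`-separated) column
  maps are built in, others are configurable via
  `prosplice.peptide_filter.ColumnMap`. Decoy convention defaults to the
  `DECOY_` accession prefix (suffix dialects accepted).
- **Read depth**: region-depth TSV (`chrom, start, end, sample, mean_depth`;
  0-based half-open) or a bedGraph adapter.
- **Quantification**: wide log2-abundance TSV (rows = protein groups or
  peptides, columns = samples) plus a sample-to-condition map.
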