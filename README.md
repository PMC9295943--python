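# cenrich

Tools for designing and validating **restriction-digestion based enrichment of
centromeric and pericentromeric satellite DNA**.

Human centromeres are built from megabase-scale tandem arrays of AT-rich
~171-bp α-satellite monomers, organized into higher-order repeat (HOR) units
and flanked by other satellite families (HSat1–5, notably HSATII). Because
these arrays are highly homogeneous, many frequent-cutter restriction enzymes
have recognition sites almost everywhere in the genome *except* inside the
arrays. Digesting genomic DNA with a well-chosen enzyme combination therefore
shreds the bulk genome into small pieces while leaving satellite arrays as
rare, very long fragments — and a simple size selection of high-molecular-
weight material yields a sample highly enriched in centromeric DNA, at a
fraction of the cost of whole-genome sequencing.

`cenrich` implements the computational side of this strategy:

- **In silico digestion** (`cenrich.restriction`): IUPAC-degenerate
  recognition sites, multi-enzyme plans, greedy left-most non-overlapping
  site resolution, and site-removal digestion semantics (each retained site
  is excised and the remaining runs are the predicted fragments). The six
  enzymes of the reference combinations ship with the package: ScrFI
  (`CCNGG`), NlaIV (`GGNNCC`), EcoO109I (`RGGNCCY`), BstUI (`CGCG`), MscI
  (`TGGCCA`) and AseI (`ATTAAT`).
- **Enrichment prediction and panel screening** (`cenrich.enrichment`): given
  a genome FASTA and a BED of target regions, predict per-size-bin target
  fragment and base-pair percentages and the fold enrichment over the
  genome-wide baseline; screen all combinations of an enzyme panel for
  high-enrichment candidates.
- **Sequencing-based validation** (`cenrich.seqval`): classify reads as
  satellite-derived by canonical 18-mer content (≥ 2 hits per read), build
  binned log2 enrichment profiles against a whole-genome control, call
  enrichment domains (> 5-fold runs of 2-kb bins), quantify residual uncut
  restriction sites in reads, read-count length proxies, and coverage
  threshold tables.
- **Methylation comparison** (`cenrich.methylation`): per-CpG methylation
  frequency (percent of valid calls that are methylated), strict-threshold
  change classification between conditions (WT frequency > 40 %, coverage
  > 10 in both samples, |Δ| > 10 points), per-family aggregation, and
  detection of locally hypomethylated dip regions.
- **Synthetic data** (`cenrich.synthetic`): toy genomes with site-free
  tandem-repeat arrays and ground-truth records, size-selected read pools,
  and paired WT/KO methylation tables with known family-specific effects.

## The central quantity

For a size bin *b* after digestion, with `bp_target(b)` the target-derived
base-pairs and `bp_total(b)` all base-pairs in the bin,

```
pct_bp_target(b) = 100 · bp_target(b) / bp_total(b)
fold_bp(b)       = pct_bp_target(b) / baseline_pct
```

where `baseline_pct` is the undigested genome's target base-pair percentage
(≈ 2.8 % for human centromeric regions). `fold_bp` is the enrichment a size
selection of bin *b* would achieve; a selection pooling all bins above a
cutoff is scored the same way on pooled counts.

## Worked example

Build a synthetic genome (one site-free 34.2-kb satellite array in a 342-kb
chromosome, target fraction 0.10; background carries ScrFI/NlaIV/EcoO109I
sites every ~500 bp) and predict enrichment for the three-enzyme combination:

```bash
cenrich simulate genome --seed 3 --out-prefix toy
# target fraction 0.1000 -> toy.fasta/.bed/.truth.json

cenrich predict --genome toy.fasta --regions toy.bed \
    --combo ScrFI,NlaIV,EcoO109I --bins 5000..55000:5000 --out table.tsv
# baseline 10.000% target bp; table -> table.tsv
```

The table shows 619 background fragments all below 5 kb and the intact array
as the single high-molecular-weight fragment:

```
          bin  n_frag_target  n_frag_total  bp_target  bp_total  pct_frag_target  pct_bp_target  fold_bp
     [0,5000)              0           619          0    304081              0.0            0.0      0.0
[30000,35000)              1             1      34200     34200            100.0          100.0     10.0
```

Every fragment above 5 kb is target-derived (`pct_frag_target = 100`), and
the fold enrichment of the selected material is exactly `1/f = 10` — the
theoretical maximum for a genome with target fraction `f = 0.10`.

Screening all 41 combinations of the shipped panel ranks enzymes by how
completely they shred the background below the size cutoff:

```bash
cenrich screen --genome toy.fasta --regions toy.bed --max-size 3 \
    --objective agg_fold@5000 --bins 5000..5000:5000 --out screen.tsv
# best: BstUI (score 10.000); 41 combos -> screen.tsv
```

Frequent cutters reach the 10-fold ceiling on this toy; the rare-cutting
MscI/AseI pair scores 2.8 because much of the background survives above the
cutoff.

## Scope

The package operates downstream of standard tooling: it does not align
reads, call methylation from raw signal, or model the wet-lab fractionation
physics. Count tables, read sets and methylation call tables produced by
external pipelines are consumed as plain text (FASTA/FASTQ, BED, bedGraph,
TSV).
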