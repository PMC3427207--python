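# crossreg

Cross-cohort detection of transcription factors whose expression changes
drive target-gene expression differences between two groups (e.g. species
or diets), replicated across two independent expression cohorts.

The pipeline combines:

- **Preprocessing** — log2 + quantile normalization, detection filtering
  (reliably detected OR group-specifically detected genes), batch-mean
  removal, and cross-cohort combination by two-stage z-scoring.
- **Differential expression** — per-gene t/ANOVA contrasts with a
  permutation-calibrated FDR: the p cutoff is chosen so the median
  significant-gene count under group-label shuffling is the target
  fraction of the observed count. Effect sizes use the pooled-SD
  standardized mean difference d, with |d| > 0.8 as the modest-effect gate.
- **TF regulatory-effect statistics** — for each TF regulon, a two-sided
  rank-sum comparison of Pearson correlations between the TF and its
  effect-size-gated targets versus other TFs' targets; global
  significance by permuting TF–target relationships; cross-cohort
  consistency via the Spearman correlation of per-target correlation
  vectors (CoC) with its own permutation null.
- **Motif analysis** — a MATCH-style PWM scanner (information-weighted,
  min–max normalized so the consensus scores 1, with a core sub-score),
  conservation filtering (≥80 % covered bases, mean ≥0.6), and three
  binding-site authenticity nulls: TSS-proximity (one-sided KS vs
  uniform), dinucleotide-preserving Eulerian shuffles with per-base-type
  conservation permutation, and a G/C-matched DNase-overlap placement null.
- **Tissue specificity** — per-gene focal-tissue z-scores per species,
  exact background-median alignment, one-sided rank-sum comparison.
- **Enrichment** — per-category one-sided Fisher tests with
  resampling-based FDR and a global significance statistic.
- **Synthetic data** — seeded generators for two-cohort regulatory
  scenarios (planted driver TFs, coupled targets, batch structure),
  promoters with planted conserved PWM sites, open-chromatin tracks, and
  paired tissue atlases, all with ground-truth labels for
  parameter-recovery testing.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(planted-truth recovery rates, null calibration, exact-shuffle and
enumeration-oracle checks), one test per criterion. Unit and property
tests (including hypothesis-based invariants) live alongside per module.

## CLI

```sh
crossreg simulate --seed 1 --out sim/                # synthetic scenario
crossreg preprocess --expr e.tsv --meta m.tsv --mode counts --out norm.tsv
crossreg de --expr norm.tsv --meta norm.meta.tsv --contrast g1,g2 \
            --fdr 0.10 --nperm 1000 --seed 1 --out de.tsv
crossreg tf-scan --expr norm.tsv --meta norm.meta.tsv --regulons r.tsv \
                 --contrast g1,g2 --out scan.tsv
crossreg coc --expr-a a.tsv --meta-a a.meta.tsv --expr-b b.tsv \
             --meta-b b.meta.tsv --regulons r.tsv --contrast g1,g2 --out coc.tsv
crossreg motif scan|null|dnase|tss ...               # binding-site analyses
crossreg specificity --atlas-a ha.tsv --atlas-b ma.tsv --focal liver \
                     --foreground fg.txt --background bg.txt --out spec.json
crossreg enrich --test-set ts.txt --background bg.txt --annotation go.tsv \
                --out enrich.tsv
crossreg run-all --config run.yaml                   # end-to-end with manifest
crossreg validate --expr e.tsv --meta m.tsv ...      # input consistency report
```

File formats: expression/metadata/regulon/annotation/atlas tables are TSV
with headers; promoters are FASTA with `gene|tss_offset` headers plus a
per-base conservation TSV (`gene  pos  score`); open-chromatin intervals
are BED3 (gene id in the chrom column); PWMs use the TRANSFAC matrix
dialect with a `CC core=a..b` line.

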