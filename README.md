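# aberex

Detection of aberrant 5′/3′ splice-site usage from splice-junction evidence,
and differential canonical/aberrant transcript analysis, for SF3B1-mutated
uveal melanoma (UM) cohorts.

Missense mutations in the spliceosome factor *SF3B1* (most often at R625 in
UM) shift branch-point recognition so that the mutant spliceosome uses
cryptic 3′ splice sites, typically 10–30 nt from the canonical acceptor.
The resulting aberrant transcripts — exon extensions and shortenings at
either splice site — are a transcriptomic hallmark of *SF3B1*-mutant tumors,
and their differential usage can stratify patients with early (< 60 months
progression-free survival, PFS) versus late (≥ 60 months) metastatic onset.

`aberex` is a reusable, tested implementation of that analysis for
bioinformaticians working with bulk RNA-seq of spliceosome-mutant cohorts.
Because the original patient cohorts are access-controlled, the package
ships a first-class synthetic-data generator that emulates every input with
known ground truth, so the full pipeline is testable end to end on a laptop.

## Method overview

1. **Junction evidence** — per-sample splice junctions (STAR `SJ.out.tab`
   format) are merged across the cohort, keeping unannotated junctions with
   ≥ 3 uniquely-mapped reads in ≥ 2 samples whose ends do not all coincide
   with canonical exon boundaries.
2. **Novel exonic regions** — each non-canonical junction end is assigned to
   the nearest canonical exon (same strand, matching splice side, within
   500 nt) and converted into an extension or shortening region spanning the
   bases between the observed splice site and the canonical boundary; the
   region inherits the exon's gene annotations and is written next to the
   canonical features as a custom GFF3.
3. **Flattening and counting** — canonical plus novel exons are split into
   non-overlapping exonic portions (counting bins, novelty-labelled);
   primary alignments are counted per bin.
4. **Differential exon usage (DEU)** — per bin, the two-row profile (bin
   count vs. the sum of its sibling bins) is modelled with a
   negative-binomial GLM containing a bin×condition interaction; the
   interaction estimate / ln 2 is the usage log2 fold change. Significant:
   BH-adjusted p ≤ 0.05 and |log2FC| ≥ 0.5.
5. **Differential gene expression (DGE)** — per-gene NB Wald test with
   median-of-ratios size factors, a mean–dispersion trend
   α(μ) = a₀ + a₁/μ, batch covariates and shrunk fold changes. Candidates:
   |log2FC| ≥ 0.5, q ≤ 0.05, mean count ≥ 10.
6. **Enrichment** — preranked permutation GSEA on the DGE Wald statistics.
7. **Clinical statistics** — PFS derivation with explicit censoring rules,
   the 60-month early/late stratification, Kaplan–Meier estimation with
   Greenwood/log-log intervals, exact r×c Fisher and Student t cohort
   comparisons, Wilcoxon rank-sum validation tests, qPCR ΔCt/ΔΔCt and the
   immunohistochemistry IRS score.

## Worked example

Run the whole synthetic-cohort pipeline with one command:

```sh
aberex run --seed 4 --out-dir demo/
```

This simulates an annotation, per-sample junction files, count matrices and
a clinical table; derives novel regions; flattens; and runs DEU, DGE, GSEA
and the clinical statistics.  The manifest (`demo/manifest.json`) from that
seed reports:

```
junctions:  12 merged novel junctions -> 12 novel exonic regions (12 planted)
counting:   261 exonic portions, 12 carrying a planted usage shift
deu:        261 portions tested, 13 significant
dge:        2000 genes tested, 29 candidates
clinical:   146 patients; 50 early / 85 late; KM median PFS 132.0 months;
            LTD t-test p = 7.3e-08
```

Every planted novel acceptor region was recovered as a significant DEU bin;
the extra flagged bin is a sibling bin whose usage genuinely shifts when the
aberrant isoform rises.  The Kaplan–Meier median PFS and the largest-tumor-
diameter (LTD) contrast mirror the bimodal early/late structure the
generator plants (early-onset tumors are larger, 17.7 vs 14.7 mm on
average).

The same stages are available individually (`aberex simulate`, `junctions`,
`count`, `deu`, `dge`, `gsea`, `clinical`) and as library functions; see the
module docstrings under `src/aberex/`.

## Layout

```
src/aberex/
  annotation.py    # interval model, GFF3/GTF I/O, exon flattening
  junctions.py     # SJ.out.tab ingestion, filtering, novel-region derivation
  counting.py      # primary-alignment counting over bins and genes
  differential.py  # size factors, dispersions, NB Wald DGE, DEU, PCA, BH
  enrichment.py    # preranked permutation GSEA
  clinical.py      # PFS, KM, exact Fisher, t/Wilcoxon, qPCR, IRS
  simulate.py      # synthetic-data generator with ground-truth tables
  pipeline.py      # end-to-end orchestration + manifest
  cli.py           # `aberex` command-line interface
docs/methods.md    # modelling assumptions, defaults, limitations
```
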