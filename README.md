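# damtarget

An integrative analysis pipeline for calling the direct targets of a
transcription factor from **DamID-seq binding** and **depletion RNA-seq**,
modeled on the regulatory-genomics workflow used to establish master
cell-identity regulators (the motivating case: the homeodomain factor
Prospero maintaining enteroendocrine-cell identity in the *Drosophila*
midgut).

The package is aimed at computational biologists who have (or simulate)
three kinds of evidence and want a transparent, fully testable path from
counts to a direct-target table:

1. **Cell-type signatures** — from bulk RNA-seq of a small cell-type
   panel, each gene is scored per focal type by
   `score = log10(RPKM)/5 + FC`, with
   `FC = RPKM_focal / mean(RPKM over all types)`, after removing genes
   with focal RPKM < 3.5; the top 250 scores form the type's signature.
2. **Depletion differential expression** — a deliberately simple
   negative-binomial engine (median-of-ratios size factors,
   method-of-moments dispersion with local moderation, delta-method
   Wald test, Benjamini–Hochberg FDR), calling genes at
   padj < 0.01 and |log2FC| > 0.5.
3. **Permutation GSEA** — weighted Kolmogorov–Smirnov running-sum
   enrichment score, normalized against label- or set-permutation
   nulls (NES), to ask whether a signature moves coherently under
   depletion.
4. **DamID at GATC-fragment resolution** — the genome is cut at every
   GATC (DpnII) site; fusion-vs-Dam-only enrichment is tested per
   fragment with the same NB engine; fragments with log2FC > 1 and
   padj < 0.01 merge into peaks, which are assigned to genes
   (gene body + 2 kb upstream of the TSS, strand-aware).
5. **Integration** — a gene is a *direct target* when it is bound and
   differentially expressed; down-regulated targets are candidate
   activated genes.
6. **Consensus-motif scanning** — degenerate motifs such as
   `T-A/T-A-G-A/C/G-C-G/A/T` (IUPAC `TWAGVCD`) are scanned over
   enhancer windows on both strands with a mismatch budget, reported in
   signed TSS-relative coordinates (+1 = TSS base, no zero).

A seeded synthetic-data module generates all inputs with planted ground
truth (markers, regulated genes, bound fragments, motif positions), so
every stage's recovery and calibration is measurable end to end.

## Worked example

Run the whole pipeline on simulated inputs:

```sh
damtarget run --seed 1 --out demo_run
```

which prints (seed 1, default study conditions: 5,000 genes, 3 cell
types × 3 replicates, 200 markers/type at 8-fold; 3 control vs 3
knockdown with 80% of focal markers down 4-fold; ~1 Mb genome,
100 fragments bound 8-fold in 2 fusion vs 3 Dam-only replicates):

```json
{
  "gsea_nes": -3.591180982336633,
  "gsea_pvalue": 0.001310615989515072,
  "n_bound_genes": 9,
  "n_de_down": 164,
  "n_de_up": 101,
  "n_down_targets": 6,
  "n_motif_hits": 100,
  "n_peak_genes": 9,
  "n_peaks": 32,
  "n_significant_fragments": 100,
  "n_targets": 9,
  "n_up_targets": 3,
  "seed": 1,
  "signature_overlap": 6,
  "signature_overlap_down_fraction": 1.0
}
```

Reading the numbers: depleting the factor knocks down 164 genes and the
focal-type signature collapses coherently (NES −3.59, permutation
p ≈ 0.0013 — negative because the signature sits at the repressed end of
the ranking). All 100 planted bound fragments are recovered and merge
into 32 peaks over 9 genes; intersecting binding with expression calls 9
direct targets (6 down = candidate activated genes, 3 up = candidate
repressed). Six targets are signature genes, and every one of them is
down-regulated. The run directory contains per-stage TSV tables
(signatures, DE results, fragment statistics, peaks, targets, motif
hits), the simulated inputs (counts, FASTA, GFF3), the planted truth and
a manifest per stage.

Individual stages are available both as library functions
(`damtarget.countmodel.nb_wald_test`, `damtarget.damid.call_binding`,
`damtarget.motif.scan`, ...) and as subcommands
(`simulate`, `signature`, `de`, `gsea`, `damid map|count|call|annotate`,
`integrate`, `motif`).

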