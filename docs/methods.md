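# Methods

This note documents the statistical models, parameter choices and
numerical conventions behind `damtarget`, and what the synthetic-data
tests do and do not establish about real data.

## Count model

Counts `K_ij` (feature *i*, sample *j*) are modeled as negative binomial
with mean `s_j * q_i(g_j)` and variance `mu + alpha_i * mu^2`:
`s_j` is a per-sample size factor, `q_i(g)` the normalized abundance in
group `g`, `alpha_i` a per-feature dispersion. The engine is a
transparent simplification of the DESeq2-style workflow — no GLM
iteration, no outlier replacement, no independent filtering, no
fold-change shrinkage — so that every number it produces has a
closed-form derivation that simulations with planted truth can check.

- **Size factors** are the median-of-ratios convention: for sample *j*,
  the median over features with nonzero counts everywhere of
  `K_ij / geometric_mean_i(K)`. They are scale-equivariant; because the
  geometric-mean reference itself moves by `c^(1/m)` when one of *m*
  samples is scaled by *c*, only factor *ratios* are meaningful.
- **Dispersion** is a pooled within-group method-of-moments estimate on
  normalized counts, `alpha_hat = max(0, (s2 - c*mu)/mu^2)` with
  `c = mean(1/s_j)` correcting the Poisson term, then moderated 50/50
  toward the 10%-trimmed mean of the ~200 features nearest in mean
  expression. A rolling *median* was considered instead: with three
  replicates per group the raw estimates are strongly right-skewed and
  the median of the local window sits well below the typical
  dispersion, which underestimates standard errors and inflates the
  null p < 0.05 fraction to ~0.077; the trimmed mean brings it to
  ~0.067 in the same null simulations while remaining robust to the
  handful of genuinely high-dispersion features in a window.
- **Wald test**: log2 fold change of normalized group means with a
  pseudocount of 0.5 (`log2((m_t+0.5)/(m_c+0.5))`), standard error by
  the delta method under the NB variance of each group mean, statistic
  referred to a standard normal, two-sided. The pseudocount bounds
  estimates when one group is all zero; features with zero counts in
  *both* groups get NaN p-values and do not enter the BH `m`.
- **BH adjustment** is the classic step-up rule, NaN-passing,
  permutation-invariant, capped at 1 (cross-checked against
  statsmodels in the test suite).
- **Calling thresholds** are strict inequalities: padj < 0.01 and
  |log2FC| > 0.5 for expression, log2FC > 1 and padj < 0.01
  (enrichment direction only) for DamID fragments. A boundary value is
  excluded.

A concordance test against pyDESeq2 (the GLM-based reference) on a
planted 300-gene experiment shows fold-change correlation > 0.999 and
absolute differences below 0.05 log2 units on well-expressed genes; the
engines differ by design in their shrinkage behavior at low counts.

## Signature scoring

Per focal cell type: drop genes whose focal RPKM is below 3.5, then
`score = log10(RPKM_focal)/5 + RPKM_focal / mean(RPKM over all types)`,
rank descending, keep the top 250. Interpretation choices made here:

- The `log10(RPKM)` term uses the **focal type's** RPKM — the same
  value as the fold-change numerator. The score is computed "per cell
  type", and only the focal value is type-specific.
- RPKM per type is the arithmetic mean over that type's replicates,
  computed before filtering and scoring.
- The filter uses only the focal type's RPKM, so a gene may qualify for
  one type while being below the floor in another.
- Ties at the top-N boundary are broken lexicographically by gene id,
  making selection deterministic.

Because the floor is applied before the log, the log argument is always
≥ 3.5. A uniform rescaling of all RPKMs shifts every surviving score by
`log10(c)/5` and leaves the ranking unchanged.

## GSEA

The enrichment score is the classic weighted running sum: walking down
the ranked list, set members add `|metric|^p` normalized by the sum over
members (default weight p = 1), non-members subtract `1/(n - n_hits)`;
ES is the extremum by absolute deviation. Numerical conventions: the
running sum is clipped to [−1, 1] against accumulation round-off, and
the extremum is selected on |running sum| rounded to 9 decimals with
the earliest index winning ties. The ranking metric defaults to the
Wald statistic (alternatives: log2FC, signed −log10 p), with ties broken
by gene id. A set containing every ranked gene has no misses and is
reported as ES = 1 with a degeneracy flag.

**Permutation null.** Phenotype permutation relabels samples and
recomputes the whole ranking; with three-vs-three designs only
C(6,3) = 20 distinct relabelings exist, flooring the p-value at 1/20.
`mode="auto"` therefore switches to gene-set permutation (random
same-size sets from the ranked list) whenever fewer than 100 distinct
relabelings exist, and records the mode in the result; phenotype mode
remains available explicitly and enumerates all relabelings
exhaustively when few. NES divides ES by the mean |ES| of same-sign
permutations; the p-value is the same-sign tail frequency with an
add-one correction, so `p >= 1/(n_used+1)`. Sets with no same-sign
permutation get NES = NaN rather than a fabricated value.

## DamID

The native resolution unit is the GATC fragment: the genome is cut at
every occurrence start of `GATC` (its own reverse complement, so one
strand suffices; matching is case-insensitive), fragments tile each
chromosome exactly, and a cut at position 0 does not emit an empty
fragment. Intervals are assigned to the fragment containing their
**5′ start** — DamID fragments begin at GATC cuts, so 5′ ends carry
the signal; midpoints would blur fragment boundaries.

Enrichment testing reuses the count engine with the fusion condition as
treatment and is one-sided by filtering: only fragments *above* the
fold-change threshold enter peaks (depleted fragments stay in the
result table but are never merged). Peaks are maximal runs of
significant fragments allowing `max_gap_fragments` intervening
non-significant fragments (default 0); peak log2FC is the
base-mean-weighted mean over members, peak significance the minimum
member padj. Genes are assigned to peaks when the peak overlaps the
gene body extended 2 kb upstream of the TSS (strand-aware). Both the
merge gap and the 2 kb window are parameters: published peak counts
from comparable workflows are ambiguous about the merge unit and the
assignment window, so both conventions are explicit and recorded in
output metadata. Replicate QC is the Pearson correlation of
log2(normalized count + 1) across fragments.

## Integration

A gene is bound if any significant peak is assigned to it (gene-level,
not peak-level, intersection), and a direct target if it is bound and
differentially expressed. Down-regulated targets are candidate
activated genes; up-regulated targets candidate repressed genes. The
gene universe for overlap statistics is the set of genes actually
tested (defined padj), not all annotated genes. Summary counts are
partition-consistent by construction
(`n_targets = n_down_targets + n_up_targets`).

## Motif scanning

A consensus motif is an ordered list of allowed-base sets, parsed from
dash/slash notation (`T-A/T-A-G-A/C/G-C-G/A/T`) or an IUPAC word
(`TWAGVCD`). Scanning counts mismatches per window on both strands;
`N` matches nothing (conservative); all overlapping hits are reported;
minus-strand hits carry plus-strand coordinates and the motif-strand
word. The default mismatch budget is 0, but the budget is exposed
because known functional sites include words that deviate from the
consensus at one position (e.g. `TAAGCTG`, which violates position 6).

TSS-relative coordinates are signed and 1-based with no zero: +1 is the
TSS base, −1 the first base upstream, measured along the gene's
orientation; intervals are reported (5′-most, 3′-most). Enhancer
extraction returns the gene-oriented sequence of a relative window, so
a scan of an extracted window plus the offset arithmetic reproduces
genomic hits exactly — the round trip the tests exercise with planted
fixtures at −1595..−1589, −1471..−1465 and +1734..+1740.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the analysis
assumes, with defaults shaped like the motivating study design:

| Parameter | Default | Meaning |
|---|---|---|
| `n_genes` | 5,000 | transcriptome size (desk-scale) |
| `celltypes` | EE, progenitor, EC | focal type first |
| `replicates_per_group` | 3 | both cell-type and depletion designs |
| `markers_per_type` / `marker_fold` | 200 / 8 | planted cell-type markers |
| `depletion_fraction` / `depletion_fold` | 0.8 / 4 | share of focal markers lost on knockdown |
| `up_fraction` / `up_fold` | 0.02 / 4 | minority of non-markers that *rise* (genes not restricted to the focal type) |
| `nb_dispersion` | 0.05 | typical bulk-replicate overdispersion |
| `library_size_mean` | 5×10⁶ | reads per RNA-seq sample |
| `chrom_length` | 1 Mb | toy chromosome; ~4,000 GATC fragments (one per ~256 bp of random sequence) |
| `fusion_replicates` / `control_replicates` | 2 / 3 | DamID design |
| `n_bound_fragments` / `damid_enrichment` | 100 / 8 | planted binding near regulated TSSs |

Baseline expression is log-normal (meanlog 4, sdlog 1.5) on an
RPKM-like scale — chosen to straddle the 3.5-RPKM filter — converted to
expected counts through log-uniform gene lengths (500–10,000 bp) and
per-sample library sizes (log-normal, sd 0.1 around the mean). Counts
are NB draws with the gamma-Poisson parameterization; dispersion → 0
degenerates to Poisson. Each generator draws from a stream seeded by
`(seed, stream_tag)`, so the four assays are independent yet jointly
byte-reproducible. The joint-experiment generator annotates the toy
genome with gene ids drawn from the expression universe (a mix of
planted-down, planted-up and unregulated genes) and records the exact
bound-gene truth under the same body+2 kb rule the annotator uses, so
target calling can be scored for set equality, not just overlap.

Planted motif words must match the consensus; rejection sampling
re-randomizes any *accidental* 0-mismatch consensus match inside a
planted gene's scan window (±2,500 bp), so recovered hits equal planted
hits exactly.

Not emulated: read-level sequencing (no FASTQ, alignment or error
models), batch effects, GC or mappability bias, library-composition
artifacts beyond the bound-fragment inflation, gene-gene correlation,
and isoform structure. Passing recovery tests therefore demonstrates
the *statistical contract* of each caller under its assumed model — not
robustness to the technical artifacts of real libraries.

## Problem sizes and runtimes

Tests and the acceptance script run the study at desk scale by choice:
5,000 genes for signature/GSEA stages, 2,000 genes × 10–20 seeds for
null calibration, one 1 Mb chromosome (~4,000 fragments) for DamID, and
reduced scales (600–800 genes, 200–300 kb) for pipeline determinism
checks. The full suite completes in about a minute on one CPU; the
acceptance script in under ten seconds.

## Known limitations

- The NB Wald test with three replicates is mildly anti-conservative at
  the raw p < 0.05 level (~0.067 observed vs 0.05 nominal in null
  simulations); BH-adjusted calls at padj < 0.01 remain far below the
  nominal rate. Exact small-sample inference is out of scope.
- With 20 distinct label permutations, phenotype-mode p-values cannot
  go below 0.05; headline significance for small designs rests on the
  gene-set permutation null, and the result records which null was
  used.
- Peak counts depend on the merge-gap convention; fragment-level and
  merged-run counts can differ severalfold on dense binding.
- `score_signatures` presumes the configured cell-type panel is
  complete; signatures are only comparative within the panel.
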