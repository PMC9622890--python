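"""Seeded synthetic data with the structure the pipeline assumes.

Generators for (i) three-cell-type bulk RNA-seq count matrices with
planted cell-type markers, (ii) a control-vs-knockdown depletion
experiment in which most of the focal type's signature is
down-regulated (with a small up-regulated minority, mirroring genes
whose expression is not restricted to the focal type), (iii) a toy
genome with annotated TSSs and planted consensus-motif words at
recorded TSS-relative positions, and (iv) a DamID fragment-count
experiment (2 fusion vs 3 Dam-only replicates) with planted bound
fragments near regulated genes' TSSs.

Every generator takes a :class:`SimulationConfig`, draws from a
generator seeded by ``(config.seed, stream_tag)`` so the four streams
are independent but jointly reproducible, and returns a
:class:`SimulationTruth` carrying exactly the planted ground truth
needed to score downstream callers.

Counts are negative binomial with variance ``mu + alpha * mu**2``.
Baseline expression is log-normal on an RPKM-like scale (meanlog 4,
sdlog 1.5), spanning the 3.5-RPKM signature filter; gene lengths are
log-uniform 500-10,000 bp and matter only for RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import damid as _damid
from .countmodel import CountMatrix
from .motif import parse_consensus, revcomp, relative_to_absolute, scan

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "PROS_CONSENSUS",
    "DEFAULT_PLANTS",
    "simulate_celltype_counts",
    "simulate_depletion_experiment",
    "simulate_genome_with_motifs",
    "simulate_damid",
    "simulate_joint_experiment",
]

#: the degenerate homeodomain-factor consensus used throughout the toys
PROS_CONSENSUS = "T-A/T-A-G-A/C/G-C-G/A/T"

#: default motif plants: (gene index, 5'-most TSS-relative start, word,
#: hit strand relative to the gene orientation).  The first three echo
#: the enhancer-fixture coordinates used in the validation experiments.
DEFAULT_PLANTS = (
    (0, -1595, "TTAGCCG", "+"),
    (0, -1471, "TAAGACG", "+"),
    (1, 1734, "TTAGCCG", "+"),
    (2, -820, "TAAGCCT", "-"),
)

_STREAM_CELLTYPE = 1
_STREAM_DEPLETION = 2
_STREAM_GENOME = 3
_STREAM_DAMID = 4


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study, with study-shaped defaults.

    The default design mirrors the emulated experiments: three cell
    types x three replicates for marker discovery; a 3-vs-3
    control/knockdown comparison in which 80% of the focal-type markers
    drop 4-fold and a 2% minority of other genes rises 4-fold; and a
    2-vs-3 fusion/Dam-only DamID layout with 100 fragments bound
    8-fold on a 1 Mb toy chromosome.
    """

    n_genes: int = 5000
    celltypes: tuple = ("EE", "progenitor", "EC")
    replicates_per_group: int = 3
    markers_per_type: int = 200
    marker_fold: float = 8.0
    depletion_fraction: float = 0.8
    depletion_fold: float = 4.0
    up_fraction: float = 0.02
    up_fold: float = 4.0
    nb_dispersion: float = 0.05
    library_size_mean: int = 5_000_000
    seed: int = 0
    # genome / DamID toy
    chrom_length: int = 1_000_000
    n_annotated_genes: int = 12
    scan_window: int = 2500
    n_bound_fragments: int = 100
    damid_enrichment: float = 8.0
    damid_library_size: int = 2_000_000
    fusion_replicates: int = 2
    control_replicates: int = 3
    # baseline expression model
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.5

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "replicates_per_group", "markers_per_type",
            "library_size_mean", "chrom_length", "n_annotated_genes",
            "n_bound_fragments", "damid_library_size",
            "fusion_replicates", "control_replicates", "scan_window",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("marker_fold", "depletion_fold", "up_fold", "damid_enrichment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (1 = null)")
        for name in ("depletion_fraction", "up_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if len(self.celltypes) != len(set(self.celltypes)):
            raise ValueError("cell types must be unique")


@dataclass
class SimulationTruth:
    """Planted ground truth plus the internal baselines later stages reuse."""

    planted_markers: dict = field(default_factory=dict)
    planted_down: dict = field(default_factory=dict)  # gene -> true log2fc
    planted_up: dict = field(default_factory=dict)
    planted_bound_fragments: dict = field(default_factory=dict)  # frag -> fold
    planted_bound_genes: set = field(default_factory=set)
    planted_motif_hits: list = field(default_factory=list)
    baseline_rpkm: pd.Series | None = None
    gene_lengths: pd.Series | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2); Poisson when alpha ~ 0."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def _baselines(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[pd.Series, pd.Series]:
    genes = _gene_ids(config.n_genes)
    lengths = np.exp(
        rng.uniform(np.log(500.0), np.log(10_000.0), config.n_genes)
    ).round()
    rpkm = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.n_genes)
    return (
        pd.Series(rpkm, index=genes, name="baseline_rpkm"),
        pd.Series(lengths, index=genes, name="length"),
    )


def simulate_celltype_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SimulationTruth]:
    """Three cell-type transcriptomes with planted marker genes.

    Marker genes of type *t* have their expected expression multiplied
    by ``marker_fold`` in *t* only; counts are NB draws around
    cell-type-specific expected counts derived from the RPKM-like
    baselines, gene lengths and per-sample library sizes.
    """
    n_types = len(config.celltypes)
    if config.markers_per_type * n_types > config.n_genes:
        raise ValueError(
            f"cannot plant {config.markers_per_type} markers for each of "
            f"{n_types} cell types in {config.n_genes} genes"
        )
    rng = _rng(config, _STREAM_CELLTYPE)
    baseline, lengths = _baselines(rng, config)
    genes = list(baseline.index)

    chosen = rng.choice(
        config.n_genes, size=config.markers_per_type * n_types, replace=False
    )
    planted_markers = {
        ct: {genes[i] for i in chosen[k * config.markers_per_type : (k + 1) * config.markers_per_type]}
        for k, ct in enumerate(config.celltypes)
    }

    cols, data, groups = [], [], {}
    for ct in config.celltypes:
        profile = baseline.copy()
        profile.loc[sorted(planted_markers[ct])] *= config.marker_fold
        expected_per_len = profile.to_numpy() * lengths.to_numpy()  # ~ RPKM * kb
        frac = expected_per_len / expected_per_len.sum()
        for r in range(config.replicates_per_group):
            lib = config.library_size_mean * np.exp(rng.normal(0.0, 0.1))
            mu = frac * lib
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            name = f"{ct}_rep{r + 1}"
            cols.append(name)
            data.append(counts)
            groups[name] = ct
    counts_df = pd.DataFrame(
        np.column_stack(data), index=genes, columns=cols
    )
    cm = CountMatrix(counts_df, pd.Series(groups), lengths)
    truth = SimulationTruth(
        planted_markers=planted_markers,
        baseline_rpkm=baseline,
        gene_lengths=lengths,
    )
    return cm, truth


def simulate_depletion_experiment(
    base_truth: SimulationTruth | None,
    config: SimulationConfig,
) -> tuple[CountMatrix, SimulationTruth]:
    """Control vs knockdown counts in the focal (first) cell type.

    A ``depletion_fraction`` of the focal type's planted markers is
    divided by ``depletion_fold`` in the knockdown group; an
    ``up_fraction`` of the remaining genes is multiplied by
    ``up_fold``.  With both effects at zero/one the two groups are
    exchangeable NB draws.

    ``base_truth`` should come from :func:`simulate_celltype_counts`;
    passing ``None`` generates fresh baselines and treats a random
    ``markers_per_type``-sized gene set as the focal signature.
    """
    rng = _rng(config, _STREAM_DEPLETION)
    focal = config.celltypes[0]
    if base_truth is None:
        baseline, lengths = _baselines(rng, config)
        genes = list(baseline.index)
        idx = rng.choice(config.n_genes, size=config.markers_per_type, replace=False)
        markers = {genes[i] for i in idx}
        base_truth = SimulationTruth(
            planted_markers={focal: markers},
            baseline_rpkm=baseline,
            gene_lengths=lengths,
        )
    if base_truth.baseline_rpkm is None or base_truth.gene_lengths is None:
        raise ValueError("base_truth lacks baselines; run simulate_celltype_counts first")
    if focal not in base_truth.planted_markers:
        raise ValueError(f"base_truth lacks markers for focal type {focal!r}")

    baseline = base_truth.baseline_rpkm
    lengths = base_truth.gene_lengths
    genes = list(baseline.index)
    markers = sorted(base_truth.planted_markers[focal])

    profile = baseline.copy()
    profile.loc[markers] *= config.marker_fold

    n_down = int(round(config.depletion_fraction * len(markers)))
    down_genes = sorted(
        np.array(markers)[rng.choice(len(markers), size=n_down, replace=False)]
    )
    non_markers = sorted(set(genes) - set(markers))
    n_up = int(round(config.up_fraction * len(non_markers)))
    up_genes = sorted(
        np.array(non_markers)[rng.choice(len(non_markers), size=n_up, replace=False)]
    )

    kd_profile = profile.copy()
    kd_profile.loc[down_genes] /= config.depletion_fold
    kd_profile.loc[up_genes] *= config.up_fold

    cols, data, groups = [], [], {}
    for label, prof in (("control", profile), ("knockdown", kd_profile)):
        expected_per_len = prof.to_numpy() * lengths.to_numpy()
        frac = expected_per_len / expected_per_len.sum()
        for r in range(config.replicates_per_group):
            lib = config.library_size_mean * np.exp(rng.normal(0.0, 0.1))
            counts = _nb_draw(rng, frac * lib, config.nb_dispersion)
            name = f"{label}_rep{r + 1}"
            cols.append(name)
            data.append(counts)
            groups[name] = label
    cm = CountMatrix(
        pd.DataFrame(np.column_stack(data), index=genes, columns=cols),
        pd.Series(groups),
        lengths,
    )
    truth = SimulationTruth(
        planted_markers=dict(base_truth.planted_markers),
        planted_down={g: -np.log2(config.depletion_fold) for g in down_genes},
        planted_up={g: np.log2(config.up_fold) for g in up_genes},
        baseline_rpkm=baseline,
        gene_lengths=lengths,
    )
    return cm, truth


def simulate_genome_with_motifs(
    config: SimulationConfig,
    plants: tuple = DEFAULT_PLANTS,
    gene_ids: list[str] | None = None,
) -> tuple[dict, pd.DataFrame, SimulationTruth]:
    """Toy chromosome with annotated TSSs and planted consensus words.

    Random bases naturally contain GATC sites (~one per 256 bp), which
    the DamID toy reuses.  Each plant writes a consensus-matching word
    at a recorded TSS-relative interval on the requested strand of the
    gene orientation; rejection sampling then scrubs every planted
    gene's scan window (TSS +/- ``scan_window``) of *accidental*
    0-mismatch consensus matches, so recovered hits equal planted hits.
    """
    rng = _rng(config, _STREAM_GENOME)
    L = config.chrom_length
    n_genes = config.n_annotated_genes
    margin = config.scan_window + 7
    bases = np.array(list("ACGT"))
    seq = rng.choice(4, size=L)

    # evenly spaced TSSs with jitter, kept clear of the chromosome ends
    slots = np.linspace(margin, L - margin, n_genes + 2)[1:-1]
    jitter = rng.integers(-margin // 4, margin // 4 + 1, size=n_genes)
    tss = (slots + jitter).astype(int)
    strands = np.array(["+", "-"])[np.arange(n_genes) % 2]
    glens = np.exp(rng.uniform(np.log(1000.0), np.log(5000.0), n_genes)).round().astype(int)
    if gene_ids is None:
        gene_ids = [f"tg{i:02d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError(
            f"gene_ids has {len(gene_ids)} entries for {n_genes} annotated genes"
        )
    genes = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "chrom": "chr1",
            "tss": tss,
            "strand": strands,
            "length": glens,
        }
    )

    motif = parse_consensus(PROS_CONSENSUS)
    truth = SimulationTruth()
    planted_abs: list[tuple[int, int]] = []
    for gene_idx, rel_start, word, hit_strand in plants:
        if gene_idx >= n_genes:
            raise ValueError(f"plant refers to gene index {gene_idx} of {n_genes}")
        if motif.mismatches(word) != 0:
            raise ValueError(f"planted word {word!r} does not match the consensus")
        g = genes.iloc[gene_idx]
        k = len(word)
        rel_end = rel_start + k - 1 if rel_start > 0 or rel_start + k - 1 < 0 else None
        if rel_end is None:  # window crosses the TSS: skip the nonexistent 0
            rel_end = rel_start + k
        if max(abs(rel_start), abs(rel_end)) + 7 > config.scan_window:
            raise ValueError(
                f"plant at {rel_start} exceeds the +/-{config.scan_window} scan window"
            )
        a = relative_to_absolute(rel_start, int(g["tss"]), g["strand"])
        b = relative_to_absolute(rel_end, int(g["tss"]), g["strand"])
        lo, hi = min(a, b), max(a, b)
        oriented = word if hit_strand == "+" else revcomp(word)
        plus_word = oriented if g["strand"] == "+" else revcomp(oriented)
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        seq[lo : hi + 1] = [code[c] for c in plus_word]
        planted_abs.append((lo, hi + 1))
        truth.planted_motif_hits.append(
            {
                "gene": g["gene_id"],
                "rel_start": rel_start,
                "rel_end": rel_end,
                "strand": hit_strand,
                "word": word,
            }
        )

    # rejection sampling: scrub accidental consensus matches from the
    # scan windows of genes that carry plants
    planted_gene_idx = sorted({p[0] for p in plants})
    for _ in range(200):
        dirty = []
        chrom = "".join(bases[seq])
        for gi in planted_gene_idx:
            g = genes.iloc[gi]
            w_lo = max(0, int(g["tss"]) - config.scan_window - 7)
            w_hi = min(L, int(g["tss"]) + config.scan_window + 7)
            for hit in scan(chrom[w_lo:w_hi], motif, max_mismatch=0):
                a, b = w_lo + hit.start, w_lo + hit.end
                if not any(a < phi and plo < b for plo, phi in planted_abs):
                    dirty.append((a, b))
        if not dirty:
            break
        for a, b in dirty:
            seq[a:b] = rng.choice(4, size=b - a)
    else:
        raise RuntimeError("rejection sampling failed to clear accidental motifs")

    genome = {"chr1": "".join(bases[seq])}
    return genome, genes, truth


def simulate_damid(
    genome: dict,
    genes: pd.DataFrame,
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
    regulated_genes: list[str] | None = None,
) -> tuple[CountMatrix, _damid.GatcFragmentMap, SimulationTruth]:
    """Fragment counts for fusion (2 reps) vs Dam-only (3 reps).

    A shared accessibility-like log-normal baseline (scaled by fragment
    length) sets expected counts in both conditions; planted bound
    fragments — drawn preferentially from fragments near the TSSs of
    ``regulated_genes`` (default: all annotated genes) — have their
    fusion-condition means multiplied by ``damid_enrichment``.
    """
    rng = _rng(config, _STREAM_DAMID)
    frag_map = _damid.gatc_fragment_map(genome)
    tab = frag_map.table
    n_frags = len(tab)
    if config.n_bound_fragments > n_frags:
        raise ValueError(
            f"requested {config.n_bound_fragments} bound fragments but the map "
            f"has only {n_frags}"
        )

    frag_len = (tab["end"] - tab["start"]).to_numpy(dtype=float)
    weight = rng.lognormal(0.0, 1.0, n_frags) * frag_len / frag_len.mean()

    if regulated_genes is None:
        regulated_genes = list(genes["gene_id"])
    near_tss: list[int] = []
    gsub = genes[genes["gene_id"].isin(regulated_genes)]
    for _, g in gsub.iterrows():
        lo, hi = int(g["tss"]) - 2000, int(g["tss"]) + 2000
        sub = tab[(tab["chrom"] == g["chrom"]) & (tab["start"] < hi) & (tab["end"] > lo)]
        near_tss.extend(sub.index.tolist())
    near_tss = sorted(set(near_tss))
    n_near = min(len(near_tss), config.n_bound_fragments)
    picked = list(
        np.array(near_tss)[rng.choice(len(near_tss), size=n_near, replace=False)]
    ) if near_tss else []
    remaining = sorted(set(range(n_frags)) - set(picked))
    n_extra = config.n_bound_fragments - len(picked)
    if n_extra > 0:
        picked += list(
            np.array(remaining)[rng.choice(len(remaining), size=n_extra, replace=False)]
        )
    bound_idx = np.array(sorted(picked))
    bound_ids = tab["fragment_id"].iloc[bound_idx].tolist()

    # which annotated genes a perfect caller would report as bound,
    # under the same body + 2 kb upstream rule the annotator uses
    spans = _damid.gene_spans(genes, upstream_bp=2000)
    bound_genes: set = set()
    for i in bound_idx:
        f = tab.iloc[int(i)]
        for chrom, lo, hi, gid in spans:
            if chrom == f["chrom"] and f["start"] < hi and lo < f["end"]:
                bound_genes.add(gid)

    frac = weight / weight.sum()
    cols, data, groups = [], [], {}
    layout = [("fusion", config.fusion_replicates), ("dam_only", config.control_replicates)]
    for label, n_reps in layout:
        mu_base = frac.copy()
        if label == "fusion":
            mu_base = mu_base.copy()
            mu_base[bound_idx] *= config.damid_enrichment
        for r in range(n_reps):
            lib = config.damid_library_size * np.exp(rng.normal(0.0, 0.1))
            counts = _nb_draw(rng, mu_base * lib, config.nb_dispersion)
            name = f"{label}_rep{r + 1}"
            cols.append(name)
            data.append(counts)
            groups[name] = label
    cm = CountMatrix(
        pd.DataFrame(
            np.column_stack(data), index=tab["fragment_id"].tolist(), columns=cols
        ),
        pd.Series(groups),
    )
    out_truth = truth if truth is not None else SimulationTruth()
    out_truth.planted_bound_fragments = {
        fid: config.damid_enrichment for fid in bound_ids
    }
    out_truth.planted_bound_genes = bound_genes
    return cm, frag_map, out_truth


def simulate_joint_experiment(config: SimulationConfig) -> dict:
    """Full linked study: cell types, depletion, genome, DamID.

    The toy genome's annotated genes are drawn from the expression
    simulation's universe — a mix of planted-down, planted-up and
    unregulated genes — and bound fragments are planted near the
    regulated ones, so binding and expression share a namespace and the
    expected direct-target set is ``planted_bound_genes &
    (planted_down | planted_up)``.

    Returns a dict with keys ``celltype_cm, depletion_cm, genome,
    genes, damid_cm, frag_map, truth``.
    """
    ct_cm, ct_truth = simulate_celltype_counts(config)
    dep_cm, truth = simulate_depletion_experiment(ct_truth, config)

    rng = _rng(config, _STREAM_GENOME + 10)
    down = sorted(truth.planted_down)
    up = sorted(truth.planted_up)
    n = config.n_annotated_genes
    n_down = min(len(down), n // 2)
    n_up = min(len(up), n // 4)
    chosen = list(np.array(down)[rng.choice(len(down), n_down, replace=False)]) if n_down else []
    chosen += list(np.array(up)[rng.choice(len(up), n_up, replace=False)]) if n_up else []
    rest = sorted(set(ct_cm.features) - set(down) - set(up) - set(chosen))
    n_rest = n - len(chosen)
    chosen += list(np.array(rest)[rng.choice(len(rest), n_rest, replace=False)])
    chosen = sorted(chosen)

    genome, genes, truth = simulate_genome_with_motifs(config, gene_ids=chosen)
    # carry the expression truth through
    truth.planted_markers = ct_truth.planted_markers
    truth.planted_down = {g: -np.log2(config.depletion_fold) for g in down}
    truth.planted_up = {g: np.log2(config.up_fold) for g in up}
    truth.baseline_rpkm = ct_truth.baseline_rpkm
    truth.gene_lengths = ct_truth.gene_lengths
    regulated = [g for g in chosen if g in truth.planted_down or g in truth.planted_up]
    dam_cm, frag_map, truth = simulate_damid(
        genome, genes, config, truth, regulated_genes=regulated or None
    )
    return {
        "celltype_cm": ct_cm,
        "depletion_cm": dep_cm,
        "genome": genome,
        "genes": genes,
        "damid_cm": dam_cm,
        "frag_map": frag_map,
        "truth": truth,
    }
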