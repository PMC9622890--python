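"""End-to-end pipeline: simulate -> signature -> DE -> GSEA -> DamID ->
integration -> motif scan, with per-stage run manifests.

The pipeline is deterministic for a fixed seed: rerunning into a fresh
directory reproduces every result table byte for byte (manifests carry
a timestamp and are the only non-reproducible artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, damid as damid_mod, io as io_mod
from .countmodel import call_de, nb_wald_test
from .gsea import permutation_nes, rank_genes
from .integration import call_targets, signature_overlap
from .motif import parse_consensus, extract_enhancer, scan
from .signature import rpkm, score_signatures, signature_gene_sets
from .synthetic import PROS_CONSENSUS, SimulationConfig, simulate_joint_experiment

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study's thresholds."""

    seed: int = 0
    out_dir: str = "damtarget_run"
    # signature
    min_rpkm: float = 3.5
    top_n: int = 250
    # differential expression
    de_padj_max: float = 0.01
    de_min_abs_log2fc: float = 0.5
    # GSEA
    n_perm: int = 1000
    gsea_mode: str = "auto"
    gsea_metric: str = "wald_stat"
    # DamID
    damid_min_log2fc: float = 1.0
    damid_padj_max: float = 0.01
    max_gap_fragments: int = 0
    upstream_bp: int = 2000
    # motif
    consensus: str = PROS_CONSENSUS
    max_mismatch: int = 0
    motif_scan_window: int = 2500
    # synthetic inputs
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(sim_unknown)}")
        cfg = cls(**raw, simulation=SimulationConfig(**sim_raw))
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["celltypes"] = list(d["simulation"]["celltypes"])
        return d


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(out: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    payload = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "input_hashes": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated inputs; return a summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # --- simulate (linked study: shared gene namespace) -------------
    study = simulate_joint_experiment(sim)
    ct_cm, dep_cm = study["celltype_cm"], study["depletion_cm"]
    genome, genes = study["genome"], study["genes"]
    dam_cm, frag_map = study["damid_cm"], study["frag_map"]
    truth = study["truth"]
    io_mod.write_counts_tsv(ct_cm, out / "celltype_counts.tsv")
    io_mod.write_metadata_tsv(ct_cm.groups, out / "celltype_metadata.tsv")
    io_mod.write_counts_tsv(dep_cm, out / "depletion_counts.tsv")
    io_mod.write_metadata_tsv(dep_cm.groups, out / "depletion_metadata.tsv")
    io_mod.write_fasta(genome, out / "genome.fa")
    io_mod.write_gene_tsv(genes, out / "genes.tsv")
    io_mod.write_gff3(genes, out / "genes.gff3")
    io_mod.write_counts_tsv(dam_cm, out / "damid_counts.tsv")
    io_mod.write_metadata_tsv(dam_cm.groups, out / "damid_metadata.tsv")
    io_mod.write_truth_json(truth, out / "truth.json")
    _manifest(out, "simulate", {"seed": config.seed}, [out / "celltype_counts.tsv"])

    # --- signature --------------------------------------------------
    rpkm_table = rpkm(ct_cm)
    io_mod.write_tsv(rpkm_table, out / "rpkm.tsv", index_label="gene")
    signatures = score_signatures(rpkm_table, config.min_rpkm, config.top_n)
    for ct, tab in signatures.items():
        io_mod.write_tsv(tab, out / f"signature_{ct}.tsv")
    gene_sets = signature_gene_sets(signatures)
    io_mod.write_gmt(gene_sets, out / "signatures.gmt")
    _manifest(
        out, "signature",
        {"min_rpkm": config.min_rpkm, "top_n": config.top_n},
        [out / "celltype_counts.tsv"],
    )

    # --- differential expression ------------------------------------
    de = nb_wald_test(dep_cm, control="control", treatment="knockdown")
    io_mod.write_tsv(de, out / "de_results.tsv", index_label="feature_id")
    de_up, de_down = call_de(de, config.de_padj_max, config.de_min_abs_log2fc)
    _manifest(
        out, "de",
        {"padj_max": config.de_padj_max, "min_abs_log2fc": config.de_min_abs_log2fc},
        [out / "depletion_counts.tsv"],
    )

    # --- GSEA of the focal signature under depletion ----------------
    focal = sim.celltypes[0]
    focal_set = gene_sets[f"{focal}_signature"]
    gsea_res = permutation_nes(
        dep_cm, "control", "knockdown", focal_set,
        n_perm=config.n_perm, mode=config.gsea_mode,
        seed=config.seed, metric=config.gsea_metric,
        set_name=f"{focal}_signature",
    )
    pd.DataFrame(
        [{
            "set": gsea_res.set_name, "es": gsea_res.es, "nes": gsea_res.nes,
            "pvalue": gsea_res.pvalue, "n_permutations": gsea_res.n_permutations,
            "mode": gsea_res.mode, "n_leading_edge": len(gsea_res.leading_edge),
        }]
    ).pipe(io_mod.write_tsv, out / "gsea_results.tsv")
    _manifest(out, "gsea", {"n_perm": config.n_perm, "mode": config.gsea_mode}, [])

    # --- DamID ------------------------------------------------------
    corr = damid_mod.replicate_correlation(dam_cm)
    io_mod.write_tsv(corr, out / "damid_replicate_correlation.tsv", index_label="sample")
    sig_frags, frag_de = damid_mod.call_binding(
        dam_cm, min_log2fc=config.damid_min_log2fc, padj_max=config.damid_padj_max
    )
    io_mod.write_tsv(frag_de, out / "damid_fragment_results.tsv", index_label="fragment_id")
    peaks = damid_mod.merge_peaks(sig_frags, frag_map, frag_de, config.max_gap_fragments)
    peaks, n_distinct_genes = damid_mod.annotate_peaks(peaks, genes, config.upstream_bp)
    peak_tab = pd.DataFrame(
        [{
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "n_fragments": len(p.fragment_ids), "log2fc": p.log2fc,
            "min_padj": p.min_padj, "genes": ",".join(p.gene_ids),
        } for p in peaks]
    )
    io_mod.write_tsv(peak_tab, out / "damid_peaks.tsv")
    _manifest(
        out, "damid",
        {"min_log2fc": config.damid_min_log2fc, "padj_max": config.damid_padj_max,
         "max_gap_fragments": config.max_gap_fragments, "upstream_bp": config.upstream_bp},
        [out / "damid_counts.tsv"],
    )

    # --- integration ------------------------------------------------
    bound_genes = set().union(*(set(p.gene_ids) for p in peaks)) if peaks else set()
    # restrict DE direction sets to the annotated toy genes when integrating
    target_tab, target_summary = call_targets(bound_genes, de_up, de_down, de)
    io_mod.write_tsv(target_tab, out / "targets.tsv", index_label="gene")
    ranked = rank_genes(de, config.gsea_metric)
    targets = set(target_tab.index[target_tab["target"]])
    overlap = signature_overlap(targets, focal_set, ranked, de_down)
    summary = {
        "seed": config.seed,
        "n_de_up": len(de_up),
        "n_de_down": len(de_down),
        "gsea_nes": gsea_res.nes,
        "gsea_pvalue": gsea_res.pvalue,
        "n_significant_fragments": len(sig_frags),
        "n_peaks": len(peaks),
        "n_peak_genes": n_distinct_genes,
        **target_summary,
        "signature_overlap": overlap["n_overlap"],
        "signature_overlap_down_fraction": overlap.get("down_fraction", float("nan")),
    }
    _manifest(out, "integrate", {}, [out / "targets.tsv"])

    # --- motif scan of annotated-gene windows -----------------------
    motif = parse_consensus(config.consensus)
    hit_rows = []
    w = config.motif_scan_window
    for _, g in genes.iterrows():
        seq = extract_enhancer(genome[g["chrom"]], int(g["tss"]), g["strand"], -w, w)
        for hit in scan(seq, motif, config.max_mismatch, seq_id=g["gene_id"]):
            # hit coords are within the gene-oriented window starting at -w
            offset = hit.start - w  # bases before the TSS base
            rel_start = offset if offset < 0 else offset + 1
            rel_last = offset + len(motif) - 1
            rel_end = rel_last if rel_last < 0 else rel_last + 1
            hit_rows.append(
                {
                    "gene": g["gene_id"], "rel_start": rel_start, "rel_end": rel_end,
                    "strand": hit.strand, "mismatches": hit.mismatches,
                    "matched_seq": hit.matched_seq,
                }
            )
    motif_tab = pd.DataFrame(
        hit_rows,
        columns=["gene", "rel_start", "rel_end", "strand", "mismatches", "matched_seq"],
    )
    io_mod.write_tsv(motif_tab, out / "motif_hits.tsv")
    _manifest(out, "motif", {"consensus": config.consensus, "max_mismatch": config.max_mismatch}, [])

    summary["n_motif_hits"] = len(motif_tab)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return summary
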