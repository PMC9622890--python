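"""Binding-and-expression intersection: calling direct TF targets.

A gene is a *direct target* when it is both bound (at least one
significant DamID peak assigned to it) and differentially expressed
upon depletion of the factor.  Down-regulated targets are candidate
activated genes; up-regulated targets candidate repressed genes.  The
module also quantifies how a cell-type signature set behaves among the
targets (overlap size, fraction down, and a GSEA of the intersection
against the depletion ranking).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .gsea import GseaResult, enrichment_score

__all__ = ["call_targets", "signature_overlap"]


def call_targets(
    damid_genes: set,
    de_up: set,
    de_down: set,
    de: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Intersect bound genes with differentially expressed genes.

    Returns a per-gene table over ``damid_genes | de_up | de_down``
    with columns ``bound, de_direction, target`` (plus DE stats when
    ``de`` is given) and a summary dict with partition-consistent
    counts: ``n_targets = n_down_targets + n_up_targets``.
    """
    if not damid_genes:
        warnings.warn("no bound genes supplied; target set is empty")
    overlap_updown = de_up & de_down
    if overlap_updown:
        raise ValueError(f"genes both up and down: {sorted(overlap_updown)[:5]}")
    universe = sorted(damid_genes | de_up | de_down)
    rows = []
    for g in universe:
        direction = "up" if g in de_up else ("down" if g in de_down else "none")
        bound = g in damid_genes
        rows.append(
            {
                "gene": g,
                "bound": bound,
                "de_direction": direction,
                "target": bound and direction != "none",
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    if de is not None:
        table = table.join(de[["base_mean", "log2fc", "padj"]], how="left")
    targets = table.index[table["target"]]
    n_down = int((table.loc[targets, "de_direction"] == "down").sum())
    n_up = int((table.loc[targets, "de_direction"] == "up").sum())
    summary = {
        "n_bound_genes": len(damid_genes),
        "n_de_up": len(de_up),
        "n_de_down": len(de_down),
        "n_targets": len(targets),
        "n_down_targets": n_down,
        "n_up_targets": n_up,
    }
    return table, summary


def signature_overlap(
    targets: set,
    signature_genes: list[str],
    ranked: pd.Series,
    de_down: set,
    weight: float = 1.0,
) -> dict:
    """Behavior of a signature set among the called targets.

    Reports the overlap |targets ∩ signature|, the fraction of the
    overlap that is down-regulated, and a running-sum enrichment score
    of the intersection set against the depletion ranking (negative ES
    means the bound signature genes sit at the repressed end).  GSEA is
    skipped (with a notice) when the intersection is empty.
    """
    if not signature_genes:
        raise ValueError("signature set is empty")
    sig = set(signature_genes)
    inter = targets & sig
    result: dict = {
        "n_signature": len(sig),
        "n_overlap": len(inter),
        "overlap_genes": sorted(inter),
    }
    if inter:
        result["down_fraction"] = len(inter & de_down) / len(inter)
        members = [g for g in inter if g in ranked.index]
        if members:
            es, _, leading = enrichment_score(ranked, members, weight)
            result["gsea"] = GseaResult(
                set_name="targets_in_signature",
                es=es,
                nes=float("nan"),
                pvalue=float("nan"),
                fdr=float("nan"),
                leading_edge=leading,
                n_permutations=0,
                mode="none",
            )
    else:
        warnings.warn("target/signature intersection empty; GSEA skipped")
        result["down_fraction"] = float("nan")
    return result
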