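"""Cell-type signature-gene scoring from replicate-averaged RPKM profiles.

Given bulk expression of a small panel of cell types (by default the
fly-midgut trio: enteroendocrine cells, esg+ progenitors, enterocytes),
each gene is scored per focal cell type by combining absolute abundance
and comparative enrichment:

    fold_change = RPKM_focal / mean(RPKM over all cell types)
    score       = log10(RPKM_focal) / 5 + fold_change

Genes whose focal-type RPKM is below a floor (default 3.5) are removed
before scoring, and the top-N scored genes (default 250) form the cell
type's signature set.  Because the floor is applied before the log, the
log10 argument is always >= 3.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .countmodel import CountMatrix

__all__ = ["rpkm", "score_signatures", "signature_gene_sets"]


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Replicate-averaged RPKM per cell type.

    ``RPKM_ij = count_ij * 1e9 / (length_i * total_j)`` per sample, then
    the arithmetic mean over each group's replicates.  The group labels
    of ``cm`` are taken to be cell types.
    """
    if cm.lengths is None:
        raise ValueError("RPKM requires feature lengths")
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    per_sample = cm.counts.mul(1e9).div(totals, axis=1).div(cm.lengths, axis=0)
    return per_sample.T.groupby(cm.groups).mean().T


def score_signatures(
    rpkm_table: pd.DataFrame,
    min_rpkm: float = 3.5,
    top_n: int = 250,
) -> dict[str, pd.DataFrame]:
    """Score and rank signature genes for every cell type.

    Parameters
    ----------
    rpkm_table
        Genes x cell types, replicate-averaged RPKM (output of
        :func:`rpkm`).
    min_rpkm
        Genes with focal-type RPKM strictly below this value are
        excluded for that type (they may still qualify for another).
    top_n
        Signature size per cell type.  Score ties at the boundary are
        broken by gene id (lexicographic), keeping selection
        deterministic.

    Returns
    -------
    dict mapping cell type to a DataFrame with columns
    ``gene, rpkm, fold_change, score, rank`` sorted by descending score.
    """
    mean_all = rpkm_table.mean(axis=1)
    out: dict[str, pd.DataFrame] = {}
    for celltype in rpkm_table.columns:
        focal = rpkm_table[celltype]
        keep = focal >= min_rpkm
        if not keep.any():
            warnings.warn(f"all genes fall below the RPKM floor for {celltype!r}")
            out[celltype] = pd.DataFrame(
                columns=["gene", "rpkm", "fold_change", "score", "rank"]
            )
            continue
        focal_kept = focal[keep]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = focal_kept / mean_all[keep]
        fc = fc.fillna(0.0)
        score = np.log10(focal_kept) / 5.0 + fc
        tab = pd.DataFrame(
            {
                "gene": focal_kept.index,
                "rpkm": focal_kept.to_numpy(),
                "fold_change": fc.to_numpy(),
                "score": score.to_numpy(),
            }
        )
        tab = tab.sort_values(
            ["score", "gene"], ascending=[False, True], kind="stable"
        ).head(top_n)
        tab["rank"] = np.arange(1, len(tab) + 1)
        out[celltype] = tab.reset_index(drop=True)
    return out


def signature_gene_sets(signatures: dict[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Collapse scored signatures to named gene sets (GMT-ready)."""
    return {
        f"{celltype}_signature": list(tab["gene"]) for celltype, tab in signatures.items()
    }
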