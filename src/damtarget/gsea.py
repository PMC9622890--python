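"""From-scratch gene set enrichment analysis.

Weighted Kolmogorov-Smirnov running-sum enrichment score (ES), a
permutation null for the normalized enrichment score (NES) and its
empirical p-value, and leading-edge extraction.

Two permutation modes are supported.  *Phenotype* permutation re-labels
samples and recomputes the ranking (and hence the ES) under each
relabeling; with three-vs-three designs only C(6,3) = 20 distinct
relabelings exist, which floors the attainable p-value at 1/20.
*Gene-set* permutation draws random sets of the same size from the
ranked list.  ``mode="auto"`` uses phenotype permutation when at least
100 distinct relabelings exist and otherwise falls back to gene-set
permutation, recording the choice in the result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmodel import CountMatrix, nb_wald_test

__all__ = [
    "GseaResult",
    "rank_genes",
    "enrichment_score",
    "permutation_nes",
    "gsea_fdr",
]

#: default exponent on |metric| for hit weights (GSEA convention)
DEFAULT_WEIGHT = 1.0

#: auto mode switches to gene-set permutation below this many distinct
#: label permutations
MIN_PHENOTYPE_PERMS = 100

_METRICS = {"stat", "wald_stat", "log2fc", "signed_logp"}


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float  # NaN when no same-sign permutation exists
    pvalue: float
    fdr: float  # NaN until computed across a family of sets
    leading_edge: list[str]
    n_permutations: int
    mode: str
    degenerate: bool = False
    running_sum: np.ndarray | None = field(default=None, repr=False)


def rank_genes(de: pd.DataFrame, metric: str = "wald_stat") -> pd.Series:
    """Rank genes best-to-worst by a signed DE metric.

    ``metric`` is one of ``wald_stat``/``stat`` (default), ``log2fc`` or
    ``signed_logp`` (sign(log2fc) * -log10 p).  Genes with undefined
    metric values are dropped.  Ties are broken by gene id so the order
    is deterministic.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown ranking metric {metric!r}")
    if metric in ("stat", "wald_stat"):
        vals = de["stat"]
    elif metric == "log2fc":
        vals = de["log2fc"]
    else:
        with np.errstate(divide="ignore"):
            vals = np.sign(de["log2fc"]) * -np.log10(de["pvalue"])
        vals = pd.Series(vals, index=de.index)
    vals = vals.dropna()
    vals = vals[np.isfinite(vals)]
    if vals.empty:
        raise ValueError("no genes with finite ranking metric")
    order = sorted(vals.index, key=lambda g: (-vals[g], g))
    return pd.Series(vals.loc[order], name=metric)


def _es_core(
    metric: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, np.ndarray, int]:
    """ES, running sum and extremum index for one ranked list / set."""
    n = metric.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hits == n:
        # no misses: the running sum climbs to 1 by convention
        rs = np.cumsum(np.abs(metric) ** weight)
        total = rs[-1]
        rs = rs / total if total > 0 else np.linspace(1 / n, 1.0, n)
        return 1.0, rs, n - 1
    w = np.abs(metric) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:  # all hit metrics exactly zero: equal weights
        hit_w = hit_mask.astype(float)
        total_hit = float(n_hits)
    step = hit_w / total_hit - (~hit_mask) / (n - n_hits)
    rs = np.clip(np.cumsum(step), -1.0, 1.0)  # guard accumulation round-off
    # extremum: largest |running sum|, earliest index on (near-)ties
    idx = int(np.argmax(np.round(np.abs(rs), 9)))
    return float(rs[idx]), rs, idx


def enrichment_score(
    ranked: pd.Series,
    geneset,
    weight: float = DEFAULT_WEIGHT,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score with leading edge.

    Walking down the ranked list, set members ("hits") add
    ``|metric|**weight`` normalized by the sum over hits; non-members
    subtract ``1/(n - n_hits)``.  The ES is the running-sum value of
    largest absolute deviation from zero.  The leading edge contains the
    hits at or before the extremum for positive ES, and at or after it
    for negative ES.

    Returns ``(es, running_sum, leading_edge)``.
    """
    genes = ranked.index.to_numpy()
    hit_mask = np.isin(genes, list(geneset))
    es, rs, idx = _es_core(ranked.to_numpy(dtype=float), hit_mask, weight)
    if es >= 0:
        le = [g for g, h in zip(genes[: idx + 1], hit_mask[: idx + 1]) if h]
    else:
        le = [g for g, h in zip(genes[idx:], hit_mask[idx:]) if h]
    return es, rs, le


def _distinct_label_permutations(groups: np.ndarray) -> int:
    labels, counts = np.unique(groups, return_counts=True)
    n = counts.sum()
    total = math.factorial(int(n))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permutation_nes(
    cm: CountMatrix | None,
    control: str,
    treatment: str,
    geneset,
    n_perm: int = 1000,
    mode: str = "auto",
    seed: int | None = None,
    metric: str = "wald_stat",
    weight: float = DEFAULT_WEIGHT,
    set_name: str = "geneset",
    ranked: pd.Series | None = None,
) -> GseaResult:
    """Permutation-normalized enrichment score for one gene set.

    The observed ranking comes from :func:`nb_wald_test` of treatment vs
    control.  Under phenotype permutation the sample labels are permuted
    (exhaustively when few enough, otherwise sampled) and the ranking
    recomputed; under gene-set permutation random same-size sets are
    drawn from the ranked list.

    NES = ES / mean(|permuted ES| of the same sign); p-value is the
    direction-consistent empirical tail with an add-one correction, so
    p >= 1/(n_used + 1).

    A precomputed ``ranked`` list may be supplied to skip the DE step;
    it suffices for gene-set permutation, while phenotype permutation
    still requires the count matrix.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if mode not in ("auto", "phenotype", "geneset"):
        raise ValueError(f"unknown permutation mode {mode!r}")

    rng = np.random.default_rng(seed)
    cm2 = cm.subset_groups([control, treatment]) if cm is not None else None
    if ranked is None:
        if cm2 is None:
            raise ValueError("either counts or a ranked list is required")
        de = nb_wald_test(cm2, control, treatment)
        ranked = rank_genes(de, metric=metric)
    members = [g for g in set(geneset) if g in ranked.index]
    if not members:
        raise ValueError("gene set is disjoint from the ranked list")
    es, _, leading = enrichment_score(ranked, members, weight)
    degenerate = len(members) == len(ranked)

    if cm2 is None:
        n_distinct = 0
        if mode == "phenotype":
            raise ValueError("phenotype permutation requires the count matrix")
    else:
        n_distinct = _distinct_label_permutations(cm2.groups.to_numpy())
    if mode == "auto":
        mode = "phenotype" if n_distinct >= MIN_PHENOTYPE_PERMS else "geneset"

    perm_es: list[float] = []
    if mode == "phenotype":
        samples = list(cm2.samples)
        groups = cm2.groups
        n_treat = int((groups == treatment).sum())
        all_assignments = list(itertools.combinations(range(len(samples)), n_treat))
        observed = tuple(
            i for i, s in enumerate(samples) if groups[s] == treatment
        )
        pool = [a for a in all_assignments if a != observed]
        if len(pool) > n_perm:
            pool = [pool[i] for i in rng.choice(len(pool), n_perm, replace=False)]
        for assignment in pool:
            labels = pd.Series(
                [treatment if i in assignment else control for i in range(len(samples))],
                index=samples,
            )
            perm_cm = CountMatrix(cm2.counts, labels, cm2.lengths)
            perm_de = nb_wald_test(perm_cm, control, treatment)
            perm_ranked = rank_genes(perm_de, metric=metric)
            e, _, _ = enrichment_score(perm_ranked, members, weight)
            perm_es.append(e)
    else:
        genes = ranked.index.to_numpy()
        metric_arr = ranked.to_numpy(dtype=float)
        k = len(members)
        member_pos = np.flatnonzero(np.isin(genes, members))
        for _ in range(n_perm):
            pos = rng.choice(len(genes), size=k, replace=False)
            mask = np.zeros(len(genes), dtype=bool)
            mask[pos] = True
            e, _, _ = _es_core(metric_arr, mask, weight)
            perm_es.append(e)
        del member_pos

    perm_arr = np.asarray(perm_es)
    same_sign = perm_arr[np.sign(perm_arr) == np.sign(es)] if es != 0 else perm_arr
    if same_sign.size == 0:
        nes = float("nan")
    else:
        nes = es / float(np.mean(np.abs(same_sign)))
    n_used = same_sign.size
    k_extreme = int((np.abs(same_sign) >= abs(es)).sum())
    pvalue = (1 + k_extreme) / (1 + n_used) if n_used else float("nan")

    return GseaResult(
        set_name=set_name,
        es=es,
        nes=nes,
        pvalue=pvalue,
        fdr=float("nan"),
        leading_edge=leading,
        n_permutations=len(perm_es),
        mode=mode,
        degenerate=degenerate,
    )


def gsea_fdr(
    results: list[GseaResult], perm_nes_pool: np.ndarray | None = None
) -> list[GseaResult]:
    """Benjamini-Hochberg-style FDR across a family of set results.

    With a pooled permutation-NES distribution available the standard
    NES-pooling estimate is used: q(set) = [fraction of pooled permuted
    NES at least as extreme, same sign] / [fraction of observed NES at
    least as extreme, same sign], capped at 1.  Without a pool, the
    empirical p-values are BH-adjusted instead.
    """
    obs = np.array([r.nes for r in results])
    if perm_nes_pool is not None and perm_nes_pool.size:
        for r in results:
            if np.isnan(r.nes):
                continue
            sign = np.sign(r.nes)
            pool_same = perm_nes_pool[np.sign(perm_nes_pool) == sign]
            obs_same = obs[np.sign(obs) == sign]
            num = (
                (np.abs(pool_same) >= abs(r.nes)).mean() if pool_same.size else 1.0
            )
            den = (np.abs(obs_same) >= abs(r.nes)).mean()
            r.fdr = min(1.0, num / den) if den > 0 else 1.0
    else:
        from .countmodel import bh_adjust

        padj = bh_adjust(np.array([r.pvalue for r in results]))
        for r, q in zip(results, padj):
            r.fdr = float(q)
    return results
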