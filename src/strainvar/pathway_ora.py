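"""Hypergeometric pathway over-representation with Benjamini-Hochberg
correction.

For each pathway with at least one candidate-gene overlap, the upper-tail
probability P(X >= k) of drawing k pathway genes in a candidate set of size n
from a universe of N genes containing K pathway genes is computed; p values
are BH-adjusted across the tested family and flagged significant at
adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N, K, n), stable in log space.

    N = universe size, K = pathway genes in universe, n = candidate set size,
    k = candidates in pathway.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    # sf is computed from logpmf internally; use survival at k-1
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    adjusted_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


@dataclass(frozen=True)
class ORAResult:
    pathway_id: str
    database: str
    k: int
    K: int
    n: int
    N: int
    p_raw: Optional[float]
    p_adj: Optional[float]
    candidate_genes: frozenset
    significant: bool
    tested: bool


def build_universe(pathways: Iterable, universe_mode: str = "annotated",
                   gene_models=None) -> set:
    """Gene universe for the test: either all genes annotated to >= 1 pathway
    ("annotated", default) or an explicit gene-model universe ("genemodels")."""
    if universe_mode == "annotated":
        universe: set = set()
        for pw in pathways:
            universe |= pw.genes
        return universe
    if universe_mode == "genemodels":
        if gene_models is None:
            raise ValueError("universe_mode='genemodels' requires gene models")
        return {gm.gene_id for gm in gene_models}
    raise ValueError(f"unknown universe_mode {universe_mode!r}")


def run_ora(
    candidates: set,
    pathways: Sequence,
    universe_mode: str = "annotated",
    gene_models=None,
    alpha: float = 0.05,
) -> list:
    """Test candidate genes against every pathway; BH across all pathways
    with >= 1 candidate overlap; results sorted by adjusted then raw p.

    Pathways with zero candidate overlap are reported untested (no p values).
    An empty universe or an empty candidate-universe intersection yields all
    results untested.
    """
    if not pathways:
        raise ValueError("no pathways to test")
    universe = build_universe(pathways, universe_mode, gene_models)
    cand = set(candidates) & universe

    prepared = []
    for pw in pathways:
        genes_in_universe = pw.genes & universe
        overlap = cand & genes_in_universe
        prepared.append((pw, genes_in_universe, overlap))

    tested = [t for t in prepared if t[2] and cand and universe]
    praw = [
        hypergeom_upper_tail(len(ov), len(cand), len(giu), len(universe))
        for _, giu, ov in tested
    ]
    padj = bh_adjust(praw)
    padj_by_id = {t[0].pathway_id: (pr, pa) for t, pr, pa in zip(tested, praw, padj)}

    results = []
    for pw, giu, ov in prepared:
        if pw.pathway_id in padj_by_id:
            pr, pa = padj_by_id[pw.pathway_id]
            results.append(
                ORAResult(
                    pathway_id=pw.pathway_id,
                    database=pw.database,
                    k=len(ov),
                    K=len(giu),
                    n=len(cand),
                    N=len(universe),
                    p_raw=pr,
                    p_adj=pa,
                    candidate_genes=frozenset(ov),
                    significant=pa < alpha,
                    tested=True,
                )
            )
        else:
            results.append(
                ORAResult(
                    pathway_id=pw.pathway_id,
                    database=pw.database,
                    k=0,
                    K=len(giu),
                    n=len(cand),
                    N=len(universe),
                    p_raw=None,
                    p_adj=None,
                    candidate_genes=frozenset(),
                    significant=False,
                    tested=False,
                )
            )
    results.sort(
        key=lambda r: (not r.tested, r.p_adj if r.p_adj is not None else 2.0,
                       r.p_raw if r.p_raw is not None else 2.0, r.pathway_id)
    )
    return results


def ora_table(results: Sequence[ORAResult]):
    """Results as a DataFrame mirroring a pathway-report table (name,
    database, corrected p, candidate genes)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pathway": r.pathway_id,
                "database": r.database,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "tested": r.tested,
                "candidate_genes": ",".join(sorted(r.candidate_genes)),
            }
            for r in results
        ]
    )
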