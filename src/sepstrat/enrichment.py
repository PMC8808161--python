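"""Single-sample gene-set enrichment (GSVA-style) and over-representation
analysis.

The per-sample enrichment statistic follows the gene-set variation analysis
construction: a Gaussian-kernel cumulative density estimate per gene across
samples, per-sample conversion to symmetric rank scores, and a weighted
Kolmogorov-Smirnov random walk down each sample's ranked gene list. The
score is the difference of the extreme deviations of the walk, which is
naturally bounded in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .de import bh_adjust

__all__ = [
    "gsva_scores",
    "classify_by_enrichment",
    "ora",
    "ora_batch",
    "OraResult",
]


def _kernel_cdf(x: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each entry against its own gene's
    cross-sample distribution. Bandwidth = per-gene SD * n^(-1/5)."""
    g, n = x.shape
    sd = x.std(axis=1, ddof=1)
    h = sd * n ** (-0.2)
    out = np.empty_like(x, dtype=float)
    for start in range(0, g, chunk):
        stop = min(start + chunk, g)
        xs = x[start:stop]
        hs = h[start:stop][:, None, None]
        diff = (xs[:, :, None] - xs[:, None, :]) / hs  # (chunk, n_eval, n_ref)
        out[start:stop] = ndtr(diff).mean(axis=2)
    return out


def gsva_scores(
    expr: pd.DataFrame, gene_sets: dict[str, list[str]], tau: float = 1.0
) -> pd.DataFrame:
    """Per-sample enrichment scores (samples x gene sets), each in [-1, 1].

    ``expr`` is an expression matrix (genes x samples, any monotone scale);
    set genes absent from the matrix are dropped with a warning, and a set
    with fewer than 2 present genes is an error. Genes constant across all
    samples are excluded from the ranking.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"excluded {int(constant.sum())} constant genes from enrichment scoring")
        expr = expr.loc[~constant]
        x = x[~constant]
    gene_index = {g: i for i, g in enumerate(expr.index)}

    members: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in gene_index]
        absent = len(genes) - len(present)
        if absent:
            warnings.warn(f"gene set {name!r}: {absent} genes absent from the matrix")
        if len(present) < 2:
            raise ValueError(f"gene set {name!r} has fewer than 2 genes in the matrix")
        members[name] = np.array([gene_index[g] for g in present])

    z = _kernel_cdf(x)
    g, n = z.shape
    # per sample: rank genes by z descending (rank 1 = highest statistic)
    order = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(g)
    for j in range(n):
        ranks[order[:, j], j] = rows + 1
    # symmetric rank score, largest magnitude at both extremes of the list
    weight = np.abs(g / 2.0 - ranks + 0.5) ** tau

    scores = np.zeros((n, len(members)))
    for si, (name, idx) in enumerate(members.items()):
        in_set = np.zeros(g, dtype=bool)
        in_set[idx] = True
        decrement = 1.0 / (g - len(idx))
        for j in range(n):
            oj = order[:, j]
            set_mask = in_set[oj]
            w = np.where(set_mask, weight[oj, j], 0.0)
            wsum = w.sum()
            steps = np.where(set_mask, w / wsum, -decrement)
            walk = np.cumsum(steps)
            scores[j, si] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return pd.DataFrame(scores, index=expr.columns, columns=list(members))


def classify_by_enrichment(scores: pd.DataFrame):
    """Assign each sample the signature with the highest enrichment score.

    Returns a frame with the label, the top-minus-second margin, and a tie
    flag; exact ties break deterministically toward the first signature name
    in column order.
    """
    if scores.shape[1] < 2:
        raise ValueError("need scores for at least 2 signatures")
    scores = scores[sorted(scores.columns)]
    vals = scores.to_numpy()
    best = np.argmax(vals, axis=1)  # first maximum wins: ties break by name order
    sorted_vals = np.sort(vals, axis=1)
    margin = sorted_vals[:, -1] - sorted_vals[:, -2]
    tied = margin == 0
    return pd.DataFrame(
        {
            "label": scores.columns[best],
            "margin": margin,
            "tie": tied,
        },
        index=scores.index,
    )


@dataclass
class OraResult:
    name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p: float
    enrichment_ratio: float
    adj_p: float = np.nan


def ora(gene_list, gene_set, universe, name: str = "set") -> OraResult:
    """Hypergeometric over-representation test (upper tail, P(X >= overlap))."""
    universe = set(universe)
    gene_list = set(gene_list)
    gene_set = set(gene_set)
    outside = (gene_list | gene_set) - universe
    if outside:
        raise ValueError(f"ids outside the universe: {sorted(outside)[:5]}")
    m = len(universe)
    k = len(gene_list & gene_set)
    p = float(stats.hypergeom.sf(k - 1, m, len(gene_set), len(gene_list)))
    expected = len(gene_set) * len(gene_list) / m if m else np.nan
    ratio = k / expected if expected else np.nan
    return OraResult(
        name=name,
        overlap=k,
        list_size=len(gene_list),
        set_size=len(gene_set),
        universe_size=m,
        p=min(p, 1.0),
        enrichment_ratio=float(ratio),
    )


def ora_batch(gene_list, gene_sets: dict[str, list[str]], universe) -> list[OraResult]:
    """ORA over a gene-set collection with BH adjustment, sorted by adj_p."""
    if not gene_sets:
        raise ValueError("need at least one gene set")
    names = list(gene_sets)
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene-set names")
    results = [ora(gene_list, genes, universe, name=name) for name, genes in gene_sets.items()]
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    results.sort(key=lambda r: (r.adj_p, r.p, r.name))
    return results


def ora_table(results: list[OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "overlap": r.overlap,
                "list_size": r.list_size,
                "set_size": r.set_size,
                "universe_size": r.universe_size,
                "enrichment_ratio": r.enrichment_ratio,
                "pvalue": r.p,
                "padj": r.adj_p,
            }
            for r in results
        ]
    )
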