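"""Count normalization, severity grouping, and negative-binomial differential
expression.

The DE test is a deliberately plain NB Wald test: per-gene method-of-moments
dispersion shared between the two groups, group means fit by maximum
likelihood with library-size offsets, and a normal reference for the Wald
statistic. There is no dispersion shrinkage, outlier replacement, or
independent filtering — the test is self-contained and adequate for
recovering planted effects at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "normalize_log2",
    "assign_severity",
    "nb_wald_de",
    "bh_adjust",
    "filter_de",
    "DEResult",
]

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
MEAN_FLOOR = 1e-6

DE_COLUMNS = ["gene_id", "log2fc", "se", "stat", "pvalue", "padj"]


@dataclass
class DEResult:
    """A differential-expression table plus the genes that could not be tested."""

    table: pd.DataFrame
    dropped: list[str] = field(default_factory=list)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample contribute to
    the per-sample median of count/geometric-mean ratios.
    """
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in all samples; cannot normalize")
    kp = k[positive]
    geomean = np.exp(np.log(kp).mean(axis=1, keepdims=True))
    s = np.median(kp / geomean, axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_log2(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), genes x samples."""
    if not counts.columns.equals(factors.index):
        factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    x = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    return pd.DataFrame(np.log2(x + pseudocount), index=counts.index, columns=counts.columns)


def assign_severity(sofa24) -> str | None:
    """SOFA-based severity stratum: High >=5, Intermediate >=2 and <5, Low <2.

    Missing scores return ``None`` (excluded from severity analyses).
    """
    if sofa24 is None or (isinstance(sofa24, float) and np.isnan(sofa24)):
        return None
    if not 0 <= sofa24 <= 24:
        raise ValueError(f"SOFA score out of range [0, 24]: {sofa24}")
    if sofa24 >= 5:
        return "High"
    if sofa24 >= 2:
        return "Intermediate"
    return "Low"


def _nb_ml_mean(y: np.ndarray, s: np.ndarray, phi: np.ndarray, n_iter: int = 30):
    """Vectorized Newton solve for per-gene NB means with size-factor offsets.

    Maximizes the NB log-likelihood in eta = log(mu) with known dispersion
    phi, mean model m_j = s_j * exp(eta). Returns (mu, fisher_info) where the
    information is in eta units.
    """
    tot = y.sum(axis=1)
    mu = np.maximum(tot / s.sum(), MEAN_FLOOR)
    eta = np.log(mu)
    phi_col = phi[:, None]
    for _ in range(n_iter):
        m = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + phi_col * m
        score = ((y - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(eta)
    m = s[None, :] * mu[:, None]
    info = (m / (1.0 + phi_col * m)).sum(axis=1)
    return np.maximum(mu, MEAN_FLOOR), np.maximum(info, 1e-12)


def _moment_dispersion(y: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Method-of-moments dispersion contribution from one group.

    On normalized counts z = y/s: Var(z) ~= mu * mean(1/s) + phi * mu^2,
    so phi ~= (var(z) - mu * mean(1/s)) / mu^2.
    """
    z = y / s[None, :]
    mu = z.mean(axis=1)
    var = z.var(axis=1, ddof=1)
    inv_s = float(np.mean(1.0 / s))
    mu_safe = np.maximum(mu, MEAN_FLOOR)
    return (var - mu * inv_s) / mu_safe**2, mu


def nb_wald_de(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
) -> DEResult:
    """Two-group NB Wald differential expression (group A over group B).

    Genes with all-zero counts in both groups are dropped and reported in
    ``DEResult.dropped``. Adjusted p-values are Benjamini-Hochberg over the
    tested genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if factors is None:
        factors = size_factors(counts[group_a + group_b])
    ya = counts[group_a].to_numpy(dtype=float)
    yb = counts[group_b].to_numpy(dtype=float)
    sa = factors.reindex(group_a).to_numpy(dtype=float)
    sb = factors.reindex(group_b).to_numpy(dtype=float)

    keep = (ya.sum(axis=1) + yb.sum(axis=1)) > 0
    dropped = list(counts.index[~keep])
    ya, yb = ya[keep], yb[keep]

    phi_a, _ = _moment_dispersion(ya, sa)
    phi_b, _ = _moment_dispersion(yb, sb)
    na, nb_ = len(group_a), len(group_b)
    phi = ((na - 1) * phi_a + (nb_ - 1) * phi_b) / (na + nb_ - 2)
    phi = np.maximum(phi, DISPERSION_FLOOR)

    mu_a, info_a = _nb_ml_mean(ya, sa, phi)
    mu_b, info_b = _nb_ml_mean(yb, sb, phi)

    log2fc = np.log2(mu_a / mu_b)
    se = np.sqrt(1.0 / info_a + 1.0 / info_b) / LN2
    stat = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {
            "gene_id": counts.index[keep],
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        }
    ).set_index("gene_id", drop=False)
    return DEResult(table=table, dropped=dropped)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def filter_de(
    det: pd.DataFrame,
    min_fold: float = 1.25,
    max_adj_p: float = 0.05,
    direction: str = "both",
) -> list[str]:
    """Genes passing inclusive fold-change and adjusted-p thresholds.

    ``min_fold`` is on the linear scale (e.g. 1.25); up means fold >= min_fold,
    down means fold <= 1/min_fold.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if direction not in {"up", "down", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    fold = np.power(2.0, det["log2fc"].to_numpy())
    sig = det["padj"].to_numpy() <= max_adj_p
    up = fold >= min_fold
    down = fold <= 1.0 / min_fold
    if direction == "up":
        keep = sig & up
    elif direction == "down":
        keep = sig & down
    else:
        keep = sig & (up | down)
    return list(det["gene_id"].to_numpy()[keep])
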