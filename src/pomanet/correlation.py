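"""Spearman inverse-correlation screening of outlier miRNA × outlier gene
pairs across paired samples.

A miRNA represses its targets, so a genuine regulatory interaction should
show up as a *negative* monotone association between the miRNA's and the
target's expression across matched specimens.  Every combination of outlier
miRNA and outlier gene is tested with the tie-corrected Spearman rank
correlation; a pair is retained iff rho <= rho_cutoff (default −0.6,
inclusive) and the two-sided p-value < p_cutoff (default 0.05, uncorrected —
an optional BH filter is available downstream but is off by default).

p-values use the t approximation t = rho·sqrt((n−2)/(1−rho²)) on n−2 df;
for n <= 9 an exact rank-permutation p-value is available.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, SampleAnnotation, paired_samples
from .lsoss import OutlierResult

logger = logging.getLogger(__name__)

EXACT_N_MAX = 9
RHO_TOL = 1e-9  # absolute tolerance on the rho cutoff comparison

SAMPLE_MODES = ("all-paired", "case-only")


def spearman(x, y, method: str = "approx") -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided p-value.

    ``method``: "approx" (t approximation, any n), "exact" (full rank
    permutation, n <= 9), or "auto" (exact when feasible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("spearman requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "approx"
    if method == "approx":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        rho = float(stats.spearmanr(x, y).statistic)
        return rho, spearman_exact_p(x, y)
    raise ValueError(f"unknown method {method!r}")


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p-value: fraction of the n! rank
    permutations of y whose |rho| >= |rho_obs| (within round-off)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > EXACT_N_MAX:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    sy = ry.std()
    rho_obs = abs(float(np.mean(zx * (ry - ry.mean()) / sy)))
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n); permuting midranks preserves tie pattern
    rho_all = np.abs((ry_perm - ry.mean()) @ zx) / (n * sy)
    return float(np.mean(rho_all >= rho_obs - 1e-12))


def passes_cutoffs(rho: float, p: float, rho_cutoff: float, p_cutoff: float) -> bool:
    """Retention rule: rho at or below the (negative) cutoff, p strictly below."""
    return (rho <= rho_cutoff + RHO_TOL) and (p < p_cutoff)


def _rank_zscores(X: np.ndarray):
    """Row-wise midranks standardized to zero mean / unit variance.

    Returns (Z, keep) where constant rows are flagged out of ``keep``.
    """
    R = stats.rankdata(X, axis=1)
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    sd[sd == 0] = 1.0
    return (R - mu) / sd, keep


def screen_pairs(
    mirna_outliers: list[OutlierResult],
    gene_outliers: list[OutlierResult],
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    ann: SampleAnnotation,
    rho_cutoff: float = -0.6,
    p_cutoff: float = 0.05,
    sample_mode: str = "all-paired",
) -> pd.DataFrame:
    """Test all outlier-miRNA × outlier-gene pairs for inverse correlation.

    Returns the retained pairs as a DataFrame ``mirna_id, gene_id, rho,
    p_value, n_samples`` sorted by rho ascending (strongest anticorrelation
    first).  Accounting is attached in ``.attrs``: ``n_tested`` (pairs
    actually correlated), ``n_skipped`` (pairs lost to constant vectors),
    ``n_samples``.
    """
    if sample_mode not in SAMPLE_MODES:
        raise ValueError(f"sample_mode must be one of {SAMPLE_MODES}")
    pairs = paired_samples(ann, mirna_expr.sample_ids, gene_expr.sample_ids)
    if sample_mode == "case-only":
        pairs = pairs[pairs["class_label"] == "case"]
    n = len(pairs)
    if n == 0:
        raise ValueError("no shared paired samples between the two matrices")
    if n < 4:
        raise ValueError(f"only {n} paired samples; need >= 4 for correlation")

    m_ids = [r.feature_id for r in mirna_outliers]
    g_ids = [r.feature_id for r in gene_outliers]
    empty = pd.DataFrame(columns=["mirna_id", "gene_id", "rho", "p_value", "n_samples"])
    empty.attrs.update({"n_tested": 0, "n_skipped": 0, "n_samples": n})
    if not m_ids or not g_ids:
        return empty

    Xm = mirna_expr.data.loc[m_ids, list(pairs["mirna_sample"])].to_numpy(dtype=float)
    Xg = gene_expr.data.loc[g_ids, list(pairs["gene_sample"])].to_numpy(dtype=float)
    Zm, keep_m = _rank_zscores(Xm)
    Zg, keep_g = _rank_zscores(Xg)
    n_skipped = (np.sum(~keep_m) * len(g_ids)
                 + np.sum(~keep_g) * len(m_ids)
                 - np.sum(~keep_m) * np.sum(~keep_g))
    if n_skipped:
        logger.info("screen_pairs: %d pairs skipped (constant vectors)", n_skipped)

    rho = (Zm @ Zg.T) / n
    np.clip(rho, -1.0, 1.0, out=rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 1e-300))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval[np.abs(rho) >= 1.0 - 1e-12] = 0.0

    retain = (
        (rho <= rho_cutoff + RHO_TOL)
        & (pval < p_cutoff)
        & keep_m[:, None]
        & keep_g[None, :]
    )
    ii, jj = np.nonzero(retain)
    out = pd.DataFrame(
        {
            "mirna_id": [m_ids[i] for i in ii],
            "gene_id": [g_ids[j] for j in jj],
            "rho": rho[ii, jj],
            "p_value": pval[ii, jj],
            "n_samples": n,
        }
    )
    out = out.sort_values(
        ["rho", "mirna_id", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    n_tested = int(np.sum(keep_m)) * int(np.sum(keep_g))
    out.attrs.update(
        {"n_tested": n_tested, "n_skipped": int(n_skipped), "n_samples": n}
    )
    logger.info(
        "screen_pairs: tested %d pairs over %d samples, retained %d "
        "(rho <= %.3g, p < %.3g)",
        n_tested, n, len(out), rho_cutoff, p_cutoff,
    )
    return out


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
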