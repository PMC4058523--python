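"""Outlier differential expression via the least-sum-of-ordered-subset-squares
t-statistic (LSOSS).

Classical two-sample statistics lose power when only a *subset* of case
samples express a feature aberrantly — the typical situation for oncogene
activation in heterogeneous tumors.  LSOSS addresses this regime directly:

1. sort the case-class values of a feature ascending;
2. split the sorted vector into two contiguous subsets at the index k that
   minimizes the summed within-subset sum of squared deviations (a 1-D
   2-segment least-squares segmentation);
3. call the subset whose mean lies farther from the control mean the outlier
   subset O (so down-regulated outliers are detected symmetrically); and
4. form a pooled-variance t-like contrast between O and the controls:

       t_L = (mean(O) − mean(control)) / sqrt(s_p² (1/|O| + 1/n_ctrl)),

   with s_p² pooled over O and the controls on |O| + n_ctrl − 2 df.

Because the split is chosen to maximize homogeneity, the null distribution of
t_L is not a t distribution; significance is assigned by whole-vector
class-label permutation, with the same permutations reused across features
(valid for Benjamini–Hochberg correction across the feature family).

Numerical guards: the pooled SD is floored at ``eps × median pooled SD over
features`` (eps = 0.01) so near-constant features cannot produce infinities;
if the floor is still zero (e.g. a single-feature call on constant data) a
±1e6 sentinel replaces an infinite statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

SP_FLOOR_EPS = 0.01
T_SENTINEL = 1.0e6


@dataclass
class OutlierResult:
    """Per-feature LSOSS outcome.

    ``outlier_subset`` holds the case sample ids of the contiguous block of
    rank-ordered case values selected as outliers (positional indices when no
    sample ids are supplied).  ``direction`` is the sign of
    mean(outlier subset) − mean(control).  ``degenerate`` flags features where
    both candidate subsets are equidistant from the control mean (e.g. a
    constant feature), making the direction arbitrary.
    """

    feature_id: str
    statistic: float
    split_index: int
    outlier_subset: tuple
    direction: str  # "up" | "down"
    p_value: float
    q_value: float
    degenerate: bool = False


def lsoss_split(values) -> tuple[int, float]:
    """Optimal contiguous 2-subset split of the sorted values.

    Returns ``(k_star, cost)`` where the first subset is the k_star smallest
    values (1 ≤ k_star < n) and cost is the minimal summed within-subset sum
    of squared deviations.  Ties are broken toward the smallest k.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("lsoss_split requires a 1-D vector with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("lsoss_split requires finite values")
    costs = _split_costs(np.sort(x)[None, :])[0]
    k = int(np.argmin(costs)) + 1  # np.argmin returns the first minimum
    cost = float(costs[k - 1])
    if np.ptp(x) == 0:
        logger.debug("lsoss_split: constant vector (degenerate split)")
    return k, cost


def _split_costs(xs: np.ndarray) -> np.ndarray:
    """Within-subset SS cost of every split, rows = features, xs sorted."""
    n = xs.shape[1]
    ks = np.arange(1, n)
    c1 = np.cumsum(xs, axis=1)
    c2 = np.cumsum(xs * xs, axis=1)
    ss_low = c2[:, :-1] - c1[:, :-1] ** 2 / ks
    s1_high = c1[:, -1:] - c1[:, :-1]
    s2_high = c2[:, -1:] - c2[:, :-1]
    ss_high = s2_high - s1_high ** 2 / (n - ks)
    # clip tiny negative round-off
    return np.maximum(ss_low, 0.0) + np.maximum(ss_high, 0.0)


def _lsoss_matrix(case: np.ndarray, ctrl: np.ndarray):
    """Vectorized LSOSS over rows (features).

    Returns ``(t, k, upper, degenerate)``: the statistic, split index, whether
    the outlier subset is the upper block, and the equidistant-subsets flag.
    """
    nf, n = case.shape
    nc = ctrl.shape[1]
    if n < 2 or nc < 2:
        raise ValueError("LSOSS requires >= 2 case and >= 2 control samples")
    xs = np.sort(case, axis=1)
    costs = _split_costs(xs)
    k = np.argmin(costs, axis=1) + 1  # first minimum -> smallest k
    rows = np.arange(nf)
    c1 = np.cumsum(xs, axis=1)
    c2 = np.cumsum(xs * xs, axis=1)
    s1_low = c1[rows, k - 1]
    s2_low = c2[rows, k - 1]
    mean_low = s1_low / k
    mean_high = (c1[:, -1] - s1_low) / (n - k)
    ss_low = np.maximum(s2_low - s1_low ** 2 / k, 0.0)
    ss_high = np.maximum(
        (c2[:, -1] - s2_low) - (c1[:, -1] - s1_low) ** 2 / (n - k), 0.0
    )
    mean_ctrl = ctrl.mean(axis=1)
    ss_ctrl = ((ctrl - mean_ctrl[:, None]) ** 2).sum(axis=1)

    d_low = np.abs(mean_low - mean_ctrl)
    d_high = np.abs(mean_high - mean_ctrl)
    upper = d_high >= d_low  # tie -> upper block
    degenerate = d_high == d_low

    n_out = np.where(upper, n - k, k)
    mean_out = np.where(upper, mean_high, mean_low)
    ss_out = np.where(upper, ss_high, ss_low)

    df = n_out + nc - 2
    sp = np.sqrt((ss_out + ss_ctrl) / df)
    floor = SP_FLOOR_EPS * np.median(sp)
    sp_eff = np.maximum(sp, floor)
    diff = mean_out - mean_ctrl
    se = sp_eff * np.sqrt(1.0 / n_out + 1.0 / nc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff != 0, np.sign(diff) * T_SENTINEL, 0.0))
    return t, k, upper, degenerate


def lsoss_statistic(case_values, control_values, case_ids=None,
                    feature_id: str = "") -> OutlierResult:
    """LSOSS statistic for a single feature (no permutation p-value).

    ``case_ids``, when given, labels the case samples so the outlier subset is
    reported as sample ids; otherwise positional indices are reported.
    """
    case = np.asarray(case_values, dtype=float)[None, :]
    ctrl = np.asarray(control_values, dtype=float)[None, :]
    t, k, upper, degen = _lsoss_matrix(case, ctrl)
    subset = _subset_members(case[0], int(k[0]), bool(upper[0]), case_ids)
    return OutlierResult(
        feature_id=feature_id,
        statistic=float(t[0]),
        split_index=int(k[0]),
        outlier_subset=subset,
        direction="up" if t[0] > 0 or (t[0] == 0 and upper[0]) else "down",
        p_value=float("nan"),
        q_value=float("nan"),
        degenerate=bool(degen[0]),
    )


def _subset_members(case_row: np.ndarray, k: int, upper: bool, case_ids):
    order = np.argsort(case_row, kind="stable")
    block = order[k:] if upper else order[:k]
    if case_ids is None:
        return tuple(int(i) for i in sorted(block))
    ids = np.asarray(case_ids)
    return tuple(sorted(str(s) for s in ids[block]))


def lsoss_scan(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    n_perm: int = 999,
    seed: int = 0,
) -> list[OutlierResult]:
    """Per-feature LSOSS scan with class-label permutation p-values.

    p = (1 + #{perms with |t_perm| >= |t_obs|}) / (1 + n_perm), the same
    label permutations applied to every feature; q by Benjamini–Hochberg.
    With ``n_perm == 0`` the statistics are returned with missing p/q.
    """
    labels = ann.labels_for(m.sample_ids)
    case_idx = np.flatnonzero(labels == "case")
    ctrl_idx = np.flatnonzero(labels == "control")
    X = m.values
    t_obs, k_obs, upper_obs, degen_obs = _lsoss_matrix(X[:, case_idx], X[:, ctrl_idx])

    n_samples = X.shape[1]
    n_case = case_idx.size
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        abs_obs = np.abs(t_obs)
        counts = np.zeros(X.shape[0], dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(n_samples)
            t_p, _, _, _ = _lsoss_matrix(X[:, perm[:n_case]], X[:, perm[n_case:]])
            counts += np.abs(t_p) >= abs_obs
        p = (1.0 + counts) / (1.0 + n_perm)
        q = multipletests(p, method="fdr_bh")[1]
    else:
        p = np.full(X.shape[0], np.nan)
        q = np.full(X.shape[0], np.nan)

    sample_ids = np.asarray(m.sample_ids)
    case_ids = sample_ids[case_idx]
    results = []
    for i, fid in enumerate(m.feature_ids):
        subset = _subset_members(
            X[i, case_idx], int(k_obs[i]), bool(upper_obs[i]), case_ids
        )
        results.append(
            OutlierResult(
                feature_id=fid,
                statistic=float(t_obs[i]),
                split_index=int(k_obs[i]),
                outlier_subset=subset,
                direction="up" if t_obs[i] > 0 or (t_obs[i] == 0 and upper_obs[i])
                else "down",
                p_value=float(p[i]),
                q_value=float(q[i]),
                degenerate=bool(degen_obs[i]),
            )
        )
    return results


def select_outliers(
    results: list[OutlierResult],
    q_cutoff: float | None = None,
    top_n: int | None = None,
    top_frac: float | None = 0.5,
) -> list[OutlierResult]:
    """Features carried forward to correlation screening.

    The outlier stage is a recall-oriented screen: specificity is supplied
    downstream by the inverse-correlation test and the reference-network
    intersection, so the default keeps the top half of features by |t_L|
    (``top_frac = 0.5``).  Alternatives: an absolute ``top_n``, or an FDR
    gate ``q < q_cutoff`` (BH over the permutation p-values) — note the
    latter has little resolution in small unbalanced designs, where
    subset-shift permutation p-values are conservative.  Precedence:
    top_n > q_cutoff > top_frac.
    """
    ranked = sorted(results, key=lambda r: (-abs(r.statistic), r.feature_id))
    if top_n is not None:
        return ranked[: int(top_n)]
    if q_cutoff is not None:
        return [r for r in ranked if np.isfinite(r.q_value) and r.q_value < q_cutoff]
    if top_frac is not None:
        if not 0 < top_frac <= 1:
            raise ValueError("top_frac must be in (0, 1]")
        return ranked[: int(round(top_frac * len(ranked)))]
    return ranked


def outlier_table(results: list[OutlierResult]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": r.feature_id,
            "statistic": r.statistic,
            "split_index": r.split_index,
            "outlier_subset": ",".join(str(s) for s in r.outlier_subset),
            "direction": r.direction,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "degenerate": int(r.degenerate),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "statistic", "split_index", "outlier_subset",
            "direction", "p_value", "q_value", "degenerate",
        ],
    )


def write_outlier_table(results: list[OutlierResult], path) -> None:
    outlier_table(results).to_csv(path, sep="\t", index=False)


def read_outlier_table(path) -> list[OutlierResult]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "outlier_subset": str})
    out = []
    for _, row in df.iterrows():
        subset = tuple(
            s for s in str(row["outlier_subset"]).split(",") if s and s != "nan"
        )
        out.append(
            OutlierResult(
                feature_id=str(row["feature_id"]),
                statistic=float(row["statistic"]),
                split_index=int(row["split_index"]),
                outlier_subset=subset,
                direction=str(row["direction"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                degenerate=bool(row.get("degenerate", 0)),
            )
        )
    return out
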