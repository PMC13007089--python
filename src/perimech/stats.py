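"""Nonparametric group comparison and robustness statistics.

Kruskal-Wallis across the three diagnostic groups, two-sided
Mann-Whitney U for pairwise contrasts, Benjamini-Hochberg step-up FDR
across all contrasts x metrics jointly, Cliff's delta and the
Hodges-Lehmann shift as effect sizes, within-group case-resampling
bootstrap for the ordering of the small WHO II cohort, and Spearman
associations between topology metrics and rim-shell modulus contrasts.

Conventions: U is the statistic of the first-listed group (count of
x > y pairs plus half-ties), so Cliff's delta — oriented as the second
group relative to the first — is delta = 1 - 2U/(n1*n2).  Hodges-Lehmann
is the median of all pairwise differences x_i - y_j (first minus second).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_ORDER = ("WHO_I", "WHO_II", "GBM")

#: effect-size interpretation bands for |Cliff's delta|
CLIFFS_BANDS = ((0.147, "negligible"), (0.33, "small"), (0.474, "medium"), (np.inf, "large"))

#: metrics entering the pairwise comparison family (m = 7 metrics x 3 contrasts = 21)
COMPARISON_METRICS = ("radial_auc", "branch_point_density", "skel_length_density",
                      "tail_auc", "entropy_bits", "ipr", "convexity")
#: full set tested at the Kruskal-Wallis stage
KW_METRICS = ("tail_auc", "frac_above_020", "frac_above_050", "entropy_bits", "ipr",
              "convexity", "branch_point_density", "skel_length_density", "radial_auc")


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected H and chi-square p (k-1 df); identical values -> (0, 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis: need >=2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def mann_whitney_pair(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of the FIRST group.

    Exact when n1*n2 <= 400 and the pooled sample has no ties, else the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_pair: empty group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x, y) -> tuple[float, str]:
    """Cliff's delta oriented as the second group relative to the first:
    delta = [#(y > x) - #(y < x)] / (n1*n2) = 1 - 2U/(n1*n2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    U, _ = mann_whitney_pair(x, y)
    delta = 1.0 - 2.0 * U / (x.size * y.size)
    return float(delta), cliffs_band(delta)


def cliffs_band(delta: float) -> str:
    mag = abs(delta)
    for hi, label in CLIFFS_BANDS:
        if mag < hi or hi is np.inf:
            return label
    return "large"


def cliffs_delta_from_u(U: float, n1: int, n2: int) -> float:
    """Effect size recovered from a reported U statistic and group sizes."""
    return 1.0 - 2.0 * U / (n1 * n2)


def hodges_lehmann(x, y) -> float:
    """Median of all n1*n2 pairwise differences x_i - y_j (first minus second)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("hodges_lehmann: empty group")
    return float(np.median(x[:, None] - y[None, :]))


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, returned in input order.

    ``m`` is the size of the hypothesis family; it may exceed the number
    of p-values supplied (the remaining hypotheses are assumed to rank
    below every supplied one, i.e. their p-values are larger).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class ComparisonResult:
    metric: str
    H: float
    p_kw: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_groups(table: pd.DataFrame, metrics=COMPARISON_METRICS,
                   kw_metrics=KW_METRICS, alpha: float = 0.05,
                   group_col: str = "group", q_threshold: float = 0.05
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full group comparison: Kruskal-Wallis per metric, all pairwise
    Mann-Whitney rows with effect sizes, BH-FDR across the whole
    pairwise family (m = len(metrics) x 3 contrasts).

    Pairwise significance is gated on the omnibus test (KW p < alpha)
    AND q < q_threshold; non-gated rows are still reported and flagged.
    Returns (kruskal table, pairwise table).
    """
    groups = {g: table[table[group_col] == g] for g in GROUP_ORDER}
    kw_rows = []
    for metric in kw_metrics:
        vals = [groups[g][metric].dropna().to_numpy() for g in GROUP_ORDER]
        H, p = kruskal_wallis(vals)
        kw_rows.append({"metric": metric, "H": H, "p_kw": p,
                        **{f"median_{g}": float(np.median(v)) if len(v) else np.nan
                           for g, v in zip(GROUP_ORDER, vals)}})
    kw = pd.DataFrame(kw_rows)

    contrasts = [("WHO_I", "WHO_II"), ("WHO_I", "GBM"), ("WHO_II", "GBM")]
    m_family = len(metrics) * len(contrasts)
    pw_rows = []
    for metric in metrics:
        p_kw = float(kw.loc[kw["metric"] == metric, "p_kw"].iloc[0]) \
            if metric in set(kw["metric"]) else np.nan
        for g1, g2 in contrasts:
            x = groups[g1][metric].dropna().to_numpy()
            y = groups[g2][metric].dropna().to_numpy()
            U, p = mann_whitney_pair(x, y)
            delta, band = cliffs_delta(x, y)
            pw_rows.append({
                "metric": metric, "group1": g1, "group2": g2,
                "U": U, "p": p, "cliffs_delta": delta, "delta_band": band,
                "hl_shift": hodges_lehmann(x, y),
                "p_kw": p_kw, "gated": bool(np.isfinite(p_kw) and p_kw < alpha),
            })
    pw = pd.DataFrame(pw_rows)
    pw["q"] = bh_fdr(pw["p"].to_numpy(), m=m_family)
    pw["significant"] = pw["gated"] & (pw["q"] < q_threshold)
    return kw, pw


@dataclass
class BootstrapResult:
    metric: str
    p_intermediate: float
    ci_who2_minus_who1: tuple[float, float]
    ci_gbm_minus_who2: tuple[float, float]
    n_iter: int
    seed: int


def bootstrap_ordering(values_by_group: dict, metric: str = "",
                       n_iter: int = 10_000, seed: int = 0) -> BootstrapResult:
    """Within-group case-resampling bootstrap of group medians.

    Reports the probability that the WHO II median lies strictly between
    the WHO I and GBM medians in either consistent direction, plus 95%
    percentile CIs for the (WHO II - WHO I) and (GBM - WHO II) median
    differences.
    """
    rng = np.random.default_rng(seed)
    samples = {g: np.asarray(values_by_group[g], dtype=float) for g in GROUP_ORDER}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"bootstrap_ordering: group {g} has fewer than 2 cases")
    meds = np.empty((n_iter, 3))
    for j, g in enumerate(GROUP_ORDER):
        v = samples[g]
        idx = rng.integers(0, v.size, size=(n_iter, v.size))
        meds[:, j] = np.median(v[idx], axis=1)
    m1, m2, m3 = meds[:, 0], meds[:, 1], meds[:, 2]
    intermediate = ((m1 < m2) & (m2 < m3)) | ((m1 > m2) & (m2 > m3))
    d21 = m2 - m1
    d32 = m3 - m2
    return BootstrapResult(
        metric=metric,
        p_intermediate=float(intermediate.mean()),
        ci_who2_minus_who1=(float(np.percentile(d21, 2.5)), float(np.percentile(d21, 97.5))),
        ci_gbm_minus_who2=(float(np.percentile(d32, 2.5)), float(np.percentile(d32, 97.5))),
        n_iter=n_iter, seed=seed,
    )


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho and two-sided p; constant input -> NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2 or np.unique(y[np.isfinite(y)]).size < 2:
        warnings.warn("spearman: constant column, correlation undefined")
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y, nan_policy="omit")
    return float(rho), float(p)


def association_suite(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman associations of the rim-shell contrasts with the topology
    metrics, plus size-bias checks of radial-AUC vs tumor-size proxies."""
    if len(table) < 4:
        raise ValueError("association_suite: need >= 4 cases")
    pairs = [(c, m) for c in ("delta_g_prime", "delta_tan_delta")
             for m in ("radial_auc", "skel_length_density", "branch_point_density")]
    pairs += [("radial_auc", "shell_voxel_count"), ("radial_auc", "tumor_slice_area_mm2")]
    rows = []
    for a, b in pairs:
        rho, p = spearman(table[a].to_numpy(), table[b].to_numpy())
        rows.append({"x": a, "y": b, "rho": rho, "p": p, "n": len(table)})
    return pd.DataFrame(rows)
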