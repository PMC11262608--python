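"""Correlation of subject-level oculomotor metrics with clinical covariates.

Spearman rank correlation uses average ranks for ties; its two-sided
p-value comes from the exact permutation distribution for n <= 10 (all n!
pairings enumerated) and from the t approximation
``t = rho * sqrt((n-2) / (1 - rho^2))`` for larger n.  Pearson r uses the
standard two-sided t test.  Grids are computed over pairwise-complete
observations (no listwise deletion) and are *not* corrected for multiple
testing; reports carry an explicit uncorrected-p caveat together with the
number of tests performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "rank_correlation",
    "product_moment_correlation",
    "correlation_grid",
    "cohort_summary",
    "CohortSummary",
    "render_report",
    "effect_size_label",
]

_EXACT_MAX_N = 10
_perm_cache: dict[int, np.ndarray] = {}


def _permutation_array(n: int) -> np.ndarray:
    """All permutations of range(n), shape (n!, n), built incrementally."""
    if n in _perm_cache:
        return _perm_cache[n]
    perms = np.zeros((1, 1), dtype=np.int8)
    for m in range(2, n + 1):
        k = perms.shape[0]
        blocks = []
        for pos in range(m):
            block = np.empty((k, m), dtype=np.int8)
            block[:, :pos] = perms[:, :pos]
            block[:, pos] = m - 1
            block[:, pos + 1 :] = perms[:, pos:]
            blocks.append(block)
        perms = np.concatenate(blocks, axis=0)
    if n <= _EXACT_MAX_N:
        _perm_cache[n] = perms
    return perms


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    covariate: str
    method: str  # spearman | pearson
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    significant: Optional[bool] = None
    status: str = "ok"  # ok | insufficient_data | undefined


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided p from the exhaustive permutation distribution of the
    rank cross-product (equivalent to enumerating rho; ties supported by
    permuting the actual average ranks)."""
    n = len(rx)
    perms = _permutation_array(n)
    s_obs = float(rx @ ry)
    center = n * rx.mean() * ry.mean()
    s_perm = np.zeros(perms.shape[0])
    ry32 = ry.astype(np.float64)
    for col in range(n):
        s_perm += rx[col] * ry32[perms[:, col]]
    dev = np.abs(s_perm - center)
    return float(np.mean(dev >= abs(s_obs - center) - 1e-9))


def rank_correlation(
    x,
    y,
    metric: str = "x",
    covariate: str = "y",
    alpha: Optional[float] = None,
    exact_max_n: int = _EXACT_MAX_N,
) -> CorrelationResult:
    """Spearman rank correlation with an exact small-sample p-value.

    Missing values are removed pairwise.  Fewer than 3 complete pairs
    yields an ``insufficient_data`` result; a zero-variance input yields
    ``undefined``.
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    sig = None
    if n < 3:
        return CorrelationResult(
            metric, covariate, "spearman", None, None, n, None, "insufficient_data"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(
            metric, covariate, "spearman", None, None, n, None, "undefined"
        )
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry)
    else:
        p = _t_pvalue(rho, n)
    if alpha is not None:
        sig = p < alpha
    return CorrelationResult(metric, covariate, "spearman", rho, p, n, sig)


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def product_moment_correlation(
    x,
    y,
    metric: str = "x",
    covariate: str = "y",
    alpha: Optional[float] = None,
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p."""
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    sig = None
    if n < 3:
        return CorrelationResult(
            metric, covariate, "pearson", None, None, n, None, "insufficient_data"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(
            metric, covariate, "pearson", None, None, n, None, "undefined"
        )
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    p = _t_pvalue(r, n)
    if alpha is not None:
        sig = p < alpha
    return CorrelationResult(metric, covariate, "pearson", r, p, n, sig)


def correlation_grid(
    records: pd.DataFrame,
    metrics: Sequence[str],
    covariates: Sequence[str],
    method: str = "spearman",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One correlation per metric x covariate pair, pairwise-complete.

    Returns a DataFrame with columns metric, covariate, method, rho, p,
    n, significant (p < alpha, uncorrected), status.
    """
    if not len(metrics) or not len(covariates):
        raise ValueError("metric and covariate lists must be non-empty")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    fn = rank_correlation if method == "spearman" else product_moment_correlation
    rows = []
    for m in metrics:
        for c in covariates:
            res = fn(records[m], records[c], metric=m, covariate=c, alpha=alpha)
            rows.append(
                {
                    "metric": m,
                    "covariate": c,
                    "method": res.method,
                    "rho": res.rho,
                    "p": res.p_value,
                    "n": res.n,
                    "significant": res.significant,
                    "status": res.status,
                }
            )
    return pd.DataFrame(rows)


#: |rho| bands for report prose; configurable because usage in the field
#: is not consistent.
DEFAULT_EFFECT_BANDS = ((0.1, "weak"), (0.3, "moderate"), (0.5, "high"))


def effect_size_label(rho: float, bands=DEFAULT_EFFECT_BANDS) -> str:
    label = "negligible"
    for threshold, name in bands:
        if abs(rho) >= threshold:
            label = name
    return label


@dataclass
class CohortSummary:
    """Descriptive cohort tables: demographics, stage and score summaries."""

    n_total: int
    sex_counts: dict
    sex_percent: dict
    age: pd.DataFrame  # rows: all/female/male; cols: mean, median, sd
    hy_counts: pd.DataFrame  # index: group (total/male/female), cols: stages
    hy_percent: pd.DataFrame
    hy_weighted_mean: dict  # per sex and overall, 2 decimals
    score_stats: pd.DataFrame  # mean/sd per score column


_SCORE_COLUMNS = (
    "mmse",
    "cantab_prmcd",
    "cantab_prmmcld",
    "cantab_prmpci",
    "cantab_prmmcli",
    "cantab_swm_te",
)


def cohort_summary(records: pd.DataFrame) -> CohortSummary:
    """Counts, percentages (2 decimals) and moments of the clinical table.

    SDs use the sample (n-1) denominator; the Hoehn & Yahr summary is the
    count-weighted mean stage per sex, rounded to 2 decimals.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    n = len(records)
    sex = records["sex"]
    sex_counts = sex.value_counts().to_dict()
    sex_percent = {k: round(100.0 * v / n, 2) for k, v in sex_counts.items()}

    def _age_row(sub):
        a = sub["age"].to_numpy(float)
        return {
            "mean": float(np.mean(a)),
            "median": float(np.median(a)),
            "sd": float(np.std(a, ddof=1)) if len(a) > 1 else np.nan,
        }

    age = pd.DataFrame(
        {
            "all": _age_row(records),
            "female": _age_row(records[sex == "female"]),
            "male": _age_row(records[sex == "male"]),
        }
    ).T[["mean", "median", "sd"]]

    stages = sorted(records["hy_stage"].dropna().unique())
    groups = {
        "total": records,
        "male": records[sex == "male"],
        "female": records[sex == "female"],
    }
    hy_counts = pd.DataFrame(
        {
            g: [int((sub["hy_stage"] == s).sum()) for s in stages]
            for g, sub in groups.items()
        },
        index=stages,
    ).T
    hy_percent = (100.0 * hy_counts / n).round(2)
    hy_weighted_mean = {}
    for g, sub in groups.items():
        st = sub["hy_stage"].dropna().to_numpy(float)
        hy_weighted_mean[g] = round(float(np.mean(st)), 2) if len(st) else np.nan

    score_rows = {}
    for col in _SCORE_COLUMNS:
        if col in records:
            v = records[col].dropna().to_numpy(float)
            if len(v):
                score_rows[col] = {
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                }
    score_stats = pd.DataFrame(score_rows).T if score_rows else pd.DataFrame()

    return CohortSummary(
        n_total=n,
        sex_counts=sex_counts,
        sex_percent=sex_percent,
        age=age,
        hy_counts=hy_counts,
        hy_percent=hy_percent,
        hy_weighted_mean=hy_weighted_mean,
        score_stats=score_stats,
    )


def render_report(
    summary: CohortSummary,
    grid: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
) -> str:
    """Plain-markdown cohort + correlation report."""
    lines = ["# Cohort summary", ""]
    lines.append(f"n = {summary.n_total}")
    for s, c in sorted(summary.sex_counts.items()):
        lines.append(f"- {s}: n = {c} ({summary.sex_percent[s]:.2f}%)")
    lines += ["", "## Age (years)", summary.age.round(2).to_string(), ""]
    lines += [
        "## Hoehn & Yahr stage counts",
        summary.hy_counts.to_string(),
        "",
        "Percent of cohort:",
        summary.hy_percent.to_string(),
        "",
        "Count-weighted mean stage: "
        + ", ".join(
            f"{g} = {v:.2f}" for g, v in summary.hy_weighted_mean.items()
        ),
        "",
    ]
    if len(summary.score_stats):
        lines += [
            "## Neuropsychological scores",
            summary.score_stats.round(2).to_string(),
            "",
        ]
    if grid is not None and len(grid):
        n_tests = int(grid["p"].notna().sum())
        lines += [
            "## Correlations",
            "",
            f"{n_tests} tests at alpha = {alpha}; p-values are NOT corrected "
            "for multiple testing — interpret significance flags with care.",
            "",
        ]
        shown = grid.copy()
        shown["effect"] = [
            effect_size_label(r) if r is not None and np.isfinite(r) else ""
            for r in shown["rho"].fillna(np.nan)
        ]
        lines.append(shown.round(4).to_string(index=False))
        lines.append("")
    return "\n".join(lines)
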