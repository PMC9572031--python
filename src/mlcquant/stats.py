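"""Nonparametric statistical battery for eye-level cohort tables.

The analysis plan mirrors a standard ophthalmology workflow: Shapiro–Wilk
normality (α = 0.05) gates summary format (mean ± SD vs median (IQR)) and the
correlation method (Pearson vs Spearman); independent-samples Mann–Whitney U
compares groups; the Friedman test compares the three within-eye regions
(edematous, non-edematous, whole image) with Dunn's pairwise rank comparisons
Bonferroni-adjusted (×3, capped at 1).

The cohort table is a pandas DataFrame with one row per eye; see
``COHORT_COLUMNS`` for the schema.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "COHORT_COLUMNS",
    "Summary",
    "StatResult",
    "CorrelationResult",
    "validate_cohort",
    "summarize",
    "mann_whitney",
    "friedman_with_posthoc",
    "correlate",
    "build_report",
]

log = logging.getLogger(__name__)

ALPHA = 0.05

#: Schema of the eye-level cohort table.
COHORT_COLUMNS = (
    "eye_id",
    "group",          # control | acute | chronic
    "rvo_type",       # BRVO | CRVO | none
    "mlc_count",
    "mlc_density",
    "density_edematous",
    "density_non_edematous",
    "density_whole",
    "cft_um",
    "mrt_um",
    "vd_dcp_pct",
    "vd_scp_pct",
    "duration_days",
)


def validate_cohort(df: pd.DataFrame, required: tuple[str, ...] = COHORT_COLUMNS) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")


def _is_normal(values: np.ndarray) -> bool:
    """Shapiro–Wilk gate at α = 0.05; zero-range samples are non-normal."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return False
    return bool(sps.shapiro(values).pvalue > ALPHA)


@dataclass
class Summary:
    n: int
    normal: bool
    mean: float
    sd: float
    median: float
    iqr: float

    @property
    def formatted(self) -> str:
        if self.normal:
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        return f"{self.median:.2f} ({self.iqr:.2f})"


def summarize(values) -> Summary:
    """Mean ± SD for normal samples, median (IQR) otherwise.

    The IQR is Q3 − Q1 with linear-interpolation quantiles; SD uses the
    sample (n − 1) convention.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values to summarize")
    q1, q3 = np.percentile(values, [25, 75])
    return Summary(
        n=len(values),
        normal=_is_normal(values),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        median=float(np.median(values)),
        iqr=float(q3 - q1),
    )


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    n: tuple[int, ...] = ()
    summaries: tuple[str, ...] = ()
    detail: dict = field(default_factory=dict)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_statistic(pooled_ranks: np.ndarray, idx_a: np.ndarray, n_a: int) -> float:
    return float(pooled_ranks[idx_a].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b) -> StatResult:
    """Two-sided independent-samples Mann–Whitney U test.

    Exact enumeration of the permutation distribution of U (midranks, so ties
    are handled) when both sides have at most 8 observations; tie-corrected
    normal approximation with continuity correction otherwise. The reported
    statistic is U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_obs = _u_statistic(ranks, np.arange(n_a), n_a)
    if max(n_a, n_b) <= 8:
        us = np.array(
            [
                _u_statistic(ranks, np.fromiter(idx, int, n_a), n_a)
                for idx in itertools.combinations(range(n_a + n_b), n_a)
            ]
        )
        eps = 1e-9
        p = 2.0 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean())
        p = min(float(p), 1.0)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return StatResult(
        test_name="mann_whitney_u",
        statistic=u_obs,
        p_value=p,
        n=(n_a, n_b),
        detail={"method": method},
    )


def friedman_with_posthoc(triples, labels: tuple[str, ...] = ("edematous", "non_edematous", "whole")) -> list[StatResult]:
    """Friedman test over related samples plus Dunn's pairwise comparisons.

    ``triples`` is an (n, k) array-like, one row per eye and one column per
    condition; rows with missing values are dropped (count logged). Each
    pairwise Dunn p-value is multiplied by the number of pairs (Bonferroni)
    and capped at 1.
    """
    arr = np.asarray(triples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(labels):
        raise ValueError(f"expected an (n, {len(labels)}) array")
    complete = np.isfinite(arr).all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        log.info("friedman: dropped %d incomplete rows", dropped)
    arr = arr[complete]
    n, k = arr.shape
    if n < 3:
        raise ValueError("need at least 3 complete rows")

    within_ranks = np.apply_along_axis(_midranks, 1, arr)
    if np.ptp(arr, axis=1).max() == 0:
        # every row fully tied: no evidence of any condition effect
        chi2, p = 0.0, 1.0
    else:
        res = sps.friedmanchisquare(*(arr[:, j] for j in range(k)))
        chi2, p = float(res.statistic), float(res.pvalue)
    results = [
        StatResult(
            test_name="friedman",
            statistic=chi2,
            p_value=p,
            n=(n,),
            detail={"k": k, "dropped": dropped, "mean_ranks": within_ranks.mean(axis=0).tolist()},
        )
    ]
    mean_ranks = within_ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_pair = float(2.0 * sps.norm.sf(abs(z)))
        results.append(
            StatResult(
                test_name=f"dunn_{labels[i]}_vs_{labels[j]}",
                statistic=float(z),
                p_value=p_pair,
                adjusted_p=min(1.0, n_pairs * p_pair),
                n=(n,),
            )
        )
    return results


@dataclass
class CorrelationResult:
    method: str  # pearson | spearman
    r: float
    p_value: float
    n: int


def correlate(x, y, method: str | None = None) -> CorrelationResult:
    """Normality-gated correlation.

    With ``method=None``, Pearson is used iff both variables pass
    Shapiro–Wilk at α = 0.05, Spearman (average-rank ties) otherwise; pass
    ``"pearson"`` or ``"spearman"`` to override the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method is None:
        method = "pearson" if (_is_normal(x) and _is_normal(y)) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p_value=float(p), n=len(x))


_TABLE2_VARIABLES = (
    ("duration_days", "Disease duration (days)"),
    ("mrt_um", "MRT (um)"),
    ("cft_um", "CFT (um)"),
    ("vd_dcp_pct", "VD of DCP (%)"),
    ("vd_scp_pct", "VD of SCP (%)"),
    ("mlc_count", "MLC count"),
    ("mlc_density", "MLC density (cells/mm2)"),
)


def build_report(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables from a cohort DataFrame.

    Returns ``{"groups": ..., "regions": ..., "correlations": ...}``:

    - ``groups``: one row per variable with acute / chronic / all-RVO /
      control summaries and Mann–Whitney p-values for all-RVO vs control and
      acute vs chronic;
    - ``regions``: area / count / density for the edematous, non-edematous
      and whole regions (eyes with a divisible edematous region), with the
      Friedman p and Bonferroni-adjusted pairwise p-values;
    - ``correlations``: cell count vs CFT and MRT within the acute and
      chronic groups (count and density give identical rank correlations
      because the whole-image area is a constant; both rows are emitted).
    """
    validate_cohort(cohort)
    groups = {name: cohort[cohort["group"] == name] for name in ("acute", "chronic", "control")}
    rvo = cohort[cohort["group"].isin(["acute", "chronic"])]

    def cell(frame: pd.DataFrame, col: str) -> str:
        vals = frame[col].dropna().to_numpy()
        if len(vals) < 3:
            return ""
        return summarize(vals).formatted

    def pcell(a: pd.DataFrame, b: pd.DataFrame, col: str) -> float:
        va, vb = a[col].dropna().to_numpy(), b[col].dropna().to_numpy()
        if len(va) == 0 or len(vb) == 0:
            return np.nan
        return mann_whitney(va, vb).p_value

    rows = []
    for col, label in _TABLE2_VARIABLES:
        rows.append(
            {
                "variable": label,
                "acute": cell(groups["acute"], col),
                "chronic": cell(groups["chronic"], col),
                "all_rvo": cell(rvo, col),
                "control": cell(groups["control"], col),
                "p_rvo_vs_control": pcell(rvo, groups["control"], col)
                if col != "duration_days"
                else np.nan,
                "p_acute_vs_chronic": pcell(groups["acute"], groups["chronic"], col),
            }
        )
    table_groups = pd.DataFrame(rows)

    region_cols = ["density_edematous", "density_non_edematous", "density_whole"]
    with_edema = rvo.dropna(subset=region_cols)
    with_edema = with_edema[with_edema["area_edematous_mm2"] > 0] if "area_edematous_mm2" in with_edema else with_edema
    if len(with_edema) >= 3:
        triples = with_edema[region_cols].to_numpy()
        fried = friedman_with_posthoc(triples)
        pair_p = {r.test_name: r.adjusted_p for r in fried[1:]}
        region_rows = []
        for i, region in enumerate(["edematous", "non_edematous", "whole"]):
            region_rows.append(
                {
                    "region": region,
                    "n": len(with_edema),
                    "density_summary": summarize(triples[:, i]).formatted,
                    "friedman_p": fried[0].p_value,
                    "adj_p_edematous_vs_non_edematous": pair_p["dunn_edematous_vs_non_edematous"],
                    "adj_p_edematous_vs_whole": pair_p["dunn_edematous_vs_whole"],
                    "adj_p_non_edematous_vs_whole": pair_p["dunn_non_edematous_vs_whole"],
                }
            )
        table_regions = pd.DataFrame(region_rows)
    else:
        table_regions = pd.DataFrame(
            columns=[
                "region",
                "n",
                "density_summary",
                "friedman_p",
                "adj_p_edematous_vs_non_edematous",
                "adj_p_edematous_vs_whole",
                "adj_p_non_edematous_vs_whole",
            ]
        )

    corr_rows = []
    for grp in ("acute", "chronic"):
        frame = groups[grp]
        for xcol in ("mlc_count", "mlc_density"):
            for ycol in ("cft_um", "mrt_um"):
                sub = frame[[xcol, ycol]].dropna()
                if len(sub) < 5 or np.ptp(sub[xcol]) == 0 or np.ptp(sub[ycol]) == 0:
                    continue
                res = correlate(sub[xcol], sub[ycol])
                corr_rows.append(
                    {
                        "group": grp,
                        "x": xcol,
                        "y": ycol,
                        "method": res.method,
                        "r": res.r,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    table_corr = pd.DataFrame(
        corr_rows, columns=["group", "x", "y", "method", "r", "p_value", "n"]
    )
    return {"groups": table_groups, "regions": table_regions, "correlations": table_corr}
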