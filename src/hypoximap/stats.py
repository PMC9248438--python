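"""Rank-based group comparisons and correlations over the ROI table.

The comparisons mirror the study design: tumor vs contralateral normal
tissue, central vs peripheral intratumoral regions, high vs low HIF
expression groups, and correlation/regression of each imaging
parameter against the HIF score across tumor ROIs.  Group comparisons
use the Mann-Whitney U test; the exact two-sided p-value is obtained
by exhaustive enumeration of group-label assignments (mid-rank tie
handling) whenever that is tractable, otherwise a tie-corrected normal
approximation with continuity correction is used.  Correlations report
both Spearman (headline) and Pearson coefficients because study
write-ups commonly mix the two; a Holm-adjusted p column accompanies
every block but never drives the significance flag, matching the
uncorrected design.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05
ENUMERATION_LIMIT = 200_000

#: report scaling: column name -> (display name, multiplier, unit)
PARAM_DISPLAY = {
    "r2star": ("R2*", 1.0, "Hz"),
    "d": ("D", 1e6, "x10^-6 mm^2/s"),
    "dstar": ("D*", 1e6, "x10^-6 mm^2/s"),
    "f": ("f", 100.0, "%"),
    "perfusion": ("Perfusion", 1e6, "x10^-6 mm^2/s"),
    "hif_score": ("HIF-Score", 1.0, "score"),
}

IMAGING_PARAMS = ("r2star", "d", "dstar", "f", "perfusion")


@dataclass
class GroupComparison:
    """Two-group Mann-Whitney comparison of one parameter."""

    parameter: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    u_statistic: float
    p_value: float
    significant: bool
    method: str  # "exact" | "normal-approximation" | "degenerate"


@dataclass
class CorrelationResult:
    """Spearman + Pearson + OLS of one parameter against the HIF score."""

    parameter: str
    n: int
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    r_squared: float
    regression_p: float


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(x, y, mode: str = "auto") -> GroupComparison:
    """Mann-Whitney U test of two samples.

    U counts pairs with x_i > y_j plus half the ties.  ``mode`` is
    "auto" (exact when the number of group-label assignments is at most
    2x10^5, else asymptotic), "exact" or "asymptotic".  The two-sided
    exact p enumerates every assignment of the pooled values to the two
    groups, with mid-rank ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # = #{x>y} + ties/2

    if np.all(pooled == pooled[0]):
        return GroupComparison(
            parameter="", group_labels=("x", "y"), n=(n1, n2),
            mean=(float(x.mean()), float(y.mean())),
            sd=(float(x.std(ddof=1)) if n1 > 1 else 0.0,
                float(y.std(ddof=1)) if n2 > 1 else 0.0),
            u_statistic=float(u), p_value=1.0, significant=False,
            method="degenerate")

    n_assign = comb(n1 + n2, n1)
    use_exact = mode == "exact" or (mode == "auto" and n_assign <= ENUMERATION_LIMIT)
    mu = n1 * n2 / 2.0
    if use_exact:
        obs_dev = abs(u - mu)
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                hits += 1
        p = hits / n_assign
        method = "exact"
    else:
        nn = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (nn * (nn - 1))
        var = n1 * n2 / 12.0 * (nn + 1 - tie_term)
        if var <= 0:
            p, method = 1.0, "degenerate"
        else:
            z = (abs(u - mu) - 0.5) / sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))
            method = "normal-approximation"
    return GroupComparison(
        parameter="", group_labels=("x", "y"), n=(n1, n2),
        mean=(float(x.mean()), float(y.mean())),
        sd=(float(x.std(ddof=1)) if n1 > 1 else 0.0,
            float(y.std(ddof=1)) if n2 > 1 else 0.0),
        u_statistic=float(u), p_value=float(p),
        significant=bool(p < ALPHA), method=method)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def linear_regression(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares y on x: (slope, intercept, R², p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0:
        raise ValueError("x has no variance")
    res = sps.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue**2), float(res.pvalue))


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (reported, never flag-driving)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def _comparison_block(df: pd.DataFrame, params, group_col: str,
                      labels: tuple[str, str]) -> list[dict]:
    g1 = df[df[group_col] == labels[0]]
    g2 = df[df[group_col] == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        logger.warning("comparison %s vs %s skipped: empty/undersized group",
                       *labels)
        return []
    rows = []
    for par in params:
        scale = PARAM_DISPLAY[par][1]
        x = g1[f"mean_{par}"].dropna().to_numpy() * scale \
            if par != "hif_score" else g1["hif_score"].dropna().to_numpy()
        y = g2[f"mean_{par}"].dropna().to_numpy() * scale \
            if par != "hif_score" else g2["hif_score"].dropna().to_numpy()
        cmp_ = mann_whitney_u(x, y)
        cmp_.parameter = PARAM_DISPLAY[par][0]
        cmp_.group_labels = labels
        rows.append(asdict(cmp_) | {"unit": PARAM_DISPLAY[par][2]})
    holm = holm_adjust([r["p_value"] for r in rows])
    for r, h in zip(rows, holm):
        r["p_holm"] = h
    return rows


def _correlation_block(df: pd.DataFrame) -> list[dict]:
    tumor = df[df["tissue_class"] == "tumor"]
    rows = []
    for par in IMAGING_PARAMS:
        sub = tumor[[f"mean_{par}", "hif_score"]].dropna()
        if len(sub) < 3:
            logger.warning("correlation block for %s skipped: too few ROIs", par)
            continue
        scale = PARAM_DISPLAY[par][1]
        x = sub[f"mean_{par}"].to_numpy() * scale
        y = sub["hif_score"].to_numpy()
        rho, p_rho = spearman(x, y)
        r, p_r = pearson(x, y)
        slope, intercept, r2, p_reg = linear_regression(x, y)
        rows.append(asdict(CorrelationResult(
            parameter=PARAM_DISPLAY[par][0], n=len(sub),
            spearman_rho=rho, spearman_p=p_rho,
            pearson_r=r, pearson_p=p_r,
            slope=slope, intercept=intercept, r_squared=r2,
            regression_p=p_reg)) | {"unit": PARAM_DISPLAY[par][2]})
    holm = holm_adjust([r["spearman_p"] for r in rows])
    for r, h in zip(rows, holm):
        r["spearman_p_holm"] = h
    return rows


def build_report(roi_table: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Assemble the full statistics report from a pooled ROI table.

    Expects the tidy per-ROI table written by the grid stage (columns
    mean_<param>, hif_score, hif_label, tissue_class, region_class and
    in_analysis).  Returns a JSON-serializable dict with four blocks:

    1. tumor vs normal (all parameters incl. the HIF score);
    2. central vs peripheral intratumoral (spatial distribution);
    3. high vs low HIF expression (imaging parameters, tumor ROIs);
    4. correlation/regression of imaging parameters vs the HIF score.
    """
    df = roi_table
    if "in_analysis" in df.columns:
        df = df[df["in_analysis"]]
    else:
        df = df[df["included"]]
    df = df.copy()

    all_params = list(IMAGING_PARAMS) + ["hif_score"]
    report: dict = {
        "alpha": alpha,
        "n_rois": int(len(df)),
        "n_tumor": int((df["tissue_class"] == "tumor").sum()),
        "n_normal": int((df["tissue_class"] == "normal").sum()),
        "notes": [
            "Spearman is the headline correlation; Pearson reported alongside.",
            "Holm-adjusted p-values are informational only.",
        ],
    }
    report["tumor_vs_normal"] = _comparison_block(
        df, all_params, "tissue_class", ("tumor", "normal"))
    tumor_df = df[df["tissue_class"] == "tumor"]
    report["central_vs_peripheral"] = _comparison_block(
        tumor_df, all_params, "region_class", ("central", "peripheral"))
    report["high_vs_low_hif"] = _comparison_block(
        tumor_df, list(IMAGING_PARAMS), "hif_label", ("high", "low"))
    report["correlations"] = _correlation_block(df)
    return report


def report_to_markdown(report: dict) -> str:
    """Render the report blocks as Markdown tables."""
    lines = [
        "# ROI statistics report",
        "",
        f"ROIs analysed: {report['n_rois']} "
        f"({report['n_tumor']} tumor, {report['n_normal']} normal); "
        f"alpha = {report['alpha']}",
        "",
    ]
    for key, title in [("tumor_vs_normal", "Tumor vs normal tissue"),
                       ("central_vs_peripheral", "Central vs peripheral tumor"),
                       ("high_vs_low_hif", "High vs low HIF expression")]:
        rows = report.get(key, [])
        if not rows:
            continue
        a, b = rows[0]["group_labels"]
        lines += [f"## {title}", "",
                  f"| Parameter | {a} (mean ± SD, N={rows[0]['n'][0]}) | "
                  f"{b} (mean ± SD, N={rows[0]['n'][1]}) | U | p |",
                  "|---|---|---|---|---|"]
        for r in rows:
            star = "*" if r["significant"] else ""
            lines.append(
                f"| {r['parameter']} ({r['unit']}) "
                f"| {r['mean'][0]:.2f} ± {r['sd'][0]:.2f} "
                f"| {r['mean'][1]:.2f} ± {r['sd'][1]:.2f} "
                f"| {r['u_statistic']:.1f} | {r['p_value']:.3g}{star} |")
        lines.append("")
    rows = report.get("correlations", [])
    if rows:
        lines += ["## Correlation with the HIF score (tumor ROIs)", "",
                  "| Parameter | n | Spearman rho (p) | Pearson r (p) | "
                  "slope | R² |", "|---|---|---|---|---|---|"]
        for r in rows:
            lines.append(
                f"| {r['parameter']} | {r['n']} "
                f"| {r['spearman_rho']:.3f} ({r['spearman_p']:.3g}) "
                f"| {r['pearson_r']:.3f} ({r['pearson_p']:.3g}) "
                f"| {r['slope']:.4g} | {r['r_squared']:.3f} |")
        lines.append("")
    return "\n".join(lines)
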