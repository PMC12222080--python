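"""Three-tier group comparison with FDR control and effect sizes.

Tier 1: Welch t-tests on whole-graph metrics (global efficiency,
characteristic path length) per band, condition and sliding window.
Tier 2: mixed-design ANOVA on node-level metrics with driving experience as
the between-subjects factor and intrinsic network as the within-subjects
factor; the experience main effect is the primary output.
Tier 3: follow-up per-node Welch tests, run only where the corresponding
ANOVA experience effect survives FDR, summarized by network affiliation.

p-values are pooled into Benjamini-Hochberg families per
(tier, metric, band, condition), across windows and units.  Cohen's d is
signed experienced minus novice, so higher novice connectivity yields
negative d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "cohens_d",
    "welch_t",
    "fdr_bh",
    "stars",
    "mixed_anova",
    "node_followup_t",
    "run_group_stats",
]

GLOBAL_METRICS = ("global_efficiency", "char_path_length")
NODE_METRICS = ("s_in", "s_out", "s_total", "clustering")


@dataclass
class TestResult:
    """A single two-sample comparison: statistic, df, p, and Cohen's d."""

    statistic: float
    df: float
    p: float
    d: float


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def welch_t(a, b, label: str = "") -> TestResult:
    """Unequal-variance two-sample t-test with Satterthwaite df.

    Raises on degenerate samples (n < 2 or zero variance), naming the cell
    via ``label``.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    where = f" in {label}" if label else ""
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need n >= 2 per sample{where}")
    if a.var(ddof=1) == 0 or b.var(ddof=1) == 0:
        raise ValueError(f"zero-variance sample{where}")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        d=cohens_d(a, b),
    )


def fdr_bh(pvals, alpha: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, bool), pvals
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def stars(p_fdr: float) -> str:
    """Significance stars: * / ** / *** for p_FDR below 0.05 / 0.01 / 0.001."""
    if p_fdr < 0.001:
        return "***"
    if p_fdr < 0.01:
        return "**"
    if p_fdr < 0.05:
        return "*"
    return ""


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "network",
    subject: str = "subject",
    between: str = "group",
) -> pd.DataFrame:
    """Mixed-design ANOVA (between: experience group; within: brain region).

    Requires complete repeated measures — every subject observed at every
    within-factor level — and at least two subjects per group.  Returns the
    three-effect table (between, within, interaction) with F, dfs, p and
    partial eta squared.
    """
    import pingouin as pg

    pivot = table.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="count", fill_value=0
    )
    if (pivot != 1).any().any():
        bad = [
            (s, w)
            for s in pivot.index
            for w in pivot.columns
            if pivot.loc[s, w] != 1
        ]
        raise ValueError(f"incomplete or duplicated within-subject cells: {bad}")
    per_group = table.groupby(between, observed=True)[subject].nunique()
    if (per_group < 2).any() or len(per_group) != 2:
        raise ValueError("need exactly two groups with >= 2 subjects each")

    aov = pg.mixed_anova(
        data=table, dv=dv, within=within, subject=subject, between=between
    )
    return aov.rename(columns={"p-unc": "p", "p_unc": "p"})


def node_followup_t(
    table: pd.DataFrame,
    gate: pd.DataFrame,
    alpha: float = 0.05,
    group_order: tuple = ("experienced", "novice"),
) -> pd.DataFrame:
    """Per-node Welch follow-ups in cells whose ANOVA effect survived FDR.

    ``gate`` is the tier-2 result table (one row per metric/band/condition/
    window with a ``p_fdr`` column); only its significant cells are followed
    up.  Returns per-node results (no FDR applied here — the caller pools the
    family).
    """
    sig = gate[gate["p_fdr"] < alpha]
    rows = []
    for _, cell in sig.iterrows():
        sub = table[
            (table["metric"] == cell["metric"])
            & (table["band"] == cell["band"])
            & (table["condition"] == cell["condition"])
            & (table["window"] == cell["window"])
            & (table["unit"] == "node")
        ]
        for node, df_node in sub.groupby("unit_id", sort=False):
            a = df_node.loc[df_node["group"] == group_order[0], "value"].to_numpy()
            b = df_node.loc[df_node["group"] == group_order[1], "value"].to_numpy()
            r = welch_t(a, b, label=f"{cell['metric']}/{node}/{cell['window']}")
            rows.append(
                {
                    "tier": "node_followup",
                    "metric": cell["metric"],
                    "band": cell["band"],
                    "condition": cell["condition"],
                    "window": cell["window"],
                    "unit": "node",
                    "unit_id": node,
                    "network": df_node["network"].iloc[0],
                    "statistic": r.statistic,
                    "df": r.df,
                    "p": r.p,
                    "d": r.d,
                }
            )
    return pd.DataFrame(rows)


def _apply_family_fdr(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Pool p-values per (tier, metric, band, condition) and adjust by BH."""
    if df.empty:
        df = df.copy()
        df["p_fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        df["stars"] = pd.Series(dtype=str)
        return df
    out = []
    for _, fam in df.groupby(["tier", "metric", "band", "condition"], sort=False):
        fam = fam.copy()
        reject, p_adj = fdr_bh(fam["p"].to_numpy(), alpha)
        fam["p_fdr"] = p_adj
        fam["significant"] = reject
        fam["stars"] = [stars(p) for p in p_adj]
        out.append(fam)
    return pd.concat(out, ignore_index=True)


def run_group_stats(
    metric_table: pd.DataFrame,
    alpha: float = 0.05,
    group_order: tuple = ("experienced", "novice"),
) -> dict:
    """Run the full three-tier comparison on a long metric table.

    Returns a dict with the tier tables (``global``, ``anova``,
    ``followup``), a follow-up summary by network and window, and the FDR
    family definition actually used.
    """
    results_global = []
    for (metric, band, condition), df_mc in metric_table[
        metric_table["metric"].isin(GLOBAL_METRICS)
    ].groupby(["metric", "band", "condition"], sort=False):
        for window, df_w in df_mc.groupby("window", sort=False):
            a = df_w.loc[df_w["group"] == group_order[0], "value"].to_numpy()
            b = df_w.loc[df_w["group"] == group_order[1], "value"].to_numpy()
            r = welch_t(a, b, label=f"{metric}/{band}/{condition}/{window}")
            results_global.append(
                {
                    "tier": "global", "metric": metric, "band": band,
                    "condition": condition, "window": window, "unit": "graph",
                    "unit_id": "graph", "statistic": r.statistic, "df": r.df,
                    "p": r.p, "d": r.d,
                }
            )
    global_df = _apply_family_fdr(pd.DataFrame(results_global), alpha)

    node_rows = metric_table[
        (metric_table["unit"] == "node")
        & metric_table["metric"].isin(NODE_METRICS)
    ]
    results_anova = []
    for (metric, band, condition), df_mc in node_rows.groupby(
        ["metric", "band", "condition"], sort=False
    ):
        for window, df_w in df_mc.groupby("window", sort=False):
            per_net = (
                df_w.groupby(["subject", "group", "network"], observed=True)["value"]
                .mean()
                .reset_index()
            )
            aov = mixed_anova(per_net, dv="value", within="network")
            between = aov[aov["Source"] == "group"].iloc[0]
            results_anova.append(
                {
                    "tier": "anova", "metric": metric, "band": band,
                    "condition": condition, "window": window, "unit": "network-set",
                    "unit_id": "experience", "statistic": float(between["F"]),
                    "df": float(between["DF1"]), "df2": float(between["DF2"]),
                    "p": float(between["p"]), "np2": float(between["np2"]),
                }
            )
    anova_df = _apply_family_fdr(pd.DataFrame(results_anova), alpha)

    followup = node_followup_t(metric_table, anova_df, alpha, group_order)
    followup_df = _apply_family_fdr(followup, alpha)
    if not followup_df.empty:
        summary = (
            followup_df.groupby(
                ["metric", "band", "condition", "network", "window"], sort=False
            )["significant"]
            .agg(n_significant="sum", n_nodes="count")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["metric", "band", "condition", "network", "window",
                     "n_significant", "n_nodes"]
        )
    return {
        "global": global_df,
        "anova": anova_df,
        "followup": followup_df,
        "followup_summary": summary,
        "fdr_family": {
            "definition": "p-values pooled per (tier, metric, band, condition) "
                          "across windows and units",
            "alpha": alpha,
            "method": "benjamini-hochberg",
            "d_sign": f"{group_order[0]} minus {group_order[1]}",
        },
    }
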