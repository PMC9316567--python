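"""Statistical comparisons, summary tables, and figures.

Group comparisons follow the study design: the Mann-Whitney U test compares
cell groups *within* an experiment; the Wilcoxon signed-rank test compares
*paired* per-co-culture medians of two groups across experiments; and the
paired t-test serves the small methylation series where only a few paired
experiment medians exist.  All tests are two-sided, with no
multiple-testing correction by default (an optional Holm adjustment is
provided).

The tabulation layer reproduces the per-experiment count/percentage layout
of the classification and EU-domain tables, with percentages against the
total number of co-cultured cells rounded half-away-from-zero to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import EU_DOMAINS, Group, Role, round_half_up

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "paired_t",
    "holm_adjust",
    "tabulate_groups",
    "tabulate_eu_domains",
    "plot_cartesian",
    "plot_phenotype_vs_eu",
]

_GROUP_COLUMNS = [
    ("indist_red", "Cells Indistinguishable from Fibroblast Controls"),
    ("red_some_green", "Fibroblasts with Some Cancer Cell Labelling"),
    ("uncertain", "Cells of Uncertain Origin"),
    ("green_some_red", "Cancer Cells with Some Fibroblast Labelling"),
    ("indist_green", "Cells Indistinguishable from Cancer Cell Controls"),
]

#: interior EU bins of width 20 used for binned phenotype medians
#: (indistinguishable cells are excluded from these)
EU_BIN_EDGES = [(-50.0, -30.0), (-30.0, -10.0), (-10.0, 10.0), (10.0, 30.0), (30.0, 50.0)]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group comparison."""

    scope: str          # 'within' (one experiment) or 'across' (paired medians)
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def mann_whitney(a, b, *, group_a: str = "A", group_b: str = "B") -> GroupComparison:
    """Two-sided Mann-Whitney U (rank-sum) test between two cell groups.

    Exact null distribution for small untied samples, normal approximation
    with tie and continuity correction otherwise (scipy's 'auto' policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison("within", group_a, group_b, "mann-whitney-u",
                           float(res.statistic), float(res.pvalue), a.size, b.size)


def wilcoxon_signed_rank(a, b=None, *, group_a: str = "A", group_b: str = "B") -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    Pairs are typically per-co-culture medians of two groups across
    experiments.  Zero differences are dropped (Wilcoxon's convention);
    the null distribution is exact for small untied samples.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValueError("all paired differences are zero")
    res = stats.wilcoxon(d, alternative="two-sided", zero_method="wilcox", method="auto")
    return GroupComparison("across", group_a, group_b, "wilcoxon-signed-rank",
                           float(res.statistic), float(res.pvalue), d.size, d.size)


def paired_t(a, b=None, *, group_a: str = "A", group_b: str = "B") -> GroupComparison:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)).

    Used for the small methylation series.  Zero variance of the
    differences leaves the statistic undefined and raises.
    """
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = float(np.mean(d) / (np.std(d, ddof=1) / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    return GroupComparison("across", group_a, group_b, "paired-t", t, p, d.size, d.size)


def holm_adjust(comparisons: list[GroupComparison]) -> list[float]:
    """Holm step-down adjusted p-values (optional; raw p-values are the default)."""
    p = np.array([c.p_value for c in comparisons])
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return list(adj)


def _fmt(count: int, pct: float) -> str:
    if count == 0:
        return "0 (0%)"
    return f"{count} ({pct:.1f}%)"


def tabulate_groups(experiments: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-experiment counts of co-cultured cells by Cartesian-plot group.

    One row per experiment with control counts, per-group ``count (pct%)``
    strings, numeric count/pct columns, and the co-cultured total.
    Percentages are against total co-cultured cells; an ``unclassified``
    column appears only when such cells exist.
    """
    rows = []
    any_unclassified = False
    for exp_id, df in experiments.items():
        cc = df[df["role"] == Role.COCULTURED.value]
        total = len(cc)
        row: dict[str, object] = {
            "experiment": exp_id,
            "control_fibroblasts": int((df["role"] == Role.CONTROL_RED.value).sum()),
        }
        for key, title in _GROUP_COLUMNS:
            n = int((cc["group"] == key).sum())
            pct = round_half_up(100.0 * n / total, 1) if total else 0.0
            row[title] = _fmt(n, pct)
            row[f"n_{key}"] = n
            row[f"pct_{key}"] = pct
        n_un = int((cc["group"] == Group.UNCLASSIFIED.value).sum())
        if n_un:
            any_unclassified = True
        row["n_unclassified"] = n_un
        row["pct_unclassified"] = round_half_up(100.0 * n_un / total, 1) if total else 0.0
        row["total_cocultured"] = total
        row["control_cancer_cells"] = int((df["role"] == Role.CONTROL_GREEN.value).sum())
        rows.append(row)
    table = pd.DataFrame(rows)
    if not any_unclassified and not table.empty:
        table = table.drop(columns=["n_unclassified", "pct_unclassified"])
    return table


def tabulate_eu_domains(experiments: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-experiment counts of co-cultured cells by the seven EU domains."""
    rows = []
    for exp_id, df in experiments.items():
        cc = df[df["role"] == Role.COCULTURED.value]
        total = len(cc)
        row: dict[str, object] = {"experiment": exp_id}
        for dom in EU_DOMAINS:
            n = int((cc["eu_domain"] == dom).sum())
            pct = round_half_up(100.0 * n / total, 1) if total else 0.0
            row[dom] = _fmt(n, pct)
            row[f"n_{dom}"] = n
            row[f"pct_{dom}"] = pct
        row["total_cocultured"] = total
        rows.append(row)
    return pd.DataFrame(rows)


_GROUP_COLORS = {
    Group.INDIST_RED.value: "#c0392b",
    Group.RED_SOME_GREEN.value: "#e67e22",
    Group.UNCERTAIN.value: "#7f8c8d",
    Group.GREEN_SOME_RED.value: "#27ae60",
    Group.INDIST_GREEN.value: "#145a32",
    Group.UNCLASSIFIED.value: "#2980b9",
}


def plot_cartesian(
    classified: pd.DataFrame,
    out: str | Path,
    scale: str = "linear",
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Cartesian plot: co-cultured cells by group, controls as open triangles.

    ``scale='log'`` uses log-log axes; cells with a zero normalized value in
    either channel cannot be drawn there and are dropped with an annotation
    of how many were excluded.
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"scale must be 'linear' or 'log', got {scale!r}")
    fig, ax = plt.subplots(figsize=(6, 6))
    cc = classified[classified["role"] == Role.COCULTURED.value]
    n_dropped = 0
    if scale == "log":
        drop = (cc["green_norm"] <= 0) | (cc["red_norm"] <= 0)
        n_dropped = int(drop.sum())
        cc = cc[~drop]
    for grp, color in _GROUP_COLORS.items():
        sel = cc[cc["group"] == grp]
        if len(sel):
            ax.scatter(sel["green_norm"], sel["red_norm"], s=12, c=color,
                       label=grp, alpha=0.7, linewidths=0)
    for role, color in ((Role.CONTROL_GREEN.value, "#27ae60"),
                        (Role.CONTROL_RED.value, "#c0392b")):
        ctl = classified[classified["role"] == role]
        if scale == "log":
            ctl = ctl[(ctl["green_norm"] > 0) & (ctl["red_norm"] > 0)]
        ax.scatter(ctl["green_norm"], ctl["red_norm"], s=30, marker="^",
                   facecolors="none", edgecolors=color, label=role)
    lim = max(float(classified["green_norm"].max()), float(classified["red_norm"].max()))
    if scale == "log":
        ax.set_xscale("log")
        ax.set_yscale("log")
        pos = pd.concat([cc["green_norm"], cc["red_norm"]])
        lo = max(float(pos[pos > 0].min()) * 0.5, 1e-3) if (pos > 0).any() else 1e-3
        ax.plot([lo, lim], [lo, lim], "k--", lw=1)
        if n_dropped:
            ax.annotate(f"{n_dropped} cell(s) with zero NFU not shown",
                        xy=(0.02, 0.98), xycoords="axes fraction", va="top", fontsize=8)
    else:
        ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("green fluorescence (NFU)")
    ax.set_ylabel("red fluorescence (NFU)")
    ax.legend(fontsize=7, loc="upper right")
    out = Path(out)
    written = []
    for fmt in formats:
        path = out.with_suffix(f".{fmt}")
        fig.savefig(path, dpi=150)
        written.append(path)
    plt.close(fig)
    return written


def binned_eu_medians(classified: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    """Phenotype medians of co-cultured cells in width-20 EU bins.

    Cells indistinguishable from controls are excluded; bins follow the
    interior EU domains (-50,-30], ..., (10,30], (30,50).  Empty bins are
    omitted.
    """
    cc = classified[(classified["role"] == Role.COCULTURED.value)
                    & ~classified["group"].isin([Group.INDIST_GREEN.value,
                                                 Group.INDIST_RED.value,
                                                 Group.UNCLASSIFIED.value])]
    rows = []
    for lo, hi in EU_BIN_EDGES:
        upper_open = hi == 50.0
        sel = cc[(cc["eu"] > lo) & ((cc["eu"] < hi) if upper_open else (cc["eu"] <= hi))]
        if len(sel):
            rows.append({"eu_lo": lo, "eu_hi": hi, "eu_mid": (lo + hi) / 2,
                         "n": len(sel), "median": float(sel[phenotype].median())})
    return pd.DataFrame(rows)


def plot_phenotype_vs_eu(
    classified: pd.DataFrame,
    phenotype: str,
    out: str | Path,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Phenotype (circularity, area, or cnf_norm) against Exchange Units.

    Scatter of co-cultured cells with control-population medians drawn as
    large triangles at the EU poles and width-20 EU-bin medians overlaid.
    """
    if phenotype not in ("circularity", "area", "cnf_norm"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    fig, ax = plt.subplots(figsize=(7, 5))
    cc = classified[classified["role"] == Role.COCULTURED.value].dropna(subset=["eu", phenotype])
    ax.scatter(cc["eu"], cc[phenotype], s=10, c="#555555", alpha=0.5, linewidths=0)
    med = binned_eu_medians(classified, phenotype)
    if len(med):
        ax.plot(med["eu_mid"], med["median"], "o-", c="#2c3e50", label="EU-bin medians")
    for role, eu_pole, color in ((Role.CONTROL_GREEN.value, 50, "#27ae60"),
                                 (Role.CONTROL_RED.value, -50, "#c0392b")):
        ctl = classified[classified["role"] == role].dropna(subset=[phenotype])
        if len(ctl):
            ax.scatter([eu_pole], [float(ctl[phenotype].median())], marker="^", s=140,
                       c=color, label=f"{role} median", zorder=3)
    ax.set_xlabel("Exchange Units")
    ax.set_ylabel(phenotype)
    ax.legend(fontsize=8)
    out = Path(out)
    written = []
    for fmt in formats:
        path = out.with_suffix(f".{fmt}")
        fig.savefig(path, dpi=150)
        written.append(path)
    plt.close(fig)
    return written
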