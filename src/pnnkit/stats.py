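"""Factorial group statistics for the 2×2 genotype × housing design.

Each metric is analysed with a normality-gated choice between the
parametric route — two-way ANOVA (Type II sums of squares, robust to the
mild imbalance of 3-4 animals per group) with Tukey HSD over the four
cell means — and the non-parametric route — Kruskal–Wallis H across the
four genotype × housing cells (tie-corrected, chi-square reference with
df = 3) followed by Dunn's pairwise z-tests on mean ranks with Holm
adjustment.  The gate is Shapiro–Wilk per group at alpha = 0.05 and can
be overridden; every decision is recorded in the result object.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .geometry import ParameterError

__all__ = [
    "StatResult",
    "normality_gate",
    "two_way_anova",
    "kruskal_wallis_dunn",
    "dunn_posthoc",
    "analyze_metric",
    "CELL_SEP",
]

CELL_SEP = " / "
FACTORS = ("genotype", "housing")
ALPHA = 0.05


@dataclass
class StatResult:
    """Outcome of one metric's group comparison."""

    metric: str
    test: str                       # "two-way ANOVA" or "Kruskal-Wallis"
    statistics: dict                # effect -> (statistic, p)
    posthoc: pd.DataFrame           # pairwise comparisons, adjusted p
    alpha: float = ALPHA
    gate: dict = field(default_factory=dict)

    @property
    def p_values(self) -> dict:
        return {k: v[1] for k, v in self.statistics.items()}

    def significant(self) -> dict:
        return {k: p < self.alpha for k, p in self.p_values.items()}


def _cells(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Split values into the four genotype×housing cells (sorted labels)."""
    for col in (*FACTORS, "value"):
        if col not in table.columns:
            raise ParameterError(f"measurement table needs a {col!r} column")
    vals = table.dropna(subset=["value"])
    out = {}
    for (g, h), grp in vals.groupby(list(FACTORS), observed=True, sort=True):
        out[f"{g}{CELL_SEP}{h}"] = grp["value"].to_numpy(dtype=float)
    return out


def normality_gate(table: pd.DataFrame, alpha: float = ALPHA,
                   force: str | None = None) -> dict:
    """Choose the test family: ``parametric`` or ``nonparametric``.

    Shapiro–Wilk per cell at a Bonferroni-shared level (``alpha`` divided
    by the number of cells, so truly normal data stay on the parametric
    route in ~``1 - alpha`` of datasets rather than ``0.95**k``); any
    rejection, any constant cell (degenerate normality) or any cell with
    fewer than 3 values forces the non-parametric route.  ``force``
    overrides the data-driven choice.
    """
    report: dict = {"per_group": {}, "alpha": alpha, "forced": force}
    if force is not None:
        if force not in ("parametric", "nonparametric"):
            raise ParameterError("force must be 'parametric' or 'nonparametric'")
        report["choice"] = force
        return report
    choice = "parametric"
    cells = _cells(table)
    alpha_each = alpha / max(len(cells), 1)
    report["alpha_per_group"] = alpha_each
    for name, vals in cells.items():
        if len(vals) < 3:
            warnings.warn(
                f"group {name!r} has n={len(vals)} < 3; normality untestable, "
                "falling back to the non-parametric route", stacklevel=2)
            report["per_group"][name] = {"n": len(vals), "p": None}
            choice = "nonparametric"
            continue
        if np.ptp(vals) == 0:
            report["per_group"][name] = {"n": len(vals), "p": 0.0}
            choice = "nonparametric"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(vals).pvalue)
        report["per_group"][name] = {"n": len(vals), "p": p}
        if p < alpha_each:
            choice = "nonparametric"
    report["choice"] = choice
    return report


def two_way_anova(table: pd.DataFrame, metric: str = "",
                  posthoc: bool = True, gate: dict | None = None) -> StatResult:
    """Two-way ANOVA (Type II) with Tukey HSD over the four cell means."""
    cells = _cells(table)
    for g in sorted(set(table["genotype"])):
        for h in sorted(set(table["housing"])):
            if f"{g}{CELL_SEP}{h}" not in cells:
                raise ParameterError(
                    f"empty design cell ({g}, {h}): two-way ANOVA undefined")
    df = table.dropna(subset=["value"]).copy()
    model = ols("value ~ C(genotype) * C(housing)", data=df).fit()
    tab = anova_lm(model, typ=2)

    def row(name):
        r = tab.loc[name]
        return (float(r["F"]), float(r["PR(>F)"]))

    statistics = {
        "genotype": row("C(genotype)"),
        "housing": row("C(housing)"),
        "interaction": row("C(genotype):C(housing)"),
    }
    if posthoc:
        labels = df["genotype"].astype(str) + CELL_SEP + df["housing"].astype(str)
        tk = pairwise_tukeyhsd(df["value"].to_numpy(dtype=float),
                               labels.to_numpy(), alpha=ALPHA)
        ph = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        ph = ph.rename(columns={"p-adj": "p_adj"})
    else:
        ph = pd.DataFrame()
    return StatResult(metric, "two-way ANOVA", statistics, ph,
                      gate=gate or {})


def dunn_posthoc(cells: dict[str, np.ndarray],
                 p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's z-tests on mean ranks for all group pairs.

    For groups i, j with mean ranks R̄ᵢ, R̄ⱼ over the pooled sample of
    size N, the statistic is ``z = (R̄ᵢ − R̄ⱼ) / sqrt((N(N+1)/12 − T) ·
    (1/nᵢ + 1/nⱼ))`` with tie term ``T = Σ(t³ − t) / (12(N − 1))``.
    Two-sided normal p-values, adjusted by ``p_adjust`` (holm,
    bonferroni or none).
    """
    names = sorted(cells)
    pooled = np.concatenate([cells[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for k in names:
        n = len(cells[k])
        mean_ranks[k] = float(ranks[start:start + n].mean())
        sizes[k] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1))) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        rows.append({"group1": a, "group2": b, "z": float(z),
                     "p_raw": float(2 * sps.norm.sf(abs(z)))})
    ph = pd.DataFrame(rows)
    if p_adjust in (None, "none"):
        ph["p_adj"] = ph["p_raw"]
    else:
        ph["p_adj"] = multipletests(ph["p_raw"], method=p_adjust)[1]
    ph["reject"] = ph["p_adj"] < ALPHA
    return ph


def kruskal_wallis_dunn(table: pd.DataFrame, metric: str = "",
                        posthoc: bool = True, p_adjust: str = "holm",
                        gate: dict | None = None) -> StatResult:
    """Kruskal–Wallis H across the four cells, then Dunn's post hoc."""
    cells = _cells(table)
    if len(cells) < 2:
        raise ParameterError("Kruskal-Wallis needs at least two groups")
    for g in sorted(set(table["genotype"])):
        for h in sorted(set(table["housing"])):
            if len(cells.get(f"{g}{CELL_SEP}{h}", ())) == 0:
                raise ParameterError(
                    f"empty design cell ({g}, {h}) in Kruskal-Wallis input")
    values = [cells[k] for k in sorted(cells)]
    if all(np.ptp(np.concatenate(values)) == 0 for _ in (0,)):
        h_stat, p = 0.0, 1.0  # all observations identical
    else:
        h_stat, p = sps.kruskal(*values)
    statistics = {"omnibus": (float(h_stat), float(p))}
    ph = dunn_posthoc(cells, p_adjust) if posthoc else pd.DataFrame()
    return StatResult(metric, "Kruskal-Wallis", statistics, ph,
                      gate=gate or {})


def analyze_metric(table: pd.DataFrame, metric: str = "",
                   force: str | None = None, posthoc: bool = True,
                   p_adjust: str = "holm") -> StatResult:
    """Normality-gated analysis of one metric's measurement table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gate = normality_gate(table, force=force)
    if gate["choice"] == "parametric":
        return two_way_anova(table, metric, posthoc, gate)
    return kruskal_wallis_dunn(table, metric, posthoc, p_adjust, gate)
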