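"""Nonparametric statistical cascade over per-cell metrics.

For each metric and chamber position stratum: a Kolmogorov–Smirnov check
of normality per group (reported, never gating), a Kruskal–Wallis
omnibus test across conditions, and two-sided Mann–Whitney U follow-ups
of every treatment against the control, starred at p < 0.05 (*) and
p < 0.001 (***). No multiple-testing correction is applied by default;
a Bonferroni option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatsReport", "run_stats", "significance_stars"]

MIN_GROUP_N = 3


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class StatsReport:
    metric: str
    normality: pd.DataFrame  # stratum, condition, n, ks_stat, ks_p
    omnibus: pd.DataFrame  # stratum, kw_H, kw_p, n_groups
    pairwise: pd.DataFrame  # stratum, condition, n, n_ctl, U, p, stars

    def summary(self) -> str:
        lines = [f"metric: {self.metric}"]
        for _, row in self.omnibus.iterrows():
            lines.append(
                f"  [{row.stratum}] Kruskal-Wallis H={row.kw_H:.3f} "
                f"p={row.kw_p:.3g} ({int(row.n_groups)} groups)"
            )
            sub = self.pairwise[self.pairwise.stratum == row.stratum]
            for _, pw in sub.iterrows():
                lines.append(
                    f"    {pw.condition} vs CTL: U={pw.U:.1f} "
                    f"p={pw.p:.3g} {pw.stars}"
                )
        return "\n".join(lines)


def _ks_normality(values: np.ndarray) -> tuple[float, float]:
    """KS statistic and p against a normal fitted to the sample."""
    mu, sd = float(np.mean(values)), float(np.std(values, ddof=1))
    if sd == 0:
        return float("nan"), float("nan")
    stat, p = sps.kstest(values, "norm", args=(mu, sd))
    return float(stat), float(p)


def run_stats(
    cells: pd.DataFrame,
    metric: str,
    condition_col: str = "condition",
    position_col: str = "position",
    control: str = "CTL",
    strata: list[str] | None = None,
    bonferroni: bool = False,
) -> StatsReport:
    """Run the full cascade on one metric of a per-cell table.

    Strata (position labels) with fewer than two conditions of at least
    three observations each are skipped with a warning. Pairwise tests
    are only run in strata where the omnibus test was computed.
    """
    for col in (metric, condition_col, position_col):
        if col not in cells.columns:
            raise KeyError(f"missing column {col!r}")
    data = cells[[metric, condition_col, position_col]].dropna()
    strata = strata or sorted(data[position_col].unique())

    norm_rows, omni_rows, pair_rows = [], [], []
    for stratum in strata:
        sub = data[data[position_col] == stratum]
        groups = {
            cond: g[metric].to_numpy(dtype=float)
            for cond, g in sub.groupby(condition_col)
            if len(g) >= MIN_GROUP_N
        }
        for cond, vals in groups.items():
            ks_stat, ks_p = _ks_normality(vals)
            norm_rows.append(
                {"stratum": stratum, "condition": cond, "n": len(vals),
                 "ks_stat": ks_stat, "ks_p": ks_p}
            )
        if len(groups) < 2:
            warnings.warn(
                f"stratum {stratum!r}: fewer than two groups with "
                f">= {MIN_GROUP_N} observations; skipped",
                stacklevel=2,
            )
            continue
        try:
            H, kw_p = sps.kruskal(*groups.values())
        except ValueError:  # all values identical across groups
            H, kw_p = float("nan"), 1.0
        omni_rows.append(
            {"stratum": stratum, "kw_H": float(H), "kw_p": float(kw_p),
             "n_groups": len(groups)}
        )
        if control not in groups:
            warnings.warn(f"stratum {stratum!r}: no {control} group for pairwise tests",
                          stacklevel=2)
            continue
        ctl_vals = groups[control]
        treatments = [c for c in groups if c != control]
        m = len(treatments) if bonferroni else 1
        for cond in treatments:
            vals = groups[cond]
            if np.all(vals == vals[0]) and np.all(ctl_vals == vals[0]):
                U, p = len(vals) * len(ctl_vals) / 2.0, 1.0
            else:
                U, p = sps.mannwhitneyu(vals, ctl_vals, alternative="two-sided")
            p = min(float(p) * m, 1.0)
            pair_rows.append(
                {"stratum": stratum, "condition": cond, "n": len(vals),
                 "n_ctl": len(ctl_vals), "U": float(U), "p": p,
                 "stars": significance_stars(p)}
            )
    return StatsReport(
        metric=metric,
        normality=pd.DataFrame(norm_rows, columns=["stratum", "condition", "n", "ks_stat", "ks_p"]),
        omnibus=pd.DataFrame(omni_rows, columns=["stratum", "kw_H", "kw_p", "n_groups"]),
        pairwise=pd.DataFrame(
            pair_rows,
            columns=["stratum", "condition", "n", "n_ctl", "U", "p", "stars"],
        ),
    )
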