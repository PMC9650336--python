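"""Group comparison of efficiency metrics: Welch's t-test with BH-FDR.

Global efficiency is compared between the ME and NE groups per (band,
threshold) with Welch's unequal-variance t-test.  Regional efficiencies are
tested the same way and corrected for multiple comparisons with the
Benjamini-Hochberg step-up procedure *within* each (band, threshold) family
of four scalp regions -- partitioning the scalp into four regions is itself
the device that keeps the family small.  Significance flags use p < alpha for
the global scope and FDR-adjusted q < alpha for regional scopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError, ParameterError

__all__ = [
    "GroupSample",
    "welch_t",
    "fdr_bh",
    "build_stats_table",
    "render_markdown",
]

GLOBAL_SCOPE = "global"
REGION_PREFIX = "region:"


@dataclass
class GroupSample:
    """Efficiency observations of one group for one (band, threshold, scope) cell."""

    values: np.ndarray
    group: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("group sample contains non-finite values")


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, Welch-Satterthwaite df, two-sided p).

    Two constant, equal samples leave the statistic undefined; two constant,
    different samples are reported as p = 0 (with a warning) since the groups
    are trivially separated.
    """
    a = np.asarray(getattr(a, "values", a), dtype=np.float64)
    b = np.asarray(getattr(b, "values", b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            raise DegenerateTestError("both groups constant and equal: t undefined")
        warnings.warn("both groups constant but different; reporting p = 0",
                      RuntimeWarning, stacklevel=2)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (monotone-adjusted q-values, reject flags).

    Rejection uses q < alpha; the reject set is always a prefix of the
    p-sorted hypothesis list.
    """
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    if np.any(pvals < 0) or np.any(pvals > 1) or not np.all(np.isfinite(pvals)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return qvals, qvals < alpha


def build_stats_table(observations: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Welch + FDR comparison table over efficiency observations.

    ``observations`` is tidy with columns (band, threshold, scope, group,
    value); scope is ``"global"`` or ``"region:<name>"`` and group is
    ``"ME"``/``"NE"``.  One output row per (band, threshold, scope) with group
    means/SDs, t, df, p, q and the significance flag.  Cells with fewer than
    two observations in either group are kept as missing rows (NaN statistics)
    rather than fabricated.
    """
    required = {"band", "threshold", "scope", "group", "value"}
    missing_cols = required - set(observations.columns)
    if missing_cols:
        raise ParameterError(f"observations missing columns: {sorted(missing_cols)}")
    rows = []
    for (band, thr, scope), cell in observations.groupby(
            ["band", "threshold", "scope"], sort=True):
        me = cell.loc[cell["group"] == "ME", "value"].to_numpy()
        ne = cell.loc[cell["group"] == "NE", "value"].to_numpy()
        row = {
            "band": band, "threshold": thr, "scope": scope,
            "n_me": me.size, "n_ne": ne.size,
            "mean_me": me.mean() if me.size else np.nan,
            "sd_me": me.std(ddof=1) if me.size > 1 else np.nan,
            "mean_ne": ne.mean() if ne.size else np.nan,
            "sd_ne": ne.std(ddof=1) if ne.size > 1 else np.nan,
            "t": np.nan, "df": np.nan, "p": np.nan,
        }
        if me.size >= 2 and ne.size >= 2:
            try:
                row["t"], row["df"], row["p"] = welch_t(me, ne)
            except DegenerateTestError:
                pass  # leave the cell's statistics missing
        rows.append(row)
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    table["significant"] = False
    is_global = table["scope"] == GLOBAL_SCOPE
    table.loc[is_global, "q"] = table.loc[is_global, "p"]
    # BH within each (band, threshold) family of regional scopes
    is_region = table["scope"].str.startswith(REGION_PREFIX)
    for (_, _), idx in table.loc[is_region].groupby(["band", "threshold"]).groups.items():
        ps = table.loc[idx, "p"]
        ok = ps.notna()
        if ok.any():
            q, rej = fdr_bh(ps[ok].to_numpy(), alpha=alpha)
            table.loc[ps[ok].index, "q"] = q
            table.loc[ps[ok].index, "significant"] = rej
    table.loc[is_global, "significant"] = table.loc[is_global, "p"] < alpha
    return table


def _fmt_cell(mean: float, sd: float) -> str:
    if np.isnan(mean):
        return "--"
    return f"{mean:.2f} ({sd:.2f})"


def _fmt_p(p: float, significant: bool) -> str:
    if np.isnan(p):
        return "--"
    if not significant:
        return "ns"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_markdown(table: pd.DataFrame, band: str, regional: bool = False) -> str:
    """Render one band's comparison as a Markdown table.

    Rows are thresholds; column blocks are the global scope or the four scalp
    regions, each showing "mean (SD)" per group and the (corrected) p-value,
    with non-significant cells printed as "ns".
    """
    sub = table[table["band"] == band]
    if regional:
        scopes = sorted(s for s in sub["scope"].unique() if s.startswith(REGION_PREFIX))
        names = [s.removeprefix(REGION_PREFIX) for s in scopes]
    else:
        scopes = [GLOBAL_SCOPE]
        names = ["global"]
    header = ["Threshold"]
    for name in names:
        header += [f"{name} MEs", f"{name} NEs", f"{name} p"]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for thr in sorted(sub["threshold"].unique()):
        cells = [f"{thr:.2f}"]
        for scope in scopes:
            row = sub[(sub["threshold"] == thr) & (sub["scope"] == scope)]
            if row.empty:
                cells += ["--", "--", "--"]
                continue
            r = row.iloc[0]
            pcol = r["q"] if scope != GLOBAL_SCOPE else r["p"]
            cells += [_fmt_cell(r["mean_me"], r["sd_me"]),
                      _fmt_cell(r["mean_ne"], r["sd_ne"]),
                      _fmt_p(pcol, bool(r["significant"]))]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
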