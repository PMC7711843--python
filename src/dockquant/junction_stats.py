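"""Correlation and summary statistics over measured docking sites.

The statistical readout mirrors the study design: plain Pearson correlation
coefficients between the four per-site measurements — morphology class code
(0/0.5/1), membrane separation (nm), GUV protrusion flag (0/1) and total
density count — with two-sided p-values from the t statistic
``t = r*sqrt((n-2)/(1-r^2))``, and verbal strength labels on |r|
(negligible < 0.1 <= small < 0.3 <= moderate < 0.5 <= strong).  Class code
and protrusion flag are deliberately treated as plain numeric columns, as
they are coded in the source data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CC_COLUMNS", "CCResult", "cc_matrix", "strength_label",
           "summarize", "simulate_junction_population"]

#: measurement columns entering the correlation matrix, in display order
CC_COLUMNS = ["class_code", "separation_nm", "protrusion_flag", "n_densities"]

_STRENGTH_BOUNDS = (0.1, 0.3, 0.5)


@dataclass
class CCResult:
    """Pearson correlation matrix over the four junction measurements."""

    r: pd.DataFrame  # symmetric, unit diagonal; NaN where undefined
    p: pd.DataFrame  # two-sided p-values from the t statistic
    n: int
    labels: pd.DataFrame = field(init=False)  # strength labels for |r|
    #: Bonferroni-adjusted p-values over the off-diagonal pairs (transparency
    #: column; the headline p-values are unadjusted)
    p_bonferroni: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.labels = self.r.map(strength_label)
        k = len(self.r)
        m = k * (k - 1) // 2
        self.p_bonferroni = (self.p * m).clip(upper=1.0)


def strength_label(r: float) -> str:
    """Verbal label for a correlation magnitude.

    |r| < 0.1 negligible, [0.1, 0.3) small, [0.3, 0.5) moderate,
    >= 0.5 strong; NaN maps to ``missing``.  Boundaries are left-closed.
    """
    if np.isnan(r):
        return "missing"
    a = abs(r)
    if a < _STRENGTH_BOUNDS[0]:
        return "negligible"
    if a < _STRENGTH_BOUNDS[1]:
        return "small"
    if a < _STRENGTH_BOUNDS[2]:
        return "moderate"
    return "strong"


def cc_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> CCResult:
    """Pairwise Pearson correlations over the measurement columns.

    Rows with a missing value in any used column are dropped.  A
    zero-variance column yields NaN (undefined, *not* zero) against every
    other column.  Requires at least 3 complete rows.
    """
    columns = columns or CC_COLUMNS
    data = table[columns].dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows for correlations, got {n}")
    x = data.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    k = len(columns)
    r = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                r[i, j] = 1.0 if sd[i] > 0 else np.nan
            elif sd[i] > 0 and sd[j] > 0:
                r[i, j] = np.corrcoef(x[:, i], x[:, j])[0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    idx = pd.Index(columns)
    return CCResult(pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx), n)


def cc_by_condition(table: pd.DataFrame,
                    condition_col: str = "condition_label",
                    columns: list[str] | None = None) -> dict[str, CCResult]:
    """Correlation matrices per condition plus the pooled matrix.

    Groups (or the pool) with fewer than 3 complete rows are skipped."""
    out = {}
    if len(table.dropna(subset=columns or CC_COLUMNS)) >= 3:
        out["pooled"] = cc_matrix(table, columns)
    if condition_col in table.columns:
        for label, g in table.groupby(condition_col, sort=False):
            if len(g.dropna(subset=columns or CC_COLUMNS)) >= 3:
                out[str(label)] = cc_matrix(g, columns)
    return out


def summarize(table: pd.DataFrame, bin_width: float = 1.0) -> dict:
    """Headline summary of a junction table.

    Returns, overall and per condition when a ``condition_label`` column is
    present: the fraction of sites with separation < 10 nm, the count with
    separation > 20 nm, per-class separation min/max, mean +/- SD of the
    density count, mean +/- SD of contact diameters over ring-like contacts,
    and per-class separation histograms (``bin_width`` nm bins) ready for a
    stacked plot.
    """
    def one(g: pd.DataFrame) -> dict:
        s = g["separation_nm"].dropna()
        out: dict = {"n_sites": int(len(g))}
        if len(s) == 0:
            out.update(frac_below_10nm=None, n_above_20nm=0)
        else:
            out["frac_below_10nm"] = float((s < 10.0).mean())
            out["n_above_20nm"] = int((s > 20.0).sum())
        out["separation_range_by_class"] = {
            _class_name(code): [float(cs.min()), float(cs.max())]
            for code, cg in g.groupby("class_code")
            if len(cs := cg["separation_nm"].dropna())
        }
        nd = g["n_densities"].dropna()
        out["n_densities_mean_sd"] = (
            [float(nd.mean()), float(nd.std(ddof=1))] if len(nd) > 1 else None)
        if "contact_diameter_nm" in g.columns:
            cd = g.loc[(g["class_code"] == 1.0) & (g["contact_diameter_nm"] > 0),
                       "contact_diameter_nm"].dropna()
            out["contact_diameter_mean_sd"] = (
                [float(cd.mean()), float(cd.std(ddof=1))] if len(cd) > 1 else None)
            out["n_ring_contacts"] = int(len(cd))
        if len(s):
            edges = np.arange(0.0, float(s.max()) + 2 * bin_width, bin_width)
            hist = {}
            for code, cg in g.groupby("class_code"):
                counts, _ = np.histogram(cg["separation_nm"].dropna(), bins=edges)
                hist[_class_name(code)] = counts.tolist()
            out["separation_histogram"] = {"bin_edges_nm": edges.tolist(),
                                           "counts_by_class": hist}
        return out

    report = {"overall": one(table)}
    if "condition_label" in table.columns:
        report["by_condition"] = {
            str(label): one(g)
            for label, g in table.groupby("condition_label", sort=False)
        }
    return report


def _class_name(code: float) -> str:
    return {0.0: "clustered", 0.5: "intermediate", 1.0: "ring_like"}.get(
        float(code), f"class_{code}")


def simulate_junction_population(n: int, seed: int,
                                 class_probs=(1 / 3, 1 / 3, 1 / 3),
                                 separation_ranges=((5.0, 26.0), (3.0, 8.0),
                                                    (0.0, 7.0))) -> pd.DataFrame:
    """Idealised junction population for statistical checks.

    Draws class codes 0/0.5/1 with the given probabilities and, per class,
    membrane separations uniform over the class range — the population model
    under which the class/separation correlation has the closed form
    ``r = Cov / sqrt(Var_code * Var_sep)`` (equal class probabilities and the
    default ranges give r ~ -0.757).  No rendering or measurement noise.
    """
    rng = np.random.default_rng(seed)
    cls = rng.choice(3, size=n, p=list(class_probs))
    codes = np.array([0.0, 0.5, 1.0])[cls]
    ranges = np.asarray(separation_ranges, float)
    lo, hi = ranges[cls, 0], ranges[cls, 1]
    sep = rng.uniform(lo, hi)
    return pd.DataFrame({"class_code": codes, "separation_nm": sep})
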