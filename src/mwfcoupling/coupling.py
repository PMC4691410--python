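"""Age-residualized coupling between regional measures.

For each region and each measure pair — (thickness, adjacent-WM MWF),
(thickness, cortical MWF), (cortical MWF, adjacent-WM MWF) — the Pearson
product-moment correlation of the age residuals is computed, converted to a
two-sided p-value through the exact t transform with n - 2 degrees of
freedom, and flagged for significance with the Holm-Bonferroni step-down
procedure at a family-wise alpha of 0.05.  The default family is the 33
regions of one hemisphere for one measure pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import COUPLING_PAIRS

__all__ = [
    "CouplingResult",
    "pearson_r",
    "pearson_p",
    "holm_bonferroni",
    "coupling_analysis",
]


@dataclass(frozen=True)
class CouplingResult:
    region: str
    hemisphere: str
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    significant: bool
    alpha: float
    family_size: int


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a series")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via the t transform.

    t = r sqrt(n-2) / sqrt(1-r^2) is Student-t with n - 2 degrees of freedom
    under the null of zero correlation; |r| = 1 returns the p = 0 sentinel.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df))


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection flags, in input order.

    Sort p ascending; reject the k-th smallest (1-based) while
    p_(k) < alpha / (m - k + 1); the first failure stops the procedure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):  # k is 0-based rank
        if p[idx] < alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject


def coupling_analysis(
    residual_table: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = COUPLING_PAIRS,
    alpha: float = 0.05,
    family: str = "per_hemisphere",
) -> pd.DataFrame:
    """Region-wise residual correlations with family-wise correction.

    ``residual_table`` is long over (region, hemisphere) with one row per
    scan and ``resid_<measure>`` columns.  Each (hemisphere, pair) family —
    33 regions by default — receives its own Holm-Bonferroni correction;
    ``family="pooled"`` corrects over both hemispheres jointly.  Regions
    missing a residual column entry are skipped with a warning.
    """
    if family not in ("per_hemisphere", "pooled"):
        raise ValueError(f"unknown family {family!r}")
    results: list[CouplingResult] = []
    rows = []
    for (region, hemi), grp in residual_table.groupby(["region", "hemisphere"], sort=True):
        for pair in pairs:
            cols = [f"resid_{m}" for m in pair]
            if any(c not in grp or grp[c].isna().any() for c in cols):
                warnings.warn(
                    f"skipping region {region!r} ({hemi}): missing residuals for {pair}",
                    stacklevel=2,
                )
                continue
            x, y = (grp[c].to_numpy() for c in cols)
            r = pearson_r(x, y)
            rows.append(
                {
                    "region": region,
                    "hemisphere": hemi,
                    "measure_a": pair[0],
                    "measure_b": pair[1],
                    "r": r,
                    "p": pearson_p(r, len(x)),
                    "n": len(x),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(significant=[], alpha=[], family_size=[])

    group_cols = ["measure_a", "measure_b"]
    if family == "per_hemisphere":
        group_cols = ["hemisphere", *group_cols]
    out["significant"] = False
    out["family_size"] = 0
    for _, grp in out.groupby(group_cols, sort=False):
        flags = holm_bonferroni(grp["p"].to_numpy(), alpha=alpha)
        out.loc[grp.index, "significant"] = flags
        out.loc[grp.index, "family_size"] = len(grp)
    out["alpha"] = alpha
    return out
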