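"""Ideal T1-weighted signal and gray / adjacent-white-matter contrast.

An inversion-recovery readout at inversion time TI, ignoring proton-density
effects, has the ideal signal S(T1) = 1 - 2 exp(-TI/T1).  With TI = 950 ms
(the MP-RAGE inversion time of the study protocols), the regional contrast
between adjacent white matter and cortical gray matter is S(T1_wm) -
S(T1_gm); since WM T1 is shorter than GM T1 in this age range the contrast
is positive.  Region-wise, contrast is correlated against cortical
thickness (age-residualized by default) with the same Pearson and
Holm-Bonferroni machinery used for the MWF couplings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coupling import holm_bonferroni, pearson_p, pearson_r
from .trajectories import residualize

__all__ = [
    "DEFAULT_TI_MS",
    "ideal_signal",
    "gm_wm_contrast",
    "add_contrast_columns",
    "contrast_thickness_correlation",
]

DEFAULT_TI_MS = 950.0


def ideal_signal(t1_ms, ti_ms: float = DEFAULT_TI_MS):
    """Ideal inversion-recovery signal 1 - 2 exp(-TI/T1).

    Strictly decreasing in T1, strictly increasing in TI, bounded in (-1, 1).
    Accepts scalars or arrays.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if ti_ms <= 0:
        raise ValueError("TI must be positive")
    out = 1.0 - 2.0 * np.exp(-ti_ms / t1)
    return float(out) if np.isscalar(t1_ms) else out


def gm_wm_contrast(
    t1_gm_ms,
    t1_wm_ms,
    ti_ms: float = DEFAULT_TI_MS,
    mode: str = "signed",
):
    """Gray / adjacent-WM contrast of ideal T1-weighted signals.

    ``signed`` (default): S(T1_wm) - S(T1_gm).  ``michelson``:
    (S_wm - S_gm) / (|S_wm| + |S_gm|), an amplitude-normalized alternative.
    """
    s_gm = ideal_signal(t1_gm_ms, ti_ms)
    s_wm = ideal_signal(t1_wm_ms, ti_ms)
    if mode == "signed":
        return s_wm - s_gm
    if mode == "michelson":
        return (s_wm - s_gm) / (np.abs(s_wm) + np.abs(s_gm))
    raise ValueError(f"unknown contrast mode {mode!r}")


def add_contrast_columns(
    table: pd.DataFrame,
    ti_ms: float = DEFAULT_TI_MS,
    mode: str = "signed",
) -> pd.DataFrame:
    """Append ``s_gm``, ``s_wm`` and ``t1_contrast`` per scan-region row from
    the ``cortical_t1_ms`` / ``adjacent_t1_ms`` columns."""
    out = table.copy()
    out["s_gm"] = ideal_signal(out["cortical_t1_ms"].to_numpy(), ti_ms)
    out["s_wm"] = ideal_signal(out["adjacent_t1_ms"].to_numpy(), ti_ms)
    out["t1_contrast"] = gm_wm_contrast(
        out["cortical_t1_ms"].to_numpy(), out["adjacent_t1_ms"].to_numpy(), ti_ms, mode
    )
    return out


def contrast_thickness_correlation(
    table: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "per_hemisphere",
    residualize_by_age: bool = True,
    ti_ms: float = DEFAULT_TI_MS,
    mode: str = "signed",
) -> pd.DataFrame:
    """Region-wise Pearson correlation of T1 contrast with cortical thickness.

    Both series are age-residualized against a logarithmic trajectory by
    default; ``residualize_by_age=False`` correlates the raw values.  Regions
    where either series is constant across scans are reported with NaN r and
    excluded from the correction family.
    """
    if "t1_contrast" not in table:
        table = add_contrast_columns(table, ti_ms=ti_ms, mode=mode)
    rows = []
    for (region, hemi), grp in table.groupby(["region", "hemisphere"], sort=True):
        ages = grp["age_days"].to_numpy()
        c = grp["t1_contrast"].to_numpy()
        th = grp["thickness_mm"].to_numpy()
        try:
            if residualize_by_age:
                c = residualize(ages, c)
                th = residualize(ages, th)
            r = pearson_r(c, th)
            p = pearson_p(r, len(c))
        except ValueError:
            r, p = float("nan"), float("nan")
        rows.append(
            {"region": region, "hemisphere": hemi, "r": r, "p": p, "n": len(grp)}
        )
    out = pd.DataFrame(rows)
    out["significant"] = False
    out["family_size"] = 0
    valid = out[out["p"].notna()]
    keys = valid["hemisphere"] if family == "per_hemisphere" else np.zeros(len(valid))
    for _, grp in valid.groupby(keys, sort=False):
        flags = holm_bonferroni(grp["p"].to_numpy(), alpha=alpha)
        out.loc[grp.index, "significant"] = flags
        out.loc[grp.index, "family_size"] = len(grp)
    out["alpha"] = alpha
    return out
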