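"""Growth-trajectory fitting and model selection.

Per (region, hemisphere, measure) series, three candidate age models are
fitted by ordinary least squares:

    logarithmic   y = a ln(t) + b
    linear        y = a t + b
    quadratic     y = c2 t^2 + c1 t + c0

with t the age in days.  Models are compared by the Bayesian Information
Criterion BIC = n ln(RSS/n) + k ln(n) with k the number of regression
coefficients; the minimal-BIC model wins and near-ties (delta BIC below a
threshold, default 2) are reported alongside.  Residualizing a measure
against its fitted trajectory removes the age effect before any
cross-measure correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_FORMS",
    "TrajectoryFit",
    "ModelSelection",
    "design_matrix",
    "fit_model",
    "bic",
    "select_model",
    "residualize",
    "fit_cohort",
    "residualize_cohort",
]

#: canonical model-form order; also the deterministic tie-break order
MODEL_FORMS = ("logarithmic", "quadratic", "linear")

_N_PARAMS = {"logarithmic": 2, "linear": 2, "quadratic": 3}


@dataclass(frozen=True)
class TrajectoryFit:
    """One model form fitted by OLS to one age series.

    ``coefficients`` are ``(a, b)`` for logarithmic/linear and
    ``(c2, c1, c0)`` for quadratic.  A perfect fit (RSS = 0) carries a
    ``bic`` of -inf as a sentinel.
    """

    model_form: str
    coefficients: tuple[float, ...]
    rss: float
    n_obs: int
    bic: float

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def predict(self, ages_days: np.ndarray) -> np.ndarray:
        X = design_matrix(np.asarray(ages_days, dtype=float), self.model_form)
        return X @ np.asarray(self.coefficients)


@dataclass(frozen=True)
class ModelSelection:
    fits: dict[str, TrajectoryFit]
    best: str
    ties: tuple[str, ...]


def design_matrix(ages_days: np.ndarray, model_form: str) -> np.ndarray:
    t = np.asarray(ages_days, dtype=float)
    if model_form == "logarithmic":
        if np.any(t <= 0):
            raise ValueError("ages must be positive for the logarithmic model")
        return np.column_stack([np.log(t), np.ones_like(t)])
    if model_form == "linear":
        return np.column_stack([t, np.ones_like(t)])
    if model_form == "quadratic":
        return np.column_stack([t**2, t, np.ones_like(t)])
    raise ValueError(f"unknown model form {model_form!r}")


def bic(rss: float, n_obs: int, n_params: int) -> float:
    """BIC = n ln(RSS/n) + k ln(n); -inf sentinel for a perfect fit."""
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0.0:
        return float("-inf")
    return n_obs * math.log(rss / n_obs) + n_params * math.log(n_obs)


def fit_model(ages_days, values, model_form: str = "logarithmic") -> TrajectoryFit:
    """Ordinary least squares fit of one age model.

    Solves the normal equations exactly (via LAPACK least squares); raises
    on a rank-deficient design, e.g. when all ages coincide.
    """
    t = np.asarray(ages_days, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("ages and values must be 1-D and equally long")
    k = _N_PARAMS[model_form]
    if len(y) < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {model_form}")
    X = design_matrix(t, model_form)
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(f"rank-deficient design for {model_form} (degenerate ages)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    # numerically-zero RSS means a perfect fit
    if rss < 1e-12 * max(1.0, float(y @ y)):
        rss = 0.0
    return TrajectoryFit(
        model_form=model_form,
        coefficients=tuple(float(c) for c in beta),
        rss=rss,
        n_obs=len(y),
        bic=bic(rss, len(y), k),
    )


def select_model(fits, tie_threshold: float = 2.0) -> ModelSelection:
    """Pick the minimal-BIC fit; report near-ties (delta BIC < threshold).

    Ties in the exact minimum are broken by the canonical model-form order
    (logarithmic, quadratic, linear).  All fits must share ``n_obs``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select among")
    if len({f.n_obs for f in fits}) > 1:
        raise ValueError("fits compare different n_obs")
    by_form = {f.model_form: f for f in fits}
    ordered = [f for form in MODEL_FORMS for f in (by_form.get(form),) if f is not None]
    best = min(ordered, key=lambda f: f.bic)  # min is stable: canonical order breaks ties
    ties = tuple(
        f.model_form
        for f in ordered
        if f.model_form != best.model_form and f.bic - best.bic < tie_threshold
    )
    return ModelSelection(fits=by_form, best=best.model_form, ties=ties)


def residualize(ages_days, values, model_form: str = "logarithmic") -> np.ndarray:
    """Residuals of an OLS age-trajectory fit (mean zero by construction)."""
    fit = fit_model(ages_days, values, model_form)
    return np.asarray(values, dtype=float) - fit.predict(np.asarray(ages_days, dtype=float))


def fit_cohort(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("thickness_mm", "cortical_mwf", "adjacent_mwf"),
    model_forms: tuple[str, ...] = MODEL_FORMS,
    tie_threshold: float = 2.0,
) -> pd.DataFrame:
    """Fit every model form per (region, hemisphere, measure) of a long scan
    table; returns one row per fit with coefficients, RSS, BIC and the
    selected model flagged."""
    rows = []
    for (region, hemi), grp in table.groupby(["region", "hemisphere"], sort=True):
        ages = grp["age_days"].to_numpy()
        for measure in measures:
            fits = [fit_model(ages, grp[measure].to_numpy(), form) for form in model_forms]
            sel = select_model(fits, tie_threshold)
            for f in fits:
                coefs = f.coefficients + (math.nan,) * (3 - len(f.coefficients))
                rows.append(
                    {
                        "region": region,
                        "hemisphere": hemi,
                        "measure": measure,
                        "model_form": f.model_form,
                        "coef_hi": coefs[0],
                        "coef_mid": coefs[1],
                        "coef_lo": coefs[2],
                        "rss": f.rss,
                        "n_obs": f.n_obs,
                        "bic": f.bic,
                        "selected": f.model_form == sel.best,
                        "tie": f.model_form in sel.ties,
                    }
                )
    return pd.DataFrame(rows)


def residualize_cohort(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("thickness_mm", "cortical_mwf", "adjacent_mwf"),
    model_form: str = "logarithmic",
) -> pd.DataFrame:
    """Append ``resid_<measure>`` columns: per (region, hemisphere) residuals
    from the chosen trajectory form (logarithmic throughout by default)."""
    out = table.copy()
    for m in measures:
        out[f"resid_{m}"] = np.nan
    for (_, _), grp in table.groupby(["region", "hemisphere"], sort=False):
        ages = grp["age_days"].to_numpy()
        for m in measures:
            out.loc[grp.index, f"resid_{m}"] = residualize(ages, grp[m].to_numpy(), model_form)
    return out
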