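"""Synthetic developmental cohorts with the statistical structure the
region-wise coupling analysis assumes.

The generator emulates a longitudinal early-childhood imaging study: 134
children contributing 177 scans (36 children scanned at least twice, 7 of
those three times, repeat visits roughly one year apart), ages 363-2198 days
corrected to a 40-week gestation, and 33 bilateral cortical regions.  Per
region, cortical thickness and the two myelin water fractions follow
logarithmic-in-age trajectories ``a * ln(age_days) + b``; the three residuals
are drawn jointly from a zero-mean trivariate normal whose correlation
matrix encodes the age-independent coupling between the measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .reference import MEASURES

__all__ = [
    "CohortSpec",
    "RegionTrajectorySpec",
    "ResidualCouplingSpec",
    "T1Spec",
    "generate_ages",
    "generate_measures",
    "generate_cohort_table",
    "default_trajectory_specs",
    "default_coupling_specs",
    "DEFAULT_RESIDUAL_SD",
]

HEMISPHERES = ("left", "right")

#: default residual standard deviations per measure (mm for thickness,
#: MWF fraction for the myelin measures)
DEFAULT_RESIDUAL_SD = {
    "thickness_mm": 0.1,
    "adjacent_mwf": 0.01,
    "cortical_mwf": 0.01,
}


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal cohort layout.

    ``n_repeat2`` counts children scanned at least twice; ``n_repeat3`` is
    the subset of those scanned a third time, so the total number of scans
    is ``n_children + n_repeat2 + n_repeat3``.
    """

    n_children: int = 134
    n_repeat2: int = 36
    n_repeat3: int = 7
    age_range_days: tuple[float, float] = (363.0, 2198.0)
    mean_repeat_gap_days: float = 365.0
    repeat_gap_sd_days: float = 60.0
    age_distribution: str = "uniform"  # or "truncnorm"
    age_mean_days: float = 1044.0
    age_sd_days: float = 523.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeat3 > self.n_repeat2:
            raise ValueError("n_repeat3 must not exceed n_repeat2")
        if self.n_repeat2 > self.n_children:
            raise ValueError("n_repeat2 must not exceed n_children")
        lo, hi = self.age_range_days
        if not lo < hi:
            raise ValueError("age_range_days must satisfy min < max")
        if self.age_distribution not in ("uniform", "truncnorm"):
            raise ValueError(f"unknown age_distribution {self.age_distribution!r}")

    @property
    def n_scans(self) -> int:
        return self.n_children + self.n_repeat2 + self.n_repeat3


@dataclass(frozen=True)
class RegionTrajectorySpec:
    """Logarithmic growth model per measure for one (region, hemisphere).

    ``coefficients[measure] = (a, b)`` with model ``a * ln(age_days) + b``;
    ``residual_sd[measure]`` is the SD of the additive Gaussian residual in
    the measure's own units.
    """

    region: str
    hemisphere: str
    coefficients: dict[str, tuple[float, float]]
    residual_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_SD)
    )

    def __post_init__(self) -> None:
        for m in MEASURES:
            if m not in self.coefficients:
                raise ValueError(f"missing coefficients for measure {m!r}")
            if self.residual_sd.get(m, 0.0) < 0:
                raise ValueError(f"negative residual_sd for measure {m!r}")

    def mean(self, measure: str, age_days: np.ndarray) -> np.ndarray:
        a, b = self.coefficients[measure]
        return a * np.log(age_days) + b


@dataclass(frozen=True)
class ResidualCouplingSpec:
    """3x3 residual correlation matrix over ``MEASURES`` for one region."""

    region: str
    hemisphere: str
    corr_matrix: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.corr_matrix, dtype=float)
        if c.shape != (3, 3):
            raise ValueError("corr_matrix must be 3x3")
        if not np.allclose(c, c.T):
            raise ValueError(f"corr_matrix for region {self.region!r} not symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError(f"corr_matrix for region {self.region!r} lacks unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError(
                f"corr_matrix for region {self.region!r} is not positive semi-definite"
            )
        object.__setattr__(self, "corr_matrix", c)


@dataclass(frozen=True)
class T1Spec:
    """Regional longitudinal relaxation time generation.

    T1 is modelled as flat (or slowly varying logarithmically) in age with
    additive Gaussian noise; order-of-magnitude 3T early-childhood defaults.
    """

    gm_ms: float = 1400.0
    wm_ms: float = 900.0
    gm_log_slope: float = 0.0  # ms per ln(day)
    wm_log_slope: float = 0.0
    noise_sd_ms: float = 0.0


def generate_ages(spec: CohortSpec) -> pd.DataFrame:
    """Sample scan ages for a longitudinal cohort.

    Returns a table with columns ``child_id``, ``scan_id``, ``age_days``,
    one row per scan.  The first ``n_repeat2`` children receive a second
    scan one jittered gap later, and the first ``n_repeat3`` of those a
    third; repeat ages are truncated to the cohort age range.  Deterministic
    given ``spec.seed``.
    """
    lo, hi = spec.age_range_days
    if (spec.n_repeat2 or spec.n_repeat3) and hi - lo <= spec.mean_repeat_gap_days / 2:
        raise ValueError(
            "infeasible repeat structure: age range too narrow for the repeat gap"
        )
    rng = np.random.default_rng(spec.seed)

    n_extra = np.zeros(spec.n_children, dtype=int)
    n_extra[: spec.n_repeat2] += 1
    n_extra[: spec.n_repeat3] += 1

    if spec.age_distribution == "uniform":
        first = rng.uniform(lo, hi, spec.n_children)
    else:
        a, b = (lo - spec.age_mean_days) / spec.age_sd_days, (
            hi - spec.age_mean_days
        ) / spec.age_sd_days
        first = stats.truncnorm.rvs(
            a, b, loc=spec.age_mean_days, scale=spec.age_sd_days,
            size=spec.n_children, random_state=rng,
        )
    # leave room so repeat scans do not all pile up at the range ceiling
    room = n_extra * spec.mean_repeat_gap_days
    first = np.minimum(first, hi - room)
    first = np.maximum(first, lo)

    rows = []
    for child in range(spec.n_children):
        age = first[child]
        rows.append((f"sub-{child:03d}", f"sub-{child:03d}_ses-1", age))
        for visit in range(n_extra[child]):
            gap = rng.normal(spec.mean_repeat_gap_days, spec.repeat_gap_sd_days)
            age = float(np.clip(age + max(gap, 1.0), lo, hi))
            rows.append((f"sub-{child:03d}", f"sub-{child:03d}_ses-{visit + 2}", age))
    return pd.DataFrame(rows, columns=["child_id", "scan_id", "age_days"])


def default_trajectory_specs(
    hemispheres: tuple[str, ...] = HEMISPHERES,
    residual_sd: dict[str, float] | None = None,
) -> list[RegionTrajectorySpec]:
    """Trajectory specs for all 33 regions from the published left-hemisphere
    coefficients (mirrored onto the right hemisphere)."""
    sd = dict(DEFAULT_RESIDUAL_SD if residual_sd is None else residual_sd)
    return [
        RegionTrajectorySpec(
            region=region,
            hemisphere=hemi,
            coefficients={m: reference.TRAJECTORY_COEFFICIENTS[region][m] for m in MEASURES},
            residual_sd=sd,
        )
        for region in reference.REGIONS
        for hemi in hemispheres
    ]


def default_coupling_specs(
    hemispheres: tuple[str, ...] = HEMISPHERES,
    zero_coupling: bool = False,
) -> list[ResidualCouplingSpec]:
    """Residual coupling specs from the published region-wise correlations.

    ``zero_coupling=True`` substitutes the identity matrix everywhere (null
    cohort for calibration checks).
    """
    return [
        ResidualCouplingSpec(
            region=region,
            hemisphere=hemi,
            corr_matrix=np.eye(3)
            if zero_coupling
            else reference.coupling_correlation_matrix(region),
        )
        for region in reference.REGIONS
        for hemi in hemispheres
    ]


def generate_measures(
    ages: pd.DataFrame,
    traj_specs: list[RegionTrajectorySpec],
    coupling_specs: list[ResidualCouplingSpec],
    seed: int = 0,
    t1_spec: T1Spec | None = None,
    child_intercept_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw per-scan regional measures around their age trajectories.

    For every scan and (region, hemisphere), the three measures are the
    trajectory means plus a correlated residual triple: ``eps ~ N(0, D C D)``
    with ``C`` the region's residual correlation matrix and ``D`` the
    diagonal of residual SDs.  Regional T1 values are generated from
    ``t1_spec`` (flat by default).  MWF columns are clipped to [0, 1].

    ``child_intercept_sd`` optionally adds a shared per-child random
    intercept per measure, introducing within-subject dependence between
    repeat scans (off by default: all scans treated as exchangeable).
    """
    t1_spec = t1_spec or T1Spec()
    coupling_by_key = {(c.region, c.hemisphere): c for c in coupling_specs}
    rng = np.random.default_rng(seed)

    age = ages["age_days"].to_numpy(dtype=float)
    log_age = np.log(age)
    n = len(age)

    child_ids = ages["child_id"].to_numpy()
    intercepts: dict[str, dict] = {}
    if child_intercept_sd:
        uniq = pd.unique(child_ids)
        for m, sd in child_intercept_sd.items():
            draws = rng.normal(0.0, sd, len(uniq))
            intercepts[m] = dict(zip(uniq, draws))

    frames = []
    for ts in traj_specs:
        key = (ts.region, ts.hemisphere)
        if key not in coupling_by_key:
            raise ValueError(f"no ResidualCouplingSpec for {key}")
        corr = coupling_by_key[key].corr_matrix
        sds = np.array([ts.residual_sd.get(m, 0.0) for m in MEASURES])
        cov = corr * np.outer(sds, sds)
        if np.any(sds > 0):
            eps = rng.multivariate_normal(np.zeros(3), cov, size=n)
        else:
            eps = np.zeros((n, 3))

        cols = {
            "child_id": child_ids,
            "scan_id": ages["scan_id"].to_numpy(),
            "age_days": age,
            "region": ts.region,
            "hemisphere": ts.hemisphere,
        }
        for j, m in enumerate(MEASURES):
            a, b = ts.coefficients[m]
            vals = a * log_age + b + eps[:, j]
            if intercepts.get(m):
                vals = vals + np.array([intercepts[m][c] for c in child_ids])
            if m.endswith("_mwf"):
                vals = np.clip(vals, 0.0, 1.0)
            cols[m] = vals
        t1_noise = (
            rng.normal(0.0, t1_spec.noise_sd_ms, (n, 2))
            if t1_spec.noise_sd_ms > 0
            else np.zeros((n, 2))
        )
        cols["cortical_t1_ms"] = t1_spec.gm_ms + t1_spec.gm_log_slope * log_age + t1_noise[:, 0]
        cols["adjacent_t1_ms"] = t1_spec.wm_ms + t1_spec.wm_log_slope * log_age + t1_noise[:, 1]
        frames.append(pd.DataFrame(cols))

    return pd.concat(frames, ignore_index=True)


def generate_cohort_table(
    cohort: CohortSpec | None = None,
    traj_specs: list[RegionTrajectorySpec] | None = None,
    coupling_specs: list[ResidualCouplingSpec] | None = None,
    seed: int | None = None,
    **measure_kwargs,
) -> pd.DataFrame:
    """End-to-end convenience: ages plus measures with study-default specs."""
    cohort = cohort or CohortSpec()
    if seed is not None:
        cohort = replace(cohort, seed=seed)
    ages = generate_ages(cohort)
    return generate_measures(
        ages,
        traj_specs or default_trajectory_specs(),
        coupling_specs or default_coupling_specs(),
        # decouple the measure stream from the age stream
        seed=(cohort.seed * 69069 + 12345) % (2**31 - 1),
        **measure_kwargs,
    )
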