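"""End-to-end orchestration: simulate -> extract -> fit -> couple ->
contrast -> report.

Stages exchange long-format TSV tables (one row per scan x region), so a
user can substitute real Freesurfer / relaxometry extractions for the
synthetic stage.  Every output table carries the seed and a short
configuration hash for provenance; re-running with the same configuration
reproduces the files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import contrast as contrast_mod
from . import coupling as coupling_mod
from . import trajectories
from .geometry import BlurSpec, extract_regional_measures
from .phantom import PhantomSpec, generate_phantom
from .synthetic import CohortSpec, T1Spec, generate_cohort_table

logger = logging.getLogger("mwfcoupling")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    t1: T1Spec = field(default_factory=T1Spec)
    blur: BlurSpec = field(default_factory=BlurSpec)
    tie_threshold: float = 2.0
    alpha: float = 0.05
    family: str = "per_hemisphere"  # or "pooled"
    ti_ms: float = contrast_mod.DEFAULT_TI_MS
    contrast_mode: str = "signed"
    contrast_residualized: bool = True
    out_dir: str = "mwfcoupling-out"
    make_plots: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:10]


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    df = df.copy()
    df["seed"] = cfg.seed
    df["config"] = cfg.config_hash()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %s (%d rows)", path, len(df))


def run_pipeline(
    config: PipelineConfig,
    scan_table: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle to ``out_dir``.

    ``scan_table`` may supply a pre-existing long scan table (e.g. real
    extractions); otherwise a synthetic cohort is generated with the
    configured seed.  Returns the bundle as a dict of DataFrames:
    ``scans``, ``coefficients``, ``model_selection``, ``coupling``,
    ``contrast``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}
    t0 = time.perf_counter()

    if scan_table is None:
        from dataclasses import replace

        cohort = replace(config.cohort, seed=config.seed)
        scan_table = generate_cohort_table(cohort, t1_spec=config.t1)
    bundle["scans"] = scan_table
    _write(scan_table, out / "scans.tsv", config)

    fits = trajectories.fit_cohort(scan_table, tie_threshold=config.tie_threshold)
    coefficients = fits[fits["model_form"] == "logarithmic"][
        ["region", "hemisphere", "measure", "coef_hi", "coef_mid", "rss", "n_obs"]
    ].rename(columns={"coef_hi": "log_slope", "coef_mid": "intercept"})
    bundle["coefficients"] = coefficients
    _write(coefficients, out / "coefficients.tsv", config)

    selection = fits.pivot_table(
        index=["region", "hemisphere", "measure"], columns="model_form", values="bic"
    ).reset_index()
    best = (
        fits[fits["selected"]]
        .set_index(["region", "hemisphere", "measure"])["model_form"]
        .rename("best")
    )
    selection = selection.join(best, on=["region", "hemisphere", "measure"])
    bundle["model_selection"] = selection
    _write(selection, out / "model_selection.tsv", config)

    residuals = trajectories.residualize_cohort(scan_table)
    coupling = coupling_mod.coupling_analysis(
        residuals, alpha=config.alpha, family=config.family
    )
    bundle["coupling"] = coupling
    _write(coupling, out / "coupling.tsv", config)

    contrast_table = contrast_mod.add_contrast_columns(
        scan_table, ti_ms=config.ti_ms, mode=config.contrast_mode
    )
    contrast_corr = contrast_mod.contrast_thickness_correlation(
        contrast_table,
        alpha=config.alpha,
        family=config.family,
        residualize_by_age=config.contrast_residualized,
        ti_ms=config.ti_ms,
        mode=config.contrast_mode,
    )
    bundle["contrast"] = contrast_corr
    _write(contrast_corr, out / "contrast.tsv", config)

    if config.make_plots:
        _plot_bundle(bundle, out)

    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return bundle


def extract_phantom(
    phantom_spec: PhantomSpec,
    blur_spec: BlurSpec | None = None,
    scan_id: str = "scan-0",
) -> pd.DataFrame:
    """Phantom-only stage: generate volumes and run regional extraction."""
    labels, mwf, t1 = generate_phantom(phantom_spec)
    return extract_regional_measures(labels, mwf, t1, blur_spec, scan_id=scan_id)


def _plot_bundle(bundle: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    scans = bundle["scans"]
    regions = list(scans["region"].unique())[:3]
    fig, axes = plt.subplots(1, len(regions), figsize=(4 * len(regions), 3.2), squeeze=False)
    for ax, region in zip(axes[0], regions):
        grp = scans[(scans["region"] == region) & (scans["hemisphere"] == "left")]
        ax.scatter(grp["age_days"], grp["thickness_mm"], s=6, alpha=0.6)
        ages = np.linspace(grp["age_days"].min(), grp["age_days"].max(), 100)
        fit = trajectories.fit_model(grp["age_days"], grp["thickness_mm"], "logarithmic")
        ax.plot(ages, fit.predict(ages), color="k")
        ax.set_title(region, fontsize=8)
        ax.set_xlabel("age (days)")
        ax.set_ylabel("thickness (mm)")
    fig.tight_layout()
    fig.savefig(out / "trajectories.png", dpi=120)
    plt.close(fig)
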