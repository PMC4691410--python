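"""Small volumetric phantoms: a white-matter core wrapped by a parcellated
cortical ribbon, with piecewise-constant MWF and T1 maps.

The geometry is a concentric cuboid: a WM core at the centre of the grid, a
GM shell (the "cortical ribbon") of configurable thickness around it, and
background elsewhere.  The shell is cut into ``n_regions`` parcels by equal
angular sectors in the axial plane; the core is cut by the same sectors so
that each parcel has its own stretch of adjacent white matter.  This is a
stand-in for a Freesurfer-style parcellation plus quantitative maps on a
shared voxel grid — just enough structure to exercise mask blurring,
subtraction and regional averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GM, WM, LabelEntry, LabelVolume, QuantMap

__all__ = ["PhantomRegionValues", "PhantomSpec", "generate_phantom"]


@dataclass(frozen=True)
class PhantomRegionValues:
    """Quantitative values for one parcel and its adjacent WM sector."""

    mwf_gm: float
    mwf_wm: float
    t1_gm_ms: float = 1400.0
    t1_wm_ms: float = 900.0


def _default_region_values(n: int) -> tuple[PhantomRegionValues, ...]:
    # distinct, physiologically plausible values so mix-ups are detectable
    return tuple(
        PhantomRegionValues(
            mwf_gm=0.06 + 0.01 * k,
            mwf_wm=0.12 + 0.02 * k,
            t1_gm_ms=1400.0 - 20.0 * k,
            t1_wm_ms=900.0 - 15.0 * k,
        )
        for k in range(n)
    )


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 1.2
    n_regions: int = 4
    ribbon_thickness_voxels: int = 2
    margin_voxels: int = 3
    region_values: tuple[PhantomRegionValues, ...] | None = None
    noise_sd: float = 0.0
    t1_noise_sd_ms: float = 0.0
    hemisphere: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        nx, ny, _ = self.grid_shape
        core = min(nx, ny) - 2 * (self.margin_voxels + self.ribbon_thickness_voxels)
        if core < 2:
            raise ValueError(
                "grid too small for ribbon + core: "
                f"shape {self.grid_shape}, ribbon {self.ribbon_thickness_voxels}, "
                f"margin {self.margin_voxels}"
            )
        if self.region_values is not None and len(self.region_values) != self.n_regions:
            raise ValueError("region_values length must equal n_regions")

    @property
    def values(self) -> tuple[PhantomRegionValues, ...]:
        return self.region_values or _default_region_values(self.n_regions)

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(f"parcel-{k:02d}" for k in range(self.n_regions))


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, QuantMap, QuantMap]:
    """Build (labels, MWF map, T1 map) on a shared grid and affine.

    Labels: 0 background, 1 WM core, 2..n_regions+1 the GM parcels.  Maps
    are piecewise constant at the spec's regional values plus optional
    Gaussian noise (MWF clipped to [0, 1] afterwards).
    """
    nx, ny, nz = spec.grid_shape
    m = spec.margin_voxels
    rib = spec.ribbon_thickness_voxels

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    # Chebyshev distance from centre gives square rings
    half_outer_x, half_outer_y = nx / 2.0 - m, ny / 2.0 - m
    dx, dy = np.abs(x - cx), np.abs(y - cy)
    inside_outer = (dx <= half_outer_x - 0.5) & (dy <= half_outer_y - 0.5)
    inside_core = (dx <= half_outer_x - rib - 0.5) & (dy <= half_outer_y - rib - 0.5)
    shell = inside_outer & ~inside_core

    theta = np.arctan2(y - cy, x - cx)  # (-pi, pi]
    sector = np.floor((theta + np.pi) / (2 * np.pi) * spec.n_regions).astype(int)
    sector = np.clip(sector, 0, spec.n_regions - 1)

    plane = np.zeros((nx, ny), dtype=np.int32)
    plane[inside_core] = 1
    plane[shell] = sector[shell] + 2
    labels[:, :, :] = plane[:, :, None]

    mwf = np.zeros(spec.grid_shape, dtype=float)
    t1 = np.zeros(spec.grid_shape, dtype=float)
    vals = spec.values
    wm_mwf_plane = np.zeros((nx, ny))
    wm_t1_plane = np.zeros((nx, ny))
    for k in range(spec.n_regions):
        sel = inside_core & (sector == k)
        wm_mwf_plane[sel] = vals[k].mwf_wm
        wm_t1_plane[sel] = vals[k].t1_wm_ms
    mwf[plane == 1] = np.broadcast_to(wm_mwf_plane[:, :, None], spec.grid_shape)[plane == 1]
    t1[plane == 1] = np.broadcast_to(wm_t1_plane[:, :, None], spec.grid_shape)[plane == 1]
    for k in range(spec.n_regions):
        sel = labels == k + 2
        mwf[sel] = vals[k].mwf_gm
        t1[sel] = vals[k].t1_gm_ms

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        mwf = np.clip(mwf + rng.normal(0.0, spec.noise_sd, spec.grid_shape), 0.0, 1.0)
    if spec.t1_noise_sd_ms > 0:
        t1 = t1 + rng.normal(0.0, spec.t1_noise_sd_ms, spec.grid_shape)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    table = {1: LabelEntry("white matter core", spec.hemisphere, WM)}
    for k, name in enumerate(spec.region_names):
        table[k + 2] = LabelEntry(name, spec.hemisphere, GM)

    label_volume = LabelVolume(labels, affine, table)
    return (
        label_volume,
        QuantMap(mwf, affine, units="fraction"),
        QuantMap(t1, affine, units="ms"),
    )
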