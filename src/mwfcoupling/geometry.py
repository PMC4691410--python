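"""Adjacent-white-matter mask construction and regional map statistics.

A cortical parcel's "adjacent white matter" is sampled by blurring the
binary parcel mask with a 2-D Gaussian kernel (4 mm FWHM by default,
slice-wise in the axial plane), zeroing the blurred weights everywhere the
parcellation is not white matter, and taking the weighted mean of the
quantitative map under the surviving weights.  Cortical means are plain
(unweighted) statistics over the parcel's own voxels.

Volumes travel as ``LabelVolume`` / ``QuantMap`` pairs sharing a voxel grid
and affine; NIfTI-1 plus a TSV label table is the on-disk form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GM",
    "WM",
    "BACKGROUND",
    "LabelEntry",
    "LabelVolume",
    "QuantMap",
    "BlurSpec",
    "fwhm_to_sigma",
    "blur_parcel_2d",
    "adjacent_wm_mask",
    "weighted_regional_mean",
    "cortical_regional_mean",
    "extract_regional_measures",
    "load_label_volume",
    "save_label_volume",
    "load_quant_map",
    "save_quant_map",
]

#: tissue-class names used in label tables
GM = "gray_matter"
WM = "white_matter"
BACKGROUND = "background"

#: FWHM = sigma * 2*sqrt(2 ln 2)
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class LabelEntry:
    region: str
    hemisphere: str
    tissue_class: str


@dataclass
class LabelVolume:
    """Integer parcellation on a voxel grid: 0 = background."""

    voxels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, LabelEntry]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def label_of(self, region: str, hemisphere: str | None = None) -> int:
        for lab, entry in self.label_table.items():
            if entry.region == region and (hemisphere is None or entry.hemisphere == hemisphere):
                return lab
        raise KeyError(f"no label for region {region!r} (hemisphere {hemisphere!r})")

    def parcel_mask(self, region: str, hemisphere: str | None = None) -> np.ndarray:
        return self.voxels == self.label_of(region, hemisphere)

    def tissue_mask(self, tissue_class: str) -> np.ndarray:
        labs = [l for l, e in self.label_table.items() if e.tissue_class == tissue_class]
        return np.isin(self.voxels, labs)

    def parcels(self, tissue_class: str = GM) -> list[tuple[int, LabelEntry]]:
        return [(l, e) for l, e in sorted(self.label_table.items()) if e.tissue_class == tissue_class]


@dataclass
class QuantMap:
    """Floating-point quantitative map sharing a grid with its parcellation."""

    voxels: np.ndarray
    affine: np.ndarray
    units: str = "fraction"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("quantitative map must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass(frozen=True)
class BlurSpec:
    """In-plane Gaussian blur: FWHM in mm, applied slice-wise.

    ``plane`` names the two voxel axes the 2-D kernel acts in (default
    (0, 1), the axial plane of the phantoms); the third axis is untouched.
    The discrete kernel is truncated at ``truncation_sigmas`` and normalized
    to unit sum.
    """

    fwhm_mm: float = 4.0
    plane: tuple[int, int] = (0, 1)
    truncation_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")
        if sorted(self.plane) not in ([0, 1], [0, 2], [1, 2]):
            raise ValueError("plane must name two distinct axes in {0,1,2}")

    @property
    def sigma_mm(self) -> float:
        return fwhm_to_sigma(self.fwhm_mm)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian FWHM -> standard deviation: sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    return fwhm_mm / FWHM_PER_SIGMA


def blur_parcel_2d(
    parcel_mask: np.ndarray,
    spec: BlurSpec,
    voxel_size_mm: np.ndarray | tuple[float, float, float],
) -> np.ndarray:
    """Slice-wise 2-D Gaussian blur of a binary parcel mask.

    The kernel has unit sum, so each slice's total mass is conserved (up to
    truncation error) and outputs stay in [0, 1].
    """
    mask = np.asarray(parcel_mask)
    if mask.ndim != 3:
        raise ValueError("parcel mask must be 3-D")
    data = mask.astype(float)
    if not np.all((data == 0) | (data == 1)):
        raise ValueError("parcel mask must be binary")
    if data.sum() == 0:
        warnings.warn("blurring an empty parcel mask", stacklevel=2)
        return data

    vox = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = np.zeros(3)
    for ax in spec.plane:
        sigma_vox[ax] = spec.sigma_mm / vox[ax]
    return ndimage.gaussian_filter(
        data, sigma=sigma_vox, mode="constant", cval=0.0, truncate=spec.truncation_sigmas
    )


def adjacent_wm_mask(
    blurred: np.ndarray,
    labels: LabelVolume,
    region: str,
    floor: float = 1e-6,
) -> np.ndarray:
    """Restrict a blurred parcel mask to white-matter voxels.

    Subtracting cortex and non-brain from the blurred mask is implemented as
    retaining only the WM tissue class.  Raises if no WM voxel carries
    weight above ``floor``.
    """
    blurred = np.asarray(blurred, dtype=float)
    if blurred.shape != labels.voxels.shape:
        raise ValueError("blurred mask and label volume must share a grid")
    out = np.where(labels.tissue_mask(WM), blurred, 0.0)
    if out.max(initial=0.0) <= floor:
        raise ValueError(f"region {region!r} has no adjacent WM")
    return out


def weighted_regional_mean(quant_map: QuantMap, weights: np.ndarray) -> float:
    """Weighted mean sum(w v) / sum(w) of a map under a weight mask."""
    w = np.asarray(weights, dtype=float)
    if w.shape != quant_map.voxels.shape:
        raise ValueError("weights and map must share a grid")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    return float((w * quant_map.voxels).sum() / total)


def cortical_regional_mean(
    quant_map: QuantMap,
    labels: LabelVolume,
    region: str,
    hemisphere: str | None = None,
) -> tuple[float, float]:
    """Unweighted mean and SD of a map over one cortical parcel."""
    mask = labels.parcel_mask(region, hemisphere)
    if not mask.any():
        raise ValueError(f"parcel {region!r} is empty")
    vals = quant_map.voxels[mask]
    return float(vals.mean()), float(vals.std())


def extract_regional_measures(
    labels: LabelVolume,
    mwf_map: QuantMap,
    t1_map: QuantMap | None = None,
    blur_spec: BlurSpec | None = None,
    scan_id: str = "scan-0",
) -> pd.DataFrame:
    """Regional extraction for one scan: cortical mean/SD plus adjacent-WM
    weighted mean, for MWF and (optionally) T1, one row per GM parcel.

    Parcels with no adjacent white matter in kernel reach are skipped with a
    warning rather than aborting the scan.
    """
    blur_spec = blur_spec or BlurSpec()
    vox = labels.voxel_size_mm
    rows = []
    for lab, entry in labels.parcels(GM):
        parcel = labels.voxels == lab
        blurred = blur_parcel_2d(parcel, blur_spec, vox)
        try:
            wm_weights = adjacent_wm_mask(blurred, labels, entry.region)
        except ValueError as exc:
            warnings.warn(f"skipping {entry.region!r}: {exc}", stacklevel=2)
            continue
        c_mean, c_sd = cortical_regional_mean(mwf_map, labels, entry.region, entry.hemisphere)
        row = {
            "scan_id": scan_id,
            "region": entry.region,
            "hemisphere": entry.hemisphere,
            "cortical_mwf": c_mean,
            "cortical_mwf_sd": c_sd,
            "adjacent_mwf": weighted_regional_mean(mwf_map, wm_weights),
        }
        if t1_map is not None:
            t_mean, _ = cortical_regional_mean(t1_map, labels, entry.region, entry.hemisphere)
            row["cortical_t1_ms"] = t_mean
            row["adjacent_t1_ms"] = weighted_regional_mean(t1_map, wm_weights)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI-1 + TSV I/O


def save_label_volume(volume: LabelVolume, nifti_path: str | Path, table_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.int32), volume.affine), str(nifti_path))
    rows = [
        {"label": lab, "region": e.region, "hemisphere": e.hemisphere, "tissue_class": e.tissue_class}
        for lab, e in sorted(volume.label_table.items())
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def load_label_volume(nifti_path: str | Path, table_path: str | Path) -> LabelVolume:
    img = nib.load(str(nifti_path))
    table = pd.read_csv(table_path, sep="\t")
    entries = {
        int(r.label): LabelEntry(str(r.region), str(r.hemisphere), str(r.tissue_class))
        for r in table.itertuples()
    }
    return LabelVolume(np.asarray(img.dataobj).astype(np.int32), img.affine, entries)


def save_quant_map(quant_map: QuantMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(quant_map.voxels.astype(np.float64), quant_map.affine), str(path))


def load_quant_map(path: str | Path, units: str = "fraction") -> QuantMap:
    img = nib.load(str(path))
    return QuantMap(np.asarray(img.dataobj, dtype=float), img.affine, units=units)
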