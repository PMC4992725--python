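"""Neuromelanin-sensitive MRI measurement chain.

Quantifies the substantia nigra (SN) and locus coeruleus (LC) on
magnetization-transfer-prepared T1-weighted images, where neuromelanin-rich
tissue appears hyperintense:

* background statistics from circular (or explicit-mask) reference ROIs in
  the cerebral crus,
* a per-slice/per-side binary map of voxels brighter than MN_CC + 3 SD_CC,
* largest-connected-component SN isolation over four consecutive slices,
  yielding SN volume (mm^3) and the contrast-to-noise ratio
  CNR_SN = (MN_SN - MN_CC) / SD_CC,
* LC localization as the brightest voxel adjacent to the fourth ventricle
  (LC_MAX), LC intensity as the mean of LC_MAX and its four in-plane
  neighbours, and CNR_LC against a pontine-tegmentum reference ROI,
* %CNR normalization to the healthy-control median, asymmetry indices, and
  averaging across repeated ROI placements.

Conventions: volumes are indexed (row, column, slice) with the slice axis
last; the left/right split is the mid-plane of the row axis (left = lower
row indices); voxel coordinates are 0-based and circle membership uses the
voxel-centre rule. Background/tegmentum ROI statistics use the population
standard deviation (the threshold is a statement about the voxel
population); repeat averaging uses the sample standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import label as cc_label

__all__ = [
    "ImageVolume",
    "RoiSpec",
    "RegionStats",
    "SnMeasurement",
    "LcMeasurement",
    "NmPipelineError",
    "region_stats",
    "binary_map",
    "segment_sn",
    "cnr_sn",
    "measure_sn",
    "locate_lc",
    "lc_intensity",
    "cnr_lc",
    "measure_lc",
    "percent_cnr",
    "asymmetry_index",
    "average_repeats",
    "jitter_roi",
]

SIDES = ("left", "right")
#: multiplier k in the segmentation threshold MN_CC + k * SD_CC
THRESHOLD_MULTIPLIER = 3.0
#: in-plane Chebyshev radius (voxels) of the "adjacent to the fourth
#: ventricle" search band used for LC localization
LC_BAND_RADIUS = 2


class NmPipelineError(ValueError):
    """Raised for invalid ROIs, degenerate references, or empty regions."""


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar image with voxel spacing in mm.

    ``data`` is indexed (row, column, slice); ``spacing`` gives mm per voxel
    along each axis; the slice axis is always the last one.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise NmPipelineError(f"expected a 3-D volume, got {data.ndim}-D")
        if not np.all(np.isfinite(data)):
            raise NmPipelineError(
                f"volume contains {int(np.sum(~np.isfinite(data)))} non-finite voxels"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise NmPipelineError(f"voxel spacing must be positive, got {self.spacing}")
        if self.slice_axis != 2:
            raise NmPipelineError("slice axis must be the last (index 2) axis")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def get_slice(self, index: int) -> np.ndarray:
        return self.data[:, :, index]

    def side_rows(self, side: str) -> slice:
        """Row range of one side; the midline splits the row axis in half."""
        if side not in SIDES:
            raise NmPipelineError(f"unknown side {side!r}")
        mid = self.data.shape[0] // 2
        return slice(0, mid) if side == "left" else slice(mid, self.data.shape[0])


@dataclass(frozen=True)
class RoiSpec:
    """A sampling region on one slice: a circle or an explicit 2-D mask.

    Circle membership uses the voxel-centre convention: voxel (i, j) is in
    the ROI iff its centre lies within ``diameter_mm / 2`` of ``center``
    (fractional voxel coordinates), distances measured in mm.
    """

    shape: str  # "circle" | "mask"
    slice_index: int
    side: str = "left"
    center: tuple[float, float] | None = None  # (row, col), voxel coords
    diameter_mm: float | None = None
    mask: np.ndarray | None = None  # 2-D bool, full in-plane shape
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "mask"):
            raise NmPipelineError(f"ROI shape must be 'circle' or 'mask', got {self.shape!r}")
        if self.side not in SIDES:
            raise NmPipelineError(f"unknown side {self.side!r}")
        if self.shape == "circle":
            if self.center is None or self.diameter_mm is None:
                raise NmPipelineError(f"circle ROI {self.name!r} needs center and diameter")
            if self.diameter_mm <= 0:
                raise NmPipelineError(f"ROI {self.name!r}: diameter must be > 0")
        elif self.mask is None:
            raise NmPipelineError(f"mask ROI {self.name!r} needs an explicit mask")

    def rasterize(self, vol: ImageVolume) -> np.ndarray:
        """Boolean in-plane membership mask on this ROI's slice."""
        nr, nc, ns = vol.shape
        if not 0 <= self.slice_index < ns:
            raise NmPipelineError(f"ROI {self.name!r}: slice {self.slice_index} out of range")
        if self.shape == "mask":
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (nr, nc):
                raise NmPipelineError(
                    f"ROI {self.name!r}: mask shape {m.shape} != slice shape {(nr, nc)}"
                )
            return m
        ci, cj = self.center
        r = self.diameter_mm / 2.0
        si, sj = vol.spacing[0], vol.spacing[1]
        # circle must lie fully inside the grid
        if (ci - r / si < -0.5 or ci + r / si > nr - 0.5
                or cj - r / sj < -0.5 or cj + r / sj > nc - 0.5):
            raise NmPipelineError(f"ROI {self.name!r}: circle extends beyond the grid")
        ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        d2 = ((ii - ci) * si) ** 2 + ((jj - cj) * sj) ** 2
        return d2 <= r * r


@dataclass(frozen=True)
class RegionStats:
    """Mean / population-SD summary of a sampled region (MN, SD, n)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise NmPipelineError("RegionStats requires at least one voxel")
        if self.sd < 0:
            raise NmPipelineError("RegionStats SD must be >= 0")


@dataclass
class SnMeasurement:
    """Per-side SN segmentation result."""

    side: str
    mask: np.ndarray  # 3-D bool
    slices: list[int]  # analyzed slice window
    volume_mm3: float
    cnr_per_slice: dict[int, float]
    cnr: float  # unweighted mean across slices
    missing: bool = False  # no suprathreshold cluster found on this side


@dataclass
class LcMeasurement:
    """Per-side LC contrast result."""

    side: str
    lc_max: dict[int, tuple[int, int]]  # slice -> (row, col)
    mn_lc: dict[int, float]
    cnr_per_slice: dict[int, float]
    cnr: float
    percent_cnr: float | None = None


# --------------------------------------------------------------------------
# background statistics and thresholding
# --------------------------------------------------------------------------


def region_stats(vol: ImageVolume, roi: RoiSpec) -> RegionStats:
    """Mean and population SD of the ROI voxels on the ROI's slice."""
    member = roi.rasterize(vol)
    values = vol.get_slice(roi.slice_index)[member]
    if values.size == 0:
        raise NmPipelineError(f"ROI {roi.name or roi.shape!r} is empty after rasterization")
    return RegionStats(mean=float(values.mean()), sd=float(values.std(ddof=0)), n=int(values.size))


def binary_map(
    vol: ImageVolume,
    bg: RegionStats,
    slice_index: int,
    side: str,
    search_mask: np.ndarray | None = None,
    multiplier: float = THRESHOLD_MULTIPLIER,
) -> np.ndarray:
    """Suprathreshold binary map for one slice and side.

    A voxel is in the map iff its intensity is strictly greater than
    ``bg.mean + multiplier * bg.sd``, it lies on the requested side of the
    midline, and (optionally) inside a mesencephalic search region.
    ``search_mask`` may be 2-D (in-plane) or 3-D.
    """
    plane = vol.get_slice(slice_index)
    out = plane > bg.mean + multiplier * bg.sd
    keep = np.zeros_like(out)
    keep[vol.side_rows(side), :] = True
    out &= keep
    if search_mask is not None:
        sm = np.asarray(search_mask, dtype=bool)
        if sm.ndim == 3:
            sm = sm[:, :, slice_index]
        out &= sm
    return out


# --------------------------------------------------------------------------
# SN segmentation, volume and CNR
# --------------------------------------------------------------------------


def _largest_component(mask2d: np.ndarray) -> np.ndarray:
    """Largest 8-connected in-plane component (empty in -> empty out)."""
    if not mask2d.any():
        return np.zeros_like(mask2d)
    lab = cc_label(mask2d, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _best_window(areas: dict[int, int], length: int) -> list[int]:
    """Consecutive slice window of ``length`` maximizing total area.

    Slices with zero area count as zero. If fewer than ``length`` slices
    carry signal, all signal slices are used and a warning is issued.
    """
    nonzero = sorted(s for s, a in areas.items() if a > 0)
    if not nonzero:
        return []
    if len(nonzero) < length:
        warnings.warn(
            f"only {len(nonzero)} slice(s) show suprathreshold signal; "
            f"using all of them instead of a {length}-slice window",
            stacklevel=3,
        )
        return nonzero
    lo, hi = min(areas), max(areas)
    best, best_total = None, -1
    for start in range(lo, hi - length + 2):
        window = list(range(start, start + length))
        total = sum(areas.get(s, 0) for s in window)
        if total > best_total:
            best, best_total = window, total
    return [s for s in best if areas.get(s, 0) > 0] if best_total > 0 else []


def segment_sn(
    vol: ImageVolume,
    masks: dict[int, np.ndarray],
    side: str,
    window: int = 4,
) -> SnMeasurement:
    """Isolate the SN on one side from per-slice binary maps.

    Per slice the largest 8-connected in-plane component is kept; the
    ``window`` consecutive slices maximizing total suprathreshold area are
    stacked (the slices "in which the SN is visible"); the volume is the
    voxel count times the voxel volume. A side with no suprathreshold
    cluster yields a flagged, empty measurement rather than an exception.
    """
    comps = {s: _largest_component(m) for s, m in masks.items()}
    areas = {s: int(c.sum()) for s, c in comps.items()}
    chosen = _best_window(areas, window)
    full = np.zeros(vol.shape, dtype=bool)
    for s in chosen:
        full[:, :, s] = comps[s]
    n = int(full.sum())
    return SnMeasurement(
        side=side,
        mask=full,
        slices=chosen,
        volume_mm3=n * vol.voxel_volume_mm3,
        cnr_per_slice={},
        cnr=float("nan") if n == 0 else 0.0,
        missing=(n == 0),
    )


def cnr_sn(
    vol: ImageVolume,
    sn: SnMeasurement,
    bg: dict[int, RegionStats],
) -> SnMeasurement:
    """Fill per-slice and side-average CNR_SN = (MN_SN - MN_CC) / SD_CC.

    The side value is the unweighted mean over the analyzed slices.
    """
    if sn.missing:
        return sn
    per_slice: dict[int, float] = {}
    for s in sn.slices:
        m = sn.mask[:, :, s]
        if not m.any():
            continue
        st = bg[s]
        if st.sd == 0:
            raise NmPipelineError(f"degenerate background on slice {s}: SD_CC = 0")
        per_slice[s] = (float(vol.get_slice(s)[m].mean()) - st.mean) / st.sd
    sn.cnr_per_slice = per_slice
    sn.cnr = float(np.mean(list(per_slice.values())))
    return sn


def measure_sn(
    vol: ImageVolume,
    bg_rois: dict[tuple[int, str], RoiSpec],
    search_mask: np.ndarray | None = None,
    window: int = 4,
    multiplier: float = THRESHOLD_MULTIPLIER,
) -> dict[str, SnMeasurement]:
    """Full SN chain for both sides.

    ``bg_rois`` maps (slice_index, side) to the cerebral-crus reference ROI
    for that slice and side; background statistics are kept side-specific.
    """
    out: dict[str, SnMeasurement] = {}
    for side in SIDES:
        stats = {
            s: region_stats(vol, roi)
            for (s, sd), roi in bg_rois.items()
            if sd == side
        }
        masks = {
            s: binary_map(vol, st, s, side, search_mask, multiplier)
            for s, st in stats.items()
        }
        sn = segment_sn(vol, masks, side, window)
        out[side] = cnr_sn(vol, sn, stats)
    return out


# --------------------------------------------------------------------------
# LC localization and contrast
# --------------------------------------------------------------------------


def locate_lc(
    vol: ImageVolume,
    ventricle_mask: np.ndarray,
    slice_index: int,
    side: str,
    band_radius: int = LC_BAND_RADIUS,
) -> tuple[int, int]:
    """LC_MAX: brightest voxel adjacent to the fourth ventricle.

    The adjacency band is the set of voxels within ``band_radius`` in-plane
    voxels (Chebyshev) of the ventricle mask, excluding the mask itself,
    restricted to the requested side. Intensity ties are broken by the
    smallest (row, column) pair.
    """
    vm = np.asarray(ventricle_mask, dtype=bool)
    if vm.ndim == 3:
        vm = vm[:, :, slice_index]
    if vm.shape != vol.shape[:2]:
        raise NmPipelineError("ventricle mask shape does not match the volume")
    size = 2 * band_radius + 1
    band = binary_dilation(vm, structure=np.ones((size, size), dtype=bool)) & ~vm
    keep = np.zeros_like(band)
    keep[vol.side_rows(side), :] = True
    band &= keep
    if not band.any():
        raise NmPipelineError(
            f"empty LC search band on slice {slice_index}, side {side}"
        )
    plane = vol.get_slice(slice_index)
    vmax = plane[band].max()
    cand = np.argwhere(band & (plane == vmax))
    row, col = min(map(tuple, cand))
    return int(row), int(col)


def lc_intensity(vol: ImageVolume, slice_index: int, point: tuple[int, int]) -> float:
    """Mean of LC_MAX and its four in-plane abutting voxels.

    Neighbours falling outside the grid are dropped with a warning.
    """
    nr, nc, _ = vol.shape
    r, c = point
    pts = [(r, c), (r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
    inside = [(i, j) for i, j in pts if 0 <= i < nr and 0 <= j < nc]
    if len(inside) < len(pts):
        warnings.warn(
            f"LC_MAX at {point} on slice {slice_index} touches the grid edge; "
            f"using {len(inside)} of 5 voxels",
            stacklevel=2,
        )
    plane = vol.get_slice(slice_index)
    return float(np.mean([plane[i, j] for i, j in inside]))


def cnr_lc(
    vol: ImageVolume,
    lc_points: dict[int, tuple[int, int]],
    teg_rois: dict[int, RoiSpec],
    side: str = "left",
) -> LcMeasurement:
    """CNR_LC = (MN_LC - MN_TG) / SD_TG, averaged over the LC slices.

    ``lc_points`` maps slice index to the LC_MAX coordinate located on it;
    ``teg_rois`` maps the same slices to the pontine-tegmentum reference ROI
    (6-mm circle in practice, any RoiSpec accepted).
    """
    mn_lc: dict[int, float] = {}
    per_slice: dict[int, float] = {}
    for s, pt in sorted(lc_points.items()):
        st = region_stats(vol, teg_rois[s])
        if st.sd == 0:
            raise NmPipelineError(f"degenerate tegmentum reference on slice {s}: SD_TG = 0")
        mn = lc_intensity(vol, s, pt)
        mn_lc[s] = mn
        per_slice[s] = (mn - st.mean) / st.sd
    if not per_slice:
        raise NmPipelineError("no LC slices provided")
    return LcMeasurement(
        side=side,
        lc_max=dict(lc_points),
        mn_lc=mn_lc,
        cnr_per_slice=per_slice,
        cnr=float(np.mean(list(per_slice.values()))),
    )


def measure_lc(
    vol: ImageVolume,
    ventricle_mask: np.ndarray,
    lc_slices: list[int],
    teg_rois: dict[tuple[int, str], RoiSpec],
    band_radius: int = LC_BAND_RADIUS,
) -> dict[str, LcMeasurement]:
    """Locate the LC on each of the given slices and compute CNR_LC per side."""
    out: dict[str, LcMeasurement] = {}
    for side in SIDES:
        pts = {s: locate_lc(vol, ventricle_mask, s, side, band_radius) for s in lc_slices}
        rois = {s: teg_rois[(s, side)] for s in lc_slices}
        out[side] = cnr_lc(vol, pts, rois, side)
    return out


# --------------------------------------------------------------------------
# normalization, asymmetry, repeats
# --------------------------------------------------------------------------


def percent_cnr(value: float | np.ndarray, hc_median: float) -> float | np.ndarray:
    """Express a CNR as a percentage of the healthy-control median."""
    if hc_median <= 0:
        raise NmPipelineError(f"HC median must be > 0, got {hc_median}")
    return value / hc_median * 100.0


def asymmetry_index(ipsi: float, contra: float) -> float:
    """AI = |(ipsi - contra) / (ipsi + contra)| x 200, in [0, 200].

    ``contra`` is the brain side opposite the clinically worse hemibody
    (for healthy controls the right side is taken as ipsilateral by
    convention). Applied identically to putamen/caudate DAT binding, SN
    volume and CNR_SN.
    """
    if ipsi < 0 or contra < 0:
        raise NmPipelineError("asymmetry index requires nonnegative inputs")
    total = ipsi + contra
    if total == 0:
        raise NmPipelineError("asymmetry index undefined for ipsi + contra = 0")
    return abs((ipsi - contra) / total) * 200.0


def average_repeats(measurements: list[dict[str, float]]) -> tuple[dict[str, float], dict[str, float]]:
    """Mean and sample SD per measure across repeated measurement runs."""
    if len(measurements) < 2:
        raise NmPipelineError("repeat averaging needs at least two repeats")
    keys = measurements[0].keys()
    if any(m.keys() != keys for m in measurements):
        raise NmPipelineError("repeats report inconsistent measure sets")
    mean = {k: float(np.mean([m[k] for m in measurements])) for k in keys}
    sd = {k: float(np.std([m[k] for m in measurements], ddof=1)) for k in keys}
    return mean, sd


def jitter_roi(roi: RoiSpec, rng: np.random.Generator, amplitude: int = 1) -> RoiSpec:
    """Re-place a circular ROI with +/- ``amplitude`` voxel uniform jitter.

    Emulates intra-rater variability in background-ROI positioning across
    repeated measurements. Mask ROIs are returned unchanged.
    """
    if roi.shape != "circle":
        return roi
    dr, dc = rng.integers(-amplitude, amplitude + 1, size=2)
    return RoiSpec(
        shape="circle",
        slice_index=roi.slice_index,
        side=roi.side,
        center=(roi.center[0] + int(dr), roi.center[1] + int(dc)),
        diameter_mm=roi.diameter_mm,
        name=roi.name,
    )
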