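"""Iron-sensitive MRI: R2* mapping and quantitative-map ROI sampling.

The apparent transverse relaxation rate R2* = 1/T2* (s^-1) rises with
tissue iron. From a dual-echo gradient-echo magnitude pair the two-point
closed form

    R2* = ln(S(TE1) / S(TE2)) / (TE2 - TE1)

is the log-linear least-squares fit (exact for two echoes). Echo times
enter in ms and are converted to seconds internally, so maps are in s^-1.
Noise can drive the apparent R2* negative; such voxels are clamped to 0
(tissue R2* is nonnegative) and flagged in the validity mask, as are
voxels with nonpositive signal. Susceptibility maps (ppm) produced
elsewhere are sampled through the same ROI machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nm import ImageVolume

__all__ = [
    "DualEchoPair",
    "QuantMap",
    "RoiSample",
    "IronPipelineError",
    "fit_r2star",
    "quant_map_from_volume",
    "sample_sn_rois",
    "select_sn_slices",
    "average_two_repeats",
]


class IronPipelineError(ValueError):
    """Invalid dual-echo input or degenerate ROI sampling."""


@dataclass(frozen=True)
class DualEchoPair:
    """Magnitude volumes at two echo times (ms), on one grid."""

    te1: ImageVolume
    te2: ImageVolume
    te1_ms: float
    te2_ms: float

    def __post_init__(self) -> None:
        if self.te1.shape != self.te2.shape:
            raise IronPipelineError(
                f"echo grids differ: {self.te1.shape} vs {self.te2.shape}"
            )
        if self.te1.spacing != self.te2.spacing:
            raise IronPipelineError("echo voxel spacings differ")
        if not 0 < self.te1_ms < self.te2_ms:
            raise IronPipelineError(
                f"need 0 < TE1 < TE2, got {self.te1_ms}/{self.te2_ms} ms"
            )


@dataclass
class QuantMap:
    """A quantitative map with a validity mask.

    ``kind`` is ``"r2star"`` (s^-1) or ``"susceptibility"`` (ppm). Invalid
    voxels (nonpositive signal, or clamped negative apparent R2*) carry a
    False entry in ``valid``.
    """

    kind: str
    values: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("r2star", "susceptibility"):
            raise IronPipelineError(f"unknown map kind {self.kind!r}")


@dataclass(frozen=True)
class RoiSample:
    """Per-side ROI summary of a quantitative map."""

    side: str
    mean: float
    n: int
    invalid_fraction: float


def fit_r2star(pair: DualEchoPair, clamp_negative: bool = True) -> QuantMap:
    """Voxelwise two-point R2* fit.

    R2* = ln(S1/S2) / (TE2 - TE1) with TE in seconds. Voxels where either
    magnitude is nonpositive are invalidated (not raised). Where
    S2 >= S1 (zero or negative apparent decay) the value is clamped to 0
    and flagged invalid; with ``clamp_negative=False`` the negative
    estimate is kept (still flagged).
    """
    s1, s2 = pair.te1.data, pair.te2.data
    dte_s = (pair.te2_ms - pair.te1_ms) / 1000.0
    positive = (s1 > 0) & (s2 > 0)
    r2 = np.zeros(s1.shape, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2[positive] = np.log(s1[positive] / s2[positive]) / dte_s
    nondecay = positive & (s2 >= s1)
    valid = positive & ~nondecay
    if clamp_negative:
        r2[r2 < 0] = 0.0
    r2[~positive] = 0.0
    return QuantMap(kind="r2star", values=r2, valid=valid, spacing=pair.te1.spacing)


def quant_map_from_volume(vol: ImageVolume, kind: str = "susceptibility") -> QuantMap:
    """Wrap a precomputed map (e.g. a susceptibility map in ppm) for sampling."""
    return QuantMap(kind=kind, values=vol.data.copy(),
                    valid=np.ones(vol.shape, dtype=bool), spacing=vol.spacing)


def select_sn_slices(mask: np.ndarray, n: int = 6) -> list[int]:
    """The ``n`` consecutive slices where the mask has the largest total area.

    Helper for the "six central slices with the largest SN area" rule; the
    caller remains free to pass any slice set to :func:`sample_sn_rois`.
    """
    areas = mask.reshape(-1, mask.shape[2]).sum(axis=0)
    occupied = np.flatnonzero(areas)
    if occupied.size == 0:
        raise IronPipelineError("mask is empty")
    if occupied.size <= n:
        return occupied.tolist()
    best, best_total = None, -1
    for start in range(occupied.min(), occupied.max() - n + 2):
        total = int(areas[start:start + n].sum())
        if total > best_total:
            best, best_total = start, total
    return list(range(best, best + n))


def sample_sn_rois(
    qmap: QuantMap,
    roi_masks: dict[str, np.ndarray],
    slices: list[int] | None = None,
) -> dict[str, RoiSample]:
    """Unweighted per-side mean of the map over SN ROI masks.

    ``roi_masks`` maps side label to a 3-D boolean mask (at most six
    slices in the study protocol; pass ``slices`` to restrict). Invalid
    voxels are excluded from the mean and their fraction reported; a mask
    with no valid voxel is an error.
    """
    out: dict[str, RoiSample] = {}
    for side, mask in roi_masks.items():
        m = np.asarray(mask, dtype=bool)
        if m.shape != qmap.values.shape:
            raise IronPipelineError(f"{side}: mask shape does not match the map")
        if slices is not None:
            keep = np.zeros_like(m)
            keep[:, :, list(slices)] = True
            m = m & keep
        n_total = int(m.sum())
        if n_total == 0:
            raise IronPipelineError(f"{side}: empty SN ROI mask")
        ok = m & qmap.valid
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise IronPipelineError(f"{side}: SN ROI mask is entirely invalid")
        out[side] = RoiSample(
            side=side,
            mean=float(qmap.values[ok].mean()),
            n=n_ok,
            invalid_fraction=1.0 - n_ok / n_total,
        )
    return out


def average_two_repeats(
    m1: dict[str, RoiSample], m2: dict[str, RoiSample]
) -> dict[str, float]:
    """Arithmetic mean of two repeated ROI measurements, per side."""
    if m1.keys() != m2.keys():
        raise IronPipelineError("repeats report different sides")
    return {side: (m1[side].mean + m2[side].mean) / 2.0 for side in m1}
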