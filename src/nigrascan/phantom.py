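"""Synthetic phantoms and cohorts for the NM/iron MRI pipelines.

Nothing here is an anatomical simulation: the phantoms are minimal digital
objects that exercise every measurement rule with a known ground truth.

* NM phantoms: a midbrain-like slab at 0.5 x 0.5 x 3.0 mm voxels containing
  two hyperintense SN blobs of controlled true volume and contrast (in
  background-SD units), two cerebral-crus cylinders hosting the background
  reference ROIs, and a pons-like set of slices with a rectangular fourth
  ventricle flanked by 5-voxel LC crosses and a pontine-tegmentum slab for
  the LC reference ROI.
* Dual-echo phantoms: mono-exponential magnitude pairs
  S(TE) = S0 * exp(-R2* . TE) with per-region true R2*.
* Susceptibility phantoms: per-region constant values in ppm over a 0-ppm
  background.
* Cohorts: per-subject measurement tables drawn from the printed PD / HC
  group means and SDs, truncated at zero, with a Gaussian-copula rank
  coupling between contralateral SN volume and putaminal DAT binding
  within the PD group.

Noise is additive Gaussian. For exact (noiseless) oracles the background
can carry a deterministic +/-SD checkerboard texture instead: any region
containing equally many voxels of the two parities then reproduces the
nominal background mean and population SD exactly, so the full ROI ->
threshold -> CNR chain has closed-form expected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .nm import ImageVolume, RoiSpec

__all__ = [
    "PhantomError",
    "StructureSpec",
    "PhantomSpec",
    "DualEchoSpec",
    "SusceptibilitySpec",
    "CohortSpec",
    "NmPhantom",
    "DualEchoPhantom",
    "NmLayout",
    "LABEL_CODES",
    "GROUP_DISTRIBUTIONS",
    "make_nm_phantom",
    "make_dual_echo_phantom",
    "make_susceptibility_phantom",
    "make_cohort",
    "default_nm_spec",
    "nm_layout",
    "default_iron_spec",
    "default_susceptibility_spec",
    "true_volume_mm3",
]


class PhantomError(ValueError):
    """Invalid phantom specification (overlap, bounds, bad parameters)."""


#: integer codes written to the ground-truth label volume
LABEL_CODES = {
    "background": 0,
    "SN_left": 1,
    "SN_right": 2,
    "LC_left": 3,
    "LC_right": 4,
    "crus_left": 5,
    "crus_right": 6,
    "tegmentum": 7,
    "fourth_ventricle": 8,
}

#: fraction of the background SD by which the LC cross centre is tipped up
#: (and each arm down by a quarter of it) so that LC_MAX localization is
#: deterministic while the 5-voxel mean stays exactly at the target
LC_TIP_FRACTION = 0.04


# --------------------------------------------------------------------------
# structure geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureSpec:
    """One phantom structure.

    ``kind``:
      * ``disk_stack`` — per-slice in-plane disks whose voxel counts follow
        elliptical cross-sections and sum to ``round(volume_mm3 / voxvol)``
        exactly; used for the SN.
      * ``cross`` — a 5-voxel in-plane "+" repeated on each slice (the LC).
      * ``cylinder`` — elliptic cylinder with in-plane ``semi_axes`` voxels.
      * ``box`` — axis-aligned box given by inclusive index ranges.

    ``cnr`` is the NM intensity offset in background-SD units; ``r2star``
    (s^-1) and ``chi_ppm`` are the per-region values used by the iron and
    susceptibility generators.
    """

    sid: str
    kind: str
    center: tuple[float, float] = (0.0, 0.0)  # (row, col) voxel coords
    slices: tuple[int, ...] = ()
    volume_mm3: float | None = None
    semi_axes: tuple[float, float] | None = None
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    cnr: float = 0.0
    r2star: float | None = None
    chi_ppm: float | None = None


def _disk(center: tuple[float, float], n: int, shape: tuple[int, int]) -> np.ndarray:
    """The ``n`` lattice points nearest ``center`` (deterministic tie-break)."""
    nr, nc = shape
    ci, cj = center
    rad = int(np.ceil(np.sqrt(n / np.pi))) + 3
    i0, i1 = int(np.floor(ci - rad)), int(np.ceil(ci + rad))
    j0, j1 = int(np.floor(cj - rad)), int(np.ceil(cj + rad))
    if i0 < 0 or j0 < 0 or i1 >= nr or j1 >= nc:
        raise PhantomError("disk exceeds grid bounds")
    pts = [
        ((i - ci) ** 2 + (j - cj) ** 2, i, j)
        for i in range(i0, i1 + 1)
        for j in range(j0, j1 + 1)
    ]
    pts.sort()
    mask = np.zeros(shape, dtype=bool)
    for _, i, j in pts[:n]:
        mask[i, j] = True
    return mask


def _allocate_slice_counts(total: int, n_slices: int) -> list[int]:
    """Split ``total`` voxels over slices by elliptical cross-section weights."""
    u = (np.arange(n_slices) - (n_slices - 1) / 2) / (n_slices / 2 + 0.4)
    w = np.clip(1.0 - u * u, 0.05, None)
    raw = total * w / w.sum()
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding keeps the total exact
    for k in np.argsort(raw - counts)[::-1][: total - counts.sum()]:
        counts[k] += 1
    return counts.tolist()


def _structure_mask(st: StructureSpec, shape: tuple[int, int, int],
                    spacing: tuple[float, float, float]) -> np.ndarray:
    nr, nc, ns = shape
    mask = np.zeros(shape, dtype=bool)
    if any(s < 0 or s >= ns for s in st.slices):
        raise PhantomError(f"structure {st.sid!r} exceeds the slice range")
    if st.kind == "disk_stack":
        if st.volume_mm3 is None or st.volume_mm3 <= 0:
            raise PhantomError(f"structure {st.sid!r}: target volume must be > 0")
        voxvol = float(np.prod(spacing))
        total = int(round(st.volume_mm3 / voxvol))
        if total < 1:
            raise PhantomError(f"structure {st.sid!r}: volume below one voxel")
        counts = _allocate_slice_counts(total, len(st.slices))
        for s, n in zip(st.slices, counts):
            if n > 0:
                try:
                    mask[:, :, s] = _disk(st.center, n, (nr, nc))
                except PhantomError as e:
                    raise PhantomError(f"structure {st.sid!r}: {e}") from None
    elif st.kind == "cross":
        r, c = int(round(st.center[0])), int(round(st.center[1]))
        pts = [(r, c), (r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
        if any(not (0 <= i < nr and 0 <= j < nc) for i, j in pts):
            raise PhantomError(f"structure {st.sid!r} exceeds grid bounds")
        for s in st.slices:
            for i, j in pts:
                mask[i, j, s] = True
    elif st.kind == "cylinder":
        if st.semi_axes is None:
            raise PhantomError(f"structure {st.sid!r}: cylinder needs semi_axes")
        a, b = st.semi_axes
        ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        inplane = ((ii - st.center[0]) / a) ** 2 + ((jj - st.center[1]) / b) ** 2 <= 1.0
        lo = min(st.center[0] - a, st.center[1] - b)
        if lo < 0 or st.center[0] + a >= nr or st.center[1] + b >= nc:
            raise PhantomError(f"structure {st.sid!r} exceeds grid bounds")
        for s in st.slices:
            mask[:, :, s] = inplane
    elif st.kind == "box":
        (r0, r1), (c0, c1), (s0, s1) = st.box
        if r0 < 0 or c0 < 0 or s0 < 0 or r1 >= nr or c1 >= nc or s1 >= ns:
            raise PhantomError(f"structure {st.sid!r} exceeds grid bounds")
        mask[r0:r1 + 1, c0:c1 + 1, s0:s1 + 1] = True
    else:
        raise PhantomError(f"structure {st.sid!r}: unknown kind {st.kind!r}")
    if not mask.any():
        raise PhantomError(f"structure {st.sid!r} rasterizes to zero voxels")
    return mask


def _build_labels(structures: list[StructureSpec], shape, spacing) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    labels = np.zeros(shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    for st in structures:
        if st.sid not in LABEL_CODES:
            raise PhantomError(f"unknown structure id {st.sid!r}")
        m = _structure_mask(st, shape, spacing)
        clash = labels[m]
        if np.any(clash != 0):
            codes = {int(c) for c in np.unique(clash) if c != 0}
            others = [k for k, v in LABEL_CODES.items() if v in codes]
            raise PhantomError(f"structure {st.sid!r} overlaps {', '.join(others)}")
        labels[m] = LABEL_CODES[st.sid]
        masks[st.sid] = m
    return labels, masks


def true_volume_mm3(labels: np.ndarray, sid: str, spacing: tuple[float, float, float]) -> float:
    """Ground-truth structure volume: voxel count times voxel volume."""
    return float(np.sum(labels == LABEL_CODES[sid]) * np.prod(spacing))


# --------------------------------------------------------------------------
# NM phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """NM phantom specification.

    Background intensity is ``bg_mean`` with nominal SD ``bg_sd`` (the unit
    in which structure CNRs are expressed). ``noise_sd`` is additive
    Gaussian noise on every voxel; ``texture`` is the deterministic
    background pattern under structure-free voxels: ``constant`` or
    ``checkerboard`` (+/- bg_sd with voxel-index parity).
    """

    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    bg_mean: float = 100.0
    bg_sd: float = 10.0
    noise_sd: float = 10.0
    texture: str = "constant"
    seed: int | None = None
    structures: tuple[StructureSpec, ...] = ()

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"voxel spacing must be positive, got {self.spacing}")
        if self.bg_sd <= 0:
            raise PhantomError("background SD must be > 0")
        if self.noise_sd < 0:
            raise PhantomError("noise SD must be >= 0")
        if self.texture not in ("constant", "checkerboard"):
            raise PhantomError(f"unknown texture {self.texture!r}")


@dataclass
class NmPhantom:
    """A rendered phantom: image volume plus ground-truth labels."""

    vol: ImageVolume
    labels: np.ndarray
    spec: "PhantomSpec | SusceptibilitySpec"

    def mask(self, sid: str) -> np.ndarray:
        return self.labels == LABEL_CODES[sid]


def make_nm_phantom(spec: PhantomSpec) -> NmPhantom:
    """Render an NM phantom and its ground-truth label volume.

    Each structure's voxels take base intensity
    ``bg_mean + cnr * bg_sd`` (LC crosses: centre +4 eps, arms - eps with
    eps = LC_TIP_FRACTION * bg_sd, preserving the 5-voxel mean exactly),
    plus Gaussian noise. Identical spec and seed give identical arrays.
    """
    spec.validate()
    labels, masks = _build_labels(list(spec.structures), spec.shape, spec.spacing)
    base = np.full(spec.shape, spec.bg_mean, dtype=np.float64)
    offset = np.zeros(spec.shape, dtype=np.float64)
    for st in spec.structures:
        if st.cnr == 0.0:
            continue
        m = masks[st.sid]
        offset[m] = st.cnr * spec.bg_sd
        if st.kind == "cross":
            eps = LC_TIP_FRACTION * spec.bg_sd
            r, c = int(round(st.center[0])), int(round(st.center[1]))
            offset[m] -= eps
            offset[r, c, list(st.slices)] += 5.0 * eps
    if spec.texture == "checkerboard":
        ii, jj, kk = np.indices(spec.shape)
        board = ((ii + jj + kk) % 2 * 2 - 1) * spec.bg_sd
        base += np.where(offset == 0.0, board, 0.0)
    data = base + offset
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, spec.shape)
    return NmPhantom(vol=ImageVolume(data, spec.spacing), labels=labels, spec=spec)


# default geometry (voxel coordinates on the 64 x 64 x 12 grid) ------------

_SN_SLICES = (2, 3, 4, 5)
_LC_SLICES = (7, 8, 9)
_SN_CENTERS = {"left": (20.0, 24.0), "right": (43.0, 24.0)}
_CRUS_CENTERS = {"left": (18.0, 10.0), "right": (45.0, 10.0)}
_LC_CENTERS = {"left": (26.0, 29.0), "right": (37.0, 29.0)}
_TEG_CIRCLE_CENTERS = {"left": (25.0, 20.0), "right": (38.0, 20.0)}
_TEG_RECTS = {"left": ((22, 30), (17, 23)), "right": ((34, 42), (17, 23))}
_CRUS_RECTS = {"left": ((14, 22), (7, 13)), "right": ((41, 49), (7, 13))}


def default_nm_spec(
    sn_volume_mm3: float | tuple[float, float] = 344.0,
    sn_cnr: float | tuple[float, float] = 4.91,
    lc_cnr: float | tuple[float, float] = 4.89,
    bg_mean: float = 100.0,
    bg_sd: float = 10.0,
    noise_sd: float = 10.0,
    texture: str = "constant",
    seed: int | None = None,
) -> PhantomSpec:
    """Standard NM phantom layout.

    Scalar volume/CNR arguments apply to both sides; pairs are
    (left, right). Defaults reproduce a healthy-control-like object; the
    noiseless oracle configuration is ``noise_sd=0, texture="checkerboard"``.
    """
    def pair(x):
        return (x, x) if np.isscalar(x) else tuple(x)

    vol_l, vol_r = pair(sn_volume_mm3)
    cnr_l, cnr_r = pair(sn_cnr)
    lc_l, lc_r = pair(lc_cnr)
    structures = (
        StructureSpec("SN_left", "disk_stack", _SN_CENTERS["left"], _SN_SLICES,
                      volume_mm3=vol_l, cnr=cnr_l),
        StructureSpec("SN_right", "disk_stack", _SN_CENTERS["right"], _SN_SLICES,
                      volume_mm3=vol_r, cnr=cnr_r),
        StructureSpec("crus_left", "cylinder", _CRUS_CENTERS["left"], (1, 2, 3, 4, 5, 6),
                      semi_axes=(5.0, 5.0)),
        StructureSpec("crus_right", "cylinder", _CRUS_CENTERS["right"], (1, 2, 3, 4, 5, 6),
                      semi_axes=(5.0, 5.0)),
        StructureSpec("tegmentum", "cylinder", (31.5, 20.0), _LC_SLICES,
                      semi_axes=(14.0, 7.5)),
        StructureSpec("fourth_ventricle", "box",
                      box=((28, 35), (28, 31), (_LC_SLICES[0], _LC_SLICES[-1])), cnr=-3.0),
        StructureSpec("LC_left", "cross", _LC_CENTERS["left"], _LC_SLICES, cnr=lc_l),
        StructureSpec("LC_right", "cross", _LC_CENTERS["right"], _LC_SLICES, cnr=lc_r),
    )
    return PhantomSpec(bg_mean=bg_mean, bg_sd=bg_sd, noise_sd=noise_sd,
                       texture=texture, seed=seed, structures=structures)


@dataclass
class NmLayout:
    """ROI/mask declarations matching the default NM phantom geometry."""

    bg_rois: dict[tuple[int, str], RoiSpec]
    teg_rois: dict[tuple[int, str], RoiSpec]
    sn_slices: tuple[int, ...]
    lc_slices: tuple[int, ...]
    search_mask: np.ndarray
    sn_window: int = 4


def _rect_mask(shape2d: tuple[int, int], rows: tuple[int, int], cols: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape2d, dtype=bool)
    m[rows[0]:rows[1], cols[0]:cols[1]] = True
    return m


def nm_layout(spec: PhantomSpec, exact: bool = False) -> NmLayout:
    """Analysis ROIs for the default geometry.

    ``exact=False`` uses the study's circular ROIs (4-mm crus circles, 6-mm
    tegmentum circles). ``exact=True`` swaps in explicit rectangular masks
    with an even column count: on the checkerboard texture these are
    parity-balanced, so their statistics equal the nominal background
    (mean, SD) exactly and noiseless oracle values are recovered to
    round-off.
    """
    shape2d = spec.shape[:2]
    bg_rois: dict[tuple[int, str], RoiSpec] = {}
    teg_rois: dict[tuple[int, str], RoiSpec] = {}
    for side in ("left", "right"):
        for s in _SN_SLICES:
            name = f"crus_{side}_s{s}"
            if exact:
                rows, cols = _CRUS_RECTS[side]
                bg_rois[(s, side)] = RoiSpec("mask", s, side, mask=_rect_mask(shape2d, rows, cols), name=name)
            else:
                bg_rois[(s, side)] = RoiSpec("circle", s, side, center=_CRUS_CENTERS[side],
                                             diameter_mm=4.0, name=name)
        for s in _LC_SLICES:
            name = f"teg_{side}_s{s}"
            if exact:
                rows, cols = _TEG_RECTS[side]
                teg_rois[(s, side)] = RoiSpec("mask", s, side, mask=_rect_mask(shape2d, rows, cols), name=name)
            else:
                teg_rois[(s, side)] = RoiSpec("circle", s, side, center=_TEG_CIRCLE_CENTERS[side],
                                              diameter_mm=6.0, name=name)
    search = np.zeros(spec.shape, dtype=bool)
    search[6:58, 16:41, min(_SN_SLICES):max(_SN_SLICES) + 1] = True
    return NmLayout(bg_rois=bg_rois, teg_rois=teg_rois, sn_slices=_SN_SLICES,
                    lc_slices=_LC_SLICES, search_mask=search)


# --------------------------------------------------------------------------
# dual-echo and susceptibility phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DualEchoSpec:
    """Dual-echo gradient-echo phantom: S(TE) = S0 exp(-R2* TE) + noise."""

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    te1_ms: float = 9.2
    te2_ms: float = 23.0
    s0: float = 1000.0
    r2star_background: float = 20.0
    noise_sd: float = 0.0
    seed: int | None = None
    structures: tuple[StructureSpec, ...] = ()

    def validate(self) -> None:
        if not 0 < self.te1_ms < self.te2_ms:
            raise PhantomError(f"need 0 < TE1 < TE2, got {self.te1_ms}/{self.te2_ms} ms")
        if self.s0 <= 0:
            raise PhantomError(f"baseline signal S0 must be > 0, got {self.s0}")
        if self.r2star_background < 0:
            raise PhantomError("background R2* must be >= 0")
        for st in self.structures:
            if st.r2star is None or st.r2star < 0:
                raise PhantomError(f"structure {st.sid!r}: R2* must be >= 0")
        if self.noise_sd < 0:
            raise PhantomError("noise SD must be >= 0")


@dataclass
class DualEchoPhantom:
    te1: ImageVolume
    te2: ImageVolume
    labels: np.ndarray
    r2star_truth: np.ndarray
    spec: DualEchoSpec

    def mask(self, sid: str) -> np.ndarray:
        return self.labels == LABEL_CODES[sid]


def make_dual_echo_phantom(spec: DualEchoSpec) -> DualEchoPhantom:
    """Magnitude pair obeying the mono-exponential decay law exactly
    (before noise), with a ground-truth R2* map in s^-1."""
    spec.validate()
    labels, masks = _build_labels(list(spec.structures), spec.shape, spec.spacing)
    r2 = np.full(spec.shape, spec.r2star_background, dtype=np.float64)
    for st in spec.structures:
        r2[masks[st.sid]] = st.r2star
    rng = np.random.default_rng(spec.seed)
    vols = []
    for te_ms in (spec.te1_ms, spec.te2_ms):
        sig = spec.s0 * np.exp(-r2 * te_ms / 1000.0)
        if spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd, spec.shape)
        vols.append(ImageVolume(sig, spec.spacing))
    return DualEchoPhantom(te1=vols[0], te2=vols[1], labels=labels,
                           r2star_truth=r2, spec=spec)


_IRON_SN_SLICES = (5, 6, 7, 8, 9, 10)


def default_iron_spec(
    r2star: float | tuple[float, float] = 41.17,
    sn_volume_mm3: float = 400.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    **kwargs,
) -> DualEchoSpec:
    """SN disk stacks over six 1-mm slices with the given true R2* (s^-1)."""
    r_l, r_r = (r2star, r2star) if np.isscalar(r2star) else tuple(r2star)
    structures = (
        StructureSpec("SN_left", "disk_stack", (22.0, 28.0), _IRON_SN_SLICES,
                      volume_mm3=sn_volume_mm3, r2star=r_l),
        StructureSpec("SN_right", "disk_stack", (41.0, 28.0), _IRON_SN_SLICES,
                      volume_mm3=sn_volume_mm3, r2star=r_r),
    )
    return DualEchoSpec(structures=structures, noise_sd=noise_sd, seed=seed, **kwargs)


@dataclass(frozen=True)
class SusceptibilitySpec:
    """Susceptibility phantom: per-region ppm values over a 0-ppm background."""

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    seed: int | None = None
    structures: tuple[StructureSpec, ...] = ()

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise PhantomError("noise SD must be >= 0")
        for st in self.structures:
            if st.chi_ppm is None:
                raise PhantomError(f"structure {st.sid!r}: chi_ppm missing")


def default_susceptibility_spec(
    chi_ppm: float | tuple[float, float] = 0.16,
    sn_volume_mm3: float = 400.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SusceptibilitySpec:
    c_l, c_r = (chi_ppm, chi_ppm) if np.isscalar(chi_ppm) else tuple(chi_ppm)
    structures = (
        StructureSpec("SN_left", "disk_stack", (22.0, 28.0), _IRON_SN_SLICES,
                      volume_mm3=sn_volume_mm3, chi_ppm=c_l),
        StructureSpec("SN_right", "disk_stack", (41.0, 28.0), _IRON_SN_SLICES,
                      volume_mm3=sn_volume_mm3, chi_ppm=c_r),
    )
    return SusceptibilitySpec(structures=structures, noise_sd=noise_sd, seed=seed)


def make_susceptibility_phantom(spec: SusceptibilitySpec) -> NmPhantom:
    """Susceptibility map phantom (ppm); stands in for a dipole-inversion
    output, which this package deliberately does not compute."""
    spec.validate()
    labels, masks = _build_labels(list(spec.structures), spec.shape, spec.spacing)
    chi = np.zeros(spec.shape, dtype=np.float64)
    for st in spec.structures:
        chi[masks[st.sid]] = st.chi_ppm
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        chi = chi + rng.normal(0.0, spec.noise_sd, spec.shape)
    return NmPhantom(vol=ImageVolume(chi, spec.spacing), labels=labels, spec=spec)


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

#: printed group distributions (mean, SD) per measure: PD patients (n=18)
#: vs healthy controls (n=18). Units: DAT binding ratios (putamen/caudate),
#: mm^3 (SN volume), background-SD units (CNRs), s^-1 (R2*), ppm (chi).
GROUP_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "putamen_contra": {"pd": (1.60, 0.67), "hc": (4.60, 0.83)},
    "putamen_ipsi": {"pd": (2.06, 0.75), "hc": (4.65, 0.83)},
    "caudate_contra": {"pd": (2.97, 1.02), "hc": (4.92, 0.98)},
    "caudate_ipsi": {"pd": (3.28, 0.97), "hc": (4.94, 0.96)},
    "sn_volume_contra": {"pd": (236.0, 50.0), "hc": (344.0, 51.0)},
    "sn_volume_ipsi": {"pd": (283.0, 84.0), "hc": (362.0, 60.0)},
    "cnr_sn_contra": {"pd": (4.28, 0.41), "hc": (4.91, 0.38)},
    "cnr_sn_ipsi": {"pd": (4.42, 0.45), "hc": (4.83, 0.37)},
    "cnr_lc_contra": {"pd": (3.54, 0.87), "hc": (4.89, 0.61)},
    "cnr_lc_ipsi": {"pd": (3.85, 0.96), "hc": (5.07, 0.47)},
    "r2star_contra": {"pd": (41.17, 10.96), "hc": (37.47, 5.16)},
    "r2star_ipsi": {"pd": (43.30, 10.01), "hc": (39.09, 5.74)},
    "susceptibility_contra": {"pd": (0.16, 0.05), "hc": (0.13, 0.03)},
    "susceptibility_ipsi": {"pd": (0.15, 0.05), "hc": (0.13, 0.03)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort table specification.

    Measures are drawn per group from zero-truncated normal distributions
    with the given means/SDs (defaults: the printed PD/HC study values).
    Within the PD group, contralateral SN volume and putaminal DAT binding
    are coupled through a Gaussian copula at rank correlation
    ``rho_sn_dat`` (the study's correlation claims are Spearman, so the
    coupling is rank-based).
    """

    n_pd: int = 18
    n_hc: int = 18
    measures: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in GROUP_DISTRIBUTIONS.items()}
    )
    rho_sn_dat: float = 0.75
    seed: int | None = None

    def validate(self) -> None:
        if self.n_pd < 2 or self.n_hc < 2:
            raise PhantomError("group sizes must be >= 2")
        if not -1.0 <= self.rho_sn_dat <= 1.0:
            raise PhantomError(f"target rank correlation must be in [-1, 1], got {self.rho_sn_dat}")
        for name, groups in self.measures.items():
            for g, (m, s) in groups.items():
                if s <= 0:
                    raise PhantomError(f"{name}/{g}: SD must be > 0")


def _trunc_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    a = (0.0 - mean) / sd
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _trunc_draw(rng: np.random.Generator, mean: float, sd: float, n: int,
                lower: float = 0.0, upper: float = np.inf) -> np.ndarray:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a per-subject measurement table.

    Returns one row per subject with group label, all group-distribution measures
    (ipsi/contra), asymmetry indices derived from the drawn sides, and
    rough clinical covariates (age for both groups; disease duration and
    UPDRS scores for PD only).
    """
    from .nm import asymmetry_index  # local import to avoid cycle at import time

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in (("PD", spec.n_pd), ("HC", spec.n_hc)):
        g = group.lower()
        cols: dict[str, np.ndarray] = {}
        # rank-coupled pair within PD: SN volume (contra) and putamen DAT (contra)
        coupled = ("sn_volume_contra", "putamen_contra")
        if group == "PD" and spec.rho_sn_dat != 0.0:
            r_pearson = 2.0 * np.sin(np.pi * spec.rho_sn_dat / 6.0)
            cov = np.array([[1.0, r_pearson], [r_pearson, 1.0]])
            z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
            u = norm.cdf(z)
            for k, name in enumerate(coupled):
                m, s = spec.measures[name][g]
                cols[name] = _trunc_ppf(u[:, k], m, s)
        for name, groups in spec.measures.items():
            if name in cols:
                continue
            m, s = groups[g]
            cols[name] = _trunc_draw(rng, m, s, n)
        df = pd.DataFrame(cols)
        df.insert(0, "subject_id", [f"{group}{i + 1:02d}" for i in range(n)])
        df.insert(1, "group", group)
        # clinical covariates: medians/ranges emulating the study's cohort
        if group == "PD":
            df["age_yr"] = np.round(_trunc_draw(rng, 64, 8, n, 46, 77), 1)
            df["disease_duration_yr"] = np.round(_trunc_draw(rng, 7, 3.5, n, 3, 15), 1)
            df["updrs_iii"] = np.round(_trunc_draw(rng, 14, 5, n, 5, 25))
            df["updrs_ak"] = np.round(_trunc_draw(rng, 6, 2, n, 1, 8))
        else:
            df["age_yr"] = np.round(_trunc_draw(rng, 58, 8, n, 47, 77), 1)
            df["disease_duration_yr"] = np.nan
            df["updrs_iii"] = np.nan
            df["updrs_ak"] = np.nan
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    for ai, stem in (("ai_putamen", "putamen"), ("ai_caudate", "caudate"),
                     ("ai_sn_volume", "sn_volume"), ("ai_sn_cnr", "cnr_sn")):
        table[ai] = [
            asymmetry_index(i, c)
            for i, c in zip(table[f"{stem}_ipsi"], table[f"{stem}_contra"])
        ]
    return table
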