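"""File I/O, configuration, and the end-to-end pipeline driver.

Formats: NIfTI-1 (``.nii``/``.nii.gz``) for volumes and integer label
maps, CSV with a header row for tables, YAML for ROI/run configuration,
JSON for reports and the run manifest. Voxel coordinates in configs are
0-based (row, column, slice) indices; voxel spacing travels in the NIfTI
header. All randomness flows from explicit seeds in the configuration —
there is no hidden global state — and a manifest records seeds, package
version and SHA-256 hashes of every input and output, so a rerun with the
same seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .iron import DualEchoPair, average_two_repeats, fit_r2star, quant_map_from_volume, sample_sn_rois
from .nm import (
    ImageVolume,
    NmPipelineError,
    RoiSpec,
    asymmetry_index,
    average_repeats,
    jitter_roi,
    measure_lc,
    measure_sn,
)
from .phantom import (
    CohortSpec,
    NmLayout,
    default_iron_spec,
    default_nm_spec,
    default_susceptibility_spec,
    LABEL_CODES,
    make_cohort,
    make_dual_echo_phantom,
    make_nm_phantom,
    make_susceptibility_phantom,
    nm_layout,
)
from .stats import group_compare, icc_reliability, predict_dat, roc_analysis, spearman_battery

__all__ = [
    "ConfigError",
    "validate_nifti",
    "load_volume",
    "save_volume",
    "save_labels",
    "load_labels",
    "load_cohort",
    "save_cohort",
    "layout_to_dict",
    "layout_from_dict",
    "load_yaml",
    "measure_nm_subject",
    "measure_iron_subject",
    "RunConfig",
    "run_full_pipeline",
]

log = logging.getLogger("nigrascan")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


# --------------------------------------------------------------------------
# NIfTI and CSV
# --------------------------------------------------------------------------


def validate_nifti(path: str | Path) -> ImageVolume:
    """Load a NIfTI file as an :class:`ImageVolume`.

    Rejects non-3-D data and volumes with non-finite voxels (with a
    count); voxel spacing is taken from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ConfigError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    bad = int(np.sum(~np.isfinite(data)))
    if bad:
        raise ConfigError(f"{path}: {bad} non-finite voxel(s)")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data, tuple(float(z) for z in zooms))


load_volume = validate_nifti


def save_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing on the affine diagonal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))
    return path


def save_labels(labels: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))
    return path


def load_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label file: {path}")
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.int16)


def load_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort file: {path}")
    table = pd.read_csv(path)
    if "group" not in table.columns:
        raise ConfigError(f"{path}: cohort CSV needs a 'group' column")
    return table


def save_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6g")
    return path


# --------------------------------------------------------------------------
# ROI layout <-> YAML
# --------------------------------------------------------------------------


def _roi_to_dict(roi: RoiSpec) -> dict:
    d: dict = {"slice": roi.slice_index, "side": roi.side, "name": roi.name}
    if roi.shape == "circle":
        d.update(center=[float(roi.center[0]), float(roi.center[1])],
                 diameter_mm=float(roi.diameter_mm))
    else:
        rows = np.any(roi.mask, axis=1).nonzero()[0]
        cols = np.any(roi.mask, axis=0).nonzero()[0]
        d.update(rect={"rows": [int(rows.min()), int(rows.max()) + 1],
                       "cols": [int(cols.min()), int(cols.max()) + 1]})
    return d


def _roi_from_dict(d: dict, shape2d: tuple[int, int]) -> RoiSpec:
    common = dict(slice_index=int(d["slice"]), side=d.get("side", "left"),
                  name=d.get("name", ""))
    if "rect" in d:
        m = np.zeros(shape2d, dtype=bool)
        r0, r1 = d["rect"]["rows"]
        c0, c1 = d["rect"]["cols"]
        m[r0:r1, c0:c1] = True
        return RoiSpec("mask", mask=m, **common)
    return RoiSpec("circle", center=tuple(float(c) for c in d["center"]),
                   diameter_mm=float(d["diameter_mm"]), **common)


def layout_to_dict(layout: NmLayout) -> dict:
    """Serialize an NM analysis layout (voxel-index convention, 0-based)."""
    sr = np.argwhere(layout.search_mask)
    return {
        "coordinate_convention": "voxel_indices_0based",
        "sn": {
            "slices": list(layout.sn_slices),
            "window": layout.sn_window,
            "background_rois": [_roi_to_dict(r) for r in layout.bg_rois.values()],
            "search_region": {
                "rows": [int(sr[:, 0].min()), int(sr[:, 0].max()) + 1],
                "cols": [int(sr[:, 1].min()), int(sr[:, 1].max()) + 1],
                "slices": [int(sr[:, 2].min()), int(sr[:, 2].max()) + 1],
            },
        },
        "lc": {
            "slices": list(layout.lc_slices),
            "ventricle_label": LABEL_CODES["fourth_ventricle"],
            "tegmentum_rois": [_roi_to_dict(r) for r in layout.teg_rois.values()],
        },
    }


def layout_from_dict(d: dict, shape: tuple[int, int, int]) -> NmLayout:
    shape2d = shape[:2]
    sn, lc = d["sn"], d["lc"]
    bg = {}
    for rd in sn["background_rois"]:
        roi = _roi_from_dict(rd, shape2d)
        bg[(roi.slice_index, roi.side)] = roi
    teg = {}
    for rd in lc["tegmentum_rois"]:
        roi = _roi_from_dict(rd, shape2d)
        teg[(roi.slice_index, roi.side)] = roi
    search = np.zeros(shape, dtype=bool)
    sr = sn.get("search_region")
    if sr is None:
        search[:] = True
    else:
        search[sr["rows"][0]:sr["rows"][1], sr["cols"][0]:sr["cols"][1],
               sr["slices"][0]:sr["slices"][1]] = True
    return NmLayout(bg_rois=bg, teg_rois=teg, sn_slices=tuple(sn["slices"]),
                    lc_slices=tuple(lc["slices"]), search_mask=search,
                    sn_window=int(sn.get("window", 4)))


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


# --------------------------------------------------------------------------
# per-subject measurement drivers
# --------------------------------------------------------------------------


def measure_nm_subject(
    vol: ImageVolume,
    layout: NmLayout,
    ventricle_mask: np.ndarray,
    n_repeats: int = 4,
    seed: int | None = None,
    hc_medians: dict[str, float] | None = None,
) -> dict:
    """Full NM measurement for one subject, repeated with re-placed ROIs.

    Each repeat re-places every circular reference ROI with +/-1 voxel
    uniform jitter (emulating intra-rater variability) and recomputes SN
    volume, CNR_SN and CNR_LC per side; means and sample SDs across
    repeats are returned, along with the per-repeat values (for ICC) and
    the SN mask of the first repeat.
    """
    if n_repeats < 2:
        raise NmPipelineError("need at least two repeats")
    rng = np.random.default_rng(seed)
    per_repeat: list[dict[str, float]] = []
    first_masks: dict[str, np.ndarray] = {}
    for rep in range(n_repeats):
        bg = {k: (r if rep == 0 else jitter_roi(r, rng)) for k, r in layout.bg_rois.items()}
        teg = {k: (r if rep == 0 else jitter_roi(r, rng)) for k, r in layout.teg_rois.items()}
        sn = measure_sn(vol, bg, layout.search_mask, layout.sn_window)
        lcm = measure_lc(vol, ventricle_mask, list(layout.lc_slices), teg)
        row: dict[str, float] = {}
        for side in ("left", "right"):
            row[f"sn_volume_{side}"] = sn[side].volume_mm3
            row[f"cnr_sn_{side}"] = sn[side].cnr
            row[f"cnr_lc_{side}"] = lcm[side].cnr
            if rep == 0:
                first_masks[side] = sn[side].mask
        per_repeat.append(row)
    mean, sd = average_repeats(per_repeat)
    result = {"mean": mean, "sd": sd, "repeats": per_repeat, "sn_masks": first_masks}
    if hc_medians:
        result["percent_cnr"] = {
            k: mean[k] / hc_medians[k] * 100.0 for k in hc_medians if k in mean
        }
    return result


def measure_iron_subject(
    pair: DualEchoPair,
    chi_vol: ImageVolume | None,
    sn_masks: dict[str, np.ndarray],
    n_repeats: int = 2,
) -> dict:
    """R2* (and optionally susceptibility) SN means with two-repeat averaging.

    The second repeat emulates a re-delineation as a conservative inner
    trace: the mask eroded by one in-plane voxel (a re-drawn ROI varies at
    the boundary but stays on the structure). Falls back to the original
    mask where erosion would empty it.
    """
    from scipy.ndimage import binary_erosion

    r2map = fit_r2star(pair)
    chimap = quant_map_from_volume(chi_vol) if chi_vol is not None else None
    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[:, 1, 0] = structure[1, :, 0] = True  # in-plane 4-neighbourhood
    reps_r2, reps_chi = [], []
    for rep in range(n_repeats):
        if rep == 0:
            masks = sn_masks
        else:
            masks = {}
            for s, m in sn_masks.items():
                inner = binary_erosion(m, structure=structure)
                masks[s] = inner if inner.any() else m
        reps_r2.append(sample_sn_rois(r2map, masks))
        if chimap is not None:
            reps_chi.append(sample_sn_rois(chimap, masks))
    out: dict = {"r2star": average_two_repeats(reps_r2[0], reps_r2[-1])}
    if chimap is not None:
        out["susceptibility"] = average_two_repeats(reps_chi[0], reps_chi[-1])
    return out


# --------------------------------------------------------------------------
# end-to-end driver
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full synthetic run.

    ``imaging_subjects`` controls how many phantom subjects per group are
    imaged and measured; cohort statistics run on a simulated table of
    ``n_pd`` / ``n_hc`` subjects (phantom imaging at cohort scale would
    add nothing: the cohort generator draws from the same distributions
    the phantoms are built from).
    """

    seed: int = 0
    out_dir: Path = Path("results")
    imaging_subjects: int = 2  # per group
    nm_repeats: int = 4
    iron_repeats: int = 2
    n_pd: int = 18
    n_hc: int = 18
    rho_sn_dat: float = 0.75
    cohort_csv: Path | None = None  # use an existing table instead of simulating
    roc_measure: str = "sn_volume_contra"
    roc_direction: str = "lower"
    battery: list[tuple[str, str]] = field(default_factory=lambda: [
        ("sn_volume_contra", "putamen_contra"),
        ("sn_volume_contra", "caudate_contra"),
        ("cnr_sn_contra", "putamen_contra"),
        ("cnr_sn_contra", "caudate_contra"),
        ("cnr_lc_contra", "putamen_contra"),
        ("cnr_lc_contra", "caudate_contra"),
    ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = load_yaml(path) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.out_dir = Path(cfg.out_dir)
        if cfg.cohort_csv is not None:
            cfg.cohort_csv = Path(cfg.cohort_csv)
            if not cfg.cohort_csv.exists():
                raise FileNotFoundError(f"no such cohort file: {cfg.cohort_csv}")
        if not isinstance(cfg.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {cfg.seed!r}")
        cfg.battery = [tuple(p) for p in cfg.battery]
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, subject: str, t0: float, seed) -> None:
    log.info("stage=%s subject=%s elapsed=%.3fs seed=%s", name, subject, time.time() - t0, seed)


def run_full_pipeline(config: RunConfig) -> dict:
    """Phantoms -> NM + iron measurements -> cohort table -> statistics.

    Writes all outputs under ``config.out_dir`` and returns the manifest
    (also written as ``manifest.json``). Any stage failure raises with the
    stage name and subject id.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    child = {name: s for name, s in zip(
        ("imaging", "cohort"), ss.spawn(2))}
    outputs: list[Path] = []

    # ---- imaging stage: phantom subjects, measured end to end ----
    rows = []
    repeat_matrix: dict[str, list[list[float]]] = {
        "sn_volume_left": [], "cnr_sn_left": [], "cnr_lc_left": []}
    img_seeds = child["imaging"].spawn(2 * config.imaging_subjects)
    idx = 0
    from .phantom import GROUP_DISTRIBUTIONS  # group parameters for subject truth

    for group in ("PD", "HC"):
        g = group.lower()
        for k in range(config.imaging_subjects):
            sid = f"{group}{k + 1:02d}"
            seeds = img_seeds[idx].generate_state(4)
            idx += 1
            t0 = time.time()
            try:
                nm_spec = default_nm_spec(
                    sn_volume_mm3=GROUP_DISTRIBUTIONS["sn_volume_contra"][g][0],
                    sn_cnr=GROUP_DISTRIBUTIONS["cnr_sn_contra"][g][0],
                    lc_cnr=GROUP_DISTRIBUTIONS["cnr_lc_contra"][g][0],
                    seed=int(seeds[0] % (2**31)),
                )
                ph = make_nm_phantom(nm_spec)
                layout = nm_layout(nm_spec)
                nm_res = measure_nm_subject(
                    ph.vol, layout, ph.labels == LABEL_CODES["fourth_ventricle"],
                    n_repeats=config.nm_repeats, seed=int(seeds[1] % (2**31)))
                iron_spec = default_iron_spec(
                    r2star=GROUP_DISTRIBUTIONS["r2star_contra"][g][0],
                    noise_sd=5.0, seed=int(seeds[2] % (2**31)))
                de = make_dual_echo_phantom(iron_spec)
                chi_spec = default_susceptibility_spec(
                    chi_ppm=GROUP_DISTRIBUTIONS["susceptibility_contra"][g][0],
                    noise_sd=0.02, seed=int(seeds[2] % (2**31)))
                chi = make_susceptibility_phantom(chi_spec)
                iron_res = measure_iron_subject(
                    DualEchoPair(de.te1, de.te2, iron_spec.te1_ms, iron_spec.te2_ms),
                    chi.vol,
                    {"left": de.mask("SN_left"), "right": de.mask("SN_right")},
                    n_repeats=config.iron_repeats)
            except Exception as e:
                raise RuntimeError(f"stage=imaging subject={sid}: {e}") from e
            _stage("imaging", sid, t0, int(seeds[0] % (2**31)))
            if sid == "PD01":
                outputs.append(save_volume(ph.vol, out / "phantom_PD01_nm.nii.gz"))
                outputs.append(save_labels(ph.labels, nm_spec.spacing, out / "phantom_PD01_labels.nii.gz"))
                mask = nm_res["sn_masks"]["left"] | nm_res["sn_masks"]["right"]
                outputs.append(save_labels(mask.astype(np.int16), nm_spec.spacing,
                                           out / "phantom_PD01_sn_mask.nii.gz"))
            row = {"subject_id": sid, "group": group}
            row.update(nm_res["mean"])
            for side in ("left", "right"):
                row[f"r2star_{side}"] = iron_res["r2star"][side]
                row[f"susceptibility_{side}"] = iron_res["susceptibility"][side]
            row["ai_sn_volume"] = asymmetry_index(row["sn_volume_right"], row["sn_volume_left"])
            rows.append(row)
            for key in repeat_matrix:
                repeat_matrix[key].append([r[key] for r in nm_res["repeats"]])
    measures = pd.DataFrame(rows)
    outputs.append(save_cohort(measures, out / "imaging_measures.csv"))

    # ---- cohort stage ----
    t0 = time.time()
    if config.cohort_csv is not None:
        cohort = load_cohort(config.cohort_csv)
    else:
        cohort = make_cohort(CohortSpec(
            n_pd=config.n_pd, n_hc=config.n_hc, rho_sn_dat=config.rho_sn_dat,
            seed=int(child["cohort"].generate_state(1)[0] % (2**31))))
        outputs.append(save_cohort(cohort, out / "cohort.csv"))
    _stage("cohort", "-", t0, config.seed)

    # ---- statistics stage ----
    t0 = time.time()
    try:
        comparisons = [group_compare(cohort, m) for m in
                       ("sn_volume_contra", "cnr_sn_contra", "cnr_lc_contra",
                        "putamen_contra", "r2star_contra", "susceptibility_contra")
                       if m in cohort.columns]
        comp_df = pd.DataFrame([asdict(c) for c in comparisons])
        outputs.append(save_cohort(comp_df, out / "group_tests.csv"))
        battery = [p for p in config.battery
                   if p[0] in cohort.columns and p[1] in cohort.columns]
        corr = spearman_battery(cohort, battery, group="PD")
        corr_df = pd.DataFrame([asdict(c) for c in corr])
        outputs.append(save_cohort(corr_df, out / "correlations.csv"))
        roc = roc_analysis(cohort, config.roc_measure, config.roc_direction)
        roc_json = {
            "measure": roc.measure, "direction": roc.direction, "auc": roc.auc,
            "n_pd": roc.n_pd, "n_hc": roc.n_hc,
            "cutoff_sens100": asdict(roc.cutoff_sens100) if roc.cutoff_sens100 else None,
            "cutoff_spec100": asdict(roc.cutoff_spec100) if roc.cutoff_spec100 else None,
            "cutoff_best_accuracy": asdict(roc.cutoff_best_accuracy) if roc.cutoff_best_accuracy else None,
        }
        (out / "roc.json").write_text(json.dumps(roc_json, indent=2))
        outputs.append(out / "roc.json")
        pred = {resp: asdict(predict_dat(cohort, resp))
                for resp in ("putamen_contra", "caudate_contra") if resp in cohort.columns}
        (out / "prediction.json").write_text(json.dumps(pred, indent=2))
        outputs.append(out / "prediction.json")
        icc = {key: asdict(icc_reliability(np.asarray(mat)))
               for key, mat in repeat_matrix.items() if len(mat) >= 3}
        if icc:
            (out / "icc.json").write_text(json.dumps(icc, indent=2))
            outputs.append(out / "icc.json")
    except Exception as e:
        raise RuntimeError(f"stage=stats subject=-: {e}") from e
    _stage("stats", "-", t0, config.seed)

    manifest = {
        "package": "nigrascan",
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in asdict(config).items()},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        "inputs": ({str(config.cohort_csv): _sha256(config.cohort_csv)}
                   if config.cohort_csv else {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
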