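"""End-to-end orchestration: register -> segment -> classify -> quantify.

A run takes >=2 scans of one bone (day 0 first), registers all later time
points onto the day-0 reference, crops one axial ROI (defined on the
reference, propagated unchanged), segments the day-0 cortex into
endocortical and periosteal regions, classifies formed/resorbed voxels for
every day-0 -> day-t interval, and writes one tidy morphometry row per
(region, interval) plus label volumes and a provenance log.

All intervals are anchored at day 0, not chained scan-to-scan.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .io import ImageVolume, RegionLabelVolume, read_volume, write_label_volume
from .morphometry import (MorphometryRecord, dynamic_surfaces, dynamic_volumes,
                          net_change_curves, rates, records_to_frame,
                          static_morphometry, thickness_stats)
from .registration import (RigidTransform, axial_roi_slices, isolate_main_bone,
                           prealign, register_rigid_nmi, resample)
from .remodeling import (RemodelingMap, classify_voxels, conservation_holds,
                         filter_small_packages, label_packages)
from .segmentation import (SurfaceSet, binarize, extract_surfaces,
                           peel_surface_layer, remove_medullary_debris,
                           split_cortical_regions)

logger = logging.getLogger("cortmorph")

REGIONS = ("endocortical", "periosteal")


@dataclass
class RunConfig:
    """Protocol constants and knobs of one pipeline run.

    ``shrink_thickness_um`` defaults to three times the expected periosteal
    surface movement over the observation time (``expected_movement_um``,
    itself a tunable prior from histomorphometry).
    """

    input_paths: list[str] = field(default_factory=list)
    scan_days: list[float] = field(default_factory=lambda: [0.0, 15.0])
    voxel_size_um: float = 10.5
    threshold: float = 423.0            # on the 0-1000 grey scale
    gaussian_sigma_vox: float = 0.8
    closing_radius_vox: int = 2
    expected_movement_um: float = 40.0
    shrink_thickness_um: float | None = None
    roi_fraction: float = 0.05
    tibia_length_um: float = 17850.0
    roi_center_index: int | None = None
    min_package_size: int = 3
    surface_params_final_interval_only: bool = True
    do_registration: bool = True
    do_roi_crop: bool = True
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shrink_thickness_um is None:
            self.shrink_thickness_um = 3.0 * self.expected_movement_um
        days = list(self.scan_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("scan days must be strictly increasing")
        for name in ("voxel_size_um", "threshold", "roi_fraction",
                     "tibia_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- plain-text (key = value) serialisation --------------------------
    _LIST_FIELDS = ("input_paths", "scan_days")

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# cortmorph run configuration\n")
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if f.name in self._LIST_FIELDS:
                    value = ",".join(str(v) for v in value)
                fh.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        raw: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "input_paths":
                kwargs[f.name] = [v for v in val.split(",") if v]
            elif f.name == "scan_days":
                kwargs[f.name] = [float(v) for v in val.split(",") if v]
            elif val == "None":
                kwargs[f.name] = None
            elif f.type in ("bool",):
                kwargs[f.name] = val == "True"
            elif f.type in ("int",):
                kwargs[f.name] = int(val)
            elif f.name in ("closing_radius_vox", "min_package_size", "seed"):
                kwargs[f.name] = int(val)
            elif f.name in ("roi_center_index",):
                kwargs[f.name] = int(val)
            elif f.name in ("surface_params_final_interval_only",
                            "do_registration", "do_roi_crop"):
                kwargs[f.name] = val == "True"
            elif f.name == "output_dir":
                kwargs[f.name] = val
            else:
                kwargs[f.name] = float(val)
        return cls(**kwargs)

    def digest(self) -> str:
        text = "|".join(f"{f.name}={getattr(self, f.name)}"
                        for f in dataclasses.fields(self))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: list[MorphometryRecord]
    frame: pd.DataFrame
    net_change: pd.DataFrame
    labels_day0: RegionLabelVolume
    surfaces_day0: SurfaceSet
    remodeling_maps: dict[float, RemodelingMap]
    transforms: list[RigidTransform]
    masks: list[np.ndarray]
    log_lines: list[str]


def _masked_grey(volume: ImageVolume, config: RunConfig) -> ImageVolume:
    """Suppress the fibula analogue and debris for registration: keep grey
    values only near the largest bone component (provisional threshold)."""
    from scipy import ndimage

    provisional = binarize(volume, config.gaussian_sigma_vox, config.threshold)
    if not provisional.any():
        raise ValueError("registration: no bone above the provisional threshold")
    main = isolate_main_bone(provisional)
    keep = ndimage.binary_dilation(main, iterations=3)
    data = np.where(keep, volume.data, np.median(volume.data))
    return ImageVolume(data, volume.voxel_size_um)


def register_series(volumes: list[ImageVolume], config: RunConfig
                    ) -> tuple[list[ImageVolume], list[RigidTransform], list[str]]:
    """Register all later time points onto the first volume (Lanczos
    resampling onto the reference grid)."""
    log: list[str] = []
    reference = volumes[0]
    ref_masked = _masked_grey(reference, config)
    out_volumes = [reference]
    transforms = [RigidTransform.identity()]
    for t, moving in enumerate(volumes[1:], start=1):
        mov_masked = _masked_grey(moving, config)
        init = prealign(mov_masked, ref_masked)
        result = register_rigid_nmi(mov_masked, ref_masked, init)
        log.append(f"registration t{t}: NMI {result.final_metric:.4f} "
                   f"(init {result.info.get('nmi_init', float('nan')):.4f}), "
                   f"converged={result.converged}, iters={result.iterations}")
        out_volumes.append(resample(moving, result.transform, reference))
        transforms.append(result.transform)
    return out_volumes, transforms, log


def analyze_registered_series(volumes: list[ImageVolume],
                              scan_days: list[float],
                              config: RunConfig) -> PipelineResult:
    """Segmentation, classification and morphometry of an already
    registered (common-grid) series."""
    log: list[str] = []
    vs = volumes[0].voxel_size_um
    masks = []
    for t, vol in enumerate(volumes):
        mask = remove_medullary_debris(
            binarize(vol, config.gaussian_sigma_vox, config.threshold))
        masks.append(mask)
        log.append(f"segmentation t{t}: {int(mask.sum())} cortical voxels")

    labels0 = split_cortical_regions(masks[0], config.shrink_thickness_um,
                                     vs, config.closing_radius_vox)
    labels0.provenance.update({
        "threshold": config.threshold,
        "gaussian_sigma_vox": config.gaussian_sigma_vox})
    surfaces0 = extract_surfaces(labels0)
    peeled = [peel_surface_layer(m) for m in masks]
    bv0_vox = int(masks[0].sum())

    records: list[MorphometryRecord] = []
    maps: dict[float, RemodelingMap] = {}
    final_day = scan_days[-1]
    for t in range(1, len(volumes)):
        interval = (scan_days[0], scan_days[t])
        rmap = classify_voxels(peeled[0], peeled[t], surfaces0.peeled_labels,
                               interval_days=interval)
        if not conservation_holds(peeled[0], peeled[t], rmap):
            raise AssertionError("voxel conservation violated")  # pragma: no cover
        rmap = filter_small_packages(rmap, config.min_package_size)
        maps[scan_days[t]] = rmap
        ct_bv, ct_ar, ct_th = static_morphometry(masks[t], vs)
        want_surface = (not config.surface_params_final_interval_only
                        or scan_days[t] == final_day)
        for region in REGIONS:
            mv, ev = dynamic_volumes(rmap, masks[0], region)
            rec = MorphometryRecord(
                region=region, t_start_day=interval[0], t_end_day=interval[1],
                Ct_BV_um3=ct_bv, Ct_Ar_um2=ct_ar, Ct_Th_um=ct_th,
                MV_BV_pct=mv, EV_BV_pct=ev,
                day0_BV_um3=bv0_vox * vs ** 3)
            if want_surface:
                formed = label_packages(rmap, "formed", region)
                resorbed = label_packages(rmap, "resorbed", region)
                mth = thickness_stats(formed)
                ed = thickness_stats(resorbed)
                ms, es = dynamic_surfaces(rmap, surfaces0, region)
                rec = dataclasses.replace(
                    rec, MS_BS_pct=ms, ES_BS_pct=es,
                    MTh_um=mth.value_um, ED_um=ed.value_um,
                    no_formation=mth.empty, no_resorption=ed.empty)
            records.append(rates(rec, interval[1] - interval[0]))
        log.append(f"interval day0->day{scan_days[t]:g}: "
                   f"{int(rmap.formed.sum())} formed, "
                   f"{int(rmap.resorbed.sum())} resorbed voxels")

    frame = records_to_frame(records)
    net = net_change_curves(records)
    return PipelineResult(records=records, frame=frame, net_change=net,
                          labels_day0=labels0, surfaces_day0=surfaces0,
                          remodeling_maps=maps, transforms=[],
                          masks=masks, log_lines=log)


def run_pipeline(config: RunConfig,
                 volumes: list[ImageVolume] | None = None) -> PipelineResult:
    """Execute the full pipeline; see the module docstring.

    ``volumes`` may be supplied in memory (e.g. a phantom series);
    otherwise they are read from ``config.input_paths``.
    """
    log: list[str] = [f"cortmorph {_version}, config {config.digest()}"]
    if volumes is None:
        volumes = [read_volume(p, config.voxel_size_um)
                   for p in config.input_paths]
    if len(volumes) < 2:
        raise ValueError("at least two time points are required")
    if len(volumes) != len(config.scan_days):
        raise ValueError("one scan day per input volume is required")

    stage = "registration"
    try:
        if config.do_registration:
            volumes, transforms, reg_log = register_series(volumes, config)
            log += reg_log
        else:
            transforms = [RigidTransform.identity()] * len(volumes)
            log.append("registration skipped (pre-registered inputs)")

        stage = "roi crop"
        if config.do_roi_crop:
            sl = axial_roi_slices(volumes[0].shape[0], config.voxel_size_um,
                                  config.tibia_length_um, config.roi_fraction,
                                  config.roi_center_index)
            volumes = [ImageVolume(v.data[sl].copy(), v.voxel_size_um)
                       for v in volumes]
            log.append(f"ROI slab: slices [{sl.start}, {sl.stop}) "
                       "shared by all time points")

        stage = "analysis"
        result = analyze_registered_series(volumes, list(config.scan_days),
                                           config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result.transforms = transforms
    result.log_lines = log + result.log_lines
    for line in result.log_lines:
        logger.info(line)

    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    result.frame.to_csv(os.path.join(out, "morphometry.csv"),
                        index=False, float_format="%.6g")
    result.net_change.to_csv(os.path.join(out, "net_change.csv"),
                             index=False, float_format="%.6g")
    write_label_volume(result.labels_day0.labels, config.voxel_size_um,
                       os.path.join(out, "regions_day0.tif"),
                       sidecar=result.labels_day0.provenance)
    for day, rmap in result.remodeling_maps.items():
        write_label_volume(rmap.state, config.voxel_size_um,
                           os.path.join(out, f"remodeling_day{day:g}.tif"))
        write_label_volume(rmap.region, config.voxel_size_um,
                           os.path.join(out, f"regions_day{day:g}.tif"))
    config.to_file(os.path.join(out, "run_config.txt"))
    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")
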