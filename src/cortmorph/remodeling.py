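"""Voxel-wise (re)modeling classification between two registered scans.

Bone voxels present at both time points are quiescent; voxels present only
in the later scan were formed, voxels present only in the earlier scan
were resorbed.  Event voxels inherit a surface-region tag (endocortical /
periosteal) and are grouped into 26-connected packages (formation patches,
resorption cavities).

The comparison operates on the binarised, debris-removed, peeled masks so
that event voxels sit directly against the surfaces used by the
morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import RegionLabelVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

BACKGROUND, QUIESCENT, FORMED, RESORBED = 0, 1, 2, 3
REGION_NONE, REGION_ENDO, REGION_PERI = 0, 1, 2
_REGION_CODE = {"endocortical": REGION_ENDO, "periosteal": REGION_PERI}


@dataclass
class RemodelingMap:
    """Per-voxel remodeling state for one day-0 -> day-t comparison.

    ``state``: 0 background, 1 quiescent, 2 formed, 3 resorbed.
    ``region``: 0 none, 1 endocortical, 2 periosteal (for non-background).
    """

    state: np.ndarray
    region: np.ndarray
    voxel_size_um: float
    interval_days: tuple[float, float]

    def voxels(self, state: int, region: str | None = None) -> np.ndarray:
        sel = self.state == state
        if region is not None:
            sel &= self.region == _REGION_CODE[region]
        return sel

    @property
    def formed(self) -> np.ndarray:
        return self.state == FORMED

    @property
    def resorbed(self) -> np.ndarray:
        return self.state == RESORBED


def classify_voxels(mask_t0: np.ndarray, mask_t1: np.ndarray,
                    labels_t0: RegionLabelVolume,
                    interval_days: tuple[float, float] = (0.0, 15.0)
                    ) -> RemodelingMap:
    """Set-difference classification of two registered bone masks.

    quiescent = t0 & t1, formed = t1 \\ t0, resorbed = t0 \\ t1.

    Region ownership: voxels inside the day-0 label volume take its label;
    formed voxels (which lie outside the day-0 bone) take the region of
    the nearest day-0 labelled voxel by Euclidean distance, ties broken
    toward endocortical.  The assignment is deterministic and total.
    """
    mask_t0 = np.asarray(mask_t0, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t0.shape != mask_t1.shape or mask_t0.shape != labels_t0.labels.shape:
        raise ValueError("masks and labels must share one registered grid")

    state = np.zeros(mask_t0.shape, dtype=np.uint8)
    state[mask_t0 & mask_t1] = QUIESCENT
    state[mask_t1 & ~mask_t0] = FORMED
    state[mask_t0 & ~mask_t1] = RESORBED

    region = np.zeros(mask_t0.shape, dtype=np.uint8)
    needs = state > 0
    has_endo = (labels_t0.labels == RegionLabelVolume.ENDOCORTICAL).any()
    has_peri = (labels_t0.labels == RegionLabelVolume.PERIOSTEAL).any()
    if has_endo and has_peri:
        d_endo = ndimage.distance_transform_edt(
            labels_t0.labels != RegionLabelVolume.ENDOCORTICAL)
        d_peri = ndimage.distance_transform_edt(
            labels_t0.labels != RegionLabelVolume.PERIOSTEAL)
        region[needs] = np.where(d_endo[needs] <= d_peri[needs],
                                 REGION_ENDO, REGION_PERI)
    elif has_endo or has_peri:
        region[needs] = REGION_ENDO if has_endo else REGION_PERI
    # inside the day-0 labels the tag is the label itself
    inside = needs & (labels_t0.labels > 0)
    region[inside] = labels_t0.labels[inside]

    return RemodelingMap(state=state, region=region,
                         voxel_size_um=labels_t0.voxel_size_um,
                         interval_days=tuple(interval_days))


@dataclass
class Package:
    """One connected formation patch or resorption cavity."""

    voxel_count: int
    volume_um3: float
    mean_thickness_um: float
    footprint_voxels: int = 0


@dataclass
class PackageSet:
    kind: str                       # 'formed' | 'resorbed'
    region: str                     # 'endocortical' | 'periosteal'
    packages: list[Package] = field(default_factory=list)
    voxel_size_um: float = 0.0

    def __len__(self) -> int:
        return len(self.packages)

    @property
    def total_volume_um3(self) -> float:
        return float(sum(p.volume_um3 for p in self.packages))

    def to_records(self) -> list[dict]:
        return [{"kind": self.kind, "region": self.region,
                 "voxel_count": p.voxel_count, "volume_um3": p.volume_um3,
                 "mean_thickness_um": p.mean_thickness_um,
                 "footprint_voxels": p.footprint_voxels}
                for p in self.packages]


def label_packages(rmap: RemodelingMap, kind: str, region: str,
                   min_size: int = 1,
                   surface_mask: np.ndarray | None = None) -> PackageSet:
    """Group formed (or resorbed) voxels of one region into 26-connected
    packages with per-package volume and local-thickness statistics.

    ``min_size`` drops packages below that voxel count (default keeps
    everything, including isolated single-voxel events).  When a day-0
    surface mask is supplied, each package's surface footprint (number of
    26-adjacent surface voxels) is recorded.
    """
    from .morphometry import local_thickness

    state_code = FORMED if kind == "formed" else RESORBED
    sel = rmap.voxels(state_code, region)
    vs = rmap.voxel_size_um
    out = PackageSet(kind=kind, region=region, voxel_size_um=vs)
    if not sel.any():
        return out

    labels, n = ndimage.label(sel, structure=_STRUCT26)
    objects = ndimage.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        # keep a 1-voxel background apron: a tight crop would make the
        # distance transform treat the crop faces as bone continuation
        sl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                   for s, dim in zip(sl, labels.shape))
        comp = labels[sl] == i
        count = int(comp.sum())
        if count < min_size:
            continue
        thick = local_thickness(comp, vs, upsample=2)
        mean_th = float(thick[_upsample_mask(comp)].mean())
        footprint = 0
        if surface_mask is not None:
            grown = ndimage.binary_dilation(sel & (labels == i),
                                            structure=_STRUCT26)
            footprint = int((grown & np.asarray(surface_mask, bool)).sum())
        out.packages.append(Package(
            voxel_count=count, volume_um3=count * vs ** 3,
            mean_thickness_um=mean_th, footprint_voxels=footprint))
    return out


def _upsample_mask(mask: np.ndarray, factor: int = 2) -> np.ndarray:
    out = mask
    for axis in range(3):
        out = np.repeat(out, factor, axis=axis)
    return out


def filter_small_packages(rmap: RemodelingMap, min_size: int) -> RemodelingMap:
    """Despeckle: drop formed/resorbed 26-connected components smaller than
    ``min_size`` voxels.

    Grey-value noise flips isolated surface voxels, producing spurious 1-2
    voxel events; biological packages are orders of magnitude larger.
    Removed formed voxels revert to background (they were not bone at t0),
    removed resorbed voxels revert to quiescent.  ``min_size <= 1`` keeps
    everything.
    """
    if min_size <= 1:
        return rmap
    state = rmap.state.copy()
    for code, revert in ((FORMED, BACKGROUND), (RESORBED, QUIESCENT)):
        sel = state == code
        if not sel.any():
            continue
        labels, n = ndimage.label(sel, structure=_STRUCT26)
        sizes = np.bincount(labels.ravel())
        small = sizes < min_size
        small[0] = False
        state[small[labels]] = revert
    region = rmap.region.copy()
    region[state == BACKGROUND] = REGION_NONE
    return RemodelingMap(state=state, region=region,
                         voxel_size_um=rmap.voxel_size_um,
                         interval_days=rmap.interval_days)


def conservation_holds(mask_t0: np.ndarray, mask_t1: np.ndarray,
                       rmap: RemodelingMap) -> bool:
    """|bone(t1)| = |bone(t0)| + |formed| - |resorbed|, exactly."""
    return (int(np.asarray(mask_t1, bool).sum())
            == int(np.asarray(mask_t0, bool).sum())
            + int(rmap.formed.sum()) - int(rmap.resorbed.sum()))
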