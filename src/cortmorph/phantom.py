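"""Synthetic longitudinal microCT phantom of a long-bone diaphysis.

The phantom emulates the specimen the pipeline is designed for: a bowed
tubular cortical shell with a medullary canal, intracortical vessel
channels, loose mineralised spicules inside the canal, and stripe-shaped
surface remodeling events (formation patches and resorption cavities
elongated parallel to the bone axis).  Rendering adds the acquisition
chain — per-time-point rigid misalignment, point-spread blur and additive
Gaussian grey-value noise on a 0-1000 grey scale.

Events and geometry are defined in cylindrical coordinates around the
(possibly bowed) centreline, so patches are axis-parallel stripes.  Events
attached to interval ``i`` appear from time point ``i+1`` onward,
instantaneously (the downstream classifier is binary per scan pair).
Ground-truth masks live on the reference (time-point-0) grid; the
misalignment only affects the rendered grey volumes, so registration error
is measurable against the stored truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ImageVolume
from .morphometry import (MorphometryRecord, rates, static_morphometry,
                          thickness_stats)
from .registration import RigidTransform
from .segmentation import peel_surface_layer

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

SURFACES = ("endocortical", "periosteal")


@dataclass(frozen=True)
class RemodelingEvent:
    """A stripe-shaped surface remodeling event.

    ``thickness_um`` is the apposition height (formation) or cavity depth
    (resorption); the footprint is ``angular_span_deg`` x ``axial_span_um``
    centred at (``centroid_angle_deg``, ``centroid_z_um``).
    """

    surface: str                     # 'endocortical' | 'periosteal'
    kind: str                        # 'formation' | 'resorption'
    interval_index: int
    angular_span_deg: float
    axial_span_um: float
    thickness_um: float
    centroid_angle_deg: float
    centroid_z_um: float

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface {self.surface!r}")
        if self.kind not in ("formation", "resorption"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")


@dataclass
class PhantomSpec:
    """Geometry, events and acquisition parameters of one phantom series."""

    grid_shape: tuple[int, int, int] = (64, 96, 96)   # (z, y, x), z = axis
    voxel_size_um: float = 10.5
    outer_radius_um: float = 210.0
    inner_radius_um: float = 126.0
    bow_amplitude_um: float = 31.5
    ellipticity: float = 0.10
    vessel_count: int = 0
    vessel_radius_um: float = 8.0
    spicule_count: int = 0
    spicule_radius_um: float = 21.0
    event_list: list[RemodelingEvent] = field(default_factory=list)
    noise_sd: float = 20.0
    blur_sigma_um: float = 5.25
    misalignment_per_timepoint: list[RigidTransform] | None = None
    bone_grey: float = 700.0
    background_grey: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.misalignment_per_timepoint is None:
            self.misalignment_per_timepoint = [RigidTransform.identity()] * 2

    @property
    def n_timepoints(self) -> int:
        return len(self.misalignment_per_timepoint)

    def validate(self) -> None:
        vs = self.voxel_size_um
        if not self.inner_radius_um < self.outer_radius_um:
            raise ValueError("inner_radius_um must be < outer_radius_um")
        if min(self.inner_radius_um, self.outer_radius_um) <= 2 * vs:
            raise ValueError("all radii must exceed 2 voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ellipticity < 0.5:
            raise ValueError("ellipticity must be in [0, 0.5)")
        nz, ny, nx = self.grid_shape
        half_extent = (min(nx, ny) - 1) / 2.0 * vs
        if self.outer_radius_um * (1 + self.ellipticity) \
                + self.bow_amplitude_um + 3 * vs > half_extent:
            raise ValueError("shell plus bow does not fit the grid with a "
                             ">=3 voxel background margin")
        if self.n_timepoints < 1:
            raise ValueError("at least one time point required")


@dataclass
class PhantomGroundTruth:
    """Noise-free truth emitted alongside a phantom series.

    Masks are pre-blur, pre-noise binaries on the reference grid.
    ``true_transforms`` are the corrective transforms (inverses of the
    applied misalignments) a registration should recover.
    """

    true_bone_masks: list[np.ndarray]
    true_formed: dict[tuple[int, str], np.ndarray]
    true_resorbed: dict[tuple[int, str], np.ndarray]
    true_transforms: list[RigidTransform]
    spicule_mask: np.ndarray
    radius_map_um: np.ndarray
    mid_radius_um: float
    voxel_size_um: float

    def region_mask(self, mask: np.ndarray, region: str) -> np.ndarray:
        """Split any mask radially at the cortical mid-surface."""
        inner = self.radius_map_um < self.mid_radius_um
        return mask & (inner if region == "endocortical" else ~inner)

    def formed_between(self, t0: int, t1: int) -> np.ndarray:
        return self.true_bone_masks[t1] & ~self.true_bone_masks[t0]

    def resorbed_between(self, t0: int, t1: int) -> np.ndarray:
        return self.true_bone_masks[t0] & ~self.true_bone_masks[t1]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _cylindrical_coords(spec: PhantomSpec):
    """(scaled radius um, angle deg, z um) of every voxel centre relative
    to the bowed centreline.

    The radius is scaled by ``1 / (1 + ellipticity * cos(2 theta))`` so the
    shell has a mildly elliptical cross-section (a long-bone mid-shaft is
    distinctly non-circular; a perfectly circular tube would leave in-plane
    rotation unobservable for any registration method)."""
    nz, ny, nx = spec.grid_shape
    vs = spec.voxel_size_um
    z = np.arange(nz)[:, None, None] * vs
    y = np.arange(ny)[None, :, None] * vs
    x = np.arange(nx)[None, None, :] * vs
    cx0 = (nx - 1) / 2.0 * vs
    cy0 = (ny - 1) / 2.0 * vs
    length = (nz - 1) * vs
    cx = cx0 + spec.bow_amplitude_um * np.sin(np.pi * z / max(length, vs))
    dx = x - cx
    dy = y - cy0
    r = np.sqrt(dx ** 2 + dy ** 2)
    theta = np.degrees(np.arctan2(dy, dx))
    r = r / (1.0 + spec.ellipticity * np.cos(2.0 * np.radians(theta)))
    zmap = np.broadcast_to(z, spec.grid_shape)
    return r, np.broadcast_to(theta, spec.grid_shape), zmap


def _wrap_angle(delta_deg: np.ndarray) -> np.ndarray:
    return (delta_deg + 180.0) % 360.0 - 180.0


def _event_mask(event: RemodelingEvent, spec: PhantomSpec,
                r: np.ndarray, theta: np.ndarray, zmap: np.ndarray) -> np.ndarray:
    """Analytic stripe patch of one event on the base shell radii."""
    in_angle = np.abs(_wrap_angle(theta - event.centroid_angle_deg)) \
        <= event.angular_span_deg / 2.0
    in_axis = np.abs(zmap - event.centroid_z_um) <= event.axial_span_um / 2.0
    t, ri, ro = event.thickness_um, spec.inner_radius_um, spec.outer_radius_um
    if event.surface == "periosteal":
        radial = (r > ro) & (r <= ro + t) if event.kind == "formation" \
            else (r >= ro - t) & (r <= ro)
    else:
        radial = (r >= ri - t) & (r < ri) if event.kind == "formation" \
            else (r >= ri) & (r <= ri + t)
    return in_angle & in_axis & radial


def _validate_event(event: RemodelingEvent, spec: PhantomSpec) -> None:
    vs = spec.voxel_size_um
    nz = spec.grid_shape[0]
    z_lo = event.centroid_z_um - event.axial_span_um / 2.0
    z_hi = event.centroid_z_um + event.axial_span_um / 2.0
    if z_lo < 0 or z_hi > (nz - 1) * vs:
        raise ValueError(f"event footprint leaves the grid axially: {event}")
    if event.interval_index < 0 or event.interval_index >= spec.n_timepoints - 1:
        raise ValueError(f"event interval {event.interval_index} has no scan pair")
    wall = (spec.outer_radius_um - spec.inner_radius_um) \
        * (1 - spec.ellipticity)
    if event.kind == "resorption" and event.thickness_um >= wall:
        raise ValueError("resorption depth must be smaller than the cortical "
                         f"thickness ({wall} um): {event}")
    if event.surface == "periosteal" and event.kind == "formation":
        half_extent = (min(spec.grid_shape[1:]) - 1) / 2.0 * vs
        if (spec.outer_radius_um + event.thickness_um) \
                * (1 + spec.ellipticity) + spec.bow_amplitude_um \
                + 3 * vs > half_extent:
            raise ValueError(f"formation patch leaves the grid radially: {event}")


def _check_in_frame(transform: RigidTransform, mask: np.ndarray,
                    voxel_size_um: float) -> None:
    """Reject misalignments that move the rendered shell laterally out of
    frame.  Axial shifts only scroll the imaged section of the (much
    longer) diaphysis and are allowed; they truncate the end slices the
    way a shifted scan region does."""
    if not mask.any():
        return
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    corners_zyx = np.array(np.meshgrid(*zip(lo, hi), indexing="ij"),
                           dtype=float).reshape(3, -1).T
    corners_xyz = corners_zyx[:, ::-1] * voxel_size_um
    moved = transform.inverse().apply(corners_xyz)[:, :2]   # x, y only
    limits = (np.array(mask.shape[::-1], dtype=float)[:2] - 1) * voxel_size_um
    if (moved < -0.5 * voxel_size_um).any() or \
            (moved > limits + 0.5 * voxel_size_um).any():
        raise ValueError("misalignment moves the shell out of frame")


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def apply_acquisition(clean_mask: np.ndarray, blur_sigma_um: float,
                      noise_sd: float, bone_grey: float,
                      background_grey: float,
                      transform: RigidTransform, seed,
                      voxel_size_um: float = 10.5) -> ImageVolume:
    """Render a binary mask through the acquisition chain.

    Rigid transform (linear resampling; ``out(x) = clean(T(x))``), then
    Gaussian blur of ``blur_sigma_um``, then additive Gaussian grey noise.
    With zero blur and noise and an identity transform, thresholding at the
    grey midpoint recovers the mask exactly; integer-voxel translations
    are likewise exact under linear interpolation.
    """
    clean_mask = np.asarray(clean_mask, dtype=bool)
    if not clean_mask.any():
        raise ValueError("clean_mask is empty")
    grey = np.where(clean_mask, float(bone_grey), float(background_grey)) \
        .astype(np.float32)

    R, b = transform.affine()
    if not (np.allclose(R, np.eye(3), atol=1e-12)
            and np.allclose(b, 0.0, atol=1e-12)):
        M, off = transform.index_affine(voxel_size_um)
        grey = ndimage.affine_transform(grey, M, offset=off, order=1,
                                        mode="constant",
                                        cval=float(background_grey),
                                        output=np.float32)
    if blur_sigma_um > 0:
        grey = ndimage.gaussian_filter(grey, blur_sigma_um / voxel_size_um)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grey = grey + rng.normal(0.0, noise_sd, size=grey.shape) \
            .astype(np.float32)
    return ImageVolume(grey, voxel_size_um)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec
                     ) -> tuple[list[ImageVolume], PhantomGroundTruth]:
    """Generate a longitudinal phantom series with its ground truth.

    Deterministic for a given spec and seed, byte for byte.
    """
    spec.validate()
    for event in spec.event_list:
        _validate_event(event, spec)
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_um
    nz = spec.grid_shape[0]

    r, theta, zmap = _cylindrical_coords(spec)
    shell = (r >= spec.inner_radius_um) & (r <= spec.outer_radius_um)

    # intracortical vessel channels: radial tunnels through the wall
    for _ in range(spec.vessel_count):
        ang = rng.uniform(-180.0, 180.0)
        zc = rng.uniform(0.25, 0.75) * (nz - 1) * vs
        u = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
        # perpendicular distance to the radial ray at angle ang, height zc
        dx = r * np.cos(np.radians(theta))
        dy = r * np.sin(np.radians(theta))
        along = dx * u[0] + dy * u[1]
        perp2 = (dx - along * u[0]) ** 2 + (dy - along * u[1]) ** 2 \
            + (zmap - zc) ** 2
        tunnel = (perp2 <= spec.vessel_radius_um ** 2) & (along > 0)
        shell = shell & ~tunnel

    # loose mineralised spicules floating in the canal
    spicules = np.zeros(spec.grid_shape, dtype=bool)
    max_rc = (spec.inner_radius_um - spec.spicule_radius_um - 2 * vs) \
        * (1 - spec.ellipticity)
    for _ in range(spec.spicule_count):
        if max_rc <= 0:
            break
        ang = rng.uniform(-180.0, 180.0)
        rc = rng.uniform(0.0, max_rc)
        zc = rng.uniform(0.15, 0.85) * (nz - 1) * vs
        dx = r * np.cos(np.radians(theta)) - rc * np.cos(np.radians(ang))
        dy = r * np.sin(np.radians(theta)) - rc * np.sin(np.radians(ang))
        d2 = dx ** 2 + dy ** 2 + (zmap - zc) ** 2
        spicules |= d2 <= spec.spicule_radius_um ** 2

    # evolve the bone mask through the scripted events
    bone = [shell]
    true_formed: dict[tuple[int, str], np.ndarray] = {}
    true_resorbed: dict[tuple[int, str], np.ndarray] = {}
    for i in range(spec.n_timepoints - 1):
        current = bone[-1]
        formed_all = np.zeros(spec.grid_shape, dtype=bool)
        resorbed_all = np.zeros(spec.grid_shape, dtype=bool)
        for surface in SURFACES:
            formed_s = np.zeros(spec.grid_shape, dtype=bool)
            resorbed_s = np.zeros(spec.grid_shape, dtype=bool)
            for event in spec.event_list:
                if event.interval_index != i or event.surface != surface:
                    continue
                patch = _event_mask(event, spec, r, theta, zmap)
                if event.kind == "formation":
                    formed_s |= patch & ~current
                else:
                    resorbed_s |= patch & current
            true_formed[(i, surface)] = formed_s
            true_resorbed[(i, surface)] = resorbed_s
            formed_all |= formed_s
            resorbed_all |= resorbed_s
        bone.append((current & ~resorbed_all) | formed_all)

    volumes = []
    for t, misalignment in enumerate(spec.misalignment_per_timepoint):
        _check_in_frame(misalignment, bone[t] | spicules, vs)
        volumes.append(apply_acquisition(
            bone[t] | spicules, spec.blur_sigma_um, spec.noise_sd,
            spec.bone_grey, spec.background_grey, misalignment,
            seed=np.random.SeedSequence([spec.seed, 1000 + t]),
            voxel_size_um=vs))

    truth = PhantomGroundTruth(
        true_bone_masks=bone,
        true_formed=true_formed,
        true_resorbed=true_resorbed,
        true_transforms=[m.inverse() for m in spec.misalignment_per_timepoint],
        spicule_mask=spicules,
        radius_map_um=r.astype(np.float32),
        mid_radius_um=(spec.inner_radius_um + spec.outer_radius_um) / 2.0,
        voxel_size_um=vs,
    )
    return volumes, truth


# ---------------------------------------------------------------------------
# ground-truth morphometry (the recovery target)
# ---------------------------------------------------------------------------

def ground_truth_morphometry(truth: PhantomGroundTruth, interval_days: float,
                             t1_index: int | None = None
                             ) -> dict[str, MorphometryRecord]:
    """Morphometric truth by direct voxel counting on the noise-free masks.

    Applies the same definitions as the measurement pipeline (peeled masks,
    day-0 whole-cortex normalisation, 26-neighbour surface marking,
    inscribed-sphere package thickness) to the exact truth masks, giving
    the target values a noisy measurement should recover.
    """
    from .remodeling import label_packages
    from .remodeling import RemodelingMap

    if t1_index is None:
        t1_index = len(truth.true_bone_masks) - 1
    vs = truth.voxel_size_um
    m0, m1 = truth.true_bone_masks[0], truth.true_bone_masks[t1_index]
    m0p, m1p = peel_surface_layer(m0), peel_surface_layer(m1)
    formed = m1p & ~m0p
    resorbed = m0p & ~m1p
    bv0 = int(m0.sum())

    near_bg = ndimage.binary_dilation(~m0p, structure=_STRUCT6)
    surf0 = m0p & near_bg

    records = {}
    for surface in SURFACES:
        formed_s = truth.region_mask(formed, surface)
        resorbed_s = truth.region_mask(resorbed, surface)
        surf_s = truth.region_mask(surf0, surface)
        mv = 100.0 * int(formed_s.sum()) / bv0
        ev = 100.0 * int(resorbed_s.sum()) / bv0

        def frac(ev_mask):
            if not ev_mask.any():
                return 0.0
            grown = ndimage.binary_dilation(ev_mask, structure=_STRUCT26)
            return 100.0 * int((surf_s & grown).sum()) / int(surf_s.sum())

        # package thickness via a throwaway remodeling map
        state = np.zeros(m0.shape, dtype=np.uint8)
        state[formed_s] = 2
        state[resorbed_s] = 3
        region_code = 1 if surface == "endocortical" else 2
        region_arr = np.where(state > 0, region_code, 0).astype(np.uint8)
        rmap = RemodelingMap(state=state, region=region_arr, voxel_size_um=vs,
                             interval_days=(0.0, interval_days))
        mth = thickness_stats(label_packages(rmap, "formed", surface))
        ed = thickness_stats(label_packages(rmap, "resorbed", surface))

        ct_bv, ct_ar, ct_th = static_morphometry(m0, vs)
        rec = MorphometryRecord(
            region=surface, t_start_day=0.0, t_end_day=interval_days,
            Ct_BV_um3=ct_bv, Ct_Ar_um2=ct_ar, Ct_Th_um=ct_th,
            MV_BV_pct=mv, EV_BV_pct=ev,
            MS_BS_pct=frac(formed_s), ES_BS_pct=frac(resorbed_s),
            MTh_um=mth.value_um, ED_um=ed.value_um,
            day0_BV_um3=bv0 * vs ** 3,
            no_formation=mth.empty, no_resorption=ed.empty)
        records[surface] = rates(rec, interval_days)
    return records
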