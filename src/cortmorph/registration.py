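"""Rigid registration of follow-up scans onto the day-0 reference.

All later time points of one bone are brought into the coordinate system of
the first (reference) scan:

1. fibula/debris removal so only the main bone drives the alignment,
2. pre-alignment by superimposing intensity centres of gravity and, where
   well conditioned, the principal axes of the second-moment tensor,
3. refinement of the six rigid parameters by maximising normalised mutual
   information (Studholme formulation, 64-bin joint histogram) with a
   3-level multi-resolution Powell search,
4. a final Lanczos (windowed-sinc, a = 3) resampling onto the reference
   grid, and an axial crop to the analysis region of interest.

Transform convention (ITK-style): a transform maps points from the
reference (fixed) space into the moving space, so
``resample(moving, T)(x) = moving(T(x))``.  Physical coordinates are
``(x, y, z)`` in micrometres, see :mod:`cortmorph.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .io import ImageVolume

@dataclass(frozen=True)
class RigidTransform:
    """Rigid 3D transform: extrinsic Euler rotation about the grid axes
    followed by a translation, both about/relative to ``center_um``.

    ``T(p) = R (p - c) + c + t`` with ``R = Rz Ry Rx`` (extrinsic x-y-z
    Euler angles in degrees), ``t`` in micrometres.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(R, b)`` with ``T(p) = R p + b``."""
        R = self.rotation_matrix()
        c = np.asarray(self.center_um, dtype=float)
        t = np.asarray(self.translation_um, dtype=float)
        return R, c + t - R @ c

    def apply(self, points_xyz_um: np.ndarray) -> np.ndarray:
        R, b = self.affine()
        pts = np.atleast_2d(np.asarray(points_xyz_um, dtype=float))
        out = pts @ R.T + b
        return out[0] if np.asarray(points_xyz_um).ndim == 1 else out

    @staticmethod
    def from_affine(R: np.ndarray, b: np.ndarray,
                    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
                    ) -> "RigidTransform":
        c = np.asarray(center_um, dtype=float)
        t = np.asarray(b, dtype=float) - c + R @ c
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        return RigidTransform(tuple(angles), tuple(t), tuple(c))

    def recenter(self, center_um) -> "RigidTransform":
        """Same mapping expressed about a different rotation centre."""
        R, b = self.affine()
        return RigidTransform.from_affine(R, b, tuple(np.asarray(center_um, float)))

    def inverse(self) -> "RigidTransform":
        R, b = self.affine()
        Rinv = R.T
        return RigidTransform.from_affine(Rinv, -Rinv @ b, self.center_um)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the transform ``p -> self(inner(p))``."""
        Ro, bo = self.affine()
        Ri, bi = inner.affine()
        return RigidTransform.from_affine(Ro @ Ri, Ro @ bi + bo, self.center_um)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation as a single axis-angle in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation_matrix()).magnitude()))

    def index_affine(self, voxel_size_um: float) -> tuple[np.ndarray, np.ndarray]:
        """The transform in ``(z, y, x)`` index space, for scipy resampling."""
        R, b = self.affine()
        M = R[::-1, ::-1]
        off = b[::-1] / voxel_size_um
        return M, off


def transform_difference(a: RigidTransform, b: RigidTransform,
                         center_um=(0.0, 0.0, 0.0)) -> tuple[float, float]:
    """Residual between two transforms: (max |Δt| component in um about the
    given centre, rotation angle of the relative rotation in degrees)."""
    d = a.compose(b.inverse()).recenter(center_um)
    trans_err = float(np.max(np.abs(d.translation_um)))
    return trans_err, d.rotation_angle_deg()


def save_transform(transform: RigidTransform, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# rigid transform: angles in degrees, translation/center in um\n")
        fh.write("rotation_deg = %r\n" % (tuple(transform.rotation_deg),))
        fh.write("translation_um = %r\n" % (tuple(transform.translation_um),))
        fh.write("center_um = %r\n" % (tuple(transform.center_um),))


def load_transform(path: str) -> RigidTransform:
    values: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = tuple(float(x) for x in
                                        val.strip().strip("()").split(","))
    return RigidTransform(values["rotation_deg"], values["translation_um"],
                          values["center_um"])


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool
    iterations: int
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# bone isolation and pre-alignment
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def isolate_main_bone(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component (removes the fibula
    analogue and loose debris).  Ties are broken toward the component whose
    first voxel (in flat z-y-x scan order) comes first."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no bone present")
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # deterministic tie-break: smallest minimal flat voxel index
        flat = labels.ravel()
        first = [np.argmax(flat == lab) for lab in best]
        best = [best[int(np.argmin(first))]]
    return labels == best[0]


def _weighted_moments(volume: ImageVolume) -> tuple[np.ndarray, np.ndarray, float]:
    """Intensity-weighted centre of gravity (x, y, z um) and second-moment
    tensor.  Weights are grey values above the volume median (the median
    sits in the background for a bone-in-air/marrow scan)."""
    grey = np.asarray(volume.data, dtype=float)
    w = np.clip(grey - np.median(grey), 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("volume is empty after background suppression")
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in grey.shape), indexing="ij")
    coords = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3) * volume.voxel_size_um
    wf = w.ravel()
    cog = (coords * wf[:, None]).sum(axis=0) / total
    d = coords - cog
    cov = (d * wf[:, None]).T @ d / total
    return cog, cov, total


def _principal_axes(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs[:, -1] *= -1
    return vals, vecs


def prealign(moving: ImageVolume, reference: ImageVolume,
             degeneracy_rtol: float = 0.1,
             return_info: bool = False):
    """Initial transform superimposing intensity centres of gravity and,
    when the moment tensor is non-degenerate, aligning principal axes.

    With two eigenvalues equal within ``degeneracy_rtol`` (relative to the
    largest) the rotation is ill-determined and a translation-only
    transform is returned, reported via ``info['rotation_used']``.
    """
    cog_m, cov_m, _ = _weighted_moments(moving)
    cog_r, cov_r, _ = _weighted_moments(reference)
    vals_m, vecs_m = _principal_axes(cov_m)
    vals_r, vecs_r = _principal_axes(cov_r)

    scale = max(vals_r.max(), vals_m.max())
    degenerate = bool(
        np.min(np.abs(np.diff(vals_r))) < degeneracy_rtol * scale
        or np.min(np.abs(np.diff(vals_m))) < degeneracy_rtol * scale
    )
    if degenerate:
        R = np.eye(3)
    else:
        # sign-fixed axis matching, choosing the proper rotation of
        # smallest angle among the four det=+1 sign combinations
        best_R, best_angle = None, np.inf
        for signs in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
            R_try = vecs_m @ np.diag(signs) @ vecs_r.T
            angle = Rotation.from_matrix(R_try).magnitude()
            if angle < best_angle:
                best_R, best_angle = R_try, angle
        R = best_R
    # T(cog_r) must equal cog_m
    transform = RigidTransform.from_affine(R, cog_m - R @ cog_r, tuple(cog_r))
    info = {"rotation_used": not degenerate,
            "eigenvalues_reference": vals_r, "eigenvalues_moving": vals_m}
    if return_info:
        return transform, info
    return transform


# ---------------------------------------------------------------------------
# normalised mutual information and the rigid refinement
# ---------------------------------------------------------------------------

def normalized_mutual_information(a: np.ndarray, b: np.ndarray,
                                  bins: int = 64) -> float:
    """Studholme NMI, ``(H(A) + H(B)) / H(A, B)``, in [1, 2]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))
    hxy = entropy(p.ravel())
    if hxy == 0:
        return 2.0
    return float((entropy(px) + entropy(py)) / hxy)


def _resample_linear(moving: np.ndarray, transform: RigidTransform,
                     voxel_size_um: float, cval: float) -> np.ndarray:
    M, off = transform.index_affine(voxel_size_um)
    return ndimage.affine_transform(moving, M, offset=off, order=1,
                                    mode="constant", cval=cval,
                                    output=np.float32)


def _pyramid_level(grey: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(grey, dtype=np.float32)
    smoothed = ndimage.gaussian_filter(np.asarray(grey, dtype=np.float32),
                                       factor / 2.0)
    return smoothed[::factor, ::factor, ::factor]


def _metric_mask(reference_level: np.ndarray) -> np.ndarray:
    """Histogram support: a dilated bright-structure mask of the reference.

    Restricting the joint histogram to the neighbourhood of the bone makes
    the NMI peak far sharper than evaluating it over the (background-
    dominated) full volume.  Falls back to the full volume when the bright
    structure is tiny.
    """
    lo, hi = np.median(reference_level), reference_level.max()
    bright = reference_level > lo + 0.4 * (hi - lo)
    if bright.sum() < 500:
        return np.ones(reference_level.shape, dtype=bool)
    return ndimage.binary_dilation(bright, iterations=3)


def register_rigid_nmi(moving: ImageVolume, reference: ImageVolume,
                       init: RigidTransform | None = None,
                       levels: tuple[int, ...] = (4, 2, 1),
                       bins: int = 64,
                       metric_smooth_vox: float = 1.0,
                       max_fev_per_level: tuple[int, ...] = (600, 400, 400),
                       axial_exclude_vox: float = 6.0,
                       tolerance: float = 1e-4) -> RegistrationResult:
    """Refine a rigid transform by maximising NMI between the resampled
    moving volume and the reference.

    Powell's method over the six rigid parameters (degrees / voxels) on a
    coarse-to-fine pyramid.  Both volumes are smoothed by
    ``metric_smooth_vox`` for the metric evaluation: unfiltered per-scan
    noise produces the classic interpolation ripple in the NMI landscape
    (local extrema at integer voxel offsets), which the smoothing removes;
    the histogram is evaluated on a dilated bone mask of the reference,
    with ``axial_exclude_vox`` slices dropped from each z end (axially
    shifted scans are truncated at the end faces, which otherwise biases
    the axial estimate toward zero).
    The returned transform never scores a lower full-resolution NMI than
    ``init`` (minus ``tolerance``); if the evaluation budget is exhausted
    the best-so-far transform is returned with ``converged=False``.
    """
    if init is None:
        init = RigidTransform.identity()
    vs = reference.voxel_size_um
    center = reference.physical_center_um()
    init_c = init.recenter(center)

    mov = np.asarray(moving.data, dtype=np.float32)
    ref = np.asarray(reference.data, dtype=np.float32)
    if metric_smooth_vox > 0:
        mov = ndimage.gaussian_filter(mov, metric_smooth_vox)
        ref = ndimage.gaussian_filter(ref, metric_smooth_vox)
    cval = float(np.median(mov))

    total_fev = 0
    converged = True
    x = np.concatenate([np.asarray(init_c.rotation_deg, float),
                        np.asarray(init_c.translation_um, float) / vs])
    for factor, max_fev in zip(levels, max_fev_per_level):
        mov_l = _pyramid_level(mov, factor)
        ref_l = _pyramid_level(ref, factor)
        vs_l = vs * factor
        mask_l = _metric_mask(ref_l)
        edge = int(np.ceil(axial_exclude_vox / factor))
        if edge and 2 * edge < mask_l.shape[0]:
            mask_l[:edge] = False
            mask_l[-edge:] = False
        # resample only the mask's bounding box: the metric ignores the
        # rest of the grid, and the crop cuts the per-evaluation cost
        bbox = ndimage.find_objects(mask_l.astype(np.int8))[0]
        lo = np.array([s.start for s in bbox], dtype=float)
        shape_b = tuple(s.stop - s.start for s in bbox)
        mask_b = mask_l[bbox]
        ref_m = ref_l[bbox][mask_b]

        def neg_nmi(params):
            t = RigidTransform(tuple(params[:3]), tuple(np.asarray(params[3:]) * vs),
                               tuple(center))
            M, off = t.index_affine(vs_l)
            res = ndimage.affine_transform(
                mov_l, M, offset=M @ lo + off, output_shape=shape_b,
                order=1, mode="constant", cval=cval, output=np.float32)
            return -normalized_mutual_information(res[mask_b], ref_m, bins=bins)

        out = optimize.minimize(
            neg_nmi, x, method="Powell",
            options={"xtol": 0.02 * factor, "ftol": 1e-7,
                     "maxiter": 20, "maxfev": max_fev})
        total_fev += int(out.nfev)
        if not out.success and "function evaluations" in str(out.message):
            converged = False
        x = np.asarray(out.x, dtype=float)

    final = RigidTransform(tuple(x[:3]), tuple(x[3:] * vs), tuple(center))
    mask = _metric_mask(ref)
    nmi_final = normalized_mutual_information(
        _resample_linear(mov, final, vs, cval)[mask], ref[mask], bins=bins)
    nmi_init = normalized_mutual_information(
        _resample_linear(mov, init_c, vs, cval)[mask], ref[mask], bins=bins)
    if nmi_final < nmi_init - tolerance:
        final, nmi_final = init_c, nmi_init  # guard: never worse than init
    return RegistrationResult(transform=final, final_metric=nmi_final,
                              converged=converged, iterations=total_fev,
                              info={"nmi_init": nmi_init})


# ---------------------------------------------------------------------------
# final resampling and ROI crop
# ---------------------------------------------------------------------------

def resample(moving: ImageVolume, transform: RigidTransform,
             reference_grid: ImageVolume,
             background_grey: float | None = None) -> ImageVolume:
    """Resample ``moving`` onto the reference grid with a Lanczos
    windowed-sinc kernel (a = 3).  Voxels mapped outside the moving domain
    are filled with ``background_grey`` (default: the moving volume's
    median grey, i.e. background)."""
    import SimpleITK as sitk

    if background_grey is None:
        background_grey = float(np.median(moving.data))
    mov = sitk.GetImageFromArray(np.asarray(moving.data, dtype=np.float64))
    mov.SetSpacing((moving.voxel_size_um,) * 3)
    ref = sitk.GetImageFromArray(np.zeros(reference_grid.shape, dtype=np.float64))
    ref.SetSpacing((reference_grid.voxel_size_um,) * 3)

    R, _ = transform.affine()
    t = sitk.AffineTransform(3)
    t.SetMatrix(tuple(R.ravel()))
    t.SetCenter(tuple(np.asarray(transform.center_um, float)))
    t.SetTranslation(tuple(np.asarray(transform.translation_um, float)))
    out = sitk.Resample(mov, ref, t, sitk.sitkLanczosWindowedSinc,
                        background_grey)
    return ImageVolume(sitk.GetArrayFromImage(out), reference_grid.voxel_size_um)


def axial_roi_slices(n_slices_total: int, voxel_size_um: float,
                     tibia_length_um: float, fraction: float,
                     center_index: int | None = None) -> slice:
    """Slice range for an axial slab of ``round(fraction * length / voxel)``
    slices centred at ``center_index`` (default: the axial midpoint)."""
    n = int(round(fraction * tibia_length_um / voxel_size_um))
    if n < 1:
        raise ValueError("requested ROI is thinner than one slice")
    if center_index is None:
        center_index = n_slices_total // 2
    start = center_index - n // 2
    stop = start + n
    if start < 0 or stop > n_slices_total:
        raise ValueError(
            f"ROI slab [{start}, {stop}) exceeds the volume extent "
            f"(0, {n_slices_total})")
    return slice(start, stop)


def crop_axial_roi(volume: ImageVolume, tibia_length_um: float, fraction: float,
                   center_index: int | None = None) -> ImageVolume:
    """Crop an axial slab covering ``fraction`` of the tibia length.

    The same slice range (from :func:`axial_roi_slices`, computed once on
    the reference) must be applied to all time points of one bone.
    """
    sl = axial_roi_slices(volume.shape[0], volume.voxel_size_um,
                          tibia_length_um, fraction, center_index)
    return ImageVolume(volume.data[sl].copy(), volume.voxel_size_um)
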