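"""Image pre-processing: isotropic resampling, grey-matter-anchored
intensity normalisation to [-1, 1], lesion-centred patch extraction and
tri-planar (axial/coronal/sagittal) decomposition.

The chain applied to each timepoint is::

    resample_isotropic -> normalize_intensity -> crop_patch -> triplanar_slices

Conventions: arrays are (z, y, x), voxel indices are 0-based, physical
position = origin + index * spacing.  Normalised images anchor the
grey-matter reference intensity at 0 and scale symmetrically so the full
non-background range lies in [-1, 1]; background voxels (below an absolute
pre-normalisation threshold) are set to -1, which is also the padding
value for out-of-volume patch regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import Profile, desk_profile
from .synth import LongitudinalCase, Mask, Volume


@dataclass
class Patch:
    """A lesion-centred, normalised, fixed-shape subvolume for one timepoint."""

    values: np.ndarray          # (z, y, x), intensities in [-1, 1]
    mask: np.ndarray            # same shape, binary
    center_mm: tuple[float, float, float]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""
    timepoint: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.values.shape != self.mask.shape:
            raise ValueError("patch image and mask shapes differ")
        if self.values.min() < -1.0 - 1e-6 or self.values.max() > 1.0 + 1e-6:
            raise ValueError("patch intensities must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class TriplanarPatch:
    """Axial, coronal and sagittal slices of a patch on square canvases.

    ``planes`` is stacked (3, side, side) in the fixed order
    (axial, coronal, sagittal); non-square planes are centred on the
    canvas and padded with -1 (image) / 0 (mask).
    """

    planes: np.ndarray
    mask_planes: np.ndarray
    centroid_missing: bool = False

    def __post_init__(self):
        if self.planes.shape[0] != 3 or self.planes.shape[1] != self.planes.shape[2]:
            raise ValueError("planes must be (3, side, side)")


def resample_isotropic(
    volume: Volume, mask: Mask, target_spacing_mm: float = 0.5
) -> tuple[Volume, Mask]:
    """Resample an image/mask pair to isotropic spacing.

    The image is interpolated trilinearly, the mask with nearest-neighbour
    (then re-binarised).  Input already at the target spacing is returned
    unchanged (bit-exact copies).
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be strictly positive")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share one grid")
    if all(abs(s - target_spacing_mm) < 1e-12 for s in volume.spacing):
        return (
            Volume(volume.values.copy(), volume.spacing, volume.origin),
            Mask(mask.values.copy(), mask.spacing, mask.origin),
        )

    new_shape = tuple(
        max(1, int(round(n * s / target_spacing_mm)))
        for n, s in zip(volume.shape, volume.spacing)
    )
    # output voxel centre j sits at physical origin + j * target; its input
    # continuous index is j * target / input_spacing; edge-clamped sampling
    # keeps constant fields exactly constant at the borders
    grids = np.meshgrid(
        *[
            np.arange(n_out) * target_spacing_mm / s_in
            for n_out, s_in in zip(new_shape, volume.spacing)
        ],
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])

    def _res(arr, order):
        out = ndimage.map_coordinates(
            np.asarray(arr, dtype=np.float32), coords, order=order, mode="nearest"
        )
        return out.reshape(new_shape)

    tsp = (target_spacing_mm,) * 3
    ivals = _res(volume.values, 1)
    mvals = _res(mask.values, 0)
    return (
        Volume(ivals, tsp, volume.origin),
        Mask((mvals > 0.5).astype(np.uint8), tsp, mask.origin),
    )


def normalize_intensity(
    volume: Volume,
    gm_point: tuple[int, int, int],
    background_threshold: float = 0.0,
) -> Volume:
    """Normalise intensities to [-1, 1] anchored at a grey-matter point.

    Over non-background voxels the map is
    ``clip((I - I_gm) / max(I_max - I_gm, I_gm - I_min), -1, 1)`` with
    I_max/I_min the non-background extremes, so the grey-matter reference
    maps exactly to 0.  Background voxels (I <= threshold) are set to -1.
    """
    vals = volume.values
    gm_point = tuple(int(i) for i in gm_point)
    if any(not (0 <= g < n) for g, n in zip(gm_point, vals.shape)):
        raise ValueError(f"gm_point {gm_point} out of bounds for shape {vals.shape}")
    i_gm = float(vals[gm_point])
    if i_gm <= background_threshold:
        raise ValueError("gm_point lies in the background")
    fg = vals > background_threshold
    out = np.full_like(vals, -1.0, dtype=np.float32)
    fgv = vals[fg]
    denom = max(float(fgv.max()) - i_gm, i_gm - float(fgv.min()))
    if denom == 0.0:
        warnings.warn("constant foreground; normalized to all zeros", stacklevel=2)
        out[fg] = 0.0
    else:
        out[fg] = np.clip((fgv - i_gm) / denom, -1.0, 1.0)
    return Volume(out, volume.spacing, volume.origin)


def mask_centroid_vox(mask: np.ndarray) -> np.ndarray:
    """Voxel-rounded centroid of a non-empty binary mask."""
    idx = np.argwhere(mask > 0)
    if idx.size == 0:
        raise ValueError("empty mask has no centroid")
    return np.round(idx.mean(axis=0)).astype(int)


def crop_patch(
    volume: Volume,
    mask: Mask,
    shape: tuple[int, int, int] = (64, 96, 96),
    center_vox: tuple[int, int, int] | None = None,
    case_id: str = "",
    timepoint: int = 0,
) -> Patch:
    """Extract a fixed-shape patch centred on the lesion centroid.

    Out-of-volume regions are padded with -1 (image) and 0 (mask).  For an
    empty mask a ``center_vox`` must be supplied (taken from the most
    recent non-empty timepoint of the same case).
    """
    if center_vox is None:
        if mask.empty:
            raise ValueError("empty mask: supply center_vox from an earlier timepoint")
        center = mask_centroid_vox(mask.values)
    else:
        center = np.asarray(center_vox, dtype=int)
    shape = tuple(int(s) for s in shape)
    out_img = np.full(shape, -1.0, dtype=np.float32)
    out_msk = np.zeros(shape, dtype=np.uint8)
    starts = [c - s // 2 for c, s in zip(center, shape)]
    src, dst = [], []
    for st, s, n in zip(starts, shape, volume.shape):
        lo, hi = max(st, 0), min(st + s, n)
        if lo >= hi:
            raise ValueError("patch window lies entirely outside the volume")
        src.append(slice(lo, hi))
        dst.append(slice(lo - st, hi - st))
    out_img[tuple(dst)] = volume.values[tuple(src)]
    out_msk[tuple(dst)] = mask.values[tuple(src)]
    center_mm = tuple(
        float(o + c * sp)
        for o, c, sp in zip(volume.origin, center, volume.spacing)
    )
    return Patch(out_img, out_msk, center_mm, spacing=tuple(volume.spacing),
                 case_id=case_id, timepoint=timepoint)


def _center_on_canvas(plane: np.ndarray, side: int, pad_value: float) -> np.ndarray:
    canvas = np.full((side, side), pad_value, dtype=plane.dtype)
    r0 = (side - plane.shape[0]) // 2
    c0 = (side - plane.shape[1]) // 2
    canvas[r0 : r0 + plane.shape[0], c0 : c0 + plane.shape[1]] = plane
    return canvas


def triplanar_slices(patch: Patch) -> TriplanarPatch:
    """The three orthogonal planes through the in-patch mask centroid.

    Axial (y, x), coronal (z, x) and sagittal (z, y) slices are stacked in
    that fixed order on a square canvas of side max(patch.shape); an empty
    patch mask falls back to the geometric centre (flagged).
    """
    nz, ny, nx = patch.shape
    missing = not bool(patch.mask.any())
    if missing:
        cz, cy, cx = nz // 2, ny // 2, nx // 2
    else:
        cz, cy, cx = mask_centroid_vox(patch.mask)
        cz, cy, cx = (
            int(np.clip(cz, 0, nz - 1)),
            int(np.clip(cy, 0, ny - 1)),
            int(np.clip(cx, 0, nx - 1)),
        )
    side = max(patch.shape)
    img_planes = np.stack(
        [
            _center_on_canvas(patch.values[cz, :, :], side, -1.0),
            _center_on_canvas(patch.values[:, cy, :], side, -1.0),
            _center_on_canvas(patch.values[:, :, cx], side, -1.0),
        ]
    )
    msk_planes = np.stack(
        [
            _center_on_canvas(patch.mask[cz, :, :], side, 0),
            _center_on_canvas(patch.mask[:, cy, :], side, 0),
            _center_on_canvas(patch.mask[:, :, cx], side, 0),
        ]
    )
    return TriplanarPatch(img_planes, msk_planes, centroid_missing=missing)


# --------------------------------------------------------------------------
# per-case pipeline


@dataclass
class PreparedCase:
    """All per-timepoint tensors a downstream arm may consume."""

    case_id: str
    label: str
    y: int
    months: list[float]
    patches: list[Patch] = field(default_factory=list)
    triplanar: list[TriplanarPatch] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return len(self.patches)

    def triplanar_stack(self, k: int | None = None) -> np.ndarray:
        """(T, 3, side, side) image tensor for the first k timepoints."""
        tp = self.triplanar[: (k or len(self.triplanar))]
        return np.stack([t.planes for t in tp])

    def patch_stack(self, k: int | None = None) -> np.ndarray:
        """(T, 1, z, y, x) image tensor for the first k timepoints."""
        ps = self.patches[: (k or len(self.patches))]
        return np.stack([p.values[None] for p in ps])


def preprocess_case(
    case: LongitudinalCase,
    profile: Profile | None = None,
    background_threshold: float = 0.0,
) -> PreparedCase:
    """Run the full chain on every timepoint of one case.

    The grey-matter reference voxel is carried through resampling via its
    physical coordinate.  Vanished lesions at follow-up reuse the most
    recent non-empty centroid as the patch centre.
    """
    profile = profile or desk_profile()
    prepared = PreparedCase(
        case_id=case.case_id,
        label=case.label,
        y=case.y,
        months=[m for _, _, m in case.timepoints],
    )
    last_center: tuple[int, int, int] | None = None
    for t, (vol, mask, _) in enumerate(case.timepoints, start=1):
        rvol, rmask = resample_isotropic(vol, mask, profile.target_spacing_mm)
        scale = [s / t2 for s, t2 in zip(vol.spacing, rvol.spacing)]
        gm_r = tuple(
            int(np.clip(round(g * sc), 0, n - 1))
            for g, sc, n in zip(case.gm_point, scale, rvol.shape)
        )
        nvol = normalize_intensity(rvol, gm_r, background_threshold)
        if rmask.empty:
            if last_center is None:
                raise ValueError(f"timepoint {t}: empty mask with no prior centroid")
            center = last_center
        else:
            center = tuple(int(c) for c in mask_centroid_vox(rmask.values))
            last_center = center
        patch = crop_patch(
            nvol, rmask, profile.patch_shape, center_vox=center,
            case_id=case.case_id, timepoint=t,
        )
        prepared.patches.append(patch)
        prepared.triplanar.append(triplanar_slices(patch))
    return prepared
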