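"""Training-time geometric augmentation for patches and tri-planar stacks.

One parameter draw per sample: in-plane rotation (about the axial axis in
3D), isotropic scaling, horizontal flip and per-axis translation.  The
image is resampled trilinearly (padding with -1, the normalised
background level) and re-clipped to [-1, 1]; a paired mask gets the
identical transform with nearest-neighbour interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..config import TrainConfig


@dataclass(frozen=True)
class AugmentParams:
    angle_deg: float
    scale: float
    flip: bool
    shifts_px: tuple[float, ...]  # one entry per spatial axis

    @classmethod
    def identity(cls, ndim: int) -> "AugmentParams":
        return cls(0.0, 1.0, False, (0.0,) * ndim)


def sample_augment(rng: np.random.Generator, cfg: TrainConfig, ndim: int) -> AugmentParams:
    return AugmentParams(
        angle_deg=float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)),
        scale=float(rng.uniform(*cfg.scale_range)),
        flip=bool(rng.random() < cfg.flip_prob),
        shifts_px=tuple(
            float(rng.uniform(-cfg.translate_px, cfg.translate_px))
            for _ in range(ndim)
        ),
    )


def _forward_matrix(params: AugmentParams, ndim: int) -> np.ndarray:
    """Output = M (input - c) + c + t; rotation in the last two axes."""
    th = np.deg2rad(params.angle_deg)
    rot2 = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    m = np.eye(ndim)
    m[ndim - 2 :, ndim - 2 :] = rot2
    m = m * params.scale
    if params.flip:  # horizontal flip: negate the last (x) axis
        m[:, -1] *= -1.0
    return m


def apply_augment(
    image: np.ndarray,
    params: AugmentParams,
    mask: np.ndarray | None = None,
):
    """Transform a (C, *spatial) image (and optional mask) in place of shape.

    The same spatial transform is applied to every channel.  Returns the
    transformed image, or an (image, mask) pair when a mask is given.
    """
    ndim = image.ndim - 1
    spatial = image.shape[1:]
    m = _forward_matrix(params, ndim)
    minv = np.linalg.inv(m)
    c = (np.asarray(spatial, dtype=np.float64) - 1.0) / 2.0
    t = np.asarray(params.shifts_px, dtype=np.float64)
    offset = c - minv @ (c + t)

    def _tx(arr, order, cval):
        out = np.empty_like(arr)
        for ch in range(arr.shape[0]):
            out[ch] = ndimage.affine_transform(
                arr[ch], minv, offset=offset, order=order, cval=cval,
                mode="constant", prefilter=False,
            )
        return out

    img_out = np.clip(_tx(image.astype(np.float32), 1, -1.0), -1.0, 1.0)
    if mask is None:
        return img_out
    mask_out = _tx(mask.astype(np.float32), 0, 0.0).astype(np.uint8)
    return img_out, mask_out
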