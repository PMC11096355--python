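"""Eigen-CAM saliency for trained encoders.

The saliency map is the projection of the last convolutional activation
block onto its first principal component: spatial positions are flattened
into a positions x channels matrix, column means are subtracted, each
position is projected onto the first right singular vector, and the
absolute projection is min-max normalised to [0, 1] and upsampled to the
input patch resolution.  It is gradient-free, so it depends only on the
learned representation, not on a class score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class CamMap:
    """A saliency map aligned to an input patch, values in [0, 1]."""

    values: np.ndarray
    constant: bool = False  # all-constant activations yield an all-zero map
    case_id: str = ""
    timepoint: int = 0

    def __post_init__(self):
        if not self.constant:
            if self.values.min() < -1e-8 or self.values.max() > 1.0 + 1e-8:
                raise ValueError("CAM values must lie in [0, 1]")


def eigen_cam(
    activations: np.ndarray,
    output_shape: tuple[int, ...] | None = None,
) -> CamMap:
    """Eigen-CAM of one activation block of shape (channels, *spatial).

    ``output_shape`` linearly upsamples the map to the patch resolution.
    """
    act = np.asarray(activations, dtype=np.float64)
    if act.ndim < 2 or act.size == 0:
        raise ValueError("activations must be a non-empty (channels, *spatial) block")
    c = act.shape[0]
    spatial = act.shape[1:]
    a = act.reshape(c, -1).T  # positions x channels
    a = a - a.mean(axis=0, keepdims=True)
    if np.allclose(a, 0.0):
        out = np.zeros(output_shape or spatial)
        return CamMap(out, constant=True)
    # first right singular vector of the centred positions x channels matrix
    _, _, vt = np.linalg.svd(a, full_matrices=False)
    proj = np.abs(a @ vt[0]).reshape(spatial)
    lo, hi = proj.min(), proj.max()
    if hi - lo < 1e-15:
        out = np.zeros(output_shape or spatial)
        return CamMap(out, constant=True)
    cam = (proj - lo) / (hi - lo)
    if output_shape is not None and tuple(output_shape) != spatial:
        zoom = [o / s for o, s in zip(output_shape, spatial)]
        cam = ndimage.zoom(cam, zoom, order=1)
        lo, hi = cam.min(), cam.max()
        cam = (cam - lo) / (hi - lo) if hi > lo else cam * 0.0
    return CamMap(cam)


def cam_sequence(results, data, case_id: str, out_dir: str | Path | None = None) -> list[CamMap]:
    """Per-timepoint Eigen-CAM maps for one case under a trained model.

    ``results`` is a fitted :class:`~lesiontrack.models.NeuralResults`;
    maps are aligned to the model's input canvas (the axial tri-planar
    plane for 2D models, the 3D patch for 3D models).  With ``out_dir``,
    overlay PNGs are written per timepoint.
    """
    if getattr(results, "encoder", None) is None:
        raise ValueError("cam_sequence requires a fitted neural results object")
    case = next((c for c in data.cases if c.case_id == case_id), None)
    if case is None:
        raise KeyError(f"case {case_id!r} not in cohort")
    model = results.model
    maps = []
    for t in range(model.n_timepoints):
        x = model._tensor(case)[t : t + 1].astype(np.float32)
        results.encoder.forward(x, train=False, keep_activation=True)
        act = results.encoder.last_activation[0]
        target = x.shape[2:]
        cam = eigen_cam(act, output_shape=target)
        cam.case_id = case.case_id
        cam.timepoint = t + 1
        maps.append(cam)
    if out_dir is not None:
        _write_overlays(maps, case, model, Path(out_dir))
    return maps


def _write_overlays(maps, case, model, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    for t, cam in enumerate(maps):
        x = model._tensor(case)[t]
        if x.ndim == 3:  # (3, H, W) tri-planar: show the axial channel
            bg, fg = x[0], cam.values[0] if cam.values.ndim == 3 else cam.values
        else:  # (1, D, H, W): central axial slice
            mid = x.shape[1] // 2
            bg, fg = x[0, mid], cam.values[mid]
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(bg, cmap="gray", vmin=-1, vmax=1)
        ax.imshow(fg, cmap="jet", alpha=0.4, vmin=0, vmax=1)
        ax.set_axis_off()
        fig.savefig(out_dir / f"{case.case_id}_t{t + 1}_cam.png",
                    bbox_inches="tight", dpi=100)
        plt.close(fig)


def lesion_focus_fraction(maps: list[CamMap], mask_planes: list[np.ndarray]) -> float:
    """Fraction of timepoints whose mean in-lesion CAM exceeds the mean
    out-of-lesion CAM (a scalar 'focus' statistic for synthetic checks)."""
    hits, total = 0, 0
    for cam, mask in zip(maps, mask_planes):
        m = np.asarray(mask) > 0
        if not m.any() or m.all():
            continue
        v = cam.values if cam.values.shape == m.shape else cam.values[0]
        if v[m].mean() > v[~m].mean():
            hits += 1
        total += 1
    return hits / total if total else 0.0
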