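"""Synthetic longitudinal lesion cohorts with analytically known labels.

Each case is one rim-enhancing ellipsoidal lesion followed over four
timepoints (one pre-treatment scan and three follow-ups).  Non-progressive
lesions shrink monotonically after treatment and may vanish entirely;
progressive (PD) lesions shrink initially and then regrow past their
post-treatment nadir by at least 20% and 1 mm — the same longest-diameter
regrowth rule used clinically for brain metastases.  Because labels are
assigned from the generating diameter schedule, every downstream
classifier can be validated against ground truth that is exact by
construction.

Volumes are written/read as NIfTI pairs (image + binary mask per
timepoint) with a JSON sidecar carrying the label, acquisition offsets in
months and the grey-matter reference voxel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import CohortSpec

PD = "PD"
NON_PD = "non-PD"

# ellipsoid radial fraction beyond which the enhancing rim is rendered
_RIM_START = 0.70
# lesions below this equivalent diameter are treated as resolved (mask empty)
_VANISH_MM = 4.0
_GM_BLOB_RADIUS_VOX = 2.5


@dataclass
class Volume:
    """A 3D scalar grid in (z, y, x) axis order with physical metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("Volume.values must be 3D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume.values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class Mask:
    """Binary lesion mask sharing the grid of a :class:`Volume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("non-binary mask: values outside {0, 1}")
        self.values = arr.astype(np.uint8)
        if self.values.ndim != 3:
            raise ValueError("Mask.values must be 3D (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def empty(self) -> bool:
        return not bool(self.values.any())


@dataclass
class LongitudinalCase:
    """One lesion's ordered sequence of scans, masks and its response label."""

    case_id: str
    lesion_id: str
    timepoints: list[tuple[Volume, Mask, float]]  # (volume, mask, months)
    label: str  # PD | non-PD
    gm_point: tuple[int, int, int]  # voxel index of the grey-matter reference
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (1 <= len(self.timepoints) <= 4):
            raise ValueError("a case carries 1-4 timepoints")
        months = [m for _, _, m in self.timepoints]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("timepoints must be strictly increasing in months")
        if self.label not in (PD, NON_PD):
            raise ValueError(f"label must be {PD!r} or {NON_PD!r}")
        if self.timepoints[0][1].empty:
            raise ValueError("mask at timepoint 1 must be non-empty")
        for _, mask, _ in self.timepoints:
            if mask.values[self.gm_point] != 0:
                raise ValueError("gm_point must lie outside every lesion mask")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def y(self) -> int:
        return 1 if self.label == PD else 0


# --------------------------------------------------------------------------
# diameter trajectories


def _sample_schedule(
    spec: CohortSpec, label: str, rng: np.random.Generator
) -> list[float]:
    """Draw a 4-timepoint equivalent-diameter schedule in mm for one lesion."""
    lo, hi = spec.diameter_range_mm
    d1 = float(np.clip(rng.normal(spec.diameter_mean_mm, spec.diameter_sd_mm), lo, hi))
    shrink = lambda d: d * rng.uniform(0.35, 0.85)
    if label == NON_PD:
        d2, d3, d4 = shrink(d1), 0.0, 0.0
        d3 = d2 * rng.uniform(0.5, 1.0)
        d4 = d3 * rng.uniform(0.5, 1.0)
        sched = [d1, d2, d3, d4]
        return [0.0 if d < _VANISH_MM else d for d in sched]
    # PD: early response drawn either from a milder distribution
    # (signal_onset=2) or from the same distribution as non-PD
    # (signal_onset=3, no class signal before timepoint 3), then regrowth.
    if spec.signal_onset == 2:
        d2 = d1 * rng.uniform(0.55, 0.95)
        d3 = d2 * rng.uniform(1.05, 1.45)
    else:
        d2 = shrink(d1)
        d3 = d2 * rng.uniform(1.15, 1.60)
    d2 = max(d2, _VANISH_MM)  # PD nadir stays measurable
    d3 = max(d3, d2)
    d4 = d3 * rng.uniform(1.10, 1.50)
    # enforce the regrowth rule over the nadir (>=20% and >=1 mm) and fit
    nadir = d2
    d4 = max(d4, nadir * 1.25, nadir + 1.5)
    d4 = min(d4, hi)
    d3 = min(d3, d4)
    return [d1, d2, d3, d4]


# --------------------------------------------------------------------------
# rendering


def _render_timepoint(
    spec: CohortSpec,
    center_mm: np.ndarray,
    axis_ratios: np.ndarray,
    diameter_mm: float,
    gm_point: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[Volume, Mask]:
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm, dtype=np.float64)
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    img = np.full(shape, spec.background_intensity, dtype=np.float32)

    # grey-matter reference blob (uniform patch of gm intensity)
    gm_mm = np.asarray(gm_point) * spacing
    r2_gm = sum(((c - g) / (_GM_BLOB_RADIUS_VOX * s)) ** 2
                for c, g, s in zip(coords, gm_mm, spacing))
    img[r2_gm <= 1.0] = spec.gm_intensity

    if diameter_mm > 0:
        semi = axis_ratios * (diameter_mm / 2.0)  # (az, ay, ax) in mm
        r2 = sum(((c - cm) / a) ** 2 for c, cm, a in zip(coords, center_mm, semi))
        inside = r2 <= 1.0
        core = r2 <= _RIM_START**2
        img[inside] = spec.rim_intensity
        img[core] = spec.core_intensity
        mask_arr = inside.astype(np.uint8)
    else:
        mask_arr = np.zeros(shape, dtype=np.uint8)

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        # keep the grey-matter reference patch exactly at gm intensity
        noise[r2_gm <= 1.0] = 0.0
        img = img + noise

    sp = tuple(float(s) for s in spec.spacing_mm)
    return Volume(img, sp), Mask(mask_arr, sp)


def generate_case(
    spec: CohortSpec,
    label: str,
    seed: int,
    case_id: str = "case0000",
    lesion_id: str = "L1",
    schedule_mm: list[float] | None = None,
) -> LongitudinalCase:
    """Generate one 4-timepoint case with the requested response label.

    ``schedule_mm`` overrides the sampled diameter trajectory (used for
    controlled experiments); it is not validated against the label rule.
    """
    spec.validate()
    if label not in (PD, NON_PD):
        raise ValueError(f"label must be {PD!r} or {NON_PD!r}")
    rng = np.random.default_rng(seed)
    sched = list(schedule_mm) if schedule_mm is not None else _sample_schedule(spec, label, rng)
    if len(sched) != 4:
        raise ValueError("schedule_mm must have 4 entries")

    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    extent = shape * spacing
    d_max = max(sched)
    if d_max > min(extent[1], extent[2]):
        raise ValueError(
            f"requested diameter {d_max:.1f} mm exceeds grid extent {extent} mm"
        )

    # fixed lesion shape across timepoints: (az, ay, ax)/(d/2) ratios with
    # ax >= ay >= az so the equatorial axial section is the largest and its
    # in-plane extent equals the scheduled diameter
    ay = rng.uniform(0.75, 1.0)
    axis_ratios = np.array([rng.uniform(0.65, ay), ay, 1.0])
    # centre jittered around the grid centre but guaranteed to fit
    center = extent / 2.0
    margin = extent / 2.0 - axis_ratios * (d_max / 2.0) - 2.0 * spacing
    jitter = rng.uniform(-1.0, 1.0, size=3) * np.minimum(
        np.maximum(margin, 0.0), 0.08 * extent
    )
    center_mm = center + jitter
    if np.any(axis_ratios * d_max / 2.0 + 2.0 * spacing > extent / 2.0):
        raise ValueError(
            f"requested diameter {d_max:.1f} mm exceeds grid extent {extent} mm"
        )

    # grey-matter reference: corner region farthest from the lesion centre
    corner_off = 6
    corners = np.array(
        [[cz, cy, cx]
         for cz in (corner_off, shape[0] - 1 - corner_off)
         for cy in (corner_off, shape[1] - 1 - corner_off)
         for cx in (corner_off, shape[2] - 1 - corner_off)]
    )
    dists = np.linalg.norm(corners * spacing - center_mm, axis=1)
    gm_point = tuple(int(i) for i in corners[int(np.argmax(dists))])
    if dists.max() <= d_max / 2.0 + _GM_BLOB_RADIUS_VOX * spacing.max() + 1:
        raise ValueError("grid too small to place a grey-matter reference point")

    intervals = [
        max(1.0, rng.normal(2.6, 0.66)),
        max(1.0, rng.normal(2.8, 1.3)),
        max(1.0, rng.normal(2.9, 1.2)),
    ]
    months = [0.0] + list(np.cumsum(intervals))

    tps = []
    for d, m in zip(sched, months):
        vol, mask = _render_timepoint(spec, center_mm, axis_ratios, d, gm_point, rng)
        tps.append((vol, mask, float(m)))

    return LongitudinalCase(
        case_id=case_id,
        lesion_id=lesion_id,
        timepoints=tps,
        label=label,
        gm_point=gm_point,
        meta={"schedule_mm": sched, "center_mm": center_mm.tolist()},
    )


def generate_cohort(spec: CohortSpec) -> list[LongitudinalCase]:
    """Generate ``spec.n_cases`` cases with exact class balance.

    PD count = round(pd_fraction * n_cases); label order and per-case seeds
    are deterministic functions of ``spec.seed``.
    """
    spec.validate()
    labels = cohort_labels(spec)
    seeds = _case_seeds(spec)
    return [
        generate_case(spec, lab, int(s), case_id=f"case{i:04d}")
        for i, (lab, s) in enumerate(zip(labels, seeds))
    ]


def cohort_labels(spec: CohortSpec) -> list[str]:
    """Deterministic label sequence for a cohort (PD count by rounding)."""
    n_pd = int(round(spec.pd_fraction * spec.n_cases))
    labels = [PD] * n_pd + [NON_PD] * (spec.n_cases - n_pd)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    order = rng.permutation(spec.n_cases)
    return [labels[i] for i in order]


def _case_seeds(spec: CohortSpec) -> np.ndarray:
    ss = np.random.SeedSequence([spec.seed, 0xCA5E])
    return ss.generate_state(spec.n_cases) % (2**31)


def iter_cohort(spec: CohortSpec):
    """Yield cases one at a time (memory-friendly for large cohorts)."""
    spec.validate()
    labels = cohort_labels(spec)
    seeds = _case_seeds(spec)
    for i, (lab, s) in enumerate(zip(labels, seeds)):
        yield generate_case(spec, lab, int(s), case_id=f"case{i:04d}")


# --------------------------------------------------------------------------
# NIfTI round trip


def _affine(spacing, origin) -> np.ndarray:
    # arrays are (z, y, x); the on-disk grid keeps that axis order, with
    # per-axis scales on the diagonal and the origin in the translation
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def save_case(case: LongitudinalCase, out_dir: str | Path) -> Path:
    """Write one image+mask NIfTI pair per timepoint plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    months = []
    for t, (vol, mask, m) in enumerate(case.timepoints, start=1):
        nib.save(
            nib.Nifti1Image(vol.values, _affine(vol.spacing, vol.origin)),
            out / f"image_t{t}.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(mask.values, _affine(mask.spacing, mask.origin)),
            out / f"mask_t{t}.nii.gz",
        )
        months.append(m)
    sidecar = {
        "case_id": case.case_id,
        "lesion_id": case.lesion_id,
        "label": case.label,
        "months": months,
        "gm_point": list(case.gm_point),
        "meta": {k: v for k, v in case.meta.items() if k == "schedule_mm"},
    }
    (out / "case.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_case(case_dir: str | Path) -> LongitudinalCase:
    """Load a case written by :func:`save_case`.

    Timepoints listed out of order in the sidecar are re-sorted by months
    (with a warning); non-binary masks and image/mask shape mismatches are
    errors naming the offending timepoint.
    """
    d = Path(case_dir)
    sidecar = json.loads((d / "case.json").read_text())
    months = sidecar["months"]
    n = len(months)
    tps = []
    for t in range(1, n + 1):
        img_path = d / f"image_t{t}.nii.gz"
        mask_path = d / f"mask_t{t}.nii.gz"
        if not img_path.exists():
            raise FileNotFoundError(f"missing image file for timepoint {t}")
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask file for timepoint {t}")
        img = nib.load(str(img_path))
        msk = nib.load(str(mask_path))
        ivals = np.asarray(img.dataobj, dtype=np.float32)
        mvals = np.asarray(msk.dataobj)
        if ivals.shape != mvals.shape:
            raise ValueError(
                f"timepoint {t}: image shape {ivals.shape} != mask shape {mvals.shape}"
            )
        if not np.isin(np.unique(mvals), (0, 1)).all():
            raise ValueError(f"timepoint {t}: non-binary mask")
        spacing = tuple(float(s) for s in np.diag(img.affine)[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        tps.append(
            (Volume(ivals, spacing, origin), Mask(mvals, spacing, origin), float(months[t - 1]))
        )
    order = sorted(range(n), key=lambda i: tps[i][2])
    if order != list(range(n)):
        warnings.warn("sidecar months out of order; timepoints re-sorted", stacklevel=2)
        tps = [tps[i] for i in order]
    return LongitudinalCase(
        case_id=sidecar["case_id"],
        lesion_id=sidecar["lesion_id"],
        timepoints=tps,
        label=sidecar["label"],
        gm_point=tuple(sidecar["gm_point"]),
        meta=sidecar.get("meta", {}),
    )


def save_cohort(cases: list[LongitudinalCase], out_dir: str | Path) -> Path:
    """Save all cases plus a manifest CSV (case_id, lesion_id, label, path)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        cdir = save_case(case, out / case.case_id)
        rows.append(
            {"case_id": case.case_id, "lesion_id": case.lesion_id,
             "label": case.label, "path": str(cdir.relative_to(out))}
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def load_cohort(cohort_dir: str | Path) -> list[LongitudinalCase]:
    import pandas as pd

    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    return [load_case(root / p) for p in manifest["path"]]
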