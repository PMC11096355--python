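"""Handcrafted arms: maximum axial diameter (Dmax) and a frozen radiomics
feature set (first-order, shape, GLCM, GLRLM, GLSZM), with time-major
sequential concatenation and gradient-boosted-tree classification.

Conventions (fixed here because the clinical measurement leaves them
open):

* Dmax is measured on the axial slice with the largest lesion area (ties
  broken toward the lowest z); it is the maximum pairwise distance between
  boundary pixel centres plus one in-plane pixel pitch, so an isolated
  pixel has diameter = pixel size.  An empty (vanished) lesion has Dmax 0.
* Texture matrices use fixed-bin-width discretisation (default width 0.1
  in normalised intensity units), 13 unique 3D offsets at Chebyshev
  distance 1, and 26-connected zones.
* A vanished lesion yields an all-zero feature vector with a validity
  flag rather than a dropped timepoint, keeping sequence lengths fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

from .preprocess import Patch

DEFAULT_BIN_WIDTH = 0.1

FIRST_ORDER_NAMES = (
    "mean", "variance", "skewness", "kurtosis", "energy", "entropy",
    "min", "max", "p10", "p90", "median", "iqr",
)
SHAPE_NAMES = ("volume_mm3", "surface_mm2", "sphericity", "max_diameter_3d_mm", "elongation")
GLCM_NAMES = ("glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity", "glcm_entropy")
GLRLM_NAMES = ("glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp")
GLSZM_NAMES = ("glszm_sze", "glszm_lze", "glszm_zsn", "glszm_gln", "glszm_zp")
RADIOMICS_NAMES = FIRST_ORDER_NAMES + SHAPE_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES

# the 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair)
OFFSETS_13 = np.array(
    [
        (0, 0, 1), (0, 1, 0), (1, 0, 0),
        (0, 1, 1), (0, 1, -1),
        (1, 0, 1), (1, 0, -1),
        (1, 1, 0), (1, -1, 0),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ]
)


# --------------------------------------------------------------------------
# Dmax


def measure_dmax(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Maximum in-plane lesion diameter (mm) on the representative axial slice."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (z, y, x)")
    sy, sx = float(spacing[1]), float(spacing[2])
    if abs(sy - sx) > 1e-9:
        raise ValueError("anisotropic in-plane spacing; resample first")
    if not mask.any():
        return 0.0
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    z = int(np.argmax(areas))  # argmax takes the lowest index on ties
    sl = mask[z].astype(bool)
    boundary = sl & ~ndimage.binary_erosion(sl)
    pts = np.argwhere(boundary).astype(np.float64) * sy
    if len(pts) == 1:
        return sy
    return float(pdist(pts).max() + sy)


# --------------------------------------------------------------------------
# discretisation


@dataclass
class DiscretizedPatch:
    """Integer grey-level grid over the lesion (level 0 = outside mask)."""

    levels: np.ndarray  # int array, 0 outside mask, 1..n_levels inside
    n_levels: int
    bin_width: float

    @property
    def in_mask(self) -> np.ndarray:
        return self.levels > 0


def discretize(
    values: np.ndarray, mask: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> DiscretizedPatch:
    """Fixed-bin-width quantisation of in-mask intensities.

    Levels follow the fixed-width convention
    ``level = floor(I / w) - floor(I_min / w) + 1`` so bin edges sit on
    multiples of the width; a zero intensity range yields one level.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("cannot discretize an empty mask")
    vals = np.asarray(values, dtype=np.float64)
    inm = vals[mask]
    base = np.floor(inm.min() / bin_width)
    lv = np.zeros(vals.shape, dtype=np.int32)
    lv[mask] = (np.floor(vals[mask] / bin_width) - base).astype(np.int32) + 1
    n_levels = int(lv.max())
    return DiscretizedPatch(lv, n_levels, bin_width)


# --------------------------------------------------------------------------
# first-order


def first_order_features(
    values: np.ndarray, mask: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    """Twelve first-order statistics over in-mask voxels.

    Entropy is computed over the discretised histogram, in bits.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return np.zeros(len(FIRST_ORDER_NAMES))
    x = np.asarray(values, dtype=np.float64)[mask]
    n = x.size
    mu = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    skew = 0.0 if sd == 0 else float(np.mean((x - mu) ** 3) / sd**3)
    kurt = 0.0 if sd == 0 else float(np.mean((x - mu) ** 4) / sd**4)
    dp = discretize(values, mask, bin_width)
    counts = np.bincount(dp.levels[dp.in_mask])[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    p10, p90 = np.percentile(x, [10, 90])
    q25, q75 = np.percentile(x, [25, 75])
    return np.array(
        [
            mu, var, skew, kurt, float((x**2).sum()), entropy,
            x.min(), x.max(), p10, p90, float(np.median(x)), q75 - q25,
        ]
    )


# --------------------------------------------------------------------------
# shape


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Voxel-based shape descriptors (no meshing).

    volume = voxel count x voxel volume; surface = exposed-face area;
    sphericity = pi^(1/3) (6V)^(2/3) / A; max 3D diameter = largest
    voxel-centre pairwise distance; elongation = sqrt(l2/l1) of the
    physical coordinate covariance eigenvalues (1 = isotropic).
    """
    m = np.asarray(mask) > 0
    if not m.any():
        return np.zeros(len(SHAPE_NAMES))
    sp = np.asarray(spacing, dtype=np.float64)
    voxvol = float(np.prod(sp))
    count = int(m.sum())
    volume = count * voxvol

    face_areas = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
    surface = 0.0
    for ax, fa in enumerate(face_areas):
        pad = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = np.diff(pad.astype(np.int8), axis=ax)
        surface += float(np.abs(diff).sum()) * fa

    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface)

    pts = np.argwhere(m).astype(np.float64) * sp
    if len(pts) == 1:
        max_diam = 0.0
        elong = 1.0
    else:
        # pairwise max over boundary voxels is identical and far cheaper
        boundary = m & ~ndimage.binary_erosion(m)
        bpts = np.argwhere(boundary).astype(np.float64) * sp
        max_diam = float(pdist(bpts).max()) if len(bpts) > 1 else 0.0
        cov = np.cov(pts.T)
        ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        ev = np.clip(ev, 0.0, None)
        elong = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0
    return np.array([volume, surface, sphericity, max_diam, elong])


# --------------------------------------------------------------------------
# texture matrices


def glcm_matrix(dp: DiscretizedPatch) -> np.ndarray:
    """Symmetrised co-occurrence matrix averaged over the 13 offsets,
    normalised to sum 1 (uniform if no in-mask voxel pairs exist)."""
    ng = dp.n_levels
    lv = dp.levels
    acc = np.zeros((ng, ng), dtype=np.float64)
    n_off = 0
    for off in OFFSETS_13:
        a_sl, b_sl = [], []
        ok = True
        for o, n in zip(off, lv.shape):
            if abs(o) >= n:
                ok = False
                break
            if o >= 0:
                a_sl.append(slice(0, n - o))
                b_sl.append(slice(o, n))
            else:
                a_sl.append(slice(-o, n))
                b_sl.append(slice(0, n + o))
        if not ok:
            continue
        a = lv[tuple(a_sl)].ravel()
        b = lv[tuple(b_sl)].ravel()
        sel = (a > 0) & (b > 0)
        if sel.any():
            pair = np.bincount((a[sel] - 1) * ng + (b[sel] - 1), minlength=ng * ng)
            mat = pair.reshape(ng, ng).astype(np.float64)
            mat = mat + mat.T  # symmetrise
            if mat.sum() > 0:
                acc += mat / mat.sum()
        n_off += 1
    if acc.sum() == 0:
        return np.full((ng, ng), 1.0 / ng**2)
    return acc / acc.sum()


def glcm_features(dp: DiscretizedPatch) -> np.ndarray:
    """Contrast, correlation, energy (ASM), homogeneity (IDM), entropy."""
    p = glcm_matrix(dp)
    ng = p.shape[0]
    i, j = np.indices((ng, ng)) + 1
    contrast = float(((i - j) ** 2 * p).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 1e-12 and var_j > 1e-12:
        corr = float(((i - mu_i) * (j - mu_j) * p).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 0.0
    energy = float((p**2).sum())
    homog = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return np.array([contrast, corr, energy, homog, entropy])


def glrlm_matrix(dp: DiscretizedPatch) -> np.ndarray:
    """Run-length matrix (levels x run length) averaged over 13 directions."""
    lv = dp.levels
    ng = dp.n_levels
    max_len = int(np.ceil(np.linalg.norm(lv.shape))) + 1
    acc = np.zeros((ng, max_len), dtype=np.float64)
    inm = lv > 0
    for off in OFFSETS_13:
        same_next = _same_as_neighbour(lv, inm, off)          # lv[i] == lv[i+off]
        same_prev = _same_as_neighbour(lv, inm, -off)         # lv[i] == lv[i-off]
        run_len = _forward_run_length(same_next, off)
        starts = inm & ~same_prev
        g = lv[starts] - 1
        length = run_len[starts]
        mat = np.zeros((ng, max_len), dtype=np.float64)
        np.add.at(mat, (g, length - 1), 1.0)
        acc += mat
    acc /= len(OFFSETS_13)
    # trim trailing all-zero run-length columns (keep at least one)
    last = max(1, int(np.argwhere(acc.sum(axis=0) > 0).max()) + 1) if acc.any() else 1
    return acc[:, :last]


def _same_as_neighbour(lv: np.ndarray, inm: np.ndarray, off) -> np.ndarray:
    """Boolean grid: voxel in mask and neighbour at +off in mask with equal level."""
    out = np.zeros(lv.shape, dtype=bool)
    a_sl, b_sl = [], []
    for o, n in zip(off, lv.shape):
        if abs(o) >= n:
            return out
        if o >= 0:
            a_sl.append(slice(0, n - o))
            b_sl.append(slice(o, n))
        else:
            a_sl.append(slice(-o, n))
            b_sl.append(slice(0, n + o))
    a_sl, b_sl = tuple(a_sl), tuple(b_sl)
    out[a_sl] = inm[a_sl] & inm[b_sl] & (lv[a_sl] == lv[b_sl])
    return out


def _forward_run_length(same_next: np.ndarray, off) -> np.ndarray:
    """Length of the constant run extending from each voxel in +off direction.

    Iterative relaxation: each pass extends knowledge of the run tail by
    one step, so convergence takes at most max-run-length passes.
    """
    r = np.ones(same_next.shape, dtype=np.int32)
    while True:
        shifted = _shift(r, off)
        new = np.where(same_next, 1 + shifted, 1)
        if np.array_equal(new, r):
            return r
        r = new


def _shift(arr: np.ndarray, off) -> np.ndarray:
    """arr sampled at +off (zeros beyond the boundary)."""
    out = np.zeros_like(arr)
    a_sl, b_sl = [], []
    for o, n in zip(off, arr.shape):
        if abs(o) >= n:
            return out
        if o >= 0:
            a_sl.append(slice(0, n - o))
            b_sl.append(slice(o, n))
        else:
            a_sl.append(slice(-o, n))
            b_sl.append(slice(0, n + o))
    out[tuple(a_sl)] = arr[tuple(b_sl)]
    return out


def glrlm_features(dp: DiscretizedPatch) -> np.ndarray:
    """SRE, LRE, GLN, RLN, RP from the direction-averaged run-length matrix."""
    p = glrlm_matrix(dp)
    nr = p.sum()
    nvox = int((dp.levels > 0).sum())
    lengths = np.arange(1, p.shape[1] + 1, dtype=np.float64)
    sre = float((p / lengths**2).sum() / nr)
    lre = float((p * lengths**2).sum() / nr)
    gln = float((p.sum(axis=1) ** 2).sum() / nr)
    rln = float((p.sum(axis=0) ** 2).sum() / nr)
    rp = float(nr / nvox)
    return np.array([sre, lre, gln, rln, rp])


def glszm_matrix(dp: DiscretizedPatch) -> np.ndarray:
    """Size-zone matrix (levels x zone size) from 26-connected zones."""
    lv = dp.levels
    ng = dp.n_levels
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int((lv > 0).sum())
    acc = np.zeros((ng, max_size), dtype=np.float64)
    for g in range(1, ng + 1):
        sel = lv == g
        if not sel.any():
            continue
        labels, n_zones = ndimage.label(sel, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        np.add.at(acc, (g - 1, sizes - 1), 1.0)
    last = max(1, int(np.argwhere(acc.sum(axis=0) > 0).max()) + 1) if acc.any() else 1
    return acc[:, :last]


def glszm_features(dp: DiscretizedPatch) -> np.ndarray:
    """SZE, LZE, ZSN, GLN, ZP from the size-zone matrix."""
    p = glszm_matrix(dp)
    nz = p.sum()
    nvox = int((dp.levels > 0).sum())
    sizes = np.arange(1, p.shape[1] + 1, dtype=np.float64)
    sze = float((p / sizes**2).sum() / nz)
    lze = float((p * sizes**2).sum() / nz)
    zsn = float((p.sum(axis=0) ** 2).sum() / nz)
    gln = float((p.sum(axis=1) ** 2).sum() / nz)
    zp = float(nz / nvox)
    return np.array([sze, lze, zsn, gln, zp])


# --------------------------------------------------------------------------
# per-timepoint vectors and sequences


def _bbox(mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask > 0)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def radiomics_vector(
    patch: Patch,
    spacing: tuple[float, float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[np.ndarray, bool]:
    """The frozen radiomics vector for one timepoint.

    Returns ``(vector, valid)``; a vanished lesion yields zeros with
    ``valid=False``.  Texture matrices are computed on the lesion
    bounding box for speed (they only involve in-mask voxels).
    """
    if not patch.mask.any():
        return np.zeros(len(RADIOMICS_NAMES)), False
    fo = first_order_features(patch.values, patch.mask, bin_width)
    sh = shape_features(patch.mask, spacing)
    box = _bbox(patch.mask)
    dp = discretize(patch.values[box], patch.mask[box], bin_width)
    tex = np.concatenate([glcm_features(dp), glrlm_features(dp), glszm_features(dp)])
    return np.concatenate([fo, sh, tex]), True


@dataclass
class FeatureSequence:
    """Ordered per-timepoint feature vectors and their time-major flat form."""

    arm: str                      # dmax | radiomics | cnn
    per_timepoint: list[np.ndarray]
    feature_names: tuple[str, ...]
    valid: list[bool]
    case_id: str = ""
    y: int = 0

    def __post_init__(self):
        lens = {len(v) for v in self.per_timepoint}
        if len(lens) != 1:
            raise ValueError("per-timepoint vectors must share one length")
        if lens.pop() != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    @property
    def flat(self) -> np.ndarray:
        """All features of timepoint 1, then timepoint 2, ... (time-major)."""
        return np.concatenate(self.per_timepoint)

    @property
    def flat_names(self) -> list[str]:
        return [
            f"{name}_t{t}"
            for t in range(1, len(self.per_timepoint) + 1)
            for name in self.feature_names
        ]


def build_feature_sequence(prepared, arm: str, n_timepoints: int | None = None,
                           bin_width: float = DEFAULT_BIN_WIDTH) -> FeatureSequence:
    """Per-timepoint vectors for one :class:`~.preprocess.PreparedCase`.

    ``n_timepoints`` truncates to the first k scans (ablation support);
    the k-truncated flat vector is a prefix of the full one.
    """
    k = prepared.n_timepoints if n_timepoints is None else n_timepoints
    if k < 1:
        raise ValueError("at least one timepoint is required")
    if k > prepared.n_timepoints:
        raise ValueError(f"requested {k} timepoints, case has {prepared.n_timepoints}")
    if arm not in ("dmax", "radiomics"):
        raise ValueError("arm must be 'dmax' or 'radiomics'")
    per, valid = [], []
    for patch in prepared.patches[:k]:
        spacing = _patch_spacing(patch)
        if arm == "dmax":
            per.append(np.array([measure_dmax(patch.mask, spacing)]))
            valid.append(bool(patch.mask.any()))
        else:
            vec, ok = radiomics_vector(patch, spacing, bin_width)
            per.append(vec)
            valid.append(ok)
    names = ("dmax_mm",) if arm == "dmax" else RADIOMICS_NAMES
    return FeatureSequence(
        arm=arm, per_timepoint=per, feature_names=names, valid=valid,
        case_id=prepared.case_id, y=prepared.y,
    )


def _patch_spacing(patch: Patch) -> tuple[float, float, float]:
    return tuple(patch.spacing)


# --------------------------------------------------------------------------
# boosted-tree arm


def fit_gbt_arm(
    train_sequences: list[FeatureSequence],
    eval_sequences: list[FeatureSequence],
    seed: int = 0,
    max_depth: int = 3,
    n_estimators: int = 200,
    learning_rate: float = 0.1,
):
    """Train a gradient-boosted-tree classifier on flat feature vectors.

    Returns PD probabilities for the evaluation sequences.  Deterministic
    under a fixed seed; refuses single-class training labels.
    """
    from xgboost import XGBClassifier

    x_tr = np.stack([s.flat for s in train_sequences])
    y_tr = np.array([s.y for s in train_sequences])
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    x_ev = np.stack([s.flat for s in eval_sequences])
    if x_ev.shape[1] != x_tr.shape[1]:
        raise ValueError("train/eval flat feature lengths differ")
    clf = XGBClassifier(
        max_depth=max_depth,
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        objective="binary:logistic",
        random_state=int(seed) % (2**31),
        n_jobs=1,
        verbosity=0,
        eval_metric="logloss",
    )
    clf.fit(x_tr, y_tr)
    return clf.predict_proba(x_ev)[:, 1]
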