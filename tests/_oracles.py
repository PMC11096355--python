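"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops / direct
definitions, independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np

OFFSETS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


# --------------------------------------------------------------------------
# ROC


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pair enumeration, ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best (cutoff, sens, spec) by looping every candidate threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = sorted(set(scores))
    cands = [-np.inf] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])] + [np.inf]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for c in cands:
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= c)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < c)
        sens, spec = tp / n_pos, tn / n_neg
        j = sens + spec - 1
        if best is None or (j, spec, c) > (best[0], best[2], best[3]):
            best = (j, sens, spec, c)
    return best[3], best[1], best[2]


# --------------------------------------------------------------------------
# first-order / shape


def first_order_oracle(values, mask, bin_width=0.1):
    x = np.asarray(values, dtype=float)[np.asarray(mask) > 0]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = var**0.5
    skew = 0.0 if sd == 0 else sum((v - mu) ** 3 for v in x) / n / sd**3
    kurt = 0.0 if sd == 0 else sum((v - mu) ** 4 for v in x) / n / sd**4
    energy = sum(v**2 for v in x)
    levels = discretize_oracle(x, bin_width)
    counts = {}
    for l in levels:
        counts[l] = counts.get(l, 0) + 1
    entropy = -sum((c / n) * np.log2(c / n) for c in counts.values())
    p10, p90 = np.percentile(x, [10, 90])
    q25, q75 = np.percentile(x, [25, 75])
    return np.array([
        mu, var, skew, kurt, energy, entropy,
        min(x), max(x), p10, p90, float(np.median(x)), q75 - q25,
    ])


def discretize_oracle(values, bin_width):
    vals = [float(v) for v in values]  # bin in double precision throughout
    base = np.floor(min(vals) / bin_width)
    return [int(np.floor(v / bin_width) - base) + 1 for v in vals]


def shape_oracle(mask, spacing):
    m = np.asarray(mask) > 0
    sz, sy, sx = spacing
    vox = [(z, y, x) for z in range(m.shape[0])
           for y in range(m.shape[1]) for x in range(m.shape[2]) if m[z, y, x]]
    volume = len(vox) * sz * sy * sx
    face = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    surface = 0.0
    for z, y, x in vox:
        for ax, (dz, dy, dx) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
            for sgn in (1, -1):
                nz, ny, nx = z + sgn * dz, y + sgn * dy, x + sgn * dx
                outside = not (
                    0 <= nz < m.shape[0] and 0 <= ny < m.shape[1] and 0 <= nx < m.shape[2]
                ) or not m[nz, ny, nx]
                if outside:
                    surface += face[ax]
    sphericity = np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface
    pts = np.array(vox, dtype=float) * np.array(spacing)
    max_d = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            max_d = max(max_d, float(np.linalg.norm(pts[i] - pts[j])))
    if len(pts) > 1:
        ev = np.sort(np.linalg.eigvalsh(np.cov(pts.T)))[::-1]
        ev = np.clip(ev, 0, None)
        elong = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0
    else:
        elong = 1.0
    return np.array([volume, surface, sphericity, max_d, elong])


# --------------------------------------------------------------------------
# texture matrices (explicit voxel loops)


def glcm_oracle_matrix(levels, ng):
    lv = np.asarray(levels)
    acc = np.zeros((ng, ng))
    for off in OFFSETS_13:
        mat = np.zeros((ng, ng))
        it = np.ndindex(*lv.shape)
        for pos in it:
            a = lv[pos]
            if a == 0:
                continue
            nb = tuple(p + o for p, o in zip(pos, off))
            if all(0 <= q < s for q, s in zip(nb, lv.shape)) and lv[nb] > 0:
                b = lv[nb]
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
        if mat.sum() > 0:
            acc += mat / mat.sum()
    return acc / acc.sum() if acc.sum() else np.full((ng, ng), 1.0 / ng**2)


def glcm_oracle_features(levels, ng):
    p = glcm_oracle_matrix(levels, ng)
    contrast = corr_num = energy = homog = entropy = 0.0
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            contrast += (i - j) ** 2 * v
            corr_num += (i + 1 - mu_i) * (j + 1 - mu_j) * v
            energy += v**2
            homog += v / (1 + (i - j) ** 2)
            if v > 0:
                entropy -= v * np.log2(v)
    corr = corr_num / np.sqrt(var_i * var_j) if var_i > 1e-12 and var_j > 1e-12 else 0.0
    return np.array([contrast, corr, energy, homog, entropy])


def glrlm_oracle_matrix(levels, ng):
    """Run-length matrix averaged over 13 directions, by explicit walking."""
    lv = np.asarray(levels)
    runs_by_dir = []
    for off in OFFSETS_13:
        runs = []
        for pos in np.ndindex(*lv.shape):
            g = lv[pos]
            if g == 0:
                continue
            prev = tuple(p - o for p, o in zip(pos, off))
            inside = all(0 <= q < s for q, s in zip(prev, lv.shape))
            if inside and lv[prev] == g:
                continue  # not a run start
            length = 1
            cur = pos
            while True:
                nxt = tuple(p + o for p, o in zip(cur, off))
                if all(0 <= q < s for q, s in zip(nxt, lv.shape)) and lv[nxt] == g:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((g, length))
        runs_by_dir.append(runs)
    max_len = max((l for runs in runs_by_dir for _, l in runs), default=1)
    acc = np.zeros((ng, max_len))
    for runs in runs_by_dir:
        for g, l in runs:
            acc[g - 1, l - 1] += 1
    return acc / len(OFFSETS_13)


def glrlm_oracle_features(levels, ng):
    p = glrlm_oracle_matrix(levels, ng)
    nvox = int((np.asarray(levels) > 0).sum())
    nr = p.sum()
    sre = lre = 0.0
    for g in range(p.shape[0]):
        for l in range(p.shape[1]):
            sre += p[g, l] / (l + 1) ** 2
            lre += p[g, l] * (l + 1) ** 2
    gln = sum(p[g, :].sum() ** 2 for g in range(p.shape[0]))
    rln = sum(p[:, l].sum() ** 2 for l in range(p.shape[1]))
    return np.array([sre / nr, lre / nr, gln / nr, rln / nr, nr / nvox])


def glszm_oracle_features(levels, ng):
    """Size-zone features from 26-connected zones found by flood fill."""
    lv = np.asarray(levels)
    visited = np.zeros(lv.shape, dtype=bool)
    zones = []
    neigh = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for pos in np.ndindex(*lv.shape):
        if lv[pos] == 0 or visited[pos]:
            continue
        g = lv[pos]
        stack, size = [pos], 0
        visited[pos] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in neigh:
                nb = tuple(p + o for p, o in zip(cur, d))
                if (all(0 <= q < s for q, s in zip(nb, lv.shape))
                        and not visited[nb] and lv[nb] == g):
                    visited[nb] = True
                    stack.append(nb)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    p = np.zeros((ng, max_size))
    for g, s in zones:
        p[g - 1, s - 1] += 1
    nz = p.sum()
    nvox = int((lv > 0).sum())
    sze = sum(p[g, s] / (s + 1) ** 2 for g in range(ng) for s in range(max_size))
    lze = sum(p[g, s] * (s + 1) ** 2 for g in range(ng) for s in range(max_size))
    zsn = sum(p[:, s].sum() ** 2 for s in range(max_size))
    gln = sum(p[g, :].sum() ** 2 for g in range(ng))
    return np.array([sze / nz, lze / nz, zsn / nz, gln / nz, nz / nvox])


# --------------------------------------------------------------------------
# Dmax


def dmax_oracle(mask, pitch):
    """Representative-axial-slice max diameter by direct pair loops."""
    m = np.asarray(mask) > 0
    if not m.any():
        return 0.0
    areas = [int(m[z].sum()) for z in range(m.shape[0])]
    z = int(np.argmax(areas))
    sl = m[z]
    boundary = []
    for y in range(sl.shape[0]):
        for x in range(sl.shape[1]):
            if not sl[y, x]:
                continue
            edge = False
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < sl.shape[0] and 0 <= nx < sl.shape[1]) or not sl[ny, nx]:
                    edge = True
            if edge:
                boundary.append((y, x))
    best = 0.0
    for i in range(len(boundary)):
        for j in range(i + 1, len(boundary)):
            dy = boundary[i][0] - boundary[j][0]
            dx = boundary[i][1] - boundary[j][1]
            best = max(best, (dy * dy + dx * dx) ** 0.5)
    return (best + 1.0) * pitch


# --------------------------------------------------------------------------
# Eigen-CAM


def eigen_cam_oracle(activations):
    """Direct SVD projection: |centred A . v1| min-max normalised."""
    act = np.asarray(activations, dtype=float)
    a = act.reshape(act.shape[0], -1).T
    a = a - a.mean(axis=0)
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    proj = np.abs(a @ vt[0]).reshape(act.shape[1:])
    lo, hi = proj.min(), proj.max()
    return (proj - lo) / (hi - lo)
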