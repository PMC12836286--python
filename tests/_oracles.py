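"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as plain Python loops (or calls
into generic optimizers), sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

DIRECTIONS_13 = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
]


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def brute_glcm_matrix(levels, mask, direction, n_levels):
    """Co-occurrence counts by explicit voxel-pair enumeration (both orders)."""
    m = np.zeros((n_levels, n_levels))
    shape = mask.shape
    for p in np.argwhere(mask):
        q = tuple(p + direction)
        if _inside(shape, q) and mask[q]:
            i = levels[tuple(p)] - 1
            j = levels[q] - 1
            m[i, j] += 1
            m[j, i] += 1
    return m / m.sum() if m.sum() else m


def brute_glcm_features(levels, mask, n_levels):
    feats = []
    for d in DIRECTIONS_13:
        p = brute_glcm_matrix(levels, mask, d, n_levels)
        if p.sum() == 0:
            continue
        lv = np.arange(1, n_levels + 1, dtype=float)
        px = p.sum(axis=1)
        mu = (lv * px).sum()
        sigma2 = ((lv - mu) ** 2 * px).sum()
        energy = contrast = corr = homog = ent = dissim = shade = prom = 0.0
        for i in range(n_levels):
            for j in range(n_levels):
                v = p[i, j]
                if v == 0:
                    continue
                a, b = i + 1.0, j + 1.0
                energy += v * v
                contrast += (a - b) ** 2 * v
                homog += v / (1 + (a - b) ** 2)
                ent -= v * np.log2(v)
                dissim += abs(a - b) * v
                shade += (a + b - 2 * mu) ** 3 * v
                prom += (a + b - 2 * mu) ** 4 * v
                if sigma2 > 0:
                    corr += (a - mu) * (b - mu) * v / sigma2
        feats.append(
            dict(
                glcm_energy=energy,
                glcm_contrast=contrast,
                glcm_correlation=corr,
                glcm_homogeneity=homog,
                glcm_entropy=ent,
                glcm_dissimilarity=dissim,
                glcm_cluster_shade=shade,
                glcm_cluster_prominence=prom,
            )
        )
    if not feats:
        return None
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


def brute_runs(levels, mask, direction):
    """All maximal same-level in-mask runs along one direction."""
    shape = mask.shape
    d = np.array(direction)
    runs = []
    for p in np.argwhere(mask):
        prev = tuple(p - d)
        lv = levels[tuple(p)]
        if _inside(shape, prev) and mask[prev] and levels[prev] == lv:
            continue  # not a run start
        length = 1
        q = p + d
        while _inside(shape, tuple(q)) and mask[tuple(q)] and levels[tuple(q)] == lv:
            length += 1
            q = q + d
        runs.append((int(lv), length))
    return runs


def brute_glrlm_features(levels, mask, n_levels):
    n_vox = int(mask.sum())
    feats = []
    for d in DIRECTIONS_13:
        runs = brute_runs(levels, mask, d)
        nr = len(runs)
        if nr == 0:
            continue
        sre = sum(1.0 / l**2 for _, l in runs) / nr
        lre = sum(float(l**2) for _, l in runs) / nr
        by_level = {}
        by_len = {}
        for g, l in runs:
            by_level[g] = by_level.get(g, 0) + 1
            by_len[l] = by_len.get(l, 0) + 1
        gln = sum(c**2 for c in by_level.values()) / nr
        rln = sum(c**2 for c in by_len.values()) / nr
        rp = nr / n_vox
        lgre = sum(1.0 / g**2 for g, _ in runs) / nr
        hgre = sum(float(g**2) for g, _ in runs) / nr
        srlge = sum(1.0 / (g**2 * l**2) for g, l in runs) / nr
        srhge = sum(g**2 / l**2 for g, l in runs) / nr
        lrlge = sum(l**2 / g**2 for g, l in runs) / nr
        lrhge = sum(float(g**2 * l**2) for g, l in runs) / nr
        feats.append(
            dict(
                glrlm_short_run_emphasis=sre,
                glrlm_long_run_emphasis=lre,
                glrlm_gray_level_nonuniformity=gln,
                glrlm_run_length_nonuniformity=rln,
                glrlm_run_percentage=rp,
                glrlm_low_gray_run_emphasis=lgre,
                glrlm_high_gray_run_emphasis=hgre,
                glrlm_short_run_low_gray_emphasis=srlge,
                glrlm_short_run_high_gray_emphasis=srhge,
                glrlm_long_run_low_gray_emphasis=lrlge,
                glrlm_long_run_high_gray_emphasis=lrhge,
            )
        )
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


def brute_zones(levels, mask):
    """26-connected same-level zones by flood fill."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    zones = []
    for p0 in np.argwhere(mask):
        p0 = tuple(p0)
        if seen[p0]:
            continue
        lv = levels[p0]
        stack = [p0]
        seen[p0] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for o in offsets:
                q = tuple(np.array(p) + o)
                if (
                    _inside(shape, q)
                    and mask[q]
                    and not seen[q]
                    and levels[q] == lv
                ):
                    seen[q] = True
                    stack.append(q)
        zones.append((int(lv), size))
    return zones


def brute_glszm_features(levels, mask):
    zones = brute_zones(levels, mask)
    nz = len(zones)
    n_vox = int(mask.sum())
    by_level = {}
    by_size = {}
    for g, s in zones:
        by_level[g] = by_level.get(g, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
    mu_g = sum(g for g, _ in zones) / nz
    mu_s = sum(s for _, s in zones) / nz
    probs = [c / nz for c in _zone_counts(zones).values()]
    return {
        "glszm_small_area_emphasis": sum(1.0 / s**2 for _, s in zones) / nz,
        "glszm_large_area_emphasis": sum(float(s**2) for _, s in zones) / nz,
        "glszm_gray_level_nonuniformity": sum(c**2 for c in by_level.values()) / nz,
        "glszm_gray_level_nonuniformity_normalized": sum(
            c**2 for c in by_level.values()
        )
        / nz**2,
        "glszm_size_zone_nonuniformity": sum(c**2 for c in by_size.values()) / nz,
        "glszm_size_zone_nonuniformity_normalized": sum(
            c**2 for c in by_size.values()
        )
        / nz**2,
        "glszm_zone_percentage": nz / n_vox,
        "glszm_gray_level_variance": sum((g - mu_g) ** 2 for g, _ in zones) / nz,
        "glszm_zone_variance": sum((s - mu_s) ** 2 for _, s in zones) / nz,
        "glszm_zone_entropy": -sum(p * np.log2(p) for p in probs),
        "glszm_low_gray_zone_emphasis": sum(1.0 / g**2 for g, _ in zones) / nz,
        "glszm_high_gray_zone_emphasis": sum(float(g**2) for g, _ in zones) / nz,
        "glszm_small_area_low_gray_emphasis": sum(
            1.0 / (g**2 * s**2) for g, s in zones
        )
        / nz,
        "glszm_small_area_high_gray_emphasis": sum(g**2 / s**2 for g, s in zones)
        / nz,
        "glszm_large_area_low_gray_emphasis": sum(s**2 / g**2 for g, s in zones)
        / nz,
        "glszm_large_area_high_gray_emphasis": sum(
            float(g**2 * s**2) for g, s in zones
        )
        / nz,
    }


def _zone_counts(zones):
    counts = {}
    for gs in zones:
        counts[gs] = counts.get(gs, 0) + 1
    return counts


def brute_ngtdm_features(levels, mask, n_levels, guard=1e-6):
    shape = mask.shape
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for p in np.argwhere(mask):
        p = tuple(p)
        neigh = [
            levels[tuple(np.array(p) + o)]
            for o in offsets
            if _inside(shape, tuple(np.array(p) + o)) and mask[tuple(np.array(p) + o)]
        ]
        if not neigh:
            continue
        g = levels[p]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - np.mean(neigh))
    n_total = n_i.sum()
    if n_total == 0:
        return {
            "ngtdm_coarseness": 1.0 / guard,
            "ngtdm_contrast": 0.0,
            "ngtdm_busyness": 0.0,
            "ngtdm_complexity": 0.0,
            "ngtdm_strength": 0.0,
        }
    p_i = n_i / n_total
    present = [g for g in range(1, n_levels + 1) if p_i[g - 1] > 0]
    ngp = len(present)
    coarse = 1.0 / max(sum(p_i[g - 1] * s_i[g - 1] for g in present), guard)
    if ngp > 1:
        contrast = (
            sum(
                p_i[a - 1] * p_i[b - 1] * (a - b) ** 2
                for a in present
                for b in present
            )
            / (ngp * (ngp - 1))
            * sum(s_i[g - 1] for g in present)
            / n_total
        )
        denom = sum(
            abs(a * p_i[a - 1] - b * p_i[b - 1]) for a in present for b in present
        )
        busy = sum(p_i[g - 1] * s_i[g - 1] for g in present) / denom if denom else 0.0
        compl = (
            sum(
                abs(a - b)
                * (p_i[a - 1] * s_i[a - 1] + p_i[b - 1] * s_i[b - 1])
                / (p_i[a - 1] + p_i[b - 1])
                for a in present
                for b in present
            )
            / n_total
        )
        s_tot = sum(s_i[g - 1] for g in present)
        strength = (
            sum(
                (p_i[a - 1] + p_i[b - 1]) * (a - b) ** 2
                for a in present
                for b in present
            )
            / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busy = compl = strength = 0.0
    return {
        "ngtdm_coarseness": float(coarse),
        "ngtdm_contrast": float(contrast),
        "ngtdm_busyness": float(busy),
        "ngtdm_complexity": float(compl),
        "ngtdm_strength": float(strength),
    }


# ---------------------------------------------------------------------------
# SVM dual QP oracle


def qp_dual_oracle(K: np.ndarray, y: np.ndarray, C: float) -> float:
    """Max of the SVM dual on a small instance via SLSQP + KKT polish."""
    n = len(y)
    Q = K * np.outer(y, y)

    def fun(a):
        return 0.5 * a @ Q @ a - a.sum()

    res = minimize(
        fun,
        np.zeros(n),
        jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    a = res.x
    # active-set polish: exact KKT solve on the free variables
    for _ in range(5):
        eps = 1e-6 * C
        free = (a > eps) & (a < C - eps)
        if free.sum() == 0:
            break
        F = np.where(free)[0]
        Bd = np.where(~free)[0]
        nf = len(F)
        M = np.zeros((nf + 1, nf + 1))
        M[:nf, :nf] = Q[np.ix_(F, F)]
        M[:nf, nf] = y[F]
        M[nf, :nf] = y[F]
        rhs = np.zeros(nf + 1)
        rhs[:nf] = 1 - Q[np.ix_(F, Bd)] @ a[Bd]
        rhs[nf] = -(y[Bd] @ a[Bd])
        sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
        a2 = a.copy()
        a2[F] = np.clip(sol[:nf], 0, C)
        if abs(a2 @ y) < 1e-8 and fun(a2) < fun(a):
            a = a2
        else:
            break
    return -fun(a)


# ---------------------------------------------------------------------------
# DeLong oracle


def delong_oracle(labels, scores_a, scores_b):
    """Paired DeLong p-value by explicit placement-value enumeration."""
    labels = np.asarray(labels)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    m, n = len(pos), len(neg)

    def placements(scores):
        v10 = np.zeros(m)
        v01 = np.zeros(n)
        for a, i in enumerate(pos):
            for b, j in enumerate(neg):
                if scores[i] > scores[j]:
                    psi = 1.0
                elif scores[i] == scores[j]:
                    psi = 0.5
                else:
                    psi = 0.0
                v10[a] += psi
                v01[b] += 1.0 - psi
        return v10 / n, v01 / m

    va10, va01 = placements(np.asarray(scores_a, dtype=float))
    vb10, vb01 = placements(np.asarray(scores_b, dtype=float))
    auc_a, auc_b = va10.mean(), vb10.mean()

    def cov(u, v):
        return ((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1)

    var = (
        cov(va10, va10) / m
        + cov(vb10, vb10) / m
        - 2 * cov(va10, vb10) / m
        + cov(va01, va01) / n
        + cov(vb01, vb01) / n
        - 2 * cov(va01, vb01) / n
    )
    from scipy.stats import norm

    delta = auc_a - auc_b
    if var <= 0:
        return (auc_a, auc_b, 0.0, 1.0 if delta == 0 else float("nan"))
    z = delta / np.sqrt(var)
    return auc_a, auc_b, z, 2 * float(norm.sf(abs(z)))
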