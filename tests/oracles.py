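"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately simple re-derivation of a quantity the package
computes, implemented without reference to the package's own code paths.
"""

import numpy as np
from scipy.linalg import orthogonal_procrustes


def pairwise_gpa_mean(shapes, n_sweeps=200, tol=1e-13):
    """Consensus shape by alternating pairwise Procrustes alignment.

    Centre and unit-scale every shape, then repeatedly: rotate each shape
    onto the current average with scipy's orthogonal Procrustes (projecting
    any reflection back to a rotation), re-average, re-normalise.
    """
    arrs = []
    for s in shapes:
        a = np.asarray(s, float)
        a = a - a.mean(axis=0)
        arrs.append(a / np.sqrt((a ** 2).sum()))
    ref = arrs[0]
    for _ in range(n_sweeps):
        rotated = []
        for a in arrs:
            r, _ = orthogonal_procrustes(a, ref)
            if np.linalg.det(r) < 0:  # force a proper rotation
                u, _, vt = np.linalg.svd(r)
                d = np.ones(2)
                d[-1] = -1.0
                r = u @ np.diag(d) @ vt
            rotated.append(a @ r)
        new = np.mean(rotated, axis=0)
        new = new - new.mean(axis=0)
        new = new / np.sqrt((new ** 2).sum())
        if np.sqrt(((new - ref) ** 2).mean()) < tol:
            ref = new
            break
        ref = new
    return ref


def bruteforce_mjsw(points, femur_idx, tibia_idx):
    """Minimum femur-tibia distance by explicit double loop."""
    best = np.inf
    for i in femur_idx:
        for j in tibia_idx:
            d = float(np.hypot(*(points[i] - points[j])))
            best = min(best, d)
    return best


def gridsearch_circle(points, span=5.0, levels=10, grid=21):
    """Circle centre minimising the algebraic (Kasa) loss by iteratively
    refined grid search; for a fixed centre the optimal r^2 is the mean
    squared distance."""
    pts = np.asarray(points, float)
    centre = pts.mean(axis=0)
    half = span
    for _ in range(levels):
        gx = np.linspace(centre[0] - half, centre[0] + half, grid)
        gy = np.linspace(centre[1] - half, centre[1] + half, grid)
        best = (np.inf, centre)
        for cx in gx:
            for cy in gy:
                d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
                r2 = d2.mean()
                loss = ((d2 - r2) ** 2).sum()
                if loss < best[0]:
                    best = (loss, np.array([cx, cy]))
        centre = best[1]
        half /= grid / 2.5
    r = float(np.sqrt(((pts - centre) ** 2).sum(axis=1).mean()))
    return centre, r


def rkoa_score_expression(areas, mjsw, cutoffs=(1.0, 3.0, 6.0)):
    """Single-expression rKOA score: 0.5 * sum of per-site area grades plus
    the JSN grade from the mJSW thresholds."""
    ost = sum(min(3, sum(a >= c for c in cutoffs)) for a in areas)
    jsn = 0 if mjsw >= 3 else (1 if mjsw >= 2.5 else (2 if mjsw >= 2 else 3))
    return 0.5 * ost + jsn
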