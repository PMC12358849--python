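"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a direct transcription of the definition —
per-window loops, all-pairs enumeration, combinatorial enumeration —
and deliberately shares no code with the production implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def windowed_order_bruteforce(
    theta_deg: np.ndarray, valid: np.ndarray, radius_px: float
) -> np.ndarray:
    """Windowed nematic order parameter by explicit per-window loops."""
    rows, cols = theta_deg.shape
    out = np.full((rows, cols), np.nan)
    r_int = int(np.floor(radius_px))
    for i in range(rows):
        for j in range(cols):
            if not valid[i, j]:
                continue
            cs = ss = 0.0
            n = 0
            for di in range(-r_int, r_int + 1):
                for dj in range(-r_int, r_int + 1):
                    if di * di + dj * dj > radius_px * radius_px:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols and valid[ii, jj]:
                        a = 2.0 * np.radians(theta_deg[ii, jj])
                        cs += np.cos(a)
                        ss += np.sin(a)
                        n += 1
            if n > 0:
                out[i, j] = min(1.0, np.sqrt(cs * cs + ss * ss) / n)
    return out


def autocorrelation_bruteforce(
    theta_deg: np.ndarray,
    valid: np.ndarray,
    pixel_size_um: float,
    dr_um: float,
    r_max_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs binned ⟨cos 2Δθ⟩, same binning grid as the production code."""
    pts = np.argwhere(valid)
    n_bins = int(np.ceil(r_max_um / dr_um))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            dy = (pts[a, 0] - pts[b, 0]) * pixel_size_um
            dx = (pts[a, 1] - pts[b, 1]) * pixel_size_um
            d = np.sqrt(dx * dx + dy * dy)
            k = int(d // dr_um)
            if 0 <= k < n_bins:
                dth = np.radians(
                    theta_deg[pts[a, 0], pts[a, 1]] - theta_deg[pts[b, 0], pts[b, 1]]
                )
                sums[k] += np.cos(2.0 * dth)
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        C = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    r = np.concatenate([[0.0], (np.arange(n_bins) + 0.5) * dr_um])
    return r, np.concatenate([[1.0], C])


def lineage_bruteforce(
    parents: np.ndarray, children: np.ndarray, min_overlap_frac: float
) -> dict[int, set[int]]:
    """child → parents by looping over every label pair and pixel mask.

    Symmetric overlap rule: linked when the intersection covers the
    required fraction of the parent or of the child.
    """
    links: dict[int, set[int]] = {
        c: set() for c in range(1, int(children.max()) + 1)
    }
    for p in range(1, int(parents.max()) + 1):
        pmask = parents == p
        p_area = pmask.sum()
        if p_area == 0:
            continue
        for c in range(1, int(children.max()) + 1):
            cmask = children == c
            c_area = cmask.sum()
            if c_area == 0:
                continue
            inter = np.logical_and(pmask, cmask).sum()
            if inter / p_area >= min_overlap_frac or inter / c_area >= min_overlap_frac:
                links[c].add(p)
    return links


def mann_whitney_exact_bruteforce(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by enumerating all group assignments.

    U statistic for sample a; p = fraction of C(n+m, n) relabelings whose
    min(U, nm−U) is at least as extreme (i.e. ≤ the observed one).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yj in y:
                u += (xi > yj) + 0.5 * (xi == yj)
        return u

    u_obs = u_stat(a, b)
    stat_obs = min(u_obs, n * m - u_obs)
    pooled = a + b
    idx = range(n + m)
    count = total = 0
    for grp in combinations(idx, n):
        ga = [pooled[i] for i in grp]
        gb = [pooled[i] for i in idx if i not in grp]
        u = u_stat(ga, gb)
        if min(u, n * m - u) <= stat_obs + 1e-12:
            count += 1
        total += 1
    return u_obs, count / total
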