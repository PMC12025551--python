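"""Independent brute-force implementations of the metric suite.

Deliberately naive: explicit set operations and all-pairs Euclidean
distances, no shared code with the package implementation.  Used as the
reference in oracle-equivalence tests.
"""

from __future__ import annotations

import numpy as np


def surface_points(grid: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels with at least one background 4-neighbour
    (out-of-image counts as background)."""
    h, w = grid.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not grid[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not grid[rr, cc]:
                    pts.append((r, c))
                    break
    return pts


def _all_pairs_min(points_a, points_b, spacing):
    """For each point of a, the min Euclidean mm distance to b (brute force)."""
    out = []
    for ra, ca in points_a:
        best = np.inf
        for rb, cb in points_b:
            d = np.hypot((ra - rb) * spacing[0], (ca - cb) * spacing[1])
            best = min(best, d)
        out.append(best)
    return np.array(out)


def brute_force_metrics(pm: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0)) -> dict:
    """All eight metrics plus HD, computed by enumeration."""
    pm = pm.astype(bool)
    gt = gt.astype(bool)
    inter = int((pm & gt).sum())
    union = int((pm | gt).sum())
    vp, vg = int(pm.sum()), int(gt.sum())
    tp = inter
    fp = int((pm & ~gt).sum())
    fn = int((~pm & gt).sum())

    out = {
        "DSC": 100.0 if vp + vg == 0 else 200.0 * inter / (vp + vg),
        "VOE": 0.0 if union == 0 else 100.0 * (1 - inter / union),
        "RVD": np.nan if vg == 0 else 100.0 * (vp - vg) / vg,
        "REC": np.nan if tp + fn == 0 else 100.0 * tp / (tp + fn),
        "PRE": np.nan if tp + fp == 0 else 100.0 * tp / (tp + fp),
    }
    sp = surface_points(pm)
    sg = surface_points(gt)
    diag = np.hypot(pm.shape[0] * spacing[0], pm.shape[1] * spacing[1])
    if not sp and not sg:
        out.update(ASD=0.0, HD=0.0, HD95=0.0)
    elif not sp or not sg:
        out.update(ASD=diag, HD=diag, HD95=diag)
    else:
        d_pg = _all_pairs_min(sp, sg, spacing)
        d_gp = _all_pairs_min(sg, sp, spacing)
        out["ASD"] = (d_pg.sum() + d_gp.sum()) / (len(sp) + len(sg))
        out["HD"] = max(d_pg.max(), d_gp.max())
        out["HD95"] = max(np.percentile(d_pg, 95), np.percentile(d_gp, 95))
    return out


def exact_wilcoxon_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p-value by enumerating all 2^n sign
    assignments (zero differences dropped; mid-p not used)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = _rank(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2.0
    count = 0
    for bits in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2 ** n


def _rank(x):
    """Average ranks (1-based) with tie handling."""
    order = np.argsort(x)
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
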