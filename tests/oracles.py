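"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles (explicit
loops, from-scratch state) and deliberately shares no code with the
package's incremental engine.
"""

from __future__ import annotations

import numpy as np

SLOPES = {"none": 0.0, "low": 0.25, "medium": 0.6, "high": 1.0}


def naive_removal_order(stack, rule, curve, radius, mask=None, z=0.25):
    """Greedy removal order, recomputing every quantity from scratch each step."""
    grid = stack.grid
    Q = stack.Q
    w = stack.weights
    vidx = grid.valid_indices()
    C = vidx.size
    rows, cols = np.unravel_index(vidx, grid.shape)
    pos_of_flat = {int(f): i for i, f in enumerate(vidx)}
    slope = SLOPES[curve]
    levels = (
        mask.levels.ravel()[vidx] if mask is not None else np.ones(C, dtype=int)
    )
    remaining = set(range(C))
    order = []

    def rho(i):
        if radius == 0:
            return 1.0
        tot = rem = 0
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = rows[i] + dr, cols[i] + dc
                if (
                    0 <= rr < grid.nrows
                    and 0 <= cc < grid.ncols
                    and grid.valid_mask[rr, cc]
                ):
                    tot += 1
                    if pos_of_flat[rr * grid.ncols + cc] in remaining:
                        rem += 1
        return 1.0 if tot == 0 else rem / tot

    n_species = len(w)
    for level in (0, 1, 2):
        while True:
            cand = sorted(i for i in remaining if levels[i] == level)
            if not cand:
                break
            f = {i: 1.0 - slope * (1.0 - rho(i)) for i in remaining}
            rem_pen = np.zeros(n_species)
            R = np.zeros(n_species)
            for k in remaining:
                rem_pen += f[k] * Q[k]
                R += Q[k]
            deltas = []
            for i in cand:
                if rule == "caz":
                    best = 0.0
                    for j in range(n_species):
                        if rem_pen[j] > 0:
                            best = max(best, w[j] * f[i] * Q[i, j] / rem_pen[j])
                    deltas.append(best)
                else:
                    d = 0.0
                    for j in range(n_species):
                        Rj = max(R[j], 0.0)
                        d += w[j] * (Rj**z - max(Rj - f[i] * Q[i, j], 0.0) ** z)
                    deltas.append(d)
            deltas = np.asarray(deltas)
            dmin = deltas.min()
            tol = 1e-9 * max(abs(dmin), 1e-30)
            pick = min(c for c, d in zip(cand, deltas) if d <= dmin + tol)
            remaining.discard(pick)
            order.append(int(vidx[pick]))
    return np.asarray(order)


def kendall_tau_brute(x, y):
    """Tie-corrected (tau-b) Kendall correlation over all pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


def pearson_brute(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def morans_i_lag1(layer, valid):
    """Moran's I with rook (lag-1) contiguity weights over valid cells."""
    z = layer - layer[valid].mean()
    z = np.where(valid, z, 0.0)
    num = 0.0
    wsum = 0
    nr, nc = layer.shape
    for dr, dc in ((0, 1), (1, 0)):
        a = valid[: nr - dr, : nc - dc] & valid[dr:, dc:]
        num += 2 * (z[: nr - dr, : nc - dc] * z[dr:, dc:])[a].sum()
        wsum += 2 * a.sum()
    denom = (z[valid] ** 2).sum()
    n = valid.sum()
    return (n / wsum) * (num / denom)


def mean_nn_distance(mask2d):
    """Mean nearest-neighbour distance among the True cells of a raster."""
    from scipy.spatial import cKDTree

    pts = np.column_stack(np.nonzero(mask2d)).astype(float)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(d[:, 1].mean())
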