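"""Independent reference computations used to validate the pipeline.

Everything here deliberately avoids the package's own algorithms: rotations
come from scipy's quaternion-based align_vectors, minima from dense grids
plus scipy local refinement, seams from marching-squares contours, saddles
from a minimax (watershed) graph search, and basins from a discrete
steepest-descent map.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# alignment oracles

def kabsch_rmsd_oracle(ref: np.ndarray, mob: np.ndarray) -> float:
    """Minimal RMSD over proper rotations + translation (fixed order).

    3-D uses scipy's quaternion-based align_vectors; 2-D uses the closed
    form for the optimal planar rotation angle (a 3-D embedding would
    wrongly admit in-plane reflections via out-of-plane rotations).
    """
    P = ref - ref.mean(axis=0)
    Q = mob - mob.mean(axis=0)
    if P.shape[1] == 2:
        # sum p . R(th) q = A cos th + B sin th, maximized in closed form
        A = float(np.sum(P * Q))
        B = float(np.sum(P[:, 1] * Q[:, 0] - P[:, 0] * Q[:, 1]))
        th = np.arctan2(B, A)
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s], [s, c]])
        diff = Q @ R.T - P
        return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    rot, _ = Rotation.align_vectors(P, Q)
    diff = rot.apply(Q) - P
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def permutation_rmsd_oracle(ref: np.ndarray, mob: np.ndarray,
                            labels: tuple[str, ...]) -> float:
    """Exhaustive minimum over identical-label permutations (n <= 8)."""
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    best = np.inf
    group_lists = list(groups.values())
    for combo in itertools.product(
            *[itertools.permutations(g) for g in group_lists]):
        perm = np.arange(len(labels))
        for g, pg in zip(group_lists, combo):
            perm[np.array(g)] = np.array(pg)
        best = min(best, kabsch_rmsd_oracle(ref, mob[perm]))
    return best


# ---------------------------------------------------------------------------
# grid oracles on 2-D surfaces

def grid_minima(f, xlim, ylim, n=400, refine=True):
    """Local minima of f(x, y) by dense-grid search + BFGS refinement."""
    xs = np.linspace(*xlim, n)
    ys = np.linspace(*ylim, n)
    Z = np.array([[f(x, y) for y in ys] for x in xs])
    mins = []
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            w = Z[i - 1:i + 2, j - 1:j + 2]
            if Z[i, j] == w.min() and (w > Z[i, j]).sum() == 8:
                mins.append((xs[i], ys[j]))
    if not refine:
        return [(x, y, f(x, y)) for x, y in mins]
    refined = []
    for x0, y0 in mins:
        res = minimize(lambda p: f(p[0], p[1]), [x0, y0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        refined.append((res.x[0], res.x[1], float(res.fun)))
    # dedupe refined minima
    unique = []
    for x, y, e in refined:
        if not any(np.hypot(x - u[0], y - u[1]) < 1e-4 for u in unique):
            unique.append((x, y, e))
    return unique


def basin_map(f_grad, xlim, ylim, n=400):
    """Discrete steepest-descent basin labels on an n x n grid.

    Each cell points to its lowest 8-neighbor; following pointers to
    terminal cells partitions the grid into basins of attraction.
    Returns (xs, ys, labels, ridge) where ridge marks cells adjacent to a
    different basin.
    """
    xs = np.linspace(*xlim, n)
    ys = np.linspace(*ylim, n)
    Z = np.array([[f_grad(x, y) for y in ys] for x in xs])
    # pointer to steepest-descent neighbor (or self at a local minimum)
    ptr = np.empty((n, n), dtype=np.int64)
    idx = np.arange(n * n).reshape(n, n)
    pad = np.full((n + 2, n + 2), np.inf)
    pad[1:-1, 1:-1] = Z
    best = np.full((n, n), np.inf)
    ptr[:] = idx
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = pad[1 + di:n + 1 + di, 1 + dj:n + 1 + dj]
            dist = np.hypot(di, dj)
            slope = (nb - Z) / dist
            take = slope < best
            best = np.where(take, slope, best)
            shifted = np.roll(np.roll(idx, -di, axis=0), -dj, axis=1)
            ptr = np.where(take & (slope < 0), shifted, ptr)
    flat = ptr.ravel()
    # pointer jumping to terminal cells
    for _ in range(64):
        nxt = flat[flat]
        if np.array_equal(nxt, flat):
            break
        flat = nxt
    labels = flat.reshape(n, n)
    ridge = np.zeros((n, n), dtype=bool)
    ridge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    ridge[1:, :] |= labels[:-1, :] != labels[1:, :]
    ridge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    ridge[:, 1:] |= labels[:, :-1] != labels[:, 1:]
    return xs, ys, labels, ridge


def minimax_saddle(f, a, b, xlim, ylim, n=400):
    """Saddle energy between points a, b: minimax path on the grid graph
    (Dijkstra on the 'maximum energy along path' objective), then local
    refinement of the argmax point as a stationary point of the gradient.
    """
    xs = np.linspace(*xlim, n)
    ys = np.linspace(*ylim, n)
    Z = np.array([[f(x, y) for y in ys] for x in xs])

    def cell(p):
        return (int(np.argmin(np.abs(xs - p[0]))),
                int(np.argmin(np.abs(ys - p[1]))))

    sa, sb = cell(a), cell(b)
    best = np.full((n, n), np.inf)
    best[sa] = Z[sa]
    heap = [(Z[sa], sa)]
    prev = {}
    while heap:
        val, (i, j) = heapq.heappop(heap)
        if val > best[i, j]:
            continue
        if (i, j) == sb:
            break
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < n and 0 <= nj < n:
                    nv = max(val, Z[ni, nj])
                    if nv < best[ni, nj]:
                        best[ni, nj] = nv
                        prev[(ni, nj)] = (i, j)
                        heapq.heappush(heap, (nv, (ni, nj)))
    # trace back and find the argmax cell on the optimal path
    path = [sb]
    while path[-1] != sa:
        path.append(prev[path[-1]])
    k = max(path, key=lambda c: Z[c])
    x0 = np.array([xs[k[0]], ys[k[1]]])
    from scipy.optimize import approx_fprime, root

    def grad(p):
        return approx_fprime(p, lambda q: f(q[0], q[1]), 1e-7)

    sol = root(grad, x0, method="hybr", options={"xtol": 1e-12})
    if sol.success and np.linalg.norm(sol.x - x0) < 0.1:
        return float(f(sol.x[0], sol.x[1])), sol.x
    return float(Z[k]), x0


# ---------------------------------------------------------------------------
# seam oracles

def seam_polyline(delta_f, xlim, ylim, n=1200):
    """Zero contour(s) of delta_f(x, y) via marching squares (scikit-image),
    with every vertex refined onto the zero set by 1-D bisection along the
    local finite-difference gradient of delta_f."""
    from skimage import measure
    xs = np.linspace(*xlim, n)
    ys = np.linspace(*ylim, n)
    D = np.array([[delta_f(x, y) for y in ys] for x in xs])
    segments = []
    for c in measure.find_contours(D, 0.0):
        cx = np.interp(c[:, 0], np.arange(n), xs)
        cy = np.interp(c[:, 1], np.arange(n), ys)
        pts = np.column_stack([cx, cy])
        refined = []
        h = 1e-6
        for p in pts:
            g = np.array([
                (delta_f(p[0] + h, p[1]) - delta_f(p[0] - h, p[1])) / (2 * h),
                (delta_f(p[0], p[1] + h) - delta_f(p[0], p[1] - h)) / (2 * h)])
            gn = np.linalg.norm(g)
            if gn > 1e-12:
                # one Newton step onto the zero set, iterated
                q = p.copy()
                for _ in range(10):
                    val = delta_f(q[0], q[1])
                    if abs(val) < 1e-12:
                        break
                    q = q - val * g / (gn * gn)
                refined.append(q)
            else:
                refined.append(p)
        segments.append(np.array(refined))
    return segments


def polyline_local_minima(pts, values, closed=False):
    """Indices of strict local minima of ``values`` along a polyline."""
    n = len(values)
    out = []
    rng = range(n) if closed else range(1, n - 1)
    for k in rng:
        vm = values[(k - 1) % n]
        vp = values[(k + 1) % n]
        if values[k] < vm and values[k] < vp:
            out.append(k)
    return out
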