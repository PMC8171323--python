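"""Harvesting, clustering and MECI characterization (discovery steps 2-3).

Near-degenerate frames are harvested from a seam trajectory, aligned and
clustered (K-means, elbow criterion), and cluster representatives are
refined to minimum-energy conical intersections (MECIs) with a
Lagrange-Newton constrained optimizer.  Each converged MECI is
characterized by its orthonormal branching-plane vectors g and h and by
the slopeness

    sigma = || P_gh  grad (E_i + E_j)/2 ||,

the norm of the mean-energy gradient projected onto the branching plane:
zero for an ideally peaked intersection, growing with sloped character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .align import align_rmsd
from .geometry import AdiabaticPoint, Geometry
from .metadynamics import Trajectory
from .models import SurfaceModel

__all__ = ["ClusteringResult", "MECIRecord", "harvest_seam_frames",
           "cluster_frames", "optimize_meci", "branching_plane",
           "slopeness", "dedupe_mecis"]


@dataclass
class ClusteringResult:
    chosen_k: int
    centroids: list[Geometry]
    assignments: np.ndarray
    inertia_by_k: dict[int, float]
    seed: int


@dataclass
class MECIRecord:
    """A converged (or best-effort) minimum-energy conical intersection."""

    geometry: Geometry
    state_pair: tuple[int, int]
    e_mean: float
    gap_at_convergence: float
    g_vec: np.ndarray
    h_vec: np.ndarray
    sigma: float
    converged: bool
    n_iterations: int
    h_is_fallback: bool = False
    meci_id: str = ""


def harvest_seam_frames(traj: Trajectory, gap_max: float = 0.1) -> list[Geometry]:
    """Frames whose adiabatic gap is below ``gap_max``, in trajectory order."""
    if gap_max <= 0:
        raise ValueError("gap_max must be > 0")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    return [f for f, g in zip(traj.frames, traj.gaps) if g < gap_max]


def _aligned_matrix(frames: list[Geometry], ref: Geometry,
                    allow_permutations: bool) -> np.ndarray:
    """Stack frames aligned onto ``ref`` as row vectors."""
    rows = []
    for f in frames:
        if f.n_particles == 1:
            rows.append(f.coords)
        else:
            rows.append(align_rmsd(ref, f, allow_permutations).apply(f).ravel())
    return np.array(rows)


def cluster_frames(frames: list[Geometry], k_max: int, seed: int = 0,
                   energies: np.ndarray | None = None,
                   allow_permutations: bool = True) -> ClusteringResult:
    """Align frames and K-means them; pick k by the elbow criterion.

    All frames are aligned (with label permutations, when enabled) to a
    reference frame — the lowest-mean-energy frame if ``energies`` is
    given, else the first — and K-means is run on the aligned coordinate
    vectors for k = 1..k_max (10 restarts each).  The chosen k maximizes
    the second difference of the inertia curve (maximum-curvature knee),
    ties broken toward smaller k.  Centroids are snapped to the nearest
    actual frame so downstream optimizations start from physical
    geometries.
    """
    if len(frames) < k_max:
        raise ValueError(f"need at least k_max={k_max} frames, "
                         f"got {len(frames)}")
    ref_idx = int(np.argmin(energies)) if energies is not None else 0
    ref = frames[ref_idx]
    X = _aligned_matrix(frames, ref, allow_permutations)

    # degenerate case: identical frames
    if np.ptp(X, axis=0).max() < 1e-12:
        return ClusteringResult(chosen_k=1, centroids=[frames[0]],
                                assignments=np.zeros(len(frames), dtype=int),
                                inertia_by_k={1: 0.0}, seed=seed)

    inertia, labels_by_k, centers_by_k = {}, {}, {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        inertia[k] = float(km.inertia_)
        labels_by_k[k] = km.labels_
        centers_by_k[k] = km.cluster_centers_

    if k_max >= 3:
        ks = np.arange(2, k_max)
        curv = np.array([inertia[k - 1] - 2 * inertia[k] + inertia[k + 1]
                         for k in ks])
        chosen_k = int(ks[int(np.argmax(curv))])
    else:
        chosen_k = k_max

    labels = labels_by_k[chosen_k]
    centroids = []
    for k in range(chosen_k):
        center = centers_by_k[chosen_k][k]
        members = np.where(labels == k)[0]
        d = np.linalg.norm(X[members] - center, axis=1)
        snap = frames[members[int(np.argmin(d))]]
        centroids.append(snap)
    return ClusteringResult(chosen_k=chosen_k, centroids=centroids,
                            assignments=labels, inertia_by_k=inertia,
                            seed=seed)


# ---------------------------------------------------------------------------
# branching plane


def _branching_frame(pt: AdiabaticPoint, i: int, j: int
                     ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orthonormal (g, h) at a near-degenerate point, plus a fallback flag.

    g_raw is the gradient of the energy difference; h_raw the
    Hellmann-Feynman coupling numerator v_i^T (dH) v_j = (E_j - E_i) d_ij,
    which stays finite through the crossing.  The pair is rotated within
    its plane until orthogonal (the rotation absorbs the arbitrary mixing
    of near-degenerate eigenvectors) and normalized.  If h_raw is
    (numerically) parallel to g — a constant diabatic coupling gives a
    one-dimensional branching space — h is replaced by an arbitrary unit
    vector orthogonal to g and flagged as a fallback.
    """
    g = pt.gap_gradient(i, j).astype(float)
    h = pt.coupling_numerator[i, j].astype(float)
    gh = float(g @ h)
    g2, h2 = float(g @ g), float(h @ h)
    if g2 + h2 == 0.0:
        raise ValueError("vanishing branching vectors: not a conical point")
    # in-plane rotation to orthogonality
    if abs(gh) > 1e-300:
        beta = 0.5 * np.arctan2(2.0 * gh, g2 - h2)
        g, h = (g * np.cos(beta) + h * np.sin(beta),
                -g * np.sin(beta) + h * np.cos(beta))
    gn, hn = np.linalg.norm(g), np.linalg.norm(h)
    if gn < hn:           # keep g as the dominant (difference-gradient) axis
        g, h, gn, hn = h, g, hn, gn
    g_u = g / gn
    fallback = bool(hn < 1e-8 * gn)
    if fallback:
        # 1-D branching space: complete the plane with any unit vector
        # orthogonal to g (deterministic choice)
        trial = np.zeros_like(g_u)
        trial[int(np.argmin(np.abs(g_u)))] = 1.0
        h_u = trial - (trial @ g_u) * g_u
        h_u /= np.linalg.norm(h_u)
    else:
        h_u = h / hn
        h_u -= (h_u @ g_u) * g_u          # numerical cleanup
        h_u /= np.linalg.norm(h_u)
    return g_u, h_u, fallback


def branching_plane(model: SurfaceModel, geometry: Geometry,
                    state_pair: tuple[int, int] = (0, 1),
                    tol_gap: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal branching-plane vectors (g, h) at a near-degenerate point.

    Requires the gap at ``geometry`` to be below ``tol_gap``.
    """
    i, j = state_pair
    pt = model.evaluate(geometry)
    if pt.gap(i, j) >= tol_gap:
        raise ValueError(
            f"gap {pt.gap(i, j):.3g} exceeds tol_gap={tol_gap:.3g}: "
            "not an intersection point")
    g_u, h_u, _ = _branching_frame(pt, i, j)
    return g_u, h_u


def slopeness(model: SurfaceModel, meci: MECIRecord) -> float:
    """Norm of the branching-plane projection of the mean-energy gradient."""
    if not meci.converged:
        raise ValueError("slopeness requires a converged MECI record")
    i, j = meci.state_pair
    pt = model.evaluate(meci.geometry)
    S = pt.mean_gradient(i, j)
    proj = (S @ meci.g_vec) * meci.g_vec + (S @ meci.h_vec) * meci.h_vec
    return float(np.linalg.norm(proj))


# ---------------------------------------------------------------------------
# Lagrange-Newton MECI optimization


def _kkt_step(B, a, gL, c, trust):
    """Solve the KKT system with a trust-radius cap on the step."""
    n = B.shape[0]
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = B
    K[:n, n] = a
    K[n, :n] = a
    rhs = np.concatenate([-gL, [-c]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    p = sol[:n]
    norm = np.linalg.norm(p)
    if norm > trust:
        p *= trust / norm
    return p


def optimize_meci(model: SurfaceModel, state_pair: tuple[int, int],
                  guess: Geometry, tol_gap: float = 1e-5,
                  tol_grad: float = 1e-4, max_iterations: int = 200,
                  trust0: float = 0.25) -> MECIRecord:
    """Minimize the pair mean energy subject to gap = 0 (Lagrange-Newton).

    A quasi-Newton (damped BFGS) Hessian of the Lagrangian is combined with
    the exact constraint linearization in a KKT step under trust-region
    control (radius halved whenever the merit function worsens).  When the
    constraint gradient degenerates — on a seam whose residual gap is
    limited by a constant diabatic coupling — the step falls back to
    minimizing the mean energy projected orthogonal to the gap-lifting
    directions.  If the trust region collapses, an exterior quadratic gap
    penalty with weight escalation (x10 per cycle, 6 cycles) restarts the
    search.

    Convergence: gap below ``tol_gap``, branching-plane-orthogonal mean
    gradient below ``tol_grad``, and a final step below 1e-8.
    """
    i, j = state_pair
    if not (0 <= i < j < model.n_states):
        raise ValueError("invalid state pair")
    x = np.array(model._check(guess), dtype=float)
    n = x.size
    B = np.eye(n)
    trust = trust0
    mu = 10.0
    gap0 = None
    growth_streak = 0
    n_iter = 0
    gL_prev = None
    p_prev = None

    def full_eval(xv):
        pt = model.evaluate(xv)
        c = pt.gap(i, j)
        gm = pt.mean_gradient(i, j)
        a = pt.gap_gradient(i, j)
        return pt, c, gm, a

    pt, c, gm, a = full_eval(x)
    gap0 = c
    e_mean = pt.mean_energy(i, j)

    broken = False
    for n_iter in range(1, max_iterations + 1):
        try:
            g_u, h_u, h_fallback = _branching_frame(pt, i, j)
        except ValueError:
            broken = True       # no crossing character anywhere nearby
            break
        lift = [g_u] if h_fallback else [g_u, h_u]
        # stationarity along the seam: project out only the directions
        # that actually lift the degeneracy
        proj_out = gm.copy()
        for d in lift:
            proj_out -= (proj_out @ d) * d

        a_norm = np.linalg.norm(a)
        if a_norm > 1e-7:
            lam = -float(a @ gm) / float(a @ a)
            gL = gm + lam * a
            p = _kkt_step(B, a, gL, c, trust)
        else:
            # constraint gradient degenerate: reduced minimization along
            # the seam (project out the gap-lifting directions)
            gL = gm.copy()
            for d in lift:
                gL -= (gL @ d) * d
            p = np.linalg.solve(B, -gL)
            for d in lift:
                p -= (p @ d) * d
            if np.linalg.norm(p) > trust:
                p *= trust / np.linalg.norm(p)
            lam = 0.0

        # convergence test (step about to be taken is negligible)
        if (c < tol_gap and np.linalg.norm(proj_out) < tol_grad
                and np.linalg.norm(p) < 1e-8):
            break

        mu = max(mu, 2.0 * abs(lam) + 1.0)
        x_new = x + p
        pt_n, c_n, gm_n, a_n = full_eval(x_new)
        e_new = pt_n.mean_energy(i, j)
        merit_old = e_mean + mu * c
        merit_new = e_new + mu * c_n
        if merit_new <= merit_old + 1e-14:
            # damped BFGS update on the Lagrangian gradient
            gL_new = gm_n + lam * a_n
            s = p
            y = gL_new - gL
            sy = float(s @ y)
            Bs = B @ s
            sBs = float(s @ Bs)
            if sy < 0.2 * sBs and sBs > 0:
                theta = 0.8 * sBs / (sBs - sy)
                y = theta * y + (1 - theta) * Bs
                sy = float(s @ y)
            if sy > 1e-12 and sBs > 0:
                B = B - np.outer(Bs, Bs) / sBs + np.outer(y, y) / sy
            x, pt, c, gm, a, e_mean = x_new, pt_n, c_n, gm_n, a_n, e_new
            trust = min(trust * 1.5, 4.0 * trust0)
            if c > 1.5 * max(gap0, tol_gap):
                growth_streak += 1
            else:
                growth_streak = 0
            if growth_streak >= 10 and c > 10.0 * max(gap0, 1e-3):
                break   # diverging away from any seam
        else:
            trust *= 0.5
            if trust < 1e-10:
                result = _penalty_fallback(model, state_pair, x, tol_gap,
                                           tol_grad)
                if result is not None:
                    x = result
                    pt, c, gm, a = full_eval(x)
                    e_mean = pt.mean_energy(i, j)
                    trust = trust0
                    B = np.eye(n)
                else:
                    break

    try:
        g_u, h_u, h_fallback = _branching_frame(pt, i, j)
    except ValueError:
        g_u = np.zeros(n)
        h_u = np.zeros(n)
        h_fallback = True
        broken = True
    lift = [g_u] if h_fallback else [g_u, h_u]
    proj_out = gm.copy()
    for d in lift:
        proj_out -= (proj_out @ d) * d
    converged = bool(not broken and c < tol_gap
                     and np.linalg.norm(proj_out) < tol_grad)
    S_in = (gm @ g_u) * g_u + (gm @ h_u) * h_u
    return MECIRecord(geometry=model.geometry(x), state_pair=(i, j),
                      e_mean=float(e_mean), gap_at_convergence=float(c),
                      g_vec=g_u, h_vec=h_u,
                      sigma=float(np.linalg.norm(S_in)),
                      converged=converged, n_iterations=n_iter,
                      h_is_fallback=h_fallback)


def _penalty_fallback(model, state_pair, x0, tol_gap, tol_grad):
    """Exterior quadratic gap penalty with weight escalation."""
    from scipy.optimize import minimize

    i, j = state_pair
    x = np.array(x0, dtype=float)
    w = 100.0
    for _ in range(6):
        def fun(xv, w=w):
            pt = model.evaluate(xv)
            gap = pt.gap(i, j)
            f = pt.mean_energy(i, j) + w * gap * gap
            g = pt.mean_gradient(i, j) + 2.0 * w * gap * pt.gap_gradient(i, j)
            return f, g

        res = minimize(fun, x, jac=True, method="BFGS",
                       options={"maxiter": 200, "gtol": 1e-10})
        x = res.x
        if model.evaluate(x).gap(i, j) < tol_gap:
            return x
        w *= 10.0
    return x


def dedupe_mecis(records: list[MECIRecord], rmsd_tol: float = 1e-3,
                 energy_tol: float = 1e-3,
                 allow_permutations: bool = True) -> list[MECIRecord]:
    """Greedy duplicate removal, keeping the lowest-mean-energy exemplar.

    Two records are duplicates when their permutation-aware aligned RMSD is
    below ``rmsd_tol`` and their mean energies differ by less than
    ``energy_tol``.  Output sorted by mean energy ascending.
    """
    unique: list[MECIRecord] = []
    for rec in sorted(records, key=lambda r: r.e_mean):
        dup = False
        for kept in unique:
            if abs(rec.e_mean - kept.e_mean) < energy_tol:
                d = align_rmsd(kept.geometry, rec.geometry,
                               allow_permutations).rmsd
                if d < rmsd_tol:
                    dup = True
                    break
        if not dup:
            unique.append(rec)
    for idx, rec in enumerate(unique):
        rec.meci_id = rec.meci_id or f"meci_{idx}"
    return unique
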