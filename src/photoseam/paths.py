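"""String-method minimum-energy paths (refinement phase).

Two path objectives are supported on the same double-ended growing string
with climbing-image refinement:

``single_state``
    the energy of one adiabatic state — ground-state paths between
    photoproducts, giving the barrier table;
``seam``
    the state-pair mean energy plus a harmonic gap penalty whose weight is
    escalated until every image sits on the seam (gap below ``gap_tol``) —
    seam-constrained paths between MECIs.

Nodes are grown alternately from both ends along the interpolated tangent
and relaxed perpendicular to the string; after joining, the chain is
relaxed with upwind (improved) tangents, arc-length re-equalization each
macro-iteration, and a climbing image on the maximum node.  Endpoints
never move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import align_rmsd
from .cone import sample_cone
from .geometry import Geometry
from .models import SurfaceModel
from .products import StationaryPoint, census, retally
from .selection import MECIRecord, _branching_frame

__all__ = ["PathResult", "find_path", "barrier_table", "profile_along_path",
           "PathProfilePoint"]


@dataclass
class PathResult:
    images: list[Geometry]
    energies: np.ndarray            # (n_images, n_states)
    gaps: np.ndarray                # (n_images,) for the path's state pair
    objective: str                  # "single_state" | "seam"
    state: int | None
    state_pair: tuple[int, int] | None
    barrier_forward: float
    barrier_reverse: float
    barrierless: bool
    converged: bool
    arc_length: np.ndarray

    @property
    def n_images(self) -> int:
        return len(self.images)

    def path_energy(self) -> np.ndarray:
        """The profiled objective energy per image (state or pair mean)."""
        if self.objective == "single_state":
            return self.energies[:, self.state]
        i, j = self.state_pair
        return 0.5 * (self.energies[:, i] + self.energies[:, j])


def _make_objective(model, objective, penalty_weight):
    if objective[0] == "single_state":
        state = objective[1]

        def fg(x):
            pt = model.evaluate(x)
            return float(pt.energies[state]), pt.gradients[state].copy(), pt
    elif objective[0] == "seam":
        i, j = objective[1]

        def fg(x):
            pt = model.evaluate(x)
            gap = pt.gap(i, j)
            v = pt.mean_energy(i, j) + 0.5 * penalty_weight * gap * gap
            g = pt.mean_gradient(i, j) + penalty_weight * gap * pt.gap_gradient(i, j)
            return v, g, pt
    else:
        raise ValueError("objective must be 'single_state' or 'seam'")
    return fg


def _tangents(X, E):
    """Improved (upwind) tangent estimates for interior nodes."""
    n = len(X)
    taus = np.zeros_like(X)
    for k in range(1, n - 1):
        dplus = X[k + 1] - X[k]
        dminus = X[k] - X[k - 1]
        if E[k + 1] > E[k] > E[k - 1]:
            tau = dplus
        elif E[k + 1] < E[k] < E[k - 1]:
            tau = dminus
        else:
            emax = max(abs(E[k + 1] - E[k]), abs(E[k - 1] - E[k]))
            emin = min(abs(E[k + 1] - E[k]), abs(E[k - 1] - E[k]))
            if E[k + 1] > E[k - 1]:
                tau = dplus * emax + dminus * emin
            else:
                tau = dplus * emin + dminus * emax
        nrm = np.linalg.norm(tau)
        taus[k] = tau / nrm if nrm > 0 else tau
    return taus


def _reparameterize(X):
    """Redistribute interior nodes to equal arc length by interpolation."""
    seg = np.linalg.norm(np.diff(X, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return X
    targets = np.linspace(0.0, s[-1], len(X))
    Xn = X.copy()
    for k in range(1, len(X) - 1):
        t = targets[k]
        idx = int(np.searchsorted(s, t, side="right")) - 1
        idx = min(max(idx, 0), len(X) - 2)
        denom = s[idx + 1] - s[idx]
        w = (t - s[idx]) / denom if denom > 0 else 0.0
        Xn[k] = (1 - w) * X[idx] + w * X[idx + 1]
    return Xn


def _relax_string(fg, X, max_macro=3000, step0=0.05, f_tol=1e-6,
                  climb_tol=1e-8, climb=True, snap=None, project=None):
    """Projected-gradient string relaxation with a climbing image.

    Per-node step lengths adapt by sign damping (halved when the projected
    force reverses, slowly regrown otherwise), which keeps the relaxation
    stable for arbitrarily stiff seam penalties.  With ``snap`` the nodes
    are re-projected onto the seam each macro-iteration and ``project``
    restricts gradients to the seam tangent space — off-seam force
    components are the constraint's business, not the string's.
    """
    n = len(X)
    steps = np.full(n, step0)
    Fprev = None
    for _ in range(max_macro):
        vals = [fg(x) for x in X]
        E = np.array([v[0] for v in vals])
        G = np.array([v[1] for v in vals])
        bases = [None] * n
        if project is not None:
            for k in range(1, n - 1):
                basis = project(X[k])
                bases[k] = basis
                if basis is not None:
                    G[k] = basis @ (basis.T @ G[k])
        taus = _tangents(X, E)
        kmax = 1 + int(np.argmax(E[1:-1])) if n > 2 else 0
        Fmax = 0.0
        climb_resid = 0.0
        F = np.zeros_like(X)
        for k in range(1, n - 1):
            g = G[k]
            t = taus[k]
            on_1d_seam = bases[k] is not None and bases[k].shape[1] == 1
            if climb and k == kmax:
                if on_1d_seam:
                    # the path is pinned to a 1-D seam: climb along it
                    ts = bases[k][:, 0]
                    F[k] = (g @ ts) * ts
                    climb_resid = abs(float(g @ ts))
                else:
                    F[k] = -(g - 2.0 * (g @ t) * t)
                    climb_resid = abs(float(g @ t))
            elif on_1d_seam:
                # no transverse freedom: carried by respacing alone
                F[k] = 0.0
            else:
                F[k] = -(g - (g @ t) * t)
            Fmax = max(Fmax, float(np.linalg.norm(F[k])))
        if Fprev is not None:
            for k in range(1, n - 1):
                if float(F[k] @ Fprev[k]) < 0.0:
                    steps[k] *= 0.5
                else:
                    steps[k] = min(steps[k] * 1.2, step0)
        Fprev = F
        Xn = X.copy()
        for k in range(1, n - 1):
            move = steps[k] * F[k]
            mn = np.linalg.norm(move)
            if mn > 0.1:
                move *= 0.1 / mn
            Xn[k] = X[k] + move
        xclimb = Xn[kmax].copy() if (climb and n > 2) else None
        Xn = _reparameterize(Xn)
        if xclimb is not None:
            Xn[kmax] = xclimb          # climbing node exempt from respacing
        if snap is not None:
            for k in range(1, n - 1):
                snapped = snap(Xn[k])
                if snapped is not None:
                    Xn[k] = snapped
        disp = float(np.max(np.linalg.norm(Xn - X, axis=1)))
        X = Xn
        # a cusp-topped path (e.g. a ground-state ridge where the surfaces
        # cross) never satisfies the gradient criterion at the climbing
        # node, but its position converges: accept once the adaptive step
        # has collapsed below the position resolution
        climb_ok = (climb_resid < climb_tol
                    or steps[kmax] * np.linalg.norm(F[kmax]) < 1e-8)
        other_ok = all(
            np.linalg.norm(F[k]) < f_tol
            or steps[k] * np.linalg.norm(F[k]) < 1e-8
            for k in range(1, n - 1) if k != kmax)
        if (not climb or climb_ok) and other_ok and (snap is None or disp < 1e-8):
            return X, True
    return X, False


def _grow_string(fg, a, b, n_images):
    """Double-ended growth: nodes added alternately along the chord."""
    left, right = [a.copy()], [b.copy()]
    while len(left) + len(right) < n_images:
        grow_left = len(left) <= len(right)
        src = left[-1] if grow_left else right[-1]
        dst = right[-1] if grow_left else left[-1]
        remaining = n_images - (len(left) + len(right))
        new = src + (dst - src) / (remaining + 1)
        # relax the fresh node perpendicular to the local tangent
        t = dst - src
        tn = np.linalg.norm(t)
        t = t / tn if tn > 0 else t
        step, fprev = 0.05, None
        for _ in range(30):
            _, g, _ = fg(new)
            f = -(g - (g @ t) * t)
            if np.linalg.norm(f) < 1e-4:
                break
            if fprev is not None:
                step = step * 0.5 if float(f @ fprev) < 0 else min(step * 1.2, 0.05)
            fprev = f
            move = step * f
            mn = np.linalg.norm(move)
            cap = 0.05 * max(tn, 1.0)
            if mn > cap:
                move *= cap / mn
            new = new + move
        (left if grow_left else right).append(new)
    return np.array(left + right[::-1])


def _seam_tangent_basis(pt, i, j):
    """Orthonormal basis of the seam tangent space (complement of the
    gap-lifting directions) at a near-degenerate point."""
    g_u, h_u, fb = _branching_frame(pt, i, j)
    lift = [g_u] if fb else [g_u, h_u]
    n = g_u.size
    A = np.array(lift).T
    Q, _ = np.linalg.qr(np.hstack([A, np.eye(n)]))
    return Q[:, A.shape[1]:]


def _trace_seam(model, x0, pair, direction, step=0.02, max_steps=4000,
                stop_at=None, tol_gap=1e-5):
    """Predictor-corrector walk along a 1-D seam from x0.

    Returns (points, reached) where ``reached`` says whether the walk came
    within ~1.5 steps of ``stop_at`` (which is then appended).  Only
    meaningful when the seam tangent space is one-dimensional.
    """
    x, pt = _reconverge_to_seam(model, x0, pair, tol_gap=tol_gap)
    if x is None:
        return [np.array(x0, dtype=float)], False
    tprev = np.asarray(direction, dtype=float)
    pts_out = [x]
    for _ in range(max_steps):
        pt = model.evaluate(x)
        tan = _seam_tangent_basis(pt, *pair)
        if tan.shape[1] != 1:
            break
        t = tan[:, 0]
        if float(t @ tprev) < 0:
            t = -t
        x_new, _ = _reconverge_to_seam(model, x + step * t, pair,
                                       tol_gap=tol_gap)
        if x_new is None:
            break
        pts_out.append(x_new)
        x = x_new
        tprev = t
        if stop_at is not None and np.linalg.norm(x_new - stop_at) < 1.5 * step:
            pts_out.append(np.array(stop_at, dtype=float))
            return pts_out, True
    return pts_out, False


def _resample_polyline(P, n):
    """n points evenly spaced in arc length along polyline P."""
    P = np.asarray(P, dtype=float)
    seg = np.linalg.norm(np.diff(P, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n)
    out = np.empty((n, P.shape[1]))
    for k, t in enumerate(targets):
        idx = min(max(int(np.searchsorted(s, t, side="right")) - 1, 0),
                  len(P) - 2)
        denom = s[idx + 1] - s[idx]
        w = (t - s[idx]) / denom if denom > 0 else 0.0
        out[k] = (1 - w) * P[idx] + w * P[idx + 1]
    return out


def _seam_initial_string(model, a, b, pair, n_images, fg):
    """Initial node chain for a seam path: walk the seam from a to b.

    The seam is traced in both tangent directions from a; if either walk
    reaches b the lower-passing arc seeds the string.  If tracing fails
    (e.g. seam tangent space not one-dimensional) the chord-grown string
    is used instead.
    """
    pt = model.evaluate(a)
    try:
        tan = _seam_tangent_basis(pt, *pair)
    except ValueError:
        tan = np.zeros((a.size, 0))
    candidates = []
    if tan.shape[1] == 1:
        t0 = tan[:, 0]
        for d in (t0, -t0):
            pts_tr, reached = _trace_seam(model, a, pair, d, stop_at=b)
            if reached:
                emax = max(model.evaluate(x).mean_energy(*pair)
                           for x in pts_tr)
                candidates.append((emax, pts_tr))
    if candidates:
        candidates.sort(key=lambda c: c[0])
        return _resample_polyline(candidates[0][1], n_images)
    return _grow_string(fg, a, b, n_images)


def find_path(model: SurfaceModel, endpoints: tuple[Geometry, Geometry],
              objective: tuple = ("single_state", 0), n_images: int = 21,
              gap_tol: float = 1e-3, f_tol: float = 1e-6,
              max_escalations: int = 5,
              penalty_weight0: float = 1e3) -> PathResult:
    """Growing-string minimum-energy path between two fixed endpoints.

    ``objective`` is ``("single_state", state)`` or ``("seam", (i, j))``.
    For seam paths the gap-penalty weight is multiplied by 10 until every
    image gap is below ``gap_tol`` (at most ``max_escalations`` times).
    Returns barriers relative to both endpoints; a path whose maximum sits
    at an endpoint (within 1e-6) is labeled barrierless.
    """
    if n_images < 5:
        raise ValueError("n_images must be >= 5")
    a = np.array(model._check(endpoints[0]), dtype=float)
    b = np.array(model._check(endpoints[1]), dtype=float)
    is_seam = objective[0] == "seam"
    pair = objective[1] if is_seam else None
    state = objective[1] if not is_seam else None

    if np.linalg.norm(a - b) < 1e-12:
        pt = model.evaluate(a)
        gaps = np.array([pt.gap(*pair)]) if is_seam else np.array([0.0])
        return PathResult(images=[model.geometry(a)],
                          energies=pt.energies[None, :], gaps=gaps,
                          objective=objective[0], state=state,
                          state_pair=pair, barrier_forward=0.0,
                          barrier_reverse=0.0, barrierless=True,
                          converged=True, arc_length=np.array([0.0]))

    w = penalty_weight0
    converged = False
    snap = project = None
    if is_seam:
        def snap(xv):
            xs, _ = _reconverge_to_seam(model, xv, pair, tol_gap=gap_tol / 10)
            return xs

        def project(xv):
            pt = model.evaluate(xv)
            if pt.gap(*pair) > gap_tol:
                return None          # off-seam: keep the full gradient
            try:
                return _seam_tangent_basis(pt, *pair)
            except ValueError:
                return None
    X0 = None
    for attempt in range(max_escalations + 1):
        fg = _make_objective(model, objective, w)
        if X0 is None:
            X0 = (_seam_initial_string(model, a, b, pair, n_images, fg)
                  if is_seam else _grow_string(fg, a, b, n_images))
        X = X0.copy()
        X[0], X[-1] = a, b
        X, converged = _relax_string(fg, X, f_tol=f_tol, snap=snap,
                                     project=project)
        X[0], X[-1] = a, b
        X0 = X.copy()
        if not is_seam:
            break
        pts = [model.evaluate(x) for x in X]
        if max(pt.gap(*pair) for pt in pts) < gap_tol:
            break
        w *= 10.0
    pts = [model.evaluate(x) for x in X]
    energies = np.array([pt.energies for pt in pts])
    gaps = (np.array([pt.gap(*pair) for pt in pts]) if is_seam
            else np.zeros(len(X)))
    prof = (0.5 * (energies[:, pair[0]] + energies[:, pair[1]]) if is_seam
            else energies[:, state])
    arc = np.concatenate([[0.0],
                          np.cumsum(np.linalg.norm(np.diff(X, axis=0), axis=1))])
    kmax = int(np.argmax(prof))
    emax = prof[kmax]
    barrierless = bool(emax <= max(prof[0], prof[-1]) + 1e-6)
    if is_seam:
        seam_ok = bool(gaps.max() < gap_tol)
        converged = converged and seam_ok
    return PathResult(images=[model.geometry(x) for x in X],
                      energies=energies, gaps=gaps, objective=objective[0],
                      state=state, state_pair=pair,
                      barrier_forward=float(emax - prof[0]),
                      barrier_reverse=float(emax - prof[-1]),
                      barrierless=barrierless, converged=bool(converged),
                      arc_length=arc)


def barrier_table(model: SurfaceModel, stationary_points: list[StationaryPoint],
                  n_images: int = 21, state: int = 0,
                  rmsd_tol: float = 0.05, energy_tol: float = 0.01
                  ) -> dict[tuple[str, str], dict]:
    """Path every ordered pair of stationary points on one state.

    Each cell holds ``{"barrier": float}`` for a direct path, or
    ``{"intermediate": label}`` when an interior image comes within the
    product-dedup tolerance of a third known stationary point, or
    ``{"failed": True}`` if the path search did not converge.
    """
    if len(stationary_points) < 2:
        raise ValueError("need at least two stationary points")
    table: dict[tuple[str, str], dict] = {}
    for pa in stationary_points:
        for pb in stationary_points:
            if pa is pb:
                continue
            path = find_path(model, (pa.geometry, pb.geometry),
                             ("single_state", state), n_images=n_images)
            cell: dict = {}
            if not path.converged:
                cell["failed"] = True
            inter = None
            for img, e in zip(path.images[1:-1],
                              path.path_energy()[1:-1]):
                for other in stationary_points:
                    if other is pa or other is pb:
                        continue
                    if (abs(e - other.energy) < energy_tol
                            and align_rmsd(other.geometry, img,
                                           allow_permutations=True).rmsd
                            < rmsd_tol):
                        inter = other.product_label
                        break
                if inter:
                    break
            if inter:
                cell["intermediate"] = inter
            else:
                cell["barrier"] = path.barrier_forward
            table[(pa.product_label, pb.product_label)] = cell
    return table


@dataclass
class PathProfilePoint:
    """Per-image seam characterization along a refined seam path."""

    index: int
    arc_length: float
    geometry: Geometry
    e_mean: float
    gap: float
    sigma: float
    fractions: dict[str, float]
    fraction_ci: dict[str, tuple[float, float]]
    skipped: bool = False


def _reconverge_to_seam(model, x, pair, tol_gap=1e-5, max_iter=60):
    """Newton steps along the gap gradient only (no sliding along the seam)."""
    i, j = pair
    x = np.array(x, dtype=float)
    for _ in range(max_iter):
        pt = model.evaluate(x)
        gap = pt.gap(i, j)
        if gap < tol_gap:
            return x, pt
        a = pt.gap_gradient(i, j)
        a2 = float(a @ a)
        if a2 < 1e-20:
            break
        x = x - (gap / a2) * a
    pt = model.evaluate(x)
    return (x, pt) if pt.gap(i, j) < tol_gap else (None, None)


def profile_along_path(model: SurfaceModel, path: PathResult,
                       cone_params: dict | None = None, seed: int = 0,
                       tol_gap: float = 1e-5, n_bootstrap: int = 1000,
                       registry: list[StationaryPoint] | None = None
                       ) -> list[PathProfilePoint]:
    """Re-run cone sampling and the product census at every path image.

    Each image is first re-converged onto the seam (pure gap-Newton, so the
    image does not slide along the path), then characterized: branching
    plane, slopeness, cone samples, product census with a registry shared
    across images, and a percentile bootstrap (seeded, ``n_bootstrap``
    replicates) for the product fractions.  Images that cannot be brought
    back onto the seam are flagged ``skipped``.
    """
    if path.objective != "seam":
        raise ValueError("profiling requires a seam path")
    if not path.converged:
        raise ValueError("profiling requires a converged seam path")
    pair = path.state_pair
    cp = {"R": 0.075, "n": 200, "gap_window": (0.0, 0.5)}
    if cone_params:
        cp.update(cone_params)
    registry = registry if registry is not None else []
    rng = np.random.default_rng(seed)
    results: list[PathProfilePoint] = []
    censuses = []
    for k, img in enumerate(path.images):
        x, pt = _reconverge_to_seam(model, img.coords, pair, tol_gap=tol_gap)
        if x is None:
            results.append(PathProfilePoint(
                index=k, arc_length=float(path.arc_length[k]), geometry=img,
                e_mean=float("nan"), gap=float("nan"), sigma=float("nan"),
                fractions={}, fraction_ci={}, skipped=True))
            censuses.append(None)
            continue
        g_u, h_u, fb = _branching_frame(pt, *pair)
        S = pt.mean_gradient(*pair)
        sigma = float(np.linalg.norm((S @ g_u) * g_u + (S @ h_u) * h_u))
        rec = MECIRecord(geometry=model.geometry(x), state_pair=pair,
                         e_mean=pt.mean_energy(*pair),
                         gap_at_convergence=pt.gap(*pair), g_vec=g_u,
                         h_vec=h_u, sigma=sigma, converged=True,
                         n_iterations=0, h_is_fallback=fb,
                         meci_id=f"path_image_{k}")
        samples = sample_cone(model, rec, R=cp["R"], n=cp["n"],
                              gap_window=cp["gap_window"],
                              seed=int(rng.integers(2**31)))
        cens, registry = census(model, samples, state_index=pair[0],
                                registry=registry)
        results.append(PathProfilePoint(
            index=k, arc_length=float(path.arc_length[k]),
            geometry=model.geometry(x), e_mean=rec.e_mean,
            gap=rec.gap_at_convergence, sigma=sigma, fractions={},
            fraction_ci={}))
        censuses.append(cens)
    # final labels are only stable once the registry stops growing
    for res, cens in zip(results, censuses):
        if cens is None:
            continue
        cens = retally(cens, registry)
        res.fractions = cens.fractions
        labels = sorted(cens.counts)
        hits = np.array(cens.hit_indices)
        lab_by_hit = np.array(
            ["unconverged" if h < 0 else registry[h].product_label
             for h in hits])
        boot = {lab: [] for lab in labels}
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(hits), len(hits))
            sub = lab_by_hit[pick]
            for lab in labels:
                boot[lab].append(np.mean(sub == lab))
        res.fraction_ci = {
            lab: (float(np.percentile(boot[lab], 2.5)),
                  float(np.percentile(boot[lab], 97.5)))
            for lab in labels}
    return results
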