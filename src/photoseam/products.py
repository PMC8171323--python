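"""Photoproduct search: lower-state optimization and census (step 5).

Every accepted cone point is relaxed on the lower state of the pair by
plain gradient-following minimization (no momentum, no thermal noise) and
the resulting stationary points are deduplicated into labeled products.
The census reports, per MECI, the fraction of cone points that reach each
product — the branching-plane map of photochemical outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import align_rmsd
from .cone import ConeSample
from .geometry import Geometry
from .models import SurfaceModel

__all__ = ["StationaryPoint", "ProductCensus", "optimize_lower_state", "census"]

#: cap on a single optimizer displacement (length units) to limit
#: basin-hopping artifacts near ridges
MAX_STEP = 0.2


@dataclass
class StationaryPoint:
    geometry: Geometry
    state_index: int
    energy: float
    gradient_norm: float
    product_label: str = ""
    support_count: int = 1
    converged: bool = True


@dataclass
class ProductCensus:
    """Per-MECI product fractions; fractions sum to one, counts to n."""

    fractions: dict[str, float]
    counts: dict[str, int]
    total: int
    meci_id: str = ""
    hit_indices: list[int] = field(default_factory=list)


def optimize_lower_state(model: SurfaceModel, state_index: int,
                         start: Geometry, tol_grad: float = 1e-7,
                         max_iterations: int = 500) -> StationaryPoint:
    """Quasi-Newton (BFGS) single-state minimization with step capping.

    Follows the gradient of one adiabatic state with a backtracking line
    search and a maximum displacement of 0.2 length units per step;
    converges when the gradient norm drops below ``tol_grad``.
    """
    if not (0 <= state_index < model.n_states):
        raise ValueError("state_index out of range")
    x = np.array(model._check(start), dtype=float)
    n = x.size
    Hinv = np.eye(n)

    def fg(xv):
        pt = model.evaluate(xv)
        return float(pt.energies[state_index]), pt.gradients[state_index]

    f, g = fg(x)
    converged = np.linalg.norm(g) < tol_grad
    it = 0
    while not converged and it < max_iterations:
        it += 1
        p = -Hinv @ g
        pn = np.linalg.norm(p)
        if pn > MAX_STEP:
            p *= MAX_STEP / pn
        # backtracking line search on the Armijo condition
        t, ok = 1.0, False
        gTp = float(g @ p)
        if gTp > 0:          # reset a corrupted Hessian
            Hinv = np.eye(n)
            p = -g
            pn = np.linalg.norm(p)
            if pn > MAX_STEP:
                p *= MAX_STEP / pn
            gTp = float(g @ p)
        for _ in range(40):
            f_new, g_new = fg(x + t * p)
            if np.isfinite(f_new) and f_new <= f + 1e-4 * t * gTp:
                ok = True
                break
            t *= 0.5
        if not ok:
            break
        s = t * p
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12:
            rho = 1.0 / sy
            I = np.eye(n)
            Hinv = ((I - rho * np.outer(s, y)) @ Hinv
                    @ (I - rho * np.outer(y, s)) + rho * np.outer(s, s))
        x, f, g = x + s, f_new, g_new
        converged = np.linalg.norm(g) < tol_grad
    if not np.isfinite(f):
        raise FloatingPointError("non-finite energy in lower-state optimization")
    return StationaryPoint(geometry=model.geometry(x), state_index=state_index,
                           energy=f, gradient_norm=float(np.linalg.norm(g)),
                           converged=bool(converged))


def census(model: SurfaceModel, cone_samples: list[ConeSample],
           state_index: int = 0, rmsd_tol: float = 0.05,
           energy_tol: float = 0.01, tol_grad: float = 1e-7,
           registry: list[StationaryPoint] | None = None
           ) -> tuple[ProductCensus, list[StationaryPoint]]:
    """Optimize every cone point on the lower state and tally products.

    Endpoints are deduplicated by permutation-aware aligned RMSD below
    ``rmsd_tol`` together with an energy difference below ``energy_tol``;
    products are labeled ``product_0, product_1, ...`` by ascending energy.
    Failed optimizations are kept under the label ``"unconverged"``.
    An existing ``registry`` of stationary points may be passed in so
    labels remain comparable across MECIs; it is extended in place.
    """
    if not cone_samples:
        raise ValueError("empty cone sample list")
    points = registry if registry is not None else []
    hits: list[int] = []          # index into points, or -1 for unconverged
    for cs in cone_samples:
        sp = optimize_lower_state(model, state_index, cs.geometry,
                                  tol_grad=tol_grad)
        if not sp.converged:
            hits.append(-1)
            continue
        match = -1
        for idx, known in enumerate(points):
            if abs(sp.energy - known.energy) < energy_tol:
                d = align_rmsd(known.geometry, sp.geometry,
                               allow_permutations=True).rmsd
                if d < rmsd_tol:
                    match = idx
                    break
        if match < 0:
            points.append(sp)
            match = len(points) - 1
        else:
            points[match].support_count += 1
        hits.append(match)

    # label by ascending energy (over the whole registry)
    order = np.argsort([p.energy for p in points], kind="stable")
    for rank, idx in enumerate(order):
        points[idx].product_label = f"product_{rank}"

    counts: dict[str, int] = {}
    for h in hits:
        label = "unconverged" if h < 0 else points[h].product_label
        counts[label] = counts.get(label, 0) + 1
    total = len(cone_samples)
    fractions = {k: v / total for k, v in counts.items()}
    meci_id = cone_samples[0].meci_id
    return (ProductCensus(fractions=fractions, counts=counts, total=total,
                          meci_id=meci_id, hit_indices=hits), points)


def retally(cens: ProductCensus, points: list[StationaryPoint]) -> ProductCensus:
    """Recompute a census' counts with the registry's current labels.

    Needed when several censuses share a growing product registry: labels
    follow ascending energy over the registry, so tallies taken earlier
    must be refreshed once the registry is final.
    """
    counts: dict[str, int] = {}
    for h in cens.hit_indices:
        label = "unconverged" if h < 0 else points[h].product_label
        counts[label] = counts.get(label, 0) + 1
    fractions = {k: v / cens.total for k, v in counts.items()}
    return ProductCensus(fractions=fractions, counts=counts, total=cens.total,
                         meci_id=cens.meci_id, hit_indices=list(cens.hit_indices))
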