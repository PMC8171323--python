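"""Branching-plane cone sampling around a MECI (discovery step 4).

Displaced geometries are drawn on the branching plane by

    r = r0 + l cos(alpha) g + l sin(alpha) h,
    l = c R,       alpha = 2 pi b,

with b, c uniform on (0, 1), g and h the orthonormalized branching-plane
unit vectors and R a user radius.  This places points with radius uniform
on (0, R) — an area density proportional to 1/r that concentrates samples
near the intersection — and angle uniform on [0, 2 pi).

An energy-gap acceptance window can be applied by rejection, preserving
the sampling law exactly; the alternative of retuning R to meet a window
is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .models import SurfaceModel
from .selection import MECIRecord

__all__ = ["ConeSample", "sample_cone", "cone_point"]

#: named default sampling parameters: the lowest-seam product search uses a
#: wide-open window with many points; the cascade re-seeding uses few points
#: and excludes the immediate vicinity of the intersection
DEFAULTS = {
    "lower_seam": {"n": 500, "R": 0.075, "gap_window": (0.0, 0.5)},
    "cascade": {"n": 10, "R": 0.075, "gap_window": (0.1, 0.5)},
}


@dataclass
class ConeSample:
    """One branching-plane displacement and its adiabatic energies."""

    b: float
    c: float
    l: float
    alpha: float
    geometry: Geometry
    gap: float
    lower_energy: float
    upper_energy: float
    meci_id: str = ""


def cone_point(meci: MECIRecord, b: float, c: float, R: float) -> np.ndarray:
    """Deterministic displacement for given uniform variates (b, c)."""
    l = c * R
    alpha = 2.0 * np.pi * b
    return (meci.geometry.coords
            + l * np.cos(alpha) * meci.g_vec
            + l * np.sin(alpha) * meci.h_vec)


def sample_cone(model: SurfaceModel, meci: MECIRecord, R: float = 0.075,
                n: int = 500, gap_window: tuple[float, float] | None = (0.0, 0.5),
                seed: int = 0, draw_budget_factor: int = 100) -> list[ConeSample]:
    """Draw ``n`` accepted cone points around a converged MECI.

    (b, c) pairs come from a seeded uniform stream; with a gap window,
    points are rejection-sampled until ``n`` satisfy
    ``lo <= gap <= hi``.  Raises ``RuntimeError`` (reporting the achieved
    acceptance rate) if the draw budget ``draw_budget_factor * n`` is
    exhausted — the signature of a radius mis-sized for the window.
    """
    if not meci.converged:
        raise ValueError("cone sampling requires a converged MECI")
    if R <= 0 or n < 1:
        raise ValueError("R must be > 0 and n >= 1")
    if gap_window is not None and not gap_window[0] < gap_window[1]:
        raise ValueError("gap window must satisfy lo < hi")
    i, j = meci.state_pair
    rng = np.random.default_rng(seed)
    out: list[ConeSample] = []
    draws = 0
    budget = draw_budget_factor * n
    while len(out) < n:
        if draws >= budget:
            rate = len(out) / draws if draws else 0.0
            raise RuntimeError(
                f"cone sampling exhausted draw budget ({budget}); "
                f"acceptance rate {rate:.3f} — radius R={R} is mis-sized "
                f"for gap window {gap_window}")
        b, c = rng.uniform(), rng.uniform()
        draws += 1
        coords = cone_point(meci, b, c, R)
        pt = model.evaluate(coords)
        gap = pt.gap(i, j)
        if gap_window is not None and not (gap_window[0] <= gap <= gap_window[1]):
            continue
        out.append(ConeSample(b=b, c=c, l=c * R, alpha=2.0 * np.pi * b,
                              geometry=model.geometry(coords), gap=gap,
                              lower_energy=float(pt.energies[i]),
                              upper_energy=float(pt.energies[j]),
                              meci_id=meci.meci_id))
    return out
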