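"""Multi-state model potential surfaces with exact analytic derivatives.

Every packaged surface is defined by a symmetric diabatic matrix H(x) whose
entries (and their gradients) are analytic.  Adiabatic states come from the
eigendecomposition H v_i = E_i v_i; gradients follow from Hellmann-Feynman,

    dE_i/dx = v_i^T (dH/dx) v_i,

and first-derivative couplings from

    d_ij = v_i^T (dH/dx) v_j / (E_j - E_i),    E_j != E_i.

The numerator v_i^T (dH) v_j stays finite through a crossing and is stored
separately so branching-plane construction never divides by a vanishing gap.

External engines can plug in by subclassing :class:`SurfaceModel` and
implementing :meth:`evaluate` directly; nothing downstream assumes analytic
diabats (the g/h construction falls back to gradient differences and
coupling vectors when no diabatic matrix is available).

Packaged families
-----------------
``jt_cone``
    Linear vibronic two-state cone in 2-D (Jahn-Teller E x e form) with an
    optional energy tilt ``s`` along x that makes the intersection sloped.
``jt_cone_3d``
    The cone plus a third coordinate carrying opposite-sign linear diagonal
    terms, turning the single intersection point into a one-dimensional seam
    line with a unique minimum-energy crossing.
``two_state_photo``
    A Muller-Brown-style sum of anisotropic Gaussian wells as the lower
    diabat, a displaced and offset copy as the upper diabat, and a tiny
    constant coupling: a two-dimensional caricature of a photochemical
    landscape with several ground-state products and a curved seam holding
    more than one seam minimum.
``three_state_cascade``
    Three diabats in 2-D (a double-well ground state and two displaced
    excited paraboloids) with y-proportional couplings, giving both an
    S2/S1 and an S0/S1 crossing below the Franck-Condon point — the test
    bed for the cascade protocol.
``particle_cluster``
    N identical 3-D particles bound by pairwise Morse interactions, upper
    state displaced in the pair distance; exercises permutation-aware
    alignment.
"""

from __future__ import annotations

import itertools
from abc import ABC, abstractmethod

import numpy as np

from .geometry import AdiabaticPoint, Geometry

__all__ = ["SurfaceModel", "AnalyticDiabaticModel", "make_model", "MODEL_FAMILIES"]

#: gap below which a state pair is treated as exactly degenerate and the
#: 1/(E_j - E_i) coupling is flagged undefined
DEGENERACY_GAP = 1e-12


class SurfaceModel(ABC):
    """Interface every potential-surface backend satisfies.

    Attributes
    ----------
    n_states, n_coords : int
    n_particles, dim : particle structure of valid geometries
    labels : per-particle tags
    energy_unit, length_unit : declared unit names (model units by default)
    """

    name: str = "surface"
    energy_unit: str = "model"
    length_unit: str = "model"

    n_states: int
    n_coords: int
    n_particles: int = 1
    dim: int = 0
    labels: tuple[str, ...] = ()

    def __init__(self):
        if not self.dim:
            self.dim = self.n_coords
        if not self.labels:
            self.labels = ("X",) * self.n_particles

    @property
    def params(self) -> dict:
        return dict(getattr(self, "_params", {}))

    def geometry(self, coords) -> Geometry:
        """Wrap a raw coordinate vector in this model's particle structure."""
        return Geometry(np.asarray(coords, dtype=float).ravel(),
                        self.n_particles, self.dim, self.labels)

    def _check(self, g) -> np.ndarray:
        x = g.coords if isinstance(g, Geometry) else np.asarray(g, dtype=float).ravel()
        if x.size != self.n_coords:
            raise ValueError(
                f"geometry has {x.size} coordinates, model expects {self.n_coords}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        return x

    @abstractmethod
    def evaluate(self, g) -> AdiabaticPoint:
        """Adiabatic energies/gradients/couplings at geometry ``g``."""


class AnalyticDiabaticModel(SurfaceModel):
    """Surface defined by an analytic diabatic matrix and its gradient."""

    @abstractmethod
    def diabatic(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (H, dH) with H (n_states, n_states) symmetric and
        dH (n_states, n_states, n_coords)."""

    def evaluate(self, g) -> AdiabaticPoint:
        x = self._check(g)
        H, dH = self.diabatic(x)
        energies, vecs = np.linalg.eigh(H)
        # deterministic sign: largest-magnitude component of each vector > 0
        for i in range(vecs.shape[1]):
            k = int(np.argmax(np.abs(vecs[:, i])))
            if vecs[k, i] < 0:
                vecs[:, i] = -vecs[:, i]
        n, nc = self.n_states, self.n_coords
        # numer[a, b, :] = v_a^T dH v_b  (symmetric in a, b)
        numer = np.einsum("ia,ijc,jb->abc", vecs, dH, vecs)
        gradients = numer[np.arange(n), np.arange(n), :]
        nac = np.zeros((n, n, nc))
        defined = ~np.eye(n, dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            de = energies[j] - energies[i]
            if abs(de) < DEGENERACY_GAP:
                defined[i, j] = defined[j, i] = False
            else:
                nac[i, j] = numer[i, j] / de
                nac[j, i] = -nac[i, j]
        return AdiabaticPoint(energies=energies, gradients=gradients,
                              nac=nac, coupling_numerator=numer,
                              nac_defined=defined)


# ---------------------------------------------------------------------------
# jt_cone / jt_cone_3d

class JahnTellerCone(AnalyticDiabaticModel):
    """Linear vibronic cone: H11/22 = (w/2) r^2 +/- kappa x + s x, H12 = lam y.

    Adiabatic energies are (w/2) r^2 + s x -/+ sqrt(kappa^2 x^2 + lam^2 y^2):
    a conical intersection at the origin, peaked for s = 0 and sloped with
    slopeness exactly |s| otherwise.
    """

    name = "jt_cone"
    n_states = 2
    n_coords = 2
    n_particles = 1

    def __init__(self, omega: float = 1.0, kappa: float = 1.0,
                 lam: float = 1.0, s: float = 0.0):
        if omega <= 0:
            raise ValueError("omega must be > 0")
        if kappa == 0 or lam == 0:
            raise ValueError(
                "kappa and lam must be nonzero (a zero coupling makes the "
                "cone degenerate along a whole axis)")
        self.omega, self.kappa, self.lam, self.s = (
            float(omega), float(kappa), float(lam), float(s))
        self._params = {"omega": omega, "kappa": kappa, "lam": lam, "s": s}
        super().__init__()

    def diabatic(self, x):
        xx, yy = x
        w, k, lm, s = self.omega, self.kappa, self.lam, self.s
        base = 0.5 * w * (xx * xx + yy * yy) + s * xx
        H = np.array([[base + k * xx, lm * yy],
                      [lm * yy, base - k * xx]])
        dbase = np.array([w * xx + s, w * yy])
        dH = np.zeros((2, 2, 2))
        dH[0, 0] = dbase + [k, 0.0]
        dH[1, 1] = dbase - [k, 0.0]
        dH[0, 1] = dH[1, 0] = [0.0, lm]
        return H, dH


class JahnTellerCone3D(JahnTellerCone):
    """Cone plus a z coordinate with diagonal terms (w/2) z^2 +/- a z.

    The degeneracy condition (kappa x + a z = 0, y = 0) is now a line: a 1-D
    seam through coordinate space with a single minimum-energy crossing
    whose location follows analytically from minimizing the mean energy
    along the seam.
    """

    name = "jt_cone_3d"
    n_coords = 3

    def __init__(self, omega: float = 1.0, kappa: float = 1.0, lam: float = 1.0,
                 s: float = 0.3, a: float = 0.5):
        if a == 0:
            raise ValueError("a must be nonzero (otherwise z decouples and "
                             "the seam degenerates)")
        super().__init__(omega=omega, kappa=kappa, lam=lam, s=s)
        self.a = float(a)
        self._params["a"] = a
        self.dim = 3

    def diabatic(self, x):
        xx, yy, zz = x
        w, k, lm, s, a = self.omega, self.kappa, self.lam, self.s, self.a
        base = 0.5 * w * (xx * xx + yy * yy + zz * zz) + s * xx
        H = np.array([[base + k * xx + a * zz, lm * yy],
                      [lm * yy, base - k * xx - a * zz]])
        dbase = np.array([w * xx + s, w * yy, w * zz])
        dH = np.zeros((2, 2, 3))
        dH[0, 0] = dbase + [k, 0.0, a]
        dH[1, 1] = dbase - [k, 0.0, a]
        dH[0, 1] = dH[1, 0] = [0.0, lm, 0.0]
        return H, dH


# ---------------------------------------------------------------------------
# two_state_photo

# Muller-Brown well parameters (A, a, b, c, x0, y0)
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def _mb_value_grad(x, y):
    dx = x - _MB_x0
    dy = y - _MB_y0
    e = _MB_A * np.exp(_MB_a * dx * dx + _MB_b * dx * dy + _MB_c * dy * dy)
    v = float(np.sum(e))
    gx = float(np.sum(e * (2.0 * _MB_a * dx + _MB_b * dy)))
    gy = float(np.sum(e * (_MB_b * dx + 2.0 * _MB_c * dy)))
    return v, gx, gy


class TwoStatePhoto(AnalyticDiabaticModel):
    """Photochemical toy landscape built on the Muller-Brown surface.

    Lower diabat: scale * MB(x, y).  Upper diabat: the same surface
    displaced by (dx, dy) and raised by ``offset``.  The diabats cross along
    a curve (the seam); a small constant coupling ``gamma`` keeps the
    adiabatic evaluation well conditioned while leaving a minimum adiabatic
    gap of 2*gamma, far below every tolerance used downstream.

    The lower adiabatic state keeps the three Muller-Brown minima — the
    "photoproducts" — and the seam supports more than one local minimum of
    the mean energy, so both seam hopping and product branching can be
    exercised at desk scale.
    """

    name = "two_state_photo"
    n_states = 2
    n_coords = 2
    n_particles = 1

    def __init__(self, scale: float = 0.01, dx: float = 0.45, dy: float = -0.3,
                 offset: float = 0.35, gamma: float = 1e-6):
        if scale <= 0:
            raise ValueError("scale must be > 0")
        if gamma < 0:
            raise ValueError("gamma must be >= 0")
        if dx == 0 and dy == 0:
            raise ValueError("upper diabat must be displaced")
        self.scale = float(scale)
        self.dx, self.dy = float(dx), float(dy)
        self.offset = float(offset)
        self.gamma = float(gamma)
        self._params = {"scale": scale, "dx": dx, "dy": dy,
                        "offset": offset, "gamma": gamma}
        super().__init__()

    def lower_diabat(self, x, y):
        v, gx, gy = _mb_value_grad(x, y)
        return self.scale * v, self.scale * gx, self.scale * gy

    def upper_diabat(self, x, y):
        v, gx, gy = _mb_value_grad(x - self.dx, y - self.dy)
        return self.scale * v + self.offset, self.scale * gx, self.scale * gy

    def diabatic(self, x):
        xx, yy = x
        v1, g1x, g1y = self.lower_diabat(xx, yy)
        v2, g2x, g2y = self.upper_diabat(xx, yy)
        H = np.array([[v1, self.gamma], [self.gamma, v2]])
        dH = np.zeros((2, 2, 2))
        dH[0, 0] = [g1x, g1y]
        dH[1, 1] = [g2x, g2y]
        return H, dH


# ---------------------------------------------------------------------------
# three_state_cascade

class ThreeStateCascade(AnalyticDiabaticModel):
    """Three diabats in 2-D supporting an S2/S1 and an S0/S1 crossing.

    Ground diabat: double well b (x^2 - 1)^2 + (w/2) y^2 (two products at
    x = +/-1).  Excited diabats: paraboloids displaced along x and offset in
    energy.  Couplings H01 and H12 are proportional to y, so each diabatic
    crossing line carries a conical intersection at y = 0.  Both crossings
    lie below the S2 energy at the Franck-Condon point (the ground-state
    minimum at x = -1), enabling the full cascade protocol.
    """

    name = "three_state_cascade"
    n_states = 3
    n_coords = 2
    n_particles = 1

    def __init__(self, barrier: float = 1.2, omega: float = 1.2,
                 d1: float = 0.1, e1: float = 0.9, w1: float = 0.8,
                 d2: float = -0.5, e2: float = 0.95, w2: float = 2.0,
                 c01: float = 0.25, c12: float = 0.25):
        if barrier <= 0 or omega <= 0 or w1 <= 0 or w2 <= 0:
            raise ValueError("curvatures must be positive")
        if c01 == 0 or c12 == 0:
            raise ValueError("couplings c01 and c12 must be nonzero")
        self.barrier, self.omega = float(barrier), float(omega)
        self.d1, self.e1, self.w1 = float(d1), float(e1), float(w1)
        self.d2, self.e2, self.w2 = float(d2), float(e2), float(w2)
        self.c01, self.c12 = float(c01), float(c12)
        self._params = {"barrier": barrier, "omega": omega, "d1": d1, "e1": e1,
                        "w1": w1, "d2": d2, "e2": e2, "w2": w2,
                        "c01": c01, "c12": c12}
        super().__init__()

    def diabatic(self, x):
        xx, yy = x
        b, w = self.barrier, self.omega
        v0 = b * (xx * xx - 1.0) ** 2 + 0.5 * w * yy * yy
        g0 = np.array([4.0 * b * xx * (xx * xx - 1.0), w * yy])
        v1 = 0.5 * self.w1 * ((xx - self.d1) ** 2 + yy * yy) + self.e1
        g1 = np.array([self.w1 * (xx - self.d1), self.w1 * yy])
        v2 = 0.5 * self.w2 * ((xx - self.d2) ** 2 + yy * yy) + self.e2
        g2 = np.array([self.w2 * (xx - self.d2), self.w2 * yy])
        H = np.array([[v0, self.c01 * yy, 0.0],
                      [self.c01 * yy, v1, self.c12 * yy],
                      [0.0, self.c12 * yy, v2]])
        dH = np.zeros((3, 3, 2))
        dH[0, 0] = g0
        dH[1, 1] = g1
        dH[2, 2] = g2
        dH[0, 1] = dH[1, 0] = [0.0, self.c01]
        dH[1, 2] = dH[2, 1] = [0.0, self.c12]
        return H, dH

    def franck_condon(self) -> Geometry:
        """Ground-state minimum at x = -1 (photoexcitation start)."""
        return self.geometry([-1.0, 0.0])


# ---------------------------------------------------------------------------
# particle_cluster

class ParticleCluster(AnalyticDiabaticModel):
    """N identical 3-D particles, pairwise Morse lower state.

    Upper diabat uses a longer equilibrium pair distance plus a constant
    energy offset (a bound-to-stretched excitation caricature); constant
    coupling gamma.  Used chiefly to exercise permutation-aware alignment
    and the XYZ file path.
    """

    name = "particle_cluster"
    n_states = 2

    def __init__(self, n: int = 4, depth: float = 1.0, alpha: float = 1.5,
                 r0: float = 1.0, shift: float = 0.3, offset: float = 0.5,
                 gamma: float = 0.02):
        if n < 2:
            raise ValueError("need at least 2 particles")
        if depth <= 0 or alpha <= 0 or r0 <= 0:
            raise ValueError("depth, alpha and r0 must be positive")
        self.n = int(n)
        self.depth, self.alpha, self.r0 = float(depth), float(alpha), float(r0)
        self.shift, self.offset, self.gamma = float(shift), float(offset), float(gamma)
        self.n_particles = self.n
        self.dim = 3
        self.n_coords = 3 * self.n
        self.labels = ("M",) * self.n
        self._params = {"n": n, "depth": depth, "alpha": alpha, "r0": r0,
                        "shift": shift, "offset": offset, "gamma": gamma}
        super().__init__()

    def _morse_sum(self, pos, r0):
        d, a = self.depth, self.alpha
        v = 0.0
        grad = np.zeros_like(pos)
        for i, j in itertools.combinations(range(self.n), 2):
            rij = pos[i] - pos[j]
            r = float(np.linalg.norm(rij))
            ex = np.exp(-a * (r - r0))
            v += d * (1.0 - ex) ** 2
            dvdr = 2.0 * d * (1.0 - ex) * a * ex
            u = rij / r
            grad[i] += dvdr * u
            grad[j] -= dvdr * u
        return v, grad.ravel()

    def diabatic(self, x):
        pos = x.reshape(self.n, 3)
        v1, g1 = self._morse_sum(pos, self.r0)
        v2, g2 = self._morse_sum(pos, self.r0 + self.shift)
        H = np.array([[v1, self.gamma], [self.gamma, v2 + self.offset]])
        dH = np.zeros((2, 2, self.n_coords))
        dH[0, 0] = g1
        dH[1, 1] = g2
        return H, dH

    def tetrahedron(self, r: float | None = None) -> Geometry:
        """Regular simplex-ish start geometry with pair distance r."""
        r = self.r0 if r is None else r
        base = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                         [0.5, np.sqrt(3) / 2, 0.0],
                         [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])
        pts = base[: self.n] * r
        if self.n > 4:
            extra = base[1] + base[2] - base[3]
            pts = np.vstack([pts, (extra * r)[None, :]])[: self.n]
        return self.geometry(pts.ravel())


MODEL_FAMILIES = {
    "jt_cone": JahnTellerCone,
    "jt_cone_3d": JahnTellerCone3D,
    "two_state_photo": TwoStatePhoto,
    "three_state_cascade": ThreeStateCascade,
    "particle_cluster": ParticleCluster,
}


def make_model(name: str, **params) -> SurfaceModel:
    """Construct a packaged model surface by family name.

    Raises ``ValueError`` for unknown names or parameters violating the
    family constraints (e.g. a coupling of zero that would make the
    intersection degenerate along a whole axis).
    """
    try:
        cls = MODEL_FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model family {name!r}; available: "
            f"{sorted(MODEL_FAMILIES)}") from None
    return cls(**params)
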