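"""Seam-constrained metadynamics: step 1 of the discovery phase.

A trajectory is propagated on the mean energy of a chosen state pair with a
restraint that binds it to the intersection seam, while Gaussian bias in an
aligned-RMSD collective variable is deposited periodically to push the
walker out of already-visited seam basins.

Seam restraint
--------------
The penalty on the adiabatic gap is harmonic below a threshold ``delta``
and linear above it, C1-continuous at the switch:

    V(gap) = (k/2) gap^2                      for gap <  delta
    V(gap) = k delta gap - (k/2) delta^2      for gap >= delta

The linear branch keeps the restoring force bounded far from the seam
(no catastrophic forces when the walker is launched from the
Franck-Condon point), while the harmonic branch leaves the seam itself
penalty- and force-free.

Integration is velocity Verlet started with zero velocity, thermostatted by
stochastic velocity rescaling (Bussi-Parrinello) with a single global
factor; k_B = 1 in model units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import align_rmsd, rmsd_gradient
from .geometry import Geometry
from .models import SurfaceModel

__all__ = ["SeamConstraint", "BiasPotential", "MDParams", "Trajectory",
           "seam_penalty", "bias_energy_forces", "propagate_seam_md"]


@dataclass
class SeamConstraint:
    """Linear/harmonic gap restraint.

    ``delta`` is the gap threshold (energy unit; the harmonic-to-linear
    switch) and ``k`` the curvature of the harmonic branch.
    """

    delta: float = 0.1
    k: float = 100.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def seam_penalty(gap: float, c: SeamConstraint) -> tuple[float, float]:
    """Penalty energy and d(penalty)/d(gap) for a non-negative gap."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if gap < c.delta:
        return 0.5 * c.k * gap * gap, c.k * gap
    return c.k * c.delta * gap - 0.5 * c.k * c.delta ** 2, c.k * c.delta


@dataclass
class BiasPotential:
    """Sum of Gaussian hills in the aligned-RMSD collective variable.

    E_bias(x) = sum_k  w * exp(-RMSD(x, ref_k)^2 / (2 dw^2)).

    Deposited reference frames are stored aligned to the run's start frame,
    which keeps the bias invariant to rigid motion of the walker.
    """

    height: float = 0.025
    width: float = 0.1
    deposit_stride: int = 50
    allow_permutations: bool = False
    references: list[Geometry] = field(default_factory=list)

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("bias height and width must be positive")
        if self.deposit_stride < 1:
            raise ValueError("deposit_stride must be >= 1")

    def deposit(self, g: Geometry, start: Geometry | None = None):
        """Add a hill at ``g`` (stored aligned to ``start`` if given)."""
        if start is not None and g.n_particles > 1:
            res = align_rmsd(start, g, self.allow_permutations)
            g = g.with_coords(res.apply(g).ravel())
        if self.references and g.signature() != self.references[0].signature():
            raise ValueError("frame signature mismatch in bias deposit")
        self.references.append(g)


def bias_energy_forces(bias: BiasPotential, g: Geometry) -> tuple[float, np.ndarray]:
    """Bias energy and force (= -dE/dx) at geometry ``g``."""
    forces = np.zeros(g.n_coords)
    if not bias.references:
        return 0.0, forces
    if g.signature() != bias.references[0].signature():
        raise ValueError("geometry incompatible with bias reference frames")
    energy = 0.0
    w2 = bias.width ** 2
    if g.n_particles == 1:
        # abstract coordinate vector: Euclidean CV, fully vectorized
        refs = np.stack([ref.coords for ref in bias.references])
        diff = g.coords[None, :] - refs
        e = bias.height * np.exp(-np.sum(diff * diff, axis=1) / (2.0 * w2))
        return float(np.sum(e)), (e[:, None] * diff).sum(axis=0) / w2
    for ref in bias.references:
        r = align_rmsd(ref, g, bias.allow_permutations).rmsd
        e = bias.height * np.exp(-r * r / (2.0 * w2))
        energy += e
        if r > 1e-14:
            grad_r = rmsd_gradient(ref, g, bias.allow_permutations)
            forces += e * (r / w2) * grad_r
    return float(energy), forces


@dataclass
class MDParams:
    """Integration parameters for the seam metadynamics.

    ``temperature`` is in model energy units with k_B = 1 (default 0.05,
    playing the role of 300 K for surfaces with well depths of order one).
    ``surface`` selects the propagated potential: ``"seam_mean"`` (mean
    energy of the pair plus gap penalty; default) or ``"upper"`` (upper
    state of the pair plus gap penalty).
    """

    temperature: float = 0.05
    timestep: float = 0.01
    n_steps: int = 1000
    tau: float = 0.5
    seed: int = 0
    mass: float = 1.0
    state_pair: tuple[int, int] = (0, 1)
    save_stride: int = 1
    surface: str = "seam_mean"

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        i, j = self.state_pair
        if not (0 <= i < j):
            raise ValueError("state_pair must satisfy i < j")
        if self.surface not in ("seam_mean", "upper"):
            raise ValueError("surface must be 'seam_mean' or 'upper'")


@dataclass
class Trajectory:
    """Logged frames and energy components of one seam-MD run."""

    frames: list[Geometry]
    steps: np.ndarray                # saved step indices
    state_energies: np.ndarray       # (n_frames, 2) energies of the pair
    gaps: np.ndarray                 # (n_frames,)
    bias_energies: np.ndarray        # (n_frames,)
    penalty_energies: np.ndarray     # (n_frames,)
    kinetic_energies: np.ndarray     # (n_frames,)
    conserved: np.ndarray            # (n_frames,) thermostat-corrected energy
    cv_from_start: np.ndarray        # (n_frames,) aligned RMSD to frame 0
    params: MDParams = None
    constraint: SeamConstraint = None
    bias: BiasPotential = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _bussi_factor(K: float, K_target: float, ndof: int, c: float,
                  rng: np.random.Generator) -> float:
    """Stochastic velocity rescaling factor (global, canonical sampling)."""
    r1 = rng.standard_normal()
    s = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
    K_new = (K + (1.0 - c) * (K_target * (r1 * r1 + s) / ndof - K)
             + 2.0 * r1 * np.sqrt(K * K_target * c * (1.0 - c) / ndof))
    return np.sqrt(max(K_new, 0.0) / K)


def propagate_seam_md(model: SurfaceModel, start: Geometry, params: MDParams,
                      constraint: SeamConstraint,
                      bias: BiasPotential | None = None) -> Trajectory:
    """Velocity-Verlet seam metadynamics, deterministic for a fixed seed.

    The effective potential is the selected surface of the state pair plus
    the seam penalty plus the metadynamics bias; initial velocities are
    zero.  A Gaussian hill is deposited every ``bias.deposit_stride`` steps
    at the current frame.  Raises ``FloatingPointError`` naming the step
    index if a non-finite energy or force is encountered.
    """
    i, j = params.state_pair
    if j >= model.n_states:
        raise ValueError("state pair outside model's state count")
    x = np.array(model._check(start), dtype=float)
    start = model.geometry(x)
    rng = np.random.default_rng(params.seed)
    ndof = x.size
    masses = np.full(ndof, params.mass)
    v = np.zeros(ndof)
    kT = params.temperature
    K_target = 0.5 * ndof * kT
    c_ts = np.exp(-params.timestep / params.tau)

    def eval_forces(xvec):
        pt = model.evaluate(xvec)
        gap = pt.gap(i, j)
        pen, dpen = seam_penalty(gap, constraint)
        if params.surface == "upper":
            pot = float(pt.energies[j])
            grad = pt.gradients[j].copy()
        else:
            pot = pt.mean_energy(i, j)
            grad = pt.mean_gradient(i, j)
        grad = grad + dpen * pt.gap_gradient(i, j)
        e_bias, f_bias = (0.0, 0.0)
        if bias is not None:
            e_bias, f_bias = bias_energy_forces(bias, model.geometry(xvec))
        force = -grad + f_bias
        return pt, gap, pot, pen, e_bias, force

    pt, gap, pot, pen, e_bias, force = eval_forces(x)

    frames, steps = [], []
    e_states, gaps, biases, pens, kins, cons, cvs = ([] for _ in range(7))
    thermo_work = 0.0

    def record(step, K):
        frames.append(model.geometry(x.copy()))
        steps.append(step)
        e_states.append([pt.energies[i], pt.energies[j]])
        gaps.append(gap)
        biases.append(e_bias)
        pens.append(pen)
        kins.append(K)
        cons.append(K + pot + pen + e_bias - thermo_work)
        cvs.append(align_rmsd(start, frames[-1],
                              bias.allow_permutations if bias else False).rmsd)

    for step in range(1, params.n_steps + 1):
        if not (np.all(np.isfinite(force)) and np.isfinite(pot)):
            raise FloatingPointError(
                f"non-finite energy/force at step {step - 1}")
        # half kick + drift
        v = v + 0.5 * params.timestep * force / masses
        x = x + params.timestep * v
        pt, gap, pot, pen, e_bias, force = eval_forces(x)
        v = v + 0.5 * params.timestep * force / masses
        # thermostat
        K = 0.5 * float(np.sum(masses * v * v))
        if kT > 0:
            if K <= 1e-300:
                # cold start (zero velocity): seed Maxwell velocities at the
                # partial-coupling temperature instead of rescaling zero
                v = rng.standard_normal(ndof) * np.sqrt(
                    kT * (1.0 - c_ts) / masses)
            else:
                v *= _bussi_factor(K, K_target, ndof, c_ts, rng)
            K_new = 0.5 * float(np.sum(masses * v * v))
            thermo_work += K_new - K
            K = K_new
        # deposit bias at the current frame
        if bias is not None and step % bias.deposit_stride == 0:
            bias.deposit(model.geometry(x.copy()), start)
            pt, gap, pot, pen, e_bias, force = eval_forces(x)
        if step % params.save_stride == 0:
            record(step, K)

    return Trajectory(frames=frames, steps=np.array(steps),
                      state_energies=np.array(e_states), gaps=np.array(gaps),
                      bias_energies=np.array(biases),
                      penalty_energies=np.array(pens),
                      kinetic_energies=np.array(kins),
                      conserved=np.array(cons), cv_from_start=np.array(cvs),
                      params=params, constraint=constraint, bias=bias)
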