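"""Core coordinate containers shared by every stage of the pipeline.

A :class:`Geometry` is a flat coordinate vector with optional particle
structure (``n_particles`` points in ``dim`` dimensions) and per-particle
labels.  Abstract low-dimensional model surfaces use a single "particle"
whose dimension equals the number of coordinates; particle models (e.g. the
Morse cluster) use ``dim = 3`` and meaningful labels so that
permutation-aware alignment can identify interchangeable particles.

An :class:`AdiabaticPoint` bundles everything an electronic-structure
evaluation returns at one geometry: adiabatic energies (ascending), one
gradient per state, and the pairwise nonadiabatic coupling vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "AdiabaticPoint"]


@dataclass(frozen=True)
class Geometry:
    """Flat coordinate vector with optional particle structure.

    Parameters
    ----------
    coords:
        Flat array of ``n_particles * dim`` real coordinates (model length
        unit).
    n_particles:
        Number of particles (>= 1).
    dim:
        Spatial dimension per particle (1-3).
    labels:
        Per-particle identity tags; particles sharing a label are
        interchangeable under permutation-aware alignment.
    """

    coords: np.ndarray
    n_particles: int = 1
    dim: int = 0
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).ravel()
        object.__setattr__(self, "coords", coords)
        dim = self.dim if self.dim else coords.size // max(self.n_particles, 1)
        object.__setattr__(self, "dim", dim)
        labels = tuple(self.labels) if self.labels else ("X",) * self.n_particles
        object.__setattr__(self, "labels", labels)
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not (1 <= self.dim <= 3) and self.n_particles > 1:
            raise ValueError("dim must be 1, 2 or 3 for particle systems")
        if coords.size != self.n_particles * self.dim:
            raise ValueError(
                f"coords has length {coords.size}, expected "
                f"{self.n_particles} x {self.dim}"
            )
        if len(labels) != self.n_particles:
            raise ValueError("labels length must equal n_particles")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_coords(self) -> int:
        return self.coords.size

    def as_matrix(self) -> np.ndarray:
        """Return coordinates as an (n_particles, dim) matrix."""
        return self.coords.reshape(self.n_particles, self.dim)

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        """Copy of this geometry with new coordinates, same structure."""
        return Geometry(np.asarray(coords, dtype=float).ravel(),
                        self.n_particles, self.dim, self.labels)

    def signature(self) -> tuple:
        """Structural identity used to check frame compatibility."""
        return (self.n_particles, self.dim, tuple(sorted(self.labels)))

    def __eq__(self, other):
        if not isinstance(other, Geometry):
            return NotImplemented
        return (self.n_particles == other.n_particles
                and self.dim == other.dim
                and self.labels == other.labels
                and np.array_equal(self.coords, other.coords))


@dataclass
class AdiabaticPoint:
    """Adiabatic energies, gradients and couplings at one geometry.

    ``energies`` are sorted ascending.  ``nac[i, j]`` is the first-derivative
    coupling vector d_ij = <psi_i | d psi_j / dR>, antisymmetric in (i, j);
    it diverges as 1/(E_j - E_i) near a degeneracy, so ``coupling_numerator``
    additionally stores the finite Hellmann-Feynman numerator
    v_i^T (dH) v_j which stays well behaved through a crossing.
    ``nac_defined[i, j]`` is False for pairs flagged as exactly degenerate.
    """

    energies: np.ndarray                  # (n_states,)
    gradients: np.ndarray                 # (n_states, n_coords)
    nac: np.ndarray                       # (n_states, n_states, n_coords)
    coupling_numerator: np.ndarray        # (n_states, n_states, n_coords)
    nac_defined: np.ndarray = field(default=None)  # (n_states, n_states) bool

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.nac_defined is None:
            n = self.energies.size
            self.nac_defined = ~np.eye(n, dtype=bool)

    @property
    def n_states(self) -> int:
        return self.energies.size

    def gap(self, i: int, j: int) -> float:
        """Absolute adiabatic energy difference |E_j - E_i|."""
        return abs(float(self.energies[j] - self.energies[i]))

    def mean_energy(self, i: int, j: int) -> float:
        return 0.5 * float(self.energies[i] + self.energies[j])

    def mean_gradient(self, i: int, j: int) -> np.ndarray:
        return 0.5 * (self.gradients[i] + self.gradients[j])

    def gap_gradient(self, i: int, j: int) -> np.ndarray:
        """Gradient of E_j - E_i (signed; j > i gives the ascending gap)."""
        return self.gradients[j] - self.gradients[i]
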