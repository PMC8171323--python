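"""Optimal superposition, RMSD, RMSD gradients, permutation-aware distances.

The aligned RMSD is the collective variable of the seam metadynamics and the
distance used when clustering harvested seam frames and deduplicating
intersections and products.  For 3-D particle systems superposition uses the
Kabsch construction (SVD with the determinant +1 constraint, equivalent to
the quaternion method); 2-D systems use the planar analogue; abstract
single-vector geometries bypass alignment entirely and use the plain
Euclidean distance.

Reflections are never allowed (rotation determinant is forced to +1), so
mirror-image structures are treated as distinct — photoproducts may be
chiral.  RMSD is mass-unweighted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Geometry

__all__ = ["AlignmentResult", "align_rmsd", "rmsd_gradient", "aligned_distance"]

#: exhaustive permutation search up to this many interchangeable particles
#: per label group; larger groups use the iterated Hungarian assignment
EXHAUSTIVE_LIMIT = 6


@dataclass
class AlignmentResult:
    """Minimal-RMSD superposition of a mobile geometry onto a reference.

    ``aligned = rotation @ (mobile[permutation[i]] - mobile_centroid)
    + ref_centroid`` matches ``ref[i]``.  ``rmsd`` is the per-particle
    root-mean-square residual (length unit); the rotation is proper
    (det = +1) and the permutation maps only between identical labels.
    """

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    permutation: np.ndarray

    def apply(self, mobile: Geometry) -> np.ndarray:
        """Return the aligned mobile coordinates as an (n, d) matrix."""
        m = mobile.as_matrix()[self.permutation]
        return m @ self.rotation.T + self.translation


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||R q_i - p_i|| for centered P, Q."""
    H = Q.T @ P
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(P.shape[1])
    D[-1, -1] = d
    return Vt.T @ D @ U.T


def _superpose(ref_c: np.ndarray, mob_c: np.ndarray) -> tuple[float, np.ndarray]:
    """RMSD and rotation for centered coordinate matrices (fixed order)."""
    if ref_c.shape[1] == 1:
        R = np.eye(1)
    else:
        R = _kabsch(ref_c, mob_c)
    diff = mob_c @ R.T - ref_c
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1)))), R


def _label_groups(labels) -> list[np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return [np.array(v) for v in groups.values()]


def _check_compatible(ref: Geometry, mobile: Geometry):
    if ref.n_particles != mobile.n_particles or ref.dim != mobile.dim:
        raise ValueError("particle count / dimension mismatch")
    if sorted(ref.labels) != sorted(mobile.labels):
        raise ValueError("label multiset mismatch")


def align_rmsd(ref: Geometry, mobile: Geometry,
               allow_permutations: bool = False) -> AlignmentResult:
    """Minimal-RMSD superposition of ``mobile`` onto ``ref``.

    With ``allow_permutations`` the RMSD is additionally minimized over
    reassignments of identical-label particles: exhaustively for groups of
    up to 6 interchangeable particles, otherwise by a Hungarian assignment
    on the inter-particle distance matrix iterated with re-alignment until
    the assignment is stable.
    """
    _check_compatible(ref, mobile)
    n, d = ref.n_particles, ref.dim
    if n == 1:
        # abstract coordinate vector: no centering, no rotation
        delta = mobile.coords - ref.coords
        return AlignmentResult(rmsd=float(np.linalg.norm(delta)),
                               rotation=np.eye(d),
                               translation=ref.coords - mobile.coords,
                               permutation=np.array([0]))

    refm = ref.as_matrix()
    mobm = mobile.as_matrix()
    ref_cm = refm.mean(axis=0)
    mob_cm = mobm.mean(axis=0)
    ref_c = refm - ref_cm
    mob_c = mobm - mob_cm

    def eval_perm(perm: np.ndarray) -> tuple[float, np.ndarray]:
        return _superpose(ref_c, mob_c[perm])

    identity = np.arange(n)
    best_rmsd, best_R = eval_perm(identity)
    best_perm = identity

    if allow_permutations:
        groups = _label_groups(mobile.labels)
        # labels must agree positionally between ref and mobile for group
        # indices to be exchangeable
        if ref.labels != mobile.labels:
            raise ValueError("permutation-aware alignment requires "
                             "positionally matching labels")
        if all(len(g) <= EXHAUSTIVE_LIMIT for g in groups):
            for combo in itertools.product(
                    *[itertools.permutations(g) for g in groups]):
                perm = identity.copy()
                for g, pg in zip(groups, combo):
                    perm[g] = pg
                r, R = eval_perm(perm)
                if r < best_rmsd - 1e-15:
                    best_rmsd, best_R, best_perm = r, R, perm
        else:
            # warm start from a rotation-invariant feature assignment:
            # each particle described by its sorted distances to all others
            dref = np.sort(np.linalg.norm(
                ref_c[:, None, :] - ref_c[None, :, :], axis=2), axis=1)
            dmob = np.sort(np.linalg.norm(
                mob_c[:, None, :] - mob_c[None, :, :], axis=2), axis=1)
            warm = identity.copy()
            for g in groups:
                cost = np.linalg.norm(
                    dref[g][:, None, :] - dmob[g][None, :, :], axis=2)
                rows, cols = linear_sum_assignment(cost)
                warm[g[rows]] = g[cols]
            for perm0 in (warm, identity.copy()):
                perm = perm0
                for _ in range(50):
                    _, R = eval_perm(perm)
                    aligned = mob_c @ R.T
                    new_perm = identity.copy()
                    for g in groups:
                        cost = np.linalg.norm(
                            ref_c[g][:, None, :] - aligned[g][None, :, :],
                            axis=2)
                        rows, cols = linear_sum_assignment(cost)
                        new_perm[g[rows]] = g[cols]
                    if np.array_equal(new_perm, perm):
                        break
                    perm = new_perm
                r, R = eval_perm(perm)
                if r < best_rmsd:
                    best_rmsd, best_R, best_perm = r, R, perm

    translation = ref_cm - best_R @ mob_cm
    return AlignmentResult(rmsd=best_rmsd, rotation=best_R,
                           translation=translation, permutation=best_perm)


def aligned_distance(a: Geometry, b: Geometry,
                     allow_permutations: bool = False) -> float:
    """Convenience: the aligned RMSD between two geometries."""
    return align_rmsd(a, b, allow_permutations=allow_permutations).rmsd


def rmsd_gradient(ref: Geometry, mobile: Geometry,
                  allow_permutations: bool = False) -> np.ndarray:
    """Gradient of the aligned RMSD with respect to the mobile coordinates.

    Uses the envelope theorem: at the optimal rotation/translation (and a
    locally stable permutation) only the explicit dependence on the mobile
    coordinates survives.  At rmsd = 0 the gradient is defined as the zero
    vector (the RMSD has a conical minimum there).
    """
    res = align_rmsd(ref, mobile, allow_permutations=allow_permutations)
    if res.rmsd < 1e-14:
        return np.zeros(mobile.n_coords)
    n = ref.n_particles
    if n == 1:
        return (mobile.coords - ref.coords) / res.rmsd
    aligned = res.apply(mobile)          # rows match ref order
    resid = aligned - ref.as_matrix()    # (n, d)
    grad_aligned = resid / (n * res.rmsd)
    grad_mobile = np.zeros_like(grad_aligned)
    grad_mobile[res.permutation] = grad_aligned @ res.rotation
    return grad_mobile.ravel()
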