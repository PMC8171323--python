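"""Harvest, clustering, MECI optimization, branching planes, slopeness."""

import numpy as np
import pytest

from photoseam.geometry import Geometry
from photoseam.metadynamics import MDParams, SeamConstraint, propagate_seam_md
from photoseam.models import make_model
from photoseam.selection import (branching_plane, cluster_frames,
                                 dedupe_mecis, harvest_seam_frames,
                                 optimize_meci, slopeness)

from .oracles import polyline_local_minima, seam_polyline


def _photo_seam_minima(photo):
    """Seam minima of the photo landscape from the contour oracle."""
    def delta(x, y):
        return (photo.lower_diabat(x, y)[0] - photo.upper_diabat(x, y)[0])
    segments = seam_polyline(delta, (-1.8, 1.3), (-0.6, 2.2), n=600)
    minima = []
    for seg in segments:
        e = np.array([0.5 * (photo.lower_diabat(x, y)[0]
                             + photo.upper_diabat(x, y)[0])
                      for x, y in seg])
        for k in polyline_local_minima(seg, e):
            minima.append((seg[k][0], seg[k][1], e[k]))
    # merge duplicates from contour stitching
    unique = []
    for x, y, e in sorted(minima, key=lambda m: m[2]):
        if not any(np.hypot(x - u[0], y - u[1]) < 0.05 for u in unique):
            unique.append((x, y, e))
    return unique


class TestHarvest:
    def test_direct_filter(self, jt_cone):
        frames = [jt_cone.geometry([0.0, g / 2]) for g in (0.05, 0.2, 0.09)]
        traj = type("T", (), {})()
        traj.frames = frames
        traj.gaps = np.array([0.05, 0.2, 0.09])
        traj.n_frames = 3
        assert len(harvest_seam_frames(traj, 0.1)) == 2
        assert len(harvest_seam_frames(traj, 1.0)) == 3
        with pytest.raises(ValueError):
            harvest_seam_frames(traj, -1.0)

    def test_recount_against_sidecar(self, jt_cone):
        params = MDParams(n_steps=2000, temperature=0.05, seed=8)
        traj = propagate_seam_md(jt_cone, jt_cone.geometry([0.3, 0.0]),
                                 params, SeamConstraint(delta=0.05, k=100.0))
        kept = harvest_seam_frames(traj, 0.1)
        assert len(kept) == int(np.sum(traj.gaps < 0.1))


class TestClustering:
    def _blobs(self, rng, centers, n_per=30, sigma=0.01):
        frames = []
        for c in centers:
            for _ in range(n_per):
                frames.append(Geometry(np.array(c) + sigma
                                       * rng.normal(size=len(c)), 1, len(c)))
        return frames

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = [(0.0, 0.0), (1.5, 0.0), (0.0, 1.5)]
        frames = self._blobs(rng, centers)
        res = cluster_frames(frames, k_max=6, seed=0)
        assert res.chosen_k == 3
        for c in centers:
            d = min(np.linalg.norm(cf.coords - np.array(c))
                    for cf in res.centroids)
            assert d < 0.05

    def test_elbow_reproducible_across_seeds(self):
        rng = np.random.default_rng(1)
        frames = self._blobs(rng, [(0, 0), (1.5, 0), (0, 1.5)])
        ks = [cluster_frames(frames, 6, seed=s).chosen_k for s in (0, 1, 2)]
        assert ks == [3, 3, 3]

    def test_identical_frames_give_single_cluster(self):
        g = Geometry(np.array([0.1, 0.2]), 1, 2)
        res = cluster_frames([g] * 10, k_max=5, seed=0)
        assert res.chosen_k == 1

    def test_permuted_copies_collapse_with_alignment(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 3))
        frames = []
        for _ in range(8):
            perm = rng.permutation(5)
            frames.append(Geometry(base[perm].ravel(), 5, 3, ("M",) * 5))
        res = cluster_frames(frames, k_max=4, seed=0,
                             allow_permutations=True)
        assert res.chosen_k == 1

    def test_too_few_frames_rejected(self):
        g = Geometry(np.array([0.0, 0.0]), 1, 2)
        with pytest.raises(ValueError):
            cluster_frames([g, g], k_max=5, seed=0)

    def test_inertia_nonincreasing_in_k(self):
        rng = np.random.default_rng(3)
        frames = self._blobs(rng, [(0, 0), (1.5, 0), (0, 1.5)])
        res = cluster_frames(frames, 6, seed=0)
        inert = [res.inertia_by_k[k] for k in sorted(res.inertia_by_k)]
        assert all(a >= b - 1e-9 for a, b in zip(inert, inert[1:]))


class TestMECIOptimization:
    def test_cone_origin_from_twenty_random_starts(self, jt_cone):
        rng = np.random.default_rng(42)
        for _ in range(20):
            guess = jt_cone.geometry(rng.uniform(-0.5, 0.5, 2))
            rec = optimize_meci(jt_cone, (0, 1), guess)
            assert rec.converged
            assert np.linalg.norm(rec.geometry.coords) < 1e-6

    def test_curved_seam_matches_analytic_minimizer(self, jt_cone_3d):
        """Seam: kappa x + a z = 0, y = 0.  Mean energy along the seam
        parameterized by z = t is (w/2)(1 + (a/k)^2) t^2 - s (a/k) t,
        minimized at t* = s (a/k) / (w (1 + (a/k)^2))."""
        p = jt_cone_3d.params
        r = p["a"] / p["kappa"]
        t_star = p["s"] * r / (p["omega"] * (1 + r * r))
        expected = np.array([-r * t_star, 0.0, t_star])
        rec = optimize_meci(jt_cone_3d, (0, 1),
                            jt_cone_3d.geometry([0.3, 0.2, -0.1]))
        assert rec.converged
        assert np.linalg.norm(rec.geometry.coords - expected) < 1e-6

    def test_photo_seam_minima_match_contour_oracle(self, photo, photo_mecis):
        oracle = _photo_seam_minima(photo)
        by_energy = sorted(m[2] for m in oracle)
        for rec in photo_mecis:
            err = min(abs(rec.e_mean - e) for e in by_energy)
            assert err < 1e-4

    def test_converged_record_invariants(self, photo, photo_mecis):
        for rec in photo_mecis:
            assert rec.gap_at_convergence < 1e-5
            pt = photo.evaluate(rec.geometry)
            gm = pt.mean_gradient(*rec.state_pair)
            out = gm - (gm @ rec.g_vec) * rec.g_vec \
                - (gm @ rec.h_vec) * rec.h_vec
            assert np.linalg.norm(out) < 1e-4

    def test_no_seam_nearby_reports_nonconvergence(self, quartic):
        rec = optimize_meci(quartic, (0, 1), quartic.geometry([0.5]),
                            max_iterations=40)
        assert not rec.converged


class TestBranchingPlane:
    def test_cone_plane_spans_xy(self, jt_cone):
        g, h = branching_plane(jt_cone, jt_cone.geometry([0.0, 0.0]))
        span = np.abs(np.column_stack([g, h]))
        assert np.linalg.det(span) == pytest.approx(1.0, abs=1e-10)
        assert abs(g @ h) < 1e-10
        assert np.linalg.norm(g) == pytest.approx(1.0)
        assert np.linalg.norm(h) == pytest.approx(1.0)

    def test_plane_orthogonal_to_seam_tangent(self, jt_cone_3d):
        p = jt_cone_3d.params
        r = p["a"] / p["kappa"]
        t_star = p["s"] * r / (p["omega"] * (1 + r * r))
        meci = jt_cone_3d.geometry([-r * t_star, 0.0, t_star])
        tangent = np.array([-r, 0.0, 1.0])
        tangent /= np.linalg.norm(tangent)
        g, h = branching_plane(jt_cone_3d, meci)
        assert abs(g @ tangent) < 1e-6
        assert abs(h @ tangent) < 1e-6

    def test_rejects_non_degenerate_point(self, jt_cone):
        with pytest.raises(ValueError, match="gap"):
            branching_plane(jt_cone, jt_cone.geometry([0.5, 0.5]))


class TestSlopeness:
    def test_peaked_cone_is_zero(self, jt_cone):
        rec = optimize_meci(jt_cone, (0, 1), jt_cone.geometry([0.2, -0.1]))
        assert slopeness(jt_cone, rec) < 1e-8

    def test_tilted_cone_equals_tilt(self, jt_cone_tilted):
        rec = optimize_meci(jt_cone_tilted, (0, 1),
                            jt_cone_tilted.geometry([0.2, -0.1]))
        assert slopeness(jt_cone_tilted, rec) == pytest.approx(0.2, abs=1e-6)

    def test_projection_excludes_seam_tangent_component(self, jt_cone_3d):
        """Adding a gradient component along the seam tangent leaves sigma
        unchanged; verified against explicit projector arithmetic."""
        rec = optimize_meci(jt_cone_3d, (0, 1),
                            jt_cone_3d.geometry([0.1, 0.1, 0.0]))
        pt = jt_cone_3d.evaluate(rec.geometry)
        S = pt.mean_gradient(0, 1)
        tangent = np.array([-jt_cone_3d.a / jt_cone_3d.kappa, 0.0, 1.0])
        tangent /= np.linalg.norm(tangent)
        P = np.outer(rec.g_vec, rec.g_vec) + np.outer(rec.h_vec, rec.h_vec)
        sig0 = np.linalg.norm(P @ S)
        sig1 = np.linalg.norm(P @ (S + 0.7 * tangent))
        assert sig1 == pytest.approx(sig0, abs=1e-10)
        assert slopeness(jt_cone_3d, rec) == pytest.approx(sig0, abs=1e-12)

    def test_unconverged_record_rejected(self, jt_cone):
        rec = optimize_meci(jt_cone, (0, 1), jt_cone.geometry([0.2, 0.0]))
        rec.converged = False
        with pytest.raises(ValueError):
            slopeness(jt_cone, rec)


class TestDedupe:
    def test_permuted_duplicates_collapse(self, cluster):
        rec = optimize_meci(cluster, (0, 1), cluster.tetrahedron(),
                            max_iterations=50)
        import copy
        dup = copy.deepcopy(rec)
        pos = dup.geometry.as_matrix()[[1, 0, 2, 3]]
        dup.geometry = cluster.geometry(pos.ravel())
        out = dedupe_mecis([rec, dup], rmsd_tol=1e-3, energy_tol=1e-3)
        assert len(out) == 1

    def test_distant_records_kept(self, photo, photo_mecis):
        out = dedupe_mecis(list(photo_mecis), rmsd_tol=1e-2, energy_tol=1e-3)
        assert len(out) == 2
        assert out[0].e_mean <= out[1].e_mean

    def test_unique_count_matches_seam_oracle(self, photo):
        """MECI searches started evenly along the seam, deduplicated,
        recover exactly the contour oracle's count of seam minima."""
        oracle = _photo_seam_minima(photo)
        def delta(x, y):
            return (photo.lower_diabat(x, y)[0]
                    - photo.upper_diabat(x, y)[0])
        segments = seam_polyline(delta, (-1.8, 1.3), (-0.6, 2.2), n=600)
        seg = max(segments, key=len)
        starts = seg[np.linspace(0, len(seg) - 1, 10, dtype=int)]
        recs = []
        for s in starts:
            r = optimize_meci(photo, (0, 1), photo.geometry(s))
            if r.converged:
                recs.append(r)
        unique = dedupe_mecis(recs, rmsd_tol=0.05, energy_tol=0.01)
        assert len(unique) == len(oracle)
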