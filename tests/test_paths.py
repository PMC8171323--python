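"""String-method paths: barriers, seam constraint, profiling."""

import numpy as np
import pytest

from photoseam.paths import barrier_table, find_path, profile_along_path
from photoseam.products import StationaryPoint

from .oracles import minimax_saddle, polyline_local_minima, seam_polyline


class TestGroundStatePaths:
    def test_quartic_double_well_barrier_is_one(self, quartic):
        p = find_path(quartic, (quartic.geometry([-1.0]),
                                quartic.geometry([1.0])),
                      ("single_state", 0), n_images=11)
        assert p.converged
        prof = p.path_energy()
        kmax = int(np.argmax(prof))
        assert 0 < kmax < p.n_images - 1
        assert abs(p.images[kmax].coords[0]) < 1e-6
        assert p.barrier_forward == pytest.approx(1.0, abs=1e-8)
        assert p.barrier_reverse == pytest.approx(1.0, abs=1e-8)

    def test_barrier_stable_under_image_doubling(self, quartic):
        b = [find_path(quartic, (quartic.geometry([-1.0]),
                                 quartic.geometry([1.0])),
                       ("single_state", 0), n_images=n).barrier_forward
             for n in (11, 22)]
        assert abs(b[0] - b[1]) < 1e-3

    def test_photo_barrier_matches_saddle_oracle(self, photo):
        """Lower-state barrier between two wells against the minimax
        (watershed) saddle oracle."""
        a, b = [0.623, 0.028], [-0.050, 0.467]
        p = find_path(photo, (photo.geometry(a), photo.geometry(b)),
                      ("single_state", 0), n_images=21)
        assert p.converged

        def lower(x, y):
            return photo.evaluate([x, y]).energies[0]
        e_saddle, _ = minimax_saddle(lower, a, b, (-1.8, 1.3), (-0.6, 2.2),
                                     n=300)
        e_a = photo.evaluate(a).energies[0]
        assert p.barrier_forward == pytest.approx(e_saddle - e_a, abs=1e-3)

    def test_identical_endpoints_trivial_path(self, quartic):
        g = quartic.geometry([1.0])
        p = find_path(quartic, (g, g), ("single_state", 0))
        assert p.n_images == 1
        assert p.barrierless

    def test_endpoints_never_move(self, photo):
        a, b = photo.geometry([0.623, 0.028]), photo.geometry([-0.050, 0.467])
        p = find_path(photo, (a, b), ("single_state", 0), n_images=9)
        assert np.array_equal(p.images[0].coords, a.coords)
        assert np.array_equal(p.images[-1].coords, b.coords)


class TestSeamPaths:
    def test_seam_path_matches_contour_oracle(self, photo, photo_mecis):
        """Path maximum against a dense parameterization of the seam, and
        every image on the seam."""
        gap_tol = 1e-3
        p = find_path(photo, (photo_mecis[0].geometry,
                              photo_mecis[1].geometry),
                      ("seam", (0, 1)), n_images=11, gap_tol=gap_tol)
        assert p.converged
        assert p.gaps.max() < gap_tol

        def delta(x, y):
            return (photo.lower_diabat(x, y)[0]
                    - photo.upper_diabat(x, y)[0])
        segments = seam_polyline(delta, (-1.8, 1.3), (-0.6, 2.2), n=1200)
        seg = max(segments, key=len)
        e = np.array([0.5 * (photo.lower_diabat(x, y)[0]
                             + photo.upper_diabat(x, y)[0])
                      for x, y in seg])
        # oracle: max of the seam energy along the arc between the MECIs
        ia = int(np.argmin(np.linalg.norm(
            seg - photo_mecis[0].geometry.coords, axis=1)))
        ib = int(np.argmin(np.linalg.norm(
            seg - photo_mecis[1].geometry.coords, axis=1)))
        lo, hi = sorted((ia, ib))
        inner = e[lo:hi + 1].max()
        outer = max(e[:lo + 1].max(), e[hi:].max()) if (lo > 0 and
                                                        hi < len(e) - 1) \
            else np.inf
        oracle_max = min(inner, outer)
        assert p.path_energy().max() == pytest.approx(oracle_max, abs=1e-3)

    def test_seam_path_endpoint_energies(self, photo, photo_mecis):
        p = find_path(photo, (photo_mecis[0].geometry,
                              photo_mecis[1].geometry),
                      ("seam", (0, 1)), n_images=9)
        prof = p.path_energy()
        assert prof[0] == pytest.approx(photo_mecis[0].e_mean, abs=1e-6)
        assert prof[-1] == pytest.approx(photo_mecis[1].e_mean, abs=1e-6)


class TestBarrierTable:
    @staticmethod
    def _sp(model, coords, label):
        pt = model.evaluate(coords)
        from photoseam.geometry import Geometry
        return StationaryPoint(geometry=model.geometry(coords),
                               state_index=0,
                               energy=float(pt.energies[0]),
                               gradient_norm=0.0, product_label=label)

    def test_two_wells_numeric_both_directions(self, quartic):
        pts = [self._sp(quartic, [-1.0], "product_0"),
               self._sp(quartic, [1.0], "product_1")]
        table = barrier_table(quartic, pts, n_images=11)
        assert table[("product_0", "product_1")]["barrier"] == pytest.approx(
            1.0, abs=1e-6)
        assert table[("product_1", "product_0")]["barrier"] == pytest.approx(
            1.0, abs=1e-6)

    def test_intermediate_well_reported_by_label(self):
        """Three collinear wells: the outer pair's cell names the middle."""
        from photoseam.models import AnalyticDiabaticModel

        class TripleWell(AnalyticDiabaticModel):
            name = "triple_well"
            n_states = 2
            n_coords = 1
            n_particles = 1

            def __init__(self):
                super().__init__()

            def diabatic(self, x):
                v = (x[0] ** 2 - 1.0) ** 2 * (x[0] ** 2 + 0.2)
                g = (4 * x[0] * (x[0] ** 2 - 1) * (x[0] ** 2 + 0.2)
                     + 2 * x[0] * (x[0] ** 2 - 1) ** 2)
                H = np.array([[v, 0.0], [0.0, v + 9.0]])
                dH = np.zeros((2, 2, 1))
                dH[0, 0] = g
                dH[1, 1] = g
                return H, dH

        m = TripleWell()
        pts = [self._sp(m, [-1.0], "product_0"),
               self._sp(m, [0.0], "product_1"),
               self._sp(m, [1.0], "product_2")]
        table = barrier_table(m, pts, n_images=15)
        assert table[("product_0", "product_2")] == {"intermediate":
                                                     "product_1"}
        assert "barrier" in table[("product_0", "product_1")]

    def test_thermodynamic_consistency(self, photo):
        """forward - reverse barrier equals the endpoint energy difference."""
        a, b = [0.623, 0.028], [-0.050, 0.467]
        p = find_path(photo, (photo.geometry(a), photo.geometry(b)),
                      ("single_state", 0), n_images=21)
        ea = photo.evaluate(a).energies[0]
        eb = photo.evaluate(b).energies[0]
        assert (p.barrier_forward - p.barrier_reverse) == pytest.approx(
            eb - ea, abs=1e-3)


class TestProfile:
    def test_constant_profile_at_single_meci(self, jt_cone_tilted):
        from photoseam.paths import PathResult
        from photoseam.selection import optimize_meci
        rec = optimize_meci(jt_cone_tilted, (0, 1),
                            jt_cone_tilted.geometry([0.2, 0.0]))
        img = rec.geometry
        path = PathResult(images=[img] * 5,
                          energies=np.tile(
                              jt_cone_tilted.evaluate(img).energies, (5, 1)),
                          gaps=np.zeros(5), objective="seam", state=None,
                          state_pair=(0, 1), barrier_forward=0.0,
                          barrier_reverse=0.0, barrierless=True,
                          converged=True, arc_length=np.zeros(5))
        prof = profile_along_path(jt_cone_tilted, path,
                                  cone_params={"n": 50}, seed=1,
                                  n_bootstrap=50)
        sigmas = [p.sigma for p in prof]
        assert np.allclose(sigmas, sigmas[0], atol=1e-10)
        assert np.allclose(sigmas, 0.2, atol=1e-6)
        fracs = [p.fractions for p in prof]
        assert all(f == fracs[0] for f in fracs)

    def test_fractions_vary_smoothly_along_seam_path(self, photo,
                                                     photo_mecis):
        """Endpoint censuses differ; interior fractions interpolate
        without wild jumps (each product's series is within the envelope
        seen at finer sampling)."""
        p = find_path(photo, (photo_mecis[0].geometry,
                              photo_mecis[1].geometry),
                      ("seam", (0, 1)), n_images=9)
        prof = profile_along_path(photo, p, cone_params={"n": 150}, seed=2,
                                  n_bootstrap=100)
        assert not any(r.skipped for r in prof)
        labels = sorted({k for r in prof for k in r.fractions})
        series = {lab: np.array([r.fractions.get(lab, 0.0) for r in prof])
                  for lab in labels}
        # fractions at the endpoints differ (different local basins)
        assert any(abs(series[lab][0] - series[lab][-1]) > 0.3
                   for lab in labels)
        # bootstrap intervals contain the point estimate
        for r in prof:
            for lab, (lo, hi) in r.fraction_ci.items():
                assert lo - 1e-9 <= r.fractions.get(lab, 0.0) <= hi + 1e-9
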