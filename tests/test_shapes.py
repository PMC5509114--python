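"""Riemannian shape distance, grading and consensus averaging."""

import numpy as np
import pytest

from occlumorph import (ConsensusConfig, LandmarkSet, TracingBundle,
                        canonicalize, coefficient_mean_shape, error_summary,
                        filter_tracings, mean_shape, preshape,
                        riemann_distance, tooth_outline)
from occlumorph.efa import efa_forward, normalize


def similarity(points, angle=0.0, scale=1.0, shift=(0.0, 0.0)):
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    return scale * points @ rot.T + np.asarray(shift)


def shape_at_distance(landmarks, rho, rng):
    """A configuration at exactly Riemann distance rho from ``landmarks``,
    built by moving along a unit tangent direction on the preshape sphere."""
    z = preshape(landmarks).as_complex()
    K = len(z)
    w = rng.normal(size=K) + 1j * rng.normal(size=K)
    w -= w.mean()                        # centered
    w -= np.vdot(z, w) * z               # Hermitian-orthogonal to z
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    z2 = np.cos(rho) * z + np.sin(rho) * w
    return LandmarkSet(points=np.column_stack([z2.real, z2.imag]))


class TestRiemannDistance:
    def test_identity_and_similarity_invariance(self, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        assert riemann_distance(lm, lm) < 1e-10
        moved = LandmarkSet(points=similarity(lm.points, np.deg2rad(73),
                                              4.2, (11.0, -3.0)))
        assert riemann_distance(lm, moved) < 1e-10

    def test_orthogonal_triangles_reach_pi_over_2(self):
        # CCW and CW equilateral triangles are orthogonal preshapes
        w = np.exp(2j * np.pi * np.arange(3) / 3)
        t1 = LandmarkSet(points=np.column_stack([w.real, w.imag]))
        t2 = LandmarkSet(points=np.column_stack([w.real, -w.imag]))
        assert riemann_distance(t1, t2) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_matches_rotation_grid_procrustes_oracle(self, rng):
        """Independent oracle: minimize the chordal Procrustes misfit
        over a dense rotation grid and map through arccos."""
        betas = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        for _ in range(100):
            a = rng.normal(size=(8, 2))
            b = rng.normal(size=(8, 2))
            z1 = preshape(a).as_complex()
            z2 = preshape(b).as_complex()
            misfit = [np.sum(np.abs(z1 - np.exp(1j * be) * z2) ** 2)
                      for be in betas[::1000]]
            # refine around coarse minimum
            b0 = betas[::1000][int(np.argmin(misfit))]
            fine = b0 + np.linspace(-0.1, 0.1, 2000)
            misfit = np.min([np.sum(np.abs(z1 - np.exp(1j * be) * z2) ** 2)
                             for be in fine])
            oracle = np.arccos(np.clip(1.0 - misfit / 2.0, -1, 1))
            assert riemann_distance(a, b) == pytest.approx(oracle, abs=1e-4)

    def test_metric_axioms_on_random_triples(self, rng):
        pts = [rng.normal(size=(10, 2)) for _ in range(60)]
        import itertools
        triples = list(itertools.combinations(range(60), 3))[:1000]
        d = {}
        for i, j in itertools.combinations(range(60), 2):
            dij = riemann_distance(pts[i], pts[j])
            assert 0.0 <= dij <= np.pi / 2
            assert dij == riemann_distance(pts[j], pts[i])  # exact symmetry
            d[i, j] = d[j, i] = dij
        for i, j, k in triples:
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_exact_construction_of_known_distance(self, rng, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        for rho in (0.05, 0.15, 0.25):
            other = shape_at_distance(lm, rho, rng)
            assert riemann_distance(lm, other) == pytest.approx(rho, abs=1e-9)

    def test_mismatched_k_and_degenerate_errors(self, tooth_polygon):
        lm = canonicalize(tooth_polygon, K=150)
        lm2 = canonicalize(tooth_polygon, K=100)
        with pytest.raises(ValueError):
            riemann_distance(lm, lm2)
        with pytest.raises(ValueError):
            riemann_distance(np.zeros((5, 2)), np.zeros((5, 2)))


class TestFilterTracings:
    def make_bundle(self, rng, distances, tooth_polygon):
        gold = canonicalize(tooth_polygon)
        tracings = [shape_at_distance(gold, d, rng) for d in distances]
        return TracingBundle(specimen_id="S000", gold=gold, tracings=tracings)

    def test_threshold_rule(self, rng, tooth_polygon):
        b = self.make_bundle(rng, [0.05, 0.15, 0.25], tooth_polygon)
        out = filter_tracings(b, ConsensusConfig(threshold=0.2))
        np.testing.assert_array_equal(out.kept, [True, True, False])
        assert not out.no_usable_tracings

    def test_all_beyond_threshold_flags_bundle(self, rng, tooth_polygon):
        b = self.make_bundle(rng, [0.3, 0.5, 0.4], tooth_polygon)
        out = filter_tracings(b, ConsensusConfig(threshold=0.2))
        assert not out.kept.any() and out.no_usable_tracings

    def test_monotone_in_threshold(self, rng, tooth_polygon):
        b = self.make_bundle(rng, [0.01, 0.1, 0.19, 0.21, 0.4], tooth_polygon)
        k1 = filter_tracings(b, ConsensusConfig(threshold=0.1)).kept
        k2 = filter_tracings(b, ConsensusConfig(threshold=0.25)).kept
        assert np.all(k2 | ~k1)  # kept at 0.1 is a subset of kept at 0.25

    def test_worker_mean_two_pass_excludes_gross_error(self, rng,
                                                       tooth_polygon):
        gold = canonicalize(tooth_polygon)
        good = [shape_at_distance(gold, 0.05, rng) for _ in range(2)]
        gross = shape_at_distance(gold, 0.45, rng)
        assert riemann_distance(gross, gold) > 0.4
        b = TracingBundle(specimen_id="S000", gold=None,
                          tracings=good + [gross])
        out = filter_tracings(b, ConsensusConfig(threshold=0.2,
                                                 reference_mode="worker_mean"))
        np.testing.assert_array_equal(out.kept, [True, True, False])
        survivors = mean_shape(good)
        polluted = mean_shape(good + [gross])
        assert riemann_distance(survivors, gold) < riemann_distance(polluted,
                                                                    gold)

    def test_missing_reference_errors(self, rng, tooth_polygon):
        b = self.make_bundle(rng, [0.1], tooth_polygon)
        b.gold = None
        with pytest.raises(ValueError):
            filter_tracings(b, ConsensusConfig(reference_mode="gold_standard"))


class TestMeanShape:
    def test_single_input_identity(self, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        assert riemann_distance(mean_shape([lm]), lm) < 1e-10

    def test_rotation_removed_before_averaging(self, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        rot = LandmarkSet(points=similarity(lm.points, np.deg2rad(40)))
        m = mean_shape([lm, rot])
        assert riemann_distance(m, lm) < 1e-9

    def test_equivariance_under_similarity(self, rng, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        sets = [shape_at_distance(lm, 0.05, rng) for _ in range(5)]
        m1 = mean_shape(sets)
        moved = [LandmarkSet(points=similarity(s.points, 1.1, 3.0, (5, 6)))
                 for s in sets]
        m2 = mean_shape(moved)
        assert riemann_distance(m1, m2) < 1e-9

    def test_noise_averaging_beats_individuals(self, rng, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        copies = [shape_at_distance(lm, abs(rng.normal(0, 0.02)), rng)
                  for _ in range(25)]
        m = mean_shape(copies)
        dists = [riemann_distance(c, lm) for c in copies]
        assert riemann_distance(m, lm) < np.median(dists)

    def test_rescaled_to_mean_centroid_size(self, tooth_polygon):
        lm = canonicalize(tooth_polygon)
        big = LandmarkSet(points=lm.points * 3.0)
        m = mean_shape([lm, big])
        size = np.sqrt(np.sum((m.points - m.points.mean(0)) ** 2))
        s1 = np.sqrt(np.sum((lm.points - lm.points.mean(0)) ** 2))
        assert size == pytest.approx(2.0 * s1, rel=1e-9)

    def test_coefficient_mean_agrees_for_small_dispersion(self, rng,
                                                          tooth_polygon):
        decomps = []
        for _ in range(5):
            poly = tooth_outline() + rng.normal(0, 0.002, size=(256, 2))
            decomps.append(normalize(efa_forward(poly, H=8)))
        m_coeff = coefficient_mean_shape(decomps, K=150)
        m_proc = mean_shape([canonicalize(d, H=8) for d in
                             [tooth_outline() + rng.normal(0, 0.002, (256, 2))
                              for _ in range(5)]])
        assert riemann_distance(m_coeff, m_proc) < 0.02

    def test_errors(self):
        with pytest.raises(ValueError):
            mean_shape([])


class TestErrorSummary:
    def _bundles(self, rng, tooth_polygon, dist_lists):
        gold = canonicalize(tooth_polygon)
        out = []
        for i, ds in enumerate(dist_lists):
            b = TracingBundle(specimen_id=f"S{i:03d}", gold=gold,
                              tracings=[shape_at_distance(gold, d, rng)
                                        for d in ds])
            out.append(filter_tracings(b, ConsensusConfig()))
        return out

    def test_three_point_order_statistics(self, rng, tooth_polygon):
        bundles = self._bundles(rng, tooth_polygon, [[0.1, 0.2, 0.3]])
        summary, hist = error_summary(bundles)
        row = summary.iloc[0]
        assert row["min"] == pytest.approx(0.1, abs=1e-9)
        assert row["median"] == pytest.approx(0.2, abs=1e-9)
        assert row["max"] == pytest.approx(0.3, abs=1e-9)
        assert hist["count"].sum() == 3

    def test_all_zero_distances(self, tooth_polygon):
        gold = canonicalize(tooth_polygon)
        b = TracingBundle(specimen_id="S000", gold=gold, tracings=[gold] * 3)
        b = filter_tracings(b, ConsensusConfig())
        summary, _ = error_summary([b])
        assert (summary[["min", "median", "max"]].iloc[0] <
                np.full(3, 1e-8)).all()

    def test_grouped_by_metadata(self, rng, tooth_polygon):
        import pandas as pd
        bundles = self._bundles(rng, tooth_polygon,
                                [[0.3, 0.35], [0.05, 0.06]])
        meta = pd.DataFrame({"specimen_id": ["S000", "S001"],
                             "tooth_position": ["LM1", "LM2"]})
        summary, _ = error_summary(bundles, meta, group_by="tooth_position")
        med = summary.set_index("tooth_position")["median"]
        assert med["LM1"] > med["LM2"]  # harder group has larger errors

    def test_no_distances_errors(self, tooth_polygon):
        b = TracingBundle(specimen_id="S0", gold=canonicalize(tooth_polygon))
        with pytest.raises(ValueError):
            error_summary([TracingBundle(specimen_id="S1")])
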