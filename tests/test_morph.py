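"""Morphology curation, cloning, alignment and topological validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1forge import fixtures, morph
from ca1forge.morph import (Morphology, mvs_score, pca_align_axon,
                            persistence_diagram, persistence_image,
                            persistence_image_diff, scale_clone)


def y_tree(tip_far=100.0, tip_near=80.0, branch=50.0):
    """Apical Y: branch point at `branch` um, tips at radial distances
    tip_far and tip_near."""
    dx = np.sqrt(tip_near**2 - branch**2) if tip_near > branch else 0.0
    pts = np.array([[0, 0, 0], [0, branch, 0], [0, tip_far, 0],
                    [dx, branch, 0]])
    types = np.array([1, 4, 4, 4])
    parent = np.array([-1, 0, 1, 1])
    return Morphology(pts, np.array([1e-9, 1, 1, 1]), types, parent)


def brute_force_elder_bars(m, neurite):
    """Independent elder-rule oracle: recursively reduce the neurite tree,
    returning the (tip, merge) bar multiset."""
    mask = m.neurite_mask(neurite)
    dist = np.maximum(np.linalg.norm(m.points - m.soma_center, axis=1)
                      - m.soma_radius, 0.0)
    children = m.children()
    bars = []

    def reduce(node):
        # returns the max tip distance of the surviving component
        kids = [c for c in children[node] if mask[c]]
        if not kids:
            return dist[node]
        tips = [reduce(c) for c in kids]
        order = np.argsort(tips)
        for k in order[:-1]:
            bars.append((tips[k], dist[node]))
        return max(tips[order[-1]], dist[node])

    roots = [i for i in range(m.n_nodes)
             if mask[i] and (m.parent[i] < 0 or not mask[m.parent[i]])]
    for rt in roots:
        p = m.parent[rt]
        bars.append((reduce(rt), dist[p] if p >= 0 else 0.0))
    return sorted(bars)


class TestCurate:
    def test_clean_morphology_with_zero_shrink_unchanged(self):
        m = fixtures.make_morphology("int", seed=3)
        out = morph.curate(m, shrink_z=0.0, shrink_xy=0.0)
        np.testing.assert_allclose(out.points, m.points - m.soma_center,
                                   atol=1e-12)

    def test_shrink_correction_scales_z_extent(self):
        m = fixtures.make_morphology("pc", seed=4)
        out = morph.curate(m, shrink_z=0.25, shrink_xy=0.0)
        assert np.isclose(np.ptp(out.points[:, 2]),
                          1.25 * np.ptp(m.points[:, 2]))

    def test_zero_length_segment_removed_length_unchanged(self):
        pts = np.array([[0, 0, 0], [0, 10, 0], [0, 10, 0], [0, 30, 0.0]])
        m = Morphology(pts, np.ones(4), np.array([1, 2, 2, 2]),
                       np.array([-1, 0, 1, 2]))
        out = morph.curate(m, 0.0, 0.0)
        assert out.n_nodes == 3
        assert np.isclose(out.total_length(), m.total_length())

    def test_axonless_morphology_flagged(self):
        pts = np.array([[0, 0, 0], [0, 10, 0.0]])
        m = Morphology(pts, np.ones(2), np.array([1, 3]),
                       np.array([-1, 0]))
        with pytest.raises(ValueError, match="axon"):
            morph.curate(m)


class TestScaleClone:
    def test_zero_scale_no_jitter_identity(self):
        m = fixtures.make_morphology("int", seed=5)
        out = scale_clone(m, 0.0)
        np.testing.assert_allclose(out.points, m.points)

    def test_scaling_multiplies_total_length(self):
        m = fixtures.make_morphology("pc", seed=6)
        out = scale_clone(m, 0.10)
        assert np.isclose(out.total_length(), 1.10 * m.total_length(),
                          rtol=1e-9)

    def test_fixed_seed_reproducible(self, tmp_path):
        m = fixtures.make_morphology("int", seed=7)
        a = scale_clone(m, 0.05, jitter_seed=99)
        b = scale_clone(m, 0.05, jitter_seed=99)
        morph.write_swc(a, tmp_path / "a.swc")
        morph.write_swc(b, tmp_path / "b.swc")
        assert (tmp_path / "a.swc").read_text() \
            == (tmp_path / "b.swc").read_text()

    def test_out_of_range_scale_rejected(self):
        m = fixtures.make_morphology("int", seed=8)
        with pytest.raises(ValueError):
            scale_clone(m, 0.2)

    def test_scaling_multiplies_persistence_bars(self):
        m = fixtures.make_morphology("pc", seed=9)
        s = 0.12
        bars0 = persistence_diagram(m, "apical").bars
        bars1 = persistence_diagram(scale_clone(m, s), "apical").bars
        np.testing.assert_allclose(bars1, (1 + s) * bars0, rtol=1e-9)


class TestPcaAlign:
    def test_aligned_axon_unchanged_up_to_sign(self):
        m = fixtures.make_morphology("pc", seed=10)
        once = pca_align_axon(m)
        twice = pca_align_axon(once)
        ax = m.neurite_mask("axon")
        d1 = once.points[ax] - once.points[ax].mean(0)
        d2 = twice.points[ax] - twice.points[ax].mean(0)
        # principal axes coincide
        assert np.allclose(np.abs(d1[:, 0]), np.abs(d2[:, 0]), atol=1e-6)

    def test_rotated_axon_realigned_within_one_degree(self):
        m = pca_align_axon(fixtures.make_morphology("pc", seed=11))
        ang = np.radians(37.0)
        rot = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0],
                        [-np.sin(ang), 0, np.cos(ang)]])
        out = pca_align_axon(m.transformed(rotation=rot))
        ax = out.neurite_mask("axon")
        pts = out.points[ax] - out.points[ax].mean(0)
        _, evecs = np.linalg.eigh(np.cov(pts.T))
        axis = evecs[:, -1]
        angle = np.degrees(np.arccos(min(abs(axis[0]), 1.0)))
        assert angle < 1.0

    def test_wide_clone_rejected_at_threshold(self):
        m = pca_align_axon(fixtures.make_morphology("pc", seed=12))
        ax = m.neurite_mask("axon")
        wide = m.points.copy()
        wide[ax, 2] *= 3.4
        clone = Morphology(wide, m.radii, m.types, m.parent)
        assert pca_align_axon(clone, original=m) is None
        # 3.2x stays within the 3.3 threshold
        ok = m.points.copy()
        ok[ax, 2] *= 3.2
        clone2 = Morphology(ok, m.radii, m.types, m.parent)
        assert pca_align_axon(clone2, original=m) is not None


class TestMvsScore:
    def test_identical_populations_score_zero(self):
        pop = np.array([1.0, 2.0, 3.0, 4.0])
        assert mvs_score(pop, pop) == 0.0

    def test_unit_shift_with_injected_ovs(self):
        a = np.array([0.0, 1.0, 2.0])
        b = a + 1.0
        assert mvs_score(a, b, ovs=lambda x, y: 4.0) == 0.25

    def test_good_agreement_threshold(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.05, 1, 200)
        assert mvs_score(a, b) < morph.MVS_GOOD_AGREEMENT

    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_shift_invariant(self, seed, shift):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 2, 30)
        s_ab = mvs_score(a, b)
        assert np.isclose(s_ab, mvs_score(b, a))
        assert np.isclose(s_ab, mvs_score(a + shift, b + shift),
                          rtol=1e-9, atol=1e-12)

    def test_zero_ovs_flags(self):
        a = np.array([1.0, 1.0])
        assert mvs_score(a, a, ovs=lambda x, y: 0.0) == 0.0
        assert mvs_score(a, a + 1, ovs=lambda x, y: 0.0) == np.inf


class TestPersistence:
    def test_single_unbranched_neurite_one_bar(self):
        pts = np.array([[0, 0, 0], [0, 50, 0], [0, 100, 0.0]])
        m = Morphology(pts, np.array([1e-9, 1, 1]), np.array([1, 4, 4]),
                       np.array([-1, 0, 1]))
        d = persistence_diagram(m, "apical")
        np.testing.assert_allclose(d.bars, [[100.0, 0.0]])

    def test_y_tree_elder_rule(self):
        d = persistence_diagram(y_tree(), "apical")
        got = sorted(map(tuple, d.bars))
        assert np.allclose(got[0], (80.0, 50.0))
        assert np.allclose(got[1], (100.0, 0.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_trees(self, seed):
        m = fixtures.make_morphology("int", depth=4, seed=seed)
        got = sorted(map(tuple, persistence_diagram(m, "basal").bars))
        expected = brute_force_elder_bars(m, "basal")
        np.testing.assert_allclose(got, expected, atol=1e-9)

    @pytest.mark.parametrize("seed", range(40))
    def test_bar_count_equals_leaf_count(self, seed):
        m = fixtures.make_morphology("pc", depth=3, seed=seed)
        ch = m.children()
        ax = m.neurite_mask("axon")
        leaves = sum(1 for i in range(m.n_nodes) if ax[i] and not ch[i])
        assert len(persistence_diagram(m, "axon").bars) == leaves

    def test_rotation_invariance(self):
        m = fixtures.make_morphology("pc", seed=21)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        b0 = persistence_diagram(m, "apical").bars
        b1 = persistence_diagram(m.transformed(rotation=rot),
                                 "apical").bars
        np.testing.assert_allclose(sorted(map(tuple, b0)),
                                   sorted(map(tuple, b1)), atol=1e-9)

    def test_empty_neurite_empty_diagram(self):
        m = fixtures.make_morphology("int", seed=22)
        assert len(persistence_diagram(m, "apical").bars) == 0


class TestPersistenceImage:
    def test_image_integrates_to_one(self):
        m = fixtures.make_morphology("pc", seed=23)
        d = persistence_diagram(m, "apical")
        img, (xs, ys) = persistence_image(d)
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        assert np.isclose(img.sum() * cell, 1.0, atol=1e-6)

    def test_single_bar_bump_at_bar(self):
        d = morph.PersistenceDiagram(np.array([[80.0, 20.0]]), "apical")
        img, (xs, ys) = persistence_image(d, grid_size=101)
        i, j = np.unravel_index(np.argmax(img), img.shape)
        assert abs(xs[i] - 80.0) < (xs[1] - xs[0])
        assert abs(ys[j] - 20.0) < (ys[1] - ys[0])

    def test_identical_populations_zero_difference(self):
        pop = [persistence_diagram(fixtures.make_morphology("pc", seed=s),
                                   "apical") for s in range(3)]
        diff = persistence_image_diff(pop, list(pop))
        assert np.abs(diff).max() < 1e-12


class TestSwcRoundTrip:
    def test_write_read_identity(self, tmp_path):
        m = fixtures.make_morphology("pc", seed=30)
        morph.write_swc(m, tmp_path / "m.swc")
        back = morph.read_swc(tmp_path / "m.swc")
        np.testing.assert_allclose(back.points, m.points)
        np.testing.assert_allclose(back.radii, m.radii)
        assert np.array_equal(back.types, m.types)
        assert np.array_equal(back.parent, m.parent)
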