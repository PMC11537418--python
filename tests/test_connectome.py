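"""Touch detection vs a brute-force oracle, admissibility rules, pruning
statistics, and the bouton worked example."""

import numpy as np
import pandas as pd
import pytest

from ca1forge import connectome as conn
from ca1forge import fixtures
from ca1forge.connectome import (PlacedCell, PruningConstraints,
                                 bouton_stats, find_appositions,
                                 predict_synapses_per_connection, prune)
from ca1forge.morph import Morphology


def two_segment_cells(gap_um, post_mtype="SP_PC", post_is_pc=True):
    """A presynaptic axon segment parallel to a postsynaptic dendrite at
    the given gap."""
    pre_pts = np.array([[0, 0, 0], [0, 5, 0], [0, 5, 50.0]])
    pre = Morphology(pre_pts, np.full(3, 0.5), np.array([1, 2, 2]),
                     np.array([-1, 0, 1]))
    # soma kept far from the axon so only dendrite contacts are probed
    post_pts = np.array([[gap_um + 40.0, -40.0, 0], [gap_um, 5, 0],
                         [gap_um, 5, 50.0]])
    post = Morphology(post_pts, np.array([1e-6, 0.5, 0.5]),
                      np.array([1, 3, 3]), np.array([-1, 0, 1]))
    return [PlacedCell(0, "SP_PVBC", pre, is_pyramidal=False),
            PlacedCell(1, post_mtype, post, is_pyramidal=post_is_pc)]


def brute_force_appositions(cells, thresholds=None):
    """O(n^2) all-pairs all-segments oracle using the same admissibility
    rules but no spatial pruning and an independent distance routine."""
    thresholds = thresholds or conn.TOUCH_DISTANCE_UM
    found = set()
    for post in cells:
        thr = thresholds["PC" if post.is_pyramidal else "INT"]
        for pre in cells:
            if pre.gid == post.gid:
                continue
            kinds = conn.admissible_compartments(pre.mtype, post.mtype,
                                                 post.is_pyramidal)
            if not kinds:
                continue
            pa0, pa1, pnode, _, _ = pre.segments(("axon", "AIS"))
            qa0, qa1, qnode, _, qsurf = post.segments(kinds)
            for i in range(len(pa0)):
                for j in range(len(qa0)):
                    d = _seg_dist_scalar(pa0[i], pa1[i], qa0[j], qa1[j])
                    if d - qsurf[j] <= thr:
                        found.add((pre.gid, post.gid, int(pnode[i]),
                                   int(qnode[j])))
    return found


def _point_seg_dist(p, a, b):
    ab = b - a
    denom = ab @ ab
    t = 0.0 if denom == 0 else np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


def _seg_dist_scalar(p0, p1, q0, q1):
    """Exact segment-segment distance by enumerating candidate minima:
    the four endpoint-to-segment projections plus the unclamped
    interior-interior critical point when it lies inside both segments
    (independent derivation from the implementation's clamping cascade).
    """
    cands = [_point_seg_dist(p0, q0, q1), _point_seg_dist(p1, q0, q1),
             _point_seg_dist(q0, p0, p1), _point_seg_dist(q1, p0, p1)]
    d1, d2 = p1 - p0, q1 - q0
    r = p0 - q0
    a, e, b = d1 @ d1, d2 @ d2, d1 @ d2
    c, f = d1 @ r, d2 @ r
    denom = a * e - b * b
    if denom > 1e-12:
        s = (b * f - c * e) / denom
        t = (a * f - b * c) / denom
        if 0.0 <= s <= 1.0 and 0.0 <= t <= 1.0:
            cands.append(np.linalg.norm((p0 + s * d1) - (q0 + t * d2)))
    return min(cands)


class TestFindAppositions:
    def test_parallel_segments_inside_threshold(self):
        cells = two_segment_cells(0.9)
        apps = find_appositions(cells)
        assert len(apps) >= 1
        assert (apps.distance <= 1.0).all()

    def test_parallel_segments_outside_threshold(self):
        cells = two_segment_cells(1.1)
        assert find_appositions(cells).empty

    def test_interneuron_target_uses_wider_threshold(self):
        cells = two_segment_cells(5.0, post_mtype="SP_PVBC",
                                  post_is_pc=False)
        assert len(find_appositions(cells)) >= 1

    def test_matches_brute_force_on_toy_circuit(self, toy_circuit):
        cells = toy_circuit.placed[:8] + toy_circuit.placed[-4:]
        apps = find_appositions(cells)
        got = set(zip(apps.pre_gid, apps.post_gid, apps.pre_segment,
                      apps.post_segment))
        expected = brute_force_appositions(cells)
        assert got == expected

    def test_aa_cells_contact_only_pc_ais(self):
        assert conn.admissible_compartments("SP_AA", "SP_PC", True) \
            == ("AIS",)
        assert conn.admissible_compartments("SP_AA", "SP_PVBC", False) \
            == ()

    def test_pc_pc_dendrites_only(self):
        assert conn.admissible_compartments("SP_PC", "SP_PC", True) \
            == ("dendrite",)

    def test_sca_ivy_bs_avoid_pc_somata(self):
        for mt in ("SR_SCA", "SP_Ivy", "SO_BS"):
            assert "soma" not in conn.admissible_compartments(
                mt, "SP_PC", True)

    def test_ordinary_interneuron_may_contact_soma(self):
        kinds = conn.admissible_compartments("SP_PVBC", "SP_PC", True)
        assert "soma" in kinds and "dendrite" in kinds


class TestSynapsePrediction:
    @pytest.mark.parametrize("x,cls,expected", [
        (0.0, "I-I", 0.0),
        (10.0, "I-I", 1.096),
        (2.0, "other", 2.338),
    ])
    def test_linear_coefficients(self, x, cls, expected):
        assert np.isclose(predict_synapses_per_connection(x, cls),
                          expected)


def synthetic_appositions(n_axons, conns_per_axon, syn_per_conn, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for pre in range(n_axons):
        for c in range(conns_per_axon):
            post = n_axons + pre * conns_per_axon + c
            k = max(1, rng.poisson(syn_per_conn))
            for s in range(k):
                rows.append((pre, post, "SP_PC", "SP_PVBC", s, 0.5, s,
                             0.5, 0.5, "dendrite"))
    return pd.DataFrame(rows, columns=[
        "pre_gid", "post_gid", "pre_mtype", "post_mtype", "pre_segment",
        "pre_offset", "post_segment", "post_offset", "distance",
        "compartment"])


class TestPrune:
    def test_fixed_point_removes_little(self):
        apps = synthetic_appositions(20, 10, 3.0, seed=1)
        mean0 = apps.groupby(["pre_gid", "post_gid"]).size().mean()
        cons = {"SP_PC->SP_PVBC": PruningConstraints(mean0)}
        out = prune(apps, cons, seed=2)
        assert len(out) > 0.95 * len(apps)

    def test_target_mean_synapses_per_connection(self):
        rows = []
        for pre in range(40):
            for c in range(10):
                post = 1000 + pre * 10 + c
                for s in range(8):
                    rows.append((pre, post, "SP_PC", "SP_PVBC", s, 0.5,
                                 s, 0.5, 0.5, "dendrite"))
        apps = pd.DataFrame(rows, columns=synthetic_appositions(
            1, 1, 1).columns)
        realized = []
        for seed in range(5):
            out = prune(apps, {"SP_PC->SP_PVBC": PruningConstraints(4.0)},
                        seed=seed)
            realized.append(
                out.groupby(["pre_gid", "post_gid"]).size().mean())
        assert abs(np.mean(realized) - 4.0) / 4.0 < 0.10

    def test_bouton_density_cv_near_target(self):
        # 200 axons, one connection each with many synapses on a 1000-um
        # axon; target density well below the available synapse supply
        rows = []
        for pre in range(200):
            post = 10_000 + pre
            for s in range(150):
                rows.append((pre, post, "SP_PC", "SP_PVBC", s, 0.5, s,
                             0.5, 0.5, "dendrite"))
        apps = pd.DataFrame(rows, columns=synthetic_appositions(
            1, 1, 1).columns)
        cons = {"SP_PC->SP_PVBC": PruningConstraints(
            mean_syns_per_connection=150.0, bouton_density_mean=0.08,
            bouton_density_cv=0.50)}
        lengths = {pre: 1000.0 for pre in range(200)}
        out = prune(apps, cons, axon_lengths=lengths, seed=3)
        dens = out.groupby("pre_gid").size() / 1.15 / 1000.0
        cv = dens.std(ddof=0) / dens.mean()
        assert abs(cv - 0.50) < 0.10

    def test_pruning_only_removes(self):
        apps = synthetic_appositions(10, 5, 4.0, seed=4)
        out = prune(apps, {"SP_PC->SP_PVBC": PruningConstraints(2.0)},
                    seed=5)
        assert len(out) <= len(apps)
        merged = out.merge(apps, how="left", indicator=True)
        assert (merged._merge == "both").all()

    def test_infeasible_target_keeps_all(self):
        apps = synthetic_appositions(5, 4, 2.0, seed=6)
        out = prune(apps, {"SP_PC->SP_PVBC": PruningConstraints(50.0)},
                    seed=7)
        assert len(out) == len(apps)

    def test_deterministic_under_seed(self):
        apps = synthetic_appositions(10, 5, 4.0, seed=8)
        cons = {"SP_PC->SP_PVBC": PruningConstraints(2.0)}
        a = prune(apps, cons, seed=9)
        b = prune(apps, cons, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_convergence_with_pathway_size(self):
        errs = []
        for n_conn in (50, 500):
            rows = []
            for c in range(n_conn):
                for s in range(8):
                    rows.append((c % 20, 1000 + c, "SP_PC", "SP_PVBC",
                                 s, 0.5, s, 0.5, 0.5, "dendrite"))
            apps = pd.DataFrame(rows, columns=synthetic_appositions(
                1, 1, 1).columns)
            out = prune(apps,
                        {"SP_PC->SP_PVBC": PruningConstraints(4.0)},
                        seed=10)
            realized = out.groupby(["pre_gid",
                                    "post_gid"]).size().mean()
            errs.append(abs(realized - 4.0))
        assert errs[1] <= errs[0] + 0.2


class TestBoutonStats:
    def test_worked_example_from_pv_basket_data(self):
        # 64 postsynaptic cells: 51 single-synapse connections and 13
        # multi-synapse connections averaging 48/13 = 3.69 synapses
        counts = np.concatenate([np.ones(51), np.full(13, 48 / 13)])
        mean, sd, cv = bouton_stats(counts)
        assert round(float(np.mean(counts[counts > 1])), 2) == 3.69
        assert round(sd, 2) == 1.08
        assert round(mean, 2) == 1.55
        assert round(cv, 2) == 0.70

    def test_constant_counts_zero_spread(self):
        mean, sd, cv = bouton_stats([2.0, 2.0, 2.0])
        assert sd == 0.0 and cv == 0.0

    def test_empty_or_zero_rejected(self):
        with pytest.raises(ValueError):
            bouton_stats([])
        with pytest.raises(ValueError):
            bouton_stats([0.0, 0.0])


class TestToyCircuitAudit:
    def test_all_synapses_satisfy_admissibility(self, toy_circuit):
        syn = toy_circuit.synapses
        cells = toy_circuit.cells.set_index("gid")
        for row in syn.itertuples():
            pre_mt = cells.loc[row.pre_gid, "mtype"]
            post_mt = cells.loc[row.post_gid, "mtype"]
            kinds = conn.admissible_compartments(
                pre_mt, post_mt, post_mt.endswith("PC"))
            assert kinds, (pre_mt, post_mt)

    def test_pipeline_deterministic_under_seed(self):
        a = fixtures.make_toy_circuit(n_pc=6, n_int=3, n_fibers=10,
                                      seed=11)
        b = fixtures.make_toy_circuit(n_pc=6, n_int=3, n_fibers=10,
                                      seed=11)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.synapses, b.synapses)
        pd.testing.assert_frame_equal(a.sc_synapses, b.sc_synapses)

    def test_empty_request_gives_empty_tables(self):
        with pytest.raises(Exception):
            fixtures.make_toy_circuit(n_pc=0, n_int=0, n_fibers=5,
                                      seed=12)
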