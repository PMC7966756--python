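"""Water proximity networks and motif extraction."""

from itertools import combinations

import numpy as np
import pytest

from icebound.structio import Atom, WaterSet
from icebound.synthetic_data import gen_ring, gen_trough, gen_zigzag
from icebound.water_network import (
    build_network,
    find_hydration_ring,
    find_linear_trough,
    network_stats,
)


def ws(coords, prefix="w"):
    coords = np.asarray(coords, float)
    return WaterSet([f"{prefix}{i}" for i in range(len(coords))], coords)


class TestBuildNetwork:
    def test_cutoff_boundary_closed_interval(self):
        assert len(build_network(ws([[0, 0, 0], [3.70, 0, 0]]), 3.7).edges) == 1
        assert len(build_network(ws([[0, 0, 0], [3.71, 0, 0]]), 3.7).edges) == 0

    def test_zigzag_chain_topology(self):
        z = gen_zigzag(12, 2.86, 116.0, 0.0, seed=0)
        net = build_network(z.waters, 3.7)
        assert len(net.edges) == 11
        assert [len(c) for c in net.components()] == [12]

    def test_monotone_in_cutoff(self, rng):
        pts = rng.uniform(0, 10, size=(20, 3))
        prev: set = set()
        for cutoff in (2.0, 3.0, 4.0, 6.0):
            edges = {(i, j) for i, j, _ in build_network(ws(pts), cutoff).edges}
            assert prev <= edges
            prev = edges

    def test_nonfinite_coordinates_named(self):
        with pytest.raises(ValueError, match="w1"):
            WaterSet(["w0", "w1"], np.array([[0, 0, 0], [np.inf, 0, 0]]))


class TestNetworkStats:
    def test_collinear_triple_is_180(self):
        st = network_stats(build_network(ws([[0, 0, 0], [3, 0, 0], [6, 0, 0]]), 3.7))
        assert len(st.angles) == 1
        assert st.angles[0] == pytest.approx(180.0)

    def test_planted_zigzag_recovered_exactly(self):
        z = gen_zigzag(12, 2.86, 116.0, 0.0, seed=0)
        st = network_stats(build_network(z.waters, 3.7))
        assert st.mean_distance == pytest.approx(2.86, abs=1e-9)
        assert st.mean_angle == pytest.approx(116.0, abs=1e-9)
        assert st.branch_count == 0

    def test_noisy_zigzag_recovery_unbiased(self):
        # parameter recovery within 3 standard errors over 100 seeds
        sigma = 0.1
        means_d, means_a = [], []
        for seed in range(100):
            z = gen_zigzag(12, 2.86, 116.0, sigma, seed=seed)
            st = network_stats(build_network(z.waters, 3.7))
            means_d.append(st.mean_distance)
            means_a.append(st.mean_angle)
        se_d = np.std(means_d, ddof=1) / 10
        se_a = np.std(means_a, ddof=1) / 10
        # independent endpoint noise inflates expected edge length by
        # ~ 2 sigma^2 / s (chi-distribution expansion); correct for it
        bias = 2 * sigma**2 / 2.86
        assert abs(np.mean(means_d) - (2.86 + bias)) < 3 * se_d
        assert abs(np.mean(means_a) - 116.0) < max(3 * se_a, 0.5)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            network_stats(build_network(ws([[0, 0, 0], [9, 0, 0]]), 3.7))


def exhaustive_trough(waters, tolerance):
    """Oracle: enumerate all subsets of size >= 3, exact TLS residual check."""
    from icebound.water_network import _line_residuals, _tls_line

    best = None
    n = len(waters)
    for size in range(n, 2, -1):
        for subset in combinations(range(n), size):
            pts = waters.coords[list(subset)]
            c, u = _tls_line(pts)
            if _line_residuals(pts, c, u).max() <= tolerance:
                if best is None or size > len(best):
                    best = subset
        if best:
            break
    return best


class TestLinearTrough:
    def test_exact_row_recovered(self):
        t = gen_trough(6, 4.6, 0.0, seed=0)
        tr = find_linear_trough(t.waters, None, line_tolerance=1.0)
        assert tr.n_waters == 6
        assert tr.mean_interval == pytest.approx(4.6, abs=1e-9)
        assert tr.residual < 1e-9
        assert tr.span == pytest.approx(5 * 4.6, abs=1e-9)

    def test_offline_decoy_excluded(self):
        t = gen_trough(6, 4.6, 0.0, seed=0)
        coords = np.vstack([t.waters.coords, [[11.5, 2.0, 0.0]]])
        tr = find_linear_trough(ws(coords), None, line_tolerance=1.0)
        assert tr.n_waters == 6
        assert "w6" not in tr.water_ids

    def test_agrees_with_exhaustive_oracle(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 12, size=(9, 3))
            waters = ws(pts)
            got = find_linear_trough(waters, None, line_tolerance=1.2)
            want = exhaustive_trough(waters, 1.2)
            if want is None:
                assert not got.found
            else:
                assert got.found
                assert got.n_waters == len(want)

    def test_heuristic_path_finds_planted_row(self, rng):
        # more candidates than the exhaustive limit
        t = gen_trough(8, 4.0, 0.02, seed=1)
        decoys = rng.uniform(0, 25, size=(12, 3)) + np.array([0, 5.0, 5.0])
        waters = ws(np.vstack([t.waters.coords, decoys]))
        tr = find_linear_trough(waters, None, line_tolerance=0.5)
        assert tr.n_waters >= 8

    def test_no_trough_returns_flagged_result(self):
        waters = ws([[0, 0, 0], [5, 5, 0], [9, 0, 3]])
        tr = find_linear_trough(waters, None, line_tolerance=0.01)
        assert not tr.found
        assert tr.n_waters == 0


class TestHydrationRing:
    def test_regular_decagon_cycle(self):
        r = gen_ring(10, 2.74, 3.4, 0.0, seed=0)
        ring = find_hydration_ring(r.waters, r.atoms, ring_cutoff=3.5)
        assert ring.ring_closure
        assert ring.n_waters == 10
        assert ring.mean_adjacent_distance == pytest.approx(2.74, abs=1e-9)
        assert ring.mean_carbon_distance == pytest.approx(3.4, abs=1e-6)

    def test_broken_ring_reports_open_chain(self):
        r = gen_ring(10, 2.74, 3.4, 0.0, seed=0)
        broken = r.waters.subset(list(range(9)))
        ring = find_hydration_ring(broken, r.atoms, ring_cutoff=3.5)
        assert not ring.ring_closure
        assert ring.n_waters == 9

    def test_contact_cutoff_restricts_candidates(self):
        r = gen_ring(10, 2.74, 3.4, 0.0, seed=0)
        far = np.array([[30.0, 30.0, 30.0], [32.0, 30.0, 30.0]])
        waters = ws(np.vstack([r.waters.coords, far]))
        ring = find_hydration_ring(waters, r.atoms, ring_cutoff=3.5, contact_cutoff=4.5)
        assert ring.n_waters == 10

    def test_no_carbons_raises(self):
        r = gen_ring(10, 2.74, 3.4, 0.0, seed=0)
        with pytest.raises(ValueError, match="carbon"):
            find_hydration_ring(r.waters, [], 3.5)
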