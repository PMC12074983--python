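"""Per-trace chromatin metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbtrace.traces import (
    CompartmentProfile,
    DegenerateTraceError,
    adjacent_distances,
    batch_adjacent_distances,
    batch_contact_frequencies,
    batch_pair_distances,
    batch_radius_of_gyration,
    compartment_contact_frequencies,
    contact_matrix,
    observed_fraction,
    pairwise_distances,
    polarization_index,
    qc_filter,
    radius_of_gyration,
    scrambled_polarization_control,
)

from conftest import random_trace


# ---------------------------------------------------------------------------
# Brute-force oracles (independent loop implementations)
# ---------------------------------------------------------------------------

def brute_distance(a, b):
    return sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5


def brute_contact_freqs(pos, labels, threshold):
    counts = {"AA": [0, 0], "AB": [0, 0], "BB": [0, 0]}
    n = len(pos)
    for i in range(n):
        for j in range(i + 2, n):
            if np.isnan(pos[i]).any() or np.isnan(pos[j]).any():
                continue
            key = "".join(sorted(labels[i] + labels[j]))
            counts[key][1] += 1
            if brute_distance(pos[i], pos[j]) < threshold:
                counts[key][0] += 1
    return {f"freq_{k}": (c / t if t else float("nan")) for k, (c, t) in counts.items()}


def brute_rg(pos):
    obs = [p for p in pos if not np.isnan(p).any()]
    cx = [sum(p[a] for p in obs) / len(obs) for a in range(3)]
    return (sum(brute_distance(p, cx) ** 2 for p in obs) / len(obs)) ** 0.5


class TestPairwiseDistances:
    def test_hand_checked_pythagorean_triple(self):
        d = pairwise_distances([[0, 0, 0], [3, 4, 0], [0, 0, 12]])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 2] == pytest.approx(12.0)
        assert d[1, 2] == pytest.approx(13.0)

    def test_27_tads_give_351_pairs(self, rng):
        d = pairwise_distances(random_trace(rng, 27))
        iu = np.triu_indices(27, 1)
        assert len(d[iu]) == 351
        assert np.isfinite(d[iu]).all()

    def test_degenerate_point_cloud(self):
        d = pairwise_distances(np.zeros((5, 3)))
        assert np.allclose(d, 0.0)

    def test_missing_propagates(self, rng):
        pos = random_trace(rng, 6, missing=2)
        d = pairwise_distances(pos)
        miss = np.isnan(pos).any(axis=1)
        assert np.isnan(d[miss]).all()
        assert np.isnan(d[:, miss]).all()

    def test_too_few_observed_raises(self):
        pos = np.full((5, 3), np.nan)
        pos[0] = 0
        with pytest.raises(DegenerateTraceError):
            pairwise_distances(pos)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_triangle_inequality(self, seed):
        pos = np.random.default_rng(seed).normal(0, 300, (8, 3))
        d = pairwise_distances(pos)
        assert np.allclose(d, d.T)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestAdjacentDistances:
    def test_count_and_consistency_with_matrix(self, rng):
        pos = random_trace(rng, 27)
        adj = adjacent_distances(pos)
        assert len(adj) == 26
        d = pairwise_distances(pos)
        assert np.allclose(adj, np.diag(d, k=1))

    def test_collinear_equally_spaced(self):
        pos = np.zeros((10, 3))
        pos[:, 2] = np.arange(10) * 7.5
        assert np.allclose(adjacent_distances(pos), 7.5)


class TestContactMatrix:
    def test_strict_threshold_boundary(self):
        d = np.zeros((4, 4))
        d[0, 2] = d[2, 0] = 499.9
        d[0, 3] = d[3, 0] = 500.0
        d[1, 3] = d[3, 1] = 800.0
        c = contact_matrix(d, 500.0)
        assert c[0, 2] == 1.0      # strictly below
        assert c[0, 3] == 0.0      # boundary: not a contact
        assert c[1, 3] == 0.0

    def test_adjacent_and_diagonal_not_applicable(self):
        c = contact_matrix(np.zeros((5, 5)), 500.0)
        assert np.isnan(np.diag(c)).all()
        assert np.isnan(np.diag(c, 1)).all()

    def test_collapsed_trace_all_contacts(self, rng):
        pos = np.zeros((6, 3))
        c = contact_matrix(pairwise_distances(pos), 500.0)
        iu = np.triu_indices(6, 2)
        assert (c[iu] == 1.0).all()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            contact_matrix(np.zeros((4, 4)), 0.0)


class TestCompartmentContacts:
    def test_collapsed_and_stretched_limits(self, profile6):
        collapsed = compartment_contact_frequencies(np.zeros((6, 3)), profile6)
        assert all(v == 1.0 for v in collapsed.values())
        stretched = np.zeros((6, 3))
        stretched[:, 0] = np.arange(6) * 5000.0
        far = compartment_contact_frequencies(stretched, profile6)
        assert all(v == 0.0 for v in far.values())

    def test_matches_exhaustive_enumeration(self, profile6, rng):
        for _ in range(10):
            pos = random_trace(rng, 6, scale=350.0)
            got = compartment_contact_frequencies(pos, profile6)
            want = brute_contact_freqs(pos, profile6.labels, 500.0)
            for k in got:
                assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_rigid_motion_invariance(self, profile6, rng):
        pos = random_trace(rng, 6, scale=350.0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1]])
        moved = pos @ R.T + np.array([100.0, -50.0, 3.0])
        a = compartment_contact_frequencies(pos, profile6)
        b = compartment_contact_frequencies(moved, profile6)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_shrinking_never_decreases_contact_frequency(self, profile6, rng):
        for _ in range(5):
            pos = random_trace(rng, 6, scale=400.0)
            centroid = pos.mean(axis=0)
            shrunk = centroid + (pos - centroid) * 0.5
            a = compartment_contact_frequencies(pos, profile6)
            b = compartment_contact_frequencies(shrunk, profile6)
            for k in a:
                assert b[k] >= a[k] - 1e-12


class TestRadiusOfGyration:
    def test_closed_forms(self):
        assert radius_of_gyration(np.zeros((4, 3)) + 5.0) == 0.0
        two = np.array([[0, 0, 0], [0, 0, 8.0]])
        assert radius_of_gyration(two) == pytest.approx(4.0)
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        assert radius_of_gyration(cube) == pytest.approx(np.sqrt(3) / 2)

    def test_linear_scaling(self, rng):
        pos = random_trace(rng, 12)
        assert radius_of_gyration(pos * 2.5) == pytest.approx(2.5 * radius_of_gyration(pos))

    def test_missing_excluded(self, rng):
        pos = random_trace(rng, 10, missing=3)
        assert radius_of_gyration(pos) == pytest.approx(brute_rg(pos))


class TestPolarizationIndex:
    def test_disjoint_hulls(self, rng):
        a = rng.normal(0, 1, (6, 3))
        b = rng.normal(0, 1, (6, 3)) + 100.0
        pos = np.vstack([a, b])
        prof = CompartmentProfile(tuple("AAAAAABBBBBB"), np.r_[np.ones(6), -np.ones(6)],
                                  np.arange(12) * 10**6 + 1)
        assert polarization_index(pos, prof) == pytest.approx(1.0)

    def test_coincident_hulls(self, rng):
        a = rng.normal(0, 1, (6, 3))
        pos = np.vstack([a, a])
        prof = CompartmentProfile(tuple("AAAAAABBBBBB"), np.r_[np.ones(6), -np.ones(6)],
                                  np.arange(12) * 10**6 + 1)
        assert polarization_index(pos, prof) == pytest.approx(0.0, abs=1e-6)

    def test_half_overlapping_unit_cubes(self):
        """Analytic oracle: two unit cubes overlapping in a 0.5-wide slab
        give Vs = 0.5, Va = Vb = 1, hence PI = 0.5."""
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        shifted = cube + np.array([0.5, 0, 0])
        pos = np.vstack([cube, shifted])
        prof = CompartmentProfile(tuple("A" * 8 + "B" * 8),
                                  np.r_[np.ones(8), -np.ones(8)],
                                  np.arange(16) * 10**6 + 1)
        assert polarization_index(pos, prof) == pytest.approx(0.5, abs=1e-6)

    def test_coplanar_compartment_gives_missing(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)  # coplanar
        b = np.array([[5, 5, 5], [6, 5, 5], [5, 6, 5], [5, 5, 6]], float)
        prof = CompartmentProfile(tuple("AAAABBBB"), np.r_[np.ones(4), -np.ones(4)],
                                  np.arange(8) * 10**6 + 1)
        assert np.isnan(polarization_index(np.vstack([a, b]), prof))


class TestScrambledControl:
    @pytest.fixture()
    def polarized_traces(self, rng):
        traces = []
        for _ in range(8):
            a = rng.normal(0, 150, (8, 3)) + np.array([600.0, 0, 0])
            b = rng.normal(0, 150, (8, 3))
            traces.append(np.vstack([a, b]))
        prof = CompartmentProfile(tuple("A" * 8 + "B" * 8),
                                  np.r_[np.ones(8), -np.ones(8)],
                                  np.arange(16) * 10**6 + 1)
        return traces, prof

    def test_identity_hook_reproduces_observed(self, polarized_traces):
        traces, prof = polarized_traces
        observed = np.array([polarization_index(t, prof) for t in traces])
        control = scrambled_polarization_control(traces, prof, n_perm=1, _identity=True)
        assert np.allclose(control, observed, equal_nan=True)

    def test_scrambling_lowers_polarization(self, polarized_traces):
        traces, prof = polarized_traces
        observed = np.nanmedian([polarization_index(t, prof) for t in traces])
        control = scrambled_polarization_control(traces, prof, n_perm=20, seed=4)
        assert np.nanmedian(control) < observed

    def test_random_geometry_within_null_band(self, rng):
        prof = CompartmentProfile(tuple("A" * 8 + "B" * 8),
                                  np.r_[np.ones(8), -np.ones(8)],
                                  np.arange(16) * 10**6 + 1)
        traces = [rng.normal(0, 300, (16, 3)) for _ in range(6)]
        observed = np.nanmedian([polarization_index(t, prof) for t in traces])
        control = scrambled_polarization_control(traces, prof, n_perm=50, seed=5)
        lo, hi = np.nanpercentile(control, [2.5, 97.5])
        assert lo <= observed <= hi


class TestBatchHelpers:
    def test_batch_matches_per_trace_metrics(self, profile6, rng):
        stack = np.stack([random_trace(rng, 6, missing=rng.integers(0, 2)) for _ in range(10)])
        pair_d = batch_pair_distances(stack)
        freqs = batch_contact_frequencies(pair_d, profile6)
        adj = batch_adjacent_distances(stack)
        rgs = batch_radius_of_gyration(stack)
        iu = np.triu_indices(6, 1)
        for t in range(10):
            d = pairwise_distances(stack[t])
            assert np.allclose(pair_d[t], d[iu], equal_nan=True)
            single = compartment_contact_frequencies(stack[t], profile6)
            for k in single:
                a, b = freqs[k][t], single[k]
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
            assert np.allclose(adj[t], adjacent_distances(stack[t]), equal_nan=True)
            assert rgs[t] == pytest.approx(radius_of_gyration(stack[t]))


def test_qc_filter_drops_sparse_traces(rng):
    good = random_trace(rng, 27)
    sparse = random_trace(rng, 27, missing=14)   # 13/27 observed < 60%
    kept = qc_filter([good, sparse])
    assert len(kept) == 1
    assert observed_fraction(sparse) < 0.6
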