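import numpy as np
import pytest

from bdpath.structure_io import CalphaModel
from bdpath.elastic_network import (ENMParams, all_pairs_interaction_count,
                                    build_topology, compute_forces,
                                    parse_rigid_blocks, potential_energy,
                                    rebuild_pair_list, spring_constant)
from bdpath.fixtures import make_chain


def chain_model(n, spacing=3.8, curvature=0.05, chain="A"):
    return CalphaModel(make_chain(n, spacing, curvature),
                       [(chain, i + 1, "") for i in range(n)])


def collinear_model(n=3, spacing=3.8):
    pos = np.zeros((n, 3))
    pos[:, 0] = spacing * np.arange(n)
    return CalphaModel(pos, [("A", i + 1, "") for i in range(n)])


def pair_set(topology):
    return {tuple(p) for p in topology.pairs}


def brute_force_pairs(positions, cutoff):
    """All-pairs distance scan oracle."""
    n = positions.shape[0]
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(positions[j] - positions[i]) < cutoff:
                out.add((i, j))
    return out


class TestBuildTopology:
    def test_three_collinear_beads_within_cutoff(self):
        topo = build_topology(collinear_model(), ENMParams(cutoff=8.0))
        assert pair_set(topo) == {(0, 1), (1, 2), (0, 2)}  # (0,2) at 7.6 < 8

    def test_small_cutoff_without_sequence_span(self):
        topo = build_topology(collinear_model(),
                              ENMParams(cutoff=5.0, sequence_span=0))
        assert pair_set(topo) == {(0, 1), (1, 2)}

    def test_sequence_span_adds_bonded_pairs_beyond_cutoff(self):
        topo = build_topology(collinear_model(4),
                              ENMParams(cutoff=4.0, sequence_span=2))
        # cutoff only reaches neighbours; span 2 adds (0,2) and (1,3)
        assert pair_set(topo) == {(0, 1), (1, 2), (2, 3), (0, 2), (1, 3)}

    def test_cutoff_pairs_match_distance_scan_oracle(self):
        model = chain_model(40)
        topo = build_topology(model, ENMParams(cutoff=8.0, sequence_span=0))
        assert pair_set(topo) == brute_force_pairs(model.positions, 8.0)

    def test_rigid_block_contains_all_pairs_with_unit_stiffness(self):
        model = chain_model(10)
        topo = build_topology(model, rigid_blocks=[range(10)])
        assert topo.n_pairs == all_pairs_interaction_count(10) == 45
        np.testing.assert_allclose(topo.stiffness, 1.0)

    def test_overlapping_rigid_blocks_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            build_topology(chain_model(10), rigid_blocks=[[0, 1, 2], [2, 3]])

    def test_rest_lengths_are_source_distances(self):
        model = chain_model(20)
        topo = build_topology(model)
        i, j = topo.pairs[:, 0], topo.pairs[:, 1]
        np.testing.assert_allclose(
            topo.rest_lengths,
            np.linalg.norm(model.positions[j] - model.positions[i], axis=1))

    def test_pair_count_scales_linearly_with_chain_length(self):
        sizes = np.array([100, 250, 500, 1000, 2000])
        counts = np.array([build_topology(chain_model(int(n))).n_pairs
                           for n in sizes])
        slope, intercept = np.polyfit(sizes, counts, 1)
        predicted = slope * sizes + intercept
        residual = np.abs(counts - predicted) / counts
        assert np.all(residual < 0.05)  # pairs-per-residue is constant

    def test_pair_count_formula(self):
        assert all_pairs_interaction_count(271) == 36585
        assert all_pairs_interaction_count(2) == 1


class TestSpringConstant:
    def test_sequence_neighbor_identity(self):
        params = ENMParams(sequence_constant=60.0, sequence_exponent=2.0)
        assert spring_constant(1, 3.8, params) == 60.0
        assert spring_constant(2, 7.6, params) == 15.0

    def test_cartesian_identity_at_reference_length(self):
        params = ENMParams(cartesian_constant=6.0, reference_length=3.8)
        assert spring_constant(10, 3.8, params) == pytest.approx(6.0)

    def test_cartesian_inverse_power_decay(self):
        params = ENMParams(cartesian_constant=6.0, cartesian_exponent=6.0,
                           reference_length=3.8)
        assert spring_constant(10, 7.6, params) == pytest.approx(6.0 / 64)

    def test_cartesian_rule_non_increasing_in_distance(self):
        params = ENMParams()
        d = np.linspace(4.0, 12.0, 30)
        k = [spring_constant(5, x, params) for x in d]
        assert np.all(np.diff(k) <= 0)

    def test_cross_chain_pair_uses_cartesian_rule(self):
        params = ENMParams()
        assert spring_constant(1, 3.8, params, same_chain=False) == \
            pytest.approx(params.cartesian_constant)

    def test_nonpositive_rest_length_rejected(self):
        with pytest.raises(ValueError):
            spring_constant(1, 0.0, ENMParams())


class TestForcesAndEnergy:
    def test_zero_force_at_source_conformation(self):
        model = chain_model(15)
        topo = build_topology(model)
        np.testing.assert_allclose(compute_forces(topo, model.positions), 0,
                                   atol=1e-12)
        assert potential_energy(topo, model.positions) == 0.0

    def test_two_bead_stretched_spring(self):
        model = CalphaModel(np.array([[0.0, 0, 0], [3.8, 0, 0]]),
                            [("A", 1, ""), ("A", 2, "")])
        params = ENMParams(sequence_constant=1.0, sequence_exponent=1.0,
                           sequence_span=1)
        topo = build_topology(model, params)
        stretched = np.array([[0.0, 0, 0], [4.8, 0, 0]])
        forces = compute_forces(topo, stretched)
        np.testing.assert_allclose(forces[0], [1.0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(forces[1], [-1.0, 0, 0], atol=1e-12)
        assert potential_energy(topo, stretched) == pytest.approx(0.5)

    def test_forces_are_negative_gradient_of_energy(self):
        rng = np.random.default_rng(3)
        model = chain_model(20)
        topo = build_topology(model)
        pos = model.positions + rng.normal(0, 0.3, model.positions.shape)
        forces = compute_forces(topo, pos)
        h = 1e-5
        numeric = np.zeros_like(pos)
        for i in range(pos.shape[0]):
            for c in range(3):
                plus = pos.copy(); plus[i, c] += h
                minus = pos.copy(); minus[i, c] -= h
                numeric[i, c] = -(potential_energy(topo, plus)
                                  - potential_energy(topo, minus)) / (2 * h)
        scale = np.abs(forces).max()
        np.testing.assert_allclose(forces, numeric, atol=1e-5 * max(scale, 1.0))

    def test_total_force_and_torque_vanish(self):
        rng = np.random.default_rng(4)
        model = chain_model(30)
        topo = build_topology(model)
        pos = model.positions + rng.normal(0, 0.5, model.positions.shape)
        forces = compute_forces(topo, pos)
        np.testing.assert_allclose(forces.sum(axis=0), 0, atol=1e-8)
        torque = np.cross(pos - pos.mean(axis=0), forces).sum(axis=0)
        np.testing.assert_allclose(torque, 0, atol=1e-8)

    def test_cutoff_forces_equal_all_pairs_forces_beyond_diameter(self):
        """With r_c larger than the system, the pair list is the full
        double sum and forces agree with a brute-force loop exactly."""
        model = chain_model(30)
        params = ENMParams(cutoff=1e4)
        topo = build_topology(model, params)
        assert topo.n_pairs == all_pairs_interaction_count(30)
        rng = np.random.default_rng(5)
        pos = model.positions + rng.normal(0, 0.4, model.positions.shape)
        brute = np.zeros_like(pos)
        for (i, j), k, d0 in zip(topo.pairs, topo.stiffness, topo.rest_lengths):
            delta = pos[j] - pos[i]
            d = np.linalg.norm(delta)
            f = k * (d - d0) * delta / d
            brute[i] += f
            brute[j] -= f
        np.testing.assert_allclose(compute_forces(topo, pos), brute, atol=1e-12)

    def test_energy_decreases_along_steepest_descent(self):
        rng = np.random.default_rng(6)
        model = chain_model(12)
        topo = build_topology(model)
        pos = model.positions + rng.normal(0, 0.3, model.positions.shape)
        e0 = potential_energy(topo, pos)
        forces = compute_forces(topo, pos)
        assert potential_energy(topo, pos + 1e-4 * forces) < e0

    def test_coincident_beads_named_in_error(self):
        model = collinear_model(3)
        topo = build_topology(model)
        pos = model.positions.copy()
        pos[1] = pos[0]
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            compute_forces(topo, pos)


class TestRebuildPairList:
    def test_idempotent_for_unchanged_positions(self):
        model = chain_model(25)
        topo = build_topology(model)
        rebuilt = rebuild_pair_list(topo, model.positions)
        np.testing.assert_array_equal(rebuilt.pairs, topo.pairs)
        np.testing.assert_allclose(rebuilt.rest_lengths, topo.rest_lengths)
        np.testing.assert_allclose(rebuilt.stiffness, topo.stiffness)

    def test_pair_beyond_cutoff_dropped(self):
        pos = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 7.0, 0]])
        model = CalphaModel(pos, [("A", 1, ""), ("A", 2, ""), ("B", 9, "")])
        topo = build_topology(model, ENMParams(cutoff=8.0, sequence_span=1))
        assert (0, 2) in pair_set(topo)  # 7.96 Å < 8, non-bonded
        moved = pos.copy()
        moved[2, 1] = 9.0
        rebuilt = rebuild_pair_list(topo, moved)
        assert (0, 2) not in pair_set(rebuilt)

    def test_new_pair_admitted_with_current_distance_as_rest(self):
        pos = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 9.0, 0]])
        model = CalphaModel(pos, [("A", 1, ""), ("A", 2, ""), ("B", 9, "")])
        topo = build_topology(model, ENMParams(cutoff=8.0, sequence_span=1))
        assert (1, 2) not in pair_set(topo)
        moved = pos.copy()
        moved[2, 1] = 6.0
        rebuilt = rebuild_pair_list(topo, moved)
        idx = pair_set(rebuilt)
        assert (1, 2) in idx
        row = int(np.flatnonzero((rebuilt.pairs == (1, 2)).all(axis=1))[0])
        assert rebuilt.rest_lengths[row] == pytest.approx(6.0)

    def test_persisting_pair_keeps_original_rest_length(self):
        model = collinear_model(3)
        topo = build_topology(model, ENMParams(cutoff=8.0, sequence_span=1))
        moved = model.positions.copy()
        moved[2, 0] -= 0.5  # (0,2) persists at 7.1 Å
        rebuilt = rebuild_pair_list(topo, moved)
        row = int(np.flatnonzero((rebuilt.pairs == (0, 2)).all(axis=1))[0])
        assert rebuilt.rest_lengths[row] == pytest.approx(7.6)

    def test_rigid_pair_retained_at_any_distance(self):
        model = chain_model(6)
        topo = build_topology(model, rigid_blocks=[[0, 5]])
        moved = model.positions.copy()
        moved[5] += np.array([30.0, 0, 0])
        rebuilt = rebuild_pair_list(topo, moved)
        row = int(np.flatnonzero((rebuilt.pairs == (0, 5)).all(axis=1))[0])
        original = np.linalg.norm(model.positions[5] - model.positions[0])
        assert rebuilt.rest_lengths[row] == pytest.approx(original)
        assert rebuilt.stiffness[row] == 1.0


class TestRigidBlockParsing:
    def test_whole_chain_and_span_selectors(self):
        model = CalphaModel(
            make_chain(6),
            [("A", 1, ""), ("A", 2, ""), ("A", 3, ""),
             ("B", 1, ""), ("B", 2, ""), ("B", 3, "")])
        blocks = parse_rigid_blocks("B\nA:2-3\n", model)
        assert blocks == [frozenset({3, 4, 5}), frozenset({1, 2})]

    def test_unknown_selector_rejected(self):
        model = CalphaModel(make_chain(3),
                            [("A", 1, ""), ("A", 2, ""), ("A", 3, "")])
        with pytest.raises(ValueError, match="matched no residues"):
            parse_rigid_blocks("C\n", model)
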