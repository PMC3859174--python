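"""Descriptor correctness: closed forms, brute-force oracles, invariances."""

import itertools

import numpy as np
import pytest

from qsbr import descriptors3d as d3
from qsbr.descriptors3d import (
    Conformer,
    DisconnectedGraphError,
    compute_six,
    hats,
    leverages,
    mor_descriptor,
    morse,
    msd_index,
    span,
    whim_directional,
)
from qsbr.synthetic import gen_conformer


def random_rotation(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture()
def chain9() -> Conformer:
    return gen_conformer(9, "line", spacing=1.5)


@pytest.fixture()
def blob(rng) -> Conformer:
    return gen_conformer(12, "random", seed=99)


class TestSpan:
    def test_single_atom_is_zero(self):
        assert span(gen_conformer(1)) == 0.0

    def test_two_atoms_half_distance(self):
        assert span(gen_conformer(2, "line", spacing=2.0)) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        coords = rng.normal(size=(50, 3)) * 3
        c = Conformer(["C"] * 50, coords, [(i, i + 1) for i in range(49)])
        centroid = coords.mean(0)
        oracle = max(np.linalg.norm(x - centroid) for x in coords)
        assert span(c) == pytest.approx(oracle)

    def test_elongation_increases_span(self, chain9):
        longer = gen_conformer(9, "line", spacing=2.5)
        assert span(longer) > span(chain9)


class TestMsd:
    def test_two_atom_path(self):
        assert msd_index(gen_conformer(2)) == pytest.approx(1.0)

    def test_three_atom_path_hand_value(self):
        # ordered squared distances: 2*(1 + 1 + 4) = 12; 12/(3*2) = 2
        assert msd_index(gen_conformer(3)) == pytest.approx(np.sqrt(2))

    def test_branching_decreases_msd(self):
        path5 = gen_conformer(5, "line")
        star5 = Conformer(
            ["C"] * 5, np.eye(5, 3) * 1.5, [(0, j) for j in range(1, 5)]
        )
        assert msd_index(star5) < msd_index(path5)

    def test_path_is_maximal_over_trees(self):
        # enumerate all labeled trees on 6 nodes via Pruefer sequences
        import itertools as it

        n = 6
        best = {}
        for seq in it.product(range(n), repeat=n - 2):
            degree = [1] * n
            for v in seq:
                degree[v] += 1
            seq_list, edges = list(seq), []
            leaves = sorted(i for i in range(n) if degree[i] == 1)
            deg = degree[:]
            import heapq

            heap = [i for i in range(n) if deg[i] == 1]
            heapq.heapify(heap)
            for v in seq_list:
                leaf = heapq.heappop(heap)
                edges.append((leaf, v))
                deg[v] -= 1
                if deg[v] == 1:
                    heapq.heappush(heap, v)
            u, w = heapq.heappop(heap), heapq.heappop(heap)
            edges.append((u, w))
            c = Conformer(["C"] * n, np.zeros((n, 3)), edges)
            key = tuple(sorted(map(tuple, map(sorted, edges))))
            best[key] = msd_index(c)
        path = gen_conformer(n, "line")
        assert max(best.values()) == pytest.approx(msd_index(path))

    def test_shortcut_edge_decreases_msd(self):
        c = gen_conformer(6, "line")
        with_shortcut = Conformer(
            c.elements, c.coords, c.bonds + [(0, 5)]
        )
        assert msd_index(with_shortcut) < msd_index(c)

    def test_disconnected_rejected(self):
        c = Conformer(["C"] * 4, np.random.default_rng(0).normal(size=(4, 3)), [(0, 1)])
        with pytest.raises(DisconnectedGraphError):
            msd_index(c)


class TestMorse:
    def test_zero_s_kernel_is_weight_product_sum(self):
        c = gen_conformer(2, "line", spacing=1.0)
        assert morse(c, 0.0) == pytest.approx(1.0)  # single unit-weight pair

    def test_closed_form_two_atoms(self):
        c = gen_conformer(2, "line", spacing=1.0)
        assert morse(c, 10.0) == pytest.approx(np.sin(10) / 10)

    def test_mor11_is_s_10(self):
        c = gen_conformer(5, "random", seed=1)
        assert mor_descriptor(c, 11, "u") == pytest.approx(morse(c, 10.0, "u"))

    def test_rigid_motion_invariance(self, blob, rng):
        Q = random_rotation(rng)
        moved = Conformer(blob.elements, blob.coords @ Q.T + 7.0, blob.bonds)
        assert morse(moved, 10.0, "v") == pytest.approx(
            morse(blob, 10.0, "v"), abs=1e-10
        )


class TestWhim:
    def test_planar_molecule_degenerate_third_axis(self):
        ring = gen_conformer(6, "ring")
        res = whim_directional(ring, "u")
        assert res.degenerate_axis3
        assert res.eigenvalues[2] == pytest.approx(0.0, abs=1e-12)
        assert res.accessibility[2] == 0.0

    def test_eigenvalues_match_dense_oracle(self, rng):
        c = gen_conformer(10, "random", seed=2)
        w = d3.atomic_weights(c, "u")
        X = c.coords - c.coords.mean(0)
        S = (w[:, None] * X).T @ X / w.sum()
        oracle = np.sort(np.linalg.eigvalsh(S))[::-1]
        res = whim_directional(c, "u")
        assert np.allclose(res.eigenvalues, oracle, atol=1e-10)

    def test_rotation_invariance(self, blob, rng):
        Q = random_rotation(rng)
        moved = Conformer(blob.elements, blob.coords @ Q.T - 3.0, blob.bonds)
        a = whim_directional(blob, "p")
        b = whim_directional(moved, "p")
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        assert np.allclose(a.accessibility, b.accessibility, atol=1e-10)
        assert np.allclose(a.symmetry, b.symmetry, atol=1e-10)

    def test_symmetry_in_unit_interval(self, blob):
        res = whim_directional(blob, "p")
        assert all(0.0 <= g <= 1.0 for g in res.symmetry)

    def test_symmetric_pair_fully_symmetric(self):
        c = gen_conformer(2, "line", spacing=2.0)
        res = whim_directional(c, "u")
        assert res.symmetry[0] == pytest.approx(1.0)


class TestHats:
    def test_zero_beyond_diameter(self):
        c = gen_conformer(5, "line")  # diameter 4 < 8
        assert hats(c, 8) == 0.0

    def test_nine_atom_chain_terminal_pair(self, chain9):
        h = leverages(chain9)
        assert hats(chain9, 8) == pytest.approx(h[0] * h[8])

    def test_matches_brute_force_enumeration(self):
        c = gen_conformer(9, "random", seed=5)
        h = leverages(c)
        D = c.topological_distances()
        for lag in (1, 2, 5):
            oracle = sum(
                h[i] * h[j]
                for i, j in itertools.combinations(range(9), 2)
                if D[i, j] == lag
            )
            assert hats(c, lag) == pytest.approx(oracle)

    def test_leverages_sum_to_three_for_nonplanar(self, blob):
        assert leverages(blob).sum() == pytest.approx(3.0)

    def test_disconnected_rejected(self):
        c = Conformer(["C"] * 9, np.random.default_rng(3).normal(size=(9, 3)), [(0, 1)])
        with pytest.raises(DisconnectedGraphError):
            hats(c, 8)


class TestComputeSix:
    def test_composition_consistent_with_members(self, chain9):
        vec = compute_six(chain9)
        assert vec.SPAN == pytest.approx(span(chain9))
        assert vec.MSD == pytest.approx(msd_index(chain9))
        assert vec.HATS8u == pytest.approx(hats(chain9, 8, "u"))
        assert vec.Mor11v == pytest.approx(mor_descriptor(chain9, 11, "v"))

    def test_full_vector_rigid_motion_invariance(self, blob, rng):
        Q = random_rotation(rng)
        moved = Conformer(blob.elements, blob.coords @ Q.T + 1.5, blob.bonds)
        a, b = compute_six(blob).as_dict(), compute_six(moved).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_relabeling_invariance(self, blob, rng):
        perm = rng.permutation(blob.n_atoms)
        inv = np.argsort(perm)
        relabeled = Conformer(
            [blob.elements[i] for i in perm],
            blob.coords[perm],
            [(int(inv[i]), int(inv[j])) for i, j in blob.bonds],
        )
        a, b = compute_six(blob).as_dict(), compute_six(relabeled).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_elongation_increases_span(self):
        short = compute_six(gen_conformer(7, "line", spacing=1.2))
        long = compute_six(gen_conformer(7, "line", spacing=1.8))
        assert long.SPAN > short.SPAN


class TestIO:
    def test_xyz_round_trip(self, tmp_path, blob):
        xyz = tmp_path / "c.xyz"
        bonds = tmp_path / "c.bonds"
        d3.write_xyz(blob, xyz, bonds)
        again = d3.read_xyz(xyz, bonds)
        assert again.elements == blob.elements
        assert np.allclose(again.coords, blob.coords, atol=1e-6)
        assert sorted(map(tuple, again.bonds)) == sorted(map(tuple, blob.bonds))

    def test_sdf_reader(self, tmp_path):
        pytest.importorskip("rdkit")
        sdf = tmp_path / "mol.sdf"
        sdf.write_text(
            "\n     qsbr test\n\n"
            "  3  2  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0\n"
            "    1.5000    0.0000    0.0000 C   0  0\n"
            "    3.0000    0.0000    0.0000 O   0  0\n"
            "  1  2  1  0\n"
            "  2  3  1  0\n"
            "M  END\n$$$$\n"
        )
        mols = d3.read_sdf(sdf)
        assert len(mols) == 1
        assert mols[0].elements == ["C", "C", "O"]
        assert len(mols[0].bonds) == 2
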