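"""Cluster carving: inclusion rule, unwrapping, cumulative datasets, labels."""

import numpy as np
import pytest

from deltamd import (AtomicConfiguration, CarveSpec, TwoLevelTheory,
                     build_cumulative_dataset, carve_cluster, evaluate,
                     identify_molecules, label_delta, minimum_image)
from deltamd.potentials import PairParams, ThreeBodyParams
from deltamd.structures import Trajectory


def two_molecule_box(d_oo=3.0, L=16.0):
    """Hand-built periodic box with two waters at a known O–O distance."""
    import math
    th = math.radians(104.52)
    mono = np.array([[0, 0, 0], [0.9572, 0, 0],
                     [0.9572 * math.cos(th), 0.9572 * math.sin(th), 0]])
    pos = np.vstack([mono + [1.0, 8.0, 8.0], mono + [1.0 + d_oo, 8.0, 8.0]])
    return AtomicConfiguration(elements=["O", "H", "H"] * 2, positions=pos,
                               cell=np.eye(3) * L)


class TestCarveCluster:
    def test_radius_below_nearest_neighbor_keeps_only_center(self):
        box = two_molecule_box(d_oo=3.0)
        cl = carve_cluster(box, 0, r_c=2.9)
        assert cl.n_atoms == 3

    def test_radius_straddling_neighbor_distance(self):
        box = two_molecule_box(d_oo=3.0)
        assert carve_cluster(box, 0, r_c=2.9).n_atoms == 3
        assert carve_cluster(box, 0, r_c=3.1).n_atoms == 6

    def test_center_oxygen_at_origin_and_open_boundary(self):
        box = two_molecule_box()
        cl = carve_cluster(box, 1, r_c=3.5)
        assert not cl.periodic
        o_pos = cl.positions[np.asarray(cl.elements) == "O"]
        assert np.linalg.norm(o_pos, axis=1).min() == pytest.approx(0.0, abs=1e-12)

    def test_molecules_kept_whole_across_boundary(self):
        # neighbor molecule on the far side of the boundary is unwrapped next to the center
        box = two_molecule_box(d_oo=3.0, L=16.0)
        box.positions[3:] -= np.array([6.0, 0, 0])    # O2 now at x=-2 → wrapped to 14, min-image O–O = 3
        box.positions[3:] %= 16.0
        cl = carve_cluster(box, 0, r_c=3.5)
        assert cl.n_atoms == 6
        o_pos = cl.positions[np.asarray(cl.elements) == "O"]
        d = np.linalg.norm(o_pos[1] - o_pos[0])
        assert d == pytest.approx(3.0, abs=1e-9)

    def test_too_large_radius_rejected(self, ll_source):
        with pytest.raises(ValueError, match="too large"):
            carve_cluster(ll_source[0], 0, r_c=7.5)

    def test_count_matches_brute_force(self, ll_source):
        # whole-molecule count == O(N²) neighbor count on min-image O–O distances
        rng = np.random.default_rng(4)
        for _ in range(100):
            fi = int(rng.integers(len(ll_source)))
            frame = ll_source[fi]
            topo = identify_molecules(frame)
            m = int(rng.integers(topo.n_molecules))
            r_c = float(rng.uniform(2.5, 5.5))
            cl = carve_cluster(frame, m, r_c, topology=topo)
            o_pos = frame.positions[topo.oxygens]
            d = minimum_image(o_pos - o_pos[m], frame.cell)
            expect = int(np.sum(np.linalg.norm(d, axis=1) <= r_c))
            assert cl.n_atoms == 3 * expect

    def test_monotone_in_radius(self, ll_source):
        frame = ll_source[2]
        sizes = [carve_cluster(frame, 7, r).n_atoms for r in (2.5, 3.5, 4.5, 5.5)]
        assert sizes == sorted(sizes)

    def test_occupancy_tracks_ideal_density(self, ll_source):
        # mean count at 4.5–5.5 Å within 15% of ρ_N·(4/3)πr³
        topo0 = identify_molecules(ll_source[0])
        rho_n = topo0.n_molecules / ll_source[0].edge ** 3
        for r_c in (4.5, 5.5):
            counts = []
            for frame in ll_source[::6]:
                topo = identify_molecules(frame)
                for m in range(0, topo.n_molecules, 9):
                    counts.append(carve_cluster(frame, m, r_c, topology=topo).n_atoms // 3)
            ideal = rho_n * 4 / 3 * np.pi * r_c ** 3
            assert np.mean(counts) == pytest.approx(ideal, rel=0.15)


class TestCumulativeDataset:
    def test_compact_quota_bookkeeping(self, ll_source):
        spec = CarveSpec(radii=(2.5, 3.5), counts={2.5: 40, 3.5: 10}, seed=9)
        ds = build_cumulative_dataset(ll_source, spec)
        assert len(ds) == 50
        assert int(np.sum(ds.radii == 2.5)) == 40
        assert int(np.sum(ds.radii == 3.5)) == 10

    def test_same_seed_reproduces_bitwise(self, ll_source):
        spec = CarveSpec(radii=(2.5, 3.5), counts={2.5: 15, 3.5: 5}, seed=3)
        d1 = build_cumulative_dataset(ll_source, spec)
        d2 = build_cumulative_dataset(ll_source, spec)
        for a, b in zip(d1.clusters, d2.clusters):
            assert np.array_equal(a.positions, b.positions)
        d3 = build_cumulative_dataset(
            ll_source, CarveSpec(radii=(2.5, 3.5), counts={2.5: 15, 3.5: 5}, seed=4))
        assert any(not np.array_equal(a.positions, b.positions)
                   for a, b in zip(d1.clusters, d3.clusters))

    def test_validation_split_stratified(self, ll_source):
        spec = CarveSpec(radii=(2.5, 3.5), counts={2.5: 40, 3.5: 20}, seed=1)
        ds = build_cumulative_dataset(ll_source, spec)
        for r, n in ((2.5, 40), (3.5, 20)):
            n_val = int(np.sum((ds.radii == r) & (ds.split == "val")))
            assert n_val == round(0.1 * n)

    def test_insufficient_pool_raises(self, ll_source):
        spec = CarveSpec(radii=(2.5,), counts={2.5: 10 ** 6}, seed=0)
        with pytest.raises(ValueError, match="available"):
            build_cumulative_dataset(ll_source, spec)

    def test_cluster_shapes_and_neutrality(self, ll_source):
        spec = CarveSpec(radii=(3.5,), counts={3.5: 12}, seed=5)
        ds = build_cumulative_dataset(ll_source, spec)
        for c in ds.clusters:
            assert c.n_atoms % 3 == 0
            assert c.elements.count("O") * 2 == c.elements.count("H")

    def test_save_load_round_trip(self, ll_source, theory, tmp_path):
        spec = CarveSpec(radii=(2.5,), counts={2.5: 8}, seed=2)
        ds = label_delta(build_cumulative_dataset(ll_source, spec), theory)
        ds.save(tmp_path / "ds.extxyz", tmp_path / "ds.csv")
        from deltamd.carve import load_dataset
        back = load_dataset(tmp_path / "ds.extxyz", tmp_path / "ds.csv")
        assert len(back) == 8
        assert np.allclose(back.labels, ds.labels, atol=1e-8)
        assert np.allclose(back.clusters[3].positions, ds.clusters[3].positions, atol=1e-8)


class TestLabels:
    def test_identical_levels_give_zero_labels(self, ll_source):
        same = TwoLevelTheory(
            hl_pair=PairParams(epsilon=0.00674, sigma=3.166),
            hl_three_body=ThreeBodyParams(lambda3=0.0))
        spec = CarveSpec(radii=(2.5,), counts={2.5: 5}, seed=0)
        ds = label_delta(build_cumulative_dataset(ll_source, spec), same)
        assert np.abs(ds.labels).max() < 1e-12

    def test_monomer_label_is_zero(self, theory):
        import math
        th = math.radians(104.52)
        mono = AtomicConfiguration(
            elements=["O", "H", "H"],
            positions=[[0, 0, 0], [0.9572, 0, 0],
                       [0.9572 * math.cos(th), 0.9572 * math.sin(th), 0]])
        from deltamd.carve import LabeledDataset
        ds = LabeledDataset(clusters=[mono], labels=None, radii=np.array([2.5]),
                            source_frame=np.array([0]), center_mol=np.array([0]),
                            split=np.array(["train"]))
        label_delta(ds, theory)
        assert ds.labels[0] == pytest.approx(0.0, abs=1e-12)

    def test_label_equals_two_evaluate_calls(self, theory, ll_source):
        spec = CarveSpec(radii=(3.5,), counts={3.5: 4}, seed=6)
        ds = label_delta(build_cumulative_dataset(ll_source, spec), theory)
        for c, lbl in zip(ds.clusters, ds.labels):
            direct = (evaluate(theory, "HL", c).energy
                      - evaluate(theory, "LL", c).energy)
            assert lbl == pytest.approx(direct, abs=1e-12)
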