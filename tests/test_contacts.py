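import numpy as np
import pytest

from glycostd.contacts import (
    ContactSpec, contact_distances, dbscan_conformers, kabsch_rotate,
    rdf, rmsd_series, rmsf_per_unit,
)
from glycostd.errors import SelectionError, ValidationError
from glycostd.structures import Atom, Ensemble, Frame
from glycostd.synthetic import ToyComplexSpec, generate_toy_complex

from conftest import make_atom


def _frame_from_coords(coords, names=None, chain="A", resname="ALA"):
    names = names or [f"A{i}" for i in range(len(coords))]
    return Frame([
        make_atom(n, "C", resname, i + 1, chain, c)
        for i, (n, c) in enumerate(zip(names, coords))
    ])


class TestContactDistances:
    def test_trivial_distance(self, two_atom_ensemble):
        rep = contact_distances(
            two_atom_ensemble,
            [ContactSpec("c", "L:1:S1", "P:2:NZ")],
            frame_range=slice(0, 2),
        )
        assert rep.contacts["c"]["mean"] == pytest.approx(5.0)
        assert rep.contacts["c"]["sd"] == pytest.approx(0.0)

    def test_ambiguous_address_lists_matches(self):
        fr = Frame([
            make_atom("NZ", "N", "LYS", 1, "P", (0, 0, 0)),
            make_atom("NZ", "N", "LYS", 2, "P", (1, 0, 0)),
            make_atom("S1", "S", "SUL", 3, "L", (2, 0, 0)),
        ])
        ens = Ensemble([fr])
        with pytest.raises(SelectionError, match="2 atoms"):
            contact_distances(ens, [ContactSpec("c", "L:3:S1", "NZ")], slice(0, 1))

    def test_stationary_mean_converges_to_target(self):
        target, jitter, n = 3.9, 0.3, 4000
        spec = ToyComplexSpec(
            n_frames=n, seed=13, contact_targets=[("k114", target, jitter)]
        )
        rep = contact_distances(
            generate_toy_complex(spec),
            [ContactSpec("k114", "L:20:S1", "P:120:NZ")],
            frame_range=slice(0, n),
        )
        assert rep.contacts["k114"]["mean"] == pytest.approx(
            target, abs=3 * jitter / np.sqrt(n)
        )

    def test_default_range_is_second_half(self):
        # distance jumps at half-time; the default average must only see the tail
        frames = [
            _frame_from_coords([(0, 0, 0), (10 if t < 5 else 2, 0, 0)], ["A0", "A1"])
            for t in range(10)
        ]
        rep = contact_distances(Ensemble(frames), [ContactSpec("c", "A0", "A1")])
        assert rep.contacts["c"]["mean"] == pytest.approx(2.0)


class TestRmsd:
    def test_identical_frames_zero(self):
        fr = _frame_from_coords([(0, 0, 0), (1, 1, 1)])
        series = rmsd_series(Ensemble([fr, fr]), fr, "chain A", superpose=False)
        np.testing.assert_allclose(series, 0.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 3)) * 4
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = base @ q.T + [10.0, -3.0, 7.0]
        ens = Ensemble([_frame_from_coords(base), _frame_from_coords(moved)])
        series = rmsd_series(ens, ens.frames[0], "chain A", superpose=True)
        assert series[1] < 1e-8

    def test_hand_value_without_superposition(self):
        ref = _frame_from_coords([(0, 0, 0), (5, 0, 0)])
        disp = _frame_from_coords([(1, 0, 0), (8, 0, 0)])  # displacements 1 and 3 A
        series = rmsd_series(Ensemble([disp]), ref, "chain A", superpose=False)
        assert series[0] == pytest.approx(np.sqrt(5), abs=1e-12)

    def test_atom_count_mismatch(self):
        ref = _frame_from_coords([(0, 0, 0)])
        ens = Ensemble([_frame_from_coords([(0, 0, 0), (1, 0, 0)])])
        with pytest.raises(ValidationError):
            rmsd_series(ens, ref, "chain A")


class TestRmsf:
    def test_static_ensemble_zero(self):
        fr = _frame_from_coords([(0, 0, 0), (3, 0, 0)])
        out = rmsf_per_unit(Ensemble([fr] * 4, ), ["chain A"], superpose=False)
        assert out["chain A"] == pytest.approx(0.0)

    def test_oscillating_atom_hand_value(self):
        frames = [
            _frame_from_coords([(dx, 0, 0), (10, 0, 0), (0, 10, 0)])
            for dx in (1.0, -1.0, 1.0, -1.0)
        ]
        out = rmsf_per_unit(Ensemble(frames), ["atom_name A0"], superpose=False)
        assert out["atom_name A0"] == pytest.approx(1.0)

    def test_jitter_monotonicity(self):
        rng = np.random.default_rng(5)
        frames = []
        for _ in range(60):
            a = np.array([0.0, 0.0, 0.0]) + rng.normal(scale=1.0, size=3)
            b = np.array([20.0, 0.0, 0.0]) + rng.normal(scale=0.2, size=3)
            frames.append(_frame_from_coords([a, b], ["JA", "JB"]))
        out = rmsf_per_unit(Ensemble(frames), ["atom_name JA", "atom_name JB"],
                            superpose=False)
        assert out["atom_name JA"] > out["atom_name JB"]

    def test_empty_group_errors(self):
        ens = Ensemble([_frame_from_coords([(0, 0, 0)])])
        with pytest.raises(ValidationError):
            rmsf_per_unit(ens, ["chain Z"])


class TestDbscan:
    @staticmethod
    def _family(rng, side, n):
        base = np.array([(0, 0, 0), (side, 0, 0), (side, side, 0), (0, side, 0)],
                        dtype=float)
        frames = []
        for _ in range(n):
            jitter = rng.normal(scale=0.05, size=base.shape)
            shift = rng.normal(scale=5.0, size=3)  # rigid motion is irrelevant
            frames.append(_frame_from_coords(base + jitter + shift))
        return frames

    def test_two_conformer_families(self):
        rng = np.random.default_rng(17)
        frames = self._family(rng, 2.0, 100) + self._family(rng, 4.0, 100)
        res = dbscan_conformers(Ensemble(frames), "chain A", epsilon=0.5, min_points=25)
        assert res.n_clusters == 2
        assert np.sum(res.labels == -1) == 0
        # the two halves end up in different clusters
        assert len(set(res.labels[:100])) == 1
        assert res.labels[0] != res.labels[150]

    def test_identical_frames_single_cluster(self):
        fr = _frame_from_coords([(0, 0, 0), (2, 0, 0), (0, 2, 0)])
        res = dbscan_conformers(Ensemble([fr] * 30, ), "chain A", 0.5, 25)
        assert res.n_clusters == 1

    def test_below_min_points_all_noise(self):
        fr = _frame_from_coords([(0, 0, 0), (2, 0, 0)])
        res = dbscan_conformers(Ensemble([fr] * 10), "chain A", 0.5, 25)
        assert np.all(res.labels == -1)

    def test_permutation_stability(self):
        rng = np.random.default_rng(23)
        frames = self._family(rng, 2.0, 40) + self._family(rng, 4.0, 40)
        ens = Ensemble(frames)
        res = dbscan_conformers(ens, "chain A", 0.5, 10)
        perm = rng.permutation(len(frames))
        res_p = dbscan_conformers(ens.subset_frames(perm), "chain A", 0.5, 10)
        # memberships agree up to cluster relabelling
        for i in range(len(frames)):
            for j in range(i + 1, len(frames)):
                same = res.labels[perm[i]] == res.labels[perm[j]] != -1
                same_p = res_p.labels[i] == res_p.labels[j] != -1
                assert same == same_p


class TestRdf:
    @staticmethod
    def _uniform_ensemble(n_frames=100, n_sol=500, cell=24.0, seed=21):
        rng = np.random.default_rng(seed)
        frames = []
        for t in range(n_frames):
            atoms = [make_atom("REF", "C", "REF", 1, "L", (cell / 2,) * 3)]
            for w, pos in enumerate(rng.random((n_sol, 3)) * cell):
                atoms.append(make_atom("O", "O", "HOH", 100 + w, "W", pos))
            frames.append(Frame(atoms))
        return Ensemble(frames), cell ** 3

    def test_uniform_solvent_bulk_g_is_one(self):
        ens, V = self._uniform_ensemble()
        profile = rdf(ens, "resname REF", "resname HOH and name O", 10.0, 0.1, V)
        bulk = profile.g[(profile.bin_centers >= 3.0)]
        assert np.mean(bulk) == pytest.approx(1.0, abs=0.05)

    def test_no_solvent_in_range_gives_zero(self):
        atoms = [
            make_atom("REF", "C", "REF", 1, "L", (0, 0, 0)),
            make_atom("O", "O", "HOH", 2, "W", (50, 50, 50)),
        ]
        profile = rdf(Ensemble([Frame(atoms)]), "resname REF",
                      "resname HOH", 10.0, 0.1, 1000.0)
        np.testing.assert_array_equal(profile.g, 0.0)

    def test_single_pair_hand_normalization(self):
        # one solvent atom at r = 3.05, one frame: only bin [3.0, 3.1) is hit and
        # its value is V / (Npair * 4 pi r^2 dr) with r the bin centre
        V, dr = 1000.0, 0.1
        atoms = [
            make_atom("REF", "C", "REF", 1, "L", (0, 0, 0)),
            make_atom("O", "O", "HOH", 2, "W", (3.05, 0, 0)),
        ]
        profile = rdf(Ensemble([Frame(atoms)]), "resname REF", "resname HOH",
                      10.0, dr, V)
        expected = V / (1 * 4.0 * np.pi * 3.05 ** 2 * dr)
        hit = int(3.0 / dr)
        assert profile.g[hit] == pytest.approx(expected, rel=1e-6)
        assert np.count_nonzero(profile.g) == 1

    def test_integral_matches_neighbor_count(self):
        ens, V = self._uniform_ensemble(n_frames=20, n_sol=300)
        profile = rdf(ens, "resname REF", "resname HOH", 10.0, 0.1, V)
        integral = np.sum(
            profile.g * profile.rho_bulk * 4.0 * np.pi
            * profile.bin_centers ** 2 * 0.1
        )
        # independent direct count
        xyz = ens.coords()
        ref = xyz[:, 0]
        counts = [
            np.sum(np.linalg.norm(xyz[t, 1:] - ref[t], axis=1) < 10.0)
            for t in range(len(ens))
        ]
        assert integral == pytest.approx(np.mean(counts), rel=0.01)

    def test_bad_parameters(self, two_atom_ensemble):
        with pytest.raises(ValidationError):
            rdf(two_atom_ensemble, "chain L", "chain P", r_max=-1.0)


class TestKabsch:
    def test_recovers_rotated_copy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 3))
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        y = x @ q.T + [4.0, 5.0, -6.0]
        np.testing.assert_allclose(kabsch_rotate(y, x), x, atol=1e-10)
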