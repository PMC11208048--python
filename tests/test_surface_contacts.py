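"""SASA/rASA, surface classification, contact maps and interface metrics."""

import numpy as np
import pytest

from h3opt.fixtures import build_backbone
from h3opt.structures import AtomRecord, Residue
from h3opt.surface import (
    MAX_ASA_TIEN2013,
    ContactMap,
    SurfaceProfile,
    binding_site_metrics,
    contact_map,
    contact_propensity,
    distance_mse,
    rasa,
    sasa,
    surface_profile,
    surface_residues,
)


def _res(aa, coords_names, number=1):
    atoms = [AtomRecord(n, el, c) for n, el, c in coords_names]
    return Residue(aa=aa, author_number=number, seq_index=number - 1, atoms=atoms)


class TestSasa:
    def test_single_atom_matches_sphere_area(self):
        """An isolated carbon: SASA -> 4 pi (r + probe)^2 (Bondi r = 1.7)."""
        res = [_res("A", [("CA", "C", np.zeros(3))])]
        area = sasa(res, probe=1.4, sphere_points=960)[0]
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_fully_buried_atom_is_zero(self):
        """An atom enclosed in a tight cage of neighbours has no exposure."""
        cage = []
        k = 0
        for phi in np.linspace(0, np.pi, 6):
            for theta in np.linspace(0, 2 * np.pi, 10, endpoint=False):
                c = 2.2 * np.array(
                    [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
                )
                cage.append((f"C{k}", "C", c))
                k += 1
        res = [
            _res("A", [("CA", "C", np.zeros(3))], number=1),
            _res("A", cage, number=2),
        ]
        assert sasa(res)[0] < 1e-9  # central residue fully occluded

    def test_quadrature_convergence(self, toy_pair):
        native, _, _ = toy_pair
        chain = native.chain("H")[:20]
        a = sasa(chain, sphere_points=960).sum()
        b = sasa(chain, sphere_points=1920).sum()
        assert abs(a - b) / b < 0.005

    def test_deterministic(self, toy_pair):
        native, _, _ = toy_pair
        chain = native.chain("H")[:10]
        assert np.array_equal(sasa(chain), sasa(chain))


class TestRasa:
    def test_zero_sasa(self):
        assert rasa(np.zeros(1), "A")[0] == 0.0

    def test_table_max_normalises_to_one(self):
        assert rasa(np.array([MAX_ASA_TIEN2013["A"]]), "A")[0] == pytest.approx(1.0)

    def test_extended_glycine_is_exposed(self):
        s = build_backbone("AGA", np.full(3, -120.0), np.full(3, 130.0))
        profile = surface_profile(s.chain("H"))
        assert profile.rasa[1] > 0.5

    def test_unknown_residue_rejected(self):
        from h3opt.structures import StructureError

        with pytest.raises(StructureError):
            rasa(np.array([10.0]), "X")


class TestSurfaceResidues:
    def _profile(self, rasas, seq=None):
        n = len(rasas)
        seq = seq or "A" * n
        return SurfaceProfile(sequence=seq, sasa=np.asarray(rasas) * 100,
                              rasa=np.asarray(rasas, dtype=float))

    def test_strict_cutoff(self):
        idx, _ = surface_residues(self._profile([0.30, 0.25, 0.10]))
        assert idx == [0]  # 0.25 is NOT surface (strict >)

    def test_class_counts(self):
        idx, counts = surface_residues(self._profile([0.9, 0.9, 0.9, 0.9], seq="KDAS"))
        assert counts["positive"] == 1
        assert counts["negative"] == 1
        assert counts["hydrophobic"] == 1
        assert counts["neutral-polar"] == 1

    def test_all_buried(self):
        idx, counts = surface_residues(self._profile([0.0, 0.1, 0.2]))
        assert idx == []
        assert all(v == 0 for v in counts.values())

    def test_monotone_in_cutoff(self, toy_pair):
        native, _, _ = toy_pair
        profile = surface_profile(native.chain("H"))
        sizes = [len(surface_residues(profile, cutoff=c)[0]) for c in (0.1, 0.25, 0.5)]
        assert sizes == sorted(sizes, reverse=True)


def _point_residue(aa, xyz, number):
    return _res(aa, [("CA", "C", np.asarray(xyz, dtype=float))], number)


class TestContactMap:
    def test_threshold_rule(self):
        ab = [_point_residue("A", [0, 0, 0], 1)]
        ag_in = [_point_residue("G", [4.9, 0, 0], 1)]
        ag_out = [_point_residue("G", [5.1, 0, 0], 1)]
        assert contact_map(ab, ag_in).contacts[0, 0]
        assert not contact_map(ab, ag_out).contacts[0, 0]

    def test_min_dist_equals_bruteforce_oracle(self):
        rng = np.random.default_rng(4)

        def many_atom_res(aa, number):
            atoms = [(f"C{k}", "C", rng.uniform(-8, 8, 3)) for k in range(4)]
            return _res(aa, atoms, number)

        ab = [many_atom_res("A", i + 1) for i in range(3)]
        ag = [many_atom_res("G", i + 1) for i in range(3)]
        cm = contact_map(ab, ag)
        for i, ra in enumerate(ab):
            for j, rg in enumerate(ag):
                brute = min(
                    np.linalg.norm(x.coord - y.coord)
                    for x in ra.atoms
                    for y in rg.atoms
                )
                assert cm.min_dist[i, j] == pytest.approx(brute, abs=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        ab = [_point_residue("A", rng.uniform(-5, 5, 3), i + 1) for i in range(4)]
        ag = [_point_residue("G", rng.uniform(-5, 5, 3), i + 1) for i in range(3)]
        assert np.allclose(
            contact_map(ab, ag).min_dist, contact_map(ag, ab).min_dist.T, atol=1e-12
        )

    def test_empty_chain_rejected(self):
        from h3opt.structures import StructureError

        with pytest.raises(StructureError):
            contact_map([], [_point_residue("A", [0, 0, 0], 1)])


def _map_from_dists(dists, ab_seq=None, ag_seq=None, threshold=5.0):
    d = np.asarray(dists, dtype=float)
    return ContactMap(
        min_dist=d,
        threshold=threshold,
        ab_sequence=ab_seq or "A" * d.shape[0],
        ag_sequence=ag_seq or "G" * d.shape[1],
    )


class TestBindingSiteMetrics:
    def test_perfect_prediction(self):
        m = _map_from_dists([[3.0, 8.0], [9.0, 4.0]])
        out = binding_site_metrics(m, m)
        assert out["precision"] == 1.0
        assert out["recall"] == 1.0
        assert out["accuracy"] == 1.0

    def test_confusion_arithmetic(self):
        # 100 antigen residues: 8 TP, 2 FP, 2 FN, 88 TN
        nat = np.full((1, 100), 10.0)
        nat[0, :10] = 3.0
        pred = np.full((1, 100), 10.0)
        pred[0, :8] = 3.0  # TP
        pred[0, 10:12] = 3.0  # FP
        out = binding_site_metrics(_map_from_dists(pred), _map_from_dists(nat))
        assert out["precision"] == pytest.approx(0.8)
        assert out["accuracy"] == pytest.approx(0.96)
        assert out["recall"] == pytest.approx(0.8)

    def test_empty_prediction_has_null_precision(self):
        nat = np.full((1, 10), 3.0)
        pred = np.full((1, 10), 9.0)
        out = binding_site_metrics(_map_from_dists(pred), _map_from_dists(nat))
        assert out["precision"] is None
        assert out["accuracy"] == pytest.approx(0.0)


class TestDistanceMse:
    def test_zero_on_identity(self):
        m = _map_from_dists(np.random.default_rng(0).uniform(2, 12, (4, 5)))
        out = distance_mse(m, m)
        assert all(v in (0.0, None) for v in out.values())

    def test_uniform_error(self):
        nat = _map_from_dists(np.full((3, 3), 4.0))
        pred = _map_from_dists(np.full((3, 3), 5.0))
        out = distance_mse(pred, nat, thresholds=(5.0,))
        assert out[5.0] == pytest.approx(1.0)

    def test_hand_built_toy(self):
        nat = _map_from_dists([[3.0, 6.0], [4.0, 10.0]])
        pred = _map_from_dists([[3.5, 7.0], [5.0, 9.0]])
        out = distance_mse(pred, nat, thresholds=(4.0, 6.0, 12.0))
        assert out[4.0] == pytest.approx((0.5**2 + 1.0**2) / 2)
        assert out[6.0] == pytest.approx((0.5**2 + 1.0**2 + 1.0**2) / 3)
        assert out[12.0] == pytest.approx((0.25 + 1 + 1 + 1) / 4)

    def test_no_qualifying_pairs_is_null(self):
        nat = _map_from_dists(np.full((2, 2), 20.0))
        out = distance_mse(nat, nat, thresholds=(5.0,))
        assert out[5.0] is None


class TestContactPropensity:
    def test_single_contact(self):
        m = _map_from_dists([[3.0]], ab_seq="A", ag_seq="G")
        mat, flagged = contact_propensity([m])
        from h3opt.structures import AMINO_ACIDS

        ia, ig = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("G")
        assert mat[ia, ig] == 1.0
        assert mat.sum() == 1.0
        assert flagged

    def test_no_contacts_flagged(self):
        m = _map_from_dists([[30.0]])
        mat, flagged = contact_propensity([m])
        assert not flagged
        assert np.all(mat == 0)

    def test_normalisation(self):
        rng = np.random.default_rng(6)
        maps = [
            _map_from_dists(rng.uniform(2, 10, (3, 4)),
                            ab_seq="ARD", ag_seq="GYLK")
            for _ in range(3)
        ]
        mat, flagged = contact_propensity(maps)
        assert flagged
        assert mat.sum() == pytest.approx(1.0, abs=1e-12)
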