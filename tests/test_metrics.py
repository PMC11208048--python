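"""Superposition, loop RMSDs, TM-score, GDT and Z-score aggregation."""

import numpy as np
import pytest

from h3opt.geometry import RigidTransform, kabsch, rmsd, rotation_about_axis
from h3opt.metrics import (
    SuperpositionMode,
    evaluate_model,
    gdt_fractions,
    gdt_ha,
    gdt_ts,
    h3_rmsd,
    superpose,
    tm_d0,
    tm_from_distances,
    tm_score,
    z_average,
    zscores_across_methods,
)
from h3opt.structures import StructureError


def quaternion_fit_rmsd(mobile, target):
    """Independent least-squares superposition oracle (Horn's quaternion
    method): best-fit RMSD without using the Kabsch/SVD code path."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e = float((a**2).sum() + (b**2).sum() - 2.0 * lam)
    return np.sqrt(max(e, 0.0) / len(a))


class TestSuperpose:
    def test_identical_structures(self, toy_pair):
        native, _, ann = toy_pair
        _, fit = superpose(native, native, ann=ann)
        assert fit == pytest.approx(0.0, abs=1e-9)

    def test_known_rigid_motion_recovered(self, toy_pair):
        native, _, ann = toy_pair
        tf_true = RigidTransform(rotation_about_axis([0.2, 1.0, 0.5], 2.1), np.array([3.0, -7.0, 1.0]))
        moved = native.transformed(tf_true)
        tf, fit = superpose(moved, native, ann=ann)
        assert fit < 1e-6
        assert np.allclose(tf.rotation, tf_true.inverse().rotation, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_kabsch_matches_quaternion_oracle_on_toys(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((5, 3)) * 4.0
        b = rng.standard_normal((5, 3)) * 4.0
        tf = kabsch(a, b)
        assert rmsd(tf.apply(a), b) == pytest.approx(quaternion_fit_rmsd(a, b), abs=1e-9)

    def test_fv_backbone_mode_uses_all_chains(self, toy_pair):
        native, model, ann = toy_pair
        _, fit = superpose(model, native, mode=SuperpositionMode.FV_BACKBONE)
        assert fit > 0  # the loop participates in this selection

    def test_selection_mismatch_raises(self, toy_pair):
        native, _, ann = toy_pair
        truncated = native.copy()
        truncated.chains["H"] = truncated.chains["H"][:-1]
        with pytest.raises(StructureError):
            superpose(truncated, native, ann=ann)


class TestH3Rmsd:
    def test_zero_on_identity_all_classes(self, toy_pair):
        native, _, ann = toy_pair
        for cls in ("CA", "backbone", "heavy"):
            assert h3_rmsd(native, native, ann, cls) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_displacement_arithmetic(self, toy_pair):
        """A +2 A loop shift after a clean framework fit reads as exactly 2."""
        native, _, ann = toy_pair
        shifted = native.copy()
        for i in ann.indices:
            for a in shifted.chain("H")[i].atoms:
                a.coord = a.coord + np.array([2.0, 0.0, 0.0])
        assert h3_rmsd(shifted, native, ann, "CA") == pytest.approx(2.0, abs=1e-9)
        assert h3_rmsd(shifted, native, ann, "heavy") == pytest.approx(2.0, abs=1e-9)

    def test_glycine_only_loop_sidechain_is_nan(self):
        from h3opt.fixtures import build_backbone
        from h3opt.structures import annotate_h3

        seq = "AAAAAAAA" + "GGGGGG" + "AAAAAAAA"
        n = len(seq)
        s = build_backbone(seq, np.full(n, -120.0), np.full(n, 130.0))
        ann = annotate_h3(s, "H", span=(8, 13))
        assert np.isnan(h3_rmsd(s, s, ann, "sidechain"))

    def test_rmsd_equals_bruteforce_definition_on_toys(self, toy_pair):
        native, model, ann = toy_pair
        tf, _ = superpose(model, native, ann=ann)
        got = h3_rmsd(model, native, ann, "CA")
        mob = np.array([model.chain("H")[i].coord("CA") for i in ann.indices])
        tgt = np.array([native.chain("H")[i].coord("CA") for i in ann.indices])
        manual = np.sqrt(np.mean(np.sum((tf.apply(mob) - tgt) ** 2, axis=1)))
        assert got == pytest.approx(manual, abs=1e-12)

    def test_metrics_invariant_to_joint_rigid_motion(self, toy_pair):
        native, model, ann = toy_pair
        tf = RigidTransform(rotation_about_axis([1.0, 0.0, 2.0], 0.9), np.array([10.0, 5.0, -3.0]))
        r1 = h3_rmsd(model, native, ann)
        r2 = h3_rmsd(model.transformed(tf), native.transformed(tf), ann)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestTmScore:
    def test_identity(self, toy_pair):
        native, _, _ = toy_pair
        ca = native.ca_coords("H")
        assert tm_score(ca, ca) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_at_d0(self):
        d0 = tm_d0(30)
        assert tm_from_distances(np.full(30, d0)) == pytest.approx(0.5, abs=1e-12)

    def test_short_chain_d0_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert tm_d0(10) == 0.5

    def test_search_beats_or_equals_global_fit(self, toy_pair):
        native, model, _ = toy_pair
        ca_m, ca_n = model.ca_coords("H"), native.ca_coords("H")
        assert tm_score(ca_m, ca_n) >= tm_score(ca_m, ca_n, search=False) - 1e-12

    def test_agrees_with_independent_search_oracle(self):
        """Multi-start rigid-body optimisation of the TM objective (an
        independent search strategy) agrees with the windowed heuristic."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        from h3opt.fixtures import build_backbone

        helix = build_backbone("A" * 30, np.full(30, -57.0), np.full(30, -47.0))
        coil = build_backbone(
            "A" * 30,
            np.linspace(-150.0, -60.0, 30),
            np.linspace(150.0, -40.0, 30),
        )
        a = helix.ca_coords("H")
        b = coil.ca_coords("H")
        d0 = tm_d0(30)

        def neg_tm(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            d = np.linalg.norm(a @ rot.T + x[3:] - b, axis=1)
            return -tm_from_distances(d)

        rng = np.random.default_rng(0)
        best = 0.0
        starts = [np.zeros(6)]
        tf = kabsch(a, b)
        starts.append(np.r_[Rotation.from_matrix(tf.rotation).as_rotvec(), tf.translation])
        for _ in range(30):
            starts.append(np.r_[rng.uniform(-np.pi, np.pi, 3), rng.uniform(-20, 20, 3)])
        for x0 in starts:
            res = minimize(neg_tm, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10})
            best = max(best, -res.fun)
        ours = tm_score(a, b)
        assert ours == pytest.approx(best, abs=2e-3)


class TestGdt:
    def test_identity(self, toy_pair):
        native, _, _ = toy_pair
        ca = native.ca_coords("H")
        assert gdt_ts(ca, ca) == pytest.approx(1.0)
        assert gdt_ha(ca, ca) == pytest.approx(1.0)

    def test_fixed_frame_fraction_arithmetic(self):
        rng = np.random.default_rng(3)
        native = rng.standard_normal((20, 3)) * 20.0
        model = native.copy()
        d = np.zeros(20)
        d[:10] = 0.2
        d[10:] = 3.0
        model[:, 0] += d
        ts = gdt_fractions(model, native, (1, 2, 4, 8), superposition="none").mean()
        ha = gdt_fractions(model, native, (0.5, 1, 2, 4), superposition="none").mean()
        assert ts == pytest.approx(0.75)
        assert ha == pytest.approx(0.625)
        # the search may only increase these lower bounds
        assert gdt_ts(model, native) >= ts - 1e-12
        assert gdt_ha(model, native) >= ha - 1e-12

    @pytest.mark.parametrize("seed", range(100))
    def test_ha_never_exceeds_ts_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 40))
        a = rng.standard_normal((n, 3)) * 8.0
        b = a + rng.standard_normal((n, 3)) * rng.uniform(0.2, 4.0)
        assert gdt_ha(a, b) <= gdt_ts(a, b) + 1e-12

    def test_monotone_in_cutoffs(self, toy_pair):
        native, model, _ = toy_pair
        ca_m, ca_n = model.ca_coords("H"), native.ca_coords("H")
        small = gdt_fractions(ca_m, ca_n, (0.5, 1.0, 2.0, 4.0))
        large = gdt_fractions(ca_m, ca_n, (1.0, 2.0, 4.0, 8.0))
        assert np.all(large >= small - 1e-12)


class TestZScores:
    def test_z_average(self):
        assert z_average(1.0, 1.0, 1.0) == 1.0
        assert z_average(0.0, 0.0, 0.0) == 0.0
        assert z_average(0.3, 0.6, 0.9) == pytest.approx(0.6)

    def test_two_methods_sample_sd(self):
        z = zscores_across_methods({"a": 0.8, "b": 0.9})
        assert z["a"] == pytest.approx(-np.sqrt(0.5), abs=1e-12)
        assert z["b"] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_degenerate_all_equal(self):
        z = zscores_across_methods({"a": 0.7, "b": 0.7, "c": 0.7})
        assert all(v == 0.0 for v in z.values())

    def test_location_invariance(self):
        vals = {"a": 0.5, "b": 0.8, "c": 0.65}
        z1 = zscores_across_methods(vals)
        z2 = zscores_across_methods({k: v + 10.0 for k, v in vals.items()})
        for k in vals:
            assert z1[k] == pytest.approx(z2[k], abs=1e-9)


def test_evaluate_model_report(toy_pair):
    native, model, ann = toy_pair
    report = evaluate_model(model, native, ann)
    assert report.rmsd_ca == pytest.approx(3.0, rel=0.05)
    assert report.gdt_ha <= report.gdt_ts
    assert 0.0 < report.tm_score <= 1.0
    assert report.superposition_mode == "vh_backbone_no_h3"
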