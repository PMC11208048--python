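"""Confidence gating, template lookup, grafting and routing."""

import numpy as np
import pytest

from h3opt.fixtures import FixtureSpec, make_toy_fv, perturb_model
from h3opt.geometry import RigidTransform, rotation_about_axis
from h3opt.metrics import h3_rmsd
from h3opt.structures import StructureError
from h3opt.templates import (
    GraftError,
    H3TemplateDB,
    LoopTemplate,
    Route,
    cbm_decide,
    extract_loop,
    graft_loop,
    route,
    tgm_lookup,
)


def _conf_list(length, span, h3_values, framework=95.0):
    conf = [framework] * length
    for i, v in zip(span, h3_values):
        conf[i] = v
    return conf


class TestCbm:
    @pytest.mark.parametrize(
        "h3_conf,expected_mean,accepted",
        [
            ([85.0] * 10, 0.85, True),
            ([80.0] * 10, 0.80, False),  # strict inequality at the cutoff
            ([90.0, 70.0, 80.0, 80.0] + [80.0] * 6, 0.80, False),
        ],
    )
    def test_gate_at_cutoff(self, toy_pair, h3_conf, expected_mean, accepted):
        native, _, ann = toy_pair
        conf = _conf_list(len(native.chain("H")), ann.indices, h3_conf)
        mean, accept = cbm_decide(conf, ann)
        assert mean == pytest.approx(expected_mean)
        assert accept is accepted

    def test_missing_confidence_not_imputed(self, toy_pair):
        native, _, ann = toy_pair
        conf = [95.0] * len(native.chain("H"))
        conf[ann.start_index] = None
        with pytest.raises(StructureError, match="missing confidence"):
            cbm_decide(conf, ann)

    def test_cutoff_configurable(self, toy_pair):
        native, _, ann = toy_pair
        conf = _conf_list(len(native.chain("H")), ann.indices, [85.0] * ann.length)
        _, accept = cbm_decide(conf, ann, cutoff=0.9)
        assert not accept


class TestTgm:
    def test_exact_match(self, toy_pair):
        native, _, ann = toy_pair
        tpl = extract_loop(native, ann, source_id="x1")
        db = H3TemplateDB()
        db.add(tpl)
        assert tgm_lookup(tpl.sequence, db) is tpl
        assert tgm_lookup(tpl.sequence.lower(), db) is tpl

    def test_no_fuzzy_match(self, toy_pair):
        native, _, ann = toy_pair
        tpl = extract_loop(native, ann)
        db = H3TemplateDB()
        db.add(tpl)
        near = "A" + tpl.sequence[1:]
        assert near != tpl.sequence
        assert tgm_lookup(near, db) is None

    def test_empty_db(self):
        assert tgm_lookup("ARDDYWG", H3TemplateDB()) is None

    def test_db_roundtrip_via_directory(self, toy_pair, tmp_path):
        native, _, ann = toy_pair
        db = H3TemplateDB()
        db.add(extract_loop(native, ann, source_id="src42"))
        db.save(tmp_path / "tdb")
        db2 = H3TemplateDB.load(tmp_path / "tdb")
        assert len(db2) == 1
        (seq,) = db2.entries
        assert db2.entries[seq].source_id == "src42"


class TestGraft:
    def test_self_graft_identity(self, toy_pair):
        _, model, ann = toy_pair
        tpl = extract_loop(model, ann)
        grafted, anchor_rmsd = graft_loop(model, ann, tpl)
        assert anchor_rmsd == pytest.approx(0.0, abs=1e-9)
        for a, b in zip(model.chain("H"), grafted.chain("H")):
            for x, y in zip(a.atoms, b.atoms):
                assert np.allclose(x.coord, y.coord, atol=1e-9)

    def test_rigid_motion_recovery(self, toy_pair):
        _, model, ann = toy_pair
        tpl = extract_loop(model, ann)
        tf = RigidTransform(rotation_about_axis([1.0, 0.5, 0.2], 1.3), np.array([7.0, -2.0, 4.0]))
        for r in tpl.residues:
            for a in r.atoms:
                a.coord = tf.apply(a.coord)
        grafted, anchor_rmsd = graft_loop(model, ann, tpl)
        assert anchor_rmsd < 1e-6
        for i in ann.indices:
            for x, y in zip(model.chain("H")[i].atoms, grafted.chain("H")[i].atoms):
                assert np.allclose(x.coord, y.coord, atol=1e-6)

    def test_anchor_rmsd_matches_independent_lsq_oracle(self, toy_pair):
        """Achieved anchor RMSD equals a brute-force optimal rigid fit."""
        from scipy.spatial.transform import Rotation
        from h3opt.templates import _anchor_coords

        native, model, ann = toy_pair
        tpl = extract_loop(native, ann)
        _, anchor_rmsd = graft_loop(model, ann, tpl)

        a = _anchor_coords(tpl.residues)
        b = _anchor_coords(model.chain("H")[ann.start_index : ann.end_index + 1])
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        oracle = rssd / np.sqrt(len(a))
        assert anchor_rmsd == pytest.approx(oracle, abs=1e-9)

    def test_non_loop_atoms_bitwise_unchanged(self, toy_pair):
        native, model, ann = toy_pair
        grafted, _ = graft_loop(model, ann, extract_loop(native, ann))
        for i, (a, b) in enumerate(zip(model.chain("H"), grafted.chain("H"))):
            if i in ann.indices:
                continue
            for x, y in zip(a.atoms, b.atoms):
                assert np.array_equal(x.coord, y.coord)

    def test_sequence_mismatch_rejected(self, toy_pair):
        native, model, ann = toy_pair
        tpl = extract_loop(native, ann)
        tpl.residues[0].aa = "A" if tpl.residues[0].aa != "A" else "G"
        tpl.sequence = "".join(r.aa for r in tpl.residues)
        with pytest.raises(GraftError, match="does not match"):
            graft_loop(model, ann, tpl)

    def test_missing_anchor_atom_named(self, toy_pair):
        native, model, ann = toy_pair
        tpl = extract_loop(native, ann)
        tpl.residues[0].atoms = [a for a in tpl.residues[0].atoms if a.name != "C"]
        with pytest.raises(GraftError, match="anchor atom C"):
            graft_loop(model, ann, tpl)

    def test_graft_reduces_loop_rmsd_on_perturbed_model(self):
        """With the native loop in the database, grafting must beat a badly
        perturbed prediction (the perturbation exceeds any anchor noise)."""
        spec = FixtureSpec(n_framework=60, h3_length=12, seed=21)
        native, ann = make_toy_fv(spec)
        model = perturb_model(native, ann, target_rmsd=5.0, seed=22)
        grafted, _ = graft_loop(model, ann, extract_loop(native, ann))
        assert h3_rmsd(grafted, native, ann) < h3_rmsd(model, native, ann)


class TestRouting:
    def _setup(self, toy_pair, h3_conf, with_template):
        native, model, ann = toy_pair
        conf = _conf_list(len(model.chain("H")), ann.indices, [h3_conf] * ann.length)
        db = H3TemplateDB()
        if with_template:
            db.add(extract_loop(model, ann, source_id="tpl"))
        return model, ann, conf, db

    def test_cbm_takes_precedence_over_template(self, toy_pair):
        model, ann, conf, db = self._setup(toy_pair, 90.0, True)
        decision = route(model, ann, conf, db)
        assert decision.route is Route.KEEP_AF2
        assert decision.mean_confidence == pytest.approx(0.9)

    def test_low_confidence_with_template_grafts(self, toy_pair):
        model, ann, conf, db = self._setup(toy_pair, 50.0, True)
        decision = route(model, ann, conf, db)
        assert decision.route is Route.GRAFT
        assert decision.template_id == "tpl"

    def test_fallthrough_to_network(self, toy_pair):
        model, ann, conf, db = self._setup(toy_pair, 50.0, False)
        assert route(model, ann, conf, db).route is Route.PSPM

    def test_precedence_override_flag(self, toy_pair):
        model, ann, conf, db = self._setup(toy_pair, 90.0, True)
        decision = route(model, ann, conf, db, cbm_first=False)
        assert decision.route is Route.GRAFT

    @pytest.mark.parametrize("conf_val,with_tpl", [(90.0, True), (90.0, False),
                                                   (50.0, True), (50.0, False)])
    def test_routing_total(self, toy_pair, conf_val, with_tpl):
        model, ann, conf, db = self._setup(toy_pair, conf_val, with_tpl)
        decision = route(model, ann, conf, db)
        assert decision.route in (Route.KEEP_AF2, Route.GRAFT, Route.PSPM)
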