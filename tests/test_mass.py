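"""Center-of-mass laws under deletions, and PTC rigidity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribomech import (
    DeletionError,
    DeletionSpec,
    Selection,
    SelectionError,
    apply_deletion,
    center_of_mass,
    cm_shift_report,
    coarse_grain,
    make_toy_protein_chain,
    ptc_rigidity_summary,
)
from ribomech.coarse import NodeSet, select_node_indices


def _nodeset(positions, components=None, bfactors=None, chain="A"):
    n = len(positions)
    sources = [(chain, i + 1, "CA") for i in range(n)]
    comps = list(components) if components is not None else ["core"] * n
    b = np.asarray(bfactors, dtype=float) if bfactors is not None else np.full(n, 30.0)
    return NodeSet(np.asarray(positions, dtype=float), sources, comps, b)


def _dumbbell(n1=10, n2=10, c1=(-20.0, 0, 0), c2=(20.0, 0, 0), spread=3.0, seed=0,
              n_bridge=0):
    """Two labeled lobes; optionally a few central 'bridge' nodes (PTC host)."""
    rng = np.random.default_rng(seed)
    lobe1 = np.asarray(c1) + rng.normal(0, spread, (n1, 3))
    lobe2 = np.asarray(c2) + rng.normal(0, spread, (n2, 3))
    blocks = [lobe1, lobe2]
    comps = ["lobe1"] * n1 + ["lobe2"] * n2
    if n_bridge:
        blocks.append(rng.normal(0, 1.0, (n_bridge, 3)))
        comps += ["bridge"] * n_bridge
    return _nodeset(np.vstack(blocks), comps), lobe1, lobe2


class TestCenterOfMass:
    def test_unit_cube_vertices(self):
        pos = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        assert np.allclose(center_of_mass(_nodeset(pos)), [0.5, 0.5, 0.5])

    def test_single_node_is_its_own_cm(self):
        ns = _nodeset([[3.0, -2.0, 7.0], [100.0, 0.0, 0.0]], ["a", "b"])
        assert np.allclose(center_of_mass(ns, ["a"]), [3.0, -2.0, 7.0])

    def test_dumbbell_matches_closed_form(self):
        ns, lobe1, lobe2 = _dumbbell(n1=7, n2=13)
        c1, c2 = lobe1.mean(axis=0), lobe2.mean(axis=0)
        expected = (7 * c1 + 13 * c2) / 20
        assert np.allclose(center_of_mass(ns), expected, atol=1e-9)

    def test_subset_cm_equals_brute_force_mean(self, rng):
        pos = rng.normal(0, 10, (30, 3))
        comps = ["a" if i % 3 else "b" for i in range(30)]
        ns = _nodeset(pos, comps)
        idx = [i for i, c in enumerate(comps) if c == "b"]
        assert np.allclose(center_of_mass(ns, ["b"]), pos[idx].mean(axis=0), atol=1e-9)

    def test_mass_weighted_option(self):
        ns = _nodeset([[0.0, 0, 0], [10.0, 0, 0]])
        uniform = center_of_mass(ns, masses=np.array([110.0, 110.0]))
        assert np.allclose(uniform, [5.0, 0, 0])
        weighted = center_of_mass(ns, masses=np.array([300.0, 100.0]))
        assert np.allclose(weighted, [2.5, 0, 0])

    def test_empty_selection_is_an_error(self):
        ns = _nodeset([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises((SelectionError, LookupError)):
            center_of_mass(ns, ["absent"])


class TestApplyDeletion:
    def test_removes_exactly_the_labeled_nodes(self):
        ns, _, _ = _dumbbell(n1=100, n2=50)
        out = apply_deletion(ns, DeletionSpec("d", ("lobe1",)))
        assert out.N == ns.N - 100
        assert all(c == "lobe2" for c in out.components)
        assert ns.N == 150  # original untouched

    def test_empty_spec_is_identity(self):
        ns, _, _ = _dumbbell()
        out = apply_deletion(ns, DeletionSpec("noop"))
        assert out.N == ns.N
        assert np.allclose(out.positions, ns.positions)

    def test_double_deletion_is_order_independent(self):
        ns, _, _ = _dumbbell()
        both = apply_deletion(ns, DeletionSpec("both", ("lobe1", "lobe2")))
        seq1 = apply_deletion(apply_deletion(ns, DeletionSpec("a", ("lobe1",))),
                              DeletionSpec("b", ("lobe2",)))
        seq2 = apply_deletion(apply_deletion(ns, DeletionSpec("b", ("lobe2",))),
                              DeletionSpec("a", ("lobe1",)))
        assert both.N == seq1.N == seq2.N == 0
        assert seq1.sources == seq2.sources

    def test_deleting_protected_ptc_nodes_refused(self):
        ns, _, _ = _dumbbell()
        protected = np.array([0, 1, 2])
        with pytest.raises(DeletionError):
            apply_deletion(ns, DeletionSpec("d", ("lobe1",)), protect=protected)

    def test_deletion_by_selection(self):
        ns = _nodeset(np.arange(15.0).reshape(5, 3))
        out = apply_deletion(ns, DeletionSpec("d", selections=(Selection.from_string("A:1-2"),)))
        assert out.N == 3


class TestCMShiftReport:
    def _report(self, variants):
        ns, _, _ = _dumbbell(n1=12, n2=12, seed=3, n_bridge=3)
        # the PTC stand-in lives on the central bridge nodes (seq 25-27)
        ptc = Selection.from_string("A:25-27")
        return ns, cm_shift_report(ns, variants, ptc)

    def test_deleting_one_lobe_moves_cm_to_remaining_lobe(self):
        ns, report = self._report([DeletionSpec("no_lobe2", ("lobe2",))])
        entry = report.entry("no_lobe2")
        remaining = ns.positions[[i for i, c in enumerate(ns.components) if c != "lobe2"]]
        assert np.allclose(entry.cm, remaining.mean(axis=0), atol=1e-9)
        assert entry.direction_dot < 0  # CM moved away from the deleted lobe

    def test_direction_law_for_every_single_component_deletion(self):
        ns, report = self._report(
            [DeletionSpec("d1", ("lobe1",)), DeletionSpec("d2", ("lobe2",))]
        )
        for name in ("d1", "d2"):
            assert report.entry(name).direction_dot < 0

    def test_compensation_double_deletion_smaller_shift(self, balanced):
        _, nodes, gt, ptc = balanced
        variants = [
            DeletionSpec("dL9", ("L9",)),
            DeletionSpec("dL12", ("L12",)),
            DeletionSpec("double", ("L9", "L12")),
        ]
        report = cm_shift_report(nodes, variants, ptc)
        double = report.entry("double").shift_from_wt
        assert double < report.entry("dL9").shift_from_wt
        assert double < report.entry("dL12").shift_from_wt

    def test_report_matches_fixture_ground_truth(self, balanced):
        _, nodes, gt, ptc = balanced
        variants = [DeletionSpec("dL9", ("L9",)), DeletionSpec("dL12", ("L12",)),
                    DeletionSpec("double", ("L9", "L12"))]
        report = cm_shift_report(nodes, variants, ptc)
        for name, key in [("dL9", "L9"), ("dL12", "L12"), ("double", "L9+L12")]:
            gt_cm = np.array(gt["deletion_cms"][key])
            assert np.linalg.norm(report.entry(name).cm - gt_cm) < 1e-6
        assert np.linalg.norm(report.entry("wild_type").cm - np.array(gt["wild_type_cm"])) < 1e-6

    def test_empty_variant_list_reports_wild_type_only(self):
        ns, report = self._report([])
        assert [e.name for e in report.entries] == ["wild_type"]

    def test_shifts_are_symmetric_pairwise_distances(self):
        ns, report = self._report([DeletionSpec("d1", ("lobe1",)), DeletionSpec("d2", ("lobe2",))])
        for (a, b), v in report.shifts.items():
            assert v == pytest.approx(
                float(np.linalg.norm(report.entry(a).cm - report.entry(b).cm))
            )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(t=st.tuples(*[st.floats(-100, 100) for _ in range(3)]))
    def test_translational_equivariance(self, t):
        t = np.asarray(t)
        ns, _, _ = _dumbbell(n1=8, n2=8, seed=5)
        ptc = Selection.from_string("A:1-3")
        variants = [DeletionSpec("d2", ("lobe2",))]
        rep = cm_shift_report(ns, variants, ptc)
        rep_t = cm_shift_report(ns.transformed(translation=t), variants, ptc)
        for e, e_t in zip(rep.entries, rep_t.entries):
            assert np.allclose(e_t.cm, e.cm + t, atol=1e-8)
            assert e_t.shift_from_wt == pytest.approx(e.shift_from_wt, abs=1e-8)
            assert e_t.distance_to_ptc == pytest.approx(e.distance_to_ptc, abs=1e-8)

    def test_deleting_ptc_nodes_refused_in_report(self):
        ns, _, _ = _dumbbell()
        ptc = Selection.from_string("A:1-3")
        with pytest.raises(DeletionError):
            cm_shift_report(ns, [DeletionSpec("bad", ("lobe1",))], ptc)


class TestPTCRigidity:
    def test_low_b_island_ranks_below_half(self):
        b = np.full(40, 50.0)
        b[:5] = 5.0
        ns = _nodeset(np.random.default_rng(0).normal(0, 10, (40, 3)), bfactors=b)
        summary = ptc_rigidity_summary(ns, Selection.from_string("A:1-5"))
        assert summary.ptc_mean_b == 5.0
        assert summary.median_b == 50.0
        assert summary.ptc_percentile_rank < 50.0

    def test_uniform_b_gives_midrank_fifty(self):
        ns = _nodeset(np.random.default_rng(1).normal(0, 10, (20, 3)),
                      bfactors=np.full(20, 33.0))
        summary = ptc_rigidity_summary(ns, Selection.from_string("A:1-4"))
        assert summary.ptc_percentile_rank == pytest.approx(50.0)

    def test_clamp_for_visualization_export(self):
        b = np.array([120.0, 30.0, -5.0, 70.0])
        ns = _nodeset(np.eye(4, 3) * 10, bfactors=b)
        summary = ptc_rigidity_summary(ns, Selection.from_string("A:1"),
                                       export_clamped=True)
        assert summary.clamped.tolist() == [70.0, 30.0, 0.0, 70.0]

    def test_predicted_source_requires_covariance_or_values(self):
        ns = _nodeset(np.eye(3) * 10)
        from ribomech import MissingBFactorError

        with pytest.raises(MissingBFactorError):
            ptc_rigidity_summary(ns, Selection.from_string("A:1"), source="predicted")

    def test_predicted_source_from_anm_covariance(self):
        from ribomech import ENMParameters, build_hessian, compute_modes, covariance

        nodes = coarse_grain(make_toy_protein_chain(15, seed=2))
        params = ENMParameters()
        ms = compute_modes(build_hessian(nodes.positions, params))
        cov = covariance(ms, params)
        summary = ptc_rigidity_summary(nodes, Selection.from_string("A:7-9"),
                                       source="predicted", covariance=cov)
        # interior residues of a chain are its rigid side
        assert summary.ptc_percentile_rank < 50.0

    def test_missing_experimental_bfactors_named_in_error(self):
        from ribomech import MissingBFactorError

        ns = _nodeset(np.eye(3) * 10, bfactors=[np.nan, 1.0, 2.0])
        with pytest.raises(MissingBFactorError, match="predicted"):
            ptc_rigidity_summary(ns, Selection.from_string("A:1"))


def test_select_node_indices_matches_selection_terms():
    ns = _nodeset(np.arange(30.0).reshape(10, 3))
    idx = select_node_indices(ns, Selection.from_string("A:3-5"))
    assert idx.tolist() == [2, 3, 4]
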