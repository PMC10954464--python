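"""Docking scores, superposition, clustering, interfaces and mutation rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pletools.mutagenesis import (
    Atom,
    DockingEnsemble,
    StructureModel,
    cluster_models,
    composite_score,
    consensus_targets,
    interface_residues,
    kabsch_rmsd,
    propose_mutations,
    conserved_mask_from_alignment,
)
from pletools.synthetic_data import SimConfig, make_docking_ensemble

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestCompositeScore:
    def test_zero(self):
        assert composite_score(0, 0, 0, 0) == 0.0

    def test_weighted_sum(self):
        assert composite_score(-10, -5, -2, 10) == pytest.approx(-12.0)

    @given(finite, finite, finite, finite)
    @settings(max_examples=50, deadline=None)
    def test_linear(self, a, b, c, d):
        assert composite_score(2 * a, 2 * b, 2 * c, 2 * d) == pytest.approx(
            2 * composite_score(a, b, c, d), rel=1e-12, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            composite_score(float("nan"), 0, 0, 0)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabschRmsd:
    def test_identical_sets(self):
        A = np.random.default_rng(1).normal(size=(10, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            A = rng.normal(size=(15, 3)) * 10
            R = _random_rotation(rng)
            B = A @ R.T + rng.normal(size=3) * 50
            assert kabsch_rmsd(A, B) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert kabsch_rmsd(A, B) == pytest.approx(kabsch_rmsd(B, A), abs=1e-9)

    def test_matches_scipy_alignment(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        Ac, Bc = A - A.mean(0), B - B.mean(0)
        _, rssd = Rotation.align_vectors(Bc, Ac)
        assert kabsch_rmsd(A, B) == pytest.approx(rssd / np.sqrt(12), abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def _ca_model(model_id, coords, energies=(0, 0, 0, 0), with_dna=True):
    atoms = [Atom("A", i + 1, "ALA", "CA", *c) for i, c in enumerate(coords)]
    if with_dna:
        atoms += [Atom("B", i + 1, "DA", "P", 50.0, 50.0, 3.4 * i) for i in range(5)]
    return StructureModel(model_id, atoms, *energies)


class TestClusterModels:
    def test_single_cluster_top_four(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 3)) * 5
        models = [
            _ca_model(f"m{i}", base + rng.normal(scale=0.1, size=base.shape),
                      energies=(-i, 0, 0, 0))
            for i in range(10)
        ]
        out = cluster_models(DockingEnsemble(models))
        assert len(out.clusters) == 1
        assert len(out.selected) == 4
        assert out.selected[0] == "m9"  # best composite score

    def test_small_cluster_keeps_all(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 3)) * 5
        models = [_ca_model(f"m{i}", base) for i in range(2)]
        out = cluster_models(DockingEnsemble(models))
        assert sorted(out.selected) == ["m0", "m1"]

    def test_two_planted_conformations_recovered(self):
        cfg = SimConfig(seed=11, n_models=10, coord_jitter=0.0,
                        contact_fraction=0.0, n_conformations=2)
        models, truth = make_docking_ensemble(cfg)
        out = cluster_models(DockingEnsemble(models))
        assert len(out.clusters) == 2
        for cluster in out.clusters:
            confs = {truth["conformations"][mid] for mid in cluster}
            assert len(confs) == 1  # clusters match the planted poses

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_models(DockingEnsemble([]))


class TestInterfaceResidues:
    def test_far_protein_empty_both_modes(self):
        coords = np.stack([np.full(10, -100.0), np.zeros(10), np.arange(10.0)], 1)
        model = _ca_model("far", coords)
        assert interface_residues(model, mode="contact") == set()
        assert interface_residues(model, mode="dasa") == set()

    def test_contact_mode_single_residue(self):
        coords = np.stack([np.full(10, -100.0), np.zeros(10), np.arange(10.0)], 1)
        coords[4] = [50.0, 47.0, 0.0]  # 3 A from DNA atom at (50, 50, 0)
        model = _ca_model("one", coords)
        assert interface_residues(model, mode="contact") == {5}

    def test_dasa_mode_buried_residue(self):
        coords = np.stack([np.full(10, -100.0), np.zeros(10), np.arange(10.0) * 4], 1)
        coords[4] = [50.0, 47.0, 0.0]
        model = _ca_model("one", coords)
        hits = interface_residues(model, mode="dasa", cutoff=1.0)
        assert hits == {5}

    def test_missing_dna_rejected(self):
        model = _ca_model("nodna", np.zeros((5, 3)) + np.arange(5)[:, None],
                          with_dna=False)
        with pytest.raises(ValueError):
            interface_residues(model)


class TestConsensusTargets:
    def test_strict_two_thirds(self):
        ensemble = DockingEnsemble([_ca_model(f"m{i}", np.zeros((4, 3))) for i in range(4)])
        ifaces3of4 = {"m0": {7}, "m1": {7}, "m2": {7}, "m3": set()}
        assert [r for r, _ in consensus_targets(ensemble, ifaces3of4)] == [7]
        ifaces2of3 = {"m0": {7}, "m1": {7}, "m2": set()}
        assert consensus_targets(ensemble, ifaces2of3) == []

    def test_conserved_mask_excludes(self):
        ensemble = DockingEnsemble([_ca_model("m0", np.zeros((4, 3)))])
        assert consensus_targets(ensemble, {"m0": {3}}, conserved_mask={3}) == []

    def test_planted_contacts_recovered_from_ensemble(self):
        cfg = SimConfig(seed=23)  # contact fraction 0.8 > 2/3
        models, truth = make_docking_ensemble(cfg)
        interfaces = {m.model_id: interface_residues(m, mode="contact")
                      for m in models}
        got = [r for r, s in consensus_targets(DockingEnsemble(models), interfaces)]
        assert sorted(got) == truth["planted_contacts"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_targets(DockingEnsemble([]), {})


class TestProposeMutations:
    def test_natural_variants(self):
        prop = propose_mutations(437, "N", variant_column="NTE")
        assert set(prop.proposals) == {"T", "E"}
        assert all(tags == ("natural_variant",) for tags in prop.proposals.values())

    def test_acidic_to_basic(self):
        prop = propose_mutations(10, "D")
        assert set(prop.proposals) == {"K", "R", "H"}

    def test_hydrophobic_to_hydrophilic(self):
        prop = propose_mutations(586, "I")
        assert set(prop.proposals) == set("STNQKREDH")

    def test_no_rule_fires(self):
        assert propose_mutations(1, "G").proposals == {}

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            propose_mutations(1, "B")

    def test_rules_union_tags(self):
        # C is hydrophobic; variant column adds K with a second tag
        prop = propose_mutations(2, "C", variant_column="K")
        assert set(prop.proposals["K"]) == {"hydrophobic_to_hydrophilic",
                                            "natural_variant"}


class TestConservedMask:
    def test_conserved_columns_marked(self):
        rows = ["MKV", "MKI", "MKL", "MKV"]
        mask = conserved_mask_from_alignment(rows, min_identity=0.9)
        assert mask == {1, 2}

    def test_gap_in_target_skipped(self):
        rows = ["M-V", "MKV"]
        mask = conserved_mask_from_alignment(rows, min_identity=0.9)
        assert mask == {1, 2}
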