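"""Synthetic study generator: SEM sampling, batch effects, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pathbn import simulate as sim
from pathbn.estimate import ParameterKey
from pathbn.pathway import parse_sif


class TestSimulateSem:
    def test_noiseless_limit_is_exact_linear_function(self, chain_pathway):
        gt = sim.GroundTruth(
            pathway=chain_pathway,
            node_params={g: {"A": 7.0, "B": 1.0, "C": -1.0} for g in ("case", "control")},
            edge_params={g: {("A", "B"): 2.0, ("B", "C"): 0.5} for g in ("case", "control")},
            noise_sd={"A": 1e-9, "B": 1e-9, "C": 1e-9},
        )
        mat = sim.simulate_sem(gt, "control", 50, seed=0)
        assert np.allclose(mat.loc["B"], 1 + 2 * mat.loc["A"], atol=1e-6)
        assert np.allclose(mat.loc["C"], -1 + 0.5 * mat.loc["B"], atol=1e-6)

    def test_chain_mean_matches_law_of_large_numbers(self, chain_pathway):
        gt = sim.GroundTruth(
            pathway=chain_pathway,
            node_params={g: {"A": 7.0, "B": 1.0, "C": 0.0} for g in ("case", "control")},
            edge_params={g: {("A", "B"): 2.0, ("B", "C"): 1.0} for g in ("case", "control")},
            noise_sd={"A": 1.0, "B": 1.0, "C": 1.0},
        )
        n = 10_000
        mat = sim.simulate_sem(gt, "control", n, seed=1)
        # E[B] = 1 + 2*E[A] = 15; sd(B) = sqrt(4+1); SE of mean = sd/sqrt(n)
        se = np.sqrt(5) / np.sqrt(n)
        assert abs(mat.loc["B"].mean() - 15.0) < 3 * se

    def test_covariance_matches_analytic_sem_covariance(self):
        sif = (
            "A\tu\tB\nA\tu\tC\nB\tu\tD\nC\tu\tD\nD\tu\tE\n"
        )
        pathway = parse_sif(sif, pathway_id="five")
        rng = np.random.default_rng(2)
        edges = {e: float(rng.uniform(0.3, 0.9)) for e in pathway.edges}
        gt = sim.GroundTruth(
            pathway=pathway,
            node_params={g: {n: 5.0 for n in pathway.nodes} for g in ("case", "control")},
            edge_params={g: dict(edges) for g in ("case", "control")},
            noise_sd={n: 1.0 for n in pathway.nodes},
        )
        mat = sim.simulate_sem(gt, "control", 100_000, seed=3)
        emp = np.cov(mat.to_numpy())
        _, ana = sim.analytic_moments(gt, "control")
        assert np.abs(emp - ana.to_numpy()).max() / np.abs(ana.to_numpy()).max() < 0.05

    def test_cyclic_pathway_rejected(self):
        pg = parse_sif("A\tu\tB\nB\tu\tA\n")
        gt_kwargs = dict(
            node_params={g: {"A": 1.0, "B": 1.0} for g in ("case", "control")},
            edge_params={g: {("A", "B"): 0.5, ("B", "A"): 0.5} for g in ("case", "control")},
            noise_sd={"A": 1.0, "B": 1.0},
        )
        gt = sim.GroundTruth(pathway=pg, **gt_kwargs)
        with pytest.raises(ValueError, match="cyclic"):
            sim.simulate_sem(gt, "control", 10, seed=0)

    def test_analytic_contrast_se_matches_empirical(self):
        """The SE used to calibrate effect sizes agrees with the sampling
        variability of fitted contrasts."""
        from pathbn.estimate import fit_network

        gt = sim.make_ground_truth(seed=5, n_perturbed_edges=0, n_perturbed_nodes=0)
        keys = [ParameterKey("node", "CD3E"), ParameterKey("edge", "ZAP70", "LCK")]
        rng = np.random.default_rng(6)
        diffs = {k: [] for k in keys}
        for _ in range(150):
            mc = sim.simulate_sem(gt, "case", 60, rng)
            mh = sim.simulate_sem(gt, "control", 60, rng)
            mc.columns = [f"c{i}" for i in range(60)]
            mh.columns = [f"h{i}" for i in range(60)]
            pc = fit_network(gt.pathway, mc).parameters()
            ph = fit_network(gt.pathway, mh).parameters()
            for k in keys:
                diffs[k].append(pc[k][0] - ph[k][0])
        for k in keys:
            emp_sd = np.std(diffs[k])
            ana = sim.contrast_se(gt, k, 60, 60)
            assert abs(emp_sd - ana) / ana < 0.2


class TestBatchAndDropout:
    def test_identity_transform(self, dataset_factory):
        d = dataset_factory()
        dd = sim.DatasetDesign("DS1", "P", 5, 5)
        out = sim.apply_batch_and_dropout(d, dd)
        pd.testing.assert_frame_equal(out.matrix, d.matrix)

    def test_additive_shift_moves_means(self, dataset_factory):
        d1 = dataset_factory("DS1", n_case=50, n_control=50, seed=1)
        d2 = dataset_factory("DS2", n_case=50, n_control=50, seed=2)
        dd = sim.DatasetDesign("DS2", "P", 50, 50, shift=2.0)
        shifted = sim.apply_batch_and_dropout(d2, dd)
        gap = shifted.matrix.mean(axis=1) - d1.matrix.mean(axis=1)
        assert np.allclose(gap, 2.0, atol=0.5)

    def test_dropout_restricted_to_platform(self):
        gt = sim.make_ground_truth(seed=0)
        design = sim.default_study_design(seed=0)
        bundle = sim.generate_study(gt, design)
        by_platform = {}
        for d in bundle.datasets:
            by_platform.setdefault(d.platform_id, []).append(d)
        for d in by_platform["I"]:
            assert "IL2" not in d.matrix.index
        for plat in ("A", "H"):
            for d in by_platform[plat]:
                assert "IL2" in d.matrix.index


class TestGenerateStudy:
    def test_seed_determinism_is_byte_identical(self, tmp_path):
        gt = sim.make_ground_truth(seed=4)
        design = dataclasses.replace(sim.default_study_design(seed=4), background_genes=50)
        p1 = sim.write_study(sim.generate_study(gt, design), tmp_path / "a")
        p2 = sim.write_study(sim.generate_study(gt, design), tmp_path / "b")
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, f"{key} differs between identical-seed runs"

    def test_truth_file_covers_every_parameter_once(self):
        gt = sim.make_ground_truth(seed=1)
        truth = gt.truth_frame()
        n_nodes = len(gt.pathway.nodes)
        n_edges = len(gt.pathway.edges)
        assert len(truth) == n_nodes + n_edges
        assert not truth.duplicated(subset=["type", "child", "parent"]).any()
        assert truth["perturbed"].sum() == len(gt.perturbed)
        injected_keys = {k for k, _ in gt.injected}
        assert injected_keys <= {k for k, _ in gt.perturbed}

    def test_identifiability_precondition_enforced(self):
        gt = sim.make_ground_truth(seed=0)
        tiny = sim.StudyDesign(
            datasets=(sim.DatasetDesign("DS1", "A", 3, 3),), seed=0
        )
        # max in-degree is 3 (IL2), so 3 samples per group must be refused
        with pytest.raises(ValueError, match="in-degree"):
            sim.generate_study(gt, tiny)

    def test_perturbations_calibrated_in_contrast_se_units(self):
        gt = sim.make_ground_truth(seed=7, effect_se=3.0, n_per_group=80)
        assert len(gt.injected) == 10
        truth = gt.truth_frame().set_index(["type", "child", "parent"])
        for key, direction in gt.injected:
            row = truth.loc[(key.kind, key.child, key.parent or "NA")]
            delta = row["case_value"] - row["control_value"]
            se = sim.contrast_se(gt, key, 80, 80)
            # the injected magnitude is a small multiple of the contrast SE
            # (the SE moves slightly as earlier perturbations accumulate)
            assert 1.5 <= abs(delta) / se <= 4.5
            assert np.sign(delta) == direction

    def test_edge_rewiring_preserves_marginal_means(self):
        """Edge perturbations rewire couplings at constant expression
        level: with no node injections the case and control marginal means
        coincide exactly (intercept compensation), even for a strong
        5-SE edge effect."""
        gt = sim.make_ground_truth(
            seed=3, n_perturbed_edges=5, n_perturbed_nodes=0,
            effect_se=3.0, extra_edge_se=5.0,
        )
        mean_case, _ = sim.analytic_moments(gt, "case")
        mean_ctl, _ = sim.analytic_moments(gt, "control")
        assert np.abs(mean_case - mean_ctl).max() < 1e-9
        # compensatory intercept shifts are recorded as real perturbations
        assert len(gt.perturbed) > len(gt.injected)
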