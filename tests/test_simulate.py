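"""Synthetic experiment generators: determinism, planted structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from cardiomir.cohorts import cohort_means, cohort_ns, cohort_sems
from cardiomir.exceptions import ConfigurationError, InputError
from cardiomir.expression import DE_DOWN, quantify
from cardiomir.simulate import (
    SimulationConfig,
    simulate_echo_cohort,
    simulate_knowledge_bases,
    simulate_transfection_counts,
)


class TestConfig:
    def test_invalid_values_rejected(self):
        for bad in (
            dict(n_genes=0),
            dict(library_size=0),
            dict(frac_targets_per_mirna=0.0),
            dict(n_genes=5, frac_targets_per_mirna=0.1),  # < 1 planted target
            dict(repression_fc=0.5),
            dict(homology_dropout=1.0),
            dict(gene_length_range=(0, 100)),
        ):
            with pytest.raises(ConfigurationError):
                SimulationConfig(**bad).validate()

    def test_dict_round_trip(self):
        cfg = SimulationConfig(seed=5, n_genes=123)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestTransfectionCounts:
    def test_seeded_determinism(self, small_config):
        m1, t1 = simulate_transfection_counts(small_config)
        m2, t2 = simulate_transfection_counts(small_config)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        pd.testing.assert_series_equal(m1.lengths_bp, m2.lengths_bp)
        assert t1.planted_targets == t2.planted_targets

    def test_null_effect_leaves_expected_counts_equal(self):
        cfg = SimulationConfig(seed=2, n_genes=200, repression_fc=1.0)
        _, truth = simulate_transfection_counts(cfg)
        mu = truth.expected_counts
        for col in mu.columns[1:]:
            np.testing.assert_allclose(mu[col], mu[mu.columns[0]])

    def test_planted_columns_repressed_in_expectation(self, small_experiment):
        truth = small_experiment["truth"]
        cfg = small_experiment["config"]
        mu = truth.expected_counts
        control = mu.columns[0]
        for mirna, targets in truth.planted_targets.items():
            others = mu.index.difference(list(targets))
            ratio_t = (mu.loc[list(targets), control] / mu.loc[list(targets), mirna])
            # relative to the (slightly renormalized) non-target baseline
            scale = (mu.loc[others, mirna] / mu.loc[others, control]).iloc[0]
            np.testing.assert_allclose(ratio_t * scale, cfg.repression_fc, rtol=1e-9)

    def test_observed_fold_change_matches_planted_parameter(self):
        """Planted two-fold repression is recovered from the noisy counts."""
        cfg = SimulationConfig(seed=11, n_genes=2000, frac_targets_per_mirna=0.05,
                               repression_fc=2.0, nb_dispersion=0.1)
        matrix, truth = simulate_transfection_counts(cfg)
        de = quantify(matrix)
        mirna = cfg.mirna_labels[0]
        sub = de[de["mirna"] == mirna].set_index("gene_id")
        fcs = 2.0 ** (-sub.loc[sorted(truth.planted_targets[mirna]), "log2fc"])
        assert np.mean(fcs) == pytest.approx(2.0, rel=0.15)

    def test_overlap_between_first_two_targetomes(self, small_experiment):
        truth = small_experiment["truth"]
        cfg = small_experiment["config"]
        labels = cfg.mirna_labels
        n_targets = len(truth.planted_targets[labels[0]])
        shared = truth.planted_targets[labels[0]] & truth.planted_targets[labels[1]]
        assert len(shared) == int(round(cfg.overlap_frac * n_targets))

    def test_planted_targets_within_universe(self, small_experiment):
        genes = set(small_experiment["matrix"].counts.index)
        for targets in small_experiment["truth"].planted_targets.values():
            assert targets <= genes

    def test_effect_sizes_exactly_on_planted_pairs(self, small_experiment):
        truth = small_experiment["truth"]
        expected_pairs = {
            (m, g) for m, gs in truth.planted_targets.items() for g in gs
        }
        assert set(truth.effect_sizes) == expected_pairs


class TestKnowledgeBases:
    def test_no_dropout_maps_every_gene(self):
        cfg = SimulationConfig(seed=4, n_genes=150, frac_targets_per_mirna=0.1,
                               homology_dropout=0.0, ppi_n_edges=50,
                               go_set_sizes={"cell_division": 10})
        matrix, truth = simulate_transfection_counts(cfg)
        _, homology, _, _ = simulate_knowledge_bases(cfg, truth)
        rat = set(homology.loc[homology["species"] == "rat", "gene_id"])
        assert rat == set(matrix.counts.index)
        groups_with_mouse = set(
            homology.loc[homology["species"] == "mouse", "group_id"]
        )
        assert set(homology["group_id"]) == groups_with_mouse

    def test_zero_decoys_predictions_equal_planted(self):
        cfg = SimulationConfig(seed=4, n_genes=150, frac_targets_per_mirna=0.1,
                               decoy_frac=0.0, homology_dropout=0.0, ppi_n_edges=50,
                               go_set_sizes={"cell_division": 10})
        _, truth = simulate_transfection_counts(cfg)
        predictions, homology, _, _ = simulate_knowledge_bases(cfg, truth)
        mouse_to_rat = {}
        group_members: dict[str, dict[str, str]] = {}
        for g, sp, gid in homology.itertuples(index=False):
            group_members.setdefault(g, {})[sp if gid[-1] != "b" else "paralog"] = gid
        for members in group_members.values():
            if "mouse" in members and "rat" in members:
                mouse_to_rat[members["mouse"]] = members["rat"]
        for mirna in cfg.mirna_labels:
            pred_mouse = set(predictions.loc[predictions["mirna"] == mirna, "mouse_gene"])
            assert {mouse_to_rat[m] for m in pred_mouse} == truth.planted_targets[mirna]

    def test_edge_count_as_configured(self, small_experiment):
        ppi = small_experiment["ppi"]
        cfg = small_experiment["config"]
        assert len(ppi) == cfg.ppi_n_edges
        undirected = {frozenset((a, b)) for a, b in zip(ppi["protein1"], ppi["protein2"])}
        assert len(undirected) == cfg.ppi_n_edges  # no duplicate pairs
        assert ppi["combined_score"].between(0, 1000).all()

    def test_compartment_sizes(self, small_experiment):
        cfg = small_experiment["config"]
        comps = small_experiment["compartments"]
        assert {k: len(v) for k, v in comps.items()} == cfg.go_set_sizes

    def test_determinism(self, small_config, small_experiment):
        matrix, truth = simulate_transfection_counts(small_config)
        predictions, homology, ppi, comps = simulate_knowledge_bases(small_config, truth)
        pd.testing.assert_frame_equal(predictions, small_experiment["predictions"])
        pd.testing.assert_frame_equal(homology, small_experiment["homology"])
        pd.testing.assert_frame_equal(ppi, small_experiment["ppi"])
        assert comps == small_experiment["compartments"]


class TestRecovery:
    def test_planted_recovery_at_low_dispersion(self):
        """Near-Poisson noise: threshold DE recovers planted targets cleanly.

        The fold-change threshold rule has no replicates to average over, so
        its operating point depends directly on the count overdispersion;
        at dispersion 0.01 the planted two-fold signal sits ~3 sigma from
        the 1.3-fold cutoff and recovery is near-perfect.
        """
        sens, fpr = [], []
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_genes=2000, frac_targets_per_mirna=0.05,
                                   repression_fc=2.0, nb_dispersion=0.01,
                                   ppi_n_edges=100,
                                   go_set_sizes={"cell_division": 50})
            matrix, truth = simulate_transfection_counts(cfg)
            de = quantify(matrix)
            for mirna in cfg.mirna_labels:
                sub = de[de["mirna"] == mirna]
                down = set(sub.loc[sub["de_status"] == DE_DOWN, "gene_id"])
                planted = truth.planted_targets[mirna]
                non_targets = set(matrix.counts.index) - planted
                sens.append(len(down & planted) / len(planted))
                fpr.append(len(down & non_targets) / len(non_targets))
        assert np.mean(sens) >= 0.90
        assert np.mean(fpr) <= 0.05


class TestEchoCohort:
    def _stats(self):
        means = cohort_means("ko_tac")[["IVSd", "IVSs", "LVIDd", "LVIDs",
                                        "LVPWd", "LVPWs", "BW"]]
        sems = cohort_sems("ko_tac")[means.columns]
        return means, sems

    def test_zero_sem_gives_exact_means(self):
        means, sems = self._stats()
        cohort = simulate_echo_cohort(means, sems * 0.0, n_per_group=4, seed=0)
        for group in means.index:
            sub = cohort[cohort["group"] == group]
            for col in means.columns:
                np.testing.assert_allclose(sub[col], means.loc[group, col])

    def test_seeded_reproducibility(self):
        means, sems = self._stats()
        c1 = simulate_echo_cohort(means, sems, n_per_group=10, seed=42)
        c2 = simulate_echo_cohort(means, sems, n_per_group=10, seed=42)
        pd.testing.assert_frame_equal(c1, c2)

    def test_cohort_mean_fs_near_formula_on_means(self):
        """Sampled healthy cohort: mean FS within 3 points of the 29.8 value
        the formula gives on the group means."""
        from cardiomir.cardiometrics import derive_echo_table

        means, sems = self._stats()
        cohort = simulate_echo_cohort(means.loc[["sham_wt"]], sems.loc[["sham_wt"]],
                                      n_per_group=10, seed=1)
        derived = derive_echo_table(cohort, mode="per-animal")
        assert derived["FS"].mean() == pytest.approx(29.8, abs=3.0)

    def test_invalid_inputs_rejected(self):
        means, sems = self._stats()
        with pytest.raises(InputError):
            simulate_echo_cohort(means, sems, n_per_group=0, seed=0)
        swapped = means.copy()
        swapped["LVIDs"] = means["LVIDd"]
        with pytest.raises(InputError):
            simulate_echo_cohort(swapped, sems, n_per_group=3, seed=0)

    def test_per_group_n(self):
        means, sems = self._stats()
        ns = cohort_ns("ko_tac")
        cohort = simulate_echo_cohort(means, sems, ns, seed=3)
        assert cohort.groupby("group").size().to_dict() == ns.to_dict()
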