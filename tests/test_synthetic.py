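"""Generators: structure, planted patterns, determinism, degenerate configs."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from plasmir import (
    PanelDefinition,
    SimulationConfig,
    generate_counts,
    generate_genesets,
    generate_interactome,
    generate_qpcr_plate,
    generate_target_db,
    intersect_target_sets,
    ora_test,
)
from plasmir.qpcr import ingest_ct, relative_expression

from conftest import planted_config


class TestPanel:
    def test_default_dimensions(self):
        panel = PanelDefinition()
        assert len(panel.endogenous_ids) == 798
        assert len(panel.negative_ids) == 6
        assert len(panel.positive_ids) == 6
        assert len(panel.housekeeping_ids) == 10

    def test_ladder_strictly_decreasing(self):
        ladder = PanelDefinition().positive_ladder
        assert all(a > b for a, b in zip(ladder, ladder[1:]))

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            PanelDefinition(
                endogenous_ids=["x", "y"],
                negative_ids=["x"],
                positive_ids=["p"],
                positive_ladder=[1.0],
                housekeeping_ids=["h"],
            )


class TestGenerateCounts:
    def test_shape_and_classes(self, seeded_run):
        _, cm, _ = seeded_run
        assert cm.counts.shape == (798 + 6 + 6 + 10, 24)
        assert len(cm.probes_of("endogenous")) == 798
        assert list(cm.cohorts.unique()) == ["Control", "FIGO_I", "FIGO_III", "FIGO_IV"]

    def test_seed_determinism(self):
        cfg = planted_config(seed=3)
        a, _ = generate_counts(cfg)
        b, _ = generate_counts(planted_config(seed=3))
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_different_seeds_differ(self):
        a, _ = generate_counts(planted_config(seed=1))
        b, _ = generate_counts(planted_config(seed=2))
        assert not a.counts.equals(b.counts)

    def test_null_configuration_means(self):
        # Poisson limit, no lane effects, no background: endogenous means
        # concentrate on the baseline
        cfg = SimulationConfig(
            samples_per_cohort=12,
            lane_scale_sd=0.0,
            background_mean=0.0,
            dispersion=np.inf,
            baseline_mean=100.0,
            seed=0,
        )
        cm, truth = generate_counts(cfg)
        endo = cm.class_counts("endogenous")
        assert (truth.true_mean.to_numpy() == 100.0).all()
        assert abs(endo.to_numpy().mean() - 100.0) < 0.5

    def test_planted_absence_structure(self, seeded_run):
        cfg, cm, truth = seeded_run
        g2 = [p for p, _ in cfg.planted_group2]
        g3 = [p for p, _ in cfg.planted_group3]
        # group2: signal only in FIGO_I; group3: none in Control
        assert (truth.true_mean.loc[g2, ["Control", "FIGO_III", "FIGO_IV"]] == 0).all().all()
        assert (truth.true_mean.loc[g2, "FIGO_I"] > 0).all()
        assert (truth.true_mean.loc[g3, "Control"] == 0).all()
        assert (truth.true_mean.loc[g3, ["FIGO_I", "FIGO_III", "FIGO_IV"]] > 0).all().all()
        # empirically, background-only cells stay near background level
        ctrl = cm.counts.loc[g2, cm.samples_of("Control")]
        assert ctrl.to_numpy().mean() < 6 * cfg.background_mean

    def test_non_disjoint_plants_rejected(self):
        ids = PanelDefinition().endogenous_ids
        with pytest.raises(ValueError, match="disjoint"):
            SimulationConfig(
                planted_group1=[(ids[0], 2.0)], planted_group2=[(ids[0], 2.0)]
            )

    def test_unknown_probe_rejected(self):
        cfg = SimulationConfig(planted_group1=[("no-such-probe", 2.0)])
        with pytest.raises(ValueError, match="unknown probe"):
            generate_counts(cfg)


class TestTargetDb:
    def test_shared_core_reaches_triple_intersection(self):
        groups = {
            "group1": ["mir-1", "mir-2"],
            "group2": ["mir-3"],
            "group3": ["mir-4", "mir-5"],
        }
        core = ["MET", "SMAD7", "EZH2", "TERT", "IL6"]
        db = generate_target_db(groups, shared_core=core, seed=5)
        sets = {g: db.targets_of(m) for g, m in groups.items()}
        regions = intersect_target_sets(sets)
        triple = regions.loc[regions["n_sets"] == 3, "members"].iloc[0]
        assert set(core) <= set(triple)

    def test_every_mirna_has_targets(self):
        db = generate_target_db(["a", "b", "c"], edges_per_mirna_range=(1, 1), seed=0)
        counts = db.edges.groupby("mirna").size()
        assert (counts == 1).all()

    def test_determinism_and_empty_error(self):
        a = generate_target_db(["m1", "m2"], seed=9)
        b = generate_target_db(["m1", "m2"], seed=9)
        pd.testing.assert_frame_equal(a.edges, b.edges)
        with pytest.raises(ValueError, match="non-empty"):
            generate_target_db([], seed=0)


class TestQpcrPlate:
    def test_zero_noise_identity_level(self):
        raw = generate_qpcr_plate(
            2, ["assay-x"], {"assay-x": {c: 1.0 for c in
             ("Control", "FIGO_I", "FIGO_III", "FIGO_IV")}},
            replicate_sd=0.0, sample_sd=0.0, seed=0,
        )
        plate = ingest_ct(raw)
        assert relative_expression(plate, "Control_q1", "assay-x") == pytest.approx(1.0)

    def test_level_below_detection_is_undetermined(self):
        # level 2^-40 pushes Ct to ~70, far past the 45-cycle ceiling
        raw = generate_qpcr_plate(
            1, ["lost"], {"lost": {c: 2.0 ** -40 for c in
             ("Control", "FIGO_I", "FIGO_III", "FIGO_IV")}},
            replicate_sd=0.0, sample_sd=0.0, seed=0,
        )
        lost = raw[raw["assay"] == "lost"]
        assert (lost["ct"] == "Undetermined").all()

    def test_seed_determinism(self):
        kw = dict(
            n_samples_per_cohort=2,
            assays=["a"],
            true_relative_levels={"a": {"Control": 1.0}},
            seed=4,
        )
        pd.testing.assert_frame_equal(generate_qpcr_plate(**kw), generate_qpcr_plate(**kw))

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            generate_qpcr_plate(1, ["a"], {"a": {"Control": 0.0}}, seed=0)


class TestGenesetsAndInteractome:
    def test_universe_set_gives_p_one(self):
        genes = [f"G{i}" for i in range(30)]
        coll = generate_genesets(genes, n_sets=0, set_size_range=(5, 10), enriched_set=genes, seed=0)
        res = ora_test(genes[:7], coll)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_set_size_exceeding_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            generate_genesets([f"G{i}" for i in range(5)], set_size_range=(6, 8), seed=0)

    def test_uniform_interactome_degrees_are_binomial(self):
        # hub_bias = 0: node degree ~ Binomial(2E, 1/n); chi-square GOF on
        # binned degree counts
        n, e = 500, 2500
        genes = [f"G{i:03d}" for i in range(n)]
        edges = generate_interactome(genes, n_edges=e, hub_bias=0.0, seed=2024)
        deg = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
        deg = deg.reindex(genes, fill_value=0)
        dist = st.binom(2 * e, 1.0 / n)
        edges_bins = [-1, 4, 6, 8, 10, 12, 14, 16, np.inf]
        obs, _ = np.histogram(deg, bins=np.array(edges_bins) + 0.5)
        cdf = dist.cdf(np.array(edges_bins[1:]))
        probs = np.diff(np.concatenate([[0.0], cdf]))
        probs[-1] = 1.0 - cdf[-2]
        stat, p = st.chisquare(obs, f_exp=probs * n)
        assert p > 1e-3

    def test_hub_bias_concentrates_degree(self):
        genes = [f"G{i:03d}" for i in range(300)]
        flat = generate_interactome(genes, n_edges=1500, hub_bias=0.0, seed=1)
        hubby = generate_interactome(genes, n_edges=1500, hub_bias=1.5, seed=1)

        def max_deg(edges):
            return pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts().max()

        assert max_deg(hubby) > 2 * max_deg(flat)

    def test_interactome_simple_and_deterministic(self):
        genes = [f"G{i}" for i in range(50)]
        a = generate_interactome(genes, n_edges=100, seed=3)
        b = generate_interactome(genes, n_edges=100, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert (a["gene_a"] != a["gene_b"]).all()
        keys = a.apply(lambda r: tuple(sorted(r)), axis=1)
        assert keys.is_unique
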