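"""Generator behaviour: determinism, design structure, planted signal."""

import numpy as np
import pandas as pd
import pytest
from conftest import SMALL
from pandas.testing import assert_frame_equal

from dcmmet import io as dio
from dcmmet.experiments import null_config
from dcmmet.synthdata import (
    SimConfig,
    followup_pairs,
    simulate_annotations,
    simulate_cohort,
    simulate_followup,
)


class TestSimConfig:
    def test_defaults_reproduce_reference_design(self):
        cfg = SimConfig()
        assert cfg.group_sizes == (38, 8, 12, 17)
        samples, matrix, _ = simulate_cohort(cfg)
        assert len(samples) == 75
        assert (samples.timepoint == "baseline").all()
        assert len(matrix.metabolites) == 1027

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_metabolites=10, block_sizes=(6, 6)),
            dict(within_block_rho=1.0),
            dict(n_overlap_effects=20, n_disease_effects=10, n_diet_effects=30),
            dict(missing_rate=1.5),
            dict(n_disease_effects=-1),
            dict(n_metabolites=20, n_disease_effects=15, n_diet_effects=10, n_overlap_effects=0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_empty_group_warns_not_errors(self):
        with pytest.warns(UserWarning, match="empty"):
            SimConfig(group_sizes=(10, 0, 5, 5), n_metabolites=50, block_sizes=(),
                      n_disease_effects=0, n_diet_effects=0, n_overlap_effects=0)


class TestSimulateCohort:
    def test_identical_seed_identical_output(self, small_config, small_cohort):
        samples2, matrix2, truth2 = simulate_cohort(small_config)
        samples, matrix, truth = small_cohort
        assert_frame_equal(samples, samples2)
        assert_frame_equal(matrix.values, matrix2.values)
        assert truth.disease_metabolites == truth2.disease_metabolites

    def test_truth_sets_consistent(self, small_cohort):
        _, matrix, truth = small_cohort
        assert truth.overlap_metabolites == truth.disease_metabolites & truth.diet_metabolites
        assert truth.disease_metabolites <= set(matrix.metabolites)
        assert set(truth.effect_signs) == truth.disease_metabolites | truth.diet_metabolites
        assert set(truth.effect_signs.values()) <= {-1, 1}

    def test_raw_values_nonnegative_and_annotated(self, small_cohort):
        _, matrix, _ = small_cohort
        assert np.nanmin(matrix.values.to_numpy()) >= 0
        assert matrix.annotation.index.equals(pd.Index(matrix.metabolites, name="metabolite_id"))

    def test_independent_null_has_centred_correlations(self):
        cfg = null_config(seed=3, n_metabolites=60)
        _, matrix, _ = simulate_cohort(cfg)
        logs = np.log(matrix.values.to_numpy())
        corr = np.corrcoef(logs, rowvar=False)
        off = corr[~np.eye(60, dtype=bool)]
        assert abs(off.mean()) < 0.02
        # 75 samples: individual correlations have sd ~ 1/sqrt(74)
        assert off.std() == pytest.approx(1 / np.sqrt(72), rel=0.25)

    def test_block_correlation_present(self):
        cfg = SimConfig(seed=5, n_metabolites=40, block_sizes=(10,), within_block_rho=0.7,
                        n_disease_effects=0, n_diet_effects=0, n_overlap_effects=0,
                        missing_rate=0.0, n_batches=1, dog_var_share=0.0)
        _, matrix, _ = simulate_cohort(cfg)
        logs = np.log(matrix.values.to_numpy())
        corr = np.corrcoef(logs, rowvar=False)
        in_block = corr[:10, :10][~np.eye(10, dtype=bool)].mean()
        out_block = corr[:10, 10:].mean()
        assert in_block > 0.5
        assert abs(out_block) < 0.1

    def test_missingness_is_left_censored(self):
        base = dict(n_metabolites=60, block_sizes=(), n_disease_effects=0,
                    n_diet_effects=0, n_overlap_effects=0, seed=11)
        full_cfg = SimConfig(missing_rate=0.0, **base)
        miss_cfg = SimConfig(missing_rate=0.3, **base)
        _, full, _ = simulate_cohort(full_cfg)
        _, miss, _ = simulate_cohort(miss_cfg)
        # abundance streams are independent of the missingness stream, so
        # the underlying values coincide and the mask can be located
        mask = miss.values.isna().to_numpy()
        rate = mask.mean()
        assert rate == pytest.approx(0.3, abs=0.03)
        vals = np.log(full.values.to_numpy())
        z = (vals - vals.mean(0)) / vals.std(0)
        assert z[mask].mean() < z[~mask].mean() - 0.5

    def test_ctni_tracks_linked_metabolites(self):
        cfg = SimConfig(seed=2, n_metabolites=100, block_sizes=(), missing_rate=0.0,
                        n_disease_effects=10, n_diet_effects=5, n_overlap_effects=2,
                        ctni_linked_metabolites=5)
        samples, matrix, truth = simulate_cohort(cfg)
        logs = np.log(matrix.values)
        linked = sorted(truth.ctni_metabolites)
        z = (logs[linked] - logs[linked].mean()) / logs[linked].std()
        r = np.corrcoef(np.log(samples.ctni), z.mean(axis=1))[0, 1]
        assert r > 0.5


class TestSimulateFollowup:
    def test_survivor_subset_and_pairing(self, small_cohort, small_followup, small_config):
        samples, _, _ = small_cohort
        samples_fu, matrix_fu = small_followup
        n_dcm_nt = ((samples.disease == "DCM") & (samples.diet == "NT")).sum()
        expect = round(small_config.survivor_fraction * n_dcm_nt)
        assert len(samples_fu) == expect
        assert (samples_fu.timepoint == "month9").all()
        assert set(samples_fu.dog_id) <= set(samples.dog_id[(samples.disease == "DCM") & (samples.diet == "NT")])
        pairs = followup_pairs(samples_fu)
        assert set(pairs.values()) == set(matrix_fu.samples)

    def test_survivor_fraction_validated(self, small_cohort):
        samples, matrix, truth = small_cohort
        bad = SimConfig(seed=7, **SMALL)
        object.__setattr__(bad, "survivor_fraction", 1.5)  # bypass config validation
        with pytest.raises(ValueError):
            simulate_followup(samples, matrix, truth, bad)

    @pytest.mark.parametrize("reversal,expected", [(0.0, 0.0), (1.0, -1.0)])
    def test_intervention_reverses_diet_effects(self, reversal, expected):
        """Mean paired change on diet-planted metabolites ~ -reversal * effect * sign."""
        diffs = []
        for seed in range(25):
            cfg = SimConfig(seed=seed, group_sizes=(20, 4, 4, 4), n_metabolites=40,
                            block_sizes=(), n_disease_effects=8, n_diet_effects=8,
                            n_overlap_effects=4, effect_size=1.0, missing_rate=0.0,
                            n_batches=1, survivor_fraction=1.0, intervention_reversal=reversal)
            samples, matrix, truth = simulate_cohort(cfg)
            samples_fu, matrix_fu = simulate_followup(samples, matrix, truth, cfg)
            logs_b = np.log(matrix.values)
            logs_f = np.log(matrix_fu.values)
            sd = truth.latent["sd"]
            sd_by_id = dict(zip(matrix.metabolites, sd))
            for met in truth.diet_metabolites:
                d = logs_f[met].to_numpy() - logs_b.loc[samples_fu.dog_id, met].to_numpy()
                # per-metabolite change in its own SD units, aligned by sign
                diffs.append(truth.effect_signs[met] * d.mean() / sd_by_id[met])
        assert np.mean(diffs) == pytest.approx(expected, abs=0.12)


class TestSimulateAnnotations:
    def test_seed_proteins_link_planted_metabolites(self, small_cohort, small_config):
        _, _, truth = small_cohort
        bundle = simulate_annotations(small_config, truth)
        by_protein = bundle.met2prot.groupby("protein_id").metabolite_id.apply(set)
        for p in sorted(truth.seed_proteins):
            assert len(by_protein[p] & truth.disease_metabolites) >= 2
            assert len(by_protein[p] & truth.diet_metabolites) >= 2

    def test_interactome_clean_and_deterministic(self, small_cohort, small_config):
        _, _, truth = small_cohort
        b1 = simulate_annotations(small_config, truth)
        b2 = simulate_annotations(small_config, truth)
        assert_frame_equal(b1.interactome, b2.interactome)
        assert (b1.interactome.protein_a != b1.interactome.protein_b).all()
        edges = list(zip(b1.interactome.protein_a, b1.interactome.protein_b))
        assert len(edges) == len({frozenset(e) for e in edges})

    def test_gene_sets_cover_planted_and_decoys(self, small_cohort, small_config):
        _, _, truth = small_cohort
        bundle = simulate_annotations(small_config, truth)
        assert truth.enriched_gene_sets <= set(bundle.gene_sets)
        members = bundle.gene_set_members()
        for gs in truth.enriched_gene_sets:
            assert len(members[gs] & truth.seed_proteins) >= small_config.gene_set_size - 1
        assert sum(name.startswith("DS") for name in bundle.gene_sets) == small_config.n_decoy_sets

    def test_empty_truth_gives_decoy_only_bundle(self):
        cfg = null_config(seed=1, n_metabolites=50)
        _, _, truth = simulate_cohort(cfg)
        with pytest.warns(UserWarning, match="decoy-only"):
            bundle = simulate_annotations(cfg, truth)
        assert not any(p.startswith("P") for p in bundle.met2prot.protein_id)

    def test_bundle_roundtrip(self, small_cohort, small_config, tmp_path):
        _, _, truth = small_cohort
        bundle = simulate_annotations(small_config, truth)
        dio.write_bundle(bundle, tmp_path)
        back = dio.read_bundle(tmp_path)
        assert_frame_equal(bundle.met2prot, back.met2prot)
        assert_frame_equal(bundle.interactome, back.interactome)
        assert bundle.gene_sets == back.gene_sets

    def test_truth_roundtrip(self, small_cohort, tmp_path):
        _, _, truth = small_cohort
        dio.write_truth(truth, tmp_path / "truth.json")
        back = dio.read_truth(tmp_path / "truth.json")
        assert back.disease_metabolites == truth.disease_metabolites
        assert back.effect_signs == truth.effect_signs
        assert back.seed_proteins == truth.seed_proteins
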