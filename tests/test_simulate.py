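"""Determinism and planted-truth guarantees of the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from mirpair import ConfigurationError, SyntheticConfig, generate_dataset
from mirpair.diffexpr import rank_sum_difference, run_de, signed_fold_change
from mirpair.simulate import (generate_annotations, generate_sequences,
                              generate_validation_table)
from mirpair.validation import (fit_standard_curve, relative_quantity,
                                spearman_rho)
from mirpair.simulate import dilution_series


class TestConfigValidation:
    def test_distinct_exceeding_de_rejected(self):
        cfg = SyntheticConfig(n_de_mrna=5, n_distinct=6, n_true_pairs=0)
        with pytest.raises(ConfigurationError, match="n_distinct"):
            cfg.validate()

    def test_pairs_exceeding_capacity_rejected(self):
        cfg = SyntheticConfig(n_de_mirna=1, max_targets=2, n_true_pairs=3)
        with pytest.raises(ConfigurationError, match="n_true_pairs"):
            cfg.validate()

    def test_short_utr_rejected(self):
        with pytest.raises(ConfigurationError, match="utr_len"):
            SyntheticConfig(utr_len=6).validate()


class TestGenerateDataset:
    def test_identical_seed_identical_output(self, small_config):
        a_tx, a_mi, a_truth = generate_dataset(small_config)
        b_tx, b_mi, b_truth = generate_dataset(small_config)
        pd.testing.assert_frame_equal(a_tx.values, b_tx.values)
        pd.testing.assert_frame_equal(a_mi.values, b_mi.values)
        assert a_truth.true_pairs == b_truth.true_pairs
        assert a_truth.planted_sites == b_truth.planted_sites

    def test_planted_distinct_features_fully_separated(self, small_data):
        ds_tx, _, truth = small_data
        case, control = ds_tx.case_ids, ds_tx.control_ids
        for fid in truth.distinct_ids:
            r = rank_sum_difference(ds_tx.values.loc[fid, case],
                                    ds_tx.values.loc[fid, control])
            assert r.distinct

    def test_noiseless_fold_changes_exact(self):
        cfg = SyntheticConfig(n_mrna=60, n_mirna=20, n_de_mrna=10,
                              n_de_mirna=4, n_distinct=0, n_true_pairs=4,
                              noise_sd=0.0, log_fc_mean=1.0, log_fc_sd=0.0,
                              seed=5)
        ds_tx, _, truth = generate_dataset(cfg)
        for fid in truth.de_mrna_ids:
            fc = signed_fold_change(ds_tx.values.loc[fid, ds_tx.case_ids],
                                    ds_tx.values.loc[fid, ds_tx.control_ids])
            assert abs(fc) == pytest.approx(2.0)

    def test_true_pairs_have_opposite_directions(self, small_data):
        _, _, truth = small_data
        for _, _, d_mi, d_tx in truth.true_pairs:
            assert {d_mi, d_tx} == {"up", "down"}

    def test_every_true_pair_has_a_planted_site(self, small_data):
        _, _, truth = small_data
        planted = {(m, t) for m, t, _, _ in truth.planted_sites}
        for mid, tid, _, _ in truth.true_pairs:
            assert (mid, tid) in planted

    def test_de_recovery_of_planted_features(self):
        """At log2 FC 2 and noise sd 0.5 in a 7v7 design, nearly all planted
        DE features reach p <= 0.05."""
        cfg = SyntheticConfig(n_mrna=1000, n_mirna=50, n_de_mrna=50,
                              n_de_mirna=5, n_distinct=5, n_true_pairs=5,
                              log_fc_mean=2.0, noise_sd=0.5, seed=42)
        ds_tx, _, truth = generate_dataset(cfg)
        table, _ = run_de(ds_tx)
        recovery = table.loc[truth.de_mrna_ids, "regulated"].mean()
        assert recovery >= 0.90

    def test_absent_features_not_called_present(self, small_config,
                                                small_data):
        ds_tx, _, truth = small_data
        table, summary = run_de(ds_tx)
        # absent fraction of the matrix stays uncalled
        assert summary["present"] <= small_config.n_mrna * (
            1 - small_config.frac_absent) + 1


class TestGenerateSequences:
    def test_deterministic(self, small_config, small_data):
        _, _, truth = small_data
        a = generate_sequences(small_config, truth)
        b = generate_sequences(small_config, truth)
        assert a == b

    def test_planted_site_sequence_present_at_position(self, small_data,
                                                       small_sequences):
        from mirpair.targets import site_sequence
        _, _, truth = small_data
        mirna_seqs, utr_seqs = small_sequences
        for mid, tid, stype, pos in truth.planted_sites:
            site = site_sequence(mirna_seqs[mid], stype)
            assert utr_seqs[tid][pos:pos + len(site)] == site

    def test_no_planted_sites_without_pairs(self):
        cfg = SyntheticConfig(n_mrna=40, n_mirna=10, n_de_mrna=5,
                              n_de_mirna=2, n_distinct=0, n_true_pairs=0,
                              seed=3)
        _, _, truth = generate_dataset(cfg)
        generate_sequences(cfg, truth)
        assert truth.planted_sites == []


class TestValidationTable:
    def test_noiseless_round_trip_reproduces_fold_changes(self, small_data):
        ds_tx, _, truth = small_data
        qpcr, curve_params = generate_validation_table(
            truth, ds_tx, noise_sd=0.0, seed=1)
        slope, intercept = next(iter(curve_params.values()))
        series = dilution_series(slope, intercept)
        curve = fit_standard_curve(series["quantity"], series["Ct"])
        features = [f for f in qpcr["feature_id"].unique() if f != "REF"]
        screening, validated = [], []
        for fid in features:
            rel = {}
            for sid in ds_tx.values.columns:
                sub = qpcr[(qpcr["feature_id"] == fid)
                           & (qpcr["sample_id"] == sid)]
                ref = qpcr[(qpcr["feature_id"] == "REF")
                           & (qpcr["sample_id"] == sid)]
                rel[sid] = relative_quantity(sub["Ct"].to_numpy(), curve,
                                             ref["Ct"].to_numpy(), curve)
            v_fc = signed_fold_change(
                [rel[s] for s in ds_tx.case_ids],
                [rel[s] for s in ds_tx.control_ids])
            s_fc = signed_fold_change(
                ds_tx.values.loc[fid, ds_tx.case_ids],
                ds_tx.values.loc[fid, ds_tx.control_ids])
            assert v_fc == pytest.approx(s_fc, rel=1e-9)
            screening.append(s_fc)
            validated.append(v_fc)
        assert spearman_rho(screening, validated) == pytest.approx(1.0)

    def test_reference_constant_across_samples(self, small_data):
        ds_tx, _, truth = small_data
        qpcr, _ = generate_validation_table(truth, ds_tx, noise_sd=0.0,
                                            seed=1)
        ref = qpcr[qpcr["feature_id"] == "REF"]
        assert ref["Ct"].nunique() == 1

    def test_unknown_feature_rejected(self, small_data):
        ds_tx, _, truth = small_data
        from mirpair.errors import MirpairError
        with pytest.raises(MirpairError, match="NOPE"):
            generate_validation_table(truth, ds_tx, features=["NOPE"])

    def test_fixed_seed_reproducible(self, small_data):
        ds_tx, _, truth = small_data
        a, _ = generate_validation_table(truth, ds_tx, noise_sd=0.3, seed=7)
        b, _ = generate_validation_table(truth, ds_tx, noise_sd=0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestAnnotations:
    def test_planted_term_enriched_in_de_set(self, small_config, small_data):
        _, _, truth = small_data
        go = generate_annotations(small_config, truth)
        de = set(truth.de_mrna_ids)
        n_de = sum(1 for g in de if "T001" in go.terms_for(g))
        others = [g for g in go.gene_terms if g not in de]
        n_bg = sum(1 for g in others if "T001" in go.terms_for(g))
        assert n_de / len(de) > 3 * (n_bg / max(len(others), 1))
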