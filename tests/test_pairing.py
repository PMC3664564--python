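"""Opposite-direction pair assembly, the genomic hotspot scan and sign
concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mirpair import MirpairError, assemble_pairs, genomic_map, sign_concordance
from mirpair.studydata import PUBLISHED_PAIRS, reconstruction_tables


def _de_row(fc, p=0.01, regulated=True, distinct=False):
    return {"p_value": p, "fold_change_signed": fc, "present": True,
            "regulated": regulated, "distinct": distinct}


def _tables(mrna_rows, mirna_rows, predictions):
    de_mrna = pd.DataFrame.from_dict(mrna_rows, orient="index")
    de_mirna = pd.DataFrame.from_dict(mirna_rows, orient="index")
    preds = pd.DataFrame(predictions,
                         columns=["mirna_id", "transcript_id", "score"])
    return de_mrna, de_mirna, preds


class TestAssemblePairs:
    def test_opposite_directions_make_a_pair(self):
        de_mrna, de_mirna, preds = _tables(
            {"t1": _de_row(-1.8, 0.02)}, {"m1": _de_row(2.0, 0.01)},
            [("m1", "t1", 4.0)])
        pairs = assemble_pairs(de_mrna, de_mirna, preds)
        assert len(pairs) == 1
        assert pairs.iloc[0]["mirna_id"] == "m1"

    def test_same_direction_rejected(self):
        de_mrna, de_mirna, preds = _tables(
            {"t1": _de_row(1.8)}, {"m1": _de_row(2.0)}, [("m1", "t1", 4.0)])
        assert assemble_pairs(de_mrna, de_mirna, preds).empty

    def test_unpredicted_pairs_not_invented(self):
        de_mrna, de_mirna, preds = _tables(
            {"t1": _de_row(-1.8)}, {"m1": _de_row(2.0)}, [])
        assert assemble_pairs(de_mrna, de_mirna, preds).empty

    def test_unknown_prediction_ids_skipped_and_counted(self):
        de_mrna, de_mirna, preds = _tables(
            {"t1": _de_row(-1.8)}, {"m1": _de_row(2.0)},
            [("m1", "t1", 4.0), ("mX", "t1", 4.0), ("m1", "tX", 4.0)])
        pairs = assemble_pairs(de_mrna, de_mirna, preds)
        assert len(pairs) == 1
        assert pairs.attrs["n_skipped"] == 2

    def test_row_order_invariance(self):
        de_mrna, de_mirna, preds = reconstruction_tables()
        shuffled = preds.sample(frac=1.0, random_state=3).reset_index(
            drop=True)
        a = assemble_pairs(de_mrna, de_mirna, preds)
        b = assemble_pairs(de_mrna, de_mirna, shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_removing_a_prediction_removes_exactly_that_pair(self):
        de_mrna, de_mirna, preds = reconstruction_tables()
        full = assemble_pairs(de_mrna, de_mirna, preds)
        drop = preds.iloc[1:].reset_index(drop=True)
        reduced = assemble_pairs(de_mrna, de_mirna, drop)
        lost = set(map(tuple, full[["mirna_id", "mrna_id"]].to_numpy())) - \
            set(map(tuple, reduced[["mirna_id", "mrna_id"]].to_numpy()))
        assert lost == {(preds.iloc[0]["mirna_id"],
                         preds.iloc[0]["transcript_id"])}

    def test_published_reconstruction_yields_the_eleven_pairs(self):
        de_mrna, de_mirna, preds = reconstruction_tables(
            extra_distractors=True)
        pairs = assemble_pairs(de_mrna, de_mirna, preds)
        got = {(r.mrna_id, r.mirna_id) for r in pairs.itertuples()}
        assert got == set(PUBLISHED_PAIRS)
        assert len(pairs) == 11

    def test_restrict_to_distinct(self):
        de_mrna, de_mirna, preds = _tables(
            {"t1": _de_row(-1.8, distinct=False),
             "t2": _de_row(-1.8, distinct=True)},
            {"m1": _de_row(2.0)},
            [("m1", "t1", 4.0), ("m1", "t2", 4.0)])
        pairs = assemble_pairs(de_mrna, de_mirna, preds,
                               restrict_to_distinct=True)
        assert list(pairs["mrna_id"]) == ["t2"]

    def test_recovers_planted_pairs_from_pipeline(self, small_config,
                                                  small_data,
                                                  small_sequences):
        from mirpair.diffexpr import run_de
        from mirpair.targets import predict_table
        ds_tx, ds_mi, truth = small_data
        mirna_seqs, utr_seqs = small_sequences
        de_tx, _ = run_de(ds_tx)
        de_mi, _ = run_de(ds_mi)
        mi_ids = list(de_mi.index[de_mi["regulated"]])
        preds = predict_table({m: mirna_seqs[m] for m in mi_ids}, utr_seqs)
        pairs = assemble_pairs(de_tx, de_mi, preds)
        found = {(r.mirna_id, r.mrna_id) for r in pairs.itertuples()}
        planted = {(m, t) for m, t, _, _ in truth.true_pairs}
        assert len(planted & found) / len(planted) >= 0.9
        # every reported pair satisfies the opposite-direction rule
        assert (np.sign(pairs["mirna_fc_signed"])
                != np.sign(pairs["mrna_fc_signed"])).all()


def _de_for_map(n, chrom, positions, regulated):
    return (
        pd.DataFrame({
            "present": True, "regulated": regulated,
            "p_value": np.where(regulated, 0.01, 0.5),
            "fold_change_signed": 2.0,
        }, index=[f"f{i}" for i in range(n)]),
        pd.DataFrame({"chrom": chrom, "position": positions,
                      "kind": "mRNA"}, index=[f"f{i}" for i in range(n)]),
    )


class TestGenomicMap:
    def test_clustered_regulation_flags_window(self):
        # 10 of 100 regulated, all 10 in the first 1 Mb window
        regulated = np.zeros(100, bool)
        regulated[:10] = True
        positions = np.concatenate([
            np.linspace(0, 9e5, 10),            # the hot window
            np.linspace(2e6, 99e6, 90),
        ]).astype(int)
        de, meta = _de_for_map(100, "chr1", positions, regulated)
        _, windows = genomic_map(de, meta, window_size=1_000_000)
        hot = windows[windows["n_regulated"] == 10].iloc[0]
        # binomial tail oracle: P(X >= 10), n=10 features in window, p=0.1
        assert hot["p_enrich"] == pytest.approx(
            float(binom.sf(9, 10, 0.1)))
        assert hot["p_enrich"] < 1e-8

    def test_uniform_scatter_rarely_significant(self, rng):
        hits = 0
        for _ in range(20):
            regulated = rng.random(200) < 0.1
            positions = rng.integers(0, 100_000_000, size=200)
            de, meta = _de_for_map(200, "chr1", positions, regulated)
            _, windows = genomic_map(de, meta, window_size=10_000_000)
            hits += int((windows["p_enrich"] < 0.001).any())
        assert hits <= 3

    def test_unmapped_features_skipped_and_counted(self):
        de, meta = _de_for_map(3, "chr1", [100, 200, 300],
                               np.array([True, True, True]))
        meta.loc["f1", "position"] = np.nan
        gmap, _ = genomic_map(de, meta)
        assert len(gmap) == 2
        assert gmap.attrs["n_unmapped"] == 1

    def test_neg_log10_p_matches_de_table(self):
        de, meta = _de_for_map(2, "chr1", [1, 2], np.array([True, True]))
        gmap, _ = genomic_map(de, meta)
        assert gmap["neg_log10_p"].iloc[0] == pytest.approx(-np.log10(0.01))


class TestSignConcordance:
    def test_identical_tables_fully_concordant(self):
        fc = pd.Series({"a": 2.0, "b": -3.0, "c": 1.5})
        assert sign_concordance(fc, fc) == (3, 3)

    def test_one_flip_among_four(self):
        s = pd.Series({"a": 2.0, "b": -3.0, "c": 1.5, "d": -2.0})
        v = pd.Series({"a": 2.0, "b": -3.0, "c": 1.5, "d": 2.0})
        assert sign_concordance(s, v) == (3, 4)

    def test_flat_only_matches_flat(self):
        s = pd.Series({"a": 1.0, "b": 1.0})
        v = pd.Series({"a": 1.0, "b": 2.0})
        assert sign_concordance(s, v) == (1, 2)

    def test_unmatched_features_rejected(self):
        with pytest.raises(MirpairError, match="only"):
            sign_concordance(pd.Series({"a": 2.0}), pd.Series({"b": 2.0}))
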