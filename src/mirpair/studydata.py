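"""Reconstruction of the published oral-lichen-planus screen's pairing inputs.

The original screen reported 11 candidate miRNA-mRNA pairs in which each
differentially expressed miRNA was up-regulated in OLP tissue and its
differentially expressed predicted target transcript was down-regulated.
This module encodes those pairings and directions so the pairing stage can
be exercised against the published result without any downloads.

Fold-change magnitudes and p-values below are *placeholders consistent with
the published directions* (the per-gene magnitudes were not reprinted in the
running text); the pairing rule consumes only the direction, the
significance flag and prediction membership, so the reconstruction is exact
on the identity of the pairs.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PUBLISHED_PAIRS", "reconstruction_tables"]

#: (target gene symbol, miRNA) pairs as printed, with the published
#: directions: miRNA up in cases, target mRNA down.
PUBLISHED_PAIRS: list[tuple[str, str]] = [
    ("COL21A1", "hsa-miR-155"),
    ("CYP46A1", "hsa-miR-342-3p"),
    ("KCNJ1", "hsa-miR-155"),
    ("MADCAM1", "hsa-let-7i"),
    ("MRPS26", "hsa-miR-15a"),
    ("OR2T29", "hsa-miR-143"),
    ("RPS9", "hsa-miR-132"),
    ("SLC10A1", "hsa-miR-31"),
    ("SLC16A8", "hsa-miR-31"),
    ("SNTG1", "hsa-miR-21"),
    ("TRPC5", "hsa-miR-335"),
]


def reconstruction_tables(
    extra_distractors: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DE tables and prediction table reconstructing the published pairing.

    Returns (de_mrna, de_mirna, predictions) shaped like the outputs of
    :func:`mirpair.diffexpr.run_de` / :func:`mirpair.targets.predict_table`,
    with all miRNAs up-regulated and all target transcripts down-regulated
    and significant at p <= 0.05.

    With ``extra_distractors`` the tables additionally carry features that
    must NOT produce pairs: a same-direction predicted pair, a
    non-significant target, and a predicted target absent from the DE table.
    """
    genes = sorted({g for g, _ in PUBLISHED_PAIRS})
    mirnas = sorted({m for _, m in PUBLISHED_PAIRS})

    de_mrna = pd.DataFrame({
        "p_value": 0.01,
        "fold_change_signed": -2.0,
        "direction": "down",
        "present": True,
        "regulated": True,
        "distinct": True,
    }, index=pd.Index(genes, name="feature_id"))
    de_mirna = pd.DataFrame({
        "p_value": 0.01,
        "fold_change_signed": 2.0,
        "direction": "up",
        "present": True,
        "regulated": True,
        "distinct": False,
    }, index=pd.Index(mirnas, name="feature_id"))
    predictions = pd.DataFrame(
        [{"mirna_id": m, "transcript_id": g, "score": 4.0,
          "best_site_type": "8mer", "n_sites": 1}
         for g, m in PUBLISHED_PAIRS],
    )

    if extra_distractors:
        de_mrna.loc["SAMEDIR1"] = {"p_value": 0.01,
                                   "fold_change_signed": 2.0,
                                   "direction": "up", "present": True,
                                   "regulated": True, "distinct": False}
        de_mrna.loc["NOTSIG1"] = {"p_value": 0.5,
                                  "fold_change_signed": -2.0,
                                  "direction": "down", "present": True,
                                  "regulated": False, "distinct": False}
        extra = pd.DataFrame([
            {"mirna_id": "hsa-miR-155", "transcript_id": "SAMEDIR1",
             "score": 4.0, "best_site_type": "8mer", "n_sites": 1},
            {"mirna_id": "hsa-miR-21", "transcript_id": "NOTSIG1",
             "score": 4.0, "best_site_type": "8mer", "n_sites": 1},
            {"mirna_id": "hsa-miR-21", "transcript_id": "UNKNOWN_TX",
             "score": 4.0, "best_site_type": "8mer", "n_sites": 1},
        ])
        predictions = pd.concat([predictions, extra], ignore_index=True)
    return de_mrna, de_mirna, predictions
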