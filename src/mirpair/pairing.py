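"""Opposite-direction miRNA-mRNA candidate pairs, the genomic map and the
hotspot scan, and screening-vs-validation sign concordance.

A candidate pair is a differentially expressed miRNA linked to a
differentially expressed predicted target whose regulation runs in the
opposite direction (miRNA up / target down, or vice versa) — the assembly
rule used to nominate repressive miRNA-target relations from paired
expression screens.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MirpairError

log = logging.getLogger(__name__)

__all__ = ["assemble_pairs", "genomic_map", "sign_concordance",
           "PAIR_COLUMNS"]

PAIR_COLUMNS = [
    "mirna_id", "mrna_id", "mirna_fc_signed", "mrna_fc_signed",
    "mirna_p", "mrna_p", "prediction_score", "source",
]


def _fc_sign(fc: float) -> int:
    """Direction of a signed fold change: +1 up, -1 down, 0 flat (FC == 1)."""
    if fc > 1:
        return 1
    if fc < 0:
        return -1
    return 0


def assemble_pairs(
    de_mrna: pd.DataFrame,
    de_mirna: pd.DataFrame,
    predictions: pd.DataFrame,
    alpha: float = 0.05,
    restrict_to_distinct: bool = False,
    source: str = "internal",
) -> pd.DataFrame:
    """Assemble opposite-direction candidate pairs.

    Parameters
    ----------
    de_mrna, de_mirna : DataFrames indexed by feature id with columns
        ``p_value``, ``fold_change_signed``, ``regulated`` and (mRNA side)
        ``distinct`` — the tables produced by :func:`mirpair.diffexpr.run_de`.
    predictions : prediction table with columns mirna_id, transcript_id,
        score.
    restrict_to_distinct : if True, only distinctly expressed transcripts
        (complete between-group separation) are eligible on the mRNA side.

    Returns a DataFrame with :data:`PAIR_COLUMNS`, one row per unique
    (miRNA, transcript) pair, sorted by (mrna_id, mirna_id).  Prediction rows
    whose ids are absent from the DE tables are skipped with a warning; the
    skip count is available as ``result.attrs["n_skipped"]``.
    """
    n_skipped = 0
    rows = []
    seen = set()
    for _, pred in predictions.iterrows():
        mid, tid = pred["mirna_id"], pred["transcript_id"]
        if (mid, tid) in seen:
            continue
        if mid not in de_mirna.index or tid not in de_mrna.index:
            n_skipped += 1
            continue
        seen.add((mid, tid))
        mi = de_mirna.loc[mid]
        tr = de_mrna.loc[tid]
        if not (bool(mi["regulated"]) and bool(tr["regulated"])):
            continue
        if mi["p_value"] > alpha or tr["p_value"] > alpha:
            continue
        if restrict_to_distinct and not bool(tr["distinct"]):
            continue
        s_mi = _fc_sign(mi["fold_change_signed"])
        s_tr = _fc_sign(tr["fold_change_signed"])
        if s_mi == 0 or s_tr == 0 or s_mi == s_tr:
            continue
        rows.append({
            "mirna_id": mid, "mrna_id": tid,
            "mirna_fc_signed": float(mi["fold_change_signed"]),
            "mrna_fc_signed": float(tr["fold_change_signed"]),
            "mirna_p": float(mi["p_value"]), "mrna_p": float(tr["p_value"]),
            "prediction_score": float(pred["score"])
            if pd.notna(pred["score"]) else np.nan,
            "source": source,
        })
    if n_skipped:
        log.warning("assemble_pairs: %d prediction rows skipped "
                    "(ids absent from DE tables)", n_skipped)
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs = pairs.sort_values(["mrna_id", "mirna_id"]).reset_index(drop=True)
    pairs.attrs["n_skipped"] = n_skipped
    return pairs


def genomic_map(
    de: pd.DataFrame,
    feature_meta: pd.DataFrame,
    kind: str = "mRNA",
    window_size: int = 10_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genomic map rows for regulated features plus a windowed hotspot scan.

    Map rows carry chrom, position, -log10(p) and the signed fold change for
    every regulated feature with coordinates; features without coordinates
    are skipped and counted (``map.attrs["n_unmapped"]``).

    The hotspot scan counts regulated vs present features in fixed windows
    per chromosome and attaches a binomial upper-tail enrichment p-value per
    window against the genome-wide regulated fraction; it is reported as a
    table, not thresholded into a call.
    """
    if window_size <= 0:
        raise ConfigurationError("window_size must be positive")
    meta = feature_meta.reindex(de.index)
    present = de["present"].astype(bool)
    regulated = de["regulated"].astype(bool)
    has_coord = meta["chrom"].notna() & meta["position"].notna()

    n_unmapped = int((regulated & ~has_coord).sum())
    sel = regulated & has_coord
    map_rows = pd.DataFrame({
        "feature_id": de.index[sel],
        "chrom": meta.loc[sel, "chrom"].astype(str).to_numpy(),
        "position": meta.loc[sel, "position"].astype(int).to_numpy(),
        "neg_log10_p": -np.log10(de.loc[sel, "p_value"].to_numpy(float)),
        "fc_signed": de.loc[sel, "fold_change_signed"].to_numpy(float),
        "kind": kind,
    }).sort_values(["chrom", "position"]).reset_index(drop=True)
    map_rows.attrs["n_unmapped"] = n_unmapped
    if n_unmapped:
        log.warning("genomic_map: %d regulated features without coordinates "
                    "skipped", n_unmapped)

    # hotspot scan over present features with coordinates
    base = present & has_coord
    n_present = int(base.sum())
    frac = float((regulated & base).sum()) / n_present if n_present else 0.0
    window_rows = []
    if n_present:
        dfb = pd.DataFrame({
            "chrom": meta.loc[base, "chrom"].astype(str),
            "window": meta.loc[base, "position"].astype(int) // window_size,
            "regulated": regulated[base].to_numpy(),
        })
        for (chrom, win), grp in dfb.groupby(["chrom", "window"], sort=True):
            n = len(grp)
            k = int(grp["regulated"].sum())
            p_enrich = float(stats.binom.sf(k - 1, n, frac)) if frac > 0 else 1.0
            window_rows.append({
                "chrom": chrom, "window_start": int(win) * window_size,
                "window_end": (int(win) + 1) * window_size,
                "n_features": n, "n_regulated": k,
                "expected": n * frac, "p_enrich": p_enrich,
            })
    windows = pd.DataFrame(
        window_rows,
        columns=["chrom", "window_start", "window_end", "n_features",
                 "n_regulated", "expected", "p_enrich"],
    )
    return map_rows, windows


def sign_concordance(screening_fc: pd.Series,
                     validation_fc: pd.Series) -> tuple[int, int]:
    """Count features whose validation fold-change direction matches the
    screening direction.

    A flat fold change (FC == 1) is concordant only with another flat one.
    Both series must cover exactly the same feature ids.
    """
    s_ids, v_ids = set(screening_fc.index), set(validation_fc.index)
    if s_ids != v_ids:
        raise MirpairError(
            f"unmatched features: screening-only {sorted(s_ids - v_ids)}, "
            f"validation-only {sorted(v_ids - s_ids)}"
        )
    n_same = 0
    for fid in screening_fc.index:
        if _fc_sign(screening_fc[fid]) == _fc_sign(validation_fc[fid]):
            n_same += 1
    return n_same, len(screening_fc)
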