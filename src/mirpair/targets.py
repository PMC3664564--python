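"""Canonical seed-match miRNA target prediction with a simple pairing score.

The scanner finds Watson-Crick matches in a 3'UTR (sense strand, 5'->3') to
the miRNA seed, classifying each site as one of the four canonical types::

    6mer      perfect match to miRNA positions 2-7
    7mer-A1   6mer plus an adenosine in the target opposite miRNA position 1
    7mer-m8   perfect match to miRNA positions 2-8
    8mer      7mer-m8 plus the A1 adenosine

In the UTR (read 5'->3') a site is the reverse complement of the seed, so an
8mer looks like  revcomp(m8..m2) + 'A'.  Overlapping classifications of the
same seed occurrence collapse to the strongest type.  G:U wobble pairs are
not accepted (strict Watson-Crick).  Coordinates are 0-based, half-open, on
the given UTR strand; ``utr_start`` is the 5'-most target base of the site.

Scores: 8mer=4, 7mer-m8=3, 7mer-A1=2, 6mer=1, plus a +1 3'-supplementary
bonus when the reverse complement of miRNA positions 13-16 occurs within the
10 bases immediately 5' of the site.  This is a deliberately transparent
stand-in for thermodynamic, structure-aware scoring, which is out of scope;
an externally computed prediction table can be supplied instead anywhere a
prediction table is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .io import PREDICTION_COLUMNS

__all__ = ["TargetSite", "seed_sites", "predict_table", "SITE_TYPES",
           "SITE_SCORES", "site_length", "revcomp"]

SITE_TYPES = ["6mer", "7mer-A1", "7mer-m8", "8mer"]  # weakest -> strongest
SITE_SCORES = {"6mer": 1, "7mer-A1": 2, "7mer-m8": 3, "8mer": 4}
_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
SUPP_WINDOW = 10  # bases 5' of the site searched for the 3'-supplementary match

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def site_length(site_type: str) -> int:
    return _SITE_LEN[site_type]


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement on the DNA alphabet (U normalized to T first)."""
    return _norm(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_type: str
    utr_start: int  # 0-based offset of the site's 5'-most target base
    pairing_score: int


def site_sequence(mirna_seq: str, site_type: str) -> str:
    """The exact UTR subsequence (5'->3', DNA) a site of ``site_type`` shows
    for this miRNA."""
    m = _norm(mirna_seq)
    if len(m) < 8:
        raise ConfigurationError("miRNA sequence must be at least 8 nt")
    core6 = revcomp(m[1:7])   # positions 2-7
    core7 = revcomp(m[1:8])   # positions 2-8
    return {
        "6mer": core6,
        "7mer-A1": core6 + "A",
        "7mer-m8": core7,
        "8mer": core7 + "A",
    }[site_type]


def seed_sites(mirna_seq: str, utr_seq: str, mirna_id: str = "miRNA",
               transcript_id: str = "transcript") -> list[TargetSite]:
    """Scan a UTR for canonical seed sites of one miRNA.

    Returns sites in deterministic left-to-right order of ``utr_start``;
    overlapping classifications of one seed occurrence are reported once, as
    the strongest type.
    """
    m = _norm(mirna_seq)
    if len(m) < 8:
        raise ConfigurationError(
            f"miRNA {mirna_id!r} is {len(m)} nt; need >= 8")
    utr = _norm(utr_seq)
    core6 = revcomp(m[1:7])           # match to positions 2-7
    m8_base = revcomp(m[7])           # match to position 8, sits 5' of core6
    supp = revcomp(m[12:16]) if len(m) >= 16 else None  # positions 13-16

    sites: list[TargetSite] = []
    p = utr.find(core6)
    while p != -1:
        has_m8 = p >= 1 and utr[p - 1] == m8_base
        has_a1 = p + 6 < len(utr) and utr[p + 6] == "A"
        if has_m8 and has_a1:
            stype, start = "8mer", p - 1
        elif has_m8:
            stype, start = "7mer-m8", p - 1
        elif has_a1:
            stype, start = "7mer-A1", p
        else:
            stype, start = "6mer", p
        score = SITE_SCORES[stype]
        if supp is not None:
            window = utr[max(0, start - SUPP_WINDOW):start]
            if supp in window:
                score += 1
        sites.append(TargetSite(mirna_id, transcript_id, stype, start, score))
        p = utr.find(core6, p + 1)
    return sites


def predict_table(mirna_seqs: dict[str, str], utr_seqs: dict[str, str],
                  min_site_type: str = "6mer") -> pd.DataFrame:
    """All-vs-all seed scan condensed to one row per (miRNA, transcript).

    A pair is reported when the transcript's UTR carries at least one site of
    at least ``min_site_type``; the row keeps the best site's type, the best
    pairing score and the total site count (of qualifying sites).
    """
    if min_site_type not in SITE_TYPES:
        raise ConfigurationError(f"unknown site type {min_site_type!r}")
    if not mirna_seqs or not utr_seqs:
        warnings.warn("empty FASTA input: prediction table is empty")
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    min_rank = SITE_TYPES.index(min_site_type)
    rows = []
    for mid in sorted(mirna_seqs):
        for tid in sorted(utr_seqs):
            sites = [
                s for s in seed_sites(mirna_seqs[mid], utr_seqs[tid], mid, tid)
                if SITE_TYPES.index(s.site_type) >= min_rank
            ]
            if not sites:
                continue
            best = max(sites,
                       key=lambda s: (s.pairing_score,
                                      SITE_TYPES.index(s.site_type)))
            rows.append({
                "mirna_id": mid, "transcript_id": tid,
                "score": float(best.pairing_score),
                "best_site_type": best.site_type, "n_sites": len(sites),
            })
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
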