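"""GO biological-process term counting, enrichment/depletion testing and
categorical summarization.

Terms are counted per selection (occurrences of each term over the selected
features), optionally omitting shallow terms (level below ``min_level``)
when level data are available.  Enrichment against a background selection is
tested with exact hypergeometric tails; a label-resampling permutation
alternative is available for cross-checking.  The default background is the
set of present features, not the whole annotation universe.  Annotations are
flat: no ontology-graph (is-a) propagation is performed.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import GOMapping

__all__ = ["count_terms", "hypergeometric_test", "enrich_terms",
           "categorize", "ENRICHMENT_COLUMNS"]

ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "n_selected_with_term", "n_selected",
    "n_background_with_term", "n_background", "expected",
    "p_enrich", "p_deplete", "direction",
]


def count_terms(selected_ids: Iterable[str], go: GOMapping,
                min_level: int = 0) -> tuple[Counter, int]:
    """Occurrence count per GO term over the selected features.

    Terms at level < ``min_level`` are omitted when the mapping carries level
    data (features annotated only to omitted terms still count as annotated).
    Returns (term -> count, number of selected ids without any annotation).
    """
    if min_level < 0:
        raise ConfigurationError("min_level must be >= 0")
    counts: Counter = Counter()
    n_unannotated = 0
    for fid in selected_ids:
        terms = go.terms_for(fid)
        if not terms:
            n_unannotated += 1
            continue
        for t in terms:
            if go.term_level and go.term_level.get(t, min_level) < min_level:
                continue
            counts[t] += 1
    return counts, n_unannotated


def hypergeometric_test(n_sel_term: int, n_sel: int, n_bg_term: int,
                        n_bg: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities for a term's occurrence in a
    selection drawn from a background.

    p_enrich = P(X >= observed), p_deplete = P(X <= observed) for
    X ~ Hypergeom(n_bg, n_bg_term, n_sel).  The two tails share the observed
    point mass, so p_enrich + p_deplete >= 1.
    """
    if not (0 <= n_sel_term <= n_sel <= n_bg and n_bg_term <= n_bg
            and n_sel_term <= n_bg_term):
        raise ConfigurationError(
            f"inconsistent counts: {n_sel_term} of {n_sel} selected, "
            f"{n_bg_term} of {n_bg} in background"
        )
    h = stats.hypergeom(n_bg, n_bg_term, n_sel)
    p_enrich = float(h.sf(n_sel_term - 1))
    p_deplete = float(h.cdf(n_sel_term))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def enrich_terms(
    selected_ids: Iterable[str],
    background_ids: Iterable[str],
    go: GOMapping,
    min_level: int = 0,
    alpha: float = 0.05,
    method: str = "hypergeometric",
    n_perm: int = 10_000,
    seed: int | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-term enrichment/depletion of a selection against a background.

    Membership (does the feature carry the term at least once), not
    multiplicity, enters the test.  ``method="permutation"`` replaces the
    hypergeometric tails with empirical tails from resampling selections of
    equal size from the background (with the +1 small-sample correction).
    """
    selected = list(dict.fromkeys(selected_ids))
    background = list(dict.fromkeys(background_ids))
    bg_set = set(background)
    stray = [s for s in selected if s not in bg_set]
    if stray:
        raise ConfigurationError(
            f"selected ids not in background: {stray[:5]}")
    sel_counts, _ = count_terms(selected, go, min_level)
    # membership counts
    def members(ids):
        c: Counter = Counter()
        for fid in ids:
            for t in go.terms_for(fid):
                if go.term_level and go.term_level.get(t, min_level) < min_level:
                    continue
                c[t] += 1
        return c

    sel_m = members(selected)
    bg_m = members(background)
    n_sel, n_bg = len(selected), len(background)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        terms = sorted(sel_m)
        ge = Counter()
        le = Counter()
        bg_arr = np.array(background)
        for _ in range(n_perm):
            samp = rng.choice(bg_arr, size=n_sel, replace=False)
            m = members(samp)
            for t in terms:
                if m.get(t, 0) >= sel_m[t]:
                    ge[t] += 1
                if m.get(t, 0) <= sel_m[t]:
                    le[t] += 1
    elif method != "hypergeometric":
        raise ConfigurationError(f"unknown method {method!r}")

    rows = []
    for term in sorted(sel_m):
        k, K = sel_m[term], bg_m.get(term, sel_m[term])
        if method == "hypergeometric":
            p_e, p_d = hypergeometric_test(k, n_sel, K, n_bg)
        else:
            p_e = (ge[term] + 1) / (n_perm + 1)
            p_d = (le[term] + 1) / (n_perm + 1)
        direction = ("enriched" if p_e <= alpha
                     else "depleted" if p_d <= alpha else "neither")
        rows.append({
            "term_id": term,
            "term_name": go.term_name.get(term, ""),
            "n_selected_with_term": k, "n_selected": n_sel,
            "n_background_with_term": K, "n_background": n_bg,
            "expected": n_sel * K / n_bg,
            "p_enrich": p_e, "p_deplete": p_d, "direction": direction,
        })
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if adjust == "bh" and len(table):
        from statsmodels.stats.multitest import multipletests
        table["p_enrich_adj"] = multipletests(table["p_enrich"],
                                              method="fdr_bh")[1]
        table["p_deplete_adj"] = multipletests(table["p_deplete"],
                                               method="fdr_bh")[1]
    return table


def categorize(term_counts: Mapping[str, int],
               term_category: Mapping[str, str]) -> dict[str, int]:
    """Sum term counts into categories; terms without a category go to
    "other".  Category totals conserve the term-count total."""
    out: dict[str, int] = {}
    for term, count in term_counts.items():
        cat = term_category.get(term, "other")
        out[cat] = out.get(cat, 0) + count
    return out
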