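"""Synthetic two-platform (mRNA + miRNA) expression data with planted truth.

The generator emulates the screening design the pipeline targets: a small
two-group comparison (7 cases vs 7 controls by default) measured on an mRNA
and a miRNA platform, with

* a present/absent split (absent features sit below the present-call floor),
* a minority of features differentially expressed with signed log2 shifts,
* a small subset of DE transcripts with *complete* between-group separation
  (distinct expression), enforced with a guaranteed gap,
* planted miRNA->target relations in which the miRNA and its target move in
  opposite directions, each backed by an exact seed-match site spliced into
  the target's 3'UTR,
* qPCR-like triplicate Ct tables tied to the expression values through a
  configurable standard curve, and
* flat GO annotations with one term preferentially attached to DE
  transcripts.

All randomness flows from ``config.seed`` through named per-stage
generators; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MirpairError
from .io import ExpressionDataset, GOMapping
from .targets import seed_sites, site_length, site_sequence, SITE_TYPES

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset",
           "generate_sequences", "generate_validation_table",
           "generate_annotations", "dilution_series", "mrna_ids", "mirna_ids"]

#: slope of an efficiency-1.0 standard curve: one Ct per doubling
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic screen.

    Defaults mirror the target design at reduced feature scale: 7 vs 7
    samples, ~20% of features absent, a minority of present features DE, a
    small distinct subset, and planted opposite-direction miRNA-target
    pairs.  Effect sizes are on the log2 scale.
    """

    n_case: int = 7
    n_control: int = 7
    n_mrna: int = 2000
    n_mirna: int = 300
    frac_absent: float = 0.2
    n_de_mrna: int = 100
    n_de_mirna: int = 20
    n_distinct: int = 10
    n_true_pairs: int = 10
    max_targets: int = 5          # planted targets per miRNA, at most
    log_fc_mean: float = 2.0      # mean |planted shift|, log2 scale
    log_fc_sd: float = 0.5
    noise_sd: float = 0.5         # within-group log2 sd
    baseline_mean: float = 7.0    # log2 baseline of present features
    baseline_sd: float = 2.0
    present_floor: float = 4.0    # log2 present-call floor the data target
    utr_len: int = 400
    site_type: str = "8mer"
    mirna_len: int = 22
    seed: int = 0

    def validate(self) -> None:
        c = self
        if min(c.n_case, c.n_control) < 1:
            raise ConfigurationError("need >= 1 sample per group")
        if not (0 <= c.frac_absent < 1):
            raise ConfigurationError("frac_absent must be in [0, 1)")
        for name in ("n_mrna", "n_mirna", "n_de_mrna", "n_de_mirna",
                     "n_distinct", "n_true_pairs", "max_targets"):
            if getattr(c, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if c.n_distinct > c.n_de_mrna:
            raise ConfigurationError(
                f"n_distinct ({c.n_distinct}) > n_de_mrna ({c.n_de_mrna})")
        if c.n_true_pairs > min(c.n_de_mrna,
                                c.n_de_mirna * max(c.max_targets, 0)):
            raise ConfigurationError(
                "n_true_pairs exceeds min(n_de_mrna, n_de_mirna * max_targets)")
        n_present_mrna = c.n_mrna - round(c.frac_absent * c.n_mrna)
        n_present_mirna = c.n_mirna - round(c.frac_absent * c.n_mirna)
        if c.n_de_mrna > n_present_mrna:
            raise ConfigurationError("n_de_mrna exceeds present mRNA count")
        if c.n_de_mirna > n_present_mirna:
            raise ConfigurationError("n_de_mirna exceeds present miRNA count")
        if c.site_type not in SITE_TYPES:
            raise ConfigurationError(f"unknown site type {c.site_type!r}")
        if c.utr_len < site_length(c.site_type) + 2:
            raise ConfigurationError(
                f"utr_len {c.utr_len} too short for a {c.site_type} site")
        if c.noise_sd < 0 or c.log_fc_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if c.mirna_len < 8:
            raise ConfigurationError("mirna_len must be >= 8")


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests.

    ``true_pairs`` entries are (mirna_id, mrna_id, mirna_direction,
    mrna_direction) with opposite directions by construction;
    ``planted_sites`` entries are (mirna_id, mrna_id, site_type,
    utr_position) with 0-based positions; ``chance_sites`` records
    incidental (non-planted) seed matches of true-pair miRNAs found after
    sequence generation.
    """

    de_mrna_ids: list[str]
    de_mirna_ids: list[str]
    distinct_ids: list[str]
    true_pairs: list[tuple[str, str, str, str]]
    planted_sites: list[tuple[str, str, str, int]]
    chance_sites: list[tuple[str, str, str, int]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("true_pairs", "planted_sites", "chance_sites"):
            d[key] = [tuple(x) for x in d.get(key, [])]
        return cls(**d)


def mrna_ids(config: SyntheticConfig) -> list[str]:
    return [f"TX{i:05d}" for i in range(1, config.n_mrna + 1)]


def mirna_ids(config: SyntheticConfig) -> list[str]:
    return [f"MIR{i:04d}" for i in range(1, config.n_mirna + 1)]


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    case = [f"case_{i:02d}" for i in range(1, config.n_case + 1)]
    control = [f"control_{i:02d}" for i in range(1, config.n_control + 1)]
    return case, control


def _platform(rng, ids, kind, n_de, n_distinct, de_signs, config):
    """Log2 matrix + metadata for one platform; returns (log2_values,
    feature_meta, de_ids, distinct_ids)."""
    c = config
    n = len(ids)
    n_samples = c.n_case + c.n_control
    n_absent = round(c.frac_absent * n)
    absent_idx = rng.choice(n, size=n_absent, replace=False)
    absent = np.zeros(n, bool)
    absent[absent_idx] = True

    baseline = rng.normal(c.baseline_mean, c.baseline_sd, size=n)
    baseline = np.maximum(baseline, 0.0)
    # absent features live below the present-call floor in essentially all
    # samples of both groups
    baseline[absent] = rng.uniform(0.5, max(c.present_floor - 1.5, 0.6),
                                   size=n_absent)

    present_idx = np.flatnonzero(~absent)
    de_idx = rng.choice(present_idx, size=n_de, replace=False)
    # planted features are kept clear of the floor so detectability is a
    # matter of noise, not of the present call
    baseline[de_idx] = np.maximum(baseline[de_idx], c.present_floor + 2.0)

    shifts = np.zeros(n)
    mags = np.abs(rng.normal(c.log_fc_mean, c.log_fc_sd, size=n_de))
    mags = np.maximum(mags, 0.25)
    shifts[de_idx] = de_signs * mags

    log2 = baseline[:, None] + rng.normal(0.0, c.noise_sd,
                                          size=(n, n_samples))
    log2[:, : c.n_case] += shifts[:, None]

    # guaranteed-gap enforcement for the distinct subset
    distinct_idx = de_idx[:n_distinct]
    gap = max(0.5, c.noise_sd)
    for i in distinct_idx:
        case_v = log2[i, : c.n_case]
        ctrl_v = log2[i, c.n_case:]
        if shifts[i] >= 0:
            short = ctrl_v.max() + gap - case_v.min()
            if short > 0:
                log2[i, : c.n_case] += short
        else:
            short = case_v.max() + gap - ctrl_v.min()
            if short > 0:
                log2[i, : c.n_case] -= short

    log2 = np.maximum(log2, 0.01)  # keep linear values strictly positive
    chroms = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    positions = rng.integers(0, 240_000_000, size=n)
    meta = pd.DataFrame({
        "symbol": [f"{'GENE' if kind == 'mRNA' else 'mir'}-{i}"
                   for i in range(1, n + 1)],
        "kind": kind,
        "chrom": chroms,
        "position": positions,
    }, index=pd.Index(ids, name="feature_id"))
    de_ids = [ids[i] for i in de_idx]
    distinct_ids = [ids[i] for i in distinct_idx]
    return log2, meta, de_ids, distinct_ids


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Generate the mRNA dataset, the miRNA dataset and the planted truth."""
    config.validate()
    c = config
    rng = np.random.default_rng([c.seed, 0])
    case_ids, control_ids = _sample_ids(c)
    samples = case_ids + control_ids
    sample_meta = pd.DataFrame(
        {"group": ["case"] * c.n_case + ["control"] * c.n_control},
        index=pd.Index(samples, name="sample_id"),
    )

    # miRNA directions first; paired targets get the opposite direction
    mirna_signs = rng.choice([-1, 1], size=c.n_de_mirna)
    log2_mi, meta_mi, de_mi_ids, _ = _platform(
        rng, mirna_ids(c), "miRNA", c.n_de_mirna, 0, mirna_signs, c)

    # assign true pairs: cycle DE miRNAs, at most max_targets targets each
    pair_mirna_pos = [i % c.n_de_mirna for i in range(c.n_true_pairs)] \
        if c.n_de_mirna else []
    mrna_signs = rng.choice([-1, 1], size=c.n_de_mrna)
    for j, mi_pos in enumerate(pair_mirna_pos):
        mrna_signs[j] = -mirna_signs[mi_pos]   # opposite direction, planted

    log2_tx, meta_tx, de_tx_ids, distinct_ids = _platform(
        rng, mrna_ids(c), "mRNA", c.n_de_mrna, c.n_distinct, mrna_signs, c)

    def direction(sign: int) -> str:
        return "up" if sign > 0 else "down"

    true_pairs = [
        (de_mi_ids[mi_pos], de_tx_ids[j],
         direction(mirna_signs[mi_pos]), direction(mrna_signs[j]))
        for j, mi_pos in enumerate(pair_mirna_pos)
    ]

    # one seed site per true pair, non-overlapping within each UTR
    slen = site_length(c.site_type)
    used: dict[str, list[tuple[int, int]]] = {}
    planted_sites = []
    for mid, tid, _, _ in true_pairs:
        for _ in range(200):
            pos = int(rng.integers(0, c.utr_len - slen + 1))
            if all(pos + slen <= a or pos >= b for a, b in used.get(tid, [])):
                used.setdefault(tid, []).append((pos, pos + slen))
                planted_sites.append((mid, tid, c.site_type, pos))
                break
        else:  # pragma: no cover - requires a pathological utr_len
            raise ConfigurationError(
                f"could not place a non-overlapping site in UTR of {tid}")

    truth = GroundTruth(sorted(de_tx_ids), sorted(de_mi_ids),
                        sorted(distinct_ids), true_pairs, planted_sites)
    ds_tx = ExpressionDataset(
        pd.DataFrame(2.0 ** log2_tx, index=meta_tx.index, columns=samples),
        meta_tx, sample_meta)
    ds_mi = ExpressionDataset(
        pd.DataFrame(2.0 ** log2_mi, index=meta_mi.index, columns=samples),
        meta_mi, sample_meta.copy())
    return ds_tx, ds_mi, truth


_RNA_BASES = np.array(list("ACGU"))
_DNA_BASES = np.array(list("ACGT"))


def generate_sequences(
    config: SyntheticConfig, truth: GroundTruth,
) -> tuple[dict[str, str], dict[str, str]]:
    """Random-composition miRNA (RNA) and 3'UTR (DNA) sequences with the
    planted seed-match sites spliced in at the recorded positions.

    Returns (mirna_seqs, utr_seqs).  After planting, the UTRs of all
    transcripts are scanned for incidental sites of the true-pair miRNAs;
    non-planted hits are recorded in ``truth.chance_sites``.
    """
    config.validate()
    c = config
    rng = np.random.default_rng([c.seed, 1])
    mirna_seqs = {
        mid: "".join(rng.choice(_RNA_BASES, size=c.mirna_len))
        for mid in mirna_ids(c)
    }
    utr_seqs = {
        tid: "".join(rng.choice(_DNA_BASES, size=c.utr_len))
        for tid in mrna_ids(c)
    }
    for mid, tid, stype, pos in truth.planted_sites:
        if mid not in mirna_seqs or tid not in utr_seqs:
            raise MirpairError(f"planted site references unknown id "
                               f"({mid}, {tid})")
        site = site_sequence(mirna_seqs[mid], stype)
        if pos + len(site) > c.utr_len:
            raise ConfigurationError(
                f"utr_len {c.utr_len} too short for site at {pos}")
        u = utr_seqs[tid]
        utr_seqs[tid] = u[:pos] + site + u[pos + len(site):]

    planted = {(m, t, s, p) for m, t, s, p in truth.planted_sites}
    chance = []
    for mid in sorted({m for m, _, _, _ in truth.true_pairs}):
        for tid, utr in utr_seqs.items():
            for s in seed_sites(mirna_seqs[mid], utr, mid, tid):
                key = (mid, tid, s.site_type, s.utr_start)
                if key not in planted:
                    chance.append(key)
    truth.chance_sites = chance
    return mirna_seqs, utr_seqs


def dilution_series(curve_slope: float, curve_intercept: float,
                    quantities=(1.0, 10.0, 100.0, 1000.0)) -> pd.DataFrame:
    """Exact (noise-free) Ct values of a dilution series on a given line."""
    q = np.asarray(quantities, dtype=float)
    return pd.DataFrame({
        "quantity": q,
        "Ct": curve_intercept + curve_slope * np.log10(q),
    })


def generate_validation_table(
    truth: GroundTruth,
    dataset: ExpressionDataset,
    noise_sd: float = 0.25,
    seed: int = 0,
    features: list[str] | None = None,
    slope: float = PERFECT_SLOPE,
    intercept: float = 38.0,
    reference_id: str = "REF",
    reference_quantity: float = 100.0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """qPCR-like triplicate Ct table for selected features of one dataset.

    Each feature's Ct in each sample follows the standard curve
    ``Ct = intercept + slope * log10(linear expression)`` plus independent
    N(0, noise_sd) noise per technical replicate.  The reference assay
    measures a constant quantity in every sample, so normalizing to it
    leaves the feature's relative expression intact; with ``noise_sd = 0``
    the validation fold changes equal the screening fold changes exactly.

    Returns (table, curves): the long-format table (feature_id, sample_id,
    replicate, Ct) and the per-assay standard-curve parameters
    {feature_id: (slope, intercept)} including the reference.
    """
    if features is None:
        members = [tid for _, tid, _, _ in truth.true_pairs] + \
                  [mid for mid, _, _, _ in truth.true_pairs]
        features = sorted({f for f in members if f in dataset.values.index})
    unknown = [f for f in features if f not in dataset.values.index]
    if unknown:
        raise MirpairError(f"unknown feature ids for validation: {unknown}")
    rng = np.random.default_rng([seed, 3])
    rows = []
    samples = list(dataset.values.columns)
    for fid in list(features) + [reference_id]:
        for sid in samples:
            quantity = (reference_quantity if fid == reference_id
                        else float(dataset.values.at[fid, sid]))
            ct0 = intercept + slope * np.log10(quantity)
            for rep in range(1, n_replicates + 1):
                ct = ct0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append({"feature_id": fid, "sample_id": sid,
                             "replicate": rep, "Ct": ct})
    table = pd.DataFrame(rows, columns=["feature_id", "sample_id",
                                        "replicate", "Ct"])
    curves = {fid: (slope, intercept)
              for fid in list(features) + [reference_id]}
    return table, curves


#: categories used for the synthetic GO universe; mirrors the major
#: categories a mucosal-disease screen surfaces
_CATEGORIES = ["proliferation", "apoptosis", "ion transport",
               "immune process", "development", "metabolism"]


def generate_annotations(
    config: SyntheticConfig, truth: GroundTruth,
    n_terms: int = 30,
    enriched_term_prob: float = 0.5,
    background_term_prob: float = 0.05,
) -> GOMapping:
    """Flat GO-like annotations over the mRNA universe.

    Every term gets a name, a level in 1..4 and a category; genes receive
    Poisson(2) random terms.  The first term is additionally attached to DE
    transcripts with probability ``enriched_term_prob`` (vs
    ``background_term_prob`` elsewhere), planting one genuinely enriched
    process for the enrichment stage to find.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    terms = [f"T{i:03d}" for i in range(1, n_terms + 1)]
    term_name = {t: f"process {i}" for i, t in enumerate(terms, start=1)}
    term_level = {t: 1 + (i % 4) for i, t in enumerate(terms)}
    term_level[terms[0]] = 3  # planted term must survive min_level filters
    term_category = {t: _CATEGORIES[i % len(_CATEGORIES)]
                     for i, t in enumerate(terms)}
    de_set = set(truth.de_mrna_ids)
    gene_terms: dict[str, set[str]] = {}
    for gid in mrna_ids(config):
        k = min(int(rng.poisson(2.0)), n_terms)
        chosen = set(rng.choice(terms, size=k, replace=False)) if k else set()
        p_first = enriched_term_prob if gid in de_set else background_term_prob
        if rng.random() < p_first:
            chosen.add(terms[0])
        if chosen:
            gene_terms[gid] = chosen
    return GOMapping(gene_terms, term_name, term_category, term_level)
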