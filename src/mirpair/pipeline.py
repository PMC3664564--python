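"""End-to-end orchestration: simulate -> present-call/DE -> predict -> pair
-> map -> enrich -> structure -> validate, with one config and a manifest.

Every stage writes its outputs as TSV/JSON into the run directory;
intermediate files are the only inter-stage contract, so any stage can be
re-run from files via the CLI.  Stage outputs are pure functions of
(config, seed): re-running with the same config produces byte-identical
files, and the manifest records a SHA-256 digest of each output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import StageError
from .io import (ExpressionDataset, write_expression, write_fasta,
                 write_go_mapping, write_predictions, write_qpcr, write_tsv)
from .diffexpr import run_de
from .enrichment import categorize, count_terms, enrich_terms
from .pairing import assemble_pairs, genomic_map, sign_concordance
from .simulate import (SyntheticConfig, dilution_series, generate_annotations,
                       generate_dataset, generate_sequences,
                       generate_validation_table)
from .structure import cluster_samples, pca_samples, separation_score
from .targets import predict_table
from .validation import (StandardCurve, fit_standard_curve,
                         permutation_concordance, relative_quantity)

log = logging.getLogger("mirpair.pipeline")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline run (see docs/methods.md for rationale)."""

    outdir: str = "mirpair_run"
    seed: int = 0
    alpha: float = 0.05            # regulated <=> p <= alpha (inclusive)
    floor: float = 4.0             # present-call log2 floor
    min_frac: float = 0.5          # present-call sample fraction
    mw_mode: str = "auto"          # Mann-Whitney p mode
    min_site_type: str = "6mer"    # weakest site type kept by the scanner
    restrict_to_distinct: bool = False
    k_permutations: int = 10_000   # concordance permutations
    validation_noise_sd: float = 0.25
    go_min_level: int = 2
    hotspot_window: int = 10_000_000
    external_predictions: str | None = None
    log_level: str = "INFO"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        self.synthetic.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _log2_signed_fc(fc: float) -> float:
    """Signed fold change (+r / -1/r) -> signed log2 ratio."""
    return float(np.log2(fc)) if fc > 0 else float(-np.log2(-fc))


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic dataset generated from the config.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``):
    seed, config, per-stage summary counts and SHA-256 digests of every
    output file.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s: %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, path: Path):
        written[name] = path

    summary: dict = {"seed": config.seed, "version": __version__}

    # ---------------------------------------------------------- simulate
    stage = "simulate"
    try:
        log.info("[%s] generating synthetic two-platform dataset", stage)
        ds_tx, ds_mi, truth = generate_dataset(config.synthetic)
        mirna_seqs, utr_seqs = generate_sequences(config.synthetic, truth)
        go = generate_annotations(config.synthetic, truth)
        write_expression(ds_tx, out / "mrna_matrix.tsv",
                         out / "samples.tsv", out / "mrna_features.tsv")
        write_expression(ds_mi, out / "mirna_matrix.tsv",
                         out / "samples.tsv", out / "mirna_features.tsv")
        write_fasta(mirna_seqs, out / "mirna.fasta")
        write_fasta(utr_seqs, out / "utr.fasta")
        write_go_mapping(go, out / "go_mapping.tsv", out / "go_terms.tsv")
        truth.to_json(out / "ground_truth.json")
        for n in ("mrna_matrix.tsv", "mirna_matrix.tsv", "samples.tsv",
                  "mrna_features.tsv", "mirna_features.tsv", "mirna.fasta",
                  "utr.fasta", "go_mapping.tsv", "go_terms.tsv",
                  "ground_truth.json"):
            emit(n, out / n)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------------------------------------------------------- de
    stage = "de"
    try:
        log.info("[%s] rank-based differential expression", stage)
        de_tx, sum_tx = run_de(ds_tx, alpha=config.alpha, floor=config.floor,
                               min_frac=config.min_frac, mode=config.mw_mode)
        de_mi, sum_mi = run_de(ds_mi, alpha=config.alpha, floor=config.floor,
                               min_frac=config.min_frac, mode=config.mw_mode)
        write_tsv(de_tx, out / "de_mrna.tsv", index_label="feature_id")
        write_tsv(de_mi, out / "de_mirna.tsv", index_label="feature_id")
        emit("de_mrna.tsv", out / "de_mrna.tsv")
        emit("de_mirna.tsv", out / "de_mirna.tsv")
        summary["de_mrna"] = sum_tx
        summary["de_mirna"] = sum_mi
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ----------------------------------------------------------- predict
    stage = "predict"
    try:
        if config.external_predictions:
            from .io import read_predictions
            path = Path(config.external_predictions)
            if not path.exists():
                raise FileNotFoundError(
                    f"external prediction table not found: {path}")
            predictions = read_predictions(path)
            log.info("[%s] using external prediction table %s", stage, path)
        else:
            # scanning is restricted to DE features: only regulated miRNAs
            # and present transcripts can enter pairs downstream
            mi_de_ids = list(de_mi.index[de_mi["regulated"]])
            tx_present_ids = list(de_tx.index[de_tx["present"]])
            predictions = predict_table(
                {m: mirna_seqs[m] for m in mi_de_ids if m in mirna_seqs},
                {t: utr_seqs[t] for t in tx_present_ids if t in utr_seqs},
                min_site_type=config.min_site_type)
        write_predictions(predictions, out / "predictions.tsv")
        emit("predictions.tsv", out / "predictions.tsv")
        summary["predictions"] = int(len(predictions))
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ------------------------------------------------------------- pairs
    stage = "pairs"
    try:
        pairs = assemble_pairs(de_tx, de_mi, predictions, alpha=config.alpha,
                               restrict_to_distinct=config.restrict_to_distinct)
        write_tsv(pairs, out / "pairs.tsv", index=False)
        emit("pairs.tsv", out / "pairs.tsv")
        summary["n_pairs"] = int(len(pairs))
        log.info("[%s] %d opposite-direction candidate pairs", stage,
                 len(pairs))
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --------------------------------------------------------------- map
    stage = "map"
    try:
        map_tx, win_tx = genomic_map(de_tx, ds_tx.feature_meta, "mRNA",
                                     config.hotspot_window)
        map_mi, win_mi = genomic_map(de_mi, ds_mi.feature_meta, "miRNA",
                                     config.hotspot_window)
        gmap = pd.concat([map_tx, map_mi], ignore_index=True)
        windows = pd.concat([win_tx, win_mi], ignore_index=True)
        write_tsv(gmap, out / "genomic_map.tsv", index=False)
        write_tsv(windows, out / "hotspot_windows.tsv", index=False)
        emit("genomic_map.tsv", out / "genomic_map.tsv")
        emit("hotspot_windows.tsv", out / "hotspot_windows.tsv")
        summary["map_rows"] = int(len(gmap))
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------------------------------------------------------- go
    stage = "go"
    try:
        regulated = list(de_tx.index[de_tx["regulated"]])
        background = list(de_tx.index[de_tx["present"]])
        enr = enrich_terms(regulated, background, go,
                           min_level=config.go_min_level, alpha=config.alpha)
        counts, n_unannot = count_terms(regulated, go,
                                        min_level=config.go_min_level)
        cats = categorize(counts, go.term_category)
        write_tsv(enr, out / "go_enrichment.tsv", index=False)
        cat_table = pd.DataFrame(sorted(cats.items()),
                                 columns=["category", "count"])
        write_tsv(cat_table, out / "go_categories.tsv", index=False)
        emit("go_enrichment.tsv", out / "go_enrichment.tsv")
        emit("go_categories.tsv", out / "go_categories.tsv")
        summary["go"] = {"terms_tested": int(len(enr)),
                         "enriched": int((enr["direction"] == "enriched").sum()),
                         "depleted": int((enr["direction"] == "depleted").sum()),
                         "unannotated": n_unannot}
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --------------------------------------------------------- structure
    stage = "structure"
    try:
        subset = list(de_tx.index[de_tx["distinct"]])
        if len(subset) < 2:
            subset = regulated
        dend = cluster_samples(ds_tx, subset)
        pca = pca_samples(ds_tx, subset)
        labels = ds_tx.sample_meta["group"]
        mis_cluster = separation_score(labels, dend.cut(2))
        mis_pca = separation_score(labels, pca.scores["PCA1"])
        (out / "dendrogram.newick").write_text(dend.to_newick() + "\n",
                                               newline="\n")
        write_tsv(pca.scores, out / "pca_scores.tsv",
                  index_label="sample_id")
        _write_json({
            "cluster_misassigned": int(mis_cluster),
            "pca1_misassigned": int(mis_pca),
            "pca_explained_variance": [round(float(v), 6)
                                       for v in pca.explained_variance_ratio[:2]],
            "n_features_used": len(subset),
        }, out / "separation.json")
        for n in ("dendrogram.newick", "pca_scores.tsv", "separation.json"):
            emit(n, out / n)
        summary["separation"] = {"cluster": int(mis_cluster),
                                 "pca1": int(mis_pca)}
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------------------------------------------------- validate
    stage = "validate"
    try:
        pair_tx = sorted({t for _, t, _, _ in truth.true_pairs})
        pair_mi = sorted({m for m, _, _, _ in truth.true_pairs})
        features: list[str] = []
        screening_fc: dict[str, float] = {}
        tables = []
        curves: dict[str, StandardCurve] = {}
        for ds, de_table, ids, refname in (
            (ds_tx, de_tx, pair_tx, "ACTB_REF"),
            (ds_mi, de_mi, pair_mi, "SNORD_REF"),
        ):
            if not ids:
                continue
            qpcr, curve_params = generate_validation_table(
                truth, ds, noise_sd=config.validation_noise_sd,
                seed=config.seed, features=ids, reference_id=refname)
            tables.append((qpcr, refname, ds))
            for fid, (slope, intercept) in curve_params.items():
                series = dilution_series(slope, intercept)
                curves[fid] = fit_standard_curve(series["quantity"],
                                                 series["Ct"])
            for fid in ids:
                screening_fc[fid] = float(
                    de_table.at[fid, "fold_change_signed"])
            features.extend(ids)

        # relative quantification per feature and sample, then validation FCs
        validation_fc: dict[str, float] = {}
        comparison_rows = []
        for qpcr, refname, ds in tables:
            case_ids, control_ids = ds.case_ids, ds.control_ids
            by = qpcr.groupby(["feature_id", "sample_id"])["Ct"]
            ct = by.apply(lambda s: s.to_numpy())
            fids = [f for f in qpcr["feature_id"].unique() if f != refname]
            for fid in fids:
                rel = {
                    sid: relative_quantity(ct[(fid, sid)], curves[fid],
                                           ct[(refname, sid)], curves[refname])
                    for sid in case_ids + control_ids
                }
                mc = float(np.mean([rel[s] for s in case_ids]))
                mk = float(np.mean([rel[s] for s in control_ids]))
                r = mc / mk
                validation_fc[fid] = r if r >= 1 else -1.0 / r
                comparison_rows.append({
                    "feature_id": fid,
                    "screening_fc": screening_fc[fid],
                    "validation_fc": validation_fc[fid],
                })
            write_qpcr(qpcr, out / f"qpcr_{refname}.tsv")
            emit(f"qpcr_{refname}.tsv", out / f"qpcr_{refname}.tsv")

        comparison = pd.DataFrame(
            comparison_rows,
            columns=["feature_id", "screening_fc", "validation_fc"])
        write_tsv(comparison, out / "validation_comparison.tsv", index=False)
        emit("validation_comparison.tsv", out / "validation_comparison.tsv")

        if len(comparison) >= 3:
            s_fc = pd.Series({r["feature_id"]: r["screening_fc"]
                              for r in comparison_rows})
            v_fc = pd.Series({r["feature_id"]: r["validation_fc"]
                              for r in comparison_rows})
            n_same, n_total = sign_concordance(s_fc, v_fc)
            x = np.array([_log2_signed_fc(v) for v in s_fc])
            y = np.array([_log2_signed_fc(v) for v in v_fc])
            conc = permutation_concordance(x, y, k=config.k_permutations,
                                           seed=config.seed)
            concordance = {
                "rho_observed": round(conc.rho_observed, 6),
                "k": conc.k,
                "p_empirical": conc.p_empirical,
                "p_one_sided": conc.p_one_sided,
                "n_same_direction": n_same,
                "n_signals": n_total,
            }
        else:
            concordance = {"n_signals": int(len(comparison))}
        _write_json(concordance, out / "concordance.json")
        emit("concordance.json", out / "concordance.json")
        summary["concordance"] = concordance
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------------------------------------------------- manifest
    manifest = dict(summary)
    manifest["config"] = dataclasses.asdict(config)
    manifest["outputs"] = {name: _digest(path)
                           for name, path in sorted(written.items())}
    _write_json(manifest, out / "manifest.json")
    return manifest
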