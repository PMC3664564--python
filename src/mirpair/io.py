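"""Readers and writers for every pipeline artifact.

Expression values are held internally on the *linear* scale (positive relative
expression); log2 transforms happen explicitly at computation sites.  All text
tables are TSV with a header row, UTF-8, LF line endings.  Genomic coordinates
and UTR site offsets are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

GROUPS = ("case", "control")

_DNA = set("ACGTN")
_RNA = set("ACGUN")


@dataclass
class ExpressionDataset:
    """A features x samples matrix of positive relative-expression values.

    Attributes
    ----------
    values : pandas.DataFrame
        Linear-scale expression, indexed by feature id, columns = sample ids.
    feature_meta : pandas.DataFrame
        Indexed by feature id; columns ``symbol``, ``kind`` ("mRNA"/"miRNA"),
        ``chrom``, ``position`` (0-based bp; nullable).
    sample_meta : pandas.DataFrame
        Indexed by sample id; column ``group`` in {"case", "control"}.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            bad = self.values.index[~np.isfinite(vals).all(axis=1)][0]
            raise ParseError(f"non-finite expression value in feature {bad!r}")
        if (vals <= 0).any():
            bad = self.values.index[(vals <= 0).any(axis=1)][0]
            raise ParseError(
                f"non-positive linear expression value in feature {bad!r}"
            )
        missing = set(self.sample_meta.index) - set(self.values.columns)
        if missing:
            raise ParseError(
                f"samples in sheet but not in matrix: {sorted(missing)}"
            )
        bad_groups = set(self.sample_meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ParseError(
                f"group labels outside {GROUPS}: {sorted(bad_groups)}"
            )

    @property
    def case_ids(self) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["group"] == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(
            self.sample_meta.index[self.sample_meta["group"] == "control"]
        )

    def log2(self) -> pd.DataFrame:
        """Expression on the log2 scale (explicit transform)."""
        return np.log2(self.values)

    def subset_features(self, ids: Iterable[str]) -> "ExpressionDataset":
        ids = list(ids)
        return ExpressionDataset(
            self.values.loc[ids],
            self.feature_meta.loc[ids],
            self.sample_meta.copy(),
        )


def read_expression(
    matrix_path, sample_sheet_path, scale: str = "linear",
    feature_meta_path=None,
) -> ExpressionDataset:
    """Read an expression TSV plus sample sheet into an ExpressionDataset.

    ``scale`` is "linear" or "log2"; log2 input is exponentiated so the
    dataset always stores linear values.
    """
    if scale not in ("linear", "log2"):
        raise ParseError(f"scale must be 'linear' or 'log2', got {scale!r}")
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise ParseError(f"duplicate feature id {dup!r} in {matrix_path}")
    try:
        mat = mat.astype(float)
    except ValueError as e:
        raise ParseError(f"non-numeric cell in {matrix_path}: {e}") from e
    if scale == "log2":
        mat = 2.0 ** mat
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ParseError(
                f"sample sheet {sample_sheet_path} missing column {col!r}"
            )
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate sample id {dup!r} in sample sheet")
    sample_meta = sheet.set_index("sample_id")[["group"]]
    if feature_meta_path is not None:
        feature_meta = pd.read_csv(feature_meta_path, sep="\t", index_col=0)
    else:
        feature_meta = pd.DataFrame(index=mat.index)
    for col, default in (
        ("symbol", None), ("kind", "mRNA"), ("chrom", None), ("position", None)
    ):
        if col not in feature_meta.columns:
            feature_meta[col] = default
    return ExpressionDataset(mat, feature_meta, sample_meta)


def write_expression(
    dataset: ExpressionDataset, matrix_path, sample_sheet_path,
    feature_meta_path=None,
) -> None:
    _write_tsv(dataset.values, matrix_path, index_label="feature_id")
    sheet = dataset.sample_meta.reset_index()
    sheet.columns = ["sample_id", "group"]
    _write_tsv(sheet, sample_sheet_path, index=False)
    if feature_meta_path is not None:
        _write_tsv(dataset.feature_meta, feature_meta_path,
                   index_label="feature_id")


def read_fasta(path, alphabet: str = "DNA") -> dict[str, str]:
    """Read FASTA into an id -> sequence map, normalizing U/T to ``alphabet``."""
    if alphabet not in ("DNA", "RNA"):
        raise ParseError(f"alphabet must be 'DNA' or 'RNA', got {alphabet!r}")
    allowed = _DNA if alphabet == "DNA" else _RNA
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA record id {rec.id!r} in {path}")
        s = str(rec.seq).upper()
        s = s.replace("U", "T") if alphabet == "DNA" else s.replace("T", "U")
        extra = set(s) - allowed
        if extra:
            raise ParseError(
                f"record {rec.id!r}: characters {sorted(extra)} outside "
                f"{alphabet} alphabet"
            )
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


PREDICTION_COLUMNS = ["mirna_id", "transcript_id", "score", "best_site_type",
                      "n_sites"]


def read_predictions(path) -> pd.DataFrame:
    """Read a miRNA->target prediction table.

    Required columns: mirna_id, transcript_id.  Optional: score (defaults 0),
    best_site_type, n_sites.  The result is interchangeable with internally
    computed prediction tables.
    """
    table = pd.read_csv(path, sep="\t", dtype={"mirna_id": str,
                                               "transcript_id": str})
    for col in ("mirna_id", "transcript_id"):
        if col not in table.columns:
            raise ParseError(f"prediction table {path} missing column {col!r}")
    if "score" not in table.columns:
        table["score"] = 0.0
    for col in PREDICTION_COLUMNS:
        if col not in table.columns:
            table[col] = pd.NA
    table = table[PREDICTION_COLUMNS].copy()
    table["score"] = table["score"].astype(float)
    table["best_site_type"] = table["best_site_type"].astype("string")
    table["n_sites"] = table["n_sites"].astype("Int64")
    return table


def write_predictions(table: pd.DataFrame, path) -> None:
    _write_tsv(table, path, index=False)


@dataclass
class GOMapping:
    """Flat gene -> GO term annotations plus optional term metadata.

    No ontology-graph propagation is performed: annotations are taken as
    given (a documented limitation).
    """

    gene_terms: dict[str, set[str]]
    term_name: dict[str, str] = field(default_factory=dict)
    term_category: dict[str, str] = field(default_factory=dict)
    term_level: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.term_name:
            known = set(self.term_name)
            used = set().union(*self.gene_terms.values()) if self.gene_terms \
                else set()
            orphan = used - known
            if orphan:
                raise ParseError(
                    f"terms referenced by genes but absent from term table: "
                    f"{sorted(orphan)[:5]}"
                )

    def terms_for(self, gene: str) -> set[str]:
        return self.gene_terms.get(gene, set())


def read_go_mapping(mapping_path, term_table_path=None) -> GOMapping:
    """Read gene->term TSV (gene_id, term_id) and optional term table
    (term_id, name, category, level)."""
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    for col in ("gene_id", "term_id"):
        if col not in mapping.columns:
            raise ParseError(f"GO mapping {mapping_path} missing {col!r}")
    gene_terms: dict[str, set[str]] = {}
    for gene, term in zip(mapping["gene_id"], mapping["term_id"]):
        gene_terms.setdefault(gene, set()).add(term)
    term_name: dict[str, str] = {}
    term_category: dict[str, str] = {}
    term_level: dict[str, int] = {}
    if term_table_path is not None:
        terms = pd.read_csv(term_table_path, sep="\t", dtype=str)
        if "term_id" not in terms.columns:
            raise ParseError(f"term table {term_table_path} missing 'term_id'")
        for _, row in terms.iterrows():
            tid = row["term_id"]
            if "name" in terms.columns and pd.notna(row.get("name")):
                term_name[tid] = row["name"]
            if "category" in terms.columns and pd.notna(row.get("category")):
                term_category[tid] = row["category"]
            if "level" in terms.columns and pd.notna(row.get("level")):
                term_level[tid] = int(row["level"])
    return GOMapping(gene_terms, term_name, term_category, term_level)


def write_go_mapping(go: GOMapping, mapping_path, term_table_path=None) -> None:
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(go.gene_terms) for t in sorted(go.gene_terms[g])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gene_id", "term_id"]),
               mapping_path, index=False)
    if term_table_path is not None:
        terms = sorted(set(go.term_name) | set(go.term_category)
                       | set(go.term_level))
        table = pd.DataFrame({
            "term_id": terms,
            "name": [go.term_name.get(t, "") for t in terms],
            "category": [go.term_category.get(t, "") for t in terms],
            "level": [go.term_level.get(t, "") for t in terms],
        })
        _write_tsv(table, term_table_path, index=False)


def read_qpcr(path) -> pd.DataFrame:
    """Read a qPCR Ct table (feature_id, sample_id, replicate, Ct)."""
    table = pd.read_csv(path, sep="\t")
    for col in ("feature_id", "sample_id", "replicate", "Ct"):
        if col not in table.columns:
            raise ParseError(f"qPCR table {path} missing column {col!r}")
    return table


def write_qpcr(table: pd.DataFrame, path) -> None:
    _write_tsv(table, path, index=False)


def _write_tsv(df: pd.DataFrame, path, index=True, index_label=None) -> None:
    # repr-based shortest round-trip floats; LF endings regardless of platform
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, index_label=index_label,
              lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def write_tsv(df: pd.DataFrame, path, **kw) -> None:
    """Public canonical TSV writer used by every stage."""
    _write_tsv(df, path, **kw)
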