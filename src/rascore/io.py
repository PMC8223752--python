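"""TSV dialects: expression matrices, sample annotations, result tables.

Matrix TSV: first column ``gene_id``, remaining columns sample ids.
Annotation TSV: ``sample_id`` plus the standard annotation columns; empty
string means missing.  Values round-trip at full double precision
(pandas writes shortest-representation floats by default).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import ANNOTATION_COLUMNS, Compendium, ExpressionStudy


def write_matrix(values: pd.DataFrame, path) -> None:
    out = values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="gene_id", float_precision="round_trip"
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup[:5]}")
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="sample_id", keep_default_na=False, na_values=[]
    )
    if "das28" in df.columns:
        df["das28"] = pd.to_numeric(df["das28"], errors="coerce")
    for c in ANNOTATION_COLUMNS:
        if c not in df.columns and c != "das28":
            df[c] = ""
    return df


def read_study(matrix_path, annotation_path, name: str = "") -> ExpressionStudy:
    values = read_matrix(matrix_path)
    ann = read_annotations(annotation_path)
    missing = values.columns.difference(ann.index).tolist()
    if missing:
        raise ValueError(f"samples without annotations: {missing[:5]}")
    return ExpressionStudy(
        values=values, annotations=ann.loc[values.columns], name=name
    )


def write_study(study: ExpressionStudy, matrix_path, annotation_path) -> None:
    write_matrix(study.values, matrix_path)
    write_annotations(study.annotations, annotation_path)


def read_compendium(matrix_path, annotation_path, tissue: str = "") -> Compendium:
    study = read_study(matrix_path, annotation_path)
    return Compendium(
        values=study.values, annotations=study.annotations, tissue=tissue
    )


def write_ground_truth(truth, gene_path, sample_path) -> None:
    genes = truth.true_log2fc.copy()
    genes.columns = [f"true_log2fc_{c}" for c in genes.columns]
    genes["planted_up"] = genes.index.isin(truth.planted_up)
    genes["planted_down"] = genes.index.isin(truth.planted_down)
    genes["block"] = [truth.block_membership.get(g, -1) for g in genes.index]
    genes["is_y_gene"] = genes.index.isin(truth.y_genes)
    genes.index.name = "gene_id"
    genes.to_csv(gene_path, sep="\t")
    samples = truth.sample_table.copy()
    samples.index.name = "sample_id"
    samples.to_csv(sample_path, sep="\t")


def write_de_table(de, path) -> None:
    out = de.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_panel(panel, path) -> None:
    rows = []
    for g in panel.up_genes:
        rows.append({"gene_id": g, "direction": "up",
                     "validation_auc": panel.validation_auc.get(g)})
    for g in panel.down_genes:
        rows.append({"gene_id": g, "direction": "down",
                     "validation_auc": panel.validation_auc.get(g)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path):
    from .scoring import ScorePanel

    df = pd.read_csv(path, sep="\t")
    up = df.loc[df["direction"] == "up", "gene_id"].tolist()
    down = df.loc[df["direction"] == "down", "gene_id"].tolist()
    auc = dict(zip(df["gene_id"], df["validation_auc"]))
    return ScorePanel(up_genes=up, down_genes=down, validation_auc=auc)


def read_gmt(path) -> dict:
    """GMT gene-set collections: name <tab> description <tab> genes..."""
    collections = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        collections[parts[0]] = [g for g in parts[2:] if g]
    return collections
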