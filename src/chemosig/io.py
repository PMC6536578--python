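"""Readers and writers for the pipeline's plain-text formats.

* expression panel — TSV, first column ``gene_id``, remaining columns cell
  lines (genes x cell lines);
* drug response — CSV ``cell_line,log10_ic50``;
* IC50 table — CSV ``cell_line,ic50_um[,censor,method]``;
* plates — long CSV ``cell_line,concentration_um,replicate,fluorescence,
  well_type`` with well_type in {treated, control, blank};
* ground truth — TSV ``gene_id,class`` with class in {pos, neg, null};
* partition — CSV ``cell_line,cluster``;
* reports — JSON with sorted keys (byte-stable across reruns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterPartition
from .dose_response import DoseResponseDataset
from .exceptions import DataError
from .synthetic import PanelGroundTruth

FLOAT_FORMAT = "%.10g"


def write_panel_tsv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index_label="gene_id",
                 float_format=FLOAT_FORMAT)


def read_panel_tsv(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", index_col="gene_id")
    if panel.index.duplicated().any():
        raise DataError(f"{path}: duplicated gene_id values")
    if panel.columns.duplicated().any():
        raise DataError(f"{path}: duplicated cell-line columns")
    return panel


def write_response_csv(response: pd.Series, path) -> None:
    df = response.rename("log10_ic50").rename_axis("cell_line").reset_index()
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_response_csv(path, drug: str = "drug") -> pd.Series:
    df = pd.read_csv(path)
    if not {"cell_line", "log10_ic50"} <= set(df.columns):
        raise DataError(f"{path}: need columns cell_line, log10_ic50")
    if df["cell_line"].duplicated().any():
        raise DataError(f"{path}: duplicated cell lines")
    return pd.Series(df["log10_ic50"].to_numpy(float),
                     index=df["cell_line"].astype(str), name=drug)


def write_ic50_csv(table: pd.DataFrame, path) -> None:
    """``table``: index cell_line, columns ic50_um [, censor, method]."""
    table.rename_axis("cell_line").reset_index().to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_ic50_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"cell_line", "ic50_um"} <= set(df.columns):
        raise DataError(f"{path}: need columns cell_line, ic50_um")
    if df["cell_line"].duplicated().any():
        raise DataError(f"{path}: duplicated cell lines")
    return df.set_index("cell_line")


def write_plates_csv(datasets, path) -> None:
    """Write one or more :class:`DoseResponseDataset` as a long-format CSV."""
    if isinstance(datasets, DoseResponseDataset):
        datasets = [datasets]
    rows = []
    for ds in datasets:
        for i, dose in enumerate(ds.doses):
            for rep, f in enumerate(ds.treated[i], start=1):
                rows.append((ds.cell_line, dose, rep, f, "treated"))
        for rep, f in enumerate(ds.controls, start=1):
            rows.append((ds.cell_line, "", rep, f, "control"))
        for rep, f in enumerate(ds.blanks, start=1):
            rows.append((ds.cell_line, "", rep, f, "blank"))
    pd.DataFrame(rows, columns=["cell_line", "concentration_um", "replicate",
                                "fluorescence", "well_type"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_plates_csv(path) -> dict:
    """Read a long-format plate CSV into cell_line -> DoseResponseDataset."""
    df = pd.read_csv(path)
    need = {"cell_line", "concentration_um", "replicate", "fluorescence",
            "well_type"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: need columns {sorted(need)}")
    out = {}
    for cell, grp in df.groupby("cell_line", sort=False):
        treated = grp[grp.well_type == "treated"]
        wide = treated.pivot(index="concentration_um", columns="replicate",
                             values="fluorescence").sort_index()
        out[str(cell)] = DoseResponseDataset(
            cell_line=str(cell), doses=wide.index.to_numpy(float),
            treated=wide.to_numpy(float),
            controls=grp.loc[grp.well_type == "control",
                             "fluorescence"].to_numpy(float),
            blanks=grp.loc[grp.well_type == "blank",
                           "fluorescence"].to_numpy(float),
        )
    if not out:
        raise DataError(f"{path}: no plate rows found")
    return out


def write_ground_truth_tsv(truth: PanelGroundTruth, gene_ids, path) -> None:
    pd.DataFrame({"gene_id": list(gene_ids),
                  "class": [truth.gene_class(g) for g in gene_ids]}
                 ).to_csv(path, sep="\t", index=False)


def read_ground_truth_tsv(path) -> pd.Series:
    # keep_default_na: the literal class label "null" must stay a string
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if not {"gene_id", "class"} <= set(df.columns):
        raise DataError(f"{path}: need columns gene_id, class")
    return df.set_index("gene_id")["class"]


def write_partition_csv(partition: ClusterPartition, path) -> None:
    partition.assignment.rename_axis("cell_line").reset_index().to_csv(
        path, index=False)


def read_partition_csv(path) -> ClusterPartition:
    df = pd.read_csv(path)
    if not {"cell_line", "cluster"} <= set(df.columns):
        raise DataError(f"{path}: need columns cell_line, cluster")
    assignment = pd.Series(df["cluster"].astype(int).to_numpy(),
                           index=df["cell_line"].astype(str), name="cluster")
    ids = sorted(assignment.unique())
    if ids != list(range(1, len(ids) + 1)):
        raise DataError(f"{path}: cluster ids must be 1..k without gaps")
    sizes = [int((assignment == c).sum()) for c in ids]
    return ClusterPartition(k=len(ids), assignment=assignment, sizes=sizes)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
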