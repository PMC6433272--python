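"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular formats go through pandas; gene sets use the GMT convention
(tab-separated: term, description, member genes). Every writer can attach a
provenance JSON sidecar recording how the file was produced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def write_provenance(path: str | Path, payload: Mapping) -> Path:
    """Write a ``<path>.prov.json`` sidecar describing how ``path`` was made."""
    side = Path(str(path) + ".prov.json")
    with open(side, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return side


# ---------------------------------------------------------------- chromatogram

def write_chromatogram_tsv(path: str | Path, time: np.ndarray, signal: np.ndarray) -> None:
    pd.DataFrame({"time": time, "signal": signal}).to_csv(path, sep="\t", index=False)


def read_chromatogram_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if not {"time", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: chromatogram TSV needs 'time' and 'signal' columns")
    return df["time"].to_numpy(float), df["signal"].to_numpy(float)


# ----------------------------------------------------------------- cell grades

GRADE_COLUMNS = ["grade0", "grade1", "grade2", "grade3"]


def write_cell_grades_tsv(path: str | Path, grades: pd.DataFrame) -> None:
    grades.to_csv(path, sep="\t", index=False)


def read_cell_grades_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "field", *GRADE_COLUMNS}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: cell-grade TSV needs columns {sorted(need)}")
    return df


# --------------------------------------------------------------------- cohort

def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -------------------------------------------------------------- array matrices

def write_matrix_tsv(path: str | Path, mat: pd.DataFrame) -> None:
    mat.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_manifest_tsv(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"probe_id", "chromosome", "position", "gene", "region"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: manifest TSV needs columns {sorted(need)}")
    return df


def manifest_to_bed(manifest: pd.DataFrame) -> pd.DataFrame:
    """Export probe CpG coordinates as 0-based half-open BED intervals of width 2.

    The manifest stores the 1-based coordinate of the CpG cytosine; the BED
    interval covers the CpG dinucleotide.
    """
    return pd.DataFrame(
        {
            "chrom": manifest["chromosome"],
            "chromStart": manifest["position"].astype(int) - 1,
            "chromEnd": manifest["position"].astype(int) + 1,
            "name": manifest["probe_id"],
        }
    )


def write_bed(path: str | Path, bed: pd.DataFrame) -> None:
    bed.to_csv(path, sep="\t", index=False, header=False)


# ------------------------------------------------------------------ orthologs

def write_ortholog_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"human_gene", "homolog", "ortholog", "dog_gene"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: ortholog TSV needs columns {sorted(need)}")
    df["dog_gene"] = df["dog_gene"].fillna("")
    return df


# ------------------------------------------------------------------------ GMT

def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line with fewer than 3 fields: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
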