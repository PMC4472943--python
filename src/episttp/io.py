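"""Readers/writers for expression matrices, sample designs, chase time
courses, FASTA and result reports.

The core interchange format is plain text: a tab-delimited expression
matrix (first column ``probe_id``, remaining columns sample intensities on
the linear scale) paired with a tab-delimited design table (one row per
sample). Missing intensities are encoded as ``NA`` and propagate as NaN.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GENOTYPES, TREATMENTS

DESIGN_COLUMNS = ["sample_id", "genotype", "treatment", "timepoint", "replicate"]
CHASE_COLUMNS = ["series_id", "genotype", "gene", "time_h", "value"]

_FLOAT_FMT = "%.12g"

__all__ = [
    "DESIGN_COLUMNS",
    "CHASE_COLUMNS",
    "FormatError",
    "DesignMismatchError",
    "validate_design",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_chase_csv",
    "write_chase_csv",
    "write_fasta",
    "write_report",
]


class FormatError(ValueError):
    """Malformed input table (duplicates, non-numeric values, bad columns)."""


class DesignMismatchError(ValueError):
    """Matrix columns and design sample_ids disagree."""


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design table; returns it unchanged."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design table missing columns: {missing}")
    dup = design["sample_id"][design["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample_id(s): {sorted(dup.unique())}")
    bad_g = set(design["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise FormatError(f"unknown genotype(s): {sorted(bad_g)}")
    bad_t = set(design["treatment"]) - set(TREATMENTS)
    if bad_t:
        raise FormatError(f"unknown treatment(s): {sorted(bad_t)}")
    combos = design[["genotype", "treatment", "timepoint", "replicate"]]
    if combos.duplicated().any():
        raise FormatError("duplicate (genotype, treatment, timepoint, replicate) rows")
    return design


def read_expression_matrix(
    matrix_path, design_path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate an expression matrix and its design.

    Returns the matrix with columns ordered as in the design, indexed by
    probe_id, and the validated design table.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if raw.columns[0] != "probe_id":
        raise FormatError("first column of the matrix must be 'probe_id'")
    probe_ids = raw["probe_id"]
    dup = probe_ids[probe_ids.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate probe_id(s): {sorted(dup.unique())}")
    values = raw.drop(columns=["probe_id"])
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric intensity {values.iat[r, c]!r} at probe "
            f"{probe_ids.iloc[r]!r}, sample {values.columns[c]!r}"
        )
    if (numeric < 0).to_numpy().any():
        raise FormatError("negative intensities are not allowed")
    matrix = numeric.set_axis(probe_ids.rename("probe_id"), axis=0)

    design = validate_design(pd.read_csv(design_path, sep="\t"))
    mat_samples = set(matrix.columns)
    des_samples = set(design["sample_id"])
    only_mat = sorted(mat_samples - des_samples)
    only_des = sorted(des_samples - mat_samples)
    if only_mat or only_des:
        raise DesignMismatchError(
            f"samples only in matrix: {only_mat}; only in design: {only_des}"
        )
    return matrix[design["sample_id"].tolist()], design


def write_expression_matrix(matrix: pd.DataFrame, design: pd.DataFrame,
                            matrix_path, design_path) -> None:
    """Write the matrix/design pair in the standard TSV format."""
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")
    design[DESIGN_COLUMNS].to_csv(design_path, sep="\t", index=False)


def read_chase_csv(path) -> pd.DataFrame:
    """Read a decay-chase table (series_id, genotype, gene, time_h, value)."""
    df = pd.read_csv(path)
    missing = [c for c in CHASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"chase table missing columns: {missing}")
    return df


def write_chase_csv(series_list, path) -> None:
    """Write DecaySeries objects as one flat chase CSV."""
    rows = []
    for i, s in enumerate(series_list):
        for t, v in zip(s.timepoints_h, s.values):
            rows.append(
                {
                    "series_id": f"{s.gene}_{s.genotype}_{i}",
                    "genotype": s.genotype,
                    "gene": s.gene,
                    "time_h": t,
                    "value": v,
                }
            )
    pd.DataFrame(rows, columns=CHASE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write id -> sequence mappings as FASTA."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_report(tables: dict[str, pd.DataFrame], summary: dict, out_dir) -> list[Path]:
    """Write one CSV per result table plus a JSON run summary.

    Column order is taken from each DataFrame as given; reruns on identical
    inputs produce byte-identical files. Empty tables yield header-only
    CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
    spath = out / "run_summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    written.append(spath)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
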