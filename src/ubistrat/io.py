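"""Readers and writers for the package's tab-separated table formats.

All tables are UTF-8 TSV with a header row and "NA" as the missing-value
sentinel.  Cohort tables carry cBioPortal-style discrete copy-number levels
(−2 deep loss … 2 high-level amplification); expression matrices are
genes-as-rows with a leading ``gene_id`` column; reference perturbation
profiles are a wide rank matrix (one ``drug::cell_line`` column per profile
holding each gene's 1-based rank, 1 = most up-regulated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .errors import DataValidationError
from .simulate import PerturbationEntry, ReferenceSet, SimConfig
from .stratify import CN_LEVELS

PathLike = Union[str, Path]

COHORT_CN_COLUMNS = ("cn_fzr1", "cn_usp10", "cn_usp13", "cn_skp2")
COHORT_REQUIRED = ("patient_id", "cn_fzr1", "cn_usp10", "er", "pr", "her2")
NA = "NA"


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Read and validate a cohort TSV ("NA" → missing)."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataValidationError(f"malformed cohort file {path}: {exc}") from exc
    for col in COHORT_REQUIRED:
        if col not in df.columns:
            raise DataValidationError(f"cohort file lacks required column {col!r}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DataValidationError(f"duplicate patient_id {dup!r}")
    for col in COHORT_CN_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & ~vals.isin(CN_LEVELS)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"invalid copy-number value {vals.iloc[row]!r} in column {col!r}, "
                f"row {row + 2} of {path}"  # +2: header + 1-based
            )
        df[col] = vals.astype("Int64")
    if "os_time" in df.columns and (df["os_time"].dropna() < 0).any():
        raise DataValidationError("negative os_time")
    if "positive_nodes" in df.columns:
        nodes = df["positive_nodes"].dropna()
        if (nodes < 0).any() or (nodes != nodes.astype(int)).any():
            raise DataValidationError("positive_nodes must be nonnegative integers")
        df["positive_nodes"] = df["positive_nodes"].astype("Int64")
    return df


def write_cohort(cohort: pd.DataFrame, path: PathLike) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read a genes × samples expression TSV (first column ``gene_id``)."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataValidationError(f"malformed expression file {path}: {exc}") from exc
    if df.columns[0] != "gene_id":
        raise DataValidationError("first column of an expression matrix must be gene_id")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataValidationError(f"duplicated gene id {dup!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[np.flatnonzero(bad)[0]]
            raise DataValidationError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any() or not np.all(np.isfinite(df.to_numpy(float))):
        raise DataValidationError("expression matrix contains missing/non-finite values")
    return df


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA)


def read_reference_profiles(path: PathLike) -> ReferenceSet:
    """Read a wide rank-matrix TSV into a reference perturbation set."""
    df = read_expression(path)  # same shape/validation rules
    n = df.shape[0]
    entries = []
    for col in df.columns:
        if "::" in col:
            drug, cell_line = col.split("::", 1)
        else:
            drug, cell_line = col, ""
        ranks = df[col].to_numpy(float)
        if sorted(ranks) != list(range(1, n + 1)):
            raise DataValidationError(
                f"column {col!r} is not a 1..{n} rank permutation"
            )
        order = np.argsort(ranks)
        entries.append(
            PerturbationEntry(drug, cell_line, tuple(df.index[order]))
        )
    refs = ReferenceSet(tuple(entries), tuple(df.index))
    refs.validate()
    return refs


def write_reference_profiles(refs: ReferenceSet, path: PathLike) -> None:
    data = {}
    for e in refs.entries:
        rank = {g: i + 1 for i, g in enumerate(e.ranked_genes)}
        name = f"{e.drug}::{e.cell_line}" if e.cell_line else e.drug
        data[name] = [rank[g] for g in refs.universe]
    pd.DataFrame(data, index=pd.Index(refs.universe, name="gene_id")).to_csv(
        path, sep="\t"
    )


def read_ic50(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                         float_precision="round_trip")
    for col in ("drug", "cell_line", "ln_ic50"):
        if col not in df.columns:
            raise DataValidationError(f"IC50 table lacks column {col!r}")
    if not np.all(np.isfinite(df["ln_ic50"].to_numpy(float))):
        raise DataValidationError("ln_ic50 values must be finite")
    return df


def write_ic50(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_sim_config(path: PathLike) -> SimConfig:
    """Load a SimConfig from a YAML mapping of field name → value."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataValidationError("simulation config must be a YAML mapping")
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise DataValidationError(f"unknown config fields: {sorted(unknown)}")
    for key in ("subtype_proportions", "nb_coefficients"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg
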