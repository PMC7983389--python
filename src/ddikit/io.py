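"""Delimited-table input/output.

All stage tables are plain comma-separated UTF-8 files with a header
row. The case table stores additional diagnoses as one
semicolon-joined column (the canonical on-disk form):

* cases.csv    case_id, region_id, year, main_dx, addl_dx
* regions.csv  region_id, population, travel_time_min
* mapping.csv  orpha_code, icd10_code, group_label
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import SchemaError

CASES_FILE = "cases.csv"
REGIONS_FILE = "regions.csv"
MAPPING_FILE = "mapping.csv"
TRUTH_FILE = "truth.json"
DDI_FILE = "region_ddi.csv"


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def read_cases(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"main_dx": str, "addl_dx": str},
                     keep_default_na=False)
    _require(df, ["case_id", "region_id", "year", "main_dx", "addl_dx"], "cases")
    return df


def read_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["region_id", "population", "travel_time_min"], "regions")
    return df


def read_mapping(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require(df, ["orpha_code", "icd10_code", "group_label"], "mapping")
    return df


def read_ddi(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["region_id", "n_cases", "D", "H"], "region DDI")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)


def write_dataset(ds, outdir) -> dict:
    """Write a SyntheticDataset's tables and truth file; return paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "cases": os.path.join(outdir, CASES_FILE),
        "regions": os.path.join(outdir, REGIONS_FILE),
        "mapping": os.path.join(outdir, MAPPING_FILE),
        "truth": os.path.join(outdir, TRUTH_FILE),
    }
    ds.cases.to_csv(paths["cases"], index=False)
    ds.regions.to_csv(paths["regions"], index=False)
    ds.mapping.to_csv(paths["mapping"], index=False)
    ds.truth.to_json(paths["truth"])
    return paths
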