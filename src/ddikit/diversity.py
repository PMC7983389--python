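"""Diagnostic diversity index (DDI) per residential region.

The DDI of a set of hospitalization cases is the Shannon entropy (in
nats) of the pooled diagnosis-code frequency distribution,

    H = -sum_i p_i ln p_i,    p_i = count_i / sum(counts),

where the counts pool the main and all additional discharge diagnoses
of the region's cases. Within a single case a repeated code is counted
once (repeated coding of one code during one stay is an artifact of the
abstracting process, not diagnostic information); across cases each
occurrence counts. Main and additional diagnoses are weighted equally.

Entropy of an empty pool is undefined and returned as NaN, never 0: a
region without cases has no diversity, low or high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codes import normalize_icd_code
from .errors import (
    EmptyInputError,
    InvalidCountError,
    ReferentialIntegrityError,
)

CASE_COLUMNS = ["case_id", "region_id", "year", "main_dx", "addl_dx"]
REGION_COLUMNS = ["region_id", "population", "travel_time_min"]

ADDL_SEP = ";"


@dataclass(frozen=True)
class DiagnosisCountSummary:
    """Median and interquartile range of per-case coded-diagnosis counts."""

    median: float
    q1: float
    q3: float
    n_cases: int


def shannon_index(code_counts) -> float:
    """Shannon entropy, in nats, of a code-count table.

    Parameters
    ----------
    code_counts
        Mapping code -> positive count, or a pandas Series / array of
        positive counts. An empty table yields NaN (undefined).

    Raises
    ------
    InvalidCountError
        If any count is zero or negative.
    """
    if isinstance(code_counts, Mapping):
        counts = np.asarray(list(code_counts.values()), dtype=float)
    else:
        counts = np.asarray(code_counts, dtype=float)
    if counts.size == 0:
        return float("nan")
    if np.any(counts <= 0):
        raise InvalidCountError("code counts must be strictly positive")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def explode_codes(cases: pd.DataFrame, dedup_within_case: bool = True) -> pd.DataFrame:
    """Long-format (case_id, region_id, code) table of normalized codes.

    Normalization is applied once per distinct raw spelling, so the cost
    is bounded by the vocabulary size rather than the token count.
    """
    main = cases[["case_id", "region_id", "main_dx"]].rename(columns={"main_dx": "code"})
    addl = cases.loc[cases["addl_dx"].astype(str).str.len() > 0,
                     ["case_id", "region_id", "addl_dx"]].copy()
    if len(addl):
        addl["code"] = addl["addl_dx"].astype(str).str.split(ADDL_SEP)
        addl = addl[["case_id", "region_id", "code"]].explode("code", ignore_index=True)
        long = pd.concat([main, addl], ignore_index=True)
    else:
        long = main
    uniq = pd.unique(long["code"])
    norm_map = {u: normalize_icd_code(u) for u in uniq}
    long["code"] = long["code"].map(norm_map)
    if dedup_within_case:
        long = long.drop_duplicates(["case_id", "code"])
    return long


def tally_region_codes(cases: pd.DataFrame, region_id) -> pd.Series:
    """Pooled code counts for one region.

    Unknown region ids yield an empty table (a region may simply have no
    cases); malformed codes raise.
    """
    sub = cases[cases["region_id"] == region_id]
    if sub.empty:
        return pd.Series(dtype=int, name="count")
    long = explode_codes(sub)
    counts = long["code"].value_counts().sort_index()
    counts.name = "count"
    return counts


def region_ddi_table(
    cases: pd.DataFrame,
    regions: pd.DataFrame,
    min_cases: int = 1,
    method: str = "pooled",
) -> pd.DataFrame:
    """Per-region diversity table: region_id, n_cases, D, H.

    ``method="pooled"`` (default) computes H on the pooled code
    distribution of all the region's cases. ``method="mean_case"`` is a
    sensitivity alternative that averages per-case entropies instead;
    it is near-degenerate (a case's entropy is ~ln of its code count)
    and kept only for comparison.

    Regions with fewer than ``min_cases`` cases are excluded. Cases
    referencing region ids absent from ``regions`` raise.
    """
    known = set(regions["region_id"])
    orphans = set(cases["region_id"]) - known
    if orphans:
        raise ReferentialIntegrityError(orphans)

    long = explode_codes(cases)
    n_cases = cases.groupby("region_id", sort=True).size()

    if method == "pooled":
        counts = long.groupby(["region_id", "code"], sort=False, observed=True).size()
        grp = counts.groupby(level="region_id", sort=True)
        total = grp.sum()
        # H = ln(total) - sum(c ln c)/total, vectorized over all regions
        clogc = (counts * np.log(counts)).groupby(level="region_id", sort=True).sum()
        H = np.log(total) - clogc / total
        D = grp.size()
        out = pd.DataFrame({"n_cases": n_cases, "D": D, "H": H}).reset_index()
    elif method == "mean_case":
        per_case = long.groupby(["region_id", "case_id"], sort=False).size()
        case_h = np.log(per_case.astype(float))  # codes within a case are distinct
        H = case_h.groupby(level="region_id").mean()
        D = long.groupby("region_id")["code"].nunique()
        out = pd.DataFrame({"n_cases": n_cases, "D": D, "H": H}).reset_index()
    else:
        raise ValueError(f"unknown method {method!r}")

    out = out[out["n_cases"] >= min_cases].reset_index(drop=True)
    out["n_cases"] = out["n_cases"].astype(int)
    out["D"] = out["D"].astype(int)
    return out


def diagnosis_count_summary(cases: pd.DataFrame) -> DiagnosisCountSummary:
    """Median and IQR (linear-interpolation percentiles) of codes per case."""
    if cases is None or len(cases) == 0:
        raise EmptyInputError("no cases supplied")
    addl = cases["addl_dx"].astype(str)
    n_addl = addl.str.count(ADDL_SEP) + 1
    n_addl[addl.str.len() == 0] = 0
    total = (1 + n_addl).to_numpy(dtype=float)
    q1, med, q3 = np.percentile(total, [25, 50, 75])
    return DiagnosisCountSummary(float(med), float(q1), float(q3), int(len(total)))


def case_code_lists(cases: pd.DataFrame) -> Iterable[tuple]:
    """Yield (case_id, [normalized codes]) pairs, deduplicated within case."""
    long = explode_codes(cases)
    for cid, grp in long.groupby("case_id", sort=False):
        yield cid, list(grp["code"])
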