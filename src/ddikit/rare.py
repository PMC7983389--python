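"""ORPHAcode <-> ICD-10 cross-referencing and rare-disease case flagging.

Orphanet publishes a many-to-many mapping between rare-disease
identifiers (ORPHAcodes) and ICD-10 codes, with each disease assigned
to a disease group. A hospitalization case is flagged rare-disease
associated when any of its coded diagnoses (main or additional) matches
a mapped ICD-10 code after normalization. Matching is exact on the full
normalized code; a 3-character stem prefix mode exists for sensitivity
analysis only.

Group attribution is marginal: a case hitting several groups counts
once in each (group analyses are per-group, not partitions), and a case
hitting one group through several codes still counts once in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Set, Tuple

import numpy as np
import pandas as pd

from .codes import normalize_icd_code
from .diversity import explode_codes
from .errors import EmptyInputError, ReferentialIntegrityError, SchemaError

logger = logging.getLogger(__name__)

MAPPING_COLUMNS = ["orpha_code", "icd10_code", "group_label"]


@dataclass
class OrphaMapping:
    """Normalized, indexed rare-disease cross-referencing table."""

    table: pd.DataFrame  # columns orpha_code, icd10_code (normalized), group_label
    index: Dict[str, FrozenSet[Tuple[str, str]]] = field(default_factory=dict)
    duplicates_collapsed: int = 0

    @property
    def n_orpha(self) -> int:
        return self.table["orpha_code"].nunique() if len(self.table) else 0

    @property
    def n_icd(self) -> int:
        return self.table["icd10_code"].nunique() if len(self.table) else 0

    @property
    def n_groups(self) -> int:
        return self.table["group_label"].nunique() if len(self.table) else 0

    def groups_for(self, code: str) -> Set[str]:
        return {g for _, g in self.index.get(code, frozenset())}

    def summary(self) -> dict:
        return {
            "n_rows": int(len(self.table)),
            "n_orpha_codes": int(self.n_orpha),
            "n_icd_codes": int(self.n_icd),
            "n_groups": int(self.n_groups),
            "duplicate_rows_collapsed": int(self.duplicates_collapsed),
        }


def load_mapping(table: pd.DataFrame) -> OrphaMapping:
    """Normalize, deduplicate and index a cross-referencing table.

    Raises SchemaError on missing columns and MalformedCodeError (with
    the offending row number) on unnormalizable ICD codes.
    """
    missing = [c for c in MAPPING_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"mapping table missing columns: {missing}")
    tab = table[MAPPING_COLUMNS].copy()
    normalized = []
    for rowno, raw in enumerate(tab["icd10_code"].astype(str)):
        try:
            normalized.append(normalize_icd_code(raw))
        except Exception as exc:
            raise type(exc)(f"row {rowno}: {exc}") from exc
    tab["icd10_code"] = normalized
    tab["orpha_code"] = tab["orpha_code"].astype(str)
    tab["group_label"] = tab["group_label"].astype(str)
    before = len(tab)
    tab = tab.drop_duplicates(MAPPING_COLUMNS, ignore_index=True)
    dropped = before - len(tab)
    if dropped:
        logger.info("collapsed %d duplicate mapping rows", dropped)
    index: Dict[str, set] = {}
    for orpha, icd, grp in tab.itertuples(index=False):
        index.setdefault(icd, set()).add((orpha, grp))
    mapping = OrphaMapping(
        table=tab,
        index={k: frozenset(v) for k, v in index.items()},
        duplicates_collapsed=dropped,
    )
    logger.info("mapping loaded: %s", mapping.summary())
    return mapping


def flag_cases(
    cases: pd.DataFrame,
    mapping: OrphaMapping,
    prefix_match: bool = False,
) -> pd.DataFrame:
    """Per-case rare-disease flags.

    Returns a DataFrame (case_id, is_rd, matched_codes, groups) where
    matched_codes / groups are frozensets; is_rd is True iff
    matched_codes is nonempty. With ``prefix_match`` a case code also
    matches on its 3-character stem (sensitivity mode, off by default).
    """
    long = explode_codes(cases)
    keys = set(mapping.index)
    hit = long["code"].isin(keys)
    if prefix_match:
        stems = long["code"].str[:3]
        hit = hit | stems.isin(keys)
    matched = long[hit].copy()
    if prefix_match:
        matched["match_key"] = np.where(
            matched["code"].isin(keys), matched["code"], matched["code"].str[:3]
        )
    else:
        matched["match_key"] = matched["code"]

    out = cases[["case_id"]].copy()
    if len(matched):
        per_case_codes = matched.groupby("case_id", sort=False)["code"].agg(frozenset)
        per_case_groups = (
            matched.assign(groups=matched["match_key"].map(mapping.groups_for))
            .groupby("case_id", sort=False)["groups"]
            .agg(lambda sets: frozenset().union(*sets))
        )
    else:
        per_case_codes = pd.Series(dtype=object)
        per_case_groups = pd.Series(dtype=object)
    out["matched_codes"] = out["case_id"].map(per_case_codes)
    out["groups"] = out["case_id"].map(per_case_groups)
    empty = frozenset()
    out["matched_codes"] = out["matched_codes"].apply(lambda v: v if isinstance(v, frozenset) else empty)
    out["groups"] = out["groups"].apply(lambda v: v if isinstance(v, frozenset) else empty)
    out["is_rd"] = out["matched_codes"].apply(bool)
    return out[["case_id", "is_rd", "matched_codes", "groups"]]


def rd_proportion(flags: pd.DataFrame) -> Tuple[float, int]:
    """Fraction of cases flagged, and the whole-number percentage.

    The percentage rounds half away from zero, the convention used when
    quoting headline shares like "27% of inpatient cases".
    """
    if flags is None or len(flags) == 0:
        raise EmptyInputError("no flags supplied")
    num = int(flags["is_rd"].sum())
    den = int(len(flags))
    frac = num / den
    percent = int(np.floor(100.0 * frac + 0.5))  # half away from zero (frac >= 0)
    return frac, percent


def group_region_counts(
    flags: pd.DataFrame,
    cases: pd.DataFrame,
    regions: pd.DataFrame,
    mapping: OrphaMapping,
) -> pd.DataFrame:
    """Distinct-case counts per (region, disease group), zeros explicit.

    Each case contributes at most 1 to each group it hits. The output
    is the full cartesian grid region x group with columns
    (region_id, group_label, observed, population, travel_time_min).
    """
    known = set(regions["region_id"])
    orphans = set(cases["region_id"]) - known
    if orphans:
        raise ReferentialIntegrityError(orphans)
    if not set(flags["case_id"]) <= set(cases["case_id"]):
        raise ReferentialIntegrityError(
            set(flags["case_id"]) - set(cases["case_id"]), what="case_id"
        )

    groups = sorted(mapping.table["group_label"].unique()) if len(mapping.table) else []
    case_region = cases.set_index("case_id")["region_id"]
    hits = flags.loc[flags["is_rd"], ["case_id", "groups"]].copy()
    if len(hits):
        hits = hits.explode("groups").rename(columns={"groups": "group_label"})
        hits["region_id"] = hits["case_id"].map(case_region)
        counts = (
            hits.groupby(["region_id", "group_label"], sort=False)["case_id"]
            .nunique()
            .rename("observed")
        )
    else:
        counts = pd.Series(dtype=int, name="observed")

    grid = pd.MultiIndex.from_product(
        [regions["region_id"], groups], names=["region_id", "group_label"]
    )
    out = counts.reindex(grid, fill_value=0).reset_index()
    out = out.merge(
        regions[["region_id", "population", "travel_time_min"]], on="region_id", how="left"
    )
    out["observed"] = out["observed"].astype(int)
    return out
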