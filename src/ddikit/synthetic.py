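"""Synthetic hospitalization-record generator.

The national discharge database this pipeline targets is
access-restricted, so every downstream stage is exercised against
synthetic data with the same statistical skeleton:

* ~705 residential regions with log-normal populations and travel
  times to the nearest tertiary hospital drawn uniformly over a range;
* per-region inpatient case counts Poisson in population;
* per-case total diagnosis counts 1 + geometric (capped at 51 codes:
  one main plus up to 50 additional), targeting a median of 3 codes
  with interquartile range (1, 5);
* per-region pooled code frequencies following a truncated-geometric
  law whose single shape parameter is calibrated by bisection so the
  pooled Shannon entropy tracks a prescribed log-logistic decay in
  travel time;
* rare-disease-associated codes drawn from a reserved slice of the
  vocabulary and injected at group-specific rates
  lambda_g0 * exp(beta_g * t) per 10,000 persons, by replacing one
  code of a selected case so the diagnosis-count law is untouched.

Because injected rare-disease codes are a (small) second mixture
component of the pooled code distribution, the background entropy
target is adjusted with the exact disjoint-support mixture identity
H_mix = (1-f) H_bg + f H_rd + H_binary(f) before calibration, keeping
the pooled entropy on the prescribed curve.

The generating truth (per-region target entropy, per-region per-group
expected counts) is stored alongside the data for parameter-recovery
tests and is never consumed by analysis stages.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .decay import loglogistic_value
from .errors import ConfigurationError, InfeasibleTargetError

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

_ENTROPY_TOL = 1e-6  # nats; calibration stopping rule


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG substream keyed by stage name."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# --------------------------------------------------------------------------
# truncated-geometric code-frequency family

def truncated_geometric_probs(q: float, K: int) -> np.ndarray:
    """p_i proportional to q (1-q)^(i-1), i = 1..K, renormalized."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    logw = np.log1p(-q) * np.arange(K)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def calibrate_code_distribution(target_H: float, K: int) -> float:
    """Shape parameter q whose truncated-geometric entropy hits target_H.

    Entropy decreases monotonically in q from ln K (q -> 0, uniform) to
    0 (q -> 1, degenerate), so plain bisection converges; the returned
    q reproduces target_H within 1e-6 nats.

    Raises
    ------
    InfeasibleTargetError
        If target_H <= 0 or target_H >= ln K (the upper bound is
        attained only in the uniform limit and is excluded).
    """
    if K < 2:
        raise InfeasibleTargetError("need a vocabulary of at least 2 codes")
    hmax = np.log(K)
    if not 0 < target_H < hmax:
        raise InfeasibleTargetError(
            f"target entropy {target_H} outside attainable range (0, ln {K} = {hmax:.6f})"
        )
    lo, hi = 1e-12, 1.0 - 1e-12  # H(lo) ~ ln K, H(hi) ~ 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        h = _entropy(truncated_geometric_probs(mid, K))
        if abs(h - target_H) < _ENTROPY_TOL:
            return mid
        if h > target_H:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# vocabulary

def build_vocabulary(K: int) -> np.ndarray:
    """Deterministic array of K distinct ICD-10-like codes (A000, A001, ...)."""
    if K > 26000:
        raise ConfigurationError("vocabulary limited to 26,000 codes")
    codes = np.empty(K, dtype="U4")
    for i in range(K):
        letter = _LETTERS[i // 1000]
        rem = i % 1000
        codes[i] = f"{letter}{rem // 10:02d}{rem % 10}"
    return codes


def split_vocabulary(config: ScenarioConfig) -> Tuple[np.ndarray, np.ndarray]:
    """(background codes, rare-disease codes), a seeded disjoint split.

    Rare-disease codes are excluded from background coding so that
    per-group counts reflect the injection rates alone.
    """
    vocab = build_vocabulary(config.vocab_size)
    rng = substream(config.seed, "vocabulary")
    perm = rng.permutation(config.vocab_size)
    n_rd = config.n_rd_codes
    rd = vocab[perm[:n_rd]]
    background = vocab[perm[n_rd:]]
    return background, rd


def group_code_sets(config: ScenarioConfig) -> List[np.ndarray]:
    """Round-robin assignment of rare-disease codes to disease groups."""
    _, rd = split_vocabulary(config)
    return [rd[g :: config.n_groups] for g in range(config.n_groups)]


def group_labels(config: ScenarioConfig) -> List[str]:
    return [f"group_{g + 1:02d}" for g in range(config.n_groups)]


# --------------------------------------------------------------------------
# truth container

@dataclass
class SyntheticTruth:
    """Generating ground truth, for recovery tests only."""

    h_target: pd.Series              # region_id -> target pooled entropy (nats)
    expected_rd: pd.DataFrame        # region_id x group_label expected counts
    params: dict                     # flat generating parameters

    def to_json(self, path) -> None:
        payload = {
            "params": self.params,
            "h_target": {str(k): float(v) for k, v in self.h_target.items()},
            "expected_rd": {
                str(r): {g: float(v) for g, v in row.items()}
                for r, row in self.expected_rd.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        h = pd.Series(payload["h_target"]).astype(float)
        h.index = h.index.astype(int)
        exp = pd.DataFrame(payload["expected_rd"]).T.astype(float)
        exp.index = exp.index.astype(int)
        return cls(h_target=h.sort_index(), expected_rd=exp.sort_index(),
                   params=payload["params"])


@dataclass
class SyntheticDataset:
    """Generated tables plus the generating truth."""

    cases: pd.DataFrame
    regions: pd.DataFrame
    mapping: pd.DataFrame
    truth: SyntheticTruth


# --------------------------------------------------------------------------
# generation stages

def generate_regions(config: ScenarioConfig) -> pd.DataFrame:
    """Region table: region_id, population, travel_time_min.

    Travel times uniform over the configured range; populations are
    positive integers from the log-normal law (median, sigma).
    """
    config.validate()
    rng = substream(config.seed, "regions")
    n = config.n_regions
    lo, hi = config.travel_time_range
    t = rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(lo))
    pop = rng.lognormal(np.log(config.pop_median), config.pop_sigma, n)
    pop = np.maximum(1, np.round(pop)).astype(np.int64)
    return pd.DataFrame({
        "region_id": np.arange(1, n + 1, dtype=np.int64),
        "population": pop,
        "travel_time_min": t,
    })


def _expected_rd_matrix(regions: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    """Expected injected counts, regions x groups: pop/1e4 * lambda0 * exp(beta t)."""
    t = regions["travel_time_min"].to_numpy()[:, None]
    pop = regions["population"].to_numpy(dtype=float)[:, None]
    lam0 = config.group_baseline_rates[None, :]
    beta = config.group_slopes[None, :]
    return pop / 1e4 * lam0 * np.exp(beta * t)


def _mean_codes_per_case(p: float) -> float:
    """E[min(1 + geometric failures, 51)] = (1 - (1-p)^51) / p."""
    return (1.0 - (1.0 - p) ** 51) / p


def _background_entropy_target(
    h_target: float, f: float, h_rd: float
) -> float:
    """Invert the disjoint-support mixture entropy identity.

    H_mix = (1-f) H_bg + f H_rd + H_b(f) with f the expected fraction
    of code slots carrying an injected rare-disease code.
    """
    if f <= 0:
        return h_target
    hb = -f * np.log(f) - (1 - f) * np.log1p(-f)
    return (h_target - f * h_rd - hb) / (1.0 - f)


def generate_cases(
    regions: pd.DataFrame, config: ScenarioConfig
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Case table and generating truth for a region table.

    Per region the case count is Poisson(population x rate); each case
    has 1 + geometric(diag_count_p) codes capped at 51, drawn from the
    region's calibrated truncated-geometric background distribution;
    rare-disease codes are then injected by replacing one code of
    Poisson(lambda_g0 exp(beta_g t) pop / 1e4) distinct cases per group.
    """
    config.validate()
    if len(regions) == 0:
        raise ConfigurationError("regions table is empty")
    rng = substream(config.seed, "cases")
    background, _ = split_vocabulary(config)
    gcodes = group_code_sets(config)
    glabels = group_labels(config)
    k_bg = len(background)

    mu_rd = _expected_rd_matrix(regions, config)
    t_arr = regions["travel_time_min"].to_numpy()
    pop_arr = regions["population"].to_numpy(dtype=float)
    rid_arr = regions["region_id"].to_numpy()
    h_target = loglogistic_value(t_arr, config.ddi_curve)
    mean_codes = _mean_codes_per_case(config.diag_count_p)

    # per-group code-set entropies: uniform within a group
    ln_gsize = np.log(np.array([max(len(g), 1) for g in gcodes], dtype=float))

    case_rows_region: List[np.ndarray] = []
    all_main: List[np.ndarray] = []
    all_addl: List[pd.Series] = []
    n_cases_per_region = rng.poisson(pop_arr * config.hospitalization_rate)

    # calibrate one background distribution per region
    q_cache: Dict[float, float] = {}
    next_case_id = 1
    records: List[pd.DataFrame] = []
    for r in range(len(regions)):
        n_cases = int(n_cases_per_region[r])
        if n_cases == 0:
            continue
        # expected injected-slot fraction and rare-disease mixture entropy
        mu_g = mu_rd[r]
        mu_tot = float(mu_g.sum())
        exp_cases = max(pop_arr[r] * config.hospitalization_rate, 1e-12)
        f = min(mu_tot / (exp_cases * mean_codes), 0.5)
        if mu_tot > 0:
            w = mu_g / mu_tot
            nz = w > 0
            h_rd = float(-(w[nz] * np.log(w[nz])).sum() + (w * ln_gsize).sum())
        else:
            h_rd, f = 0.0, 0.0
        h_bg = _background_entropy_target(float(h_target[r]), f, h_rd)
        if not 0 < h_bg < np.log(k_bg):
            raise ConfigurationError(
                f"region {rid_arr[r]}: adjusted background entropy {h_bg:.3f} "
                "infeasible; lower rare-disease rates or raise the curve"
            )
        key = round(h_bg, 6)
        if key not in q_cache:
            q_cache[key] = calibrate_code_distribution(h_bg, k_bg)
        cdf = np.cumsum(truncated_geometric_probs(q_cache[key], k_bg))
        cdf[-1] = 1.0

        d = np.minimum(rng.geometric(config.diag_count_p, n_cases), 51)
        n_slots = int(d.sum())
        idx = np.searchsorted(cdf, rng.random(n_slots), side="right")
        codes = background[idx].astype(object)

        starts = np.concatenate([[0], np.cumsum(d)])

        # rare-disease injection: distinct cases, one replaced slot each
        n_inj_g = rng.poisson(mu_g)
        total_inj = int(n_inj_g.sum())
        if total_inj > n_cases:  # cap; only plausible in tiny scenarios
            scale = n_cases / total_inj
            n_inj_g = np.floor(n_inj_g * scale).astype(int)
            total_inj = int(n_inj_g.sum())
        if total_inj > 0:
            chosen = rng.choice(n_cases, size=total_inj, replace=False)
            grp_of = np.repeat(np.arange(config.n_groups), n_inj_g)
            offs = rng.integers(0, d[chosen])
            slot_pos = starts[chosen] + offs
            for g in range(config.n_groups):
                sel = grp_of == g
                if not sel.any():
                    continue
                pool = gcodes[g]
                codes[slot_pos[sel]] = pool[rng.integers(0, len(pool), sel.sum())]

        case_ids = np.arange(next_case_id, next_case_id + n_cases, dtype=np.int64)
        next_case_id += n_cases
        main = codes[starts[:-1]]
        slot_case = np.repeat(np.arange(n_cases), d)
        first = np.zeros(n_slots, dtype=bool)
        first[starts[:-1]] = True
        addl = np.full(n_cases, "", dtype=object)
        rest = ~first
        if rest.any():
            joined = (
                pd.Series(codes[rest]).groupby(slot_case[rest]).agg(";".join)
            )
            addl[joined.index.to_numpy()] = joined.to_numpy()
        records.append(pd.DataFrame({
            "case_id": case_ids,
            "region_id": rid_arr[r],
            "main_dx": main.astype(str),
            "addl_dx": addl,
        }))

    if records:
        cases = pd.concat(records, ignore_index=True)
    else:
        cases = pd.DataFrame(columns=["case_id", "region_id", "main_dx", "addl_dx"])
    # years are uninformative here; assigned uniformly over the window
    cases.insert(2, "year", rng.integers(2009, 2013, len(cases)))
    cases["addl_dx"] = cases["addl_dx"].astype(str)

    truth = SyntheticTruth(
        h_target=pd.Series(h_target, index=rid_arr, name="h_target"),
        expected_rd=pd.DataFrame(mu_rd, index=rid_arr, columns=glabels),
        params=config.to_flat_dict(),
    )
    return cases, truth


def generate_mapping(config: ScenarioConfig) -> pd.DataFrame:
    """Synthetic ORPHAcode <-> ICD-10 cross-referencing table.

    Every flagged rare-disease code appears in at least one row; a
    configurable fraction carries a second ORPHAcode (the real
    nomenclature maps some ICD codes to several rare diseases). Each
    ICD code belongs to exactly one disease group.
    """
    config.validate()
    rng = substream(config.seed, "mapping")
    gcodes = group_code_sets(config)
    glabels = group_labels(config)
    rows = []
    orpha = 100001
    for g, codes in enumerate(gcodes):
        for code in codes:
            rows.append((f"ORPHA:{orpha}", code, glabels[g]))
            orpha += 1
            if rng.random() < config.mapping_multiplicity:
                rows.append((f"ORPHA:{orpha}", code, glabels[g]))
                orpha += 1
    return pd.DataFrame(rows, columns=["orpha_code", "icd10_code", "group_label"])


def generate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Generate a full scenario: regions, cases, mapping, truth."""
    regions = generate_regions(config)
    cases, truth = generate_cases(regions, config)
    mapping = generate_mapping(config)
    return SyntheticDataset(cases=cases, regions=regions, mapping=mapping, truth=truth)
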