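import numpy as np
import pandas as pd
import pytest

from conftest import make_cases, make_regions
from ddikit.codes import normalize_icd_code
from ddikit.errors import EmptyInputError, MalformedCodeError, SchemaError
from ddikit.rare import (
    flag_cases,
    group_region_counts,
    load_mapping,
    rd_proportion,
)


def mapping_df(rows):
    return pd.DataFrame(rows, columns=["orpha_code", "icd10_code", "group_label"])


def brute_force_flags(cases, mapping_table):
    """Row-scan reference implementation of case flagging."""
    out = []
    for _, case in cases.iterrows():
        codes = {normalize_icd_code(case["main_dx"])}
        if case["addl_dx"]:
            codes |= {normalize_icd_code(c) for c in case["addl_dx"].split(";")}
        matched, groups = set(), set()
        for _, row in mapping_table.iterrows():
            icd = normalize_icd_code(row["icd10_code"])
            if icd in codes:
                matched.add(icd)
                groups.add(row["group_label"])
        out.append((case["case_id"], bool(matched), frozenset(matched),
                    frozenset(groups)))
    return pd.DataFrame(out, columns=["case_id", "is_rd", "matched_codes", "groups"])


class TestLoadMapping:
    def test_normalizes_and_indexes(self):
        m = load_mapping(mapping_df([("O1", "E84.0", "g1"), ("O2", "E84.0", "g1")]))
        assert m.index == {"E840": frozenset({("O1", "g1"), ("O2", "g1")})}
        assert m.summary()["n_orpha_codes"] == 2

    def test_empty_table(self):
        m = load_mapping(mapping_df([]))
        assert m.summary() == {
            "n_rows": 0, "n_orpha_codes": 0, "n_icd_codes": 0, "n_groups": 0,
            "duplicate_rows_collapsed": 0,
        }

    def test_duplicate_rows_collapsed_and_counted(self):
        m = load_mapping(mapping_df([("O1", "E840", "g1")] * 3))
        assert len(m.table) == 1
        assert m.duplicates_collapsed == 2

    def test_missing_column_raises_schema_error(self):
        with pytest.raises(SchemaError):
            load_mapping(pd.DataFrame({"orpha_code": ["O1"]}))

    def test_bad_icd_code_reports_row_number(self):
        with pytest.raises(MalformedCodeError, match="row 1"):
            load_mapping(mapping_df([("O1", "E840", "g1"), ("O2", "???", "g1")]))


class TestFlagCases:
    def test_direct_lookup(self):
        cases = make_cases([(1, "r1", "E84.0", ["J18.9"])])
        m = load_mapping(mapping_df([("O1", "E840", "g1")]))
        f = flag_cases(cases, m)
        assert bool(f.loc[0, "is_rd"])
        assert f.loc[0, "matched_codes"] == frozenset({"E840"})

    def test_unmapped_case_not_flagged(self):
        cases = make_cases([(1, "r1", "J18.9", [])])
        m = load_mapping(mapping_df([("O1", "E840", "g1")]))
        f = flag_cases(cases, m)
        assert not bool(f.loc[0, "is_rd"])
        assert f.loc[0, "groups"] == frozenset()

    def test_one_code_mapping_two_groups(self):
        cases = make_cases([(1, "r1", "E84.0", [])])
        m = load_mapping(mapping_df([("O1", "E840", "g1"), ("O2", "E840", "g2")]))
        f = flag_cases(cases, m)
        assert f.loc[0, "groups"] == frozenset({"g1", "g2"})

    def test_prefix_match_mode(self):
        cases = make_cases([(1, "r1", "E84.99", [])])
        m = load_mapping(mapping_df([("O1", "E84", "g1")]))
        assert not bool(flag_cases(cases, m).loc[0, "is_rd"])
        assert bool(flag_cases(cases, m, prefix_match=True).loc[0, "is_rd"])

    def test_indexed_lookup_equals_brute_force_scan(self, rng):
        """1,000 random case/mapping instances, exact agreement."""
        vocab = [f"A{i:02d}" for i in range(30)] + [f"B{i:02d}" for i in range(10)]
        for trial in range(1000):
            r = np.random.default_rng(trial)
            n_cases = r.integers(1, 6)
            rows = []
            for cid in range(n_cases):
                k = int(r.integers(1, 5))
                codes = list(r.choice(vocab, k, replace=False))
                rows.append((cid, "r1", codes[0], codes[1:]))
            cases = make_cases(rows)
            n_map = int(r.integers(1, 8))
            mtab = mapping_df([
                (f"O{j}", r.choice(vocab), f"g{int(r.integers(1, 4))}")
                for j in range(n_map)
            ])
            got = flag_cases(cases, load_mapping(mtab)).sort_values("case_id")
            want = brute_force_flags(cases, mtab).sort_values("case_id")
            pd.testing.assert_frame_equal(
                got.reset_index(drop=True), want.reset_index(drop=True)
            )

    def test_adding_mapping_rows_never_unflags(self, rng):
        """Monotonicity: a superset mapping flags a superset of cases."""
        vocab = [f"C{i:02d}" for i in range(20)]
        rows = [(cid, "r1", vocab[cid], list(rng.choice(vocab, 2)))
                for cid in range(10)]
        cases = make_cases(rows)
        base = mapping_df([("O1", vocab[0], "g1"), ("O2", vocab[5], "g2")])
        bigger = pd.concat([base, mapping_df([("O3", vocab[7], "g3")])],
                           ignore_index=True)
        f1 = flag_cases(cases, load_mapping(base))
        f2 = flag_cases(cases, load_mapping(bigger))
        assert (f2["is_rd"] | ~f1["is_rd"]).all()
        for a, b in zip(f1["groups"], f2["groups"]):
            assert a <= b


class TestRdProportion:
    def test_worked_example_renders_27_percent(self):
        flags = pd.DataFrame({
            "case_id": np.arange(5_390_591),
            "is_rd": np.arange(5_390_591) < 1_464_753,
        })
        frac, pct = rd_proportion(flags)
        assert pct == 27
        assert frac == pytest.approx(1_464_753 / 5_390_591)

    def test_zero_and_full(self):
        flags = pd.DataFrame({"case_id": [1, 2], "is_rd": [False, False]})
        assert rd_proportion(flags)[1] == 0
        flags["is_rd"] = True
        assert rd_proportion(flags)[1] == 100

    def test_rounding_half_away_from_zero(self):
        flags = pd.DataFrame({"case_id": range(200), "is_rd": [True] * 51 + [False] * 149})
        assert rd_proportion(flags)[1] == 26  # 25.5% rounds up

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            rd_proportion(pd.DataFrame(columns=["case_id", "is_rd"]))


class TestGroupRegionCounts:
    def setup_method(self):
        self.regions = make_regions([("r1", 100, 5.0), ("r2", 200, 50.0)])
        self.mapping = load_mapping(mapping_df([
            ("O1", "E840", "g1"), ("O2", "E841", "g1"), ("O3", "Q870", "g2"),
        ]))

    def test_case_in_two_groups_counts_in_each(self):
        cases = make_cases([(1, "r1", "E840", ["Q870"])])
        flags = flag_cases(cases, self.mapping)
        out = group_region_counts(flags, cases, self.regions, self.mapping)
        got = out.set_index(["region_id", "group_label"])["observed"]
        assert got[("r1", "g1")] == 1 and got[("r1", "g2")] == 1

    def test_two_codes_one_group_counts_once(self):
        cases = make_cases([(1, "r1", "E840", ["E841"])])
        flags = flag_cases(cases, self.mapping)
        out = group_region_counts(flags, cases, self.regions, self.mapping)
        got = out.set_index(["region_id", "group_label"])["observed"]
        assert got[("r1", "g1")] == 1

    def test_zero_cells_materialized(self):
        cases = make_cases([(1, "r1", "E840", [])])
        flags = flag_cases(cases, self.mapping)
        out = group_region_counts(flags, cases, self.regions, self.mapping)
        assert len(out) == 4  # 2 regions x 2 groups
        got = out.set_index(["region_id", "group_label"])["observed"]
        assert got[("r2", "g1")] == 0 and got[("r2", "g2")] == 0

    def test_conservation_vs_flagged_cases(self, rng):
        """Sum over groups of distinct-case counts >= flagged cases,
        equality iff no case hits two groups."""
        vocab = ["E840", "E841", "Q870", "J189"]
        rows = [(cid, "r1", rng.choice(vocab), list(rng.choice(vocab, 2)))
                for cid in range(50)]
        cases = make_cases(rows)
        flags = flag_cases(cases, self.mapping)
        out = group_region_counts(flags, cases, self.regions, self.mapping)
        total = out["observed"].sum()
        n_flagged = int(flags["is_rd"].sum())
        multi = sum(len(g) > 1 for g in flags["groups"])
        assert total == n_flagged + sum(
            len(g) - 1 for g in flags["groups"] if len(g) > 1
        )
        assert total >= n_flagged
        if multi == 0:
            assert total == n_flagged
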